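"""Promoter-occupancy enrichment simulation for TF binding (hypergeometric).

Given a ChIP-seq peak set and a TSS table, promoters are built as windows
around each TSS, genes are flagged bound when their promoter shares at
least one base with a peak (0-based half-open intervals), and enrichment
of a marker-derived gene set against the bound universe is scored with an
upper-tail hypergeometric test.  The full simulation scores, per
transcription factor, the group-1 set, the group-2 set and 10 random
negative-control sets of 150 genes each (12 tests), Benjamini-Hochberg
corrected within that family.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "GenomicIntervalSet",
    "EnrichmentTest",
    "build_promoters",
    "overlap_flags",
    "hypergeom_upper",
    "run_simulation",
]

log = logging.getLogger(__name__)


@dataclass
class GenomicIntervalSet:
    """Named genomic intervals, 0-based half-open, sorted per chromosome."""

    table: pd.DataFrame  # columns chrom, start, end, name

    def __post_init__(self) -> None:
        t = self.table
        required = ["chrom", "start", "end", "name"]
        if list(t.columns[:4]) != required:
            t = t.rename(columns=dict(zip(t.columns[:4], required)))
        t = t[required].copy()
        if t[["start", "end"]].isna().any().any():
            raise ValueError("NaN coordinates")
        t["start"] = t["start"].astype(np.int64)
        t["end"] = t["end"].astype(np.int64)
        if (t["start"] >= t["end"]).any():
            bad = t[t["start"] >= t["end"]].index[0]
            raise ValueError(f"interval with start >= end at row {bad}")
        if t["name"].duplicated().any():
            raise ValueError("interval names must be unique within a set")
        self.table = t.sort_values(["chrom", "start", "end"],
                                   kind="stable").reset_index(drop=True)

    @classmethod
    def from_records(cls, rows) -> "GenomicIntervalSet":
        return cls(pd.DataFrame(rows,
                                columns=["chrom", "start", "end", "name"]))

    def __len__(self) -> int:
        return len(self.table)


@dataclass
class EnrichmentTest:
    """One hypergeometric enrichment record.

    N: universe size; K: universe genes with a bound promoter; n: gene-set
    size; k: bound genes in the set; p upper-tail; p_adj BH within the
    12-test family of one TF simulation.
    """

    set_name: str
    N: int
    K: int
    n: int
    k: int
    p: float
    p_adj: float = np.nan


def build_promoters(
    tss: pd.DataFrame,
    upstream_bp: int = 2000,
    downstream_bp: int = 2000,
    chrom_lengths: dict[str, int] | None = None,
) -> pd.DataFrame:
    """Promoter windows around each TSS, strand-aware.

    A + strand gene at position t maps to [max(0, t - upstream),
    t + downstream); - strand is mirrored.  Returns a frame indexed by gene
    with columns chrom, start, end, strand.
    """
    t = tss.copy()
    required = {"gene", "chrom", "pos", "strand"}
    if not required.issubset(t.columns):
        raise ValueError(f"TSS table needs columns {sorted(required)}")
    if (t["pos"] < 0).any():
        raise ValueError("TSS positions must be >= 0")
    if not t["strand"].isin(["+", "-"]).all():
        raise ValueError("strand must be '+' or '-'")
    dup = t[t.duplicated("gene", keep=False)]
    if len(dup):
        conflict = dup.groupby("gene").filter(
            lambda g: g[["chrom", "pos", "strand"]].drop_duplicates().shape[0]
            > 1
        )
        if len(conflict):
            raise ValueError(
                "conflicting TSS for genes: "
                f"{sorted(conflict['gene'].unique())}"
            )
        t = t.drop_duplicates("gene")

    plus = t["strand"] == "+"
    start = np.where(plus, t["pos"] - upstream_bp, t["pos"] - downstream_bp)
    end = np.where(plus, t["pos"] + downstream_bp, t["pos"] + upstream_bp)
    start = np.maximum(start, 0)
    if chrom_lengths:
        limit = t["chrom"].map(chrom_lengths)
        if limit.notna().all():
            end = np.minimum(end, limit.astype(np.int64))
    out = pd.DataFrame({
        "chrom": t["chrom"].to_numpy(),
        "start": start.astype(np.int64),
        "end": end.astype(np.int64),
        "strand": t["strand"].to_numpy(),
    }, index=pd.Index(t["gene"], name="gene"))
    return out


def overlap_flags(
    promoters: pd.DataFrame,
    peaks: GenomicIntervalSet,
    min_overlap_bp: int = 1,
) -> pd.Series:
    """Bound flag per gene: promoter shares >= min_overlap_bp with a peak.

    Half-open semantics: [0, 10) and [10, 20) do not overlap.  Genes on
    chromosomes absent from the peak set are unbound (logged).
    """
    flags = pd.Series(False, index=promoters.index)
    peaks_by_chrom = dict(tuple(peaks.table.groupby("chrom", sort=False)))
    missing = set(promoters["chrom"]) - set(peaks_by_chrom)
    if missing:
        log.info("no peaks on chromosomes %s: genes there unbound",
                 sorted(missing))
    for chrom, grp in promoters.groupby("chrom", sort=False):
        if chrom not in peaks_by_chrom:
            continue
        pk = peaks_by_chrom[chrom]
        starts = pk["start"].to_numpy()
        ends = pk["end"].to_numpy()
        # sorted sweep: for each promoter, overlap bp with best candidate
        # peaks; cumulative max of ends enables a single searchsorted pass
        cum_end = np.maximum.accumulate(ends)
        for gene, row in grp.iterrows():
            s, e = row["start"], row["end"]
            # peaks starting before promoter end are overlap candidates
            hi = np.searchsorted(starts, e - min_overlap_bp, side="right")
            if hi == 0:
                continue
            # among them, any extending past promoter start by the margin?
            if cum_end[hi - 1] >= s + min_overlap_bp:
                ov = np.minimum(ends[:hi], e) - np.maximum(starts[:hi], s)
                if ov.max() >= min_overlap_bp:
                    flags.loc[gene] = True
    return flags


def hypergeom_upper(k: int, n: int, K: int, N: int) -> float:
    """Upper-tail hypergeometric p: P(X >= k) for X ~ Hypergeom(N, K, n)."""
    if not (0 <= k <= min(n, K) and 0 <= n <= N and 0 <= K <= N):
        raise ValueError(
            f"impossible counts: k={k}, n={n}, K={K}, N={N}"
        )
    if k == 0:
        return 1.0
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def run_simulation(
    markers: pd.DataFrame,
    universe: list[str] | np.ndarray,
    peaks_per_tf: dict[str, GenomicIntervalSet],
    tss: pd.DataFrame,
    n_random: int = 10,
    random_size: int = 150,
    seed: int = 0,
    upstream_bp: int = 2000,
    downstream_bp: int = 2000,
    group_names: tuple[str, str] = ("FHF", "SHF"),
    ortholog_map: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Score marker-set promoter occupancy per TF against random controls.

    Group-1 genes are the markers with avg_log2FC > 0, group-2 those with
    avg_log2FC < 0, both restricted to the universe (genes with promoter
    coordinates).  ``n_random`` negative-control sets of ``random_size``
    genes are drawn without replacement from the universe minus both marker
    sets.  For each TF, the 12 tests are BH-corrected as one family.
    ``ortholog_map`` optionally translates marker gene ids to the TSS
    table's namespace before everything else.
    """
    promoters = build_promoters(tss, upstream_bp, downstream_bp)
    universe = [g for g in universe if g in promoters.index]
    uset = set(universe)
    N = len(universe)
    if N == 0:
        raise ValueError("empty universe: no genes with promoters")

    def to_universe(genes) -> list[str]:
        if ortholog_map is not None:
            genes = [ortholog_map.get(g) for g in genes]
        return sorted({g for g in genes if g in uset})

    set1 = to_universe(markers.loc[markers["avg_log2FC"] > 0, "gene"])
    set2 = to_universe(markers.loc[markers["avg_log2FC"] < 0, "gene"])
    gene_sets: dict[str, list[str]] = {}
    for name, s in zip(group_names, (set1, set2)):
        if not s:
            log.warning("marker set %s empty in universe: skipped", name)
        else:
            gene_sets[name] = s

    pool = sorted(uset - set(set1) - set(set2))
    if len(pool) < random_size:
        raise ValueError(
            f"universe minus markers ({len(pool)}) smaller than "
            f"requested random draw ({random_size})"
        )
    rng = np.random.default_rng(seed)
    for i in range(n_random):
        gene_sets[f"random_{i + 1:02d}"] = list(
            rng.choice(pool, size=random_size, replace=False)
        )

    rows = []
    for tf, peaks in peaks_per_tf.items():
        bound = overlap_flags(promoters.loc[universe], peaks)
        K = int(bound.sum())
        tests = []
        for name, genes in gene_sets.items():
            k = int(bound.loc[genes].sum())
            tests.append(EnrichmentTest(
                set_name=name, N=N, K=K, n=len(genes), k=k,
                p=hypergeom_upper(k, len(genes), K, N),
            ))
        p_adj = multipletests([t.p for t in tests], method="fdr_bh")[1]
        for t, pa in zip(tests, p_adj):
            t.p_adj = float(pa)
            rows.append({"tf": tf, "set_name": t.set_name, "N": t.N,
                         "K": t.K, "n": t.n, "k": t.k, "p": t.p,
                         "p_adj": t.p_adj})
    return pd.DataFrame(rows)
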