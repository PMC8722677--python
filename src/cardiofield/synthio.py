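"""Seeded synthetic-data generators for all six input modalities.

Each generator takes a :class:`SimSpec` and returns the modality's native
in-memory container together with a :class:`GroundTruth` record sufficient to
score the downstream analysis stage.  All randomness flows through a single
``numpy.random.Generator`` seeded from the spec, so identical specs yield
byte-identical output.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Any

import numpy as np
import pandas as pd

from .afm_hertz import ForceCurve, hertz_force_coefficient
from .occupancy_sim import GenomicIntervalSet
from .optical_ap import VoltageTraceSet
from .qpm_motion import PhaseStack, DEFAULT_ALPHA_UM3_PER_PG
from .respirometry import OCRTrace
from .scexpr import CountMatrix

__all__ = [
    "SimSpec",
    "GroundTruth",
    "InvalidParameterError",
    "gen_ap_traces",
    "gen_force_curves",
    "gen_phase_stack",
    "gen_counts",
    "gen_genome_fixture",
    "gen_ocr_trace",
]

MODALITIES = ("ap", "afm", "qpm", "counts", "genome", "ocr")


class InvalidParameterError(ValueError):
    """A generator parameter violates its contract."""


@dataclass(frozen=True)
class SimSpec:
    """Specification of one synthetic dataset.

    Parameters
    ----------
    modality : str
        One of ``ap, afm, qpm, counts, genome, ocr``.
    seed : int
        Seed for the generator's private RNG.
    params : dict
        Modality-specific parameters; unset keys fall back to defaults.
    n_replicates : int
        Number of independent replicates (sites, curves, wells, ...).
    """

    modality: str
    seed: int
    params: dict[str, Any] = field(default_factory=dict)
    n_replicates: int = 1

    def __post_init__(self) -> None:
        if self.modality not in MODALITIES:
            raise InvalidParameterError(f"unknown modality {self.modality!r}")
        if self.n_replicates < 1:
            raise InvalidParameterError("n_replicates must be positive")
        for key, val in self.params.items():
            if isinstance(val, (int, float)) and not np.isfinite(val):
                raise InvalidParameterError(f"non-finite parameter {key!r}")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)

    def get(self, key: str, default: Any) -> Any:
        return self.params.get(key, default)


@dataclass
class GroundTruth:
    """True parameter values carried alongside a generated dataset."""

    modality: str
    values: dict[str, Any] = field(default_factory=dict)

    def __getitem__(self, key: str) -> Any:
        return self.values[key]

    def __contains__(self, key: str) -> bool:
        return key in self.values


# --------------------------------------------------------------------------
# Optical-mapping action-potential traces
# --------------------------------------------------------------------------

def ap_template(
    t_ms: np.ndarray,
    amplitude: float,
    apd30_ms: float,
    apd80_ms: float,
    upstroke_ms: float,
) -> np.ndarray:
    """Piecewise-linear action-potential waveform, one cycle, t=0 at activation.

    The repolarisation is pinned so the trace first falls below 70% of the
    amplitude exactly at ``apd30_ms`` and below 20% exactly at ``apd80_ms``;
    the true APD30/APD80 are therefore exact by construction.
    """
    tail_ms = 0.25 * (apd80_ms - apd30_ms)
    knots_t = np.array(
        [0.0, upstroke_ms, apd30_ms, apd80_ms, apd80_ms + tail_ms]
    )
    knots_v = amplitude * np.array([0.0, 1.0, 0.7, 0.2, 0.0])
    return np.interp(t_ms, knots_t, knots_v, left=0.0, right=0.0)


def gen_ap_traces(spec: SimSpec) -> tuple[VoltageTraceSet, GroundTruth]:
    """Generate voltage-dye fluorescence trains with known AP durations."""
    p = spec.get
    frame_rate = float(p("frame_rate_hz", 500.0))
    n_sites = int(p("n_sites", spec.n_replicates))
    n_beats = int(p("n_beats", 5))
    amplitude = float(p("amplitude", 1.0))
    apd30 = float(p("apd30_ms", 200.0))
    apd80 = float(p("apd80_ms", 350.0))
    cl = float(p("cycle_length_ms", 800.0))
    upstroke = float(p("upstroke_ms", 10.0))
    noise_sd = float(p("noise_sd", 0.0))
    polarity = p("polarity", "up")
    drift = float(p("baseline_drift", 0.0))  # a.u. per second

    if apd30 >= apd80:
        raise InvalidParameterError("apd30_ms must be < apd80_ms")
    if cl <= apd80:
        raise InvalidParameterError("cycle_length_ms must exceed apd80_ms")
    if upstroke >= apd30:
        raise InvalidParameterError("upstroke_ms must be < apd30_ms")
    if polarity not in ("up", "down"):
        raise InvalidParameterError("polarity must be 'up' or 'down'")

    dt = 1000.0 / frame_rate
    n_samples = int(round(n_beats * cl / dt))
    t = np.arange(n_samples) * dt
    phase = np.mod(t, cl)  # activation of beat j at t = j*cl exactly
    template = ap_template(phase, amplitude, apd30, apd80, upstroke)

    rng = spec.rng()
    traces = {}
    for i in range(n_sites):
        x = template + drift * (t / 1000.0)
        if noise_sd > 0:
            x = x + rng.normal(0.0, noise_sd, size=n_samples)
        if polarity == "down":
            x = -x
        traces[f"site{i:03d}"] = x

    tset = VoltageTraceSet(
        frame_rate_hz=frame_rate,
        samples=traces,
        group_label=str(p("group_label", "synthetic")),
    )
    gt = GroundTruth(
        "ap",
        {
            "true_apd30_ms": {s: apd30 for s in traces},
            "true_apd80_ms": {s: apd80 for s in traces},
            "true_cycle_length_ms": {s: cl for s in traces},
            "true_amplitude": amplitude,
            "activation_times_ms": np.arange(n_beats) * cl,
        },
    )
    return tset, gt


# --------------------------------------------------------------------------
# AFM approach curves
# --------------------------------------------------------------------------

def gen_force_curves(spec: SimSpec) -> tuple[list[ForceCurve], GroundTruth]:
    """Synthesize approach curves obeying the spherical-tip Hertz relation.

    Beyond the contact point the force follows
    ``F = (4*sqrt(R)/3) * E/(1-nu^2) * delta^(3/2)``; the piezo position is
    ``z = contact_z + d + delta`` with ``d = F/k`` the cantilever deflection.
    """
    p = spec.get
    E_pa = float(p("E_pa", 5000.0))
    R_um = float(p("R_um", 5.0))
    k = float(p("k_nN_per_nm", 0.286))
    nu = float(p("nu", 0.5))
    contact_z = float(p("contact_z_um", 2.0))
    z_step = float(p("z_step", 0.01))
    max_force = float(p("max_force_nN", 3.0))
    noise_sd = float(p("noise_sd", 0.0))  # nN, on force/deflection
    pre_contact_um = float(p("pre_contact_um", 1.0))

    if E_pa <= 0:
        raise InvalidParameterError("E_pa must be positive")
    if R_um <= 0:
        raise InvalidParameterError("R_um must be positive")
    if not 0.0 <= nu <= 0.5:
        raise InvalidParameterError("nu must lie in [0, 0.5]")

    k_um = k * 1000.0  # nN per µm of deflection
    C = hertz_force_coefficient(E_pa, R_um, nu)  # nN / µm^(3/2)
    delta_max = (max_force / C) ** (2.0 / 3.0)
    z_max = contact_z + delta_max + max_force / k_um
    z = np.arange(contact_z - pre_contact_um, z_max + 1e-12, z_step)

    # invert z - contact = delta + C*delta^(3/2)/k for delta, per sample
    def delta_of(dz: float) -> float:
        if dz <= 0:
            return 0.0
        lo, hi = 0.0, dz
        for _ in range(80):  # bisection; monotone increasing in delta
            mid = 0.5 * (lo + hi)
            if mid + C * mid ** 1.5 / k_um < dz:
                lo = mid
            else:
                hi = mid
        return 0.5 * (lo + hi)

    delta = np.array([delta_of(dz) for dz in z - contact_z])
    force = C * delta ** 1.5

    rng = spec.rng()
    curves = []
    for _ in range(spec.n_replicates):
        f = force.copy()
        if noise_sd > 0:
            f = f + rng.normal(0.0, noise_sd, size=f.size)
        curves.append(
            ForceCurve(z=z.copy(), d=f / k_um, k=k, R=R_um, nu=nu,
                       direction="approach")
        )
    gt = GroundTruth(
        "afm",
        {
            "true_E_pa": [E_pa] * spec.n_replicates,
            "true_contact_z_um": [contact_z] * spec.n_replicates,
            "delta_um": delta,
            "force_nN": force,
        },
    )
    return curves, gt


# --------------------------------------------------------------------------
# Quantitative-phase stacks
# --------------------------------------------------------------------------

def _render_blob(
    shape: tuple[int, int],
    center: tuple[float, float],
    sigma_px: float,
    mass_pg: float,
    radius_px: float,
) -> np.ndarray:
    """Truncated-Gaussian dry-mass distribution (pg per pixel)."""
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
    r2 = (yy - center[0]) ** 2 + (xx - center[1]) ** 2
    img = np.exp(-0.5 * r2 / sigma_px**2)
    img[r2 > radius_px**2] = 0.0
    s = img.sum()
    if s <= 0:
        raise InvalidParameterError("blob rendered empty; check geometry")
    return img * (mass_pg / s)


def gen_phase_stack(spec: SimSpec) -> tuple[PhaseStack, GroundTruth]:
    """Render drifting / pulsating dry-mass blobs as a phase-shift stack.

    Each cell is a compact truncated-Gaussian mass distribution converted to
    optical path difference through the specific refractive increment.
    Pulsating cells alternate between two two-lobe states that exchange a
    fraction of the cell mass; the ground-truth percent mass fluctuation is
    computed directly from the two rendered states (pixel-sum oracle).
    """
    p = spec.get
    n_frames = int(p("n_frames", 10))
    shape = tuple(p("shape", (128, 128)))
    px_um = float(p("pixel_size_um", 0.5))
    interval = float(p("frame_interval_min", 10.0))
    alpha = float(p("alpha", DEFAULT_ALPHA_UM3_PER_PG))
    noise = float(p("background_noise", 0.0))  # OPD nm, additive Gaussian
    cells = p("cells", [{"center": (64.0, 64.0), "mass_pg": 300.0,
                         "motion": "static"}])
    # wide sigma relative to the truncation radius keeps every in-support
    # pixel well above background, so thresholding recovers the full support
    sigma_px = float(p("sigma_px", 25.0))
    radius_px = float(p("radius_px", 14.0))
    lobe_offset_px = float(p("lobe_offset_px", 2.0))

    # reject overlapping cells: fixtures must segment unambiguously
    margin = 2 * radius_px + abs(lobe_offset_px) + 4
    centers = [np.asarray(c["center"], float) for c in cells]
    for i in range(len(centers)):
        for j in range(i + 1, len(centers)):
            drift_i = np.asarray(cells[i].get("drift_px", (0, 0)), float)
            drift_j = np.asarray(cells[j].get("drift_px", (0, 0)), float)
            end_i = centers[i] + drift_i * (n_frames - 1)
            end_j = centers[j] + drift_j * (n_frames - 1)
            dmin = min(np.linalg.norm(centers[i] - centers[j]),
                       np.linalg.norm(end_i - end_j))
            if dmin < margin:
                raise InvalidParameterError(
                    f"cells {i} and {j} closer than the {margin:.0f}px margin"
                )

    rng = spec.rng()
    mass_frames = np.zeros((n_frames,) + shape)
    gt_centroids: list[list[tuple[float, float]]] = []
    gt_masses: list[float] = []
    gt_fluct: list[float] = []

    for ci, cell in enumerate(cells):
        c0 = np.asarray(cell["center"], float)
        mass = float(cell.get("mass_pg", 300.0))
        motion = cell.get("motion", "static")
        per_frame = []
        if motion == "pulsate":
            f = float(cell.get("pulsate_fraction", 0.1))
            off = np.array([0.0, lobe_offset_px])
            states = []
            for hi_first in (True, False):
                m1 = mass * (0.5 + (f / 2 if hi_first else -f / 2))
                m2 = mass - m1
                img = _render_blob(shape, tuple(c0 - off), sigma_px, m1,
                                   radius_px)
                img += _render_blob(shape, tuple(c0 + off), sigma_px, m2,
                                    radius_px)
                states.append(img)
            gt_fluct.append(100.0 * np.abs(states[1] - states[0]).sum() / mass)
            for t in range(n_frames):
                img = states[t % 2]
                mass_frames[t] += img
                com = _center_of_mass(img)
                per_frame.append((com[0] * px_um, com[1] * px_um))
        else:
            v = np.asarray(cell.get("drift_px", (0.0, 0.0)), float)
            if motion == "static":
                v = np.zeros(2)
            for t in range(n_frames):
                c = c0 + v * t
                img = _render_blob(shape, tuple(c), sigma_px, mass, radius_px)
                mass_frames[t] += img
                com = _center_of_mass(img)
                per_frame.append((com[0] * px_um, com[1] * px_um))
            gt_fluct.append(0.0)
        gt_centroids.append(per_frame)
        gt_masses.append(mass)

    # mass [pg] -> OPD [nm]: opd_nm = 1000 * alpha * mass / pixel_area
    opd = 1000.0 * alpha * mass_frames / (px_um**2)
    if noise > 0:
        opd = opd + rng.normal(0.0, noise, size=opd.shape)

    stack = PhaseStack(frames=opd, pixel_size_um=px_um,
                       frame_interval_min=interval)
    gt = GroundTruth(
        "qpm",
        {
            "true_centroids_um": gt_centroids,
            "true_mass_pg": gt_masses,
            "true_pct_mass_fluctuation": gt_fluct,
            "true_drift_um_per_frame": [
                float(np.linalg.norm(np.asarray(c.get("drift_px", (0, 0)),
                                                float)) * px_um)
                if c.get("motion") == "drift" else 0.0
                for c in cells
            ],
            "alpha": alpha,
        },
    )
    return stack, gt


def _center_of_mass(img: np.ndarray) -> tuple[float, float]:
    total = img.sum()
    yy, xx = np.mgrid[0 : img.shape[0], 0 : img.shape[1]]
    return float((yy * img).sum() / total), float((xx * img).sum() / total)


# --------------------------------------------------------------------------
# UMI count matrices
# --------------------------------------------------------------------------

def gen_counts(spec: SimSpec) -> tuple[CountMatrix, GroundTruth]:
    """Two-group UMI count matrix with programmed markers and QC casualties.

    Baseline expression is gamma-Poisson (negative binomial); markers carry a
    group-specific fold change and optionally a forced detection fraction via
    a Bernoulli expression gate.  Engineered QC failures: cells restricted to
    <200 detected genes, cells downsampled below the UMI floor, and genes
    expressed in fewer than 3 cells.
    """
    p = spec.get
    n_genes = int(p("n_genes", 2000))
    n_cells = int(p("n_cells_per_group", 100))
    lib_size = float(p("library_size", 8000.0))
    dispersion = float(p("dispersion", 0.3))
    markers = p("markers", [])  # dicts: gene index, group, log2fc, pct per grp
    n_lowgene = int(p("n_lowgene_cells", 0))
    n_lowumi = int(p("n_lowumi_cells", 0))
    n_raregenes = int(p("n_rare_genes", 0))
    group_names = tuple(p("group_names", ("FHF", "SHF")))

    for m in markers:
        if float(m.get("log2fc", 1.0)) == 0.0 and "pct" not in m:
            raise InvalidParameterError(
                f"declared marker {m.get('gene')} has fold change 1"
            )

    rng = spec.rng()
    base_mu = rng.lognormal(mean=0.0, sigma=1.0, size=n_genes)
    base_mu = base_mu / base_mu.sum()  # relative expression

    genes = np.array([f"G{i:05d}" for i in range(n_genes)])
    cells, labels = [], []
    for g, name in enumerate(group_names):
        cells += [f"{name}_c{i:04d}" for i in range(n_cells)]
        labels += [name] * n_cells
    cells = np.array(cells)
    labels = np.array(labels)

    mu = np.tile(base_mu[:, None], (1, 2 * n_cells)).astype(float)
    gate = np.ones_like(mu)
    marker_by_group: dict[str, list[str]] = {g: [] for g in group_names}
    for m in markers:
        gi = int(m["gene"])
        grp = int(m.get("group", 0))
        l2fc = float(m.get("log2fc", 2.0))
        cols_a = slice(0, n_cells) if grp == 0 else slice(n_cells, 2 * n_cells)
        mu[gi, cols_a] *= 2.0**l2fc
        if "pct" in m:  # (pct in marker group, pct in other group)
            pct_in, pct_out = m["pct"]
            ga = rng.random(n_cells) < pct_in
            gb = rng.random(n_cells) < pct_out
            if grp == 0:
                gate[gi, :n_cells] = ga
                gate[gi, n_cells:] = gb
            else:
                gate[gi, n_cells:] = ga
                gate[gi, :n_cells] = gb
        marker_by_group[group_names[grp]].append(genes[gi])

    lam = mu * gate
    lam = lam / np.maximum(lam.sum(axis=0, keepdims=True), 1e-300) * lib_size
    if dispersion > 0:
        shape_param = 1.0 / dispersion
        lam = lam * rng.gamma(shape_param, 1.0 / shape_param, size=lam.shape)
    counts = rng.poisson(lam).astype(np.int64)

    # engineered QC casualties occupy the trailing cells of group 2
    n_total = 2 * n_cells
    fail_cells: list[str] = []
    idx = n_total - 1
    for _ in range(n_lowgene):
        keep = rng.choice(n_genes, size=150, replace=False)
        col = np.zeros(n_genes, dtype=np.int64)
        col[keep] = rng.poisson(30.0, size=150) + 1  # plenty of UMIs, few genes
        counts[:, idx] = col
        fail_cells.append(cells[idx])
        idx -= 1
    for _ in range(n_lowumi):
        keep = rng.choice(n_genes, size=400, replace=False)
        col = np.zeros(n_genes, dtype=np.int64)
        col[keep] = rng.poisson(3.0, size=400) + 1  # >=400 genes, ~1600 UMIs
        counts[:, idx] = col
        fail_cells.append(cells[idx])
        idx -= 1

    fail_genes: list[str] = []
    marker_idx = {int(m["gene"]) for m in markers}
    gi = n_genes - 1
    for _ in range(n_raregenes):
        while gi in marker_idx:
            gi -= 1
        counts[gi, :] = 0
        counts[gi, rng.choice(idx + 1, size=2, replace=False)] = 1
        fail_genes.append(genes[gi])
        gi -= 1

    mat = CountMatrix(genes=genes, cells=cells, counts=counts,
                      group_labels=labels)
    gt = GroundTruth(
        "counts",
        {
            "true_marker_genes": marker_by_group,
            "qc_fail_cells": fail_cells,
            "qc_fail_genes": fail_genes,
        },
    )
    return mat, gt


# --------------------------------------------------------------------------
# Genomic fixture: TSS table + promoter-biased peaks
# --------------------------------------------------------------------------

def gen_genome_fixture(
    spec: SimSpec,
) -> tuple[GenomicIntervalSet, pd.DataFrame, GroundTruth]:
    """Synthetic TSS table and a peak set with programmed promoter bias.

    Promoters of genes in ``enriched_genes`` receive an overlapping peak with
    probability ``p_in``, all others with ``p_out``.  Genes are spaced widely
    enough that a peak can only overlap its own gene's promoter.
    """
    p = spec.get
    n_genes = int(p("n_genes", 2000))
    chrom_lengths = dict(p("chrom_lengths", {"chr1": 50_000_000}))
    upstream = int(p("promoter_upstream_bp", 2000))
    downstream = int(p("promoter_downstream_bp", 2000))
    enriched = list(p("enriched_genes", []))
    p_in = float(p("p_in", 0.5))
    p_out = float(p("p_out", 0.5))
    peak_width = int(p("peak_width_bp", 400))
    require_enrichment = bool(p("require_enrichment", False))

    if require_enrichment and p_in <= p_out:
        raise InvalidParameterError(
            "enrichment requested but p_in <= p_out"
        )
    if not (0 <= p_in <= 1 and 0 <= p_out <= 1):
        raise InvalidParameterError("p_in/p_out must be probabilities")

    spacing = 2 * (upstream + downstream) + 2 * peak_width + 1000
    chroms = list(chrom_lengths)
    per_chrom = int(np.ceil(n_genes / len(chroms)))
    for c in chroms:
        if per_chrom * spacing + spacing > chrom_lengths[c]:
            raise InvalidParameterError(
                f"chromosome {c} too short for {per_chrom} spaced genes"
            )

    rng = spec.rng()
    rows = []
    gi = 0
    for c in chroms:
        for j in range(per_chrom):
            if gi >= n_genes:
                break
            pos = spacing * (j + 1)
            strand = "+" if rng.random() < 0.5 else "-"
            rows.append((f"G{gi:05d}", c, pos, strand))
            gi += 1
    tss = pd.DataFrame(rows, columns=["gene", "chrom", "pos", "strand"])

    enriched_set = set(enriched)
    peaks_rows = []
    bound: dict[str, bool] = {}
    for _, r in tss.iterrows():
        prob = p_in if r.gene in enriched_set else p_out
        hit = bool(rng.random() < prob)
        bound[r.gene] = hit
        if hit:
            # peak centered inside the promoter window, guaranteed overlap
            if r.strand == "+":
                lo = max(0, r.pos - upstream)
                hi = r.pos + downstream
            else:
                lo = max(0, r.pos - downstream)
                hi = r.pos + upstream
            jitter = int(rng.integers(0, max(1, (hi - lo) - peak_width)))
            start = lo + jitter
            peaks_rows.append((r.chrom, start, start + peak_width,
                               f"peak_{r.gene}"))
    peaks = GenomicIntervalSet.from_records(peaks_rows)
    gt = GroundTruth(
        "genome",
        {"true_bound": bound, "true_enriched_set": sorted(enriched_set)},
    )
    return peaks, tss, gt


# --------------------------------------------------------------------------
# OCR stress-test traces
# --------------------------------------------------------------------------

def gen_ocr_trace(spec: SimSpec) -> tuple[list[OCRTrace], GroundTruth]:
    """Four-phase mitochondrial stress-test OCR traces with known plateaus."""
    p = spec.get
    basal_raw = float(p("basal_raw", 100.0))
    post_oligo = float(p("post_oligo", 40.0))
    post_fccp = float(p("post_fccp", 150.0))
    post_aa = float(p("post_antimycin", 10.0))
    n_per_phase = int(p("measurements_per_phase", 3))
    noise_sd = float(p("noise_sd", 0.0))
    cell_count = int(p("cell_count", 20000))
    step_min = float(p("measurement_interval_min", 6.5))
    group = str(p("group_label", "synthetic"))

    if post_aa > basal_raw:
        warnings.warn(
            "post-antimycin OCR exceeds basal OCR (physiologically odd)",
            stacklevel=2,
        )

    plateaus = [basal_raw, post_oligo, post_fccp, post_aa]
    n_pts = 4 * n_per_phase
    time = np.arange(n_pts) * step_min
    levels = np.repeat(plateaus, n_per_phase)
    inj_times = [
        (label, float(time[(i + 1) * n_per_phase] - step_min / 2))
        for i, label in enumerate(["oligomycin", "FCCP", "antimycinA"])
    ]

    rng = spec.rng()
    traces = []
    for _ in range(spec.n_replicates):
        ocr = levels + (rng.normal(0, noise_sd, n_pts) if noise_sd > 0 else 0)
        traces.append(
            OCRTrace(time_min=time.copy(), ocr=np.asarray(ocr, float),
                     ecar=None, injections=list(inj_times),
                     cell_count=cell_count, group_label=group)
        )
    gt = GroundTruth(
        "ocr",
        {
            "true_plateaus": plateaus,
            "true_non_mito": post_aa,
            "true_basal": basal_raw - post_aa,
            "true_atp_linked_ocr": basal_raw - post_oligo,
            "true_proton_leak": post_oligo - post_aa,
            "true_maximal": post_fccp - post_aa,
            "true_spare_capacity": post_fccp - basal_raw,
        },
    )
    return traces, gt
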