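"""Shared format readers and writers.

Tables travel as UTF-8 CSV/TSV with header; BED is 0-based half-open;
phase stacks as multi-page TIFF with a JSON sidecar; count matrices as
Matrix-Market triplets with gene/barcode TSVs (10x style) or dense CSV.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io as sio
import scipy.sparse as sp
import tifffile

from .occupancy_sim import GenomicIntervalSet
from .optical_ap import VoltageTraceSet
from .qpm_motion import PhaseStack
from .respirometry import OCRTrace
from .scexpr import CountMatrix

__all__ = [
    "ParseError",
    "read_table", "write_table",
    "read_bed", "write_bed",
    "read_stack", "write_stack",
    "read_mtx",
    "read_voltage_csv", "write_voltage_csv",
    "read_force_curve", "write_force_curve",
    "read_ocr", "write_ocr",
]


class ParseError(ValueError):
    """A file failed to parse under its declared dialect."""


def read_table(path: str | Path, sep: str | None = None) -> pd.DataFrame:
    path = Path(path)
    if sep is None:
        sep = "\t" if path.suffix in (".tsv", ".txt") else ","
    try:
        return pd.read_csv(path, sep=sep)
    except Exception as exc:  # surfaced with filename context
        raise ParseError(f"{path}: {exc}") from exc


def write_table(df: pd.DataFrame, path: str | Path,
                sep: str | None = None) -> None:
    path = Path(path)
    if sep is None:
        sep = "\t" if path.suffix in (".tsv", ".txt") else ","
    df.to_csv(path, sep=sep, index=False)


def read_bed(path: str | Path) -> GenomicIntervalSet:
    """BED3+ / narrowPeak; extra columns ignored, names auto-filled."""
    rows = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(f"{path}:{ln}: fewer than 3 BED fields")
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ParseError(f"{path}:{ln}: non-integer coordinates") \
                    from exc
            if start >= end:
                raise ParseError(f"{path}:{ln}: start >= end")
            name = fields[3] if len(fields) > 3 and fields[3] not in ("", ".")\
                else f"interval_{ln}"
            rows.append((fields[0], start, end, name))
    return GenomicIntervalSet.from_records(rows)


def write_bed(intervals: GenomicIntervalSet, path: str | Path) -> None:
    intervals.table.to_csv(path, sep="\t", header=False, index=False)


def read_stack(path: str | Path, sidecar: str | Path | None = None
               ) -> PhaseStack:
    """Multi-page TIFF plus JSON sidecar (pixel size, frame interval)."""
    path = Path(path)
    sidecar = Path(sidecar) if sidecar else path.with_suffix(".json")
    frames = tifffile.imread(path)
    if frames.ndim == 2:
        frames = frames[None]
    meta = json.loads(Path(sidecar).read_text())
    return PhaseStack(
        frames=np.asarray(frames, dtype=float),
        pixel_size_um=float(meta["pixel_size_um"]),
        frame_interval_min=float(meta["frame_interval_min"]),
        wavelength_nm=float(meta.get("wavelength_nm", 660.0)),
    )


def write_stack(stack: PhaseStack, path: str | Path,
                sidecar: str | Path | None = None) -> None:
    path = Path(path)
    sidecar = Path(sidecar) if sidecar else path.with_suffix(".json")
    tifffile.imwrite(path, stack.frames.astype(np.float32),
                     photometric="minisblack")
    sidecar.write_text(json.dumps({
        "pixel_size_um": stack.pixel_size_um,
        "frame_interval_min": stack.frame_interval_min,
        "wavelength_nm": stack.wavelength_nm,
    }, sort_keys=True))


def read_mtx(
    mtx_path: str | Path,
    genes_path: str | Path,
    barcodes_path: str | Path,
    labels_path: str | Path | None = None,
) -> CountMatrix:
    """10x-style triplet: matrix.mtx + genes.tsv + barcodes.tsv.

    ``labels_path`` optionally maps barcodes to group labels (TSV:
    barcode, label).
    """
    counts = sio.mmread(str(mtx_path))
    if sp.issparse(counts):
        counts = counts.tocsr()
    genes = pd.read_csv(genes_path, sep="\t", header=None)[0].to_numpy()
    cells = pd.read_csv(barcodes_path, sep="\t", header=None)[0].to_numpy()
    labels = None
    if labels_path is not None:
        lab = pd.read_csv(labels_path, sep="\t", header=None,
                          names=["barcode", "label"])
        labels = lab.set_index("barcode").loc[cells, "label"].to_numpy()
    return CountMatrix(genes=genes, cells=cells, counts=counts,
                       group_labels=labels)


def read_voltage_csv(path: str | Path, frame_rate_hz: float | None = None,
                     group_label: str = "") -> VoltageTraceSet:
    """Wide CSV: a ``time_ms`` column plus one column per site."""
    df = read_table(path)
    if "time_ms" not in df.columns:
        raise ParseError(f"{path}: missing time_ms column")
    if frame_rate_hz is None:
        dt = np.diff(df["time_ms"].to_numpy())
        if dt.size == 0 or not np.allclose(dt, dt[0]):
            raise ParseError(f"{path}: irregular sampling; pass frame rate")
        frame_rate_hz = 1000.0 / float(dt[0])
    sites = {c: df[c].to_numpy(dtype=float) for c in df.columns
             if c != "time_ms"}
    return VoltageTraceSet(frame_rate_hz=frame_rate_hz, samples=sites,
                           group_label=group_label)


def write_voltage_csv(traces: VoltageTraceSet, path: str | Path) -> None:
    n = len(next(iter(traces.samples.values())))
    df = pd.DataFrame({"time_ms": np.arange(n) * traces.dt_ms})
    for site, vals in traces.samples.items():
        df[site] = vals
    write_table(df, path)


def read_force_curve(csv_path: str | Path, sidecar: str | Path):
    from .afm_hertz import ForceCurve
    df = read_table(csv_path)
    meta = json.loads(Path(sidecar).read_text())
    return ForceCurve(
        z=df["z_um"].to_numpy(), d=df["d_um"].to_numpy(),
        k=float(meta["k_nN_per_nm"]), R=float(meta["R_um"]),
        nu=float(meta["nu"]), direction=meta.get("direction", "approach"),
    )


def write_force_curve(curve, csv_path: str | Path,
                      sidecar: str | Path) -> None:
    write_table(pd.DataFrame({"z_um": curve.z, "d_um": curve.d}), csv_path)
    Path(sidecar).write_text(json.dumps({
        "k_nN_per_nm": curve.k, "R_um": curve.R, "nu": curve.nu,
        "direction": curve.direction,
    }, sort_keys=True))


def read_ocr(csv_path: str | Path, sidecar: str | Path) -> OCRTrace:
    df = read_table(csv_path)
    meta = json.loads(Path(sidecar).read_text())
    ecar = df["ecar"].to_numpy(dtype=float) if "ecar" in df.columns else None
    return OCRTrace(
        time_min=df["time_min"].to_numpy(), ocr=df["ocr"].to_numpy(),
        ecar=ecar,
        injections=[(lab, float(t)) for lab, t in meta["injections"]],
        cell_count=int(meta["cell_count"]),
        group_label=meta.get("group_label", ""),
    )


def write_ocr(trace: OCRTrace, csv_path: str | Path,
              sidecar: str | Path) -> None:
    df = pd.DataFrame({"time_min": trace.time_min, "ocr": trace.ocr})
    if trace.ecar is not None:
        df["ecar"] = trace.ecar
    write_table(df, csv_path)
    Path(sidecar).write_text(json.dumps({
        "injections": [[lab, t] for lab, t in trace.injections],
        "cell_count": trace.cell_count,
        "group_label": trace.group_label,
    }, sort_keys=True))
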