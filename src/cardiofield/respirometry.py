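"""Mitochondrial stress-test parameters from OCR traces.

The four phases of the oligomycin -> FCCP -> antimycin-A protocol are
summarised conventionally (last pre-oligomycin measurement; minimum after
oligomycin; maximum after FCCP; minimum after antimycin A) and decomposed
into non-mitochondrial, basal, ATP-linked, proton-leak, maximal and spare
respiration, optionally normalised per 1,000 cells.  ECAR, when present,
is passed through untransformed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

__all__ = [
    "OCRTrace",
    "StressTestParams",
    "IncompleteProtocolError",
    "phase_levels",
    "stress_params",
]

log = logging.getLogger(__name__)

INJECTION_ORDER = ("oligomycin", "FCCP", "antimycinA")


class IncompleteProtocolError(ValueError):
    """An injection required by the stress-test protocol is missing."""


@dataclass
class OCRTrace:
    """One well's OCR (and optional ECAR) time series with injections."""

    time_min: np.ndarray
    ocr: np.ndarray
    ecar: np.ndarray | None
    injections: list[tuple[str, float]]
    cell_count: int
    group_label: str = ""

    def __post_init__(self) -> None:
        self.time_min = np.asarray(self.time_min, dtype=float)
        self.ocr = np.asarray(self.ocr, dtype=float)
        if self.time_min.size != self.ocr.size:
            raise ValueError("time and OCR must be equal length")
        if np.any(np.diff(self.time_min) <= 0):
            raise ValueError("time must be strictly increasing")
        if self.cell_count <= 0:
            raise ValueError("cell_count must be positive")
        times = [t for _, t in self.injections]
        if times != sorted(times):
            raise ValueError("injection times must be increasing")
        for _, t in self.injections:
            if not (self.time_min[0] <= t <= self.time_min[-1]):
                raise ValueError("injection time outside the recording")


@dataclass
class StressTestParams:
    """Derived stress-test parameters, pmol O2/min (per-1,000-cells if
    normalised).  basal == atp_linked + proton_leak by construction."""

    non_mito: float
    basal: float
    atp_linked: float
    proton_leak: float
    maximal: float
    spare_capacity: float
    normalized: bool = False

    def as_dict(self) -> dict[str, float]:
        return {k: getattr(self, k) for k in (
            "non_mito", "basal", "atp_linked", "proton_leak",
            "maximal", "spare_capacity",
        )}


def phase_levels(trace: OCRTrace, reduce: str = "extrema"
                 ) -> tuple[float, float, float, float]:
    """Summarise the four protocol phases of an OCR trace.

    With the default ``extrema`` reduction: last pre-oligomycin point,
    post-oligomycin minimum, post-FCCP maximum, post-antimycin minimum.
    ``reduce='mean'`` uses phase means instead.
    """
    inj = {label: t for label, t in trace.injections}
    missing = [lab for lab in INJECTION_ORDER if lab not in inj]
    if missing:
        raise IncompleteProtocolError(f"missing injection(s): {missing}")
    bounds = [-np.inf] + [inj[lab] for lab in INJECTION_ORDER] + [np.inf]
    phases = []
    for i in range(4):
        sel = (trace.time_min > bounds[i]) & (trace.time_min <= bounds[i + 1])
        if sel.sum() < 2:
            raise ValueError(f"fewer than 2 measurements in phase {i + 1}")
        phases.append(trace.ocr[sel])
    if reduce == "mean":
        return tuple(float(p.mean()) for p in phases)
    return (
        float(phases[0][-1]),
        float(phases[1].min()),
        float(phases[2].max()),
        float(phases[3].min()),
    )


def stress_params(
    levels: tuple[float, float, float, float],
    cell_count: int = 1,
    normalize: bool = True,
) -> StressTestParams:
    """Decompose phase levels (L1..L4) into stress-test parameters.

    non_mito = L4; basal = L1 - L4; atp_linked = L1 - L2;
    proton_leak = L2 - L4; maximal = L3 - L4; spare = maximal - basal.
    With ``normalize`` every value is divided by cell_count/1000.
    """
    l1, l2, l3, l4 = (float(v) for v in levels)
    if not all(np.isfinite([l1, l2, l3, l4])):
        raise ValueError("phase levels must be finite")
    basal = l1 - l4
    if basal < 0:
        log.warning("negative basal respiration (%.3g): non-physiological",
                    basal)
    params = {
        "non_mito": l4,
        "basal": basal,
        "atp_linked": l1 - l2,
        "proton_leak": l2 - l4,
        "maximal": l3 - l4,
        "spare_capacity": (l3 - l4) - basal,
    }
    if normalize:
        scale = cell_count / 1000.0
        params = {k: v / scale for k, v in params.items()}
    return StressTestParams(**params, normalized=normalize)
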