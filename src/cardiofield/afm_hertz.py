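"""Hertz-model analysis of AFM approach curves (spherical indenter).

Converts piezo-position / cantilever-deflection records into
force-indentation data via ``F = k*(d - d_baseline)`` and
``delta = (z - z_contact) - (d - d_baseline)``, then fits Young's modulus
with the spherical-tip Hertz relation

    F = (4*sqrt(R)/3) * E/(1 - nu^2) * delta^(3/2)

by origin-constrained least squares in ``delta^(3/2)`` space (closed form,
no convergence tuning).  The contact point, left to instrument software in
typical workflows, is treated here as a free parameter chosen to minimise
the fit residual.

Units: z and d in µm, k in nN/nm, R in µm, forces in nN, E in Pa.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .optical_ap import InsufficientDataError

__all__ = [
    "ForceCurve",
    "HertzFit",
    "CellStiffness",
    "BaselineError",
    "NoContactError",
    "DegenerateFitError",
    "NonPhysicalFitError",
    "hertz_force_coefficient",
    "force_indentation",
    "fit_hertz",
    "find_contact_and_fit",
    "cell_stiffness",
]

log = logging.getLogger(__name__)


class BaselineError(ValueError):
    """Too few pre-contact samples to estimate the deflection baseline."""


class NoContactError(ValueError):
    """No contact point found within the sweep."""


class DegenerateFitError(ValueError):
    """All indentations are zero; Young's modulus is unidentifiable."""


class NonPhysicalFitError(ValueError):
    """The least-squares slope is negative (force decreasing with depth)."""


@dataclass
class ForceCurve:
    """One AFM sweep: piezo position z (µm) and deflection d (µm).

    ``k`` is the cantilever spring constant in nN/nm, ``R`` the spherical
    tip radius in µm, ``nu`` the sample Poisson ratio.
    """

    z: np.ndarray
    d: np.ndarray
    k: float
    R: float
    nu: float
    direction: str = "approach"

    def __post_init__(self) -> None:
        self.z = np.asarray(self.z, dtype=float)
        self.d = np.asarray(self.d, dtype=float)
        if self.z.size != self.d.size or self.z.size < 10:
            raise ValueError("z and d must be equal length >= 10")
        dz = np.diff(self.z)
        if not (np.all(dz > 0) or np.all(dz < 0)):
            raise ValueError("z must be strictly monotone within a sweep")
        if self.k <= 0 or self.R <= 0:
            raise ValueError("k and R must be positive")
        if not 0.0 <= self.nu <= 0.5:
            raise ValueError("nu must lie in [0, 0.5]")
        if self.direction not in ("approach", "retract"):
            raise ValueError("direction must be approach or retract")


@dataclass
class HertzFit:
    """Result of one Hertz fit."""

    contact_point_z: float          # µm
    E: float                        # Pa
    rss: float                      # nN^2
    fit_range: tuple[float, float]  # (delta_min, delta_max) µm
    n_points_fit: int


@dataclass
class CellStiffness:
    """Per-cell stiffness: mean Young's modulus over indentation sites."""

    cell_id: str
    group_label: str
    site_E: list[float] = field(default_factory=list)

    @property
    def mean_E(self) -> float:
        return float(np.mean(self.site_E))


def hertz_force_coefficient(E_pa: float, R_um: float, nu: float) -> float:
    """Prefactor C with F[nN] = C * delta[µm]^(3/2).

    With R and delta in µm and E in Pa, F[N] = (4/3)sqrt(R[m]) E delta[m]^1.5
    /(1-nu^2); collecting the unit factors gives 1e-3 in nN/µm^(3/2).
    """
    return (4.0 / 3.0) * np.sqrt(R_um) * E_pa / (1.0 - nu**2) * 1e-3


def _slope_to_E(slope: float, R_um: float, nu: float) -> float:
    return slope * 3.0 * (1.0 - nu**2) / (4.0 * np.sqrt(R_um)) * 1e3


def force_indentation(
    curve: ForceCurve,
    contact_point_z: float,
    min_baseline: int = 5,
) -> tuple[np.ndarray, np.ndarray]:
    """Convert a sweep to (delta [µm], force [nN]) pairs past contact.

    The deflection baseline is the mean deflection before contact; the
    geometry z = z_contact + d + delta then gives the indentation.  Samples
    before contact are excluded and delta is clipped at zero.
    """
    z, d = curve.z, curve.d
    if not (z.min() <= contact_point_z <= z.max()):
        raise ValueError("contact point outside the z range")
    pre = z < contact_point_z
    if pre.sum() < min_baseline:
        raise BaselineError(
            f"only {int(pre.sum())} pre-contact samples (need {min_baseline})"
        )
    d0 = float(d[pre].mean())
    post = ~pre
    bend = d[post] - d0
    force = curve.k * 1000.0 * bend       # nN, k converted to nN/µm
    delta = (z[post] - contact_point_z) - bend
    return np.clip(delta, 0.0, None), force


def fit_hertz(
    delta: np.ndarray,
    force: np.ndarray,
    R: float,
    nu: float,
    max_delta: float | None = None,
) -> HertzFit:
    """Fit Young's modulus by origin-constrained least squares.

    Regressing F on delta^(3/2) through the origin gives the closed form
    slope = sum(F * delta^1.5) / sum(delta^3); E follows from the Hertz
    prefactor.  The fit range runs from contact to the maximum-force point
    unless ``max_delta`` narrows it.
    """
    delta = np.asarray(delta, dtype=float)
    force = np.asarray(force, dtype=float)
    if max_delta is None and force.size:
        max_delta = float(delta[int(np.argmax(force))])
    sel = (delta > 0) & (delta <= max_delta + 1e-15)
    if sel.sum() < 5:
        if np.all(delta <= 0):
            raise DegenerateFitError("all indentations are zero")
        raise ValueError(f"need >= 5 points with delta > 0, got {sel.sum()}")
    x = delta[sel] ** 1.5
    y = force[sel]
    slope = float(np.dot(y, x) / np.dot(x, x))
    if slope <= 0:
        raise NonPhysicalFitError(
            f"negative Hertz slope {slope:.3g} nN/µm^1.5 "
            f"(n={int(sel.sum())}, max|F|={np.abs(y).max():.3g} nN)"
        )
    resid = y - slope * x
    return HertzFit(
        contact_point_z=np.nan,
        E=_slope_to_E(slope, R, nu),
        rss=float(np.dot(resid, resid)),
        fit_range=(float(delta[sel].min()), float(delta[sel].max())),
        n_points_fit=int(sel.sum()),
    )


def find_contact_and_fit(
    curve: ForceCurve,
    min_baseline: int = 5,
    force_frac: float = 0.25,
    n_iter: int = 2,
) -> HertzFit:
    """Locate the contact point and fit Young's modulus.

    Under the spherical Hertz model, ``F^(2/3)`` is exactly linear in the
    tip-sample position ``y = z - bend`` with zero-crossing at the contact
    point.  The contact is therefore read off a linear regression of
    ``F^(2/3)`` (the noisy response) on ``y`` (nearly noise-free predictor)
    over the high-force region (``F >= force_frac * F_max``), with the
    deflection baseline re-estimated from the pre-contact samples and the
    regression iterated.  On noise-free curves this recovers the contact
    exactly; under noise it is free of the systematic bias that a
    residual-minimising contact-point search acquires from the
    contact/modulus trade-off.
    """
    z, d = curve.z, curve.d
    k_um = curve.k * 1000.0

    # rough baseline from the first fifth of the sweep
    n0 = max(min_baseline, z.size // 5)
    d0 = float(np.median(d[:n0]))
    noise = float(np.std(d[:n0] - d0) * k_um)

    zc = None
    slope = intercept = None
    for it in range(n_iter + 1):
        bend = d - d0
        force = k_um * bend
        fmax = force.max()
        if fmax <= max(5.0 * noise, 1e-12):
            raise NoContactError("no force rise above the noise floor")
        u_thr = (force_frac * fmax) ** (2.0 / 3.0)
        if it == 0:
            sel = force >= force_frac * fmax
        else:
            # select on the previous line's prediction, not the noisy
            # force: thresholding on noise inflates points at the cutoff
            sel = slope * (z - bend) + intercept >= u_thr
        if sel.sum() < 5:
            raise NoContactError("too few high-force samples")
        y = z[sel] - bend[sel]
        with np.errstate(invalid="ignore"):
            u = np.sign(force[sel]) * np.abs(force[sel]) ** (2.0 / 3.0)
        slope, intercept = np.polyfit(y, u, 1)
        if slope <= 0:
            raise NoContactError("force does not grow along the sweep")
        zc = float(-intercept / slope)
        if not (z.min() <= zc <= z.max()):
            raise NoContactError(f"contact estimate {zc:.3g} outside sweep")
        pre = z < zc
        if pre.sum() < min_baseline:
            raise NoContactError("contact too close to the sweep start")
        d0 = float(d[pre].mean())

    delta, force = force_indentation(curve, zc, min_baseline)
    fit = fit_hertz(delta, force, curve.R, curve.nu)
    fit.contact_point_z = zc
    return fit


def cell_stiffness(
    fits: list[HertzFit],
    cell_id: str,
    group_label: str = "",
    expected_sites: int = 5,
) -> CellStiffness:
    """Average per-site moduli into one cell stiffness (protocol: 5 sites)."""
    if not fits:
        raise InsufficientDataError("no fits for cell")
    if len(fits) != expected_sites:
        log.warning("cell %s: %d sites (protocol expects %d)",
                    cell_id, len(fits), expected_sites)
    return CellStiffness(cell_id=cell_id, group_label=group_label,
                         site_E=[f.E for f in fits])
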