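"""Hertzian contact analysis of indentation loading curves.

The effective Young's modulus is obtained by fitting

    F = (4/3) * E_eff * sqrt(R_tip) * h^(3/2)

over the first micron of indentation, where the indentation is the base
travel past the contact point minus the cantilever deflection,
``h = (z - z_contact) - F / k_cant``.  The Poisson-ratio term is absorbed
into E_eff (the instrument-style "effective" modulus); use
:func:`young_from_effective` to convert if a Poisson ratio is assumed.

The model is linear in E_eff, so the least-squares estimator is closed
form: ``E_eff = sum(F * g) / sum(g^2)`` with ``g = (4/3) sqrt(R) h^(3/2)``.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np

from .curve_io import SegmentedCurve
from .errors import (ConfigurationError, InsufficientDepthError,
                     InvalidParameterError, NoContactError)

logger = logging.getLogger(__name__)

#: default fit window: first micron of indentation
H_MAX_UM = 1.0

#: curves reaching at least this fraction of the window are fitted with a
#: warning; below it they are rejected
MIN_DEPTH_FRACTION = 0.8

#: contact-point grid-search resolution (um)
CONTACT_RESOLUTION_UM = 0.01


@dataclass
class HertzFitResult:
    """Contact point, fitted effective modulus and fit diagnostics for one
    indent.  ``z_contact`` is NaN when the fit was run on a caller-supplied
    indentation series."""

    z_contact: float      # um
    E_eff: float          # Pa
    h_max: float          # um, upper edge of the fit window used
    rmse: float           # uN, residual over the window
    n_points: int

    def __post_init__(self) -> None:
        if self.rmse < 0 or self.n_points < 0:
            raise InvalidParameterError("rmse and n_points must be >= 0")


@dataclass
class ConstructModulus:
    """Per-construct summary: the mean of the per-site moduli (five
    measurement sites along the construct length by protocol)."""

    site_values: list     # Pa
    mean_E: float         # Pa
    construct_id: str
    day: int


def compute_indentation(curve: SegmentedCurve, z_contact: float,
                        baseline_uN: float = 0.0) -> np.ndarray:
    """Indentation series (um) for the whole record:
    ``h = (z - z_contact) - (F - baseline) / k_cant``, clipped at 0.

    Force in uN divided by stiffness in N/m gives deflection in um
    directly (1 uN / 1 N/m = 1 um).
    """
    meta = curve.record.meta
    if "k_cant" not in meta:
        raise ConfigurationError("record metadata lacks k_cant")
    k = float(meta["k_cant"])
    h = (curve.record.z - z_contact) - (curve.record.F - baseline_uN) / k
    return np.maximum(h, 0.0)


def fit_hertz(h_um: np.ndarray, F_uN: np.ndarray, R_tip_um: float,
              h_max_um: float = H_MAX_UM, *,
              z_contact: float = np.nan) -> HertzFitResult:
    """Closed-form least-squares Hertz fit of ``F`` against ``h`` over
    ``0 <= h <= h_max_um``.

    Raises :class:`InsufficientDepthError` if fewer than 10 samples fall in
    the window or the maximum indentation is below 80% of the window; warns
    (and fits the available range) between 80% and 100%.
    """
    h_um = np.asarray(h_um, dtype=float)
    F_uN = np.asarray(F_uN, dtype=float)
    if not (R_tip_um > 0):
        raise InvalidParameterError(f"R_tip must be positive, got {R_tip_um}")
    reached = float(h_um.max(initial=0.0))
    if reached < MIN_DEPTH_FRACTION * h_max_um:
        raise InsufficientDepthError(
            f"maximum indentation {reached:.3f} um is below "
            f"{MIN_DEPTH_FRACTION * h_max_um:.2f} um")
    window = min(h_max_um, reached)
    if reached < h_max_um:
        warnings.warn(
            f"fitting over available {reached:.3f} um instead of the full "
            f"{h_max_um:.2f} um window", stacklevel=2)
    mask = (h_um >= 0.0) & (h_um <= window)
    n = int(mask.sum())
    if n < 10:
        raise InsufficientDepthError(f"only {n} samples in the fit window")
    h_m = h_um[mask] * 1e-6
    F_N = F_uN[mask] * 1e-6
    g = (4.0 / 3.0) * np.sqrt(R_tip_um * 1e-6) * h_m ** 1.5
    denom = float(np.dot(g, g))
    E = float(np.dot(F_N, g) / denom) if denom > 0 else 0.0
    resid = F_N - E * g
    rmse = float(np.sqrt(np.mean(resid ** 2))) * 1e6
    return HertzFitResult(z_contact=z_contact, E_eff=E, h_max=window,
                          rmse=rmse, n_points=n)


def detect_contact_point(curve: SegmentedCurve,
                         h_max_um: float = H_MAX_UM,
                         resolution_um: float = CONTACT_RESOLUTION_UM
                         ) -> HertzFitResult:
    """Find the contact point by grid search over candidate surface
    positions, minimising the Hertz-fit residual over the indentation
    window; ties break to the smallest candidate.

    The pre-contact mean force (baseline) is subtracted per candidate
    before computing the indentation and fitting.  Raises
    :class:`NoContactError` if the loading force never rises above the
    noise floor, :class:`InsufficientDepthError` if no candidate leaves
    enough indentation for a fit.
    """
    rec = curve.record
    sl = curve.load
    if len(sl) == 0:
        raise NoContactError("record has no loading phase")
    z = rec.z[sl.start:sl.stop]
    F = rec.F[sl.start:sl.stop]
    k = float(rec.meta["k_cant"])
    R = float(rec.meta["R_tip"])

    # noise-floor check on the loading phase: the late-phase mean must rise
    # clear of the early-phase baseline scatter
    n0 = max(10, len(F) // 20)
    b_mean = float(F[:n0].mean())
    b_sd = float(F[:n0].std())
    tail = float(F[-n0:].mean())
    if tail - b_mean <= 3.0 * b_sd:
        raise NoContactError(
            "loading force never rises above 3x the baseline noise sd")

    # Candidate selection minimises the residual of the full loading-curve
    # model (baseline before contact, the window-fitted Hertz branch after),
    # not just the residual inside the window: a window of pure baseline
    # fits trivially (E ~ 0), and on truncated records a too-early candidate
    # can manufacture apparent depth — both are exposed only by the samples
    # outside their window.  E itself is still estimated from the first
    # micron of indentation.
    best: HertzFitResult | None = None
    best_score = np.inf
    pref = (4.0 / 3.0) * np.sqrt(R * 1e-6) * 1e6  # uN per (m^1.5 Pa)
    candidates = np.arange(z[0], z[-1], resolution_um)
    for zc in candidates:
        pre = F[z <= zc]
        baseline = float(pre.mean()) if pre.size else 0.0
        Fc = F - baseline
        h = np.maximum((z - zc) - Fc / k, 0.0)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            try:
                fit = fit_hertz(h, Fc, R, h_max_um, z_contact=float(zc))
            except InsufficientDepthError:
                continue
        if fit.E_eff <= 0:
            continue
        pred = fit.E_eff * pref * (h * 1e-6) ** 1.5
        score = float(np.sqrt(np.mean((Fc - pred) ** 2)))
        if score < best_score:
            best, best_score = fit, score
    if best is None:
        raise InsufficientDepthError(
            "no candidate contact point leaves enough indentation depth")
    if best.h_max < h_max_um:
        warnings.warn(
            f"contact point fitted over a partial window "
            f"({best.h_max:.2f} of {h_max_um:.2f} um): treat E_eff as a "
            f"lower-quality estimate", stacklevel=2)
    return best


def young_from_effective(E_eff: float, poisson_ratio: float) -> float:
    """Convert the effective modulus to a Young's modulus under an assumed
    Poisson ratio: ``E = E_eff * (1 - nu^2)``.  Off by default everywhere;
    reported moduli are effective moduli."""
    if not (-1.0 < poisson_ratio < 0.5 or poisson_ratio == 0.5):
        raise InvalidParameterError("poisson_ratio must be in (-1, 0.5]")
    return E_eff * (1.0 - poisson_ratio ** 2)


def construct_modulus(fits: list, construct_id: str, day: int,
                      expected_sites: int = 5) -> ConstructModulus:
    """Per-construct modulus: arithmetic mean of the per-site fits
    (protocol: five sites along the construct length)."""
    if not fits:
        raise InvalidParameterError("construct_modulus needs >= 1 fit")
    values = [f.E_eff if isinstance(f, HertzFitResult) else float(f)
              for f in fits]
    if len(values) != expected_sites:
        warnings.warn(
            f"construct {construct_id}: {len(values)} sites instead of "
            f"{expected_sites}", stacklevel=2)
    return ConstructModulus(site_values=values,
                            mean_E=float(np.mean(values)),
                            construct_id=construct_id, day=int(day))


def modulus_cdf(values) -> tuple[np.ndarray, np.ndarray]:
    """Empirical CDF with plotting positions ``p_i = (i - 0.5) / n`` over
    the sorted values, so the middle value of an odd-sized sample sits
    exactly at p = 0.5 (the median)."""
    v = np.sort(np.asarray(values, dtype=float))
    if v.size == 0:
        raise InvalidParameterError("modulus_cdf needs >= 1 value")
    p = (np.arange(1, v.size + 1) - 0.5) / v.size
    return v, p


def cdf_median(values) -> float:
    """Value at CDF 0.5 (linear interpolation between plotting positions)."""
    v, p = modulus_cdf(values)
    return float(np.interp(0.5, p, v))
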