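"""Stress-relaxation statistics from hold-phase force data.

The headline statistic is the relaxation percentage

    r_relax = 100 * (F_max - F_t=10s) / F_max

with F_max the peak force at the end of the indentation ramp and F_t=10s
the force 10 s into the hold.  Higher values mean more fluid-like
behaviour; a smaller ratio indicates a more solid, elastic-like material.
For a standard linear solid held at constant indentation the closed form
is ``r_relax = 100 * (1 - alpha) * (1 - exp(-10/tau))`` with
``alpha = E_inf / E0``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

from .curve_io import SegmentedCurve
from .errors import (InsufficientHoldError, InvalidParameterError,
                     NoContactError)

#: F_max is searched within this window around hold onset (s)
PEAK_WINDOW_S = 0.1


@dataclass
class RelaxationStat:
    """Peak force, 10 s force and relaxation percentage for one hold."""

    F_max: float          # uN
    F_10s: float          # uN
    r_relax: float        # %, may be negative if the force creeps upward
    hold_duration: float  # s


@dataclass
class SLSFit:
    """Hold-phase standard-linear-solid fit: modulus ratio ``alpha``
    (= E_inf/E0), time constant ``tau`` (s) and peak force.  ``tau`` is NaN
    and ``identifiable`` False for a non-decaying (elastic) hold."""

    alpha: float
    tau: float
    F_max: float          # uN
    identifiable: bool = True


def relaxation_percentage(curve: SegmentedCurve, t_eval: float = 10.0,
                          smooth_window_s: float | None = None
                          ) -> RelaxationStat:
    """Compute the relaxation percentage over a ``t_eval``-second hold.

    F_max is the maximum force within +-0.1 s of hold onset (the peak at
    the end of the ramp); F at ``t_eval`` is linearly interpolated at the
    exact instant, or averaged over ``+-smooth_window_s`` when a smoothing
    window is requested for noisy data.  A force that creeps upward gives a
    negative percentage, reported with a warning rather than clipped.
    """
    rec = curve.record
    hold = curve.hold
    if len(hold) == 0:
        raise InsufficientHoldError("record has no hold phase")
    t0 = rec.t[hold.start]
    duration = rec.t[hold.stop - 1] - t0
    if duration < t_eval * (1.0 - 1e-9):
        raise InsufficientHoldError(
            f"hold lasts {duration:.2f} s < t_eval {t_eval:.2f} s")

    near = (rec.t >= t0 - PEAK_WINDOW_S) & (rec.t <= t0 + PEAK_WINDOW_S)
    F_max = float(rec.F[near].max())
    if F_max <= 0:
        raise NoContactError("peak force does not rise above zero")

    t_target = t0 + t_eval
    th = rec.t[hold.start:hold.stop]
    Fh = rec.F[hold.start:hold.stop]
    if smooth_window_s:
        m = np.abs(th - t_target) <= smooth_window_s
        F_t = float(Fh[m].mean())
    else:
        F_t = float(np.interp(t_target, th, Fh))
    r = 100.0 * (F_max - F_t) / F_max
    if r < 0:
        warnings.warn(f"negative relaxation percentage ({r:.2f}%): force "
                      "creeps upward during the hold", stacklevel=2)
    return RelaxationStat(F_max=F_max, F_10s=F_t, r_relax=r,
                          hold_duration=float(duration))


def fit_sls_inverse(curve: SegmentedCurve) -> SLSFit:
    """Least-squares fit of ``F(t) = F_max (alpha + (1-alpha) e^{-t/tau})``
    to the hold phase; validates the simulator rather than feeding the
    headline statistic.  A non-decaying hold yields the degenerate elastic
    answer ``alpha = 1`` with a warning."""
    hold = curve.hold
    if len(hold) == 0:
        raise InsufficientHoldError("record has no hold phase")
    rec = curve.record
    t = rec.t[hold.start:hold.stop]
    F = rec.F[hold.start:hold.stop]
    t = t - t[0]
    F0, F_end = float(F[0]), float(F[-1])
    if F0 <= 0:
        raise NoContactError("hold force does not rise above zero")
    if F_end >= F0 * (1.0 - 1e-9):
        warnings.warn("hold force does not decay; alpha = 1, tau "
                      "unidentifiable", stacklevel=2)
        return SLSFit(alpha=1.0, tau=float("nan"), F_max=F0,
                      identifiable=False)

    def model(t, F_max, alpha, tau):
        return F_max * (alpha + (1.0 - alpha) * np.exp(-t / tau))

    p0 = (F0, max(F_end / F0, 1e-3), max(t[-1] / 5.0, 1e-3))
    popt, _ = curve_fit(model, t, F, p0=p0,
                        bounds=([0.0, 0.0, 1e-6], [np.inf, 1.0, np.inf]),
                        maxfev=20000)
    F_max, alpha, tau = (float(v) for v in popt)
    return SLSFit(alpha=alpha, tau=tau, F_max=F_max, identifiable=True)


def construct_relaxation(stats: list, construct_id: str, day: int,
                         expected_sites: int = 5) -> float:
    """Per-construct relaxation percentage: mean of the per-site values
    (five measurement sites by protocol), same contract as the modulus
    aggregation."""
    if not stats:
        raise InvalidParameterError("construct_relaxation needs >= 1 stat")
    values = [s.r_relax if isinstance(s, RelaxationStat) else float(s)
              for s in stats]
    if len(values) != expected_sites:
        warnings.warn(
            f"construct {construct_id}: {len(values)} sites instead of "
            f"{expected_sites}", stacklevel=2)
    return float(np.mean(values))
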