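"""Seeded generators for every input the analysis pipeline consumes.

The generators emulate the measurement setups of the study: spherical
nanoindentation of soft cylindrical collagen constructs with an
optical-fibre cantilever (Hertzian contact, finite cantilever stiffness,
10 um/s base ramps), open-loop 10 s stress-relaxation holds with
standard-linear-solid material behaviour, RT-qPCR cycle-threshold tables
normalised to YWHAZ, per-cell orientation angles whose dispersion shrinks
with culture time, construct diameter series, and centre/periphery cell
counts.  Every generator is a pure function of its parameters and seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .curve_io import ForceRecord
from .errors import ConfigurationError, InvalidParameterError

#: the culture design days of the study
DESIGN_DAYS = (0, 2, 4, 7, 14, 21)

#: reference (housekeeping) gene for Ct normalisation
REFERENCE_GENE = "YWHAZ"

#: Ct detection cutoff in cycles; wells at/above it are "undetected"
DETECTION_CUTOFF = 35.0


@dataclass(frozen=True)
class SLSMaterial:
    """Standard linear solid: instantaneous modulus ``E0``, long-time
    modulus ``E_inf`` (both Pa, effective i.e. Poisson term absorbed) and
    relaxation time ``tau`` (s).

    The force in a rigid hold at constant indentation relaxes as
    ``F(t) = F_max * (alpha + (1 - alpha) * exp(-t / tau))`` with
    ``alpha = E_inf / E0``, so the 10 s relaxation percentage is
    ``100 * (1 - alpha) * (1 - exp(-10 / tau))``.
    """

    E0: float
    E_inf: float
    tau: float

    def __post_init__(self) -> None:
        if not (self.E0 > 0):
            raise InvalidParameterError(f"E0 must be positive, got {self.E0}")
        if not (0 < self.E_inf <= self.E0):
            raise InvalidParameterError(
                f"need 0 < E_inf <= E0, got E_inf={self.E_inf}, E0={self.E0}"
            )
        if not (self.tau > 0):
            raise InvalidParameterError(f"tau must be positive, got {self.tau}")

    @property
    def alpha(self) -> float:
        """Long-time to instantaneous modulus ratio ``E_inf / E0``."""
        return self.E_inf / self.E0

    def relaxation_percentage(self, t_eval: float = 10.0) -> float:
        """Analytic rigid-hold relaxation percentage after ``t_eval`` s."""
        return 100.0 * (1.0 - self.alpha) * (1.0 - math.exp(-t_eval / self.tau))

    @classmethod
    def from_relaxation(
        cls, r_relax_pct: float, tau: float = 2.0, E0: float = 1300.0,
        t_eval: float = 10.0,
    ) -> "SLSMaterial":
        """Build the SLS whose analytic ``t_eval``-second rigid-hold
        relaxation percentage equals ``r_relax_pct``."""
        decay = 1.0 - math.exp(-t_eval / tau)
        alpha = 1.0 - (r_relax_pct / 100.0) / decay
        if not (0 < alpha <= 1):
            raise InvalidParameterError(
                f"relaxation of {r_relax_pct}% unreachable with tau={tau}"
            )
        return cls(E0=E0, E_inf=alpha * E0, tau=tau)


@dataclass(frozen=True)
class ProbeConfig:
    """Indentation probe and acquisition settings.

    R_tip : sphere radius, um (bead diameters 50-100 um -> radii 25-50 um)
    k_cant : cantilever stiffness, N/m
    speed : base displacement rate, um/s
    rate : sampling frequency, Hz
    z_contact : true surface position along the approach axis, um
    noise_sd : additive white Gaussian force noise, nN
    seed : RNG seed for the noise
    """

    R_tip: float = 37.5
    k_cant: float = 0.5
    speed: float = 10.0
    rate: float = 1000.0
    z_contact: float = 5.0
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("R_tip", "k_cant", "speed", "rate"):
            if not (getattr(self, name) > 0):
                raise InvalidParameterError(f"{name} must be positive")
        if self.z_contact < 0 or self.noise_sd < 0:
            raise InvalidParameterError("z_contact and noise_sd must be >= 0")


def _hertz_force_si(E_eff: float, R_m: float, h_m) -> np.ndarray:
    """F = (4/3) E_eff sqrt(R) h^{3/2}, SI units."""
    h = np.maximum(np.asarray(h_m, dtype=float), 0.0)
    return (4.0 / 3.0) * E_eff * np.sqrt(R_m) * h ** 1.5


def _solve_contact_forces(travel_m: np.ndarray, E_eff: float, R_m: float,
                          k: float) -> np.ndarray:
    """Solve F = (4/3) E sqrt(R) (s - F/k)^{3/2} per sample, where ``s`` is
    the base travel past the surface.  Force is zero before contact."""
    A = (4.0 / 3.0) * E_eff * np.sqrt(R_m)
    out = np.zeros_like(travel_m)
    for i, s in enumerate(travel_m):
        if s <= 0:
            continue
        f_hi = min(k * s, A * s ** 1.5)  # F <= k s (h >= 0) and F <= F(h=s)
        out[i] = brentq(lambda f: f - A * max(s - f / k, 0.0) ** 1.5,
                        0.0, f_hi, xtol=1e-18, rtol=1e-14)
    return out


def simulate_elastic_curve(E_eff: float, probe: ProbeConfig,
                           max_depth: float = 2.0,
                           label: str = "") -> ForceRecord:
    """Simulate a purely elastic spherical indentation at constant base speed.

    The base advances at ``probe.speed`` from z=0 past the surface at
    ``probe.z_contact`` until the indentation (base travel minus cantilever
    deflection, solved self-consistently per sample) reaches ``max_depth``
    um.  Force follows the Hertz relation in contact and is zero before;
    Gaussian noise of sd ``probe.noise_sd`` nN is added throughout.

    Parameters are in the units of :class:`ProbeConfig`; ``E_eff`` in Pa.
    """
    if not (E_eff > 0):
        raise InvalidParameterError(f"E_eff must be positive, got {E_eff}")
    if max_depth < 1.0:
        raise InvalidParameterError("max_depth must be >= 1 um (fit window)")
    R_m = probe.R_tip * 1e-6
    F_end = float(_hertz_force_si(E_eff, R_m, max_depth * 1e-6))
    z_end = probe.z_contact + max_depth + F_end / probe.k_cant * 1e6  # um
    dt = 1.0 / probe.rate
    n = int(np.ceil(z_end / probe.speed / dt)) + 1
    t = np.arange(n) * dt
    z = probe.speed * t
    travel_m = (z - probe.z_contact) * 1e-6
    F_N = _solve_contact_forces(travel_m, E_eff, R_m, probe.k_cant)
    F_uN = F_N * 1e6
    rng = np.random.default_rng(probe.seed)
    F_uN = F_uN + rng.normal(0.0, probe.noise_sd * 1e-3, size=n)
    meta = {"k_cant": probe.k_cant, "R_tip": probe.R_tip, "rate": probe.rate,
            "label": label}
    phase = np.full(n, "load", dtype=object)
    return ForceRecord(t=t, z=z, F=F_uN, meta=meta, phase=phase)


def simulate_relaxation_record(mat: SLSMaterial, probe: ProbeConfig,
                               hold_s: float = 10.0, max_depth: float = 2.0,
                               mode: str = "rigid", unload_s: float = 1.0,
                               label: str = "") -> ForceRecord:
    """Simulate ramp -> hold -> retract with standard-linear-solid material.

    In the default ``"rigid"`` mode the base is frozen at the end of the
    ramp and the hold force follows the closed form
    ``F_max * (alpha + (1 - alpha) exp(-t/tau))`` — the analytically
    testable idealisation.  In ``"coupled"`` mode the open-loop constraint
    (fixed base, tip creeping as force decays through the cantilever
    compliance) is enforced by a per-step fixed-point solve of the SLS
    hereditary integral.
    """
    if mode not in ("rigid", "coupled"):
        raise InvalidParameterError(f"unknown relaxation mode {mode!r}")
    if hold_s <= 0:
        raise InvalidParameterError("hold_s must be positive")
    R_m = probe.R_tip * 1e-6
    dt = 1.0 / probe.rate

    # loading ramp: elastic response at the instantaneous modulus E0
    ramp = simulate_elastic_curve(
        mat.E0, replace(probe, noise_sd=0.0), max_depth=max_depth)
    t_load, z_load, F_load = ramp.t, ramp.z, ramp.F
    n_load = t_load.size

    n_hold = int(round(hold_s * probe.rate))
    t_hold = t_load[-1] + dt * np.arange(1, n_hold + 1)
    z_hold = np.full(n_hold, z_load[-1])

    if mode == "rigid":
        F_max = F_load[-1]
        th = dt * np.arange(1, n_hold + 1)
        F_hold = F_max * (mat.alpha + (1.0 - mat.alpha) * np.exp(-th / mat.tau))
    else:
        F_hold = _coupled_hold(mat, probe, R_m,
                               h0_m=(z_load[-1] - probe.z_contact) * 1e-6
                               - F_load[-1] * 1e-6 / probe.k_cant,
                               F0_N=F_load[-1] * 1e-6,
                               z_m=(z_load[-1] - probe.z_contact) * 1e-6,
                               n_hold=n_hold, dt=dt) * 1e6

    # retract: base moves back at probe.speed; force ramps down along an
    # elastic unloading branch anchored at the hold-end force
    n_unload = int(round(unload_s * probe.rate))
    t_un = t_hold[-1] + dt * np.arange(1, n_unload + 1)
    z_un = z_hold[-1] - probe.speed * dt * np.arange(1, n_unload + 1)
    h_end = max(z_hold[-1] - probe.z_contact - F_hold[-1] / probe.k_cant, 0.0)
    h_un = np.maximum(z_un - probe.z_contact - 0.0, 0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        frac = np.where(h_end > 0, np.minimum(h_un / h_end, 1.0), 0.0)
    F_un = F_hold[-1] * frac ** 1.5

    t = np.concatenate([t_load, t_hold, t_un])
    z = np.concatenate([z_load, z_hold, z_un])
    F = np.concatenate([F_load, F_hold, F_un])
    rng = np.random.default_rng(probe.seed)
    F = F + rng.normal(0.0, probe.noise_sd * 1e-3, size=F.size)
    phase = np.concatenate([
        np.full(n_load, "load", dtype=object),
        np.full(n_hold, "hold", dtype=object),
        np.full(n_unload, "unload", dtype=object),
    ])
    meta = {"k_cant": probe.k_cant, "R_tip": probe.R_tip, "rate": probe.rate,
            "label": label}
    return ForceRecord(t=t, z=z, F=F, meta=meta, phase=phase)


def _coupled_hold(mat: SLSMaterial, probe: ProbeConfig, R_m: float,
                  h0_m: float, F0_N: float, z_m: float, n_hold: int,
                  dt: float) -> np.ndarray:
    """Open-loop hold: fixed base position ``z_m`` (relative to surface),
    indentation h(t) = z - F(t)/k creeps forward as the SLS stress relaxes.

    The SLS contact force is the hereditary integral
    F(t) = (4/3) sqrt(R) [E_inf w(t) + (E0 - E_inf) q(t)] with
    w = h^{3/2} and q(t) = int_0^t exp(-(t-s)/tau) dw(s); q is updated
    exponentially per step and the compliance coupling is solved by
    fixed-point iteration.
    """
    pref = (4.0 / 3.0) * np.sqrt(R_m)
    decay = math.exp(-dt / mat.tau)
    half = math.exp(-dt / (2.0 * mat.tau))
    w_prev = h0_m ** 1.5
    q = w_prev  # loading was fast relative to tau start-of-hold state:
    # initialise so that F(0+) continues from the elastic ramp force
    q = (F0_N / pref - mat.E_inf * w_prev) / (mat.E0 - mat.E_inf) \
        if mat.E0 > mat.E_inf else w_prev
    F = F0_N
    out = np.empty(n_hold)
    for i in range(n_hold):
        q_old, w_old = q, w_prev
        for _ in range(200):
            h = max(z_m - F / probe.k_cant, 0.0)
            w = h ** 1.5
            q_new = decay * q_old + half * (w - w_old)
            F_new = pref * (mat.E_inf * w + (mat.E0 - mat.E_inf) * q_new)
            if abs(F_new - F) < 1e-18 + 1e-12 * abs(F):
                F, q = F_new, q_new
                break
            F = 0.5 * (F + F_new)  # damped update for stability
        else:
            F, q = F_new, q_new
        w_prev = (max(z_m - F / probe.k_cant, 0.0)) ** 1.5
        out[i] = F
    return out


def simulate_ct_table(day_effects: dict, n_reps=None, ct_ref: float = 20.0,
                      ct_base=26.0, noise_sd: float = 0.25, seed: int = 0,
                      reference_gene: str = REFERENCE_GENE,
                      detection_cutoff: float = DETECTION_CUTOFF,
                      days=DESIGN_DAYS) -> pd.DataFrame:
    """Generate a long-format qPCR Ct table.

    ``day_effects`` maps gene -> {day: log2 fold change vs baseline}; a NaN
    entry means the gene is not expressed on that day (the well is reported
    at the detection cutoff with ``detected=False``).  ``n_reps`` is the
    number of biological replicates, an int or a {day: n} mapping; Ct of
    gene g in a replicate is ``ct_base[g] - log2FC(g, day) + noise`` and the
    reference gene is centred at ``ct_ref``.

    Returns a DataFrame with columns gene, sample_id, day, Ct, detected.
    """
    if reference_gene in day_effects:
        raise ConfigurationError(
            f"{reference_gene!r} is the reference gene; model it via ct_ref")
    if not day_effects:
        raise ConfigurationError("day_effects must list at least one gene")
    if n_reps is None:
        n_reps = 3
    if isinstance(n_reps, int):
        n_reps = {d: n_reps for d in days}
    if min(n_reps.values()) < 3:
        raise ConfigurationError("need n_reps >= 3 per day")
    base = ct_base if isinstance(ct_base, dict) else \
        {g: float(ct_base) for g in day_effects}
    rng = np.random.default_rng(seed)
    rows = []
    for day in days:
        for rep in range(n_reps[day]):
            sample = f"d{day:02d}_s{rep + 1:02d}"
            ct = ct_ref + rng.normal(0.0, noise_sd)
            rows.append((reference_gene, sample, day, ct, ct < detection_cutoff))
            for gene, traj in day_effects.items():
                lfc = traj.get(day, np.nan)
                if lfc is None or (isinstance(lfc, float) and math.isnan(lfc)):
                    rows.append((gene, sample, day, detection_cutoff, False))
                    continue
                ct = base[gene] - lfc + rng.normal(0.0, noise_sd)
                if ct >= detection_cutoff:
                    rows.append((gene, sample, day, detection_cutoff, False))
                else:
                    rows.append((gene, sample, day, ct, True))
    return pd.DataFrame(rows, columns=["gene", "sample_id", "day", "Ct",
                                       "detected"])


def simulate_orientations(dispersion_by_day: dict, n_cells: int = 15,
                          n_constructs: int = 3, seed: int = 0,
                          distribution: str = "folded_normal") -> pd.DataFrame:
    """Generate per-cell acute angles (degrees) to the construct axis.

    ``dispersion_by_day`` maps day -> angular sd in degrees of a normal
    distribution centred on the tension axis; draws are folded into
    [0, 90] (orientation is axial: v and -v are the same cell axis).
    ``distribution="uniform"`` ignores the dispersion and draws uniformly
    on [0, 90] (the fully unaligned limit).
    """
    if n_cells < 15:
        raise InvalidParameterError("need >= 15 cells per construct")
    if distribution not in ("folded_normal", "uniform"):
        raise InvalidParameterError(f"unknown distribution {distribution!r}")
    rng = np.random.default_rng(seed)
    rows = []
    for day, sigma in dispersion_by_day.items():
        if sigma < 0:
            raise InvalidParameterError("dispersion must be >= 0")
        for c in range(n_constructs):
            if distribution == "uniform":
                ang = rng.uniform(0.0, 90.0, size=n_cells)
            else:
                ang = np.abs(rng.normal(0.0, sigma, size=n_cells)) % 180.0
                ang = np.where(ang > 90.0, 180.0 - ang, ang)
            cid = f"d{day:02d}_c{c + 1:02d}"
            rows += [(cid, day, i + 1, a) for i, a in enumerate(ang)]
    return pd.DataFrame(rows, columns=["construct_id", "day", "cell_id",
                                       "angle_deg"])


#: printed per-day diameter summaries of the cell-seeded constructs (mm)
DIAMETER_MEANS = {0: 2.08, 7: 0.67, 14: 0.59, 21: 0.55}
DIAMETER_SDS = {0: 0.08, 7: 0.02, 14: 0.02, 21: 0.04}
DIAMETER_NS = {0: 11, 7: 15, 14: 14, 21: 19}

#: printed per-day diameter summaries of the no-cell constructs (mm)
NOCELL_DIAMETER_MEANS = {0: 4.46, 7: 4.41, 14: 4.5, 21: 4.46}
NOCELL_DIAMETER_SDS = {0: 0.48, 7: 0.45, 14: 0.45, 21: 0.48}


def simulate_diameters(day_means: dict | None = None,
                       day_sds: dict | None = None,
                       n_per_day=None, seed: int = 0) -> pd.DataFrame:
    """Gaussian construct-diameter draws (mm), truncated at zero, with the
    study's printed per-day means/SDs and sample sizes as defaults."""
    day_means = DIAMETER_MEANS if day_means is None else day_means
    day_sds = DIAMETER_SDS if day_sds is None else day_sds
    if n_per_day is None:
        n_per_day = {d: DIAMETER_NS.get(d, 12) for d in day_means}
    if isinstance(n_per_day, int):
        n_per_day = {d: n_per_day for d in day_means}
    if any(m <= 0 for m in day_means.values()) or \
            any(s < 0 for s in day_sds.values()):
        raise InvalidParameterError("means must be > 0 and SDs >= 0")
    rng = np.random.default_rng(seed)
    rows = []
    for day, mean in day_means.items():
        sd = day_sds[day]
        for i in range(n_per_day[day]):
            d = rng.normal(mean, sd)
            while d <= 0:  # truncate at zero (practically never triggers)
                d = rng.normal(mean, sd)
            rows.append((f"d{day:02d}_c{i + 1:02d}", day, d))
    return pd.DataFrame(rows, columns=["construct_id", "day", "diameter_mm"])


def simulate_density(centre_density: float = 1000.0,
                     periphery_density: float = 2000.0,
                     region_area_mm2: float = 0.02, n_constructs: int = 10,
                     day: int = 0, seed: int = 0) -> pd.DataFrame:
    """Poisson cell counts in centre and periphery regions of equal area,
    emulating the denser peripheral cell layer of the constructs."""
    if region_area_mm2 <= 0:
        raise InvalidParameterError("region_area_mm2 must be positive")
    rng = np.random.default_rng(seed)
    rows = []
    for c in range(n_constructs):
        cid = f"d{day:02d}_c{c + 1:02d}"
        for region, dens in (("centre", centre_density),
                             ("periphery", periphery_density)):
            count = rng.poisson(dens * region_area_mm2)
            rows.append((cid, day, region, int(count), region_area_mm2))
    return pd.DataFrame(rows, columns=["construct_id", "day", "region",
                                       "cell_count", "region_area_mm2"])
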