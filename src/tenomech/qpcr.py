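"""Relative qPCR quantification: delta-Ct against a reference gene,
2^-ddCt fold changes against a control group, single-pass 2-SD outlier
exclusion, detection calling, and the exact Mann-Whitney U test.

Conventions of the study this mirrors:

* delta-Ct is per sample, ``Ct_gene - Ct_YWHAZ``.
* delta-delta-Ct subtracts the *control-group mean* delta-Ct, so the
  control group's summary fold change is exactly 1.
* the control group is Day 0, or the first day of detection for genes not
  expressed at Day 0.
* outliers are removed in one pass per gene x day group: values more than
  2 sample-SDs from the group mean.
* group comparisons use the two-sided Mann-Whitney test, exact by
  enumeration of the U null distribution for small tie-free samples; no
  multiple-testing correction is applied.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd
from scipy.stats import norm, rankdata

from .errors import ConfigurationError, InvalidParameterError
from .synthetic import DESIGN_DAYS, DETECTION_CUTOFF, REFERENCE_GENE

logger = logging.getLogger(__name__)

#: largest min(nA, nB) for which the exact U distribution is enumerated
EXACT_LIMIT = 8

#: significance tiers used in the report tables
STAR_THRESHOLDS = ((0.0001, "****"), (0.001, "***"), (0.01, "**"),
                   (0.05, "*"))

UNDETECTED = "undetected"


def delta_ct(table: pd.DataFrame,
             reference_gene: str = REFERENCE_GENE) -> pd.DataFrame:
    """Per-sample delta-Ct: ``Ct_gene - Ct_reference`` within each sample.

    Samples lacking a reference-gene measurement are dropped with a logged
    warning.  Input columns: gene, sample_id, day, Ct (and optionally
    detected, carried through).
    """
    ref = table[table["gene"] == reference_gene]
    if ref.empty:
        raise ConfigurationError(
            f"reference gene {reference_gene!r} absent from the table")
    ref_ct = ref.set_index("sample_id")["Ct"]
    genes = table[table["gene"] != reference_gene].copy()
    missing = ~genes["sample_id"].isin(ref_ct.index)
    if missing.any():
        dropped = sorted(genes.loc[missing, "sample_id"].unique())
        logger.warning("dropping samples without reference Ct: %s", dropped)
        genes = genes[~missing]
    genes["dCt"] = genes["Ct"].to_numpy() - \
        ref_ct.loc[genes["sample_id"]].to_numpy()
    return genes.reset_index(drop=True)


def fold_change_ddct(dct: pd.DataFrame, control_day=0) -> pd.DataFrame:
    """2^-ddCt fold changes relative to the control-group mean delta-Ct.

    ``control_day`` is a day number applied to every gene, or a
    {gene: day} mapping (e.g. from :func:`first_detection_day` for genes
    not expressed at Day 0).  Adds columns ddCt, fold and control_day;
    raises :class:`ConfigurationError` for an empty control group.
    """
    out = []
    for gene, g in dct.groupby("gene", sort=False):
        day = control_day.get(gene) if isinstance(control_day, dict) \
            else control_day
        if day is None:
            raise ConfigurationError(f"no control day given for {gene!r}")
        ctrl = g.loc[g["day"] == day, "dCt"]
        if ctrl.empty:
            raise ConfigurationError(
                f"empty control group for {gene!r} at day {day}")
        g = g.copy()
        g["ddCt"] = g["dCt"] - ctrl.mean()
        g["fold"] = 2.0 ** -g["ddCt"]
        g["control_day"] = day
        out.append(g)
    return pd.concat(out, ignore_index=True)


def summarise_folds(fc: pd.DataFrame) -> pd.DataFrame:
    """Per gene x day summary: the group fold change ``2^-mean(ddCt)``
    (exactly 1 for the control group) plus mean and SD of the per-sample
    folds."""
    rows = []
    for (gene, day), g in fc.groupby(["gene", "day"], sort=True):
        # group fold from the group-mean dCt, so the control day reduces to
        # 2^-(m - m) = 1 exactly rather than within rounding
        ctrl_day = g["control_day"].iloc[0]
        ctrl_mean = fc.loc[(fc["gene"] == gene)
                           & (fc["day"] == ctrl_day), "dCt"].mean()
        rows.append({
            "gene": gene, "day": day, "n": len(g),
            "fold_group": 2.0 ** -(g["dCt"].mean() - ctrl_mean),
            "fold_mean": g["fold"].mean(),
            "fold_sd": g["fold"].std(ddof=1) if len(g) > 1 else 0.0,
            "control_day": g["control_day"].iloc[0],
        })
    return pd.DataFrame(rows)


def exclude_outliers_2sd(values) -> np.ndarray:
    """Single-pass exclusion of values more than 2 sample-SDs from the
    mean; not iterated.  Groups smaller than 3 are returned unchanged with
    a warning."""
    v = np.asarray(values, dtype=float)
    if v.size < 3:
        warnings.warn("fewer than 3 values: outlier exclusion skipped",
                      stacklevel=2)
        return v
    sd = v.std(ddof=1)
    if sd == 0:
        return v
    return v[np.abs(v - v.mean()) <= 2.0 * sd]


def first_detection_day(table: pd.DataFrame, gene: str,
                        min_fraction: float = 0.5, days=DESIGN_DAYS):
    """Earliest design day on which the gene is detected (Ct below the
    cutoff) in at least ``min_fraction`` of replicates; the string
    ``"undetected"`` if no day qualifies."""
    g = table[table["gene"] == gene]
    if g.empty:
        raise ConfigurationError(f"gene {gene!r} absent from the table")
    if "detected" in g.columns:
        det = g["detected"].astype(bool)
    else:
        det = g["Ct"] < DETECTION_CUTOFF
    for day in sorted(days):
        sub = det[g["day"] == day]
        if len(sub) and sub.mean() >= min_fraction:
            return day
    return UNDETECTED


def _u_null_counts(n: int, m: int) -> np.ndarray:
    """Counts of the exact tie-free null distribution of the U statistic
    for group sizes (n, m): entry u holds the number of the C(n+m, n)
    labelings with U_A = u.  Classic recurrence
    c(n, m, u) = c(n-1, m, u-m) + c(n, m-1, u)."""
    max_u = n * m
    prev = [np.zeros(max_u + 1, dtype=float) for _ in range(m + 1)]
    for mm in range(m + 1):
        prev[mm][0] = 1.0  # n = 0: U is always 0
    for nn in range(1, n + 1):
        cur = [np.zeros(max_u + 1, dtype=float) for _ in range(m + 1)]
        cur[0][0] = 1.0
        for mm in range(1, m + 1):
            cur[mm][mm:] += prev[mm][:max_u + 1 - mm]
            cur[mm] += cur[mm - 1]
        prev = cur
    return prev[m]


def mann_whitney_exact(group_a, group_b) -> tuple[float, float]:
    """Two-sided Mann-Whitney test; returns (U, p) with U = min(U_A, U_B).

    The p-value is exact (twice the lower tail of the enumerated U null
    distribution, capped at 1) when ``min(nA, nB) <= 8`` and there are no
    ties across the pooled sample; otherwise the normal approximation with
    tie correction and continuity correction is used.  Identical constant
    groups give p = 1.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise InvalidParameterError("both groups must be non-empty")
    n, m = a.size, b.size
    pooled = np.concatenate([a, b])
    ranks = rankdata(pooled)
    u_a = float(ranks[:n].sum()) - n * (n + 1) / 2.0
    u_b = n * m - u_a
    u = min(u_a, u_b)
    has_ties = np.unique(pooled).size < pooled.size

    if min(n, m) <= EXACT_LIMIT and not has_ties:
        counts = _u_null_counts(n, m)
        total = counts.sum()
        p = 2.0 * counts[: int(round(u)) + 1].sum() / total
        return u, min(1.0, p)

    mu = n * m / 2.0
    _, tie_counts = np.unique(pooled, return_counts=True)
    N = n + m
    tie_term = float(((tie_counts ** 3 - tie_counts).sum())) / (N * (N - 1))
    var = n * m / 12.0 * ((N + 1) - tie_term)
    if var <= 0:
        return u, 1.0  # all observations tied
    z = (u - mu + 0.5) / np.sqrt(var)  # continuity correction, lower tail
    p = 2.0 * norm.cdf(z)
    return u, float(min(1.0, p))


def significance_stars(p: float) -> str:
    """Asterisk tier for a p-value: * / ** / *** / **** below
    0.05 / 0.01 / 0.001 / 0.0001; 'ns' otherwise."""
    for threshold, stars in STAR_THRESHOLDS:
        if p < threshold:
            return stars
    return "ns"


def compare_to_control(fc: pd.DataFrame,
                       exclude_outliers: bool = True) -> pd.DataFrame:
    """Per gene x day Mann-Whitney comparison of delta-Ct values against
    the gene's control group, after optional single-pass per-group 2-SD
    exclusion; returns gene, day, U, p and the star annotation."""
    rows = []
    for gene, g in fc.groupby("gene", sort=True):
        control_day = g["control_day"].iloc[0]
        groups = {}
        for day, sub in g.groupby("day"):
            v = sub["dCt"].to_numpy()
            if exclude_outliers and v.size >= 3:
                v = exclude_outliers_2sd(v)
            groups[day] = v
        ctrl = groups[control_day]
        for day in sorted(groups):
            if day == control_day:
                continue
            u, p = mann_whitney_exact(groups[day], ctrl)
            rows.append({"gene": gene, "day": day,
                         "control_day": control_day, "U": u, "p": p,
                         "stars": significance_stars(p)})
    return pd.DataFrame(rows)
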