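"""End-to-end orchestration: fixture generation, the four analysis stages,
and report tables.

``make_fixture`` writes a complete seeded synthetic dataset (indentation
curves for cell-seeded and no-cell arms, a Ct table, angle / diameter /
density CSVs); ``run_all`` consumes such a bundle and produces the per-day
report tables (diameters, angles, moduli with CDFs, relaxation, fold
changes with significance stars, densities) plus a machine-readable run
manifest.  Both are pure functions of (config, seed): rerunning with the
same config yields byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import glob as globmod
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .curve_io import read_force_record, segment_phases, write_force_record
from .errors import StageError
from .mechanics import construct_modulus, detect_contact_point, modulus_cdf
from .morphology import (cell_density, compare_regions, geometry_summary,
                         mean_angles_by_day)
from .qpcr import (compare_to_control, delta_ct, first_detection_day,
                   fold_change_ddct, summarise_folds, UNDETECTED)
from .relaxation import relaxation_percentage
from . import synthetic
from .synthetic import (ProbeConfig, SLSMaterial, simulate_ct_table,
                        simulate_density, simulate_diameters,
                        simulate_elastic_curve, simulate_orientations,
                        simulate_relaxation_record)

#: culture days with mechanics measurements
MECHANICS_DAYS = (0, 7, 14, 21)

#: fixture per-day median moduli (Pa); printed endpoints 1.3 and 9.2 kPa,
#: intermediate days follow the reported twofold-per-week progression
MODULUS_BY_DAY = {0: 1300.0, 7: 2500.0, 14: 4800.0, 21: 9200.0}
NOCELL_MODULUS = 400.0

#: fixture per-day relaxation percentages; printed endpoints 35% and 24%
RELAX_BY_DAY = {0: 35.0, 7: 31.0, 14: 27.0, 21: 24.0}
NOCELL_RELAX_BY_DAY = {0: 23.0, 7: 15.0, 14: 15.0, 21: 15.0}

#: fixture orientation dispersion (deg) decreasing with culture time
DISPERSION_BY_DAY = {0: 40.0, 2: 32.0, 4: 25.0, 7: 18.0, 14: 12.0, 21: 8.0}

#: fixture log2 expression trajectories vs each gene's control day (NaN =
#: not expressed); shapes follow the reported qualitative time courses
DAY_EFFECTS = {
    "COL1A1": {0: 0.0, 2: 0.5, 4: 1.0, 7: 1.5, 14: 1.2, 21: 1.0},
    "SCX": {0: 0.0, 2: 0.3, 4: 0.5, 7: 0.7, 14: 0.7, 21: 0.2},
    "MKX": {0: math.nan, 2: math.nan, 4: 0.0, 7: 0.8, 14: 1.5, 21: 2.0},
    "THBS2": {0: 0.0, 2: 0.5, 4: 1.0, 7: 1.8, 14: 2.2, 21: 2.5},
    "DCN": {0: 0.0, 2: 0.4, 4: 0.9, 7: 1.5, 14: 2.0, 21: 2.3},
    "LOX": {0: 0.0, 2: 0.3, 4: 0.7, 7: 1.2, 14: 1.6, 21: 2.0},
}

#: fixture qPCR per-day replicate counts (the study's printed ns)
QPCR_NS = {0: 29, 2: 19, 4: 18, 7: 25, 14: 17, 21: 16}


@dataclass
class PipelineConfig:
    """Declarative configuration for fixture generation and analysis.

    Every paper-gap default (probe geometry, detection cutoff, control-day
    rule, plateau tolerance) surfaces here and can be overridden from the
    YAML config file.
    """

    seed: int = 0
    outdir: str = "tenomech_out"
    # probe defaults
    R_tip_um: float = 37.5
    k_cant: float = 0.5
    speed_um_s: float = 10.0
    rate_hz: float = 1000.0
    noise_sd_nN: float = 0.0
    # fixture sizing
    n_constructs: int = 3
    sites_per_construct: int = 5
    # qPCR rules
    reference_gene: str = synthetic.REFERENCE_GENE
    detection_cutoff: float = synthetic.DETECTION_CUTOFF
    control_day_rule: str = "first_detection"  # or "day0"
    ct_noise_sd: float = 0.25
    # input locations (set by make_fixture or by the user)
    curves_glob: str = ""
    ct_csv: str = ""
    angles_csv: str = ""
    geometry_csv: str = ""
    density_csv: str = ""

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise StageError(f"config: unknown keys {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)


def make_fixture(config: PipelineConfig, outdir=None) -> PipelineConfig:
    """Write a complete synthetic input bundle under ``outdir/fixture`` and
    return a config whose input paths point at it.

    Curves are written for Days 0/7/14/21, both arms (cell-seeded,
    no-cell), ``n_constructs`` constructs x ``sites_per_construct`` sites,
    one elastic indentation and one 10 s relaxation hold each.
    """
    outdir = Path(outdir if outdir is not None else config.outdir)
    fixdir = outdir / "fixture"
    curvedir = fixdir / "curves"
    curvedir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)

    arms = (("hasc", MODULUS_BY_DAY, RELAX_BY_DAY),
            ("nocell", {d: NOCELL_MODULUS for d in MECHANICS_DAYS},
             NOCELL_RELAX_BY_DAY))
    for arm, mod_by_day, relax_by_day in arms:
        for day in MECHANICS_DAYS:
            for c in range(config.n_constructs):
                for s in range(config.sites_per_construct):
                    seed = int(rng.integers(0, 2**31 - 1))
                    # site-to-site modulus scatter, lognormal 15%
                    E = mod_by_day[day] * float(
                        np.exp(rng.normal(0.0, 0.15)))
                    probe = ProbeConfig(
                        R_tip=config.R_tip_um, k_cant=config.k_cant,
                        speed=config.speed_um_s, rate=config.rate_hz,
                        noise_sd=config.noise_sd_nN, seed=seed)
                    label = f"{arm}_d{day:02d}_c{c + 1:02d}_s{s + 1}"
                    rec = simulate_elastic_curve(E, probe, label=label)
                    write_force_record(rec, curvedir / f"{label}_indent.tsv")
                    mat = SLSMaterial.from_relaxation(
                        relax_by_day[day], tau=2.0, E0=E)
                    rec = simulate_relaxation_record(
                        mat, probe, label=label)
                    write_force_record(rec, curvedir / f"{label}_relax.tsv")

    ct = simulate_ct_table(
        DAY_EFFECTS, n_reps=QPCR_NS, noise_sd=config.ct_noise_sd,
        seed=config.seed, reference_gene=config.reference_gene,
        detection_cutoff=config.detection_cutoff)
    ct.to_csv(fixdir / "ct.csv", index=False)

    simulate_orientations(
        DISPERSION_BY_DAY, n_constructs=config.n_constructs,
        seed=config.seed).to_csv(fixdir / "angles.csv", index=False)
    simulate_diameters(seed=config.seed).to_csv(
        fixdir / "geometry.csv", index=False)
    simulate_density(seed=config.seed).to_csv(
        fixdir / "density.csv", index=False)

    return dataclasses.replace(
        config,
        curves_glob=str(curvedir / "*.tsv"),
        ct_csv=str(fixdir / "ct.csv"),
        angles_csv=str(fixdir / "angles.csv"),
        geometry_csv=str(fixdir / "geometry.csv"),
        density_csv=str(fixdir / "density.csv"),
    )


def _parse_label(label: str) -> tuple[str, int, str]:
    """arm_dXX_cYY_sZ -> (arm, day, construct id)."""
    parts = label.split("_")
    arm = parts[0]
    day = int(parts[1][1:])
    construct = f"{arm}_{parts[1]}_{parts[2]}"
    return arm, day, construct


def run_mechanics(config: PipelineConfig) -> dict[str, pd.DataFrame]:
    """Fit every ``*_indent.tsv`` curve, aggregate per construct and per
    day, and build the per-arm modulus CDF tables."""
    paths = sorted(p for p in globmod.glob(config.curves_glob)
                   if p.endswith("_indent.tsv"))
    if not paths:
        raise StageError(f"mechanics: no indentation curves match "
                         f"{config.curves_glob!r}")
    rows = []
    for path in paths:
        rec = read_force_record(path)
        seg = segment_phases(rec)
        fit = detect_contact_point(seg)
        arm, day, construct = _parse_label(rec.meta.get("label", Path(path).stem))
        rows.append({"arm": arm, "day": day, "construct_id": construct,
                     "label": rec.meta.get("label", ""),
                     "z_contact_um": fit.z_contact, "E_eff_Pa": fit.E_eff,
                     "rmse_uN": fit.rmse, "n_points": fit.n_points})
    indents = pd.DataFrame(rows)

    constructs = []
    for (arm, day, cid), g in indents.groupby(["arm", "day", "construct_id"]):
        cm = construct_modulus(list(g["E_eff_Pa"]), cid, day,
                               expected_sites=len(g))
        constructs.append({"arm": arm, "day": day, "construct_id": cid,
                           "mean_E_Pa": cm.mean_E, "n_sites": len(g)})
    per_construct = pd.DataFrame(constructs)

    cdf_rows = []
    for (arm, day), g in per_construct.groupby(["arm", "day"]):
        v, p = modulus_cdf(g["mean_E_Pa"])
        cdf_rows += [{"arm": arm, "day": day, "E_eff_Pa": vi, "cdf": pi}
                     for vi, pi in zip(v, p)]
    return {"indents": indents, "moduli": per_construct,
            "moduli_cdf": pd.DataFrame(cdf_rows)}


def run_relaxation(config: PipelineConfig) -> dict[str, pd.DataFrame]:
    """Compute r_relax for every ``*_relax.tsv`` curve and aggregate."""
    paths = sorted(p for p in globmod.glob(config.curves_glob)
                   if p.endswith("_relax.tsv"))
    if not paths:
        raise StageError(f"relax: no relaxation curves match "
                         f"{config.curves_glob!r}")
    rows = []
    for path in paths:
        rec = read_force_record(path)
        seg = segment_phases(rec)
        stat = relaxation_percentage(seg)
        arm, day, construct = _parse_label(rec.meta.get("label", Path(path).stem))
        rows.append({"arm": arm, "day": day, "construct_id": construct,
                     "F_max_uN": stat.F_max, "F_10s_uN": stat.F_10s,
                     "r_relax_pct": stat.r_relax})
    per_site = pd.DataFrame(rows)
    per_construct = (per_site
                     .groupby(["arm", "day", "construct_id"], as_index=False)
                     .agg(r_relax_pct=("r_relax_pct", "mean"),
                          n_sites=("r_relax_pct", "size")))
    return {"relaxation_sites": per_site, "relaxation": per_construct}


def run_qpcr(config: PipelineConfig) -> dict[str, pd.DataFrame]:
    """Full ddCt quantification of a Ct table: normalise to the reference
    gene, pick each gene's control day (Day 0 or first detection), compute
    fold changes and Mann-Whitney comparisons with stars."""
    ct = pd.read_csv(config.ct_csv)
    if "detected" not in ct.columns:
        ct["detected"] = ct["Ct"] < config.detection_cutoff
    genes = [g for g in ct["gene"].unique() if g != config.reference_gene]
    control_days = {}
    for gene in genes:
        if config.control_day_rule == "day0":
            control_days[gene] = 0
        else:
            day = first_detection_day(ct, gene)
            if day == UNDETECTED:
                continue  # never detected: nothing to quantify
            control_days[gene] = day
    detected = ct[(ct["gene"] == config.reference_gene)
                  | (ct["gene"].isin(control_days) & ct["detected"])]
    dct = delta_ct(detected, config.reference_gene)
    fc = fold_change_ddct(dct, control_days)
    return {"fold_changes": fc, "fold_summary": summarise_folds(fc),
            "qpcr_tests": compare_to_control(fc)}


def run_morphology(config: PipelineConfig) -> dict[str, pd.DataFrame]:
    """Diameter/area/volume summaries, per-construct mean angles, and
    centre-vs-periphery density comparisons."""
    geometry = pd.read_csv(config.geometry_csv)
    angles = pd.read_csv(config.angles_csv)
    density = cell_density(pd.read_csv(config.density_csv))
    return {"geometry": geometry_summary(geometry),
            "angles": mean_angles_by_day(angles),
            "density": density,
            "density_tests": compare_regions(density)}


_STAGES = (("mechanics", run_mechanics), ("relax", run_relaxation),
           ("qpcr", run_qpcr), ("morpho", run_morphology))


def run_all(config: PipelineConfig, outdir=None) -> dict[str, pd.DataFrame]:
    """Run all four stages and write every table as CSV plus a manifest.

    A stage failure raises :class:`StageError` naming the stage and removes
    any partially written outputs.
    """
    outdir = Path(outdir if outdir is not None else config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    tables: dict[str, pd.DataFrame] = {}
    written: list[Path] = []
    try:
        for name, stage in _STAGES:
            try:
                tables.update(stage(config))
            except StageError:
                raise
            except Exception as exc:
                raise StageError(f"{name}: {exc}") from exc
        for key, df in tables.items():
            path = outdir / f"{key}.csv"
            with open(path, "w") as fh:
                fh.write(f"# seed: {config.seed}\n")
                df.to_csv(fh, index=False)
            written.append(path)
        manifest = {
            "tenomech_version": __version__,
            "seed": config.seed,
            "config": dataclasses.asdict(config),
            "inputs": {"curves_glob": config.curves_glob,
                       "ct_csv": config.ct_csv,
                       "angles_csv": config.angles_csv,
                       "geometry_csv": config.geometry_csv,
                       "density_csv": config.density_csv},
            "tables": sorted(t.name for t in written),
        }
        mpath = outdir / "manifest.json"
        with open(mpath, "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
            fh.write("\n")
        written.append(mpath)
    except Exception:
        for path in written:
            path.unlink(missing_ok=True)
        raise
    return tables


__all__ = [
    "PipelineConfig", "make_fixture", "run_all", "run_mechanics",
    "run_relaxation", "run_qpcr", "run_morphology",
]
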