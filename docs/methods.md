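# Methods

This note records the models behind `tenomech`, the defaults it ships,
and the choices made where the underlying measurement protocols leave the
analysis under-determined.

## Indentation model

A spherical tip (radius `R_tip`, 25–50 µm: bead diameters of 50–100 µm)
mounted on a cantilever of stiffness `k_cant` is driven into the sample
by moving the cantilever base at constant speed (default 10 µm/s). The
measured force and base position are relative quantities; the contact
mechanics lives in the indentation

    h = (z − z_contact) − F / k_cant,

i.e. base travel past the surface minus cantilever deflection. In
contact, force follows the Hertz relation for a sphere on an elastic
half-space,

    F = (4/3) · E_eff · √R_tip · h^(3/2).

`E_eff` is the *effective* modulus: the `1/(1 − ν²)` Poisson factor is
absorbed into it, which is the quantity soft-tissue nanoindenters report.
A conversion helper (`young_from_effective`) exists for users who want to
assume a Poisson ratio; it is never applied implicitly.

The model is linear in `E_eff`, so the least-squares estimator over the
fit window is closed form, `E_eff = Σ F·g / Σ g²` with
`g = (4/3)√R·h^{3/2}`. A test verifies it agrees with iterative nonlinear
least squares to 1e−6 relative on noiseless data.

### Fit window

The fit uses the first micron of *indentation* (0 ≤ h ≤ 1 µm), not piezo
travel. Hertzian theory is a small-strain contact model; for beads of
25–50 µm radius a 1 µm indentation stays in its validity range while
averaging over a few cells' worth of material. Curves whose maximum
indentation falls in [0.8, 1) µm are fitted over the available range with
a warning; below 0.8 µm they are rejected (`InsufficientDepthError`)
rather than extrapolated.

### Contact-point detection

The contact point is not observable directly; it is estimated by grid
search at 10 nm resolution (the piezo-resolution scale) over the loading
phase. For each candidate position the pre-contact mean force is
subtracted as baseline, the indentation is formed, and `E_eff` is fitted
over the 1 µm window. The candidate is scored by the residual of the full
loading-curve model — zero force before contact, the fitted Hertz branch
after, extrapolated beyond the window — and the minimum-score candidate
wins, ties breaking to the smaller position. Scoring on the *whole* curve
rather than the window alone is deliberate: a window that sits entirely
in the pre-contact baseline fits trivially (E ≈ 0, residual ≈ noise), and
on truncated records an early candidate can manufacture apparent depth;
both degeneracies are exposed only by the samples outside the candidate's
window. The trade-off is an assumption that the material stays Hertzian
somewhat past 1 µm; for strongly depth-hardening samples the deep tail
would down-weight the true contact point, which is why the maximum
simulated depth defaults to a modest 2 µm.

Two error paths guard the search: if the late-loading mean force does not
rise 3 baseline-SDs above the early-loading mean, the tip never touched
the sample (`NoContactError`) — the late/early *mean* comparison is used
instead of a literal any-sample threshold because the maximum of ~10³
noise samples routinely exceeds 3σ. If no candidate leaves ≥ 0.8 µm of
indentation, the record is too shallow (`InsufficientDepthError`). A
best candidate that only reaches a partial window is returned with a
warning.

Noiseless simulated curves are recovered to the grid resolution and < 1 %
in modulus across 0.1–100 kPa; with 1 nN force noise on a 1.3 kPa curve
the contact point is recovered within 0.2 µm.

## Stress relaxation

During the hold the base is fixed and the force decays from its peak; the
statistic is `r_relax = 100·(F_max − F_t=10s)/F_max`. `F_max` is the
maximum force within ±0.1 s of hold onset (the peak sits at the end of
the loading ramp; a small window absorbs segmentation jitter), and
`F_t=10s` is linearly interpolated at exactly 10 s after onset. A
±0.25 s averaging window for `F_t=10s` is available behind a flag for
noisy data; it is off by default because the instantaneous value is the
defined quantity. Note that with heavy force noise the max-based `F_max`
is biased upward (extreme-value bias over the peak window), inflating
`r_relax`; the smoothing flag does not correct this, and deliberately so —
smoothing across the ramp→hold kink distorts the peak worse than the
bias it removes. Negative percentages (upward creep) are reported with a
warning, never clipped: visible QC beats silent truncation.

### Standard-linear-solid simulation

The simulator's material is a standard linear solid: instantaneous
modulus `E0`, long-time modulus `E_inf` (ratio α = E_inf/E0 ∈ (0, 1]) and
relaxation time τ. Two hold modes are provided:

* **rigid** (default): the base is frozen and the hold force follows the
  closed form `F(t) = F_max·(α + (1−α)e^{−t/τ})`, so the 10 s ratio is
  analytically `100·(1−α)(1−e^{−10/τ})`. This mode separates pipeline
  correctness from physics fidelity: every relaxation test has an exact
  expected value.
* **coupled**: the open-loop constraint is honoured — the base is fixed
  but the tip creeps forward as force decays through the cantilever
  compliance. The SLS contact force is propagated through the hereditary
  integral `F = (4/3)√R·[E_inf·w + (E0−E_inf)·q]`, `w = h^{3/2}`,
  `q(t) = ∫ e^{−(t−s)/τ} dw(s)`, with an exponential per-step update for
  `q` and a damped fixed-point solve of the compliance coupling per
  sample. Coupled holds relax less than rigid ones (the creeping tip
  partially re-loads the contact), which the tests assert as an ordering.

`SLSMaterial.from_relaxation` inverts the rigid-hold closed form so a
target percentage (e.g. the 35 % / 24 % / 23 % construct values) maps to
an (α, τ = 2 s) pair; τ = 2 s places ~99 % of the decay inside the 10 s
hold, matching holds that visually plateau by 10 s.

The loading ramp is simulated as elastic at `E0` (self-consistently with
cantilever deflection, solved per sample by bracketed root finding). The
default cantilever stiffness of 0.5 N/m is typical for optical-fibre
nanoindenters probing kPa-scale samples and is recorded in every file
header so the analysis never assumes it.

## File format and phase segmentation

Records are plain TSV with a `# key: value` metadata header (`k_cant`,
`R_tip`, `rate`, optional `label`) and columns `time_s`, `base_um`,
`force_uN`. Floats are written with 17 significant digits, making the
write→read round trip bit-identical; units are fixed in the file and all
mechanics converts to SI internally.

Phases are segmented from the base-position profile only, so force noise
cannot move a boundary: loading is the first monotone advance, the hold
is a subsequent plateau (samples within 5 nm of the plateau median — the
piezo resolution scale, configurable), unloading a following monotone
retreat. The sample at the ramp peak is assigned to the hold when one
exists, so hold onset coincides with the force peak and the 10 s clock
starts there.

## qPCR quantification

ΔCt is `Ct_gene − Ct_YWHAZ` within each sample; ΔΔCt subtracts the
*control-group mean* ΔCt, so the control group's summary fold change
`2^−mean(ΔΔCt)` is exactly 1 (the summary is computed from group-mean
ΔCt differences so this identity holds in floating point, not just in
expectation). The control group is Day 0, or the first detection day for
genes not expressed at Day 0 — detection meaning Ct below the cutoff
(default 35 cycles, configurable; undetected wells are stored at the
cutoff with a `detected=False` flag) in at least half the replicates.

Outlier exclusion is a single pass per gene × day group on ΔCt values:
drop anything beyond 2 sample-SDs of the group mean, never iterated
(iterating the rule over-trims). Group comparisons use the two-sided
Mann–Whitney test: exact, by dynamic-programming enumeration of the U
null distribution, whenever the smaller group has ≤ 8 observations and
the pooled sample is tie-free; otherwise the normal approximation with
tie and continuity corrections. The exact branch is property-tested
against brute-force enumeration of all group labelings and against an
independent library implementation. Significance tiers *, **, ***, ****
at p < 0.05, 0.01, 0.001, 0.0001; no multiple-testing correction is
applied, faithful to the source analysis.

## Morphology

Cell-axis angles use the acute-angle convention: the angle between the
cell's major axis and the construct axis folded to [0°, 90°], insensitive
to vector sign. Per-construct summaries are plain arithmetic means of 15
cells (no circular statistics — the folded domain is half a quadrant and
the reference analysis reports plain means). Cross-sections are circular
(`πd²/4`); the volume fold change between two diameters is `(d0/d1)²`
because the anchor-to-anchor length is fixed. Centre/periphery cell
densities are count/area on pre-labelled regions; the region boundary is
an input annotation, not computed here, because the peripheral layer
("three to four cells deep") has no pixel-level definition.

## Synthetic-data defaults

The generators default to the study's own conditions wherever those are
printed, and to field-typical values elsewhere:

* Diameters: Gaussian, truncated at zero, per-day means/SDs
  2.08±0.08, 0.67±0.02, 0.59±0.02, 0.55±0.04 mm (Days 0/7/14/21) with
  n = 11/15/14/19; no-cell arm constant at ≈4.46±0.48 mm.
* Moduli: per-day medians 1.3 / 2.5 / 4.8 / 9.2 kPa — printed endpoints
  with the reported twofold-per-week progression filling Days 7 and 14 —
  and 0.4 kPa flat for the no-cell arm; site-to-site scatter is lognormal
  with σ = 0.15.
* Relaxation: 35 / 31 / 27 / 24 % (linear fill between printed
  endpoints); no-cell 23 % at Day 0 dropping to 15 %.
* qPCR: per-day replicate counts 29/19/18/25/17/16 (Days 0/2/4/7/14/21),
  reference gene centred at Ct 20, gene baselines at Ct 26, noise
  0.25 cycles. The bundled log2 trajectories reproduce the qualitative
  dynamics of the profiled genes (e.g. COL1A1 rising to Day 7 and
  plateauing; MKX undetected before Day 4 then rising), since absolute
  levels are not printed.
* Orientations: folded-normal angles with per-day dispersion
  40/32/25/18/12/8°, emulating progressive alignment; a uniform option
  provides the fully unaligned limit (mean 45°).
* Densities: Poisson counts with periphery at twice the centre density
  over 0.02 mm² regions.

What the generators do *not* emulate: adhesion and substrate (bottom)
effects in indentation, force drift, amplification-efficiency differences
between primers, inter-donor variability structure, and any image-level
realism (orientations are angle tables, not pictures). Passing tests
therefore demonstrate that the analysis recovers known ground truth under
the stated statistical model, not that it is robust to every artefact of
real instruments.

## Problem sizes and determinism

Default simulated records sample at 1 kHz (≈700 samples per elastic
curve, ≈12,000 per 10 s relaxation record); the bundled fixture writes
2 arms × 4 days × 3 constructs × 5 sites of each curve type in a few
seconds. Every generator is a pure function of (parameters, seed):
identical seeds give bit-identical records, tables and report files, and
the pipeline manifest records the seed and full config of each run.

## Known limitations

* The Hertz fit assumes a homogeneous, isotropic, semi-infinite elastic
  sample; thin or layered constructs violate this and no bottom-effect
  correction is applied.
* The contact-point score extrapolates the Hertz branch past the fit
  window (see above); strongly nonlinear materials would need a
  window-limited score plus an independent depth guard.
* `F_max` from noisy records carries extreme-value bias; heavy-noise use
  should average replicate holds rather than trust single records.
* The exact Mann–Whitney branch requires tie-free data; tied small
  samples fall back to the tie-corrected normal approximation, which is
  anticonservative at very small n.
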