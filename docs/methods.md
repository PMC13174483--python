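# Methods

## Model structure and assumptions

The simulator couples two deterministic ODE subsystems.

**Coagulation subsystem.** A tissue-factor (TF) initiated extrinsic cascade
in the Hockin–Mann mass-action formulation: 34 species, 43 elementary
reactions with molecularity ≤ 2, and 42 distinct rate constants, shipped
with per-constant provenance in `src/thrombogen/data/coagulation_rates.yaml`.
The network covers TF·VII(a) assembly, extrinsic activation of factors IX
and X, intrinsic tenase (IXa·VIIIa) and prothrombinase (Xa·Va), VIIIa
A2-domain dissociation, TFPI inhibition of Xa and of the TF·VIIa·Xa
initiation complex, and irreversible ATIII inhibition of Xa, IXa, mIIa, IIa
and TF·VIIa. Mean plasma initial conditions follow the same source
(VII 10 nM, VIIa 0.1 nM, X 160 nM, IX 90 nM, II 1.4 µM, VIII 0.7 nM,
V 20 nM, TFPI 2.5 nM, ATIII 3.4 µM). Two conservation groups — total TF
across its complexes and total prothrombin-derived mass — are declared in
the model and verified both symbolically (stoichiometry) and numerically
(relative drift < 1e-6 on every shipped scenario; measured ~1e-15). The
protein C/thrombomodulin pathway, platelet surfaces, and fibrin(ogen) are
outside the cascade, as in the source framework.

*Total thrombin* is IIa + w·mIIa with w = 1.2, the conventional weighting
for meizothrombin's partial procoagulant activity; w is configurable.
Note that in this cascade the meizothrombin transient is large, so the
weighted readout can be dominated by mIIa early in the burst.

**Inflammation subsystem.** IL-6, IL-1β and TNF-α each follow
dC/dt = p·m(E) − k·C. The degradation rate k = ln2 / t½ comes directly
from plasma half-lives: 3600 s for IL-6 and IL-1β, 276 s (4.6 min) for
TNF-α. The basal production p = k·C₀ is fixed by a steady-state constraint
so that, unstimulated, each cytokine rests exactly at its normal plasma
baseline — perturbations then reflect disease, not initialization
artifacts. m(E) = 1 + emax·Eⁿ/(EC50ⁿ + Eⁿ) is a Hill multiplier in the
thrombin exposure E of the preceding coagulation phase; it applies to IL-6
and TNF-α (emax 4, EC50 1e-7 M, n 1 by default, giving roughly 2–5-fold
induction across the physiological exposure range) and is off (emax 0) for
IL-1β by default, configurable. Receptor-level signaling (PAR-1/NF-κB) is
deliberately not resolved; the laws are phenomenological input–output
relationships.

**Baselines.** Normal plasma cytokine levels are not authoritative
constants; the defaults are IL-6 2 pg/ml, TNF-α 2 pg/ml, IL-1β 0.1 pg/ml
(healthy high-sensitivity-assay medians, converted at 21/17/17 kDa). Two
constraints anchored the choice: (i) every package behaviour is expressed
relative to baseline, never in absolute pg/ml, and (ii) mildly inflamed
disease states in the shipped table (e.g. type 2 diabetes at IL-6
2.3–5.6 pg/ml) must sit *above* the healthy baseline for their inflammation
to register at all.

**Coupling laws.** Cytokine *excess* x = max(C − C₀, 0) drives all
coupling, which makes homeostasis exactly neutral by construction (a
baseline inflammation phase reproduces the unmodulated coagulation run
bit-for-bit). Three channels:

| channel | form | defaults |
|---|---|---|
| TF induction (per cytokine) | vmax·xⁿ/(EC50ⁿ+xⁿ), integrated over the phase with first-order clearance of induced TF (t½ 6 h) | IL-6: vmax 4e-15 M/s, EC50 60×C₀, n 3 · TNF-α: 1e-15, 60×C₀, 3 · IL-1β: 3e-16, 60×C₀, 3 |
| ATIII availability | 1 − smax·x̄ⁿ/(EC50ⁿ+x̄ⁿ) at the phase's time-averaged IL-6 excess, applied to ATIII(0) | smax 0.5, EC50 8×C₀, n 3 |
| TFPI availability | same, driven by time-averaged TNF-α excess, applied to TFPI(0) | smax 0.3, EC50 0.5×C₀, n 2 |

Suppression scales initial anticoagulant concentrations rather than rate
constants — the simplest mechanism consistent with reduced anticoagulant
availability; whether the biological route is reduced production or
enhanced clearance is left open. The experimental dose–response values
behind these couplings are not published numerically, so the defaults were
calibrated once against the model's qualitative dose-dependence
requirements — near-neutrality at ≤2× cytokines, steep amplification
between 10× and 50× (the hyperinflammatory tipping point), disease-cohort
orderings, and strict multi-cycle amplification — and are documented as
re-fittable: `fit_hill` (and the `fit-coupling` CLI) least-squares fits a
Hill block to any user-supplied digitized two-column CSV. IL-6 carries the
largest induction capacity, consistent with its dominant PRCC ranking among
the cytokines.

**Two-phase scheduler.** Coagulation completes in seconds-to-minutes while
cytokine-driven factor modulation evolves over hours, so the subsystems are
never co-integrated on one clock. An inflammation phase (12 h default, 24 h
preset) runs at the patient's cytokine levels; its trajectory is condensed
into an `InflammatoryModulation` (induced TF added to the trigger,
ATIII/TFPI scales); a 1,200 s coagulation phase (5 pM TF default) runs from
the modulated initial state. Across cycles, coagulation factors are
restored to the patient's values (defined computational baseline) while
cytokine state persists and the cycle's *thrombin exposure* feeds the next
inflammation phase. The exposure metric is not uniquely defined by the
protocol's description; the default is the cycle's ETP rescaled by a gain
of 1/600 s⁻¹ (≈ mean thrombin over a 10-minute window) into the feedback
Hill's concentration units, with raw peak selectable. Cycle 1 starts cold
(zero exposure). "Sustained" inflammation clamps cytokines from below at
their starting levels (elementwise max after integration) so unresolved
stimulation never relaxes away, while thrombin feedback can still push
levels above the floor; free-running relaxation is the default elsewhere.
Dose scans multiply all cytokines jointly, with the IL-1β multiplier capped
at 10× (clinical reporting ceiling).

## Virtual patients

`data/disease_table.yaml` encodes per-disease clinical ranges with explicit
resolution rules: percent-of-reference → uniform bands; mean ± SD →
normal truncated at mean ± 3 SD and clipped at 0 (cells quoting "±k%" are
read as SD = k% of the mean); "< 1%" → uniform (0, 1%] of the Normal
reference; ranges spanning ≥ 2 decades (COVID-19 IL-6 1–32,768 pg/ml,
TNF-α 1–1,000 pg/ml) → log-uniform. Hemophilia-A/Normal cytokines are
unreported and sample as point masses at baseline. Cohorts are drawn by
Latin hypercube stratification (scipy `qmc`): per parameter, exactly one
sample in each of n equal-probability strata; a seed reproduces a cohort
bit-identically, and each patient records disease, index and seed.

Three printed cells required unit reconciliation, flagged in the data file:
ATIII cells print "0.134–0.15 mg/L", three orders of magnitude below any
physiologic antithrombin level (~2.3–3.9 µM), so ATIII rows are anchored to
the model's mean plasma ATIII (3.4 µM) with the printed relative structure
kept (COVID-19 at 89.3% with 15.1% SD); VIIa cells print "0.2 mg/L" (4 nM),
~40× above circulating trace VIIa, so the VIIa reference is 0.005 mg/L
(0.1 nM, the model's plasma value) with printed percent bands kept; the
T2DM TFPI cell (197.56 ± 94.88 pg/ml) is kept as printed even though it
sits far below the 70 ng/ml normal reference, since its unit is unambiguous
— it only affects within-T2DM comparisons.

`calibrate_cohort` narrows the ranges of the three most PRCC-influential
adjustable factors by bisection — keeping the half that moves the worst
off-window median metric toward its window, with direction from the PRCC
sign — until a target fraction of resampled patients satisfies all metric
windows; exhaustion reports failure with per-iteration diagnostics rather
than silently clipping. Experimental TG windows are user-supplied
configuration, not shipped values.

## Sensitivity analysis

PRCC follows the standard LHS–PRCC recipe: rank-transform the design and
output (average ranks on ties), residualize the target column and the
output against all other ranked columns by least squares, and report the
Pearson correlation of the residuals. A stratified dummy column,
disconnected from the model, is appended to every design as a null control;
constant (point-mass) columns report NaN with a warning. Significance
testing is omitted — magnitudes and signs are the deliverable. Failed
simulations are dropped with a count; more than 1% failures aborts the run.

## Thrombin-generation metrics

Peak = curve maximum; TTP = earliest argmax time; ETP = trapezoidal
integral over the simulated horizon (no to-infinity extrapolation); lag =
earliest linearly-interpolated crossing of a threshold — 10% of the
eventual peak by default, or an absolute 2 nM (the common experimental
convention). Both rules ship because the operational definition varies
between laboratories; comparisons across runs with very different peak
amplitudes (e.g. an anticoagulant-dominant run whose burst does not
complete within the horizon) should use the absolute rule, treating a
never-crossed threshold as an unbounded lag. An all-zero curve yields
peak = ETP = 0 with NaN lag/TTP and a warning, not an exception. The
ATIII–IIa transition time is the interpolated 50%-of-final crossing of the
(monotone) complex series.

## Numerical choices

- Stiff BDF integration (`scipy.solve_ivp`) with an analytic dense
  Jacobian assembled from the stoichiometry; rtol 1e-8.
- Absolute tolerance 1e-16 mol/L. An atol near 1e-12 sits at the scale of
  the TF trigger itself (5–25 pM) and measurably degrades pM-scale species
  to ~1% accuracy; at 1e-16 a 10× tolerance refinement changes reported
  concentrations by ~1e-5 relative, comfortably inside the engine's 0.1%
  convergence contract, at no measurable runtime cost.
- Fixed reporting grids: 1 s for coagulation phases, 60 s for inflammation
  phases (resolution vs output size).
- Induced-TF accumulation uses an exact exponential integrator on the
  reporting grid (piecewise-constant midpoint rate); time-averaged excess
  uses the trapezoid rule.
- Cytokine phases integrate with LSODA at rtol 1e-10 / atol 1e-22 (the
  linear system is cheap; homeostasis must hold to < 1e-6 over 24 h).
- TTP tie-break: earliest index of the maximum. Lag interpolation is linear
  between bracketing samples; a flat segment at the threshold takes the
  earlier time.
- Degenerate inputs: zero TF trigger produces a flat (sub-pM) thrombin
  curve; zero-width distributions are point masses and are skipped by both
  the LHS stratification check and range narrowing.

## What the synthetic data does and does not emulate

The cohort generator reproduces the *marginal* clinical ranges of nine
factors and three cytokines per disease. It does not model intra-patient
correlation between factors (each parameter is sampled independently up to
LHS stratification), assay noise, pre-analytical variability, or
longitudinal disease trajectories; hemophilia severity enters only through
the VIII range, not through inhibitor titers. Passing cohort-level checks
therefore demonstrates that the *model plus printed ranges* produce the
published phenotype orderings — hemophilia-A attenuation, SCD's shortened
lag with sub-normal peak (driven by its depleted X and II pools), COVID-19
and T2DM hypercoagulability — not that any individual virtual patient is
clinically realistic. The test fixtures (triangle/logistic curves, toy
networks, monotone PRCC tables) are analytic objects with closed-form
ground truth and exercise the machinery, not the biology.

## Problem sizes

Published cohort analyses use 2,000 patients per disease and 5,000-sample
PRCC designs; both run through the same code paths here (`--n 2000`,
`--n 5000`). The shipped test suite uses scaled designs chosen as a
package default for desk-scale iteration: n = 200 cohorts for the
inflamed-disease comparisons and the PRCC sign structure, and n = 1,000
for the hemophilia/Normal peak ratio, whose value (≈ 0.247) lies close
enough to its 0.25 acceptance threshold that smaller cohorts cannot
resolve it reliably. All scaled runs are deterministic under their fixed
seeds.

## Known limitations

- No fibrin formation, fibrinolysis, platelet mechanics, or spatial clot
  growth: thrombin generation is the terminal readout.
- The inflammatory module carries three cytokines; mediators such as IL-12
  and IFN-γ, implicated in hypercoagulable states, are absent.
- Coupling parameters are qualitative-calibrated defaults, not fits to the
  original cell-stimulation datasets (whose numerical values are
  unpublished); conclusions that depend on absolute induced-TF magnitudes
  should re-fit against laboratory data via `fit_hill`.
- The meizothrombin-weighted thrombin readout inflates low-tenase
  (hemophilia-like) peaks relative to an IIa-only readout; w is exposed
  for sensitivity checks.
- SBML export is not provided; models serialize to a JSON schema.
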