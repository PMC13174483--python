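# thrombogen

A coupled inflammation–coagulation simulator for quantitative systems
pharmacology: it reproduces thrombin-generation (TG) assays in silico and
asks how pro-inflammatory cytokines reshape them.

Inflammation and coagulation feed each other. IL-1β, IL-6 and TNF-α induce
tissue factor (TF) on monocytes and endothelium and suppress the natural
anticoagulants antithrombin III (ATIII, via IL-6) and tissue factor pathway
inhibitor (TFPI, via TNF-α); thrombin (IIa), the cascade's central output,
feeds back by amplifying IL-6 and TNF-α production. `thrombogen` encodes
this loop for researchers in hemostasis modeling who want a reusable,
scriptable alternative to one-off assay simulations: virtual-patient TG
screening, inflammatory dose–response studies, and global sensitivity
analysis of TG metrics.

## The model

**Coagulation.** The TF-initiated extrinsic cascade in the Hockin–Mann
mass-action formulation: 34 species and 43 elementary reactions (molecularity
≤ 2), dC/dt = N·v(C) with v the mass-action rate vector, integrated with a
stiff BDF solver. TF triggers of 5 or 25 pM produce a thrombin burst that is
quenched by TFPI (initiation complex) and ATIII (irreversible serpin
inhibition); the ATIII–IIa complex accumulates sigmoidally and reads out net
thrombin generated. Total thrombin is IIa + 1.2·mIIa (meizothrombin carries
partial activity). All rate constants ship in an editable YAML table.

**Inflammation.** Each cytokine C follows first-order turnover
`dC/dt = p·m(E) − k·C` with `k = ln2 / t½` fixed by reported plasma
half-lives (IL-6, IL-1β ≈ 1 h; TNF-α 4.6 min), `p = k·C₀` calibrated so the
unstimulated system rests exactly at its normal plasma baseline, and `m(E)`
a Hill multiplier in the thrombin exposure E carried over from the previous
coagulation phase.

**Coupling.** Cytokine *excess over baseline* drives saturating Hill laws:
TF induction rates per cytokine (integrated over the inflammation phase with
first-order clearance of the induced pool), plus availability scales
`s(C) = 1 − smax·Cⁿ/(EC50ⁿ + Cⁿ)` applied to ATIII and TFPI initial
concentrations. At exactly baseline cytokines the coupling is exactly
neutral.

**Protocol.** Because the two subsystems live on different clocks (seconds
vs hours), simulations are phase-split: an hours-scale inflammation phase
sets TF/ATIII/TFPI conditions, then a 1,200 s coagulation phase generates
thrombin. Iterating the pair — factors reset between cycles, cytokine state
and thrombin exposure carried forward — reproduces the self-amplifying
thromboinflammatory loop. TG curves are summarized by lag time, time-to-peak
(TTP), peak thrombin, and endogenous thrombin potential (ETP, the curve's
time integral).

**Cohorts and sensitivity.** Disease parameter ranges (COVID-19, sickle
cell disease, type 2 diabetes, hemophilia A, Normal) resolve into bounded
molar distributions sampled by Latin hypercube stratification; LHS–PRCC
(partial rank correlation with a dummy-variable null control) ranks how
factors and cytokines drive each TG metric.

## Worked example

```python
from thrombogen import (PhaseProtocol, atiii_iia_series, normal_patient,
                        run_two_phase, transition_time_50)

patient = normal_patient()                 # mean plasma, baseline cytokines
res = run_two_phase(patient, PhaseProtocol())   # 12 h inflammation, 5 pM TF
print(f"peak {res.metrics.peak*1e9:.1f} nM, lag {res.metrics.lag_time:.0f} s")
traj = res.coagulation_trajectory
print(f"ATIII-IIa 50% crossing at "
      f"{transition_time_50(traj.times, atiii_iia_series(traj)):.0f} s")
```

prints

```
peak 395.2 nM, lag 495 s
ATIII-IIa 50% crossing at 772 s
```

i.e. a ~395 nM thrombin burst whose net-generation marker (ATIII–IIa)
transitions inside the expected 750–1,000 s window. A cytokine dose scan
shows the hyperinflammatory tipping point — final ATIII–IIa (nM) over
multipliers {0.5, 1, 2, 5, 10, 50} comes out as

```
383.30  383.30  383.31  383.52  384.77  480.61
```

flat through mild inflammation (1× vs 2× differ by 0.003%), then jumping
sharply between 10× and 50×. Five sustained inflammation–coagulation cycles
amplify the peak monotonically: 395.2 → 429.8 → 431.4 → 431.40 → 431.41 nM.

The same pipeline is scriptable from the shell:

```bash
thrombogen simulate --scenario baseline25 --outdir out/
thrombogen dose-scan --multipliers 0.5,1,2,5,10,50 --duration 12h
thrombogen cycles --n 5 --duration 12h
thrombogen cohort --disease COVID19 --n 2000 --seed 17 --inflam 12h
thrombogen sensitivity --disease COVID19 --n 5000 --seed 7
```

Every subcommand writes CSV trajectories / metrics plus a manifest (config
hash, seed, package version).

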