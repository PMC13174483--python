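# Clinical ranges of coagulation factors and cytokines for Normal subjects
# and four disease conditions (COVID-19-associated coagulopathy, type 2
# diabetes mellitus, sickle cell disease, hemophilia A), as collected from
# published clinical laboratory studies.
#
# Descriptor kinds:
#   range         - uniform over [low, high]; log: true samples log-uniformly
#                   (used when the printed range spans >= 2 decades)
#   mean_sd       - normal(mean, sd) truncated to mean +/- 3 SD and clipped
#                   at 0; sd_percent gives the SD as percent of the mean
#   percent_range - uniform over [ref*low_pct, ref*high_pct] / 100
#   below_percent - uniform over (0, ref*pct/100]: severe deficiency
#   point         - degenerate (point mass)
#
# Units are as printed in the source studies except where flagged:
#   * ATIII rows as printed (0.134-0.15 "mg/L") are three orders of
#     magnitude below any physiologic antithrombin level (~2.3-3.9 umol/L)
#     and cannot be reconciled to a single mass unit. They are stored in
#     mol/L, anchored to the coagulation model's mean plasma antithrombin
#     (3.4e-6 mol/L) with the printed relative structure kept: the COVID-19
#     mean is 0.134/0.15 = 89.3% of the normal reference with its printed
#     15.1% SD.
#   * VIIa reference is stored as 0.005 mg/L (~0.1 nmol/L), the standard
#     trace level of circulating activated VII and the coagulation model's
#     plasma value; the printed 0.2 mg/L would exceed 1 nmol/L by more than
#     an order of magnitude. Printed percent bands are kept. The T2DM VIIa
#     mean (printed 8.25% above the reference) is scaled onto the same
#     reference.
#
# Cytokine rows for Hemophilia A and Normal are not reported ("-"): those
# cohorts sample cytokines at the configured normal baselines (point mass,
# encoded as kind "baseline").

COVID19:
  IL6:   {kind: range, low: 1.0, high: 32768.0, unit: pg/ml, log: true}
  TNFA:  {kind: range, low: 1.0, high: 1000.0, unit: pg/ml, log: true}
  IL1B:  {kind: range, low: 0.0, high: 32.0, unit: pg/ml}
  VII:   {kind: percent_range, ref: 0.5, low_pct: 55, high_pct: 170, unit: mg/L}
  VIIa:  {kind: percent_range, ref: 0.005, low_pct: 60, high_pct: 130, unit: mg/L}
  IX:    {kind: mean_sd, mean: 7.5, sd_percent: 50.6, unit: mg/L}
  X:     {kind: mean_sd, mean: 11.1, sd_percent: 27.9, unit: mg/L}
  II:    {kind: mean_sd, mean: 107.5, sd_percent: 31.2, unit: mg/L}
  VIII:  {kind: mean_sd, mean: 0.262, sd_percent: 102.9, unit: mg/L}
  V:     {kind: mean_sd, mean: 11.7, sd_percent: 44.9, unit: mg/L}
  TFPI:  {kind: point, value: 70.0, unit: ng/ml}
  ATIII: {kind: mean_sd, mean: 3.037e-6, sd_percent: 15.1, unit: mol/L}

T2DM:
  IL6:   {kind: range, low: 2.3, high: 5.6, unit: pg/ml}
  TNFA:  {kind: range, low: 3.0, high: 5.0, unit: pg/ml}
  IL1B:  {kind: range, low: 0.2, high: 0.3, unit: pg/ml}
  VII:   {kind: percent_range, ref: 0.5, low_pct: 60, high_pct: 130, unit: mg/L}
  VIIa:  {kind: mean_sd, mean: 0.0054125, sd_percent: 26.72, unit: mg/L}
  IX:    {kind: percent_range, ref: 5.0, low_pct: 60, high_pct: 130, unit: mg/L}
  X:     {kind: percent_range, ref: 10.0, low_pct: 60, high_pct: 130, unit: mg/L}
  II:    {kind: percent_range, ref: 100.0, low_pct: 60, high_pct: 130, unit: mg/L}
  VIII:  {kind: percent_range, ref: 0.1, low_pct: 50, high_pct: 150, unit: mg/L}
  V:     {kind: percent_range, ref: 10.0, low_pct: 60, high_pct: 130, unit: mg/L}
  TFPI:  {kind: mean_sd, mean: 197.56, sd: 94.88, unit: pg/ml}
  ATIII: {kind: point, value: 3.4e-6, unit: mol/L}

SCD:
  IL6:   {kind: mean_sd, mean: 60.0, sd: 7.0, unit: pg/ml}
  TNFA:  {kind: mean_sd, mean: 122.3, sd: 16.3, unit: pg/ml}
  IL1B:  {kind: range, low: 0.0, high: 27.26, unit: pg/ml}
  VII:   {kind: mean_sd, mean: 0.31, sd_percent: 7.5, unit: mg/L}
  VIIa:  {kind: percent_range, ref: 0.005, low_pct: 60, high_pct: 130, unit: mg/L}
  IX:    {kind: percent_range, ref: 5.0, low_pct: 60, high_pct: 130, unit: mg/L}
  X:     {kind: mean_sd, mean: 6.6, sd_percent: 10.0, unit: mg/L}
  II:    {kind: mean_sd, mean: 75.0, sd_percent: 10.0, unit: mg/L}
  VIII:  {kind: percent_range, ref: 0.1, low_pct: 50, high_pct: 150, unit: mg/L}
  V:     {kind: mean_sd, mean: 7.25, sd_percent: 17.5, unit: mg/L}
  TFPI:  {kind: point, value: 70.0, unit: ng/ml}
  ATIII: {kind: point, value: 3.4e-6, unit: mol/L}

HemophiliaA:
  IL6:   {kind: baseline}
  TNFA:  {kind: baseline}
  IL1B:  {kind: baseline}
  VII:   {kind: percent_range, ref: 0.5, low_pct: 60, high_pct: 130, unit: mg/L}
  VIIa:  {kind: percent_range, ref: 0.005, low_pct: 60, high_pct: 130, unit: mg/L}
  IX:    {kind: percent_range, ref: 5.0, low_pct: 60, high_pct: 130, unit: mg/L}
  X:     {kind: percent_range, ref: 10.0, low_pct: 60, high_pct: 130, unit: mg/L}
  II:    {kind: percent_range, ref: 100.0, low_pct: 60, high_pct: 130, unit: mg/L}
  VIII:  {kind: below_percent, ref: 0.1, pct: 1.0, unit: mg/L}
  V:     {kind: percent_range, ref: 10.0, low_pct: 60, high_pct: 130, unit: mg/L}
  TFPI:  {kind: point, value: 70.0, unit: ng/ml}
  ATIII: {kind: point, value: 3.4e-6, unit: mol/L}

Normal:
  IL6:   {kind: baseline}
  TNFA:  {kind: baseline}
  IL1B:  {kind: baseline}
  VII:   {kind: percent_range, ref: 0.5, low_pct: 60, high_pct: 130, unit: mg/L}
  VIIa:  {kind: percent_range, ref: 0.005, low_pct: 60, high_pct: 130, unit: mg/L}
  IX:    {kind: percent_range, ref: 5.0, low_pct: 60, high_pct: 130, unit: mg/L}
  X:     {kind: percent_range, ref: 10.0, low_pct: 60, high_pct: 130, unit: mg/L}
  II:    {kind: percent_range, ref: 100.0, low_pct: 60, high_pct: 130, unit: mg/L}
  VIII:  {kind: percent_range, ref: 0.1, low_pct: 50, high_pct: 150, unit: mg/L}
  V:     {kind: percent_range, ref: 10.0, low_pct: 60, high_pct: 130, unit: mg/L}
  TFPI:  {kind: point, value: 70.0, unit: ng/ml}
  ATIII: {kind: point, value: 3.4e-6, unit: mol/L}
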