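# fbt — fluid bolus therapy episode analysis

Fluid boluses are among the most common interventions in intensive care
after cardiac surgery, yet their physiological effect is surprisingly hard
to pin down: boluses are given *because* the patient is doing poorly, so
naive before/after comparisons confound the treatment with its indication.
This package implements a quasi-experimental, target-trial-style analysis
of high-resolution ICU records for that question, aimed at researchers
working with patient-data-management-system exports:

1. **Episode extraction** — a fluid bolus (FB) is >= 250 ml of crystalloid
   in <= 30 min (mean rate >= 500 ml/h), detected from timestamped
   infusion records with grid-aware merging; only *isolated* boluses (no
   other FB within the -60/+60-min observation window) are analysed, and
   no-fluid control epochs of equal duration are sampled from the same
   patients.
2. **Propensity-score matching** — logistic propensity on 30-min
   pre-episode baselines (MAP, SBP, DBP, HR, CO, CVP, vasoactive-inotropic
   score) plus demographics; greedy 1:1 nearest-neighbour matching on
   logit(PS) without replacement within a 0.2-SD caliper; balance reported
   as standardised differences (SDiff < 10% gate).
3. **Trajectory analysis** — per-episode baselines and twelve 5-min bin
   means over the post-bolus hour; per variable a linear mixed model
   `value ~ bolus + time + bolus:time + baseline` with random intercepts
   for patient and episode; responder classification (> 10% above
   baseline) with Pearson chi-squared contrasts; bolus size/rate
   dose-response regressions; Bonferroni control over the 31-test family
   (alpha = 0.0016).

Because ICU EHR data cannot be redistributed, the package ships a
**synthetic-EHR generator** (`fbt.synth`) producing post-cardiac-surgery
cohorts with 2-min autocorrelated vitals, sporadic blood gases, drips,
maintenance fluid, confounding by indication, and — crucially —
*injectable ground-truth bolus-response kernels*, so every stage of the
pipeline is testable: an injected cardiac-output response of +0.2 l/min
peaking 40 min after the bolus must be recovered by the full pipeline,
effect-free cohorts must yield no detections, and matching must remove
the built-in indication bias.

## Worked example

The numbered drivers under `analysis/` run the full study on a simulated
300-patient cohort and write their tables to `results/`:

```bash
python analysis/01_simulate_cohort.py
python analysis/02_extract_and_match.py
python analysis/03_trajectories_and_mixed_models.py
python analysis/04_responders_and_dose_response.py
```

Output of the first two steps (abridged):

```
cohort: 300 patients, 2,505,466 vital-sign rows
median stay 31.6 h; 1422 fluid administrations (83% meet the bolus definition)
administration volume median 356 ml (IQR 182 ml)
episode funnel: {"detected": 1177, "isolated": 927, "window_in_stay": 870,
                 "controls": 1733, "baselines_complete": 1213, "matched_pairs": 406}
balance: worst post-match SDiff 6.1% (PASS at the 10% gate)
```

The funnel mirrors the study design: 1177 detected boluses shrink to 927
isolated ones, 870 with full in-stay windows, and 406 matched pairs; the
pre-match MAP imbalance (SDiff 49%, because low blood pressure triggers
boluses) drops to 2% after matching. Step 3 then prints, for the matched
cohort:

```
variable  coef_bolus  ci_lo_bolus  ci_hi_bolus  p_bolus  significant
      co      0.2097       0.1118       0.3076   0.0000         True
     map      0.7655      -0.1643       1.6953   0.1066        False
      ...
peak CO change after FBT: 0.24 l/min (95% CI 0.14 to 0.35) at 40 min post-bolus
```

i.e. the injected +0.2 l/min cardiac-output response is the only effect
surviving Bonferroni correction, recovered at its true time and size,
while every channel without an injected effect stays null — which is
exactly what a trustworthy pipeline should report.

A command-line interface wraps the same stages end to end:

```bash
fbt run --config demo.yaml --seed 7 --out runs/demo
fbt simulate --seed 7 --out runs/cohort
```

`fbt run` writes all artifact tables plus a manifest with the full
configuration, per-stage seeds, the episode funnel, and a content hash of
every output, so a run is reproducible bit for bit.

## Layout

```
src/fbt/        synth, episodes, derive, match, analyze, pipeline, cli,
                experiments (validation studies)
analysis/       numbered narrative drivers (simulate -> match -> models)
tests/          unit + property tests, brute-force oracles, acceptance suite
scripts/        acceptance.py
docs/methods.md model, parameters, generator scope, design decisions
```
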