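# wristmotion

Wrist-worn accelerometry pipeline for quantifying movement **quantity** and
**quality** in Duchenne muscular dystrophy (DMD) and healthy controls.

DMD causes progressive loss of skeletal muscle function, and clinic-based
instruments (NSAA, QMT, PUL 2.0) are effort-dependent, episodic, and mostly
unusable once a patient stops walking. Wrist accelerometry measures movement
continuously in free living, for ambulatory and non-ambulatory wearers
alike. This package implements the full analysis chain for such data, for
researchers in digital biomarkers and neuromuscular disease:

1. **Raw signal → activity counts** (`wristmotion.counts`): 30 Hz tri-axial
   acceleration in g is converted to vendor-style integer activity counts —
   a narrow band-pass (peak gain 0.759 Hz, −6 dB at 0.212 and 2.148 Hz),
   rectification, dead band, clipping, amplitude quantization, and
   per-epoch summation onto 1 s and 15 s grids, with the per-epoch vector
   magnitude `VM = √(x² + y² + z²)`. A 1 s epoch is *active* when VM ≥ 2.
2. **Counts → ten movement variables** (`wristmotion.metrics`):
   - quantity: total counts, counts per minute (CPM), counts per day;
     median/SD of acceleration over moving seconds (VM > 0); peak
     acceleration;
   - quality, computed per calendar day and averaged:
     **sample entropy** SampEn(m, r) = −ln(A/B) of the 1 Hz VM series in
     the hour of highest activity (regularity);
     **jerk** = mean |Δa| · f_s of the 0.2–12 Hz band-passed acceleration
     magnitude, in g/s (smoothness);
     **mean / SD frequency** = power-weighted moments of the spectral
     density, f̄ = Σ f·S(f) / Σ S(f) (order of movement).
3. **Variables → cohort statistics** (`wristmotion.stats`): Kruskal–Wallis
   tests with Benjamini–Hochberg correction across healthy control /
   ambulatory DMD / non-ambulatory DMD classes; Spearman correlations with
   Holm adjustment; log-linear mixed-effects models
   `log y ~ non-ambulatory + (1 | participant)`; a binary logistic
   classifier `logit P(ambulatory) ~ jerk + mean frequency` with bootstrap
   optimism correction and frozen-coefficient external validation; and a
   proportional-odds ordinal model over the three classes.
4. **Synthetic cohorts** (`wristmotion.synthgen`): a generative model of
   wrist wear — drifting gravity vector, nightly sleep window,
   Poisson-timed movement bouts with group-graded amplitude, rate,
   smoothness and tremor content — so the entire pipeline runs end-to-end
   with no data download and reproduces the clinical ordinal pattern
   (controls > ambulatory DMD > non-ambulatory DMD on counts, entropy and
   jerk; the reverse on the frequency measures).

## Worked example

```python
import wristmotion as wm
from wristmotion.cli import extract_rows
from wristmotion.synthgen import CohortDesign, iter_cohort
from wristmotion import stats as ws

design = CohortDesign(n_per_group=4, visits_per_dmd_participant=1,
                      wear_hours_control=8.0, wear_days_dmd=8/24,
                      transition_fraction=0.0, seed=1)
table = extract_rows(iter_cohort(design))
print(ws.attach_class(table).groupby("cls", observed=True)[
    ["counts_per_minute", "entropy", "jerk", "mean_freq"]].median().round(3))

dmd = table[table["group"] == "dmd"]
fit = ws.fit_binary_ambulation(dmd)
print(f"binary AUC={fit.auc:.3f} accuracy={fit.accuracy:.3f}")
```

prints

```
                    counts_per_minute  entropy   jerk  mean_freq
cls
healthy_control              7001.164    0.112  1.624      2.965
dmd_ambulatory                683.701    0.041  0.284      3.397
dmd_non_ambulatory             52.860    0.017  0.110      4.645
binary AUC=1.000 accuracy=1.000
```

Controls move most (CPM ≈ 7000 vs ≈ 53 in non-ambulatory DMD), with the
most irregular (entropy) and least smooth-suppressed (jerk) signals, while
disease shifts movement energy toward higher frequencies — the ordinal
pattern reported clinically. On this small, well-separated synthetic
cohort, jerk and mean frequency separate ambulatory from non-ambulatory
DMD perfectly.

The same chain is available from the shell:

```
wristmotion simulate --out cohort/ --seed 1 --n-per-group 4
wristmotion extract  --manifest cohort/manifest.csv --out metrics.csv
wristmotion analyze  --table metrics.csv --out reports/ --seed 1
```

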