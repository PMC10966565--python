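# oscillome

Source-space resting-EEG oscillation and connectivity analysis:
band-limited power, orthogonalized power-envelope connectivity (PEC),
cohort statistics with permutation/FDR/robustness screening, and
connectome-based predictive modeling (CPM) — plus a synthetic cohort
simulator that plants known group effects so every stage can be
validated against ground truth.

## The problem

Resting high-density EEG can characterize a clinical population — for
example a movement disorder such as paroxysmal kinesigenic dyskinesia —
by (i) mapping sensor recordings to ~100 parcellated brain regions with
a regularized minimum-norm inverse, (ii) measuring each region's
oscillatory activity in six canonical bands (delta 2–4, theta 5–7,
alpha 8–12, beta 13–29, low-gamma 30–59, high-gamma 60–90 Hz), (iii)
measuring amplitude synchrony between regions, and (iv) turning
group-discriminative features into a classifier of clinical state that
must transfer to an external cohort.

The methodological crux is volume conduction: one neural source mixes
instantaneously into many sensors, so naive connectivity is inflated by
zero-phase-lag artifacts. PEC addresses this by orthogonalization:
before correlating log power envelopes, the component of one signal
instantaneously in phase with the other is removed,

    y⊥x(t) = imag( y(t) · conj(x(t)) / |x(t)| ),
    PEC(x, y) = ½ [ corr(log|y⊥x|², log|x|²) + corr(log|x⊥y|², log|y|²) ].

Mixtures of a single source then yield PEC ≈ 0 while genuine amplitude
coupling survives. The CPM on top is deliberately simple: features with
two-sample t-test p < 0.3 split into positive/negative sets by effect
direction, a subject's score is Σpos − Σneg, and one fitted threshold
classifies — applied unchanged to external data.

Because raw clinical recordings are typically not shareable, the
package ships a simulator (`oscillome.synth`) that generates
multi-subject source-space cohorts with controllable per-region band
power, controllable inter-regional envelope correlations, 1/f
background and optional sensor mixing through a toy lead field.

## Worked example

```python
import numpy as np, warnings
from oscillome.synth import SynthCohortConfig, EffectSpec, gen_cohort
from oscillome.spectral import welch_psd, znorm_psd, band_power
from oscillome.stats import compare_groups, RobustnessConfig, chi_square_counts, anova_from_summary

# cohort-table statistics from printed counts / summaries
chi2, df, p = chi_square_counts([[91, 7], [94, 2], [31, 0]])
print(f"handedness: chi2={chi2:.3f}, df={df}, p={p:.3f}")
F, d1, d2, pA = anova_from_summary([24.15, 24.15, 25.03], [7.17, 7.29, 7.90], [98, 96, 31])
print(f"age: F({d1},{d2})={F:.3f}, p={pA:.3f}")

# simulate a cohort with a theta-power elevation planted in 4 regions
cfg = SynthCohortConfig(n_per_group={"HC": 12, "PKD": 12}, duration=30.0, n_regions=20, seed=0)
cfg.effects = (EffectSpec("band_power", "theta", tuple(cfg.region_names[:4]), 2.0, "PKD"),)
subjects, meta = gen_cohort(cfg)
theta = np.array([band_power(znorm_psd(welch_psd(s)))[:, 1] for s in subjects])
with warnings.catch_warnings():
    warnings.simplefilter("ignore")
    comp = compare_groups(theta, meta["group"].to_numpy(), n_perm=1000,
                          robustness=RobustnessConfig(), seed=1)
hits = [cfg.region_names[i] for i in np.flatnonzero(comp.significant)]
print(f"FDR-significant theta regions ({len(hits)}):", ", ".join(hits))
```

prints

```
handedness: chi2=4.731, df=2, p=0.094
age: F(2,222)=0.193, p=0.825
FDR-significant theta regions (4): Frontal_Sup_Medial_L, Frontal_Sup_Medial_R, Frontal_Med_Orb_L, Frontal_Med_Orb_R
```

The chi-square and F statistics are the demographic checks of a
three-arm cohort table (right/left handedness counts; age mean/SD/n per
arm). The simulation recovers exactly the four regions that carried the
planted theta elevation — after label permutation, BH-FDR and the
100×95% subsample-robustness screen — with no false positives.

A command-line layer wraps the same functions:
`oscillome run --config examples/demo.yaml --out-dir out/` simulates a
cohort with a planted theta effect, computes band-power and PEC
features, runs the statistics, trains a CPM, and writes TSVs plus a
provenance manifest; `simulate`, `preprocess`, `source`, `features`,
`stats` and `cpm` expose the individual stages.

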