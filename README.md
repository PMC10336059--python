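# ethotype

Quantifying animal personality from automated 2-D tracking data.

Behavioral ecologists ask whether individual fish (here, juvenile gilthead
seabream observed in standardized arena tests) differ *consistently* in
exploration, aggressiveness, sociability, boldness, and activity — i.e.
whether they have behavioral types — and whether those traits are
correlated into behavioral syndromes. `ethotype` implements that analysis
end to end, from per-second trajectory detections to the final variance
decomposition, together with a synthetic-data generator with known ground
truth so every stage is testable without the original recordings.

## What it computes

**Trajectory metrics** (per individual, trial, and test): time outside the
refuge (a fish inside its refuge is invisible to the tracker), minimum
distance to a stimulus centroid — with the refuge-to-stimulus distance
imputed (250 px novel object, 350 px conspecific) when a fish never came
out — time within a 100 px interaction radius, travelled distance, Von
Mises turning-angle parameters (μ, κ), and the 95% / 50% kernel
utilization-distribution areas. Pixels convert to centimetres with the
camera calibration 1 cm = 16.7 px.

**Trait scores**: each axis's correlated metrics collapse onto the first
principal component of their correlation matrix (`PC1Scorer`), oriented so
positive = more of the trait; exploration and sociability scores are
shift-log transformed before modelling.

**Adjusted repeatability**: a Gibbs-sampled Bayesian linear mixed model
(`BayesianLMM`) with trial, body length and sample origin (wild/reared) as
fixed effects and an individual random intercept decomposes the phenotypic
variance into between-individual V_ind and residual V_e, giving per draw

    R = V_ind / (V_ind + V_e)

with a 95% credibility interval. Significance uses the deviance
information criterion: refit without the random intercept and require
ΔDIC > 2.

**Behavioral syndromes**: a bivariate mixed model
(`BivariateBayesianLMM`) with 2×2 between-individual (G) and residual (R)
covariances decomposes the phenotypic correlation of a trait pair,

    r_ind = G12 / √(G11 G22),   r_e = R12 / √(R11 R22),
    r_p = (G12 + R12) / √((G11 + R11)(G22 + R22)),

again with the ΔDIC > 2 rule against the zero-covariance model.

Both estimators follow scikit-learn conventions (`fit`, `get_params`,
fitted attributes with a trailing underscore), and `PC1Scorer` is a
regular sklearn transformer.

## Worked example

Simulate a cohort with known truth (70 individuals × 4 trials,
V_ind = 0.4, V_e = 0.6, so true R = 0.40) and estimate its adjusted
repeatability:

```python
from ethotype import TraitSimConfig, simulate_trait_data, repeatability_significance

cfg = TraitSimConfig(n_individuals=70, n_trials=4, v_ind=0.4, v_e=0.6,
                     beta=(1.0, 0.03, 0.2, 0.0), seed=1)
df = simulate_trait_data(cfg)
est = repeatability_significance(df, random_state=0)
print(f"adjusted-R = {est.r_mean:.2f} [{est.bci[0]:.2f}, {est.bci[1]:.2f}]")
print(f"DIC = {est.dic:.2f}  DIC_C = {est.dic_constrained:.2f}  "
      f"dDIC = {est.delta_dic:.2f}  significant: {est.significant}")
```

prints

```
adjusted-R = 0.36 [0.24, 0.49]
DIC = 699.64  DIC_C = 776.22  dDIC = 76.58  significant: True
```

— the credibility interval covers the true R = 0.40, and removing the
individual intercept costs 77 DIC points, so individual identity clearly
matters for this trait.

The command-line pipeline chains every stage on the packaged demo
(30 individuals × 4 trials, with a true exploration–activity syndrome
built in):

```sh
ethotype all --seed 7 --out runs/demo
```

`runs/demo/report.txt` then contains per-axis Table-style summaries such as

```
Exploration  (terms: trial, length, sample)
  ...
  V_ind             0.02 [0.00, 0.06]
  V_e               0.13 [0.09, 0.18]
  adjusted-R        0.15 [0.01, 0.36]  (plug-in 0.15)
  DIC = 111.79 (DIC_C = 118.06, dDIC = 6.27, significant)
```

and the syndrome decomposition per configured pair. Note that score-level
repeatability is lower than the latent ground truth because the demo
deliberately routes the latent trait through noisy trajectory and count
metrics — exactly the attenuation real tracking data show.

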