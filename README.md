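# otoshape

Otolith-shape morphometrics, growth modelling and population-mixing
analysis for herring stocks, with a fully synthetic study system for
testing every stage against known ground truth.

## The problem

Along the Norwegian Skagerrak coast, three putative herring populations
mix over the spawning season around a brackish inland lake
(Landvikvannet): Norwegian spring spawners (NSS), coastal Skagerrak
spring spawners (CSS) and the local Landvik herring (LV). Individual fish
cannot be assigned to CSS vs LV directly, so discrimination rests on
population-level signals: otolith outline shape, vertebral count, growth
and maturation timing, all sampled by gillnet with unequal effort. This
package implements that analysis chain for anyone working on mixed-stock
discrimination from otolith morphometrics and survey biology:

1. **Outlines** — extract a closed otolith boundary from an image,
   standardise to unit area, resample as 2^k equally spaced radii from
   the centroid.
2. **Wavelet descriptors** — orthonormal discrete wavelet transform
   (symlet-10, periodic) of the radii; the retained dyadic depth is
   chosen from the reconstruction deviation.
3. **Length correction** — ANCOVA screen (coefficients with a
   group×length interaction cannot be linearly adjusted and are
   excluded), then allometric rescaling `value·(L0/length)^b` to a
   common reference length.
4. **Constrained ordination** — canonical analysis of principal
   coordinates (Euclidean case = redundancy analysis) of the scaled
   coefficients on population, tested with an ANOVA-like permutation
   pseudo-F, with Bonferroni-corrected pairwise contrasts and seasonal
   trends of the leading canonical score.
5. **Growth** — von Bertalanffy fits L(t) = L∞(1 − e^(−K(t − t0))) per
   population, optionally with parameters shared across populations.
6. **Population statistics** — catch-per-gillnet (CPUE) standardisation,
   CPUE-weighted monthly mixing proportions, vertebral-count / length /
   age comparisons, Spearman maturity seasonality, and vertebral-count
   trends against the spawning-depth environment.

Because the field data are not deposited, `otoshape.synthdata` generates
the whole study synthetically — analytic otolith outlines with localised
population effects, fish records with population-specific growth,
vertebral counts and spawning peaks, and gillnet catch tables — so every
stage is exercised against known truth. Three small survey tables
(gillnet catches, analysed counts, commercial landings) ship with the
package for the catch arithmetic.

## Worked example

```python
import warnings
from otoshape.pipeline import run_pipeline
from otoshape.synthdata import default_config

warnings.simplefilter("ignore")
res = run_pipeline(default_config(seed=42), n_perm=999)
print(res.cap.summary())
print(res.growth_fit.summary())
```

prints

```
Canonical Analysis of Principal Coordinates (Euclidean)
n obs: 433   groups: 3   canonical axes: 4
Inertia  total: 10.3829  constrained: 4.4486 (42.8%)  residual: 5.9343
df constraints: 4   df residual: 428
pseudo-F: 80.2118
permutation p: 0.001 (999 permutations)
von Bertalanffy growth model
group          Linf    (se)       K    (se)      t0    (se)     sd     n
CSS           30.96   0.134   0.434  0.0238   -1.69   0.193   0.50   185
LV            29.96   0.129   0.476  0.0299   -1.56   0.220   0.52   160
NSS           34.41   0.319   0.314  0.0236   -2.18   0.271   0.46    88
```

The ordination separates the three populations (pseudo-F 80.2 on 4
constraint df, permutation p = 0.001, the minimum attainable with 999
permutations); the group centroids on the leading canonical axis order
LV (−0.117) < CSS (0.036) < NSS (0.137), matching the configured shape
contrast. The growth fits recover the generating parameters — e.g. NSS
L∞ = 34.41 cm against a generating value of 34.51 cm — with standard
errors from the Jacobian. `res` also carries the ANCOVA screen report,
pairwise contrasts (all Bonferroni p = 0.003 here), the CAN1 seasonal
trend of the mixed fjord samples, CPUE-weighted mixing proportions per
month and habitat, and maturity/meristic test tables.

The same chain is available from the shell:

```bash
otoshape run --seed 42 --out results/run42/     # full pipeline + report.md
otoshape simulate --seed 1 --out sim/           # records + catch tables
otoshape outline img/*.png --out outlines/      # image -> x,y CSV
otoshape growth --records sim/records.csv --out vbgm.csv
```

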