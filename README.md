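# roosurvey

Grouping and spacing analysis for walked surveys of eastern grey kangaroo
populations living under contrasting human-disturbance regimes, plus a
synthetic survey generator so the whole pipeline runs — and can be
validated against known ground truth — without any field data.

The package is aimed at behavioural ecologists analysing spatially
referenced survey observations of gregarious macropods (or similar
group-living grazers): one row per sighted individual, with planar
coordinates, a demographic class, and the disturbance regime of the
cleared area it was grazing in. Disturbance regimes cross the frequency of
human interaction (High/Low: more or less than about one interaction per
week) with its intent (Benign/Harm), giving four zone types: HB, LB, LH,
HH.

## What it computes

**Chain-rule grouping.** Two animals belong to the same group if they are
within a threshold distance of each other, taken to transitive closure —
the connected components of the threshold graph (single-linkage at a fixed
cut). Conventional thresholds of 15, 30 and 50 m are the defaults. Pouch
young ride in the mother's pouch: they are excluded from the chaining
point set and from group size, but included in demographic composition.

**Spatial and demographic metrics.** Per group: size, geometric centre,
clusteredness (mean nearest-neighbour distance, groups of size > 1),
distance from the group centre to forested cover, and the six-class
demographic composition. Per vulnerable individual (mothers, young-at-foot,
pouch young): `delta = GDC − IDC`, the group-centre minus individual
distance to cover, classifying each as "front" (nearer the forest edge
than the group centre, `delta > 0`) or "behind". Grazing density is
individuals per km² of cleared habitat per session; forage quality is the
relative green channel brightness of an RGB patch,
`greenness = ΣG / Σ(R+G+B)`.

**Inference.** One-way ANOVA with Tukey HSD on log density; D'Agostino
skewness and Anscombe–Glynn kurtosis tests (implemented from the published
normal approximations); Gaussian linear mixed models with a random session
intercept (and a crossed group-size intercept where appropriate) with
likelihood-ratio tests and Tukey-adjusted least-squares-means contrasts; a
binomial GAM of front/behind positioning on a spline of distance to cover;
and the centrepiece, a negative-binomial regression of group size on log
distance to cover nested within disturbance type,

    size_ij ~ NB(mu_ij, k),   log mu_ij = a_z + b_z * log d_ij + u_j,
    u_j ~ N(0, sigma^2),

with the Gaussian session intercept `u_j` integrated out by Laplace
approximation and Wald 95% CIs. A slope `b_z` is flagged "detected" when
its CI excludes zero — the signature of interest is that the antipredator
slope (larger groups further from cover) is detected at benign zones and
not at harm zones.

**Synthetic surveys.** The generator plants all of the above: zone
polygons with the study areas (17.1, 232.4, 104, 139 ha) embedded in
forest, near-constant per-zone headcounts split into NB-sized groups whose
expected size follows the log-distance model, hard-core group placement so
the 15 m chain-rule recovers the planted partition exactly, zone-specific
demographic mixes, and an edge bias for vulnerable individuals that decays
with distance from cover.

## Worked example

```python
from roosurvey import (SimulationConfig, generate_survey, grazing_density,
                       density_anova, assign_groups)

ds = generate_survey(SimulationConfig(seed=1))      # four zones, six sessions
print("individuals:", len(ds.observations))

den = grazing_density(ds.observations, ds.landscape)
print(den.groupby("zone")["density_per_km2"].mean().round(1))
fit = density_anova(den)
print(f"F({fit.stats['df1']},{fit.stats['df2']}) = {fit.stats['F']:.2f}")

sess1 = ds.observations.query("session == 1 and disturbed != 1")
part = assign_groups(sess1, 15.0)
print("groups at 15 m:", part.n_groups)
```

prints

```
individuals: 2228
HB    194.0
HH     43.8
LB     82.8
LH     81.7
F(3,20) = 252.38
groups at 15 m: 59
```

i.e. a survey of ~370 individuals per session, densest where humans are
frequent and benign (HB, ~194/km²) and sparsest where they are frequent
and harmful (HH, ~44/km²), with the zone effect on log density
overwhelming (F on 3 and 20 df). The per-group summary
(`part.summary()`) carries size, centroid and clusteredness for each
group.

The full pipeline — simulate, group at every chain distance, metrics,
all model fits, figures, and a checksummed run manifest — runs from the
command line:

```
roosurvey all --seed 1 --out-dir out/
```

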