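# gazeri

**Relative importance of visual stimulus features for dynamic gaze behavior,
with multi-group comparison.**

When groups of observers watch a video, where they look is driven by a
mixture of influences: the stimulus center, statically or dynamically salient
content, and analyst-defined areas of interest (AoIs).  `gazeri` quantifies
these influences frame by frame.  For each frame *t* the group-level
eye-position density map **Y**(t) — a bivariate kernel density estimate of
the fixation locations — is decomposed into a *master saliency map*, a linear
combination of density-normalized feature maps **M**ₖ(t):

```
S(t) = Σₖ βₖ(t) Mₖ(t)
```

The weights β are estimated per frame by LASSO regression
(`argmin ‖Y − Σ βₖMₖ‖² + λ Σ|βₖ|`) with the penalty chosen by BIC
(`−2 log L + K log n`, K = number of nonzero weights, n = number of pixels),
so irrelevant features are shrunk exactly to zero.  Plotting βₖ(t) against
*t* gives *relative importance (RI) curves* for each feature.

For two (or more) groups, a group dummy **M̃**_G is interacted with every
feature column in a stacked design `Ỹ = βM̃ + ε`: the interaction weights
β_{k,G} measure how much a feature's importance differs between treatment
and control, and their significance is assessed by a participant-level
permutation test.  The KDE bandwidths are selected per frame and per group
by least-squares cross-validation (LSCV), so no assumptions about viewing
distance or visual angle are needed.

The package is aimed at eye-tracking researchers comparing natural or
experimental groups on dynamic stimuli, and ships a synthetic
stimulus-and-gaze generator so the entire pipeline is verifiable by parameter
recovery without any external data.

## Worked example

Simulate a two-group experiment in which the treatment group shifts 0.25 of
its fixation weight onto the static AoI, then recover the difference:

```python
from gazeri import BandwidthSearch, MasterSaliencyModel, preprocess, permutation_test
from gazeri.synthetic import make_two_group_scenario, build_feature_maps, sample_gaze

spec = make_two_group_scenario("aoi:target", 0.25, n_frames=12, n_per_group=60, seed=7)
maps = build_feature_maps(spec)                 # ground-truth mixture maps
gaze = sample_gaze(spec, maps)                  # raw 60 Hz monitor logs
table = preprocess(gaze, spec.geometry, spec.grid.n_frames)

model = MasterSaliencyModel(spec.grid, kde_search=BandwidthSearch(8, refine=False),
                            group_order=["treatment", "control"])
model.fit(table, maps)
print(model.ri_.curves["control"].head(5).round(2))
print(model.ri_.curves["treatment"].head(5).round(2))

res = permutation_test(table, maps, frames=[6], P=199, seed=1,
                       grid=spec.grid, model=model)
print(res[0].p_values)
```

Output (standardized weights; one row per frame):

```
   uniform  center_bias  aoi:object  aoi:target     # control
0      0.0         0.24        0.69        0.35
1      0.0         0.25        0.83        0.09
2      0.0         0.15        0.80        0.12
3      0.0         0.31        0.76        0.06
4      0.0         0.25        0.73        0.09

   uniform  center_bias  aoi:object  aoi:target     # treatment
0      0.0         0.22        0.40        0.72
1      0.0         0.13        0.50        0.71
2      0.0         0.22        0.55        0.65
3      0.0         0.25        0.52        0.67
4      0.0         0.25        0.61        0.54

permutation p-values, frame 6:
{'uniform:G': 1.0, 'center_bias:G': 0.005, 'aoi:object:G': 0.26, 'aoi:target:G': 0.05}
```

The treatment group's `aoi:target` weight sits well above the control
group's on every frame — the injected effect.  The uniform map is the
model's catch-all and is absorbed by the intercept, so its weight is
(correctly) zero.  Because the treatment's extra target weight is taken
proportionally from the other features, the center-bias weight also truly
differs between groups, which the permutation test picks up; the adjusted R²
per frame sits around 0.7 for this clean synthetic scenario.

## Command line

```
gazeri simulate --out data/ --n-frames 30 --delta 0.2            # synthetic dataset
gazeri fit      --gaze data/gaze.csv --geometry data/geometry.json \
                --frames-dir data/frames --aois data/aois.json --out fit/
gazeri permtest ... -P 1000 --frame-count 10 --seed 1 --out perm/
gazeri plot     --fit-dir fit/
```

`fit` writes tidy CSVs (per-frame weights, RI curves, adjusted R², KDE
bandwidths), figures (solid = control, dashed = treatment), and a
provenance record; `permtest` writes p-values and permutation box summaries.

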