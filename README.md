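# burnsel

Used/available habitat-selection analysis for animals in burned
landscapes, with a fully synthetic test bed.

Wildfires leave mosaics — high- and low-severity patches, unburned
"fire skips," regenerating older burns — and animals such as Canada
lynx respond to that structure rather than to the fire perimeter as a
whole. `burnsel` implements the complete analysis chain ecologists use
to quantify that response from GPS collar data and co-registered
rasters, and pairs it with generators that produce landscapes and
telemetry with *known* selection coefficients, so every stage of the
pipeline can be validated without any field data.

It is intended for movement and landscape ecologists who want a tested,
scriptable version of this workflow, and for methodologists who want a
sandbox where the ground truth is known.

## What it computes

**Covariates** (module `burnsel.terrain`): slope/aspect, the
folded-aspect heat load index HL(S, A, L) of McCune & Keon, D8 flow
accumulation and the wetness index CTI = ln(a / tan β), exact Euclidean
distance transforms (burn-edge distance, distance to drainage draws),
3×3 and 27×27 moving-window means and class fractions, nearest-neighbor
reassignment of masked land-cover cells, and burn age/severity
classification from canopy-cover loss.

**Sampling design** (module `burnsel.telemetry`): study-area
delineation by buffering the step path (766 m, the mean 4-hr step),
used-point extraction, equal-count uniform availability, and assembly
of the used/available covariate table. The simulator moves an animal by
discrete choice among K candidate steps with probability ∝ exp(Σ β·z) —
a step-selection process with known β — records fixes with 72% success,
and can also draw points directly from the point process with
log-intensity Σ β·z.

**Model development** (modules `burnsel.model`, `burnsel.forest`): a
random forest of 4,000 bootstrap trees classifying used (1) vs
available (0); redundancy and Spearman |r| > 0.8 collinearity screens;
a density-weighted 80/20 train/holdout split; Model Improvement Ratio
variable selection (importance / max importance, thresholds 0.0–1.0 in
0.1 steps, nested refits, combined OOB + within-class error minimized);
significance by refitting on B = 1,000 label permutations,
p = (1 + #{null ≥ observed}) / (B + 1); and partial-dependence curves
for the selected variables.

## Worked example

```python
import numpy as np
from burnsel import synth, telemetry, model

cfg = synth.preset("tripod", seed=42, shape=(200, 200))
stack = synth.build_landscape(cfg)
print(synth.achieved_burn_fractions(stack["burn"]))

track, info = telemetry.simulate_track(
    stack,
    telemetry.MovementConfig(
        betas={"frac_new_high_l": -1.0, "canopy_l": 1.0},
        n_steps=4000, seed=42,
    ),
)
print(f"fixes={len(track)} fix_rate={info['fix_rate']:.2f} "
      f"mean_step={info['mean_step_m']:.0f} m")

burn = stack["burn"]
perimeter = burn.like((burn.values != 0).astype(np.int16))
use = telemetry.burn_use_summary(track, perimeter)
print(f"{use['n_inside']} of {use['n_total']} fixes inside the burn "
      f"({use['pct_1dp']}%)")

used = telemetry.extract_used_points(track, perimeter)
avail = telemetry.sample_available(perimeter, len(used), seed=7)
table = telemetry.build_table(used, avail, stack, balance_seed=8)
result = model.run_burn_model(
    table, seed=9,
    config=model.ModelConfig(n_trees=200, n_permutations=99,
                             permutation_engine="hist"),
)
print("selected:", result.selected_vars)
print(f"OOB error={result.oob_error:.3f}  "
      f"holdout accuracy={result.holdout_accuracy:.3f}  "
      f"p={result.permutation_p:.3f}")
```

Output:

```
{'new_high': 0.63, 'new_low': 0.08, 'skip': 0.21, 'old_burn': 0.08}
fixes=2878 fix_rate=0.72 mean_step=712 m
231 of 2878 fixes inside the burn (8.0%)
selected: ['precip', 'hli_s', 'frac_new_high_l', 'frac_skip_l']
OOB error=0.114  holdout accuracy=0.804  p=0.010
```

Reading it: the generated fire mosaic hits the configured "tripod"
composition (63% high severity, 8% low, 21% skips) exactly; the
simulated collar records 72% of its 4-hour attempts; the animal — which
prefers canopy cover and avoids high-severity burn — puts 8.0% of its
fixes inside the burn perimeter; and the within-burn used/available
model is significant (p = 0.01), classifies held-out points at 80%
accuracy, and selects the high-severity and fire-skip fractions among
its predictors with the expected directions in their partial-dependence
curves.

The same workflow is scriptable from the shell:

```sh
burnsel generate --preset tripod --seed 3 --size 300 --out run/stack
burnsel simulate --stack run/stack --seed 3 --beta frac_new_high_l=-1.5 \
        --beta frac_skip_l=1.5 --out run/telemetry
burnsel model --table run/telemetry/used_available.csv --seed 3 \
        --trees 4000 --permutations 1000 --out run/model
burnsel report --model-dir run/model \
        --table run/telemetry/used_available.csv --out run/report
```

or as one meta-command, `burnsel replica --preset tripod --seed 3 --out
run/`. Every command writes a `manifest.json` from which its artifacts
can be regenerated.

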