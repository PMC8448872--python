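# crossloco

Cross-species locomotion analysis with an attention-based
domain-adversarial neural network.

The package discovers locomotion features shared between two animal
groups ("domains", e.g. two species recorded at very different spatial
scales and sampling rates) that distinguish two classes (e.g. healthy vs
dopamine-deficient individuals), and then turns the network's attention
into human-readable rules that can be validated statistically.

## Components

| module                   | role |
|--------------------------|------|
| `crossloco.trajectories` | read/convert/normalize/resample/segment 2D trajectories into per-timestep speed series; stride extraction from ground-reaction-force records |
| `crossloco.network`      | the model: 1D-conv feature block, 1D-conv attention block with a softmax attention layer, gradient-reversal layers, a class head and two domain heads (per-series and per-timestep) — implemented on a small numpy reverse-mode autodiff engine (`crossloco._autodiff`), no deep-learning framework required |
| `crossloco.training`     | the three losses, the ramped gradient-reversal strength schedule, and the iterated three-phase adversarial training loop (Adam, deterministic per seed) |
| `crossloco.explain`      | attention thresholding at 1/l, rolling-window interpretable features, and the two surrogate decision trees (attended-vs-none; class from attention-weighted features) |
| `crossloco.stats`        | derived per-trajectory features (minimum speed during high speed / during acceleration, pre-turn deceleration) and the validation tests: Welch's t, Brunner–Munzel, with Shapiro–Wilk-gated selection |
| `crossloco.synthetic`    | seeded two-domain, two-class cohort generator with planted class effects and ground-truth segments |
| `crossloco.cli`          | `crossloco simulate / preprocess / train / explain` |

All file formats are plain delimited text (trajectory CSVs + a manifest,
one-value-per-line speed series, JSON checkpoints), so everything
round-trips without binary artifacts.

## Command-line workflow

```sh
# 1. simulate a cohort (flat key: value config; all fields of CohortSpec)
cat > cohort.yaml <<EOF
n_per_cell: 40
series_len: 599
seed: 1
EOF
crossloco simulate --config cohort.yaml --out cohort/

# 2. trajectories -> normalized speed series
crossloco preprocess --manifest cohort/manifest.csv --out series/
# (optional config keys: segment_seconds, min_movement, target_len, normalize)

# 3. three-phase adversarial training
cat > train.yaml <<EOF
epochs: 30
n_filters: 8
attn_hidden: 8
head_hidden: 8
seed: 1
EOF
crossloco train --series-dir series/ --config train.yaml --out run/

# 4. highlights, surrogate trees, validation table
crossloco explain --checkpoint run/checkpoint.json --series-dir series/ --out explained/
```

Exit codes: 0 success, 2 usage/config error, 1 runtime failure.
Every command writes a `run.json` recording the seed it used.

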