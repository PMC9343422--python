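# swayseg

Data-driven head–trunk segmentation analysis of quiet-standing postural sway
recorded by a chain of tri-axial accelerometers (22 sensors, cranial to
caudal, by default).

The pipeline:

1. **Simulate** (`swayseg.synthetic`) — generate recordings whose sensors
   partition into contiguous rigid clusters sharing a band-limited Gaussian
   sway source (with per-sensor polarity, per-cluster lag, optional global
   coupling, sensor noise, gravity and static mounting tilt), together with
   the planted ground-truth segmentation.
2. **Preprocess** (`swayseg.io`, `swayseg.preprocess`) — read/write the
   plain-text recording format, correct each sensor's initial orientation
   from the quasi-static trial onset (minimal rotation mapping the
   window-mean acceleration onto the world vertical), extract the
   medial–lateral (ML) and anterior–posterior (AP) components, de-mean, and
   low-pass filter at 20 Hz (order-4 Butterworth, forward–backward).
3. **Synchronize** (`swayseg.sync`) — per sensor pair and direction: Pearson
   acceleration correlation (AC), instantaneous Hilbert phase, complex mean
   phasor `v`, phase locking value `PLV = |v|`, mean phase angle
   `theta = arg v`, and the signed synchronization index
   `V = |v| * cos(theta)/|cos(theta)|` (+1 in-phase, −1 anti-phase).
4. **Aggregate** (`swayseg.aggregate`) — average over trials and subjects
   (AAC / APLV), band means into similarity categories (VS ≥ 0.8 > S ≥ 0.6 >
   M ≥ 0.4 > W), scan the adjacent-pair chain for coherent runs (≥ high
   threshold) and link sites (< low threshold), label anatomical regions,
   and render mean/SD heatmaps.
5. **Test** (`swayseg.stats`) — two-way repeated-measures ANOVA
   (condition × sensor combination, subject as the random blocking factor)
   with Bonferroni-corrected post hoc paired comparisons; `within` (per-effect
   subject-interaction error) and `pooled` error-term variants.

## Tests

```sh
python -m pytest tests/
```

`tests/test_acceptance.py` holds the acceptance criteria (index limits, null
calibration, category boundaries, cluster-rule consistency, planted-structure
recovery over 50 seeds, brute-force oracle equivalence, ANOVA type-I
calibration); the whole suite runs in a few minutes on one CPU.

## CLI

```sh
swayseg simulate   --spec spec.yaml --seed 1 --out sim/
swayseg preprocess --in sim/recording_sim_EO_t1.csv --cutoff 20 --static-window 1.0 --out pre.csv
swayseg sync       --in pre.csv --pairs adjacent --trim 0.5 --out sync.csv
swayseg aggregate  --in sync1.csv --in sync2.csv --metric V --high 0.6 --low 0.4 --out agg/
swayseg report     --in agg/group_V.csv --out maps/
swayseg anova      --in agg/subject_stats.csv --metric ac --direction ML --error-term within
```

A segment spec is a YAML document, e.g.

```yaml
n_sensors: 22
fs: 1000.0
duration: 20.0
noise_sd: 0.3
seed: 7
clusters:
  - {sensors: [1, 8]}
  - {sensors: [9, 12]}
  - {sensors: [13, 22], polarity: {15: -1}}
```

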