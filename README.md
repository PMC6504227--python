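# rescuephys

Analysis pipeline for adult gene-restoration study designs in mouse
electrophysiology and behavior:

- **Synthetic data** (`rescuephys.synth`) — 4-channel recordings (bilateral
  cortical EEG, hippocampal CA1 LFP, neck EMG) with state-dependent Poisson
  interictal-spike trains, theta/delta oscillations on a 1/f background, and
  abrupt EMG quieting during sleep; plus behavioral cohorts (staged seizure
  latencies, fear-conditioning activities) with per-cell Gaussian designs.
  Ground truth is retained so every downstream stage is testable offline.
- **State segmentation** (`rescuephys.states`) — wake/sleep scoring from
  windowed EMG RMS with a sustained-quieting rule and optional immobility
  confirmation.
- **Interictal-spike detection** (`rescuephys.iis`) — +1 mV threshold
  detection on the depth channel, refractory merging, synchrony+amplitude
  artifact rejection, state-resolved rates (events/min), and group fold
  changes.
- **Spectral analysis** (`rescuephys.spectral`) — complex Morlet amplitude
  spectra (50 log-spaced frequencies on 1–100 Hz, six-period width,
  unit-area normalization), theta/delta power ratio with 1-s smoothing,
  representative-window selection, within-subject Phase I→II normalized
  amplitude change, animal-level bootstrap CIs, and a sign-flip permutation
  test on the theta band (exhaustive for small n).
- **Behavior statistics** (`rescuephys.behavior`) — activity suppression
  ratio, type-III two-factor ANOVA, mixed repeated-measures ANOVA, MANOVA
  (Pillai's trace), t tests, exact Wilcoxon rank sum, Cohen's d, Bonferroni
  pairwise comparisons.
- **Pipeline + CLI** (`rescuephys.pipeline`, `rescuephys.cli`) — end-to-end
  orchestration with YAML/JSON configs and JSON reports carrying full
  parameter/seed provenance.

## CLI

```bash
rescuephys simulate --duration 600 --spike-rate-wake 1 --spike-rate-sleep 18 \
    --sleep-fraction 0.4 --seed 1 --out rec.csv
rescuephys segment rec.csv --out states.bed
rescuephys iis rec.csv --states states.bed --out events.csv
rescuephys theta manifest.yaml --out theta.json          # {animal, phase, file} entries
rescuephys stats cohort.csv --plan plan.yaml --out stats.json
rescuephys run-ephys run.yaml                            # full Phase I/II study
rescuephys run-behavior run.yaml
```

Recordings are columnar CSV (`t, eeg_l, eeg_r, hlfp_mV, emg`) with a JSON
sidecar (`fs` + metadata); state intervals are BED-like text; cohort tables
are long-format CSV (`animal_id, genotype, cre, tmx, endpoint, value`).

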