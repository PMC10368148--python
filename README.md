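# meagamma

Analysis of gamma-band oscillations (GBOs, 25–59 Hz) in multichannel
microelectrode-array (MEA) recordings of hippocampal local field potentials,
plus a synthetic-data generator that provides ground truth for every stage.

The package covers the full chain:

| module | what it does |
|---|---|
| `meagamma.synth` | 6×10-grid MEA simulator: region-specific narrowband sources (CA1 ~30 Hz, CA3 ~21 Hz), sigmoidal drug-onset envelope, exponential antagonist suppression, controllable pairwise coherence, HDF5 round trip |
| `meagamma.preprocess` | zero-phase Butterworth low-pass (100 Hz), decimation to 1 kHz, linear artifact interpolation |
| `meagamma.spectral` | multitaper (Slepian) PSDs, 25–59 Hz band power, sliding band-power series, Morlet-wavelet spectrograms (width m = 25), peak frequency and Q factor (Q = f0 / half-power bandwidth) |
| `meagamma.kinetics` | sigmoid onset fits c/(1+exp(−a·t+a·b))+d, GBO₉₀ rise time (closed form), 90→10% fall interval, fractional power change (P_drug − P_vehicle)/P_vehicle |
| `meagamma.coherence` | multitaper magnitude coherence \|S_xy\|/√(S_x S_y) for all electrode pairs, band-averaged coherence per region pair, power-envelope Pearson maps, thresholded coherence graphs (edges at ≥ 0.45) |
| `meagamma.stats` | linear mixed models `response ~ fixed + (1 | Slice) + (1 | Slice:Elec1)` fit by ML (statsmodels MixedLM), nonparametric battery (Wilcoxon / KS / Kruskal–Wallis + Dunn) |
| `meagamma.pipeline` | scenario runner (control / transected / mutant) with manifest, checksums, and bit-identical reruns under a fixed seed |

## CLI

One entry point with one subcommand per stage:

```bash
meagamma simulate  --config sim.yaml --seed 1 --out rec.h5
meagamma preprocess rec.h5 --cutoff 100 --fs-out 1000 --artifacts artifacts.csv --out lfp.h5
meagamma spectra    lfp.h5 --band 25 59 --out spectra/
meagamma kinetics   lfp.h5 --drug-epoch kainate --antagonist-epoch bicuculline --out kinetics.csv
meagamma coherence  lfp.h5 --band 25 59 --threshold 0.45 --out coh/
meagamma stats      coh/records.csv --model regions --out tables/
meagamma run        --scenario transected --seed 1 --out results/
```

`meagamma run` executes all stages for a scenario and writes
`records.csv`, `kinetics.csv`, `spectra.csv`, the mixed-model report, and a
`manifest.json` with seeds and SHA-256 checksums of every artifact.

Scenario epochs default to desk-scale durations (seconds to minutes).
Full-scale settings (20 kHz, hour-long epochs) are available through the
YAML config but need several GB of memory per simulated recording.

## A note on the simulator's ground truth

The drug-onset envelope is applied so that band **power** follows the
configured sigmoid exactly (the signal amplitude is scaled by its square
root); the antagonist epoch decays power as exp(−t/τ). This makes the
closed-form GBO₉₀ = b + ln 9 / a an exact ground truth for onset-recovery
tests (`meagamma.synth.ground_truth_gbo90_min` also accounts for the
in-band noise floor). Within-region coherence is controllable analytically:
`solve_within_weight` inverts the band-averaged shared-power relation to
yield mixing weights for any target coherence.
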