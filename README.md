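# psirt1

Absolute T1 quantification from a 3D phase-sensitive inversion recovery
(PSIR) cardiac MRI acquisition.

A PSIR scan acquires two readouts per two-heartbeat kernel: one shortly
after the inversion pulse and one at the same cardiac phase of the next
beat. The second readout restores the signal phase, so signed (real)
images are reconstructed — and, as implemented here, the signed intensity
pair (M_B, M_D) of every voxel also determines its absolute T1 and M0 once
acquisition and saturation effects are modeled. The package provides:

- **`psirt1.relaxometry`** — closed-form steady-state magnetization model
  of the PSIR / IR-TFE / Look-Locker kernels, including the apparent
  relaxation (T1\*, M0\*) during a spoiled readout train.
- **`psirt1.fit`** — the iterative two-point (M_B, M_D) → (T1, M0) fit, a
  naive variant that ignores saturation (for comparison), the Look-Locker
  fit with T1\* correction, and voxelwise map fitting with convergence
  flags.
- **`psirt1.synth`** — synthetic IR-TFE (LGE-style) image generation from
  fitted maps at any inversion delay, null-time search for a target T1,
  and the PSIR/Look-Locker zero-crossing comparison.
- **`psirt1.simulate`** — an independent pulse-by-pulse oracle, a digital
  six-region phantom with known T1, the heart-rate-jitter Monte Carlo, and
  deterministic robustness sweeps (flip angle, inversion delay, imperfect
  inversion).
- **`psirt1.volio` / `psirt1.cli`** — NIfTI volume I/O, YAML sequence
  configuration, and the `psirt1` command-line tool.

## Command-line usage

All subcommands take the sequence timing either as flags (`--rr`,
`--t-inv`, `--tr`, `--flip`, `--tfe`, `--inversion-deg`) or from a flat
YAML file via `--config`; flags override the file. Defaults are the
post-contrast cardiac protocol (RR 1000 ms, T_inv 300 ms, TR 9.4 ms, flip
18°, TFE factor 23).

```sh
# generate a noisy digital phantom (two PSIR volumes + ground truth)
psirt1 phantom -o ph --noise-sigma 0.005 --seed 1

# fit T1/R1/M0 maps from the two readout volumes
psirt1 fit ph_b.nii ph_d.nii -o maps --mask-threshold 0.05

# find the inversion delay nulling T1 = 500 ms for an IR-TFE readout
psirt1 null-time --t1 500 --tr 4.4 --tfe 43

# synthesize an IR-TFE image from the fitted maps at that delay
psirt1 synth maps_t1.nii maps_m0.nii --t-inv 268 --tr 4.4 --tfe 43 -o lge.nii

# heart-rate-jitter Monte Carlo and parameter sweeps (CSV tables)
psirt1 mc-arrhythmia --t1 300 --t1 500 --hr 60 --hr 90 -o mc.csv
psirt1 sweep --vary flip --values 10 --values 15 --values 20 -o sweep.csv

# fit a Look-Locker series (CSV with columns t_ms, signal)
psirt1 ll-fit series.csv --t-inv 0 --tr 25 --flip 15 --tfe 40
```

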