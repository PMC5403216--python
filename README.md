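# replikinetics

Bound-time inference for DNA-replication proteins in live *Escherichia
coli*, from two kinds of single-cell fluorescence data:

* **sptPALM track durations** — a photoconvertible fusion (mMaple-class) is
  switched on in roughly one molecule per cell and followed as a focus
  until it unbinds or photobleaches.  Observed track durations are
  exponential with rate `k_track = k_off + k_bleach`; the package fits a
  left-truncated exponential by maximum likelihood, calibrates the bleach
  rate from a stable-binder control (LacI bound to an operator array),
  rescales it between stroboscopic protocols via
  `T_bleach = (t_interval / t_exp) · T_constant`, and recovers the bound
  time as `T_bound = T_track · T_bleach / (T_bleach − T_track)`, with BCa
  bootstrap errors and BIC/likelihood-ratio selection between one- and
  two-exponential binding models.
* **FRAP recovery curves** — a replisome focus is bleached with a focused
  pulse and its recovery fitted with the reaction-limited model
  `y(t) = c − a·e^{−bt}`, where `b = k_off` and the bound time is `1/b`,
  after trace filtering, pre-bleach normalization and correction for
  acquisition photobleaching.

It also includes the tracking front-end (nearest-neighbour linking with a
blink memory, PSF-width and intensity Gaussian-mixture filters for
immobile single molecules), derived replication arithmetic (β-clamp
loading interval, fork rate, Okazaki-fragment length, synthesis per
polymerase exchange), and a synthetic-data module that generates all of
these inputs with fully known ground truth — the test suite validates the
estimators against it end to end.

The audience is microscopists and quantitative biologists analysing
single-molecule residence times in live cells; nothing here is specific to
the replisome except the derived-metric constants.

## Worked example

Simulate a fast-exchanging subunit (true bound time 10 s) imaged with
500 ms exposures at 1 s intervals, calibrate bleaching from a stable-binder
control at continuous exposure, and estimate the bound time:

```python
import numpy as np
import replikinetics as rk

settings = rk.AcquisitionSettings(exposure_time=0.5, interval_time=1.0)
params = rk.TrackSimParams(true_bound_time=10.0, n_molecules=215, seed=1)
sample = rk.gen_track_durations(params, settings)

control = rk.gen_bleach_control(
    rk.TrackSimParams(true_bound_time=np.inf, n_molecules=150, seed=2),
    rk.AcquisitionSettings(0.5, 0.5), min_localizations=4)
calibration = rk.calibrate_bleach(control)

est = rk.bootstrap_estimate(sample, calibration, n_boot=10_000, seed=3)
```

Output:

```
n tracks          : 144
T_track           : 7.16 s
T_bleach          : 28.91 s
T_bound           : 9.51 s  (truth: 10 s)
SE / 95% CI (BCa) : 1.14 s / [7.66, 12.17] s
```

The mean track duration (7.2 s) underestimates the residence time because
photobleaching also ends tracks; dividing out the calibrated bleach rate
recovers the 10 s truth within the bootstrap interval.

The same stages are exposed on the command line
(`replikinetics simulate-tracks / track / dwell / frap / metrics / run-all`).
For instance the derived replication metrics for a 4 s polymerase bound
time:

```bash
$ replikinetics metrics --bound-time 4
{
  "clamp_loading_interval_s": 2.0434782608695654,
  "clamp_loading_interval_s_rounded": 2.0,
  "fork_rate_bp_s": 255.55555555555554,
  "fork_rate_bp_s_rounded": 260,
  "okazaki_length_bp_exact_chain": 522.2222222222223,
  "okazaki_length_bp_rounded_chain": 520.0,
  "synthesis_before_exchange_bp": 1022.2222222222222
}
```

i.e. with 23 DNA-bound β dimers per fork each resident for 47 s, a new
clamp is loaded every ~2 s; at ~260 bp/s of fork progression that implies
~520 bp Okazaki fragments, and a 4 s polymerase residence corresponds to
~1 kbp synthesized per exchange.

## Documentation

`docs/methods.md` describes the statistical model, the estimators and
their numerical details, what the synthetic-data generator does and does
not emulate, and known limitations.
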