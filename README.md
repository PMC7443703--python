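# megdbs

Synthetic DBS-MEG phantom simulation and a head-to-head comparison of
sensor-level artefact rejection methods.

Recording MEG while a deep brain stimulator is running contaminates the
data with (i) the ~130 Hz pulse train, whose square-wave harmonics alias
into spurious peaks across the whole spectrum because no MEG system samples
fast enough to digitise 140 us pulses, and (ii) movement of the stimulator
wires, which produces strong low-frequency artefacts on nearby channels.
Phantom studies answer how well cleaning algorithms remove both while
preserving the signal of interest, because the ground truth (a dipole
oscillating at 12 Hz) is known exactly.

This package makes that study design fully reproducible without hardware:

* **`megdbs.phantom`** - a generative phantom: four linked conditions
  (dipole-only *Reference*, *DMW* = dipole+movement+wires, *DSMW* =
  everything plus stimulation, and empty room) from shared noise streams,
  with a calibrated DBS/dipole power ratio (+1.75 log10 units at the
  spectral peaks) and a DBS reference channel.
* **`megdbs.cleaning`** - the four methods: frequency-domain Hampel filter,
  spectral signal space projection (S3P), ICA with mutual-information
  component selection (ICA-MI), and temporal signal space separation
  (tSSS) with log-power baseline correction.
* **`megdbs.evaluation`** - band-wise log-power RMSE against the Reference
  (dipole 11.5-12.5 Hz, movement 1-15 Hz excluding the dipole band, DBS
  peak +/-1 Hz), parameter sweeps, robustness summaries and
  optimal-parameter selection.
* **`megdbs.source`** - LCMV beamforming on a 5 mm grid inside the phantom
  sphere, bootstrap activation thresholds, and the intersection-over-union
  overlap measure D.

The RMSE criterion is

```
RMSE(band) = sqrt( (1/N) * sum_i [ (pi_i^cleaned - pi_i^ref) / pi_i^ref ]^2 )
```

where `pi_i(band)` is channel *i*'s mean log10 Welch power over the band,
and `D(A, B) = |A ∩ B| / |A ∪ B|` compares thresholded source-activation
maps (D = 1 for perfect overlap).

See `docs/methods.md` for the model, all defaults and known limitations.

## Worked example

```python
import numpy as np
from megdbs import (SimConfig, make_condition_set, preprocess_conditions,
                    welch_psd, detect_dbs_peak, BandSet, sweep)

cfg = SimConfig(duration=60.0, n_channels=128, seed=5)
cset = preprocess_conditions(make_condition_set(cfg))   # simulate + notch
f_peak = detect_dbs_peak(welch_psd(cset.dsmw))
bands = BandSet(f_peak=f_peak)
sw = sweep("hampel", [1, 2, 3, 4, 5, 6, 7, 8], cset, bands, seed=7)
print(f"DBS peak at {f_peak} Hz")
print(sw.rmse.round(5).to_string())
print("uncleaned DBS-band RMSE:", round(sw.baseline["dbs"], 5))
print("best C:", sw.best_sensor_value)
```

prints

```
DBS peak at 130.0 Hz
              1.0      2.0      3.0      4.0      5.0      6.0      7.0      8.0
dipole    0.00206  0.00206  0.00206  0.00206  0.00206  0.00206  0.00206  0.00206
movement  0.01181  0.01181  0.01181  0.01181  0.01181  0.01181  0.01181  0.01181
dbs       0.01613  0.01492  0.02702  0.03274  0.03488  0.03539  0.03551  0.03562
uncleaned DBS-band RMSE: 0.09394
best C: 2.0
```

Reading: narrow-band Hampel cleaning cuts the DBS-band error six-fold
(0.094 -> 0.015 at C = 2) while leaving the dipole and movement bands
untouched; the most aggressive threshold C = 1 slightly overcompensates,
exactly the behaviour one tunes C against. A complete run - all four
methods, report tables and 12 Hz source maps - is one command:

```bash
megdbs run --seed 5 --out results/run
```

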