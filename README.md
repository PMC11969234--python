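# kesblock

Analysis pipeline for **kilohertz-frequency electrical stimulation (KES)
conduction block** of peripheral nerves, quantified from isometric
muscle-force recordings — the readout used when block is delivered through
intrafascicular electrodes (LIFEs) in the rat sciatic nerve, with activation
in the tibial (TF) or peroneal (PF) fascicle and block in TF.

It is written for neural-engineering groups who run three-phase block
protocols (pre-block / block / post-block twitch trains at 5 Hz) and need
the standard derived quantities:

- **Block amount** `BLK = 1 − X_block / X_pre`, where `X` is the peak force
  or AUC of the stimulus-triggered averaged twitch of each phase (negative
  values flag sub-threshold facilitation).
- **Block threshold** `B_TH`: smallest KES amplitude whose block-phase
  twitch peak falls below 5% of its own pre-block peak.
- **Charge safety chain** `T_KES = 1/(2 f_KES)`,
  `Q_per_phase = 2 B_TH T_KES / π`, `S_LIFE = π ø L`,
  `σ_per_phase = Q_per_phase / S_LIFE` (µC·cm⁻²), plus strength-duration
  (Weiss) and block-duration curve handling with the 17 µs normalization
  anchor.
- **Recruitment curves** `BLK(I) = 1/(1 + e^{−β(I−σ)})`, fitted by bounded
  nonlinear least squares (0.5 < σ < 3 mA, 3 < β < 30 mA⁻¹).
- **Interfascicular selectivity** `S_TF = BLK_TF − BLK_PF`.
- **Onset response** peak, AUC and 10%-to-10% duration
  `TD = t_0.1f − t_0.1i`.
- **Muscle fatigue** `f_X = 1 − |X_pre − X_post| / X_pre` with the no-KES /
  weak-block / strong-block / ideal-block scenario grouping.

A first-class **synthetic force-trace generator** reproduces the temporal
structure of the protocols (5 Hz twitch kernels, sigmoid block with known
ground truth, gamma-shaped onset transients with closed-form 10% crossings,
per-twitch fatigue with recovery, drift and sensor noise), so every stage of
the pipeline is testable against analytic targets without animal data.

## Worked example

```python
from kesblock.synthetic_data import simulate_replica
from kesblock.stats_report import run_pipeline

simulate_replica("data", seed=21, n_bth=1, n_sel_tf=1, n_sel_pf=1,
                 n_onset_tf=1, n_onset_pf=1, n_fatigue=1,
                 ratio_step=0.25, fatigue_repeats=5, sampling_rate_hz=5000.0)
result = run_pipeline("data/manifest.csv", "out", seed=21)
thr = result["tables"]["thresholds"]
print(thr[["kes_frequency_khz", "b_th_ma", "charge_density_uc_cm2"]].head(3))
```

prints (seed 21):

```
   kes_frequency_khz  b_th_ma  charge_density_uc_cm2
0                5.0     1.11              49.167712
1               10.0     1.50              33.221427
2               15.0     2.25              33.221427
```

i.e. the detected block threshold rises with KES frequency (1.11 mA at
5 kHz to 1.5/2.25 mA at 10/15 kHz on this synthetic electrode pair), and
each threshold is converted to the injected charge density per half-cycle
for the electrode geometry drawn for that pair.  The same bundle contains
the per-trial block amounts, recruitment fits (σ, β, R²), the selectivity
table, onset metrics and the fatigue scenario summary, each written as a
CSV under `out/`.

The same flow is available from the shell:

```sh
kesblock generate --out data --seed 21
kesblock analyze --manifest data/manifest.csv --out out
kesblock report --in out --out report
```

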