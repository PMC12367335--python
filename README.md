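# wtlstm — real-time ICU length-of-stay prediction from denoised vital signs

`wtlstm` implements a wavelet-denoised LSTM (WT-LSTM) regressor that
predicts a patient's ICU length-of-stay (LOS, in days) from nothing but
three bedside vital signs — heart rate, respiration rate and SaO2 —
sampled as 5-minute medians. It targets urgent-care settings where
demographics, history and laboratory results may be unavailable (e.g.
unidentified patients), so a prediction can be made from the first 3, 6,
12 or 24 hours of monitoring alone.

## Method

Each vital-sign series `V_i(t)` is passed through a level-2 discrete
wavelet transform (DWT) filter bank: the series is convolved with an
orthonormal low-pass filter and downsampled by 2, twice, keeping the
level-2 approximation coefficients `X_i(t)` and discarding the high-pass
detail branches, which for monitor data are dominated by noise
(interventions, device error, movement artefact). The denoised
three-channel sequence feeds a standard LSTM,

```
f_t = σ(X_t·U_f + H_{t−1}·W_f)        i_t = σ(X_t·U_i + H_{t−1}·W_i)
C̃_t = tanh(X_t·U_c + H_{t−1}·W_c)     O_t = σ(X_t·U_o + H_{t−1}·W_o)
C_t = f_t ⊙ C_{t−1} + i_t ⊙ C̃_t       H_t = O_t ⊙ tanh(C_t)
```

and a linear head `ŷ = w·H_T + b` maps the final hidden state to the
predicted LOS in days. Training minimizes MSE with Adam (learning rate
chosen from {0.08, 0.1, 0.12, 0.15} by validation loss), batch 16, up to
100 epochs with early stopping, on a 56.25/18.75/25 stratified hold-out
split. Baselines: plain LSTM, BiLSTM, and OLS on per-channel
mean/min/max summaries.

Because the real evaluation cohorts live in the credentialed eICU
database, the package ships a synthetic cohort generator
(`wtlstm.simulate`) that reproduces the structure the method relies on:
right-skewed lognormal LOS driven by a latent severity, severity-coupled
channel trends that are strongest in the early hours, slow AR(1)
drift plus white monitor noise, and missing samples. Everything —
denoising benefit included — is testable offline.

The LSTM forward pass, backpropagation-through-time and the Adam
optimizer are implemented in NumPy; PyWavelets supplies named filter
coefficients and serves as an independent cross-check in the tests.

## Worked example

```python
import numpy as np
from wtlstm import (preset, simulate_cohort, TrainConfig, DenoiseConfig,
                    split_holdout, train_model, evaluate, improvement_pct)

cohort = simulate_cohort(preset("signal-rich", n_stays=400, seed=7))
cfg = TrainConfig(model_kind="wtlstm", window_hours=3, hidden_dim=16,
                  lr_grid=(0.1,), seed=0)
train, val, test = split_holdout(cohort, cfg)
model = train_model(train, val, cfg)
report = evaluate(model, test, cfg.window_hours)
print(f"WT-LSTM  3 h window: MSE {report.mse:.3f} sq-days, "
      f"RMSE {report.rmse:.3f} days, R2 {report.r2:.3f}")

from dataclasses import replace
baseline = train_model(train, val, replace(cfg, model_kind="lstm"))
base_report = evaluate(baseline, test, cfg.window_hours)
print(f"LSTM     3 h window: MSE {base_report.mse:.3f} sq-days")
print(f"improvement from the wavelet front end: "
      f"{improvement_pct(base_report.mse, report.mse):.2f}%")
```

prints

```
WT-LSTM  3 h window: MSE 1.012 sq-days, RMSE 1.006 days, R2 0.866
LSTM     3 h window: MSE 1.052 sq-days
improvement from the wavelet front end: 3.88%
```

Using only the first 3 hours of vitals, the denoised model explains ~87%
of the LOS variance on this synthetic cohort and improves on the plain
LSTM's test MSE by ~4% — the wavelet front end is doing the work of
stripping monitor noise before the recurrence sees it.

The same pipeline is scriptable from the shell:

```sh
wtlstm simulate --preset signal-rich --n-stays 400 --seed 7 --out cohort/
wtlstm train   --data cohort/ --out run/ --model-kind wtlstm --window-hours 3
wtlstm predict --model run/model.json --data cohort/ --out predictions.csv
wtlstm ablate  --data cohort/ --out ablation/ --models wtlstm,lstm --windows 3,24
```

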