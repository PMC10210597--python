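# envsca

Supervised classification of **categorical time series** — sequences over a
finite set of states such as sleep stages, behavioural codes, or DNA symbols —
using frequency-domain features: the **spectral envelope** and its
**optimal scalings**.

Many categorical series are distinguished not by which states they visit but
by *how they oscillate* through them: how fast they cycle, and through which
traversals. The spectral envelope captures the first, the optimal scalings
the second, and together they form a low-dimensional, interpretable feature
space for classification. The motivating application is distinguishing sleep
disorders (e.g. nocturnal frontal lobe epilepsy vs REM behaviour disorder)
from whole-night hypnograms, where cycling behaviour differs even when
clinical presentation overlaps.

## The method

A series X_t over m states is encoded as a (m−1)-variate 0/1 series Y_t
(baseline encoding: one reference category maps to the zero vector). For the
Fourier frequencies ω_s = s/T, s = 1..K = ⌊(T−1)/2⌋, the spectral matrix
f_y(ω) of Y_t is estimated by the kernel-smoothed periodogram

    f̂_y(ω_s) = Σ_{j=−B_T..B_T} W_j I(s+j),   B_T = ⌊√T⌋,

with symmetric nonnegative weights W_j summing to one (modified Daniell by
default). The **spectral envelope** λ̂(ω_s) is the largest eigenvalue of
Re f̂_y(ω_s) — the largest power spectrum achievable by any real scaling of
the categories — and the **optimal scalings** γ̂(ω_s) are the associated
unit eigenvector (first non-negligible entry made positive).

Given labelled training series, group features Λ̂^(j), Γ̂^(j) are the
within-group averages of λ̂ and γ̂. A test series r is assigned to the group
minimising one of three distances:

* **ENV**:    D_j = ‖λ̂⁽ʳ⁾ − Λ̂^(j)‖₂²
* **SCA**:    D_j = ‖γ̂⁽ʳ⁾ − Γ̂^(j)‖_F²
* **EnvSca**: D_j = κ‖λ̂⁽ʳ⁾ − Λ̂^(j)‖₂²/‖λ̂⁽ʳ⁾‖₂² + (1−κ)‖γ̂⁽ʳ⁾ − Γ̂^(j)‖_F²/‖γ̂⁽ʳ⁾‖_F²

with the mixing weight κ ∈ {0, 0.1, …, 1} tuned by leave-one-out
cross-validation. κ̂ is itself interpretable: values near 1 say the groups
differ in oscillatory patterns, near 0 in traversals, in between in both.
Spectral-matrix-based baselines (total variation, Kullback–Leibler and
Chernoff disparities on the whole smoothed spectral matrix) are included for
comparison, and a lag-1 multinomial-logit simulator provides the generative
presets used in the Monte-Carlo study.

## Worked example

Two groups of four-state series that cycle at different speeds (the
"case 1" preset of the simulator), ten training series each at T = 200:

```python
import numpy as np
from envsca import EnvScaModel, case_params, simulate_series

keys = np.random.SeedSequence(42).spawn(30)
train, labels, i = [], [], 0
for g in (1, 2):
    for k in range(10):
        train.append(simulate_series(case_params(1, g), 200,
                                     np.random.default_rng(keys[i]))); i += 1
        labels.append(f"group{g}")

model = EnvScaModel.from_series(train, labels)
res = model.fit(method="envsca", kappa="auto")
print(res.summary())
```

```
Envelope/Scalings classifier
============================================
method:           ENVSCA
groups (J):       2  ['group1', 'group2']
series per group: [10, 10]
frequencies (K):  99
selected (env):   99
selected (sca):   99
kappa:            1.0
LOO rate:         0.9500
group 'group1': envelope peak at frequency 0.0050 (power 0.4243)
group 'group2': envelope peak at frequency 0.4850 (power 0.4705)
```

The tuned κ̂ = 1.0 says the groups are separated by their envelopes alone —
correct by construction here: group 1 cycles slowly (envelope peak near
frequency 0), group 2 quickly (peak near 0.5) — and the leave-one-out rate
on the training set is 95%. Predicting five fresh series (two from group 1,
three from group 2) classifies all five correctly:

```python
pred = res.predict_series(test_series)
print(pred.to_frame().to_string(index=False))
```

```
series_id predicted_group  distance_group1  distance_group2
       t0          group1         0.029287         0.043369
       t1          group1         0.014346         0.065968
       t2          group2         0.065358         0.016341
       t3          group2         0.102120         0.011001
       t4          group2         0.148128         0.041147
```

The same pipeline is available from the shell:

```bash
envsca simulate --case 1 --group 1 --T 200 --n 10 --seed 7 --out g1.csv
envsca fit --train train.csv --labels labels.csv --method envsca --out model.json
envsca predict --model model.json --test test.csv --out predictions.csv
envsca features --input train.csv --out features.csv
```

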