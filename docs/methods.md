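# Methods

## Model and features

A categorical time series X_t takes values in a finite ordered state space
{c_1, …, c_m}, assumed strictly stationary with every state visited with
positive probability (no absorbing states). The baseline indicator encoding
maps X_t to the (m−1)-vector Y_t with a one in position ℓ when X_t = c_ℓ
(ℓ < m) and the zero vector for the reference category c_m. The reference
category defaults to the last element of the state space and can be chosen
freely (for hypnograms the Wake/Movement stage is the natural choice, and
the bundled synthetic hypnogram generator uses it).

The spectral matrix f_y(ω) of Y_t is a Hermitian (m−1)×(m−1) matrix per
frequency. Because its imaginary part is skew-symmetric, real quadratic
forms see only the real part, so the **spectral envelope**
λ(ω) — the largest power spectrum achievable by any real scaling of the
categories not proportional to a constant — is the top eigenvalue of
Re f_y(ω), and the **optimal scalings** γ(ω) are the corresponding unit
eigenvector. The envelope is deliberately *not* normalised by total power:
groups can then differ through overall power as well as through its
distribution across frequencies. Two identifiability conventions make γ
unique when the top eigenvalue is simple: unit Euclidean norm, and the
first entry with magnitude above 1e−8 made positive. When the top two
eigenvalues agree to within 1e−10 relative, the scalings are not identified;
the estimate keeps the eigensolver's vector and emits a warning rather than
masking the degeneracy.

## Estimation

For a series of length T the periodogram ordinates are
I(s) = d(s) d(s)ᴴ / T, where d(s) is the DFT of the rows of Y, and the
spectral estimate on the grid ω_s = s/T, s = 1..K = ⌊(T−1)/2⌋ is the
kernel-smoothed periodogram with half-width B_T = ⌊√T⌋ (span 2B_T + 1).
Conventions, fixed where the general theory leaves freedom:

* **Weights**: modified Daniell kernel (flat with half-weight endpoints) by
  default; plain Daniell available. Both are symmetric, nonnegative,
  sum-to-one.
* **Boundary**: window indices outside 1..T−1 resolve by the
  conjugate-symmetric periodic extension of the periodogram; whenever the
  window covers the excluded mean ordinate s = 0, that weight is dropped
  and the remaining weights renormalised. The s = 0 ordinate is
  mean-dominated and the envelope is defined on ω ∈ (0, 1/2], so this keeps
  low-frequency estimates from being contaminated by the sample mean.
* **Nyquist**: K = ⌊(T−1)/2⌋ excludes the Nyquist ordinate for even T.
* **Variable lengths**: when series lengths differ, each series' periodogram
  is linearly interpolated — real and imaginary parts elementwise — onto the
  full Fourier grid of the shortest series before smoothing and
  eigendecomposition, so all features share K_min frequencies. Linear
  interpolation was chosen over splines as the least-assumption dialect;
  nested grids (lengths T and 2T) reproduce shared ordinates exactly.
* For hypnogram-style analyses a percentile window (defaults: 40th to 90th
  percentile of total sleep time, half-open indices ⌊lo·T⌋ .. ⌈hi·T⌉−1) trims
  the nonstationary sleep-onset and waking stretches before estimation.

## Classifiers

Group features Λ̂^(j), Γ̂^(j) are plain arithmetic means of the training
features per group; averaged scaling columns are *not* renormalised (the
group feature is the mean, not a unit vector). Three nearest-group rules:

* ENV — squared L2 distance between envelopes;
* SCA — squared Frobenius distance between scaling matrices;
* EnvSca — κ · (env distance)/‖λ̂‖₂² + (1−κ) · (sca distance)/‖γ̂‖_F²,
  with both normalisers computed from the test series.

κ is tuned on the grid {0, 0.1, …, 1} by leave-one-out cross-validation:
each training series is held out, its group's mean features are *recomputed
without it* (the held-out series must not contribute to its own group
feature at N_j = 20, even though the difference vanishes asymptotically),
and the held-out series is classified by EnvSca. The κ with the highest LOO
rate wins; exact ties resolve to the **largest** κ. Tuning involves no
randomness and is reproducible bit for bit. Classification ties resolve to
the lowest group index and are logged.

Optional frequency selection scores each frequency by the sum over group
pairs of squared envelope (resp. scaling) differences and keeps the top
⌈pK⌉ per feature type (defaults to p = 1, i.e. off, matching the main study
conditions). When selection is active the EnvSca normalisers are computed
over the same selected subsets, keeping both terms on a comparable scale;
the selected sets are held fixed during κ tuning.

## SMB baselines

The spectral-matrix-based baselines compare whole smoothed spectral
matrices by frequency-averaged disparities in their standard
quasi-likelihood forms: total variation 1 − tr(F G)/(‖F‖_F‖G‖_F);
Kullback–Leibler tr(F G⁻¹) − log det(F G⁻¹) − (m−1); Chernoff
log det(θF + (1−θ)G) − θ log det F − (1−θ) log det G with θ selected on
{0.1, …, 0.9} by LOO. Near-singular matrices receive a trace-relative ridge
(1e−8 · tr/(m−1)) before inversion. These baselines exist for comparative
context; the package's own tests use them only for qualitative ordering
checks (the eigen-feature classifier degrades more slowly as m grows).

## Simulator

The generator is the lag-1 multinomial logit model: given the previous
state's indicator vector Y_{t−1}, category ℓ < m has probability
exp(α_ℓ′Y_{t−1}) / (1 + Σ_k exp(α_k′Y_{t−1})), with the baseline category
taking the remainder. Since Y_{t−1} is one-hot, this is a Markov chain on m
states; per-state probability rows are computed once from the logit
formulas via log-sum-exp and cached for sampling. The initial state is
drawn uniformly and 100 burn-in transitions are discarded to approximate
stationarity (the model itself is silent on initialisation; uniform start
plus burn-in is the least-informative choice).

Three preset configurations define the study conditions (m = 4 throughout):
case 1 — two groups with identical traversal structure but different
cycling speeds (diagonal persistence 1.2 vs 0.3, an envelope-separated
pair); case 2 — two groups differing mainly in traversals through
categories (scaling-separated); case 3 — three groups mixing both kinds of
differences. A varying-m family extends case 1 to any m ≥ 3 (α_ℓ is a
vector of ones with the ℓ-th entry 1.2 or 0.3). The study driver simulates,
per replication, fresh training (N_j per group) and test (50 per group)
sets, fits each requested classifier, and reports mean and standard
deviation of percent correctly classified plus the mean tuned κ̂.
Randomness flows from a single seed through spawned substreams (one per
replication, one per series), so results are independent of execution
order and reproducible bit for bit.

The synthetic hypnogram generator produces two groups of six-state series
over {W, S1, S2, S3, S4, R} with W as reference, lengths drawn uniformly
from 400–700 epochs, and group-distinct stage persistence (1.6 vs 0.5 on
the diagonal, 0.8 off-diagonal). It emulates the *structure* of sleep-stage
data — state space, heterogeneous lengths, slow cycling — but not its
clinical realism: real hypnograms have stage-specific transition grammars,
nonstationary architecture across the night, and within-group
heterogeneity. Passing tests on this fixture therefore demonstrate that the
variable-length pipeline separates groups with distinct cycling regimes,
not that any particular clinical accuracy would be attained on real data.

## Problem sizes and numerical choices

The bundled study checks run the T = 100 cells at the full 100 replications
and the T = 500 cells at 50 replications, sizes chosen to keep a complete
desk run in the minutes range while leaving Monte-Carlo standard errors
well inside the comparison bands. Spectral estimates are validated against
Hermitian symmetry (relative 1e−10) and positive semi-definiteness of the
real part (min eigenvalue ≥ −1e−10 · trace). Model files are JSON; floats
round-trip bit-exactly via shortest-round-trip decimal encoding of
binary64.

## Known limitations

* Stationarity is assumed; regime changes within a series are not modelled.
* All categories must be observed across series — a state present only at
  prediction time is a hard error, not a degraded fit.
* Only the top eigenpair is used; groups separated solely in lower
  eigenpairs of the spectral matrix are invisible to these features.
* The LOO-tuned κ̂ is plateau-sensitive: when one feature type dominates,
  the cross-validated rate is flat over a range of κ and the reported κ̂ is
  determined by the tie-break convention as much as by the data. Its
  interpretation is directional (envelope-dominated vs scaling-dominated),
  not cardinal.
* Bandwidth follows the fixed ⌊√T⌋ rule; no data-driven bandwidth selection
  is provided.
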