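"""Distance-based classifiers on envelope/scaling features.

Three classifiers are provided, all nearest-group rules in feature space:

* ``ENV`` — squared L2 distance between the test series' spectral envelope
  and each group's mean envelope;
* ``SCA`` — squared Frobenius distance between the optimal-scalings matrix
  and each group's mean scalings;
* ``EnvSca`` — the adaptive convex combination
  ``kappa * d_env / ||lam||^2 + (1-kappa) * d_sca / ||gam||_F^2``, with the
  mixing weight ``kappa`` tuned by leave-one-out cross-validation on an
  11-point grid.

The user-facing surface is the :class:`EnvScaModel` / :class:`EnvScaResults`
pair; the free functions underneath implement the individual steps.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .series import CategoricalSeries
from .spectral import EnvelopeScalings, features_for_series, interpolate_features

__all__ = [
    "GroupModel",
    "ClassificationResult",
    "EnvScaModel",
    "EnvScaResults",
    "group_features",
    "dist_env",
    "dist_sca",
    "dist_envsca",
    "classify",
    "tune_kappa",
    "select_frequencies",
    "DEFAULT_KAPPA_GRID",
]

logger = logging.getLogger(__name__)

#: the 11-point kappa grid {0.0, 0.1, ..., 1.0}
DEFAULT_KAPPA_GRID = np.round(np.arange(11) / 10, 1)

METHODS = ("env", "sca", "envsca")


# ---------------------------------------------------------------------------
# containers


@dataclass(frozen=True)
class GroupModel:
    """Fitted per-group features.

    ``Lambda[j]`` and ``Gamma[j]`` are the elementwise arithmetic means of
    the training envelopes and scalings in group ``j`` (scaling columns are
    deliberately *not* renormalised after averaging).  ``selected_env`` and
    ``selected_sca`` are the frequency indices entering the respective
    distances (all of ``0..K-1`` unless frequency selection was applied).
    """

    group_labels: tuple
    Lambda: np.ndarray  # (J, K)
    Gamma: np.ndarray  # (J, p, K)
    n_per_group: tuple
    freqs: np.ndarray
    kappa: float | None = None
    selected_env: np.ndarray = None
    selected_sca: np.ndarray = None

    def __post_init__(self):
        K = self.Lambda.shape[1]
        if self.selected_env is None:
            object.__setattr__(self, "selected_env", np.arange(K))
        if self.selected_sca is None:
            object.__setattr__(self, "selected_sca", np.arange(K))
        if self.selected_env.size == 0 or self.selected_sca.size == 0:
            raise ValueError("selected frequency sets must be nonempty")
        if (self.Lambda < 0).any():
            raise ValueError("group-mean envelopes must be nonnegative")

    @property
    def J(self) -> int:
        return len(self.group_labels)

    @property
    def K(self) -> int:
        return self.Lambda.shape[1]


@dataclass(frozen=True)
class ClassificationResult:
    """Predictions of a nearest-group rule.

    ``distances[r, j]`` is the distance of test series ``r`` to group ``j``
    (groups ordered as in ``group_labels``); ``predicted[r]`` is the label
    attaining the row minimum, ties broken toward the lowest group index.
    """

    predicted: tuple
    distances: np.ndarray
    group_labels: tuple
    method: str
    kappa: float | None = None
    loo_rate: float | None = None

    def to_frame(self, series_ids=None) -> pd.DataFrame:
        n = len(self.predicted)
        ids = list(series_ids) if series_ids is not None else list(range(n))
        df = pd.DataFrame({"series_id": ids, "predicted_group": self.predicted})
        for j, g in enumerate(self.group_labels):
            df[f"distance_{g}"] = self.distances[:, j]
        return df


# ---------------------------------------------------------------------------
# feature stacking helpers


def _stack(features: list[EnvelopeScalings]) -> tuple[np.ndarray, np.ndarray]:
    Ks = {f.K for f in features}
    if len(Ks) != 1:
        raise ValueError(
            f"features live on different frequency grids (K = {sorted(Ks)}); "
            "use interpolate_features to build a common grid first"
        )
    lam = np.stack([f.lam for f in features])  # (n, K)
    gam = np.stack([f.gam for f in features])  # (n, p, K)
    return lam, gam


def group_features(
    features: list[EnvelopeScalings], labels: list
) -> GroupModel:
    """Average envelope/scaling features within each group.

    Group labels are ordered by first appearance in ``labels`` when they are
    plain objects, or sorted when sortable; every group must be nonempty.
    """
    if len(features) != len(labels):
        raise ValueError("features and labels must have equal length")
    if not features:
        raise ValueError("no training features supplied")
    lam, gam = _stack(features)
    try:
        uniq = tuple(sorted(set(labels)))
    except TypeError:
        uniq = tuple(dict.fromkeys(labels))
    Lam, Gam, counts = [], [], []
    for g in uniq:
        idx = [i for i, l in enumerate(labels) if l == g]
        if not idx:
            raise ValueError(f"group {g!r} is empty")
        Lam.append(lam[idx].mean(axis=0))
        Gam.append(gam[idx].mean(axis=0))
        counts.append(len(idx))
    return GroupModel(
        group_labels=uniq,
        Lambda=np.stack(Lam),
        Gamma=np.stack(Gam),
        n_per_group=tuple(counts),
        freqs=features[0].freqs.copy(),
    )


# ---------------------------------------------------------------------------
# distances


def _check_K(feature: EnvelopeScalings, model: GroupModel) -> None:
    if feature.K != model.K:
        raise ValueError(
            f"feature grid K={feature.K} does not match model K={model.K}; "
            "interpolate onto a common grid first"
        )


def dist_env(feature: EnvelopeScalings, model: GroupModel, j: int) -> float:
    """Squared L2 envelope distance to group ``j`` over the selected frequencies."""
    _check_K(feature, model)
    se = model.selected_env
    d = feature.lam[se] - model.Lambda[j, se]
    return float(d @ d)


def dist_sca(feature: EnvelopeScalings, model: GroupModel, j: int) -> float:
    """Squared Frobenius scaling distance to group ``j`` over the selected frequencies."""
    _check_K(feature, model)
    ss = model.selected_sca
    d = feature.gam[:, ss] - model.Gamma[j][:, ss]
    return float((d * d).sum())


def dist_envsca(
    feature: EnvelopeScalings, model: GroupModel, j: int, kappa: float
) -> float:
    """Adaptive distance: convex combination of the normalised ENV and SCA
    distances, both normalisers computed from the *test* series feature over
    the same selected frequency subsets."""
    if not 0.0 <= kappa <= 1.0:
        raise ValueError(f"kappa must lie in [0, 1], got {kappa}")
    se, ss = model.selected_env, model.selected_sca
    env_norm = float(feature.lam[se] @ feature.lam[se])
    sca_norm = float((feature.gam[:, ss] ** 2).sum())
    if env_norm <= 0.0 or sca_norm <= 0.0:
        raise ValueError(
            "degenerate test feature: zero envelope or scaling norm over the "
            "selected frequencies (constant series?)"
        )
    return kappa * dist_env(feature, model, j) / env_norm + (1 - kappa) * dist_sca(
        feature, model, j
    ) / sca_norm


def _distance_matrix(
    lam: np.ndarray,
    gam: np.ndarray,
    model: GroupModel,
    method: str,
    kappa: float | None,
) -> np.ndarray:
    """Vectorised (n, J) distance matrix for stacked features."""
    lam_s = lam[:, model.selected_env]  # (n, k_env)
    gam_s = gam[:, :, model.selected_sca]  # (n, p, k_sca)
    Lam_s = model.Lambda[:, model.selected_env]  # (J, k_env)
    Gam_s = model.Gamma[:, :, model.selected_sca]  # (J, p, k_sca)
    if method == "env":
        d = lam_s[:, None] - Lam_s[None]
        return (d * d).sum(axis=-1)
    if method == "sca":
        d = gam_s[:, None] - Gam_s[None]
        return (d * d).sum(axis=(-2, -1))
    if method == "envsca":
        if kappa is None:
            raise ValueError("EnvSca requires kappa (fit with kappa='auto' first)")
        de = lam_s[:, None] - Lam_s[None]
        ds = gam_s[:, None] - Gam_s[None]
        env_norm = (lam_s**2).sum(axis=1)
        sca_norm = (gam_s**2).sum(axis=(1, 2))
        if (env_norm <= 0).any() or (sca_norm <= 0).any():
            raise ValueError("degenerate test feature with zero norm")
        return kappa * (de * de).sum(axis=-1) / env_norm[:, None] + (
            1 - kappa
        ) * (ds * ds).sum(axis=(-2, -1)) / sca_norm[:, None]
    raise ValueError(f"unknown method {method!r}; choose from {METHODS}")


def classify(
    features: list[EnvelopeScalings],
    model: GroupModel,
    method: str = "envsca",
    kappa: float | None = None,
) -> ClassificationResult:
    """Assign each test series to the group at minimum distance.

    Exact ties are broken toward the lowest group index and logged.
    """
    method = method.lower()
    lam, gam = _stack(features)
    if lam.shape[1] != model.K:
        raise ValueError(
            f"feature grid K={lam.shape[1]} does not match model K={model.K}"
        )
    if kappa is None:
        kappa = model.kappa
    D = _distance_matrix(lam, gam, model, method, kappa)
    pred_idx = D.argmin(axis=1)  # argmin takes the lowest index on ties
    ties = (D == D[np.arange(len(D)), pred_idx][:, None]).sum(axis=1) > 1
    if ties.any():
        logger.warning(
            "tie in classification distances for %d series; assigned to the "
            "lowest group index",
            int(ties.sum()),
        )
    predicted = tuple(model.group_labels[i] for i in pred_idx)
    return ClassificationResult(
        predicted=predicted,
        distances=D,
        group_labels=model.group_labels,
        method=method,
        kappa=kappa if method == "envsca" else None,
    )


# ---------------------------------------------------------------------------
# kappa tuning and frequency selection


def _loo_components(
    lam: np.ndarray, gam: np.ndarray, label_idx: np.ndarray, model: GroupModel
) -> tuple[np.ndarray, np.ndarray]:
    """Normalised ENV and SCA distance components under leave-one-out.

    For training series ``r`` with group ``g``, the group-``g`` mean is
    recomputed without ``r`` (other groups keep their full-sample means).
    Returns arrays ``E`` and ``S`` of shape (n, J) so that the EnvSca LOO
    distance is ``kappa * E + (1 - kappa) * S``.
    """
    se, ss = model.selected_env, model.selected_sca
    n = lam.shape[0]
    counts = np.asarray(model.n_per_group, dtype=float)
    if (counts < 2).any():
        small = [
            g for g, c in zip(model.group_labels, model.n_per_group) if c < 2
        ]
        raise ValueError(
            f"leave-one-out needs at least 2 series per group; group(s) {small} "
            "have a single member"
        )
    # leave-one-out means for each series' own group, via group sums
    Lambda_loo_own = np.empty((n, model.K))
    Gamma_loo_own = np.empty((n,) + model.Gamma.shape[1:])
    for j in range(model.J):
        members = np.flatnonzero(label_idx == j)
        lam_sum = lam[members].sum(axis=0)
        gam_sum = gam[members].sum(axis=0)
        Lambda_loo_own[members] = (lam_sum - lam[members]) / (counts[j] - 1)
        Gamma_loo_own[members] = (gam_sum - gam[members]) / (counts[j] - 1)

    lam_s = lam[:, se]
    gam_s = gam[:, :, ss]
    de = lam_s[:, None] - model.Lambda[:, se][None]
    ds = gam_s[:, None] - model.Gamma[:, :, ss][None]
    E = (de * de).sum(axis=-1)
    S = (ds * ds).sum(axis=(-2, -1))
    # overwrite the own-group column with the held-out version
    de_own = lam_s - Lambda_loo_own[:, se]
    ds_own = gam_s - Gamma_loo_own[:, :, ss]
    rows = np.arange(n)
    E[rows, label_idx] = (de_own * de_own).sum(axis=-1)
    S[rows, label_idx] = (ds_own * ds_own).sum(axis=(-2, -1))

    env_norm = (lam_s**2).sum(axis=1)
    sca_norm = (gam_s**2).sum(axis=(1, 2))
    return E / env_norm[:, None], S / sca_norm[:, None]


def tune_kappa(
    features: list[EnvelopeScalings],
    labels: list,
    grid: np.ndarray | None = None,
    model: GroupModel | None = None,
) -> tuple[float, float]:
    """Grid-search kappa by leave-one-out cross-validation.

    Each training series is held out in turn, its group's mean features are
    recomputed without it, and it is classified by the EnvSca rule; the
    returned kappa maximises the LOO correct-classification rate, with ties
    broken toward the *largest* kappa.  Returns ``(kappa_hat, loo_rate)``.
    The procedure involves no randomness, so the result is reproducible
    bit-for-bit for a fixed training set.
    """
    grid = DEFAULT_KAPPA_GRID if grid is None else np.asarray(grid, dtype=float)
    if grid.size == 0:
        raise ValueError("empty kappa grid")
    if ((grid < 0) | (grid > 1)).any():
        raise ValueError("kappa grid values must lie in [0, 1]")
    if model is None:
        model = group_features(features, labels)
    lam, gam = _stack(features)
    label_idx = np.array([model.group_labels.index(l) for l in labels])
    E, S = _loo_components(lam, gam, label_idx, model)
    best_kappa, best_rate = None, -1.0
    for kappa in grid:
        D = kappa * E + (1 - kappa) * S
        rate = float((D.argmin(axis=1) == label_idx).mean())
        if rate >= best_rate:  # >= so ties go to the largest kappa
            best_kappa, best_rate = float(kappa), rate
    return best_kappa, best_rate


def select_frequencies(
    model: GroupModel, proportion: float
) -> tuple[np.ndarray, np.ndarray]:
    """Indices of the most group-discriminative frequencies.

    Scores each frequency by the sum over unordered group pairs of the
    squared envelope (resp. scaling) differences, and keeps the
    ``ceil(proportion * K)`` largest for each feature type independently.
    Ties are broken toward the lower frequency index.
    """
    if not 0.0 < proportion <= 1.0:
        raise ValueError(f"proportion must lie in (0, 1], got {proportion}")
    if model.J < 2:
        raise ValueError("frequency selection needs at least 2 groups")
    K = model.K
    n_keep = int(np.ceil(proportion * K))
    d_env = np.zeros(K)
    d_sca = np.zeros(K)
    for j in range(model.J):
        for h in range(j + 1, model.J):
            d_env += (model.Lambda[j] - model.Lambda[h]) ** 2
            d_sca += ((model.Gamma[j] - model.Gamma[h]) ** 2).sum(axis=0)
    # stable sort on negated scores -> ties resolved toward lower index
    sel_env = np.sort(np.argsort(-d_env, kind="stable")[:n_keep])
    sel_sca = np.sort(np.argsort(-d_sca, kind="stable")[:n_keep])
    return sel_env, sel_sca


# ---------------------------------------------------------------------------
# model / results surface


class EnvScaModel:
    """Nearest-group classifier for categorical time series in the
    envelope/scalings feature space.

    Parameters
    ----------
    features : list of EnvelopeScalings
        Training features on a common frequency grid.
    labels : list
        Group label per training series.

    Use :meth:`from_series` to start from raw categorical series; it
    extracts features with the default ``floor(sqrt(T))`` smoothing
    bandwidth and interpolates periodograms onto the shortest series' grid
    when lengths differ.
    """

    def __init__(self, features: list[EnvelopeScalings], labels: list):
        if len(features) != len(labels):
            raise ValueError("features and labels must have equal length")
        self.features = list(features)
        self.labels = list(labels)
        self._lam, self._gam = _stack(self.features)

    @classmethod
    def from_series(
        cls,
        series: list[CategoricalSeries],
        labels: list,
        bandwidth: int | None = None,
        kernel: str = "modified_daniell",
    ) -> "EnvScaModel":
        lengths = {s.T for s in series}
        if len(lengths) == 1:
            feats = [features_for_series(s, bandwidth, kernel) for s in series]
        else:
            feats = interpolate_features(series, bandwidth, kernel)
        return cls(feats, labels)

    def fit(
        self,
        method: str = "envsca",
        kappa: float | str = "auto",
        kappa_grid: np.ndarray | None = None,
        select_prop: float = 1.0,
    ) -> "EnvScaResults":
        """Estimate group features and (for EnvSca) the mixing weight kappa.

        ``kappa='auto'`` tunes by LOO cross-validation on the 11-point grid;
        a float in [0, 1] fixes it.  ``select_prop < 1`` restricts the
        distances to the most discriminative frequencies before tuning.
        """
        method = method.lower()
        if method not in METHODS:
            raise ValueError(f"unknown method {method!r}; choose from {METHODS}")
        model = group_features(self.features, self.labels)
        if select_prop < 1.0:
            sel_env, sel_sca = select_frequencies(model, select_prop)
            model = replace(model, selected_env=sel_env, selected_sca=sel_sca)
        kappa_hat, loo_rate = None, None
        if method == "envsca":
            if kappa == "auto":
                kappa_hat, loo_rate = tune_kappa(
                    self.features, self.labels, kappa_grid, model=model
                )
            else:
                kappa_hat = float(kappa)
                if not 0.0 <= kappa_hat <= 1.0:
                    raise ValueError("kappa must lie in [0, 1]")
            model = replace(model, kappa=kappa_hat)
        return EnvScaResults(self, model, method, loo_rate)


class EnvScaResults:
    """Fitted classifier: group-mean features, tuned kappa, diagnostics."""

    def __init__(
        self,
        model: EnvScaModel,
        group_model: GroupModel,
        method: str,
        loo_rate: float | None,
    ):
        self.model = model
        self.group_model = group_model
        self.method = method
        self.loo_rate = loo_rate

    @property
    def kappa(self) -> float | None:
        return self.group_model.kappa

    @property
    def group_labels(self) -> tuple:
        return self.group_model.group_labels

    def predict(
        self, features: list[EnvelopeScalings], method: str | None = None
    ) -> ClassificationResult:
        res = classify(features, self.group_model, method or self.method)
        if self.loo_rate is not None:
            res = replace(res, loo_rate=self.loo_rate)
        return res

    def predict_series(
        self,
        series: list[CategoricalSeries],
        bandwidth: int | None = None,
        kernel: str = "modified_daniell",
    ) -> ClassificationResult:
        feats = [features_for_series(s, bandwidth, kernel) for s in series]
        return self.predict(feats)

    def score(self, features: list[EnvelopeScalings], labels: list) -> float:
        """Correct-classification rate on a labelled test set."""
        res = self.predict(features)
        return float(np.mean([p == l for p, l in zip(res.predicted, labels)]))

    def summary(self) -> str:
        gm = self.group_model
        lines = [
            "Envelope/Scalings classifier",
            "=" * 44,
            f"method:           {self.method.upper()}",
            f"groups (J):       {gm.J}  {list(gm.group_labels)}",
            f"series per group: {list(gm.n_per_group)}",
            f"frequencies (K):  {gm.K}",
            f"selected (env):   {len(gm.selected_env)}",
            f"selected (sca):   {len(gm.selected_sca)}",
        ]
        if self.method == "envsca":
            lines.append(f"kappa:            {gm.kappa}")
        if self.loo_rate is not None:
            lines.append(f"LOO rate:         {self.loo_rate:.4f}")
        for j, g in enumerate(gm.group_labels):
            peak = gm.freqs[int(gm.Lambda[j].argmax())]
            lines.append(
                f"group {g!r}: envelope peak at frequency {peak:.4f} "
                f"(power {gm.Lambda[j].max():.4f})"
            )
        return "\n".join(lines)

    def plot_group_features(self, axes=None):
        """Line plots of the group-mean envelopes and scalings vs frequency.

        Returns the two matplotlib axes (envelope, scalings).
        """
        import matplotlib.pyplot as plt

        gm = self.group_model
        if axes is None:
            _, axes = plt.subplots(1, 2, figsize=(10, 4))
        ax_env, ax_sca = axes
        for j, g in enumerate(gm.group_labels):
            ax_env.plot(gm.freqs, gm.Lambda[j], label=f"group {g}")
            for row in gm.Gamma[j]:
                ax_sca.plot(gm.freqs, row, alpha=0.7)
        ax_env.set_xlabel("frequency")
        ax_env.set_ylabel("spectral envelope")
        ax_env.legend()
        ax_sca.set_xlabel("frequency")
        ax_sca.set_ylabel("optimal scalings")
        return axes
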