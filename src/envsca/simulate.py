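"""Lag-1 multinomial-logit generator and the Monte-Carlo study driver.

The generative model conditions the category probabilities at time ``t`` on
the indicator encoding of the previous observation::

    p_tl = exp(alpha_l' Y_{t-1}) / (1 + sum_k exp(alpha_k' Y_{t-1})),  l < m
    p_tm = 1 / (1 + sum_k exp(alpha_k' Y_{t-1}))

Because ``Y_{t-1}`` is the one-hot encoding of the previous state, the model
is a Markov chain on the ``m`` states whose transition rows are softmaxes of
the columns of the ``alpha`` matrix; those rows are computed once from the
logit formulas and cached for the sampling loop.

Three preset parameter configurations ("cases") define the study conditions:
cases 1 and 2 have two groups and four categories, case 3 has three groups;
``varying_m_params`` extends case 1 to arbitrary numbers of categories.
"""

from __future__ import annotations

from bisect import bisect_right
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .classify import EnvScaModel, classify
from .series import CategoricalSeries, encode_baseline
from .smb import smb_fit, smb_classify, tune_chernoff_theta
from .spectral import (
    default_bandwidth,
    features_for_series,
    periodogram,
    smooth_periodogram,
)

__all__ = [
    "MultinomialLogitParams",
    "StudyDesign",
    "simulate_series",
    "case_params",
    "varying_m_params",
    "run_study",
    "synth_hypnograms",
    "ENV_METHODS",
    "SMB_METHODS",
]

ENV_METHODS = ("envsca", "env", "sca")
SMB_METHODS = ("smb-tvd", "smb-kl", "smb-ch")

DEFAULT_BURN_IN = 100


@dataclass(frozen=True)
class MultinomialLogitParams:
    """Regression vectors of the lag-1 multinomial logit model.

    ``alphas`` holds ``m - 1`` vectors, each of length ``m - 1``; category
    ``m`` is the baseline with implicit zero coefficients.  ``burn_in``
    initial draws are discarded so the retained stretch is approximately
    stationary (the chain starts from a uniformly drawn state).
    """

    alphas: tuple
    burn_in: int = DEFAULT_BURN_IN

    def __post_init__(self):
        A = np.asarray(self.alphas, dtype=float)
        if A.ndim != 2 or A.shape[0] != A.shape[1]:
            raise ValueError(
                f"alphas must form an (m-1) x (m-1) array, got shape {A.shape}"
            )
        if not np.isfinite(A).all():
            raise ValueError("alpha entries must be finite")
        if self.burn_in < 0:
            raise ValueError("burn_in must be >= 0")
        object.__setattr__(self, "alphas", tuple(tuple(r) for r in A))

    @property
    def m(self) -> int:
        return len(self.alphas) + 1

    def state_probabilities(self) -> np.ndarray:
        """(m, m) array: row j is the category distribution given previous
        state j, evaluated from the logit formulas via log-sum-exp."""
        A = np.asarray(self.alphas, dtype=float)
        m = self.m
        P = np.empty((m, m))
        for j in range(m):
            y = np.zeros(m - 1)
            if j < m - 1:
                y[j] = 1.0
            z = np.append(A @ y, 0.0)  # baseline category has logit 0
            z -= z.max()
            ez = np.exp(z)
            P[j] = ez / ez.sum()
        return P


def _state_labels(m: int) -> tuple:
    return tuple(f"c{i + 1}" for i in range(m))


def simulate_series(
    params: MultinomialLogitParams,
    T: int,
    rng: np.random.Generator | int | None = None,
    series_id: str = "",
    state_space: tuple | None = None,
) -> CategoricalSeries:
    """Draw one categorical series of length ``T`` from the logit model.

    The initial state is uniform over the ``m`` categories and the first
    ``params.burn_in`` transitions are discarded.  Deterministic given the
    generator state / seed.
    """
    if T < 1:
        raise ValueError("T must be >= 1")
    rng = np.random.default_rng(rng)
    m = params.m
    labels = _state_labels(m) if state_space is None else tuple(state_space)
    if len(labels) != m:
        raise ValueError(f"state_space must have {m} labels")
    cum = np.cumsum(params.state_probabilities(), axis=1)
    rows = cum.tolist()
    for r in rows:
        r[-1] = float("inf")  # guard against u landing beyond the fp row sum
    total = T + params.burn_in
    u = rng.random(total + 1).tolist()
    state = int(rng.integers(m))
    out = []
    for t in range(total):
        state = bisect_right(rows[state], u[t])
        out.append(state)
    kept = out[params.burn_in :]
    return CategoricalSeries(
        values=[labels[s] for s in kept],
        state_space=labels,
        series_id=series_id,
    )


# ---------------------------------------------------------------------------
# preset parameter configurations

_CASE_PARAMS = {
    (1, 1): ((1.2, 1, 1), (1, 1.2, 1), (1, 1, 1.2)),
    (1, 2): ((0.3, 1, 1), (1, 0.3, 1), (1, 1, 0.3)),
    (2, 1): ((1.2, 1, 1), (1, 0.8, 1), (1, 1, 0.4)),
    (2, 2): ((0.4, 1, 1), (1, 0.8, 1), (1, 1, 1.2)),
    (3, 1): ((0.3, 1, 1), (1, 0.3, 1), (1, 1, 0.3)),
    (3, 2): ((1.2, 1, 1), (1, 0.8, 1), (1, 1, 0.4)),
    (3, 3): ((1.25, 0.5, 1), (-2, -0.75, -1), (2, 0.75, -3)),
}

CASE_GROUPS = {1: 2, 2: 2, 3: 3}


def case_params(case: int, group: int) -> MultinomialLogitParams:
    """Printed alpha vectors of the preset simulation cases (m = 4).

    Cases 1 and 2 have groups 1-2; case 3 has groups 1-3.
    """
    if case not in CASE_GROUPS:
        raise ValueError(f"unknown case {case}; presets are 1, 2, 3")
    if (case, group) not in _CASE_PARAMS:
        raise ValueError(
            f"case {case} has groups 1..{CASE_GROUPS[case]}, got group {group}"
        )
    return MultinomialLogitParams(alphas=_CASE_PARAMS[(case, group)])


def varying_m_params(m: int, group: int) -> MultinomialLogitParams:
    """Case-1-style parameters for ``m`` categories.

    Each ``alpha_l`` is a vector of ones with its ``l``-th element replaced
    by 1.2 (group 1) or 0.3 (group 2); ``m = 4`` reproduces case 1 exactly.
    """
    if m < 3:
        raise ValueError(f"need m >= 3 categories, got {m}")
    if group not in (1, 2):
        raise ValueError(f"group must be 1 or 2, got {group}")
    diag = 1.2 if group == 1 else 0.3
    A = np.ones((m - 1, m - 1))
    np.fill_diagonal(A, diag)
    return MultinomialLogitParams(alphas=tuple(map(tuple, A)))


# ---------------------------------------------------------------------------
# Monte-Carlo study driver


@dataclass(frozen=True)
class StudyDesign:
    """One cell of the simulation study.

    ``group_params`` maps group label -> MultinomialLogitParams;
    ``n_train`` series per group are used for fitting and ``n_test`` per
    group for scoring, in each of ``replications`` independent replications.
    """

    group_params: dict
    n_train: int
    T: int
    n_test: int = 50
    replications: int = 100
    base_seed: int = 0
    case: object = None

    def __post_init__(self):
        if len(self.group_params) < 2:
            raise ValueError("need at least 2 groups")
        if self.n_train < 2:
            raise ValueError(
                "need n_train >= 2 per group (leave-one-out must leave a "
                "nonempty group)"
            )
        if self.replications < 1:
            raise ValueError("replications must be >= 1")

    @classmethod
    def from_case(
        cls,
        case: int,
        n_train: int,
        T: int,
        n_test: int = 50,
        replications: int = 100,
        base_seed: int = 0,
    ) -> "StudyDesign":
        params = {
            str(g): case_params(case, g) for g in range(1, CASE_GROUPS[case] + 1)
        }
        return cls(
            group_params=params,
            n_train=n_train,
            T=T,
            n_test=n_test,
            replications=replications,
            base_seed=base_seed,
            case=case,
        )


def _simulate_set(group_params, n_per_group, T, seed_seq, tag):
    series, labels = [], []
    keys = seed_seq.spawn(len(group_params) * n_per_group)
    i = 0
    for g, params in group_params.items():
        for k in range(n_per_group):
            rng = np.random.default_rng(keys[i])
            series.append(
                simulate_series(params, T, rng, series_id=f"{tag}-{g}-{k}")
            )
            labels.append(g)
            i += 1
    return series, labels


def _run_replication(design: StudyDesign, methods, rep_seed) -> dict:
    train_ss, test_ss = rep_seed.spawn(2)
    train, train_labels = _simulate_set(
        design.group_params, design.n_train, design.T, train_ss, "train"
    )
    test, test_labels = _simulate_set(
        design.group_params, design.n_test, design.T, test_ss, "test"
    )
    out = {}
    env_methods = [m for m in methods if m in ENV_METHODS]
    smb_methods = [m for m in methods if m in SMB_METHODS]
    if env_methods:
        model = EnvScaModel.from_series(train, train_labels)
        test_feats = [features_for_series(s) for s in test]
        for meth in env_methods:
            res = model.fit(method=meth)
            pred = res.predict(test_feats)
            rate = np.mean(
                [p == l for p, l in zip(pred.predicted, test_labels)]
            )
            out[meth] = {"rate": 100.0 * float(rate)}
            if meth == "envsca":
                out[meth]["kappa"] = res.kappa
    if smb_methods:
        B = default_bandwidth(design.T)
        train_S = [
            smooth_periodogram(periodogram(encode_baseline(s)), B) for s in train
        ]
        test_S = [
            smooth_periodogram(periodogram(encode_baseline(s)), B) for s in test
        ]
        for meth in smb_methods:
            kind = meth.split("-")[1]
            theta = (
                tune_chernoff_theta(train_S, train_labels)
                if kind == "ch"
                else None
            )
            smb_model = smb_fit(train_S, train_labels, kind=kind, theta=theta)
            pred = smb_classify(test_S, smb_model)
            rate = np.mean(
                [p == l for p, l in zip(pred, test_labels)]
            )
            out[meth] = {"rate": 100.0 * float(rate)}
    return out


def run_study(
    design: StudyDesign, methods=("envsca", "env", "sca"), return_raw: bool = False
):
    """Run the Monte-Carlo classification study for one design cell.

    For each replication a fresh training and test set is simulated, each
    requested classifier is fitted (EnvSca with LOO-tuned kappa) and scored
    on the test set.  Returns a table of mean and standard deviation of the
    percent correctly classified per method, plus the mean tuned kappa for
    EnvSca.  Fully seeded: identical design and seed give identical tables,
    independent of execution order across replications.
    """
    methods = [m.lower() for m in methods]
    unknown = set(methods) - set(ENV_METHODS) - set(SMB_METHODS)
    if unknown:
        raise ValueError(
            f"unknown methods {sorted(unknown)}; "
            f"choose from {ENV_METHODS + SMB_METHODS}"
        )
    rep_seeds = np.random.SeedSequence(design.base_seed).spawn(
        design.replications
    )
    reps = [
        _run_replication(design, methods, rs) for rs in rep_seeds
    ]
    rows = []
    for meth in methods:
        rates = np.array([r[meth]["rate"] for r in reps])
        row = {
            "case": design.case,
            "n_train": design.n_train,
            "T": design.T,
            "method": meth,
            "mean": rates.mean(),
            "sd": rates.std(ddof=1) if len(rates) > 1 else 0.0,
            "mean_kappa": np.nan,
        }
        if meth == "envsca":
            row["mean_kappa"] = float(
                np.mean([r[meth]["kappa"] for r in reps])
            )
        rows.append(row)
    table = pd.DataFrame(rows)
    if return_raw:
        return table, reps
    return table


# ---------------------------------------------------------------------------
# synthetic hypnogram fixture generator

SLEEP_STATES = ("W", "S1", "S2", "S3", "S4", "R")


def _hypnogram_params(group: int) -> MultinomialLogitParams:
    # six sleep stages; encoding order with reference W is (S1,S2,S3,S4,R).
    # Group 1 cycles slowly (strong stage persistence), group 2 wakes and
    # switches more readily, shifting envelope power toward higher
    # frequencies — mimicking a disrupted-sleep phenotype.
    diag = 1.6 if group == 1 else 0.5
    A = np.full((5, 5), 0.8)
    np.fill_diagonal(A, diag)
    return MultinomialLogitParams(alphas=tuple(map(tuple, A)))


def synth_hypnograms(
    n_per_group: int = 15,
    length_range: tuple = (400, 700),
    seed: int | np.random.SeedSequence = 0,
) -> tuple[list[CategoricalSeries], list]:
    """Two groups of synthetic six-state hypnogram-like series.

    Each series is a lag-1 multinomial-logit chain over the sleep stages
    ``W, S1, S2, S3, S4, R`` with Wake/Movement as the reference category;
    group 1 has stronger stage persistence (slower cycling) than group 2.
    Lengths are drawn uniformly from ``length_range`` so the series are
    heterogeneous in length, exercising the periodogram-interpolation path.
    Returns ``(series, labels)``.
    """
    if n_per_group < 1:
        raise ValueError("n_per_group must be >= 1")
    lo, hi = length_range
    if not 4 <= lo <= hi:
        raise ValueError("invalid length_range")
    ss = (
        seed
        if isinstance(seed, np.random.SeedSequence)
        else np.random.SeedSequence(seed)
    )
    keys = ss.spawn(2 * n_per_group)
    space = ("W",) + SLEEP_STATES[1:]
    series, labels = [], []
    i = 0
    for group in (1, 2):
        params = _hypnogram_params(group)
        for k in range(n_per_group):
            rng = np.random.default_rng(keys[i])
            T = int(rng.integers(lo, hi + 1))
            s = simulate_series(
                params,
                T,
                rng,
                series_id=f"hyp-{group}-{k}",
                state_space=("S1", "S2", "S3", "S4", "R", "W"),
            )
            # put W first but keep it as the reference category
            s = CategoricalSeries(
                values=s.values,
                state_space=space,
                reference_state="W",
                series_id=s.series_id,
            )
            series.append(s)
            labels.append(f"group{group}")
            i += 1
    return series, labels
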