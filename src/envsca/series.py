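"""Categorical time series container and baseline indicator encoding.

A categorical time series takes values in a finite state space
``{c_1, ..., c_m}``.  For spectral analysis it is represented as an
(m-1)-dimensional 0/1 vector series: one category (the *reference*) maps to
the zero vector, every other category ``c_l`` maps to the ``l``-th standard
basis vector.  This is the baseline-category representation familiar from
categorical data analysis, and it is the encoding for which the top eigenpair
of the spectral matrix recovers the spectral envelope and optimal scalings.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = ["CategoricalSeries", "IndicatorSeries", "encode_baseline"]


@dataclass(frozen=True)
class CategoricalSeries:
    """One observed categorical series over a declared finite state space.

    Parameters
    ----------
    values : sequence of hashable labels, length T
        The observed states, in time order.
    state_space : ordered sequence of m >= 2 distinct labels
        Every element of ``values`` must appear here.
    reference_state : label, optional
        The baseline category mapped to the zero vector by the indicator
        encoding.  Defaults to the last element of ``state_space``.
    series_id : str, optional
        Identifier carried through IO and prediction tables.
    """

    values: tuple
    state_space: tuple
    reference_state: object = None
    series_id: str = ""

    def __init__(self, values, state_space, reference_state=None, series_id=""):
        object.__setattr__(self, "values", tuple(values))
        object.__setattr__(self, "state_space", tuple(state_space))
        if reference_state is None:
            reference_state = self.state_space[-1]
        object.__setattr__(self, "reference_state", reference_state)
        object.__setattr__(self, "series_id", str(series_id))
        self._validate()

    def _validate(self) -> None:
        m = len(self.state_space)
        if len(set(self.state_space)) != m:
            raise ValueError("state_space contains duplicate labels")
        if m < 2:
            raise ValueError(f"need at least 2 states, got m={m}")
        if len(self.values) < 4:
            raise ValueError(
                f"series too short (T={len(self.values)}); need T >= 4 so that "
                "at least one Fourier frequency and a smoothing span exist"
            )
        if self.reference_state not in self.state_space:
            raise ValueError(
                f"reference_state {self.reference_state!r} not in state_space"
            )
        space = set(self.state_space)
        for t, v in enumerate(self.values):
            if v not in space:
                raise ValueError(
                    f"unknown state {v!r} at position {t} "
                    f"(state space is {list(self.state_space)})"
                )

    @property
    def T(self) -> int:
        return len(self.values)

    @property
    def m(self) -> int:
        return len(self.state_space)


@dataclass(frozen=True)
class IndicatorSeries:
    """Baseline 0/1 encoding of a categorical series.

    ``Y`` is T x (m-1); row t is the indicator of the observation among the
    non-reference categories (all-zero iff the observation is the reference).
    """

    Y: np.ndarray
    category_order: tuple

    def __post_init__(self):
        Y = np.asarray(self.Y)
        if Y.ndim != 2:
            raise ValueError("Y must be a 2-d array")
        if not np.isin(Y, (0, 1)).all():
            raise ValueError("Y must contain only 0/1 values")
        if (Y.sum(axis=1) > 1).any():
            raise ValueError("each row of Y may contain at most one 1")
        object.__setattr__(self, "Y", Y.astype(float))

    @property
    def T(self) -> int:
        return self.Y.shape[0]


def encode_baseline(series: CategoricalSeries) -> IndicatorSeries:
    """Encode a categorical series as a T x (m-1) indicator matrix.

    Non-reference categories keep their order from ``state_space``; the
    reference category maps to the all-zero row.
    """
    order = tuple(s for s in series.state_space if s != series.reference_state)
    col = {s: j for j, s in enumerate(order)}
    Y = np.zeros((series.T, len(order)))
    for t, v in enumerate(series.values):
        j = col.get(v)
        if j is not None:
            Y[t, j] = 1.0
    return IndicatorSeries(Y=Y, category_order=order)
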