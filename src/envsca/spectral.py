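"""Spectral envelope and optimal scalings of a categorical time series.

The pipeline is: baseline indicator encoding -> periodogram of the resulting
(m-1)-variate 0/1 series -> kernel-smoothed spectral matrix estimate ->
per-frequency top eigenpair of the real part.  The largest eigenvalue at
frequency ``omega`` is the *spectral envelope* ``lambda(omega)`` — the
largest power spectrum achievable by assigning real numbers to the
categories — and the corresponding unit eigenvector ``gamma(omega)`` holds
the *optimal scalings* that attain it.

Frequencies are the Fourier frequencies ``omega_s = s/T`` for
``s = 1, ..., K`` with ``K = floor((T-1)/2)``; the mean-dominated ``s = 0``
ordinate is excluded throughout.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .series import CategoricalSeries, IndicatorSeries, encode_baseline

__all__ = [
    "SpectralMatrixEstimate",
    "EnvelopeScalings",
    "periodogram",
    "smoothing_weights",
    "default_bandwidth",
    "smooth_periodogram",
    "envelope_scalings",
    "features_for_series",
    "interpolate_features",
    "features_on_grid",
    "spectral_matrix_on_grid",
]

#: relative tolerance used by the sign convention: the first entry of each
#: scaling vector whose magnitude exceeds this is made positive.
SIGN_EPS = 1e-8

#: relative gap below which the top two eigenvalues are treated as tied
#: (a distinct top eigenvalue is an identifiability assumption of the model).
DEGENERACY_RTOL = 1e-10


@dataclass(frozen=True)
class SpectralMatrixEstimate:
    """Smoothed spectral matrix estimate on the Fourier grid.

    Attributes
    ----------
    freqs : (K,) array
        Fourier frequencies ``s/T`` for ``s = 1..K``.
    f_hat : (K, m-1, m-1) complex array
        Smoothed spectral matrix at each frequency; Hermitian with PSD
        real part up to numerical tolerance.
    bandwidth : int
        Half-width ``B_T`` of the smoothing window (span ``2*B_T + 1``).
    weights : (2*B_T+1,) array
        Symmetric nonnegative smoothing weights summing to one.
    """

    freqs: np.ndarray
    f_hat: np.ndarray
    bandwidth: int
    weights: np.ndarray

    @property
    def K(self) -> int:
        return self.f_hat.shape[0]

    def validate(self, rtol: float = 1e-10) -> None:
        """Check the Hermitian / PSD-real-part invariants, raising on failure."""
        F = self.f_hat
        herm = np.linalg.norm(F - F.conj().transpose(0, 2, 1), axis=(1, 2))
        scale = np.linalg.norm(F, axis=(1, 2))
        if not (herm <= rtol * np.maximum(scale, 1e-300)).all():
            raise AssertionError("spectral matrix estimate is not Hermitian")
        ev = np.linalg.eigvalsh(F.real)
        tr = np.trace(F.real, axis1=1, axis2=2)
        if not (ev.min(axis=1) >= -rtol * np.maximum(tr, 1e-300)).all():
            raise AssertionError("real part of spectral estimate is not PSD")


@dataclass(frozen=True)
class EnvelopeScalings:
    """Per-series feature pair: envelope ``lam`` and scalings ``gam``.

    ``lam`` has one entry per Fourier frequency; ``gam`` is (m-1) x K with
    one unit-norm, sign-normalised scaling vector per column.
    """

    lam: np.ndarray
    gam: np.ndarray
    freqs: np.ndarray

    @property
    def K(self) -> int:
        return self.lam.shape[0]


def periodogram(Y: IndicatorSeries | np.ndarray) -> np.ndarray:
    """Raw periodogram matrices ``I(s) = d(s) d(s)^H / T`` for ``s = 0..T-1``.

    ``d(s)`` is the discrete Fourier transform of the rows of ``Y``.  Each
    ordinate is a rank-one Hermitian PSD matrix and the conjugate symmetry
    ``I(T-s) = conj(I(s))`` holds exactly.  The ``s = 0`` ordinate is
    returned for completeness (it makes the Parseval identity exact) but is
    excluded from all downstream smoothing and eigendecomposition.
    """
    A = Y.Y if isinstance(Y, IndicatorSeries) else np.asarray(Y, dtype=float)
    T = A.shape[0]
    if T < 2:
        raise ValueError("need T >= 2 observations")
    d = np.fft.fft(A, axis=0)  # (T, p)
    return np.einsum("sa,sb->sab", d, d.conj()) / T


def default_bandwidth(T: int) -> int:
    """Default smoothing half-width ``B_T = floor(sqrt(T))``."""
    return int(np.floor(np.sqrt(T)))


def smoothing_weights(bandwidth: int, kernel: str = "modified_daniell") -> np.ndarray:
    """Symmetric, nonnegative, sum-to-one weights of span ``2*bandwidth + 1``.

    ``modified_daniell`` (default) is the flat kernel with half-weight
    endpoints; ``daniell`` is the plain flat kernel.  With bandwidth 0 both
    reduce to the identity smoother.
    """
    if bandwidth < 0:
        raise ValueError(f"bandwidth must be >= 0, got {bandwidth}")
    n = 2 * bandwidth + 1
    if bandwidth == 0:
        return np.ones(1)
    if kernel == "daniell":
        return np.full(n, 1.0 / n)
    if kernel == "modified_daniell":
        w = np.ones(n)
        w[0] = w[-1] = 0.5
        return w / (2 * bandwidth)
    raise ValueError(f"unknown kernel {kernel!r}")


def _check_weights(weights: np.ndarray, bandwidth: int) -> np.ndarray:
    w = np.asarray(weights, dtype=float)
    if w.shape != (2 * bandwidth + 1,):
        raise ValueError(
            f"weights must have length {2 * bandwidth + 1}, got {w.shape}"
        )
    if (w < 0).any():
        raise ValueError("smoothing weights must be nonnegative")
    if not np.allclose(w, w[::-1]):
        raise ValueError("smoothing weights must be symmetric")
    if not np.isclose(w.sum(), 1.0):
        raise ValueError("smoothing weights must sum to 1")
    return w


def smooth_periodogram(
    I: np.ndarray,
    bandwidth: int,
    weights: np.ndarray | None = None,
    kernel: str = "modified_daniell",
) -> SpectralMatrixEstimate:
    """Kernel-smooth the periodogram onto the grid ``s = 1..K``.

    Each output ordinate is the weighted average of the ``2*bandwidth + 1``
    periodogram ordinates centred on it.  Window indices outside ``1..T-1``
    are resolved by the conjugate-symmetric periodic extension of the
    periodogram; whenever the window covers the excluded ``s = 0`` ordinate
    that weight is dropped and the remaining weights renormalised to one.

    Parameters
    ----------
    I : (T, p, p) complex array
        Full periodogram as returned by :func:`periodogram`.
    bandwidth : int
        Half-width ``B_T`` of the smoothing window.  ``0`` gives the raw
        periodogram back.
    weights : array, optional
        Explicit weights of length ``2*bandwidth + 1``; by default built
        from ``kernel``.
    """
    I = np.asarray(I)
    T = I.shape[0]
    if bandwidth < 0:
        raise ValueError(f"bandwidth must be >= 0, got {bandwidth}")
    if 2 * bandwidth + 1 >= T - 1 and bandwidth > 0:
        raise ValueError(
            f"smoothing span {2 * bandwidth + 1} too wide for T={T} "
            "(need 2*B_T + 1 < T - 1)"
        )
    w = (
        smoothing_weights(bandwidth, kernel)
        if weights is None
        else _check_weights(weights, bandwidth)
    )
    K = (T - 1) // 2
    s = np.arange(1, K + 1)
    offsets = np.arange(-bandwidth, bandwidth + 1)
    idx = (s[:, None] + offsets[None, :]) % T  # periodic extension
    W = np.broadcast_to(w, idx.shape).copy()
    W[idx == 0] = 0.0  # drop the mean ordinate
    W /= W.sum(axis=1, keepdims=True)
    f_hat = np.einsum("kj,kjab->kab", W, I[idx])
    return SpectralMatrixEstimate(
        freqs=s / T, f_hat=f_hat, bandwidth=int(bandwidth), weights=w
    )


def envelope_scalings(S: SpectralMatrixEstimate) -> EnvelopeScalings:
    """Top eigenpair of the real part of the spectral estimate per frequency.

    Returns the spectral envelope (largest eigenvalue) and the optimal
    scalings (the associated unit eigenvector, with the first entry whose
    magnitude exceeds ``SIGN_EPS`` made positive).  A warning is emitted at
    frequencies where the top eigenvalue is numerically non-distinct, since
    the scalings are then not identified.
    """
    R = S.f_hat.real
    if not np.isfinite(R).all():
        raise ValueError("spectral matrix estimate contains non-finite entries")
    try:
        vals, vecs = np.linalg.eigh(R)
    except np.linalg.LinAlgError as exc:  # pragma: no cover
        raise np.linalg.LinAlgError(
            f"eigendecomposition failed on the frequency grid: {exc}"
        ) from exc
    lam = vals[:, -1]
    gam = vecs[:, :, -1].T.copy()  # (p, K)
    if R.shape[1] > 1:
        gap = vals[:, -1] - vals[:, -2]
        tied = gap <= DEGENERACY_RTOL * np.abs(lam)
        if tied.any():
            warnings.warn(
                "top eigenvalue numerically non-distinct at frequency index(es) "
                f"{np.flatnonzero(tied).tolist()}; optimal scalings not identified there",
                RuntimeWarning,
                stacklevel=2,
            )
    _apply_sign_convention(gam)
    return EnvelopeScalings(lam=lam, gam=gam, freqs=S.freqs.copy())


def _apply_sign_convention(gam: np.ndarray) -> None:
    """In place: make the first non-negligible entry of each column positive."""
    big = np.abs(gam) > SIGN_EPS
    any_big = big.any(axis=0)
    if not any_big.all():
        warnings.warn(
            "scaling vector(s) with all entries below the sign threshold; "
            "sign left as returned by the eigensolver",
            RuntimeWarning,
            stacklevel=3,
        )
    first = np.where(any_big, big.argmax(axis=0), 0)
    lead = gam[first, np.arange(gam.shape[1])]
    flip = any_big & (lead < 0)
    gam[:, flip] *= -1.0


def features_for_series(
    series: CategoricalSeries,
    bandwidth: int | None = None,
    kernel: str = "modified_daniell",
) -> EnvelopeScalings:
    """Envelope/scalings features of one series: encode -> periodogram ->
    smooth -> eigendecompose.  ``bandwidth=None`` uses ``floor(sqrt(T))``.
    """
    if bandwidth is None:
        bandwidth = default_bandwidth(series.T)
    Y = encode_baseline(series)
    I = periodogram(Y)
    S = smooth_periodogram(I, bandwidth, kernel=kernel)
    return envelope_scalings(S)


def interpolate_features(
    series_list: list[CategoricalSeries],
    bandwidth: int | None = None,
    kernel: str = "modified_daniell",
) -> list[EnvelopeScalings]:
    """Features for series of differing lengths on a common frequency grid.

    Each series' periodogram ordinates are linearly interpolated
    (elementwise, real and imaginary parts separately) onto the Fourier grid
    of the shortest series before smoothing and eigendecomposition, so all
    returned features share ``K_min = floor((T_min - 1)/2)`` frequencies.
    When all lengths agree this is exactly :func:`features_for_series`
    applied per series.
    """
    if len(series_list) < 2:
        raise ValueError("need at least 2 series to build a common grid")
    spaces = {s.state_space for s in series_list}
    if len(spaces) > 1:
        raise ValueError("all series must share the same state space")
    T_min = min(s.T for s in series_list)
    return [
        features_on_grid(s, T_min, bandwidth=bandwidth, kernel=kernel)
        for s in series_list
    ]


def spectral_matrix_on_grid(
    series: CategoricalSeries,
    T_common: int,
    bandwidth: int | None = None,
    kernel: str = "modified_daniell",
) -> SpectralMatrixEstimate:
    """Smoothed spectral matrix of one series on the Fourier grid of a
    length-``T_common`` series, via linear interpolation of its periodogram
    ordinates (real and imaginary parts elementwise).

    ``T_common`` must not exceed the series length (interpolating onto a
    finer grid than the observed one would extrapolate beyond the observed
    frequency range).  The smoothing bandwidth defaults to
    ``floor(sqrt(T_common))``.
    """
    if T_common > series.T:
        raise ValueError(
            f"common grid length {T_common} exceeds series length {series.T}"
        )
    if bandwidth is None:
        bandwidth = default_bandwidth(T_common)
    I = periodogram(encode_baseline(series))
    if series.T == T_common:
        return smooth_periodogram(I, bandwidth, kernel=kernel)
    target = np.arange(1, T_common) / T_common  # full grid s=1..T_common-1
    src = np.arange(1, series.T) / series.T
    flat = I[1:].reshape(series.T - 1, -1)
    cols = [
        np.interp(target, src, flat[:, j].real)
        + 1j * np.interp(target, src, flat[:, j].imag)
        for j in range(flat.shape[1])
    ]
    I_common = np.stack(cols, axis=1).reshape(T_common - 1, *I.shape[1:])
    # re-attach a zero s=0 slot so indexing matches the equal-length path
    I_full = np.concatenate([np.zeros_like(I_common[:1]), I_common], axis=0)
    return smooth_periodogram(I_full, bandwidth, kernel=kernel)


def features_on_grid(
    series: CategoricalSeries,
    T_common: int,
    bandwidth: int | None = None,
    kernel: str = "modified_daniell",
) -> EnvelopeScalings:
    """Envelope/scalings of one series on a common Fourier grid; see
    :func:`spectral_matrix_on_grid` for the interpolation convention."""
    return envelope_scalings(
        spectral_matrix_on_grid(series, T_common, bandwidth, kernel)
    )
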