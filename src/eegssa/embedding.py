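"""Embedding-dimension selection and the diagnostics that justify it.

The central rule is ``L = ceil(fs / fb)``: each reconstructed component of
an SSA decomposition concentrates its spectrum in a band of width roughly
``fs / L`` Hz, so to isolate a rhythm of bandwidth ``fb`` the embedding
window must span at least ``fs / fb`` samples (one period of the band's
width).  Larger L narrows each component further but, on signals with
complicated structure, eventually mixes the rhythm of interest across
components.

The supporting machinery implemented here:

* the symmetric Toeplitz approximation ``T`` to the lag-covariance matrix
  ``X^T X`` (valid when K >> L), with lag sums
  ``z_l = sum_{n=1}^{K} s_n s_{n+l}``;
* the circulant eigenvalue formula
  ``lambda_p ~= sum_j z_|j| exp(i 2 pi j p / L)``;
* the spectral approximation ``lambda_p ~= sum_q |s_hat_q|^2 zeta_{p,q}``
  with Dirichlet-kernel weights
  ``zeta_{p,q} = 1 + 2 sum_{m=1}^{L-1} cos(2 pi m (p/L + q/K))``,
  which shows each eigenvalue to be a windowed average of the power
  spectrum over a width of about ``K / L`` DFT bins, i.e. ``fs / L`` Hz;
* the trace profile ``Tr_L = trace(X^T X)`` whose increments
  ``Tr_L - Tr_{L-1} = sum_{j=L}^{K} s_j^2`` shrink as L grows, quantifying
  the diminishing return of a larger window.

These diagnostics justify and sanity-check the rule; extraction itself
always uses the exact SVD (:mod:`eegssa.ssa`), never the approximations.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.linalg

from .bands import RhythmBand
from .series import TimeSeries

__all__ = [
    "ToeplitzCovariance",
    "SpectralApprox",
    "TraceProfile",
    "EmbeddingReport",
    "select_embedding",
    "component_bandwidth",
    "toeplitz_covariance",
    "circulant_eigenvalues",
    "spectral_approximation",
    "trace_profile",
    "recommend_embedding_report",
]


def select_embedding(fs: float, fb: float) -> int:
    """Embedding dimension for a target bandwidth: ``L = ceil(fs / fb)``.

    The ceiling guarantees the per-component bandwidth ``fs / L <= fb`` even
    when the ratio is not an integer.

    Raises
    ------
    ValueError
        If ``fb`` is not in (0, fs / 2]: a band wider than Nyquist cannot be
        resolved.
    """
    if fs <= 0:
        raise ValueError(f"sampling rate must be positive, got {fs}")
    if not 0 < fb <= fs / 2:
        raise ValueError(
            f"bandwidth fb={fb} Hz not resolvable: must satisfy 0 < fb <= fs/2 = {fs / 2}"
        )
    return math.ceil(fs / fb)


def component_bandwidth(fs: float, L: int) -> float:
    """Spectral width ``fs / L`` (Hz) of each reconstructed component."""
    if fs <= 0:
        raise ValueError(f"sampling rate must be positive, got {fs}")
    if int(L) < 1:
        raise ValueError(f"embedding dimension must be >= 1, got {L}")
    return fs / int(L)


@dataclass(frozen=True)
class ToeplitzCovariance:
    """Toeplitz approximation to the lag covariance X^T X.

    ``lags[l]`` is ``z_l = sum_{n=1}^{K} s_n s_{n+l}`` (a fixed K-term sum
    for every lag, so the required samples up to index K + L - 1 = N always
    exist); ``matrix`` is the L x L symmetric Toeplitz built from the lags.
    """

    lags: np.ndarray
    matrix: np.ndarray
    L: int
    K: int


def toeplitz_covariance(series: TimeSeries, L: int) -> ToeplitzCovariance:
    """Build the Toeplitz lag-covariance approximation for window length L.

    Valid as an approximation of X^T X when K = N - L + 1 >> L; a warning is
    emitted when K < 10 L.
    """
    L = int(L)
    N = series.n
    if not 1 <= L <= N - 1:
        raise ValueError(f"embedding dimension L={L} outside valid interval [1, {N - 1}]")
    K = N - L + 1
    if K < 10 * L:
        warnings.warn(
            f"K={K} < 10*L={10 * L}: Toeplitz approximation of X^T X may be poor",
            stacklevel=2,
        )
    s = series.values
    head = s[:K]
    z = np.array([head @ s[l : l + K] for l in range(L)])
    return ToeplitzCovariance(lags=z, matrix=scipy.linalg.toeplitz(z), L=L, K=K)


def circulant_eigenvalues(cov: ToeplitzCovariance) -> np.ndarray:
    """Circulant-style eigenvalue formula for a symmetric Toeplitz matrix.

    ``lambda_p = sum_{j=-(L-1)}^{L-1} z_|j| exp(i 2 pi j p / L)`` — real by
    symmetry; an approximation to the true eigenvalues that sharpens as the
    spectrum of the signal smooths.  Returned unsorted (index p = 0..L-1).
    """
    z = cov.lags
    L = cov.L
    p = np.arange(L)
    j = np.arange(-(L - 1), L)
    phases = np.cos(2 * np.pi * np.outer(p, j) / L)
    return phases @ z[np.abs(j)]


@dataclass(frozen=True)
class SpectralApprox:
    """Eigenvalue-spectrum approximation of the Toeplitz covariance.

    ``power[q] = |s_hat_q|^2`` is the unitary-DFT power of the first K
    samples; ``zeta[p, q]`` the Dirichlet-kernel weights;
    ``approx_eigenvalues[p] = sum_q power[q] * zeta[p, q]``.
    ``component_frequencies[p]`` maps index p to the centre frequency (Hz)
    of the spectral window that dominates lambda_p.
    """

    power: np.ndarray
    zeta: np.ndarray
    approx_eigenvalues: np.ndarray
    component_frequencies: np.ndarray
    L: int
    K: int
    fs: float


def _zeta_table(L: int, K: int) -> np.ndarray:
    """Dirichlet-kernel weights zeta_{p,q} = 1 + 2 sum_m cos(2 pi m (p/L + q/K)).

    Closed form sin((2L-1) pi x) / sin(pi x) at x = frac(p/L + q/K), equal to
    2L - 1 whenever x is an integer.  Depends on x only through its
    fractional part.
    """
    p = np.arange(L)[:, None] / L
    q = np.arange(K)[None, :] / K
    x = np.mod(p + q, 1.0)
    sin_x = np.sin(np.pi * x)
    with np.errstate(divide="ignore", invalid="ignore"):
        table = np.sin((2 * L - 1) * np.pi * x) / sin_x
    return np.where(np.abs(sin_x) < 1e-9, float(2 * L - 1), table)


def spectral_approximation(series: TimeSeries, L: int) -> SpectralApprox:
    """Approximate the Toeplitz-covariance eigenvalues from the DFT power.

    Each ``lambda_p`` is a weighted average of the power spectrum of the
    first K samples over a window about K/L bins wide (fs/L Hz), which is
    the quantitative basis of the bandwidth rule.  Diagnostic only — rhythm
    extraction always uses the exact SVD.
    """
    L = int(L)
    N = series.n
    if not 1 <= L <= N - 1:
        raise ValueError(f"embedding dimension L={L} outside valid interval [1, {N - 1}]")
    K = N - L + 1
    spec = np.fft.fft(series.values[:K])
    power = np.abs(spec) ** 2 / K  # unitary normalization: sum(power) = sum(s^2)
    zeta = _zeta_table(L, K)
    lam = zeta @ power
    p = np.arange(L)
    freqs = series.fs * np.minimum(p, L - p) / L
    return SpectralApprox(
        power=power,
        zeta=zeta,
        approx_eigenvalues=lam,
        component_frequencies=freqs,
        L=L,
        K=K,
        fs=series.fs,
    )


@dataclass(frozen=True)
class TraceProfile:
    """Trace of the covariance X^T X as a function of embedding dimension.

    ``traces[i] = trace(X^T X)`` at ``L = L_values[i]`` (equal to the sum of
    all SSA eigenvalues at that L); ``deltas[i] = Tr_L - Tr_{L-1}``, which
    satisfies the exact identity ``Tr_L - Tr_{L-1} = sum_{j=L}^{K} s_j^2``
    (1-based, K = N - L + 1) and therefore shrinks as L grows: the
    information gained by enlarging the window diminishes.
    """

    L_values: np.ndarray
    traces: np.ndarray
    deltas: np.ndarray


def _covariance_trace(squares: np.ndarray, L: int) -> float:
    """trace(X^T X) = sum_j c_L(j) s_j^2 with c_L(j) the Hankel multiplicity."""
    N = squares.size
    K = N - L + 1
    j = np.arange(1, N + 1)
    counts = np.minimum.reduce([j, np.full(N, min(L, K)), N - j + 1])
    return float(counts @ squares)


def trace_profile(series: TimeSeries, L_values) -> TraceProfile:
    """Compute the covariance-trace profile over a grid of embedding dimensions."""
    Ls = np.unique(np.asarray(L_values, dtype=int))
    N = series.n
    if Ls.size == 0:
        raise ValueError("L_values must be non-empty")
    if Ls[0] < 2 or Ls[-1] > N - 1:
        raise ValueError(f"L values must lie in [2, {N - 1}], got range [{Ls[0]}, {Ls[-1]}]")
    squares = series.values**2
    traces = np.array([_covariance_trace(squares, int(L)) for L in Ls])
    deltas = np.array(
        [_covariance_trace(squares, int(L)) - _covariance_trace(squares, int(L) - 1) for L in Ls]
    )
    return TraceProfile(L_values=Ls, traces=traces, deltas=deltas)


@dataclass(frozen=True)
class EmbeddingReport:
    """Bundled recommendation: the chosen L plus diagnostics and warnings."""

    L: int
    component_bandwidth_hz: float
    fs: float
    band: RhythmBand
    K: int
    n: int
    degenerate: bool
    warnings: tuple[str, ...]
    trace: TraceProfile | None = field(repr=False, default=None)


def recommend_embedding_report(series: TimeSeries, band: RhythmBand) -> EmbeddingReport:
    """Apply the selection rule to a concrete record and collect caveats.

    Flags (without failing) the cases where the rule's assumptions strain:
    ``L`` exceeding ``K`` is never allowed, the most detailed decomposition
    is reached near ``L = N/2``, and a constant (rank-one) record carries no
    rhythm to select a window for.
    """
    fs = series.fs
    L = select_embedding(fs, band.fb)
    N = series.n
    notes: list[str] = []
    degenerate = bool(np.ptp(series.values) == 0)
    if degenerate:
        notes.append("degenerate input: constant series has a rank-1 trajectory matrix")
    if fs / band.fb > N / 2:
        notes.append(
            f"fs/fb = {fs / band.fb:.1f} exceeds N/2 = {N / 2:.0f}: "
            "embedding dimension beyond half the record length is not meaningful"
        )
    L_eff = min(L, N - 1) if N - 1 >= 2 else L
    if L > N - L + 1:
        notes.append(f"L = {L} exceeds K = N - L + 1 = {N - L + 1}; decomposition not allowed")
    trace = None
    if not degenerate and 2 <= L_eff <= N - 1:
        lo = max(2, L_eff // 4)
        hi = min(max(2 * L_eff, lo + 1), N - 1)
        grid = np.unique(np.linspace(lo, hi, num=min(25, hi - lo + 1), dtype=int))
        trace = trace_profile(series, grid)
    return EmbeddingReport(
        L=L,
        component_bandwidth_hz=component_bandwidth(fs, L),
        fs=fs,
        band=band,
        K=N - L + 1,
        n=N,
        degenerate=degenerate,
        warnings=tuple(notes),
        trace=trace,
    )
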