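"""Core singular spectrum analysis: embedding, SVD, reconstruction.

SSA decomposes a one-dimensional signal s = (s_1, ..., s_N) in four steps:

1. *Embedding*: map s into the K x L Hankel trajectory matrix X whose row k
   is the lagged window (s_k, ..., s_{k+L-1}), with K = N - L + 1.
2. *Decomposition*: SVD X = sum_i sqrt(lambda_i) u_i v_i^T, where the
   lambda_i (squared singular values) are the eigenvalues of X^T X in
   decreasing order.
3. *Grouping*: pick the subset of elementary matrices that carries the
   structure of interest (see :mod:`eegssa.grouping`).
4. *Diagonal averaging* (Hankelization): map the grouped matrix back to a
   length-N series by averaging each anti-diagonal.

The SVD is taken on X directly rather than by eigen-decomposing X^T X, for
numerical stability; eigenvalues are reported as squared singular values.
Component indices are 1-based in user-facing interfaces ("RC1" is the
leading component).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import TYPE_CHECKING, Sequence

import numpy as np

from .bands import RhythmBand
from .series import TimeSeries

if TYPE_CHECKING:  # pragma: no cover
    from .grouping import ComponentSpectrum

__all__ = [
    "TrajectoryMatrix",
    "SSADecomposition",
    "ExtractionResult",
    "embed",
    "decompose",
    "diagonal_average",
    "reconstruct_group",
    "extract_rhythm",
]


@dataclass(frozen=True)
class TrajectoryMatrix:
    """K x L Hankel matrix of lagged signal windows (K = N - L + 1)."""

    matrix: np.ndarray
    L: int
    K: int
    fs: float

    @property
    def n(self) -> int:
        return self.K + self.L - 1


@dataclass(frozen=True)
class SSADecomposition:
    """Result of the SVD step plus per-component reconstructed series.

    Attributes
    ----------
    eigenvalues : (r,) array
        lambda_1 >= ... >= lambda_r > 0, the squared singular values of the
        trajectory matrix (units uV^2 * samples).
    left_vectors : (K, r) array
        Orthonormal left singular vectors u_i.
    right_vectors : (L, r) array
        Orthonormal right singular vectors v_i.
    components : (r, N) array
        Reconstructed component series RC_i: each rank-one elementary matrix
        sqrt(lambda_i) u_i v_i^T diagonally averaged back to a series.
    """

    eigenvalues: np.ndarray
    left_vectors: np.ndarray
    right_vectors: np.ndarray
    components: np.ndarray
    fs: float
    L: int
    K: int

    @property
    def rank(self) -> int:
        return self.eigenvalues.size

    @property
    def n(self) -> int:
        return self.K + self.L - 1

    def component_series(self, rc_index: int) -> TimeSeries:
        """Return RC ``rc_index`` (1-based) as a :class:`TimeSeries`."""
        if not 1 <= rc_index <= self.rank:
            raise IndexError(f"rc_index must be in [1, {self.rank}], got {rc_index}")
        return TimeSeries(self.components[rc_index - 1], self.fs)


def embed(series: TimeSeries, L: int) -> TrajectoryMatrix:
    """Time-delay embedding of a series into its K x L trajectory matrix.

    Row k (0-based) is the window ``(s_k, ..., s_{k+L-1})``; entries are
    constant along anti-diagonals (Hankel structure).

    Raises
    ------
    ValueError
        If ``L`` is outside the valid interval [2, N - 1].
    """
    L = int(L)
    N = series.n
    if not 2 <= L <= N - 1:
        raise ValueError(f"embedding dimension L={L} outside valid interval [2, {N - 1}]")
    K = N - L + 1
    # stride trick view, then copy so downstream code may assume contiguity
    windows = np.lib.stride_tricks.sliding_window_view(series.values, L).copy()
    return TrajectoryMatrix(matrix=windows, L=L, K=K, fs=series.fs)


def diagonal_average(matrix: np.ndarray) -> np.ndarray:
    """Map a K x L matrix to a length K + L - 1 series by anti-diagonal means.

    Inverse of :func:`embed` on Hankel matrices: each output sample is the
    mean of the matrix entries covering it.
    """
    m = np.asarray(matrix, dtype=float)
    if m.ndim != 2:
        raise ValueError(f"expected a 2-D matrix, got shape {m.shape}")
    K, L = m.shape
    n = K + L - 1
    sums = np.zeros(n)
    for col in range(L):
        sums[col : col + K] += m[:, col]
    return sums / _antidiagonal_counts(K, L)


def _antidiagonal_counts(K: int, L: int) -> np.ndarray:
    """Number of (row, col) pairs on each anti-diagonal of a K x L matrix."""
    idx = np.arange(K + L - 1)
    return np.minimum.reduce([idx + 1, np.full_like(idx, min(K, L)), K + L - 1 - idx])


def decompose(traj: TrajectoryMatrix) -> SSADecomposition:
    """SVD of the trajectory matrix plus diagonal-averaged components.

    Singular values below ``max(K, L) * eps * sigma_1`` are treated as zero
    (numerical rank), so every reported eigenvalue is strictly positive.
    An all-zero input yields rank 0 and an empty component list.
    """
    X = traj.matrix
    if not np.all(np.isfinite(X)):
        raise ValueError("trajectory matrix contains non-finite entries")
    U, sv, Vt = np.linalg.svd(X, full_matrices=False)
    if sv.size and sv[0] > 0:
        tol = max(X.shape) * np.finfo(float).eps * sv[0]
        r = int(np.count_nonzero(sv > tol))
    else:
        r = 0
    U, sv, Vt = U[:, :r], sv[:r], Vt[:r]
    counts = _antidiagonal_counts(traj.K, traj.L)
    if r:
        # anti-diagonal sums of the rank-one outer product u v^T are the
        # linear convolution of u with v
        comps = np.stack(
            [sv[i] * np.convolve(U[:, i], Vt[i]) / counts for i in range(r)]
        )
    else:
        comps = np.zeros((0, traj.n))
    return SSADecomposition(
        eigenvalues=sv**2,
        left_vectors=U,
        right_vectors=Vt.T,
        components=comps,
        fs=traj.fs,
        L=traj.L,
        K=traj.K,
    )


def reconstruct_group(decomp: SSADecomposition, group: Sequence[int]) -> TimeSeries:
    """Sum the elementary matrices over ``group`` and diagonal-average.

    ``group`` holds unique 1-based component indices.  Diagonal averaging is
    linear, so the result equals the sum of the individual component series.

    Raises
    ------
    ValueError
        If the group is empty or contains invalid/duplicate indices.
    """
    indices = list(group)
    if not indices:
        raise ValueError("group must contain at least one component index")
    if len(set(indices)) != len(indices):
        raise ValueError(f"group indices must be unique, got {indices}")
    for i in indices:
        if not 1 <= int(i) <= decomp.rank:
            raise ValueError(f"component index {i} outside [1, {decomp.rank}]")
    total = decomp.components[[int(i) - 1 for i in indices]].sum(axis=0)
    return TimeSeries(total, decomp.fs)


@dataclass(frozen=True)
class ExtractionResult:
    """Outcome of a full SSA rhythm extraction.

    ``rhythm`` is the reconstructed in-band series; when no component peaked
    inside the band the selection is empty, ``rhythm`` is all-zero and
    :attr:`is_empty` is True — a legal outcome, distinct from an error.
    """

    rhythm: TimeSeries
    selected: tuple[int, ...]
    spectra: list["ComponentSpectrum"] = field(repr=False)
    decomposition: SSADecomposition = field(repr=False)
    band: RhythmBand
    L: int

    @property
    def is_empty(self) -> bool:
        return not self.selected


def extract_rhythm(
    series: TimeSeries,
    band: RhythmBand,
    L: int | None = None,
    *,
    min_peak_power: float = 0.5,
    min_relative_power: float = 0.02,
) -> ExtractionResult:
    """Extract one rhythm: embed, decompose, group by band, reconstruct.

    Parameters
    ----------
    series : TimeSeries
        The (possibly artifact-laden) input signal.
    band : RhythmBand
        Target rhythm band; its bandwidth sets L when ``L`` is None via the
        rule ``L = ceil(fs / fb)``.
    L : int, optional
        Explicit embedding dimension, overriding the rule.
    min_peak_power, min_relative_power :
        Grouping thresholds, see :class:`eegssa.grouping.GroupingParams`.
    """
    from .embedding import select_embedding
    from .grouping import GroupingParams, component_spectra, group_by_band

    if L is None:
        L = select_embedding(series.fs, band.fb)
    traj = embed(series, L)
    decomp = decompose(traj)
    spectra = component_spectra(decomp)
    params = GroupingParams(
        band=band, min_peak_power=min_peak_power, min_relative_power=min_relative_power
    )
    selected = group_by_band(spectra, params)
    if selected:
        rhythm = reconstruct_group(decomp, selected)
    else:
        rhythm = TimeSeries(np.zeros(series.n), series.fs)
    return ExtractionResult(
        rhythm=rhythm,
        selected=selected,
        spectra=spectra,
        decomposition=decomp,
        band=band,
        L=L,
    )
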