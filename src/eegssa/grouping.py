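"""Adaptive grouping: which reconstructed components form the rhythm?

After the SVD step, each reconstructed component (RC) is characterized by
the peak frequency and peak power of its spectrum.  An RC belongs to the
rhythm of interest when its PSD peak lies inside the target band and its
peak power clears a noise floor; low-power in-band components are rejected
as noise rather than rhythm (an RC peaking below ~0.5 uV^2/Hz against
neighbours at several uV^2/Hz carries no physiological alpha).

Oscillatory sources typically occupy a *pair* of near-equal eigenvalues
(sine/cosine pair); :func:`eigenvalue_pairs` reports such pairs as a
diagnostic, but the operative selection rule is peak-frequency plus power.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import TYPE_CHECKING, Sequence

import numpy as np

from .bands import RhythmBand
from .evaluation import PSDEstimate, estimate_psd
from .series import TimeSeries

if TYPE_CHECKING:  # pragma: no cover
    from .ssa import SSADecomposition

__all__ = [
    "ComponentSpectrum",
    "GroupingParams",
    "component_spectra",
    "group_by_band",
    "eigenvalue_pairs",
]


@dataclass(frozen=True)
class ComponentSpectrum:
    """Spectral summary of one reconstructed component (1-based index)."""

    rc_index: int
    psd: PSDEstimate
    peak_frequency: float
    peak_power: float
    eigenvalue: float


@dataclass(frozen=True)
class GroupingParams:
    """Selection thresholds for :func:`group_by_band`.

    ``min_peak_power`` (uV^2/Hz) is an absolute noise floor;
    ``min_relative_power`` rejects components whose peak is a tiny fraction
    of the strongest RC peak.  A component must clear
    ``max(min_peak_power, min_relative_power * max_peak)``.
    """

    band: RhythmBand
    min_peak_power: float = 0.5
    min_relative_power: float = 0.02

    def __post_init__(self) -> None:
        if self.min_peak_power < 0:
            raise ValueError("min_peak_power must be non-negative")
        if not 0 <= self.min_relative_power <= 1:
            raise ValueError("min_relative_power must lie in [0, 1]")


def component_spectra(decomp: "SSADecomposition") -> list[ComponentSpectrum]:
    """Welch PSD, peak frequency and peak power of every RC."""
    out: list[ComponentSpectrum] = []
    for i in range(decomp.rank):
        psd = estimate_psd(TimeSeries(decomp.components[i], decomp.fs))
        out.append(
            ComponentSpectrum(
                rc_index=i + 1,
                psd=psd,
                peak_frequency=psd.peak_frequency,
                peak_power=psd.peak_power,
                eigenvalue=float(decomp.eigenvalues[i]),
            )
        )
    return out


def group_by_band(
    spectra: Sequence[ComponentSpectrum], params: GroupingParams
) -> tuple[int, ...]:
    """Indices (1-based, ascending) of RCs that belong to the band.

    A component is selected when its PSD peak frequency lies in
    ``[f_low, f_high]`` and its peak power reaches
    ``max(min_peak_power, min_relative_power * global max peak power)``.
    Deterministic and order-preserving; an empty result is legal and means
    the record carries no component peaking in the band.
    """
    if not spectra:
        return ()
    global_max = max(cs.peak_power for cs in spectra)
    floor = max(params.min_peak_power, params.min_relative_power * global_max)
    return tuple(
        cs.rc_index
        for cs in spectra
        if params.band.contains(cs.peak_frequency) and cs.peak_power >= floor
    )


def eigenvalue_pairs(
    decomp: "SSADecomposition", rel_tol: float = 0.1
) -> list[tuple[int, int]]:
    """Adjacent eigenvalue pairs within ``rel_tol`` relative difference.

    Diagnostic for oscillatory components, which occupy two near-equal
    eigenvalues; not used by the selection rule.
    """
    lam = decomp.eigenvalues
    pairs: list[tuple[int, int]] = []
    i = 0
    while i + 1 < lam.size:
        if lam[i] > 0 and (lam[i] - lam[i + 1]) / lam[i] <= rel_tol:
            pairs.append((i + 1, i + 2))
            i += 2
        else:
            i += 1
    return pairs
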