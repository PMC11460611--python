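"""Audiogram data model, inclusion screening, and filter-shape rules.

An audiogram is a set of pure-tone hearing thresholds (dB HL) at standard
audiometric frequencies.  This module screens audiograms against the study
inclusion rule (no threshold above 90 dB HL anywhere in 0.125-20 kHz),
extracts the contiguous frequency band of clinically relevant hearing loss,
and maps adjacent-threshold differences to the smoothing parameter that
controls the sharpness of the band-pass filter skirts used in treatment
sound synthesis.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

#: Standard audiometric test frequencies covered by the protocol (Hz).
STANDARD_FREQUENCIES_HZ: tuple[int, ...] = (
    125, 250, 500, 1000, 2000, 4000, 8000, 10000, 12000, 16000, 20000,
)

#: Inclusion cut: any threshold strictly above this excludes the subject.
INCLUSION_MAX_DB_HL: float = 90.0

#: Default dB HL cut defining "hearing loss" at a frequency (standard
#: clinical boundary between normal hearing and mild loss).
HEARING_LOSS_CRITERION_DB_HL: float = 25.0

#: Half-octave widening applied to a degenerate single-frequency loss band.
DEGENERATE_BAND_HALF_OCTAVES: float = 0.25


class NoHearingLossError(ValueError):
    """No threshold exceeds the hearing-loss criterion: sound enrichment
    is undefined for this audiogram."""


@dataclass(frozen=True)
class FrequencyBand:
    """A positive-frequency interval ``(f_low_hz, f_high_hz)``."""

    f_low_hz: float
    f_high_hz: float

    def __post_init__(self) -> None:
        if not (0 < self.f_low_hz < self.f_high_hz):
            raise ValueError(
                f"need 0 < f_low < f_high, got ({self.f_low_hz}, {self.f_high_hz})"
            )

    @property
    def width_octaves(self) -> float:
        return math.log2(self.f_high_hz / self.f_low_hz)

    def contains(self, f_hz: float) -> bool:
        return self.f_low_hz <= f_hz <= self.f_high_hz


@dataclass(frozen=True)
class EdgeSmoothing:
    """Smoothing parameter ``s`` attached to a band-edge frequency.

    ``s`` is the unitless 1-100 sharpness control of the band-pass filter:
    higher means a gentler spectral transition.
    """

    boundary_hz: float
    s: int

    def __post_init__(self) -> None:
        if not (1 <= self.s <= 100):
            raise ValueError(f"smoothing parameter must be in [1, 100], got {self.s}")
        if self.boundary_hz <= 0:
            raise ValueError("boundary frequency must be positive")


@dataclass(frozen=True)
class Audiogram:
    """Per-frequency hearing thresholds for one ear (or the binaural mean).

    Rows are canonically sorted by frequency on construction, so equality
    and all downstream operations are invariant to input row order.
    """

    frequencies_hz: tuple[float, ...]
    thresholds_db_hl: tuple[float, ...]
    ear: str = "binaural-mean"

    def __post_init__(self) -> None:
        freqs = tuple(float(f) for f in self.frequencies_hz)
        thrs = tuple(float(t) for t in self.thresholds_db_hl)
        if len(freqs) != len(thrs):
            raise ValueError("frequencies and thresholds must have equal length")
        if len(freqs) < 2:
            raise ValueError("an audiogram needs at least 2 frequencies")
        order = sorted(range(len(freqs)), key=lambda i: freqs[i])
        freqs = tuple(freqs[i] for i in order)
        thrs = tuple(thrs[i] for i in order)
        if any(f2 <= f1 for f1, f2 in zip(freqs, freqs[1:])):
            raise ValueError("frequencies must be strictly ascending (no duplicates)")
        if any(not (-10.0 <= t <= 120.0) for t in thrs):
            raise ValueError("thresholds must lie in [-10, 120] dB HL")
        if self.ear not in ("left", "right", "binaural-mean"):
            raise ValueError(f"unknown ear label: {self.ear!r}")
        object.__setattr__(self, "frequencies_hz", freqs)
        object.__setattr__(self, "thresholds_db_hl", thrs)

    def threshold_at(self, f_hz: float) -> float:
        """Threshold at an exact test frequency."""
        try:
            i = self.frequencies_hz.index(float(f_hz))
        except ValueError:
            raise KeyError(f"{f_hz} Hz is not a test frequency of this audiogram")
        return self.thresholds_db_hl[i]

    def interp_threshold(self, f_hz: float) -> float:
        """Threshold linearly interpolated in log-frequency; clamped at the ends."""
        import numpy as np

        x = math.log2(max(f_hz, 1e-6))
        xs = [math.log2(f) for f in self.frequencies_hz]
        return float(np.interp(x, xs, self.thresholds_db_hl))

    # -- CSV dialect: two columns `frequency_hz,threshold_db_hl`, header required

    @classmethod
    def from_csv(cls, path: str | Path, ear: str = "binaural-mean") -> "Audiogram":
        df = pd.read_csv(path)
        expected = {"frequency_hz", "threshold_db_hl"}
        if not expected.issubset(df.columns):
            raise ValueError(f"audiogram CSV must have columns {sorted(expected)}")
        return cls(
            frequencies_hz=tuple(df["frequency_hz"].astype(float)),
            thresholds_db_hl=tuple(df["threshold_db_hl"].astype(float)),
            ear=ear,
        )

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame(
            {"frequency_hz": self.frequencies_hz, "threshold_db_hl": self.thresholds_db_hl}
        ).to_csv(path, index=False)


def check_inclusion(aud: Audiogram, max_db_hl: float = INCLUSION_MAX_DB_HL) -> bool:
    """Study inclusion screen: True iff every threshold is <= 90 dB HL.

    The bound is strict on the exclusion side ("greater than 90 dB"), so a
    threshold of exactly 90 dB HL is still included.
    """
    return all(t <= max_db_hl for t in aud.thresholds_db_hl)


def hearing_loss_band(
    aud: Audiogram, criterion_db: float = HEARING_LOSS_CRITERION_DB_HL
) -> FrequencyBand:
    """Contiguous frequency band where hearing loss exceeds the criterion.

    Returns the span from the lowest to the highest test frequency whose
    threshold is strictly above ``criterion_db``.  Interior dips below the
    criterion do not split the band.  A single qualifying frequency yields
    a degenerate band, widened to a half-octave around that frequency so
    the passband is usable for synthesis.

    Raises
    ------
    NoHearingLossError
        If no threshold exceeds the criterion.
    """
    qual = [f for f, t in zip(aud.frequencies_hz, aud.thresholds_db_hl) if t > criterion_db]
    if not qual:
        raise NoHearingLossError(
            f"no threshold exceeds {criterion_db} dB HL; sound enrichment undefined"
        )
    f_lo, f_hi = qual[0], qual[-1]
    if f_lo == f_hi:
        half = 2.0 ** DEGENERATE_BAND_HALF_OCTAVES
        return FrequencyBand(f_lo / half, f_hi * half)
    return FrequencyBand(f_lo, f_hi)


def smoothing_parameter(adjacent_diff_db: float) -> int:
    """Map an adjacent-threshold difference (dB) to the 1-100 smoothing value.

    A slight difference gets proportionally high smoothing (gentle filter
    skirt); a significant difference (>= 20 dB) gets low smoothing (1-10,
    sharp skirt).  Piecewise-linear:

    * ``d < 20``:  ``s = round(100 - 2 d)``  (so d=0 -> 100, d=10 -> 80)
    * ``d >= 20``: ``s = clamp(round(10 (40 - d) / 20), 1, 10)``

    Monotone non-increasing in ``d``; always in [1, 100].
    """
    d = float(adjacent_diff_db)
    if d < 0:
        raise ValueError(f"adjacent threshold difference must be >= 0, got {d}")
    if d < 20.0:
        s = round(100.0 - 2.0 * d)
    else:
        s = round(10.0 * (40.0 - d) / 20.0)
        s = min(max(s, 1), 10)
    return int(min(max(s, 1), 100))


def edge_smoothings(aud: Audiogram, band: FrequencyBand) -> list[EdgeSmoothing]:
    """Smoothing parameters for each adjacent-frequency pair inside the band.

    Each pair of adjacent audiogram frequencies that overlaps the band emits
    ``smoothing_parameter(|delta threshold|)`` keyed to the pair's upper
    frequency.  The first and last entries govern the lower and upper filter
    skirts respectively.

    Raises
    ------
    ValueError
        If the band lies outside the audiogram's frequency range.
    """
    freqs = aud.frequencies_hz
    if band.f_high_hz < freqs[0] or band.f_low_hz > freqs[-1]:
        raise ValueError("band lies outside the audiogram frequency range")
    out: list[EdgeSmoothing] = []
    for (f1, t1), (f2, t2) in zip(
        zip(freqs, aud.thresholds_db_hl), zip(freqs[1:], aud.thresholds_db_hl[1:])
    ):
        if f2 > band.f_low_hz and f1 < band.f_high_hz:
            out.append(EdgeSmoothing(f2, smoothing_parameter(abs(t2 - t1))))
    if not out:
        # degenerate widened band between two test frequencies: fall back to
        # the maximally gentle skirt
        out.append(EdgeSmoothing(band.f_high_hz, 100))
    return out
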