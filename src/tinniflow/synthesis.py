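"""Individualized treatment-sound synthesis.

The treatment sound is built in three stages from seeded Gaussian white
noise at 44.1 kHz:

* **v1** — white noise band-pass filtered to the listener's hearing-loss
  frequency range, with a per-frequency amplitude envelope that follows the
  audiogram (gain in dB = threshold - criterion, interpolated in
  log-frequency), so the spectrum compensates the hearing-loss
  configuration;
* **v2** — an independent white noise band-pass filtered to +/-10% around
  the tinnitus pitch;
* **v3** — the mono mix v1 + g*v2 with g set so the tinnitus band sits a
  configurable number of dB above the v1 reference level, peak-normalized
  to -1 dBFS.

Filters are realized as frequency-domain gains with raised-cosine
(Hann-shaped) skirts whose transition width in octaves scales linearly
with the audiogram-derived smoothing parameter s: s=100 spans 1/3 octave,
s=1 spans 1/300 octave.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
from scipy import signal
from scipy.io import wavfile

from .audiogram import (
    Audiogram,
    EdgeSmoothing,
    FrequencyBand,
    HEARING_LOSS_CRITERION_DB_HL,
    check_inclusion,
    edge_smoothings,
    hearing_loss_band,
)

#: Maximum skirt transition width (octaves) at smoothing s = 100.
MAX_TRANSITION_OCTAVES = 1.0 / 3.0

#: Default smoothing when a band edge has no audiogram-derived value
#: (e.g. the tinnitus-pitch band): mid-scale.
DEFAULT_EDGE_S = 50

#: Welch PSD settings fixed for reproducible spectrum reports.
WELCH_NPERSEG = 4096

#: Peak normalization target (linear amplitude for -1 dBFS).
PEAK_DBFS = -1.0

#: Loop crossfade applied to the written treatment sound.
LOOP_CROSSFADE_S = 0.050


@dataclass(frozen=True)
class NoiseSpec:
    """Parameters of the seeded white-noise source."""

    fs_hz: int = 44100
    duration_s: float = 60.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.duration_s <= 0:
            raise ValueError("duration must be positive")
        if self.fs_hz <= 0:
            raise ValueError("sample rate must be positive")

    @property
    def n_samples(self) -> int:
        return int(round(self.fs_hz * self.duration_s))


@dataclass
class SoundComplex:
    """A sampled mono waveform with provenance through the synthesis chain."""

    samples: np.ndarray
    fs_hz: int
    provenance: str = "raw"  # raw | v1 | v2 | v3
    band: Optional[FrequencyBand] = None

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("samples must be finite")

    @property
    def n_samples(self) -> int:
        return self.samples.size

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs_hz

    def rms(self) -> float:
        return float(np.sqrt(np.mean(self.samples**2)))


@dataclass
class SpectrumReport:
    """Welch PSD summary of a synthesized sound."""

    freqs_hz: np.ndarray
    psd: np.ndarray
    peak_hz: float
    band_attenuation_db: float
    passband: Optional[FrequencyBand] = None
    tinnitus_band: Optional[FrequencyBand] = None

    def to_dict(self) -> dict:
        d = {
            "peak_hz": self.peak_hz,
            "band_attenuation_db": self.band_attenuation_db,
        }
        if self.passband is not None:
            d["passband_hz"] = [self.passband.f_low_hz, self.passband.f_high_hz]
        if self.tinnitus_band is not None:
            d["tinnitus_band_hz"] = [
                self.tinnitus_band.f_low_hz,
                self.tinnitus_band.f_high_hz,
            ]
        return d


def generate_white_noise(spec: NoiseSpec) -> SoundComplex:
    """Seeded i.i.d. standard-Gaussian white noise of length fs * duration."""
    rng = np.random.default_rng(spec.seed)
    samples = rng.standard_normal(spec.n_samples)
    return SoundComplex(samples=samples, fs_hz=spec.fs_hz, provenance="raw")


def _transition_octaves(s: int) -> float:
    """Skirt width in octaves for smoothing s in [1, 100]."""
    return MAX_TRANSITION_OCTAVES * s / 100.0


def band_gain_curve(
    freqs_hz: np.ndarray,
    band: FrequencyBand,
    smoothing_low: EdgeSmoothing,
    smoothing_high: EdgeSmoothing,
    skirts: str = "outer",
) -> np.ndarray:
    """Band-pass amplitude gain: unity in-band, raised-cosine skirts.

    With ``skirts="outer"`` the skirt below ``f_low`` rises from 0 at
    ``f_low * 2**-w_low`` to 1 at ``f_low`` following a Hann half-window in
    log-frequency (and mirrored above ``f_high``), so energy beyond one
    transition width outside the band is fully rejected.  With
    ``skirts="inner"`` the transitions sit inside the band edges and the
    gain is exactly zero outside the band (used for the tinnitus-pitch
    band, whose edges are a hard +/-10% specification); transition widths
    are shrunk if needed so both fit inside the band.
    """
    w_lo = _transition_octaves(smoothing_low.s)
    w_hi = _transition_octaves(smoothing_high.s)
    gain = np.zeros_like(freqs_hz, dtype=np.float64)
    pos = freqs_hz > 0
    logf = np.full_like(freqs_hz, -np.inf)
    logf[pos] = np.log2(freqs_hz[pos])
    lo, hi = math.log2(band.f_low_hz), math.log2(band.f_high_hz)

    if skirts == "outer":
        inband = (logf >= lo) & (logf <= hi)
        gain[inband] = 1.0
        lo_sk = (logf >= lo - w_lo) & (logf < lo)
        gain[lo_sk] = 0.5 * (1.0 + np.cos(np.pi * (lo - logf[lo_sk]) / w_lo))
        hi_sk = (logf > hi) & (logf <= hi + w_hi)
        gain[hi_sk] = 0.5 * (1.0 + np.cos(np.pi * (logf[hi_sk] - hi) / w_hi))
    elif skirts == "inner":
        width = hi - lo
        if w_lo + w_hi > width:
            scale = width / (w_lo + w_hi)
            w_lo, w_hi = w_lo * scale, w_hi * scale
        flat = (logf >= lo + w_lo) & (logf <= hi - w_hi)
        gain[flat] = 1.0
        lo_sk = (logf >= lo) & (logf < lo + w_lo)
        gain[lo_sk] = 0.5 * (1.0 - np.cos(np.pi * (logf[lo_sk] - lo) / w_lo))
        hi_sk = (logf > hi - w_hi) & (logf <= hi)
        gain[hi_sk] = 0.5 * (1.0 - np.cos(np.pi * (hi - logf[hi_sk]) / w_hi))
    else:
        raise ValueError(f"unknown skirts mode {skirts!r}")
    return gain


def _apply_spectral_gain(x: np.ndarray, fs_hz: int, gain_fn) -> np.ndarray:
    n = x.size
    X = np.fft.rfft(x)
    freqs = np.fft.rfftfreq(n, d=1.0 / fs_hz)
    X *= gain_fn(freqs)
    return np.fft.irfft(X, n=n)


def bandpass(
    sound: SoundComplex,
    band: FrequencyBand,
    smoothing_low: EdgeSmoothing | None = None,
    smoothing_high: EdgeSmoothing | None = None,
    skirts: str = "outer",
) -> SoundComplex:
    """Frequency-domain band-pass with smoothing-controlled skirts.

    Raises
    ------
    ValueError
        If the lower band edge reaches the Nyquist frequency.
    """
    nyq = sound.fs_hz / 2.0
    if band.f_low_hz >= nyq:
        raise ValueError(f"band edge {band.f_low_hz} Hz >= Nyquist {nyq} Hz")
    if smoothing_low is None:
        smoothing_low = EdgeSmoothing(band.f_low_hz, DEFAULT_EDGE_S)
    if smoothing_high is None:
        smoothing_high = EdgeSmoothing(band.f_high_hz, DEFAULT_EDGE_S)
    y = _apply_spectral_gain(
        sound.samples,
        sound.fs_hz,
        lambda f: band_gain_curve(f, band, smoothing_low, smoothing_high, skirts),
    )
    return SoundComplex(y, sound.fs_hz, provenance=sound.provenance, band=band)


def audiogram_envelope_db(
    freqs_hz: np.ndarray, aud: Audiogram, criterion_db: float = HEARING_LOSS_CRITERION_DB_HL
) -> np.ndarray:
    """Per-frequency v1 gain in dB: threshold(f) - criterion, interpolated
    linearly in log-frequency between audiogram points (clamped outside)."""
    xs = np.log2(np.asarray(aud.frequencies_hz))
    ys = np.asarray(aud.thresholds_db_hl) - criterion_db
    x = np.full_like(freqs_hz, xs[0], dtype=np.float64)
    pos = freqs_hz > 0
    x[pos] = np.log2(freqs_hz[pos])
    return np.interp(x, xs, ys)


def shape_to_audiogram(
    sound: SoundComplex,
    aud: Audiogram,
    band: FrequencyBand,
    criterion_db: float = HEARING_LOSS_CRITERION_DB_HL,
) -> SoundComplex:
    """Apply the audiogram-following amplitude envelope inside the band (-> v1).

    The input is expected to be already band-limited to ``band`` (the
    hearing-loss band of ``aud``); the envelope is applied across the whole
    spectrum with end-clamping, which leaves the stop band at zero.
    """
    if band.f_low_hz < aud.frequencies_hz[0] / 2 or band.f_high_hz > aud.frequencies_hz[-1] * 2:
        raise ValueError("band does not match the audiogram's frequency range")

    def gain(f: np.ndarray) -> np.ndarray:
        return 10.0 ** (audiogram_envelope_db(f, aud, criterion_db) / 20.0)

    y = _apply_spectral_gain(sound.samples, sound.fs_hz, gain)
    return SoundComplex(y, sound.fs_hz, provenance="v1", band=band)


def tinnitus_band(pitch_hz: float, spec: NoiseSpec) -> SoundComplex:
    """Independent white noise band-passed to +/-10% around the tinnitus pitch (-> v2)."""
    if pitch_hz <= 0:
        raise ValueError("pitch must be positive")
    f_lo, f_hi = 0.9 * pitch_hz, 1.1 * pitch_hz
    if f_hi >= spec.fs_hz / 2.0:
        raise ValueError(
            f"pitch {pitch_hz} Hz too high for fs {spec.fs_hz} Hz (1.1*pitch >= Nyquist)"
        )
    noise = generate_white_noise(spec)
    # inner skirts: the +/-10% edges are hard limits, so the band carries
    # no energy outside them and the composite mix peaks strictly in-band
    v2 = bandpass(noise, FrequencyBand(f_lo, f_hi), skirts="inner")
    v2.provenance = "v2"
    return v2


def welch_psd(sound: SoundComplex) -> tuple[np.ndarray, np.ndarray]:
    """Welch PSD with the module's fixed segmentation (4096 points, 50% overlap)."""
    nperseg = min(WELCH_NPERSEG, sound.n_samples)
    return signal.welch(sound.samples, fs=sound.fs_hz, nperseg=nperseg)


def band_power(freqs: np.ndarray, psd: np.ndarray, band: FrequencyBand) -> float:
    """Mean PSD inside a band (power per Hz)."""
    m = (freqs >= band.f_low_hz) & (freqs <= band.f_high_hz)
    if not m.any():
        raise ValueError("band contains no PSD bins")
    return float(np.mean(psd[m]))


def mix_v3(
    v1: SoundComplex,
    v2: SoundComplex,
    boost_db: float = 6.0,
    reference: str = "band",
) -> SoundComplex:
    """Mono mix v3 = v1 + g*v2, peak-normalized to -1 dBFS.

    ``g`` is chosen so the band-averaged PSD inside the tinnitus band (the
    band carried by ``v2``) exceeds a v1 reference level by ``boost_db``:

    * ``reference="band"`` — v1's own level inside the tinnitus band;
    * ``reference="peak"`` — v1's global PSD maximum, which guarantees the
      mixed spectrum peaks inside the tinnitus band whatever the audiogram
      shape.
    """
    if v1.fs_hz != v2.fs_hz or v1.n_samples != v2.n_samples:
        raise ValueError("v1 and v2 must share sample rate and length")
    if v2.band is None:
        raise ValueError("v2 must carry its tinnitus band")
    if reference not in ("band", "peak"):
        raise ValueError(f"unknown reference {reference!r}")

    f1, p1 = welch_psd(v1)
    _, p2 = welch_psd(v2)
    p1_band = band_power(f1, p1, v2.band)
    p2_band = band_power(f1, p2, v2.band)
    ratio = 10.0 ** (boost_db / 10.0)
    if reference == "band":
        target = p1_band * ratio
    else:
        target = float(np.max(p1)) * ratio
    if p2_band <= 0 or not np.isfinite(p2_band):
        g = 0.0
    else:
        g = math.sqrt(max(target - p1_band, 0.0) / p2_band)

    y = v1.samples + g * v2.samples
    peak = np.max(np.abs(y))
    if peak > 0:
        y = y * (10.0 ** (PEAK_DBFS / 20.0) / peak)
    return SoundComplex(y, v1.fs_hz, provenance="v3", band=v2.band)


def spectrum_report(
    sound: SoundComplex,
    passband: Optional[FrequencyBand] = None,
    tinn_band: Optional[FrequencyBand] = None,
    transition_octaves: float = MAX_TRANSITION_OCTAVES,
) -> SpectrumReport:
    """Welch PSD summary: peak frequency and measured stop-band attenuation.

    Attenuation compares the mean in-band PSD with the mean PSD beyond one
    transition width outside the passband.
    """
    freqs, psd = welch_psd(sound)
    peak_hz = float(freqs[int(np.argmax(psd))])
    atten = math.inf
    if passband is not None:
        inside = band_power(freqs, psd, passband)
        margin = 2.0 ** transition_octaves
        out_m = (freqs > 0) & (
            (freqs < passband.f_low_hz / margin) | (freqs > passband.f_high_hz * margin)
        )
        if out_m.any():
            outside = float(np.mean(psd[out_m]))
            atten = math.inf if outside == 0 else 10.0 * math.log10(inside / outside)
    return SpectrumReport(
        freqs_hz=freqs,
        psd=psd,
        peak_hz=peak_hz,
        band_attenuation_db=max(float(atten), 0.0) if np.isfinite(atten) else float("inf"),
        passband=passband,
        tinnitus_band=tinn_band,
    )


def synthesize_treatment_sound(
    aud: Audiogram,
    pitch_hz: float,
    spec: NoiseSpec,
    criterion_db: float = HEARING_LOSS_CRITERION_DB_HL,
    boost_db: float = 6.0,
) -> tuple[SoundComplex, SpectrumReport]:
    """Full v1 -> v2 -> v3 chain for one listener.

    Derives the hearing-loss band and skirt smoothings from the audiogram,
    shapes one noise to the audiogram (v1), builds the tinnitus-pitch band
    noise (v2) from an independent seeded stream, and mixes with the pitch
    band referenced ``boost_db`` above v1's spectral maximum so the result
    peaks at the tinnitus pitch.

    Raises
    ------
    ValueError
        If the audiogram fails the inclusion screen or the pitch band does
        not fit below Nyquist.
    """
    if not check_inclusion(aud):
        raise ValueError("audiogram fails the inclusion screen (> 90 dB HL threshold)")
    band = hearing_loss_band(aud, criterion_db)
    smoothings = edge_smoothings(aud, band)
    s_low, s_high = smoothings[0], smoothings[-1]

    children = np.random.SeedSequence(spec.seed).generate_state(2)
    spec1 = NoiseSpec(spec.fs_hz, spec.duration_s, int(children[0]))
    spec2 = NoiseSpec(spec.fs_hz, spec.duration_s, int(children[1]))

    noise = generate_white_noise(spec1)
    v1 = shape_to_audiogram(bandpass(noise, band, s_low, s_high), aud, band, criterion_db)
    v2 = tinnitus_band(pitch_hz, spec2)
    v3 = mix_v3(v1, v2, boost_db=boost_db, reference="peak")
    v3 = loop_crossfade(v3)
    report = spectrum_report(v3, passband=band, tinn_band=v2.band)
    return v3, report


def loop_crossfade(sound: SoundComplex, fade_s: float = LOOP_CROSSFADE_S) -> SoundComplex:
    """Blend the last ``fade_s`` seconds toward the opening samples so the
    sound loops seamlessly during long listening sessions."""
    k = int(round(fade_s * sound.fs_hz))
    if k <= 0 or 2 * k >= sound.n_samples:
        return sound
    y = sound.samples.copy()
    t = np.linspace(0.0, 1.0, k, endpoint=False)
    fade_out = np.cos(0.5 * np.pi * t) ** 2
    y[-k:] = y[-k:] * fade_out + y[:k] * (1.0 - fade_out)
    return SoundComplex(y, sound.fs_hz, provenance=sound.provenance, band=sound.band)


def write_wav(path: str | Path, sound: SoundComplex) -> None:
    """Write 16-bit PCM mono WAV."""
    x = np.clip(sound.samples, -1.0, 1.0)
    wavfile.write(str(path), sound.fs_hz, (x * 32767.0).astype(np.int16))


def wav_digest(path: str | Path) -> str:
    """SHA-256 of the WAV file bytes (used for determinism checks/logging)."""
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()
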