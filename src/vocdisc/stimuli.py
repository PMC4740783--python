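"""Synthetic vocalization-like stimuli and their band-integrated spectra.

Guinea-pig communication calls span roughly 0.3-1.3 s and fall into a few
spectrotemporal classes: low-frequency periodic calls ("purr"/"drr"-like,
energy below ~3 kHz with envelope periodicities near 10-15 Hz), broadband
harmonic calls ("scream"/"whistle"-like, harmonic stacks reaching tens of
kHz), and noisy or chirped calls.  This module generates deterministic
synthetic analogues of such a call set and computes the band-integrated
spectral profile used throughout the analysis: the one-sided power spectrum
integrated over 36 contiguous frequency bands covering 0-45.5 kHz.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy import signal
from scipy.io import wavfile

__all__ = [
    "Stimulus",
    "StimulusSet",
    "FrequencyBands",
    "SpectralProfile",
    "default_templates",
    "generate_vocalization_set",
    "make_band_edges",
    "compute_spectral_profile",
    "envelope_peak_frequency",
    "save_stimulus_set",
    "load_stimulus_set",
]

DEFAULT_SAMPLE_RATE = 97_656.0  # Hz, matches the acquisition rate of the calls
DURATION_RANGE = (0.3, 1.3)  # s
RAMP_S = 0.005  # on/off cosine ramps


@dataclass(frozen=True)
class Stimulus:
    """A single stimulus waveform plus its timing metadata.

    The waveform is zero outside [onset, onset + duration] within the trial.
    Pressure units are arbitrary; ``intensity_db`` scaling is applied at the
    StimulusSet level.
    """

    id: str
    waveform: np.ndarray
    sample_rate: float
    onset: float = 0.020
    duration: float = 0.5
    am_rate: float | None = None
    carrier_bands: tuple[tuple[float, float], ...] = ()

    def __post_init__(self) -> None:
        if not (DURATION_RANGE[0] <= self.duration <= DURATION_RANGE[1]):
            raise ValueError(
                f"stimulus {self.id!r}: duration {self.duration} s outside "
                f"[{DURATION_RANGE[0]}, {DURATION_RANGE[1]}] s"
            )
        if not np.all(np.isfinite(self.waveform)):
            raise ValueError(f"stimulus {self.id!r}: non-finite waveform")


@dataclass(frozen=True)
class StimulusSet:
    """Ordered collection of stimuli presented within equal-length trials."""

    stimuli: tuple[Stimulus, ...]
    trial_length: float = 1.0
    intensity_db: float = 70.0

    def __post_init__(self) -> None:
        ids = [s.id for s in self.stimuli]
        if len(set(ids)) != len(ids):
            raise ValueError("stimulus ids must be unique")
        for s in self.stimuli:
            if s.onset + s.duration > self.trial_length + 1e-9:
                raise ValueError(
                    f"stimulus {s.id!r} extends past trial length "
                    f"({s.onset + s.duration:.3f} > {self.trial_length} s)"
                )

    @property
    def n_voc(self) -> int:
        return len(self.stimuli)

    @property
    def ids(self) -> list[str]:
        return [s.id for s in self.stimuli]

    def amplitude_factor(self) -> float:
        """Linear amplitude scale relative to the 70 dB SPL reference."""
        return float(10.0 ** ((self.intensity_db - 70.0) / 20.0))

    def with_intensity(self, intensity_db: float) -> "StimulusSet":
        return replace(self, intensity_db=intensity_db)


@dataclass(frozen=True)
class FrequencyBands:
    """Contiguous frequency intervals (kHz) used for band integration."""

    edges: np.ndarray  # kHz, strictly increasing, length n_bands + 1

    def __post_init__(self) -> None:
        e = np.asarray(self.edges, dtype=float)
        if e.ndim != 1 or e.size < 3:
            raise ValueError("edges must be a 1-d array delimiting >= 2 bands")
        if not np.all(np.diff(e) > 0):
            raise ValueError("band edges must be strictly increasing")
        object.__setattr__(self, "edges", e)

    @property
    def n_bands(self) -> int:
        return self.edges.size - 1

    @property
    def centers_khz(self) -> np.ndarray:
        """Geometric band centers; the first (0-anchored) band uses its midpoint."""
        lo, hi = self.edges[:-1], self.edges[1:]
        c = np.sqrt(np.clip(lo, 1e-6, None) * hi)
        c[0] = 0.5 * (lo[0] + hi[0])
        return c


@dataclass(frozen=True)
class SpectralProfile:
    """Per-band fraction of total stimulus power (unit sum) and its log."""

    band_power: np.ndarray
    log_band_power: np.ndarray
    bands: FrequencyBands

    def __post_init__(self) -> None:
        bp = np.asarray(self.band_power, dtype=float)
        if bp.size != self.bands.n_bands:
            raise ValueError("band_power length must equal n_bands")
        if np.any(bp < 0):
            raise ValueError("band_power must be non-negative")
        if abs(bp.sum() - 1.0) > 1e-9:
            raise ValueError("band_power must sum to 1")


# ---------------------------------------------------------------------------
# band edges


def make_band_edges(n_bands: int = 36, f_max: float = 45.5) -> FrequencyBands:
    """Build the analysis frequency bands.

    The first two intervals are the printed anchors [0, 0.25] and
    [0.25, 0.55] kHz; the remaining ``n_bands - 2`` intervals are
    geometrically spaced from 0.55 kHz to ``f_max`` kHz, mirroring the
    log-frequency (cochleotopic) organisation of the auditory midbrain.
    """
    if n_bands < 2:
        raise ValueError("n_bands must be >= 2")
    if f_max <= 0.55:
        raise ValueError("f_max must exceed 0.55 kHz")
    if n_bands == 2:
        edges = np.array([0.0, 0.25, f_max])
    else:
        geo = np.geomspace(0.55, f_max, n_bands - 1)
        edges = np.concatenate([[0.0, 0.25], geo])
    return FrequencyBands(edges=edges)


# ---------------------------------------------------------------------------
# stimulus synthesis


@dataclass(frozen=True)
class StimulusTemplate:
    """Recipe for one synthetic call: carriers x AM envelope x ramps."""

    id: str
    duration: float
    carrier_bands: tuple[tuple[float, float], ...] = ()  # Hz, band-limited noise
    harmonic_f0: float | None = None  # Hz, fundamental of a harmonic stack
    n_harmonics: int = 0
    am_rate: float | None = None  # Hz envelope periodicity
    am_depth: float = 0.9


def default_templates() -> list[StimulusTemplate]:
    """The 11 default call analogues.

    Three low-frequency periodic calls (AM 10.3, 15.4 and 14 Hz, energy below
    3 kHz), harmonic calls with fundamentals from 0.9 to 2.3 kHz, and
    band-limited noise calls covering low, middle and high bands.  Durations
    span 0.3-0.98 s so every call fits the default 1-s trial after the 20-ms
    onset; pass longer trials (e.g. 1.6 s) for templates up to 1.3 s.
    """
    return [
        StimulusTemplate("tooth_chatter_like", 0.98, ((100.0, 2500.0),), am_rate=10.3),
        StimulusTemplate("purr_like", 0.92, ((100.0, 1800.0),), am_rate=15.4),
        StimulusTemplate("drr_like", 0.85, ((150.0, 2800.0),), am_rate=14.0),
        StimulusTemplate("low_chutter_like", 0.7, ((200.0, 1400.0),)),
        StimulusTemplate("chutter_short_like", 0.4, ((300.0, 2200.0),), am_rate=8.0),
        StimulusTemplate("whistle_like", 0.8, harmonic_f0=1800.0, n_harmonics=8),
        StimulusTemplate("low_whistle_like", 0.9, harmonic_f0=900.0, n_harmonics=6),
        StimulusTemplate("scream_long_like", 0.95, harmonic_f0=2300.0, n_harmonics=10),
        StimulusTemplate("scream_short_like", 0.3, harmonic_f0=2100.0, n_harmonics=10),
        StimulusTemplate("squeal_like", 0.6, harmonic_f0=1200.0, n_harmonics=12, am_rate=20.0),
        StimulusTemplate("noise_burst_like", 0.5, ((4000.0, 30000.0),)),
    ]


def _bandlimited_noise(rng: np.random.Generator, n: int, fs: float,
                       low: float, high: float) -> np.ndarray:
    """White Gaussian noise shaped to [low, high] Hz in the frequency domain."""
    spec = rng.standard_normal(n // 2 + 1) + 1j * rng.standard_normal(n // 2 + 1)
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    spec[(freqs < low) | (freqs > high)] = 0.0
    x = np.fft.irfft(spec, n=n)
    sd = x.std()
    return x / sd if sd > 0 else x


def _render_template(tpl: StimulusTemplate, fs: float,
                     rng: np.random.Generator) -> np.ndarray:
    n = int(round(tpl.duration * fs))
    t = np.arange(n) / fs
    x = np.zeros(n)
    for low, high in tpl.carrier_bands:
        if high >= fs / 2:
            raise ValueError(
                f"template {tpl.id!r}: carrier band upper edge {high} Hz "
                f"exceeds Nyquist ({fs / 2} Hz)"
            )
        x += _bandlimited_noise(rng, n, fs, low, high)
    if tpl.harmonic_f0 is not None:
        for h in range(1, tpl.n_harmonics + 1):
            f = tpl.harmonic_f0 * h
            if f >= fs / 2:
                break
            # harmonic amplitudes fall off 1/h; random phase per harmonic
            x += (1.0 / h) * np.sin(2 * np.pi * f * t + rng.uniform(0, 2 * np.pi))
    if tpl.am_rate is not None:
        x *= 1.0 + tpl.am_depth * np.sin(2 * np.pi * tpl.am_rate * t - np.pi / 2)
    # 5-ms raised-cosine on/off ramps
    nr = int(round(RAMP_S * fs))
    ramp = 0.5 * (1 - np.cos(np.pi * np.arange(nr) / nr))
    x[:nr] *= ramp
    x[-nr:] *= ramp[::-1]
    peak = np.max(np.abs(x))
    return x / peak if peak > 0 else x


def generate_vocalization_set(
    templates: Sequence[StimulusTemplate] | None = None,
    seed: int = 0,
    sample_rate: float = DEFAULT_SAMPLE_RATE,
    trial_length: float = 1.0,
    onset: float = 0.020,
    intensity_db: float = 70.0,
) -> StimulusSet:
    """Generate the synthetic call set deterministically from (templates, seed).

    Each template's waveform occupies [onset, onset + duration] of the trial
    and is zero elsewhere.  The default 1-s trial matches the recording
    protocol emulated throughout; use 1.6-s trials for calls up to 1.3 s.
    """
    if templates is None:
        templates = default_templates()
    if len(templates) < 2:
        raise ValueError("need at least 2 stimulus templates")
    ss = np.random.SeedSequence([int(seed) & 0x7FFFFFFF, 0x57E11])
    children = ss.spawn(len(templates))
    stimuli = []
    for tpl, child in zip(templates, children):
        wav = _render_template(tpl, sample_rate, np.random.default_rng(child))
        stimuli.append(
            Stimulus(
                id=tpl.id,
                waveform=wav,
                sample_rate=sample_rate,
                onset=onset,
                duration=tpl.duration,
                am_rate=tpl.am_rate,
                carrier_bands=tpl.carrier_bands,
            )
        )
    return StimulusSet(stimuli=tuple(stimuli), trial_length=trial_length,
                       intensity_db=intensity_db)


# ---------------------------------------------------------------------------
# spectral profiles


def compute_spectral_profile(stimulus: Stimulus, bands: FrequencyBands,
                             power_floor: float = 1e-12) -> SpectralProfile:
    """Integrate the one-sided periodogram of the stimulus over each band.

    Hann-windowed full-signal periodogram; band powers are normalised to unit
    sum and floored at ``power_floor`` before the log so empty bands stay
    finite.
    """
    x = np.asarray(stimulus.waveform, dtype=float)
    if not np.any(x != 0):
        raise ValueError("silent stimulus")
    freqs, pxx = signal.periodogram(x, fs=stimulus.sample_rate, window="hann")
    edges_hz = bands.edges * 1000.0
    idx = np.searchsorted(edges_hz, freqs, side="right") - 1
    band_power = np.zeros(bands.n_bands)
    valid = (idx >= 0) & (idx < bands.n_bands)
    np.add.at(band_power, idx[valid], pxx[valid])
    total = band_power.sum()
    if total <= 0:
        raise ValueError("stimulus has no power inside the analysis bands")
    band_power /= total
    log_bp = np.log(np.maximum(band_power, power_floor))
    return SpectralProfile(band_power=band_power, log_band_power=log_bp, bands=bands)


def envelope_peak_frequency(stimulus: Stimulus, f_max: float = 60.0) -> float:
    """Dominant periodicity (Hz) of the stimulus amplitude envelope.

    The envelope is the magnitude of the analytic signal, low-pass inspected
    via a Hann periodogram restricted to (0, f_max] Hz.
    """
    env = np.abs(signal.hilbert(stimulus.waveform))
    env = env - env.mean()
    freqs, pxx = signal.periodogram(env, fs=stimulus.sample_rate, window="hann")
    sel = (freqs > 0.5) & (freqs <= f_max)
    return float(freqs[sel][np.argmax(pxx[sel])])


# ---------------------------------------------------------------------------
# I/O


def save_stimulus_set(stimset: StimulusSet, outdir: str | Path) -> Path:
    """Write one float-PCM WAV per stimulus plus a JSON manifest; returns outdir."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "trial_length": stimset.trial_length,
        "intensity_db": stimset.intensity_db,
        "stimuli": [],
    }
    for s in stimset.stimuli:
        wavfile.write(outdir / f"{s.id}.wav", int(round(s.sample_rate)),
                      s.waveform.astype(np.float32))
        manifest["stimuli"].append(
            {
                "id": s.id,
                "onset": s.onset,
                "duration": s.duration,
                "sample_rate": s.sample_rate,
                "am_rate": s.am_rate,
                "carrier_bands": [list(b) for b in s.carrier_bands],
            }
        )
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return outdir


def load_stimulus_set(stimdir: str | Path) -> StimulusSet:
    """Rebuild a StimulusSet from a directory written by :func:`save_stimulus_set`."""
    stimdir = Path(stimdir)
    manifest = json.loads((stimdir / "manifest.json").read_text())
    stimuli = []
    for meta in manifest["stimuli"]:
        rate, wav = wavfile.read(stimdir / f"{meta['id']}.wav")
        stimuli.append(
            Stimulus(
                id=meta["id"],
                waveform=np.asarray(wav, dtype=float),
                sample_rate=float(meta["sample_rate"]),
                onset=meta["onset"],
                duration=meta["duration"],
                am_rate=meta["am_rate"],
                carrier_bands=tuple(tuple(b) for b in meta["carrier_bands"]),
            )
        )
    return StimulusSet(
        stimuli=tuple(stimuli),
        trial_length=manifest["trial_length"],
        intensity_db=manifest["intensity_db"],
    )
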