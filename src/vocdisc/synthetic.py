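"""Ground-truth synthetic multi-unit recordings.

Emulates one "shank" of 16-32 simultaneously recorded multi-unit clusters in
a tonotopically organised auditory midbrain: each unit has a best frequency
(BF), Gaussian tuning in log2 frequency, a spontaneous (baseline) rate and a
driven gain.  The instantaneous rate of unit u for stimulus s is

    lambda_u,s(t) = baseline_u + gain_u * drive_u,s(t - latency_u)
                    + c * gain_u * common_k(t),   clipped at 0,

where drive_u,s(t) is the stimulus's time-resolved band-amplitude envelope
weighted by the unit's tuning curve (so it scales linearly with stimulus
amplitude, hence with intensity in dB), and common_k(t) is a low-pass
Ornstein-Uhlenbeck path shared by all units on trial k — the single knob
that produces trial-matched ("noise") correlations between simultaneously
recorded units.  Spikes are drawn by thinning an inhomogeneous Poisson
process; no refractory period is imposed, consistent with multi-unit
activity pooling several single units.

Optionally, raw voltage traces at 24.414 kHz can be synthesised from the
spike times (template waveform + band-limited Gaussian background noise) so
the threshold-detection chain is testable end to end.
"""

from __future__ import annotations

import json
import logging
import zlib
from dataclasses import dataclass, field, replace
from pathlib import Path

import h5py
import numpy as np
from scipy import signal

from .stimuli import Stimulus, StimulusSet

logger = logging.getLogger(__name__)

__all__ = [
    "UnitSpec",
    "PopulationSpec",
    "RecordingSet",
    "generate_population",
    "simulate_responses",
    "stimulus_drive",
    "default_spike_template",
    "synthesize_voltage",
    "save_recordings",
    "load_recordings",
    "GEOMETRIES",
]

GEOMETRIES = ("linear_double_shank", "tetrode")
VOLTAGE_FS = 24414.0  # Hz
BF_LIMITS = (0.5, 45.0)  # kHz
RATE_DT = 0.001  # s, rate-model grid

# Realistic multi-unit defaults: a cluster pools ~5-10 single units, so
# spontaneous rates of tens of spikes/s and driven rates of a few hundred
# spikes/s are typical for ICC multi-unit activity.
DEFAULT_BASELINE = 50.0  # spikes/s
DEFAULT_GAIN = 800.0  # spikes/s at unit drive (peak driven rates of a few hundred)
DEFAULT_BANDWIDTH_OCT = 1.0


@dataclass(frozen=True)
class UnitSpec:
    """One multi-unit cluster: tuning, rates and array position."""

    unit_id: str
    bf: float  # kHz
    bandwidth_oct: float = DEFAULT_BANDWIDTH_OCT
    baseline_rate: float = DEFAULT_BASELINE
    gain: float = DEFAULT_GAIN
    am_preference: float | None = None
    position: tuple[int, int, float] = (0, 0, 0.0)  # (shank, contact, depth um)

    def __post_init__(self) -> None:
        if not (BF_LIMITS[0] <= self.bf <= BF_LIMITS[1]):
            raise ValueError(f"bf {self.bf} kHz outside {BF_LIMITS}")
        if self.baseline_rate < 0 or self.gain < 0:
            raise ValueError("baseline_rate and gain must be >= 0")

    def xy_um(self) -> tuple[float, float]:
        """Planar position: shanks 500 um apart, contacts along the shank."""
        shank, _, depth = self.position
        return (500.0 * shank, depth)


@dataclass(frozen=True)
class PopulationSpec:
    """A simultaneously recorded set of units plus shared-noise settings."""

    units: tuple[UnitSpec, ...]
    geometry: str = "linear_double_shank"
    shared_noise_c: float = 0.0
    shared_noise_tau: float = 10.0  # ms
    latency_jitter_ms: float = 5.0

    def __post_init__(self) -> None:
        if self.geometry not in GEOMETRIES:
            raise ValueError(f"unknown geometry {self.geometry!r}")
        if not (0.0 <= self.shared_noise_c <= 1.0):
            raise ValueError("shared_noise_c must be in [0, 1]")

    @property
    def n_units(self) -> int:
        return len(self.units)

    @property
    def unit_ids(self) -> list[str]:
        return [u.unit_id for u in self.units]

    def with_shared_noise(self, c: float, tau_ms: float | None = None
                          ) -> "PopulationSpec":
        return replace(self, shared_noise_c=c,
                       shared_noise_tau=tau_ms or self.shared_noise_tau)


@dataclass
class RecordingSet:
    """Per (unit, stimulus, trial) spike times, with optional raw voltage.

    ``spike_times[(unit_id, stim_id)]`` is a list of ``n_trials`` arrays of
    spike times in seconds within [0, trial_length).  When ``simultaneous``
    is True, trial k of every unit was driven by the same common-noise path.
    """

    population: PopulationSpec
    stimuli: StimulusSet
    n_trials: int
    spike_times: dict
    voltage: dict | None = None
    voltage_fs: float = VOLTAGE_FS
    simultaneous: bool = True
    latencies_s: dict = field(default_factory=dict)

    @property
    def trial_length(self) -> float:
        return self.stimuli.trial_length

    def trains(self, unit_id: str, stim_id: str) -> list[np.ndarray]:
        return self.spike_times[(unit_id, stim_id)]


# ---------------------------------------------------------------------------
# population generation


def generate_population(geometry: str, n_units: int,
                        bf_range: tuple[float, float] = BF_LIMITS,
                        seed: int = 0, *, shared_noise_c: float = 0.0,
                        shared_noise_tau: float = 10.0,
                        latency_jitter_ms: float = 5.0,
                        baseline_rate: float = DEFAULT_BASELINE,
                        gain: float = DEFAULT_GAIN,
                        bandwidth_oct: float = DEFAULT_BANDWIDTH_OCT,
                        ) -> PopulationSpec:
    """Build a population of BF-tuned units for one recording geometry.

    ``linear_double_shank`` places contacts 100 um apart along shanks of 16,
    with BFs log-spaced across ``bf_range`` in contact order (the tonotopic
    gradient).  ``tetrode`` draws all BFs within ``bf_range``, which should
    span at most ~0.5 octave to emulate a within-lamina recording.
    """
    if geometry not in GEOMETRIES:
        raise ValueError(f"unknown geometry {geometry!r}; choose from {GEOMETRIES}")
    if n_units < 1:
        raise ValueError("n_units must be >= 1")
    lo, hi = bf_range
    if not (BF_LIMITS[0] <= lo < hi <= BF_LIMITS[1]):
        raise ValueError(f"bf_range {bf_range} must be within {BF_LIMITS} kHz")
    rng = np.random.default_rng(np.random.SeedSequence([int(seed) & 0x7FFFFFFF, 0x9090]))
    if geometry == "linear_double_shank":
        bfs = np.geomspace(lo, hi, n_units)
        positions = [(i // 16, i % 16, 100.0 * (i % 16)) for i in range(n_units)]
    else:
        span_oct = np.log2(hi / lo)
        if span_oct > 0.5 + 1e-9:
            logger.warning("tetrode bf_range spans %.2f octaves (> 0.5)", span_oct)
        bfs = np.sort(lo * 2.0 ** (rng.uniform(0.0, span_oct, n_units)))
        positions = [(i // 4, i % 4, 25.0 * (i % 4)) for i in range(n_units)]
    units = tuple(
        UnitSpec(
            unit_id=f"mu{i:02d}",
            bf=float(bfs[i]),
            bandwidth_oct=bandwidth_oct,
            baseline_rate=baseline_rate,
            gain=gain,
            position=positions[i],
        )
        for i in range(n_units)
    )
    return PopulationSpec(units=units, geometry=geometry,
                          shared_noise_c=shared_noise_c,
                          shared_noise_tau=shared_noise_tau,
                          latency_jitter_ms=latency_jitter_ms)


# ---------------------------------------------------------------------------
# rate model


def _band_envelope(stim: Stimulus, amplitude_factor: float,
                   trial_length: float, edges_khz: np.ndarray) -> np.ndarray:
    """Time-resolved per-band amplitude envelope on the 1-ms rate grid.

    Spectrogram of the (intensity-scaled) waveform with ~5-ms windows,
    power integrated per band and square-rooted so the envelope scales
    linearly with waveform amplitude.  Rows are bands, columns 1-ms steps
    over the whole trial; zero outside the stimulus.
    """
    x = stim.waveform * amplitude_factor
    fs = stim.sample_rate
    nper = max(64, int(round(0.005 * fs)))
    freqs, times, sxx = signal.spectrogram(
        x, fs=fs, window="hann", nperseg=nper, noverlap=nper // 2,
        mode="psd",
    )
    edges_hz = edges_khz * 1000.0
    idx = np.searchsorted(edges_hz, freqs, side="right") - 1
    n_bands = edges_khz.size - 1
    band_pow = np.zeros((n_bands, times.size))
    valid = (idx >= 0) & (idx < n_bands)
    np.add.at(band_pow, idx[valid], sxx[valid])
    band_amp = np.sqrt(band_pow)
    n_steps = int(round(trial_length / RATE_DT))
    grid = (np.arange(n_steps) + 0.5) * RATE_DT
    out = np.zeros((n_bands, n_steps))
    t_abs = stim.onset + times
    for b in range(n_bands):
        out[b] = np.interp(grid, t_abs, band_amp[b], left=0.0, right=0.0)
    # zero strictly outside the stimulus interval
    out[:, grid < stim.onset] = 0.0
    out[:, grid > stim.onset + stim.duration] = 0.0
    return out


def stimulus_drive(stim: Stimulus, unit: UnitSpec, amplitude_factor: float,
                   trial_length: float, edges_khz: np.ndarray | None = None,
                   _env_cache: dict | None = None) -> np.ndarray:
    """Unit-specific drive time course (dimensionless, ~O(1) at 70 dB).

    The band envelope is computed once at the 70-dB reference (its peak
    band amplitude normalised to 1, so drive is dimensionless) and scales
    linearly with ``amplitude_factor``.  It is weighted by a Gaussian tuning
    curve in log2 frequency centred at the unit's BF with
    SD = bandwidth_oct / 2.355 (FWHM = bandwidth_oct), normalised by the
    tuning mass so drive amplitudes are comparable across bandwidths.
    """
    if edges_khz is None:
        edges_khz = np.geomspace(0.05, 45.5, 65)
    if _env_cache is not None and stim.id in _env_cache:
        env = _env_cache[stim.id]
    else:
        env = _band_envelope(stim, 1.0, trial_length, edges_khz)
        peak = env.max()
        if peak > 0:
            env = env / peak
        if _env_cache is not None:
            _env_cache[stim.id] = env
    centers = np.sqrt(edges_khz[:-1] * edges_khz[1:])
    sd_oct = unit.bandwidth_oct / 2.355
    w = np.exp(-0.5 * (np.log2(centers / unit.bf) / sd_oct) ** 2)
    return amplitude_factor * (w @ env) / w.sum()


def _ou_path(rng: np.random.Generator, n_steps: int, tau_ms: float) -> np.ndarray:
    """Unit-variance Ornstein-Uhlenbeck path on the 1-ms grid."""
    a = np.exp(-1.0 / max(tau_ms, 1e-6))
    x = np.empty(n_steps)
    x[0] = rng.standard_normal()
    innov = rng.standard_normal(n_steps - 1) * np.sqrt(1 - a * a)
    for i in range(1, n_steps):
        x[i] = a * x[i - 1] + innov[i - 1]
    return x


def _thin_poisson(rng: np.random.Generator, lam: np.ndarray,
                  dt: float) -> np.ndarray:
    """Inhomogeneous-Poisson spike times by thinning a homogeneous process."""
    lam_max = float(lam.max())
    if lam_max <= 0:
        return np.empty(0)
    duration = lam.size * dt
    n = rng.poisson(lam_max * duration)
    t = np.sort(rng.uniform(0.0, duration, n))
    idx = np.minimum((t / dt).astype(int), lam.size - 1)
    keep = rng.uniform(0.0, lam_max, n) < lam[idx]
    return t[keep]


def simulate_responses(population: PopulationSpec, stimuli: StimulusSet,
                       n_trials: int = 20, seed: int = 0) -> RecordingSet:
    """Simulate spike responses for every (unit, stimulus, trial).

    Deterministic given (population, stimuli, n_trials, seed).  Per-unit
    response latencies are drawn once within [0, latency_jitter_ms].  The
    common-noise path for trial k of stimulus s is shared across units, so
    equal trial indices are "simultaneous".  Negative instantaneous rates
    are clipped at zero (a count of clipped bins is logged).
    """
    if n_trials < 2:
        raise ValueError("n_trials must be >= 2 (cross-validation needs folds)")
    master = np.random.SeedSequence([int(seed) & 0x7FFFFFFF, 0x51A1])
    rng_lat = np.random.default_rng(master.spawn(1)[0])
    latencies = {
        u.unit_id: float(rng_lat.uniform(0.0, population.latency_jitter_ms / 1000.0))
        for u in population.units
    }
    n_steps = int(round(stimuli.trial_length / RATE_DT))
    amp = stimuli.amplitude_factor()
    env_cache: dict = {}

    # precompute unit drives per stimulus
    drives = {
        (u.unit_id, s.id): stimulus_drive(s, u, amp, stimuli.trial_length,
                                          _env_cache=env_cache)
        for u in population.units
        for s in stimuli.stimuli
    }

    c = population.shared_noise_c
    spike_times: dict = {}
    clipped = 0
    for si, stim in enumerate(stimuli.stimuli):
        for u in population.units:
            spike_times[(u.unit_id, stim.id)] = []
        for k in range(n_trials):
            common = None
            if c > 0:
                rng_c = np.random.default_rng(
                    np.random.SeedSequence([int(seed) & 0x7FFFFFFF, 0xC0, si, k]))
                common = _ou_path(rng_c, n_steps, population.shared_noise_tau)
            for ui, u in enumerate(population.units):
                lat_bins = int(round(latencies[u.unit_id] / RATE_DT))
                drive = np.roll(drives[(u.unit_id, stim.id)], lat_bins)
                if lat_bins:
                    drive[:lat_bins] = 0.0
                lam = u.baseline_rate + u.gain * drive
                if common is not None:
                    lam = lam + c * u.gain * 0.5 * common
                neg = lam < 0
                if np.any(neg):
                    clipped += int(neg.sum())
                    lam = np.where(neg, 0.0, lam)
                rng_u = np.random.default_rng(
                    np.random.SeedSequence([int(seed) & 0x7FFFFFFF, 0x5B, si, k, ui]))
                spike_times[(u.unit_id, stim.id)].append(
                    _thin_poisson(rng_u, lam, RATE_DT))
    if clipped:
        logger.info("clipped %d negative-rate bins to 0", clipped)
    return RecordingSet(population=population, stimuli=stimuli,
                        n_trials=n_trials, spike_times=spike_times,
                        simultaneous=True, latencies_s=latencies)


# ---------------------------------------------------------------------------
# voltage synthesis


def default_spike_template(fs: float = VOLTAGE_FS, amplitude: float = 1.0,
                           width_ms: float = 1.0) -> np.ndarray:
    """Positive-dominant extracellular spike shape, peak value ``amplitude``.

    A sharp positive lobe (SD ~ width/12) followed by a shallow, broader
    undershoot — the polarity the positive-going threshold detector is
    built for.  The sharp lobe concentrates energy inside the 300-3000 Hz
    detection band while keeping the waveform's total energy low, so
    spikes landing in the spontaneous window inflate the threshold
    statistic only mildly.
    """
    n = int(round(width_ms / 1000.0 * fs))
    t = (np.arange(n) - n * 0.35) / fs
    sd = width_ms / 1000.0 / 12.0
    w = np.exp(-0.5 * (t / sd) ** 2) \
        - 0.25 * np.exp(-0.5 * ((t - 3.0 * sd) / (2.5 * sd)) ** 2)
    return amplitude * w / np.max(np.abs(w))


def synthesize_voltage(recordings: RecordingSet,
                       waveform_template: np.ndarray | None = None,
                       noise_sd: float = 1.0, seed: int = 0,
                       fs: float = VOLTAGE_FS) -> RecordingSet:
    """Fill raw voltage traces: spike templates at spike times + noise.

    The background is Gaussian noise band-limited to [100, 6000] Hz and
    rescaled to ``noise_sd``.  The template must not exceed 5 ms.  Returns a
    new RecordingSet sharing spike times, with ``voltage`` populated.
    """
    if waveform_template is None:
        waveform_template = default_spike_template(fs, amplitude=10.0 * noise_sd
                                                   if noise_sd > 0 else 10.0)
    template = np.asarray(waveform_template, dtype=float)
    if template.size / fs > 0.005:
        raise ValueError("spike template longer than 5 ms")
    n_samp = int(round(recordings.trial_length * fs))
    sos = signal.butter(4, [100.0, 6000.0], btype="bandpass", fs=fs, output="sos")
    master = np.random.SeedSequence([int(seed) & 0x7FFFFFFF, 0x701])
    voltage: dict = {}
    half = template.size // 2
    for (uid, sid), trials in recordings.spike_times.items():
        traces = []
        for k, times in enumerate(trials):
            tag = zlib.crc32(f"{uid}/{sid}".encode()) & 0x7FFFFFFF
            rng = np.random.default_rng(
                np.random.SeedSequence([int(seed) & 0x7FFFFFFF, 0x702, tag, k]))
            if noise_sd > 0:
                noise = signal.sosfiltfilt(sos, rng.standard_normal(n_samp))
                noise *= noise_sd / noise.std()
            else:
                noise = np.zeros(n_samp)
            v = noise
            centers = np.round(np.asarray(times) * fs).astype(int)
            for ci in centers:
                a = ci - half
                b = a + template.size
                ta, tb = max(0, -a), template.size - max(0, b - n_samp)
                v[max(a, 0):min(b, n_samp)] += template[ta:tb]
            traces.append(v)
        voltage[(uid, sid)] = traces
    return replace_voltage(recordings, voltage, fs)


def replace_voltage(recordings: RecordingSet, voltage: dict,
                    fs: float) -> RecordingSet:
    return RecordingSet(
        population=recordings.population,
        stimuli=recordings.stimuli,
        n_trials=recordings.n_trials,
        spike_times=recordings.spike_times,
        voltage=voltage,
        voltage_fs=fs,
        simultaneous=recordings.simultaneous,
        latencies_s=recordings.latencies_s,
    )


# ---------------------------------------------------------------------------
# HDF5 I/O


def save_recordings(recordings: RecordingSet, path: str | Path) -> Path:
    """Write the /units/<id>/<stim>/trial<k> HDF5 layout plus /meta."""
    path = Path(path)
    with h5py.File(path, "w") as f:
        meta = f.create_group("meta")
        meta.attrs["geometry"] = recordings.population.geometry
        meta.attrs["n_trials"] = recordings.n_trials
        meta.attrs["trial_length"] = recordings.trial_length
        meta.attrs["intensity_db"] = recordings.stimuli.intensity_db
        meta.attrs["simultaneous"] = recordings.simultaneous
        meta.attrs["shared_noise_c"] = recordings.population.shared_noise_c
        meta.attrs["stimulus_ids"] = json.dumps(recordings.stimuli.ids)
        units = f.create_group("units")
        for u in recordings.population.units:
            g = units.create_group(u.unit_id)
            g.attrs["bf_khz"] = u.bf
            g.attrs["bandwidth_oct"] = u.bandwidth_oct
            g.attrs["baseline_rate"] = u.baseline_rate
            g.attrs["gain"] = u.gain
            g.attrs["position"] = list(u.position)
            for sid in recordings.stimuli.ids:
                gs = g.create_group(sid)
                for k, times in enumerate(recordings.spike_times[(u.unit_id, sid)]):
                    gt = gs.create_group(f"trial{k}")
                    gt.create_dataset("spike_times", data=np.asarray(times))
                    if recordings.voltage is not None:
                        gt.create_dataset(
                            "voltage",
                            data=recordings.voltage[(u.unit_id, sid)][k],
                            dtype="f4",
                        )
    return path


def load_recordings(path: str | Path, stimuli: StimulusSet) -> RecordingSet:
    """Read a RecordingSet written by :func:`save_recordings`.

    ``stimuli`` must be the stimulus set the recordings were simulated with
    (the HDF5 file stores only its ids and timing metadata).
    """
    path = Path(path)
    with h5py.File(path, "r") as f:
        meta = f["meta"].attrs
        stim_ids = json.loads(meta["stimulus_ids"])
        if stim_ids != stimuli.ids:
            raise ValueError("stimulus set does not match the recording file")
        units = []
        spike_times: dict = {}
        voltage: dict = {}
        has_voltage = False
        for uid in f["units"]:
            g = f["units"][uid]
            units.append(
                UnitSpec(
                    unit_id=uid,
                    bf=float(g.attrs["bf_khz"]),
                    bandwidth_oct=float(g.attrs["bandwidth_oct"]),
                    baseline_rate=float(g.attrs["baseline_rate"]),
                    gain=float(g.attrs["gain"]),
                    position=tuple(
                        int(v) if i < 2 else float(v)
                        for i, v in enumerate(g.attrs["position"])
                    ),
                )
            )
            for sid in stim_ids:
                gs = g[sid]
                trials, vtrials = [], []
                for k in range(int(meta["n_trials"])):
                    gt = gs[f"trial{k}"]
                    trials.append(gt["spike_times"][()])
                    if "voltage" in gt:
                        has_voltage = True
                        vtrials.append(gt["voltage"][()].astype(float))
                spike_times[(uid, sid)] = trials
                if vtrials:
                    voltage[(uid, sid)] = vtrials
        units.sort(key=lambda u: u.unit_id)
        pop = PopulationSpec(
            units=tuple(units),
            geometry=str(meta["geometry"]),
            shared_noise_c=float(meta["shared_noise_c"]),
        )
        return RecordingSet(
            population=pop,
            stimuli=stimuli,
            n_trials=int(meta["n_trials"]),
            spike_times=spike_times,
            voltage=voltage if has_voltage else None,
            simultaneous=bool(meta["simultaneous"]),
        )
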