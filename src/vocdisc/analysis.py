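"""Experiment orchestration: window sweeps, tonotopy, BF estimation, pooling.

Convenience layer that runs the classification engine across analysis
windows, maps per-vocalization accuracies onto the best-frequency axis,
matches tonotopic encoding profiles against stimulus spectra, estimates
best frequencies from pure-tone responses, and aggregates results across
shanks/positions/intensities with error propagation (grouped means with
SE = sqrt(sum sd_i^2) / m).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .discrimination import ClassificationResult, ClassifierSpec, CrossValPlan
from .features import SegmentSpec
from .pipeline import unit_classification
from .preprocessing import DEFAULT_FWHM_MS
from .stimuli import SpectralProfile
from .synthetic import PopulationSpec, RecordingSet

__all__ = [
    "WindowSweepResult",
    "TonotopicProfile",
    "MatchScore",
    "DEFAULT_PER_VOC_STARTS_S",
    "window_sweep",
    "third_octave_bins",
    "tonotopic_profile",
    "spectral_match",
    "estimate_best_frequency",
    "simulate_tone_responses",
    "aggregate",
]

# Per-vocalization analysis start points (s), one per stimulus in set order:
# each avoids onset transients and uninformative segments of its call.
DEFAULT_PER_VOC_STARTS_S = (0.54, 0.53, 0.54, 0.11, 0.52, 0.53, 0.06, 0.09,
                            0.53, 0.53, 0.21)

SWEEP_MODES = ("consecutive-10ms", "length-sweep", "consecutive-100ms")


@dataclass(frozen=True)
class WindowSweepResult:
    """CC +/- SE per analysis window, unit-averaged."""

    windows: tuple[SegmentSpec, ...]
    cc_per_window: np.ndarray
    sd_per_window: np.ndarray
    mode: str
    per_unit_cc: np.ndarray  # (n_units, n_windows)


@dataclass(frozen=True)
class TonotopicProfile:
    """Per-vocalization CC(k) averaged over units within 1/3-octave BF bins."""

    bf_bin_edges: np.ndarray  # kHz
    bf_bin_centers: np.ndarray  # kHz, only non-empty bins
    cc_k: np.ndarray  # percent, one per non-empty bin
    se: np.ndarray  # propagated SE per bin
    vocalization: str


@dataclass(frozen=True)
class MatchScore:
    """Similarity (percent) between an encoding profile and a spectrum."""

    match_pct: float
    metric: str = "euclidean"

    def __post_init__(self) -> None:
        if not (0.0 <= self.match_pct <= 100.0 + 1e-9):
            raise ValueError("match_pct must lie in [0, 100]")


# ---------------------------------------------------------------------------
# window sweeps


def _sweep_windows(mode: str, trial_length: float,
                   lengths_s: tuple[float, ...] | None,
                   start_s: float) -> list[SegmentSpec]:
    if mode == "consecutive-10ms":
        n = int(trial_length / 0.010)
        return [SegmentSpec(i * 0.010, 0.010) for i in range(n)]
    if mode == "consecutive-100ms":
        n = int(trial_length / 0.100)
        return [SegmentSpec(i * 0.100, 0.100) for i in range(n)]
    if mode == "length-sweep":
        if lengths_s is None:
            lengths_s = (0.005, 0.010, 0.020, 0.030, 0.040, 0.050,
                         0.100, 0.200, 0.300, 0.400)
        return [SegmentSpec(start_s, l) for l in lengths_s]
    raise ValueError(f"unknown sweep mode {mode!r}; choose from {SWEEP_MODES}")


def window_sweep(rec: RecordingSet, unit_ids: list[str] | None, mode: str,
                 clf: ClassifierSpec | None = None,
                 plan: CrossValPlan | None = None,
                 lengths_s: tuple[float, ...] | None = None,
                 start_s: float = 0.09,
                 per_voc_starts: dict[str, float] | None = None,
                 fwhm_ms: float = DEFAULT_FWHM_MS) -> WindowSweepResult:
    """Classify every analysis window and average CC over units.

    ``consecutive-10ms`` and ``consecutive-100ms`` tile the whole trial
    with common windows; ``length-sweep`` grows the segment length from a
    fixed start (optionally per-vocalization starts).  Windows extending
    past the trial are rejected.
    """
    unit_ids = unit_ids or rec.population.unit_ids
    windows = _sweep_windows(mode, rec.trial_length, lengths_s, start_s)
    for w in windows:
        starts = [w.start] if per_voc_starts is None else \
            [per_voc_starts.get(s, w.start) for s in rec.stimuli.ids]
        if any(s + w.length > rec.trial_length + 1e-9 for s in starts):
            raise ValueError(
                f"window (start={w.start}, len={w.length}) extends past the trial")
    per_unit = np.zeros((len(unit_ids), len(windows)))
    per_unit_sd = np.zeros_like(per_unit)
    for i, uid in enumerate(unit_ids):
        for j, w in enumerate(windows):
            res = unit_classification(rec, uid, w, clf, plan, fwhm_ms,
                                      per_voc_starts)
            per_unit[i, j] = res.cc
            per_unit_sd[i, j] = res.cc_sd
    cc = per_unit.mean(axis=0)
    se = np.sqrt((per_unit_sd ** 2).sum(axis=0)) / len(unit_ids)
    return WindowSweepResult(windows=tuple(windows), cc_per_window=cc,
                             sd_per_window=se, mode=mode, per_unit_cc=per_unit)


# ---------------------------------------------------------------------------
# tonotopic profiles


def third_octave_bins(f_min: float = 0.5, f_max: float = 45.0) -> np.ndarray:
    """1/3-octave bin edges (kHz) anchored at ``f_min``."""
    n = int(np.ceil(3 * np.log2(f_max / f_min))) + 1
    return f_min * 2.0 ** (np.arange(n + 1) / 3.0)


def tonotopic_profile(results: dict[str, ClassificationResult],
                      bfs_khz: dict[str, float], vocalization: str,
                      bin_edges: np.ndarray | None = None) -> TonotopicProfile:
    """Average one vocalization's CC(k) over units within each BF bin.

    ``results`` maps unit id to its all-vocalization ClassificationResult;
    the unit's CC(k) for the requested vocalization enters the 1/3-octave
    bin containing its BF.  Bin SE is propagated from the across-fold SDs
    of the member units (sqrt(sum sd_i^2) / m); empty bins are omitted.
    """
    if bin_edges is None:
        bin_edges = third_octave_bins()
    values: dict[int, list[tuple[float, float]]] = {}
    for uid, res in results.items():
        if vocalization not in res.classes:
            raise ValueError(f"{vocalization!r} not among classes of unit {uid}")
        k = res.classes.index(vocalization)
        b = int(np.searchsorted(bin_edges, bfs_khz[uid], side="right")) - 1
        if b < 0 or b >= bin_edges.size - 1:
            continue
        sd_k = float(res.cc_per_voc_sd()[k]) if res.fold_cc_per_voc is not None \
            else 0.0
        values.setdefault(b, []).append((float(res.cc_per_voc[k]), sd_k))
    if not values:
        raise ValueError("no unit falls inside the BF bins")
    bins = sorted(values)
    cc, se, centers = [], [], []
    for b in bins:
        vals = np.array([v for v, _ in values[b]])
        sds = np.array([s for _, s in values[b]])
        cc.append(vals.mean())
        se.append(np.sqrt((sds ** 2).sum()) / vals.size)
        centers.append(np.sqrt(bin_edges[b] * bin_edges[b + 1]))
    return TonotopicProfile(
        bf_bin_edges=bin_edges,
        bf_bin_centers=np.asarray(centers),
        cc_k=np.asarray(cc),
        se=np.asarray(se),
        vocalization=vocalization,
    )


def spectral_match(profile: TonotopicProfile, spectrum: SpectralProfile,
                   ) -> MatchScore:
    """Percent similarity of an encoding profile and a stimulus spectrum.

    Both are resampled onto the profile's BF bins (the spectrum's band
    powers are summed into each BF bin over the analysed range), normalised
    to unit sum, and compared as match = (1 - d / sqrt(2)) * 100 with d the
    Euclidean distance (sqrt(2) being the maximal distance between two
    probability vectors).
    """
    centers_khz = spectrum.bands.centers_khz
    edges = profile.bf_bin_edges
    bins_used = np.searchsorted(edges, profile.bf_bin_centers, side="right") - 1
    spec_binned = np.zeros(bins_used.size)
    for i, b in enumerate(bins_used):
        sel = (centers_khz >= edges[b]) & (centers_khz < edges[b + 1])
        spec_binned[i] = spectrum.band_power[sel].sum()
    if spec_binned.sum() == 0:
        raise ValueError("spectrum has no power in the profile's BF range")
    p = profile.cc_k / profile.cc_k.sum()
    q = spec_binned / spec_binned.sum()
    d = float(np.linalg.norm(p - q))
    return MatchScore(match_pct=(1.0 - d / np.sqrt(2.0)) * 100.0)


# ---------------------------------------------------------------------------
# best-frequency estimation from pure tones


def simulate_tone_responses(population: PopulationSpec,
                            freqs_khz: np.ndarray | None = None,
                            n_trials: int = 20, tone_s: float = 0.050,
                            seed: int = 0) -> tuple[np.ndarray, dict]:
    """Poisson spike counts to 50-ms pure tones for each unit.

    Emulates the frequency-response-area protocol: 40 log-spaced tone
    frequencies between 0.5 and 45 kHz by default.  Returns (freqs_khz,
    {unit_id: (n_freqs, n_trials) counts}).
    """
    if freqs_khz is None:
        freqs_khz = np.geomspace(0.5, 45.0, 40)
    rng = np.random.default_rng(
        np.random.SeedSequence([int(seed) & 0x7FFFFFFF, 0x70E5]))
    counts = {}
    for u in population.units:
        sd_oct = u.bandwidth_oct / 2.355
        tuning = np.exp(-0.5 * (np.log2(freqs_khz / u.bf) / sd_oct) ** 2)
        lam = (u.baseline_rate + u.gain * tuning) * tone_s
        counts[u.unit_id] = rng.poisson(lam[:, None], (freqs_khz.size, n_trials))
    return freqs_khz, counts


def estimate_best_frequency(freqs_khz: np.ndarray,
                            counts: np.ndarray) -> float:
    """BF = tone frequency eliciting the highest mean spike rate.

    ``counts`` is (n_freqs,) or (n_freqs, n_trials); ties resolve to the
    lower frequency.  All-zero responses are rejected as untuned.
    """
    freqs_khz = np.asarray(freqs_khz, dtype=float)
    counts = np.atleast_2d(np.asarray(counts, dtype=float))
    if counts.shape[0] != freqs_khz.size:
        counts = counts.T
    if freqs_khz.size < 1:
        raise ValueError("need at least one tone frequency")
    order = np.argsort(freqs_khz)
    mean_rate = counts.mean(axis=1)[order]
    if np.all(mean_rate == 0):
        raise ValueError("untuned unit (all-zero tone responses)")
    return float(freqs_khz[order][np.argmax(mean_rate)])


# ---------------------------------------------------------------------------
# aggregation with error propagation


def aggregate(results: pd.DataFrame, by: str | list[str]) -> pd.DataFrame:
    """Grouped CC means with propagated SE.

    ``results`` needs columns ``cc`` and ``cc_sd`` plus the grouping
    column(s); if a ``segment`` column exists it must be constant within
    each group (mixed analysis windows cannot be averaged).  Returns a
    frame with columns [by..., cc, se, n].
    """
    if isinstance(by, str):
        by = [by]
    missing = {"cc", "cc_sd", *by} - set(results.columns)
    if missing:
        raise ValueError(f"missing columns: {sorted(missing)}")
    if "segment" in results.columns:
        mixed = results.groupby(by)["segment"].nunique()
        if (mixed > 1).any():
            raise ValueError("mixed segment specs within an aggregation group")
    rows = []
    for key, g in results.groupby(by, sort=True):
        key = key if isinstance(key, tuple) else (key,)
        rows.append({
            **dict(zip(by, key)),
            "cc": g["cc"].mean(),
            "se": np.sqrt((g["cc_sd"] ** 2).sum()) / len(g),
            "n": len(g),
        })
    out = pd.DataFrame(rows)
    if "intensity_db" in by:
        out = out.sort_values("intensity_db").reset_index(drop=True)
    return out
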