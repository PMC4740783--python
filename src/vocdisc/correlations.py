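"""Temporal response correlations between simultaneously recorded units.

Pairwise responses x(t), y(t) of length n are cross-correlated and the
highest value within a maximum delay tau is kept:

    CorrRes = max_tau  sum_{t=1}^{n-tau} (x(t+tau) - <x>)(y(t) - <y>)
              / sqrt(sum_t (x(t) - <x>)^2 * sum_t (y(t) - <y>)^2),

for tau in [-10 ms, +10 ms] at the 1-ms trace resolution.  The numerator is
truncated to the overlapping samples while the denominators always use the
full-length deviations — exactly as defined, which means values slightly
above 1 are possible for strongly lagged self-similar traces; tau = 0
recovers the zero-lag Pearson coefficient.

Trial shuffling destroys simultaneity (and with it trial-matched shared
noise) while leaving every single-unit statistic untouched: per unit and
stimulus, trial indices are permuted uniformly; the first unit keeps the
identity permutation as the reference frame.  Comparing simultaneous vs
shuffled CorrRes quantifies the noise correlations; feeding per-trial mean
CorrRes values into the classifier alongside the concatenated time courses
tests whether those correlations carry stimulus information.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .discrimination import ClassificationResult, CrossValPlan, \
    _mean_class_correlation, crossval_assign
from .features import SegmentSpec
from .pipeline import response_matrix
from .preprocessing import DEFAULT_FWHM_MS
from .synthetic import RecordingSet

logger = logging.getLogger(__name__)

__all__ = [
    "CorrMatrix",
    "ShufflePlan",
    "StatTestResult",
    "corr_res",
    "pairwise_corr_matrix",
    "shuffle_trials",
    "classify_with_corr_features",
    "run_comparison_test",
]


@dataclass(frozen=True)
class CorrMatrix:
    """Trial-averaged pairwise max-lag correlations for one stimulus.

    Symmetric n_units x n_units matrix; by convention only the lower half
    is reported/plotted.  ``pairing`` records whether trials were matched
    by simultaneous index or by a shuffle plan.
    """

    values: np.ndarray
    unit_ids: tuple
    stimulus_id: str
    tau_max_ms: float
    pairing: str  # "simultaneous" | "shuffled"

    def lower_half(self) -> np.ndarray:
        """Strictly-lower-triangle entries (the reported pair values)."""
        i, j = np.tril_indices(self.values.shape[0], k=-1)
        return self.values[i, j]

    def mean_pair_value(self) -> float:
        return float(self.lower_half().mean())


@dataclass(frozen=True)
class ShufflePlan:
    """Per (unit, stimulus) permutation of trial indices; unit 1 = identity."""

    permutations: dict  # (unit_id, stim_id) -> np.ndarray of trial indices
    seed: int

    def trial_index(self, unit_id: str, stim_id: str, k: int) -> int:
        perm = self.permutations.get((unit_id, stim_id))
        return int(perm[k]) if perm is not None else k


@dataclass(frozen=True)
class StatTestResult:
    statistic: float
    p_value: float
    test_name: str
    alpha: float = 0.05


# ---------------------------------------------------------------------------
# Eq.-4 statistic


def corr_res(x: np.ndarray, y: np.ndarray, tau_max_ms: float = 10.0,
             bin_width_ms: float = 1.0) -> float:
    """Maximum lagged correlation within +/- tau_max (1-ms lag steps)."""
    x = np.asarray(getattr(x, "values", x), dtype=float)
    y = np.asarray(getattr(y, "values", y), dtype=float)
    if x.size != y.size:
        raise ValueError(f"trace lengths differ ({x.size} vs {y.size})")
    n = x.size
    max_lag = int(round(tau_max_ms / bin_width_ms))
    if max_lag >= n:
        raise ValueError("tau_max exceeds the trace length")
    dx = x - x.mean()
    dy = y - y.mean()
    den = np.sqrt((dx @ dx) * (dy @ dy))
    if den == 0.0:
        logger.warning("zero-variance trace in corr_res; returning 0")
        return 0.0
    best = -np.inf
    for tau in range(-max_lag, max_lag + 1):
        if tau >= 0:
            num = dx[tau:] @ dy[: n - tau]
        else:
            num = dx[: n + tau] @ dy[-tau:]
        best = max(best, num / den)
    return float(best)


# ---------------------------------------------------------------------------
# shuffling


def shuffle_trials(rec: RecordingSet, seed: int = 0
                   ) -> tuple[RecordingSet, ShufflePlan]:
    """Break simultaneity by permuting trial indices per unit and stimulus.

    Each unit's trial multiset (and hence every single-unit statistic) is
    preserved; only the alignment across units changes.  The first unit
    keeps the identity permutation as the reference frame.
    """
    if rec.n_trials < 2:
        raise ValueError("need at least 2 trials to shuffle")
    rng = np.random.default_rng(
        np.random.SeedSequence([int(seed) & 0x7FFFFFFF, 0x5F1E]))
    unit_ids = rec.population.unit_ids
    perms: dict = {}
    new_spikes: dict = {}
    for sid in rec.stimuli.ids:
        for i, uid in enumerate(unit_ids):
            perm = (np.arange(rec.n_trials) if i == 0
                    else rng.permutation(rec.n_trials))
            perms[(uid, sid)] = perm
            trials = rec.spike_times[(uid, sid)]
            new_spikes[(uid, sid)] = [trials[j] for j in perm]
    surrogate = RecordingSet(
        population=rec.population,
        stimuli=rec.stimuli,
        n_trials=rec.n_trials,
        spike_times=new_spikes,
        voltage=None,
        simultaneous=False,
        latencies_s=rec.latencies_s,
    )
    return surrogate, ShufflePlan(permutations=perms, seed=seed)


# ---------------------------------------------------------------------------
# pairwise matrices


def pairwise_corr_matrix(rec: RecordingSet, stimulus_id: str,
                         pairing: str = "simultaneous",
                         plan: ShufflePlan | None = None,
                         segment: SegmentSpec | None = None,
                         tau_max_ms: float = 10.0,
                         fwhm_ms: float = DEFAULT_FWHM_MS) -> CorrMatrix:
    """Trial-averaged CorrRes for every unit pair under one stimulus.

    ``pairing='simultaneous'`` aligns equal trial indices;
    ``pairing='shuffled'`` requires a ShufflePlan and aligns trial k of the
    reference frame with plan.trial_index(unit, stimulus, k) of each unit.
    """
    if pairing not in ("simultaneous", "shuffled"):
        raise ValueError("pairing must be 'simultaneous' or 'shuffled'")
    if pairing == "shuffled" and plan is None:
        raise ValueError("shuffled pairing requires a ShufflePlan")
    unit_ids = rec.population.unit_ids
    if segment is None:
        segment = SegmentSpec(0.0, rec.trial_length)
    traces = {}
    for uid in unit_ids:
        x, labels = response_matrix(rec, uid, segment, fwhm_ms)
        traces[uid] = x[np.asarray(labels) == stimulus_id]
    n = len(unit_ids)
    values = np.zeros((n, n))
    for a in range(n):
        for b in range(a, n):
            ua, ub = unit_ids[a], unit_ids[b]
            vals = []
            for k in range(rec.n_trials):
                ka = plan.trial_index(ua, stimulus_id, k) if pairing == "shuffled" else k
                kb = plan.trial_index(ub, stimulus_id, k) if pairing == "shuffled" else k
                vals.append(corr_res(traces[ua][ka], traces[ub][kb], tau_max_ms))
            values[a, b] = values[b, a] = float(np.mean(vals))
    return CorrMatrix(values=values, unit_ids=tuple(unit_ids),
                      stimulus_id=stimulus_id, tau_max_ms=tau_max_ms,
                      pairing=pairing)


# ---------------------------------------------------------------------------
# correlation-augmented classification


def _corr_feature_rows(traces_by_unit: list[np.ndarray],
                       tau_max_ms: float) -> np.ndarray:
    """Per-trial mean CorrRes of each unit with the other pooled units.

    Input: per-unit (n_rows x seg_len) aligned trace matrices; output
    (n_rows x n_comb).
    """
    n_units = len(traces_by_unit)
    n_rows = traces_by_unit[0].shape[0]
    out = np.zeros((n_rows, n_units))
    for r in range(n_rows):
        pair = np.zeros((n_units, n_units))
        for a in range(n_units):
            for b in range(a + 1, n_units):
                pair[a, b] = pair[b, a] = corr_res(
                    traces_by_unit[a][r], traces_by_unit[b][r], tau_max_ms)
        out[r] = pair.sum(axis=1) / (n_units - 1)
    return out


def classify_with_corr_features(rec: RecordingSet, unit_ids: Sequence[str],
                                segment: SegmentSpec,
                                plan: CrossValPlan | None = None,
                                tau_max_ms: float = 10.0,
                                fwhm_ms: float = DEFAULT_FWHM_MS,
                                per_voc_starts: dict[str, float] | None = None,
                                ) -> ClassificationResult:
    """Concatenation-pooled classification augmented with CorrRes features.

    Each test trial is assigned by a rank fusion of two per-class criteria:
    (i) mean zero-lag correlation of the concatenated time course with the
    class's training trials (maximised) and (ii) mean squared difference of
    the n_comb-vector of per-unit mean CorrRes values to the class's
    training trials (minimised).  Per-class ranks of the two criteria are
    summed and the lowest rank-sum wins; ties fall to the lowest class
    index.  When the correlation features are identical across classes the
    assignment reduces to the plain correlation template.
    """
    if len(unit_ids) < 2:
        raise ValueError("correlation features need n_comb >= 2 units")
    plan = plan or CrossValPlan()
    mats, labels = [], None
    for uid in unit_ids:
        x, lab = response_matrix(rec, uid, segment, fwhm_ms, per_voc_starts)
        mats.append(x)
        labels = lab
    pooled = np.hstack(mats)
    corr_feats = _corr_feature_rows(mats, tau_max_ms)
    labels = np.asarray(labels)
    classes = np.unique(labels)

    def assign(train_idx, test_idx):
        tr_lab = labels[train_idx]
        # criterion 1: mean time-course correlation (higher is better)
        c1 = _mean_class_correlation(pooled[test_idx], pooled[train_idx],
                                     tr_lab, classes)
        # criterion 2: mean squared CorrRes-vector difference (lower is better)
        c2 = np.stack(
            [
                ((corr_feats[test_idx][:, None, :]
                  - corr_feats[train_idx][None, tr_lab == c, :]) ** 2)
                .sum(axis=2)
                .mean(axis=1)
                for c in classes
            ],
            axis=1,
        )
        # rank fusion per test trial; stable argsort -> ties to lowest index
        r1 = np.argsort(np.argsort(-c1, axis=1, kind="stable"), axis=1)
        r2 = np.argsort(np.argsort(c2, axis=1, kind="stable"), axis=1)
        return classes[np.argmin(r1 + r2, axis=1)]

    return crossval_assign(labels, plan, assign)


# ---------------------------------------------------------------------------
# statistical dispatch


def run_comparison_test(sample_a: np.ndarray, sample_b: np.ndarray,
                        paired: bool = False, alpha: float = 0.05,
                        ) -> StatTestResult:
    """Compare two samples, dispatching on a Shapiro normality screen.

    If both samples pass Shapiro-Wilk at ``alpha`` the Student's t-test is
    used (paired or independent); otherwise the Wilcoxon-Mann-Whitney test
    (signed-rank when paired, rank-sum otherwise).  Identical zero-variance
    samples return statistic 0, p = 1 by convention.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size < 3 or b.size < 3:
        raise ValueError("each sample needs at least 3 values")
    if (np.ptp(a) == 0 and np.ptp(b) == 0 and a.mean() == b.mean()) or \
            (paired and a.size == b.size and np.array_equal(a, b)):
        return StatTestResult(0.0, 1.0, "degenerate", alpha)
    normal = (stats.shapiro(a).pvalue > alpha and stats.shapiro(b).pvalue > alpha)
    if normal:
        if paired:
            res = stats.ttest_rel(a, b)
            name = "paired t-test"
        else:
            res = stats.ttest_ind(a, b)
            name = "t-test"
    else:
        if paired:
            res = stats.wilcoxon(a, b)
            name = "wilcoxon signed-rank"
        else:
            res = stats.mannwhitneyu(a, b, alternative="two-sided")
            name = "wilcoxon-mann-whitney"
    return StatTestResult(float(res.statistic), float(res.pvalue), name, alpha)
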