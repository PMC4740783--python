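"""Pooling responses across multi-unit clusters.

Three schemes trade off which response information survives pooling:

- ``concatenate``: per-trial EPSP segments joined in a fixed unit order —
  keeps both spectral (unit identity / frequency tuning) and temporal
  information;
- ``add``: per-trial spike trains summed bin-wise — keeps temporal
  information only (units become indistinguishable);
- ``rate-concat``: per-unit mean firing rates over a 100-ms window joined
  into a rate vector, classified by minimum squared rate difference —
  keeps spectral information only.

The pooling curve grows the pooled set one unit at a time, either gradually
(nearest spatial neighbour on the array, starting from one end of the
tonotopic gradient) or randomly, and runs a full cross-validated
classification at each set size.  Performance is averaged over 2 iterations
for gradual and 3 for random ordering.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .discrimination import ClassifierSpec, CrossValPlan, crossval_classify
from .features import SegmentSpec
from .pipeline import binned_matrix, response_matrix, segment_starts
from .preprocessing import BinnedSpikeTrain, DEFAULT_BIN_S, DEFAULT_FWHM_MS
from .synthetic import RecordingSet

__all__ = [
    "PoolingSpec",
    "PoolingCurve",
    "pool_concatenate",
    "pool_add",
    "pool_rates",
    "pooled_response_matrix",
    "pooling_order",
    "pooling_curve",
    "POOLING_METHODS",
]

POOLING_METHODS = ("concatenate", "add", "rate-concat")
POOLING_ORDERS = ("gradual", "random")


@dataclass(frozen=True)
class PoolingSpec:
    """Pooling method, ordering rule and iteration count."""

    method: str = "concatenate"
    order: str = "gradual"
    n_comb: int | None = None  # None -> all units
    n_iter: int | None = None  # default: 2 gradual, 3 random
    window: SegmentSpec = field(default_factory=lambda: SegmentSpec(0.1, 0.1))
    seed: int = 0

    def __post_init__(self) -> None:
        if self.method not in POOLING_METHODS:
            raise ValueError(f"unknown pooling method {self.method!r}")
        if self.order not in POOLING_ORDERS:
            raise ValueError(f"unknown pooling order {self.order!r}")

    @property
    def iterations(self) -> int:
        if self.n_iter is not None:
            return self.n_iter
        return 2 if self.order == "gradual" else 3


@dataclass(frozen=True)
class PoolingCurve:
    """CC +/- SE for n_comb = 1..N, with the individual iteration curves."""

    n_comb: np.ndarray
    cc: np.ndarray
    sd: np.ndarray
    method: str
    order: str
    iteration_cc: np.ndarray  # (n_iter, N)
    iteration_orders: tuple  # unit-id order per iteration


# ---------------------------------------------------------------------------
# single-trial pooling primitives


def pool_concatenate(traces: Sequence[np.ndarray]) -> np.ndarray:
    """Concatenate per-unit trace segments (fixed unit order) for one trial."""
    lengths = {np.asarray(t).size for t in traces}
    if len(lengths) != 1:
        raise ValueError("all per-unit segments must have equal length")
    return np.concatenate([np.asarray(t, dtype=float) for t in traces])


def pool_add(trains: Sequence[BinnedSpikeTrain | np.ndarray]) -> np.ndarray:
    """Element-wise sum of per-unit spike-count segments; spikes conserved."""
    arrs = [t.counts if isinstance(t, BinnedSpikeTrain) else np.asarray(t)
            for t in trains]
    lengths = {a.size for a in arrs}
    if len(lengths) != 1:
        raise ValueError("all per-unit segments must have equal length")
    return np.sum(arrs, axis=0)


def pool_rates(trains: Sequence[BinnedSpikeTrain | np.ndarray],
               window_s: float = 0.100,
               bin_width: float = DEFAULT_BIN_S) -> np.ndarray:
    """Concatenated per-unit mean firing rates (spikes/s) over the window."""
    if abs(window_s - 0.100) > 1e-9:
        raise ValueError("rate pooling uses 100-ms windows")
    arrs = [t.counts if isinstance(t, BinnedSpikeTrain) else np.asarray(t)
            for t in trains]
    n_bins = int(round(window_s / bin_width))
    out = []
    for a in arrs:
        if a.size != n_bins:
            raise ValueError(f"segment has {a.size} bins; expected {n_bins}")
        out.append(a.sum() / window_s)
    return np.asarray(out, dtype=float)


# ---------------------------------------------------------------------------
# matrix-level pooling


def pooled_response_matrix(rec: RecordingSet, unit_ids: Sequence[str],
                           segment: SegmentSpec, method: str = "concatenate",
                           fwhm_ms: float = DEFAULT_FWHM_MS,
                           per_voc_starts: dict[str, float] | None = None,
                           ) -> tuple[np.ndarray, np.ndarray]:
    """Pooled per-trial response matrix in the given (fixed) unit order.

    Trial pairing across units is positional: row i of every unit's matrix
    is the same simultaneous trial index, so pooling rows preserves
    simultaneity (shuffle trials upstream to break it).
    """
    if method not in POOLING_METHODS:
        raise ValueError(f"unknown pooling method {method!r}")
    if method == "concatenate":
        mats = []
        labels = None
        for uid in unit_ids:
            x, lab = response_matrix(rec, uid, segment, fwhm_ms, per_voc_starts)
            mats.append(x)
            labels = lab
        return np.hstack(mats), labels
    segs = segment_starts(rec.stimuli.ids, segment, per_voc_starts)
    rows, labels = [], []
    for sid in rec.stimuli.ids:
        sl = segs[sid].bin_slice(DEFAULT_BIN_S)
        per_unit = [binned_matrix(rec, uid, sid)[:, sl] for uid in unit_ids]
        if method == "add":
            summed = np.sum(per_unit, axis=0)
            kernel_mat = np.stack([
                np.convolve(row.astype(float),
                            _kernel_cache(fwhm_ms))[: row.size]
                for row in summed
            ])
            rows.append(kernel_mat)
        else:  # rate-concat
            rates = np.stack(
                [m.sum(axis=1) / segs[sid].length for m in per_unit], axis=1)
            rows.append(rates)
        labels.extend([sid] * per_unit[0].shape[0])
    return np.vstack(rows), np.asarray(labels)


_KERNELS: dict[float, np.ndarray] = {}


def _kernel_cache(fwhm_ms: float) -> np.ndarray:
    from .preprocessing import alpha_kernel

    if fwhm_ms not in _KERNELS:
        _KERNELS[fwhm_ms] = alpha_kernel(fwhm_ms)
    return _KERNELS[fwhm_ms]


# ---------------------------------------------------------------------------
# pooling order and curve


def _spatial_order(rec: RecordingSet, start: str) -> list[str]:
    """Grow from the start unit by nearest spatial neighbour to the set."""
    units = {u.unit_id: np.asarray(u.xy_um()) for u in rec.population.units}
    order = [start]
    remaining = [u for u in units if u != start]
    while remaining:
        best = min(
            remaining,
            key=lambda u: (min(np.linalg.norm(units[u] - units[o])
                               for o in order), u),
        )
        order.append(best)
        remaining.remove(best)
    return order


def pooling_order(rec: RecordingSet, order: str, iteration: int,
                  seed: int = 0) -> list[str]:
    """Unit order for one pooling iteration.

    Gradual: iteration 0 grows from the lowest-BF unit, iteration 1 from
    the highest-BF unit (the two ends of the tonotopic gradient); random:
    a uniform permutation per iteration.
    """
    units = rec.population.units
    if order == "gradual":
        by_bf = sorted(units, key=lambda u: u.bf)
        start = by_bf[0] if iteration % 2 == 0 else by_bf[-1]
        return _spatial_order(rec, start.unit_id)
    if order == "random":
        rng = np.random.default_rng(
            np.random.SeedSequence([int(seed) & 0x7FFFFFFF, 0xF001, iteration]))
        ids = [u.unit_id for u in units]
        return [ids[i] for i in rng.permutation(len(ids))]
    raise ValueError(f"unknown pooling order {order!r}")


def pooling_curve(rec: RecordingSet, spec: PoolingSpec,
                  clf: ClassifierSpec | None = None,
                  plan: CrossValPlan | None = None,
                  fwhm_ms: float = DEFAULT_FWHM_MS,
                  per_voc_starts: dict[str, float] | None = None,
                  ) -> PoolingCurve:
    """CC as a function of the number of pooled units.

    For each iteration's unit order and each n_comb = 1..N, build the pooled
    response matrix and run a full cross-validated classification; the curve
    is the iteration mean with propagated SE.  ``rate-concat`` pooling uses
    the minimum squared-rate-difference rule regardless of ``clf``.
    """
    n_max = spec.n_comb or rec.population.n_units
    if n_max > rec.population.n_units:
        raise ValueError("n_comb exceeds available units")
    if clf is None:
        clf = ClassifierSpec("corr-template")
    if spec.method == "rate-concat":
        clf = ClassifierSpec("min-sq-rate")
    plan = plan or CrossValPlan()
    iter_cc = np.zeros((spec.iterations, n_max))
    iter_sd = np.zeros_like(iter_cc)
    orders = []
    for it in range(spec.iterations):
        unit_order = pooling_order(rec, spec.order, it, spec.seed)
        orders.append(tuple(unit_order))
        for n in range(1, n_max + 1):
            x, labels = pooled_response_matrix(
                rec, unit_order[:n], spec.window, spec.method, fwhm_ms,
                per_voc_starts)
            res = crossval_classify(x, labels, clf=clf, plan=plan)
            iter_cc[it, n - 1] = res.cc
            iter_sd[it, n - 1] = res.cc_sd
    cc = iter_cc.mean(axis=0)
    sd = np.sqrt((iter_sd ** 2).sum(axis=0)) / spec.iterations
    return PoolingCurve(
        n_comb=np.arange(1, n_max + 1),
        cc=cc,
        sd=sd,
        method=spec.method,
        order=spec.order,
        iteration_cc=iter_cc,
        iteration_orders=tuple(orders),
    )
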