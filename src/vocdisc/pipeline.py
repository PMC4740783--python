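"""Glue between synthetic/loaded recordings and the classification engine.

Turns a RecordingSet into 1-ms binned counts, EPSP-smoothed trace matrices
and segment-sliced response matrices (rows = trials, ordered stimulus-major)
ready for cross-validated classification.  Per-vocalization analysis start
points are supported: each stimulus's segment may begin at its own start
time while sharing one length.
"""

from __future__ import annotations

import numpy as np

from .discrimination import ClassificationResult, ClassifierSpec, CrossValPlan, \
    crossval_classify
from .features import SegmentSpec
from .preprocessing import DEFAULT_BIN_S, DEFAULT_FWHM_MS, alpha_kernel, \
    bin_spikes
from .synthetic import RecordingSet

__all__ = [
    "binned_matrix",
    "epsp_matrix",
    "segment_starts",
    "response_matrix",
    "unit_classification",
]


def binned_matrix(rec: RecordingSet, unit_id: str, stim_id: str,
                  bin_width: float = DEFAULT_BIN_S) -> np.ndarray:
    """(n_trials x n_bins) spike counts for one unit and stimulus."""
    return np.stack([
        bin_spikes(t, rec.trial_length, bin_width).counts
        for t in rec.trains(unit_id, stim_id)
    ])


def epsp_matrix(rec: RecordingSet, unit_id: str, stim_id: str,
                fwhm_ms: float = DEFAULT_FWHM_MS,
                bin_width: float = DEFAULT_BIN_S) -> np.ndarray:
    """(n_trials x n_bins) EPSP-smoothed traces for one unit and stimulus."""
    counts = binned_matrix(rec, unit_id, stim_id, bin_width)
    kernel = alpha_kernel(fwhm_ms, bin_width)
    n = counts.shape[1]
    out = np.empty((counts.shape[0], n))
    for i, row in enumerate(counts):
        out[i] = np.convolve(row.astype(float), kernel)[:n]
    return out


def segment_starts(stim_ids: list[str], segment: SegmentSpec,
                   per_voc_starts: dict[str, float] | None = None
                   ) -> dict[str, SegmentSpec]:
    """Resolve one SegmentSpec per stimulus (shared length, optional starts)."""
    out = {}
    for sid in stim_ids:
        start = segment.start if per_voc_starts is None else \
            per_voc_starts.get(sid, segment.start)
        out[sid] = SegmentSpec(start, segment.length)
    return out


def response_matrix(rec: RecordingSet, unit_id: str, segment: SegmentSpec,
                    fwhm_ms: float = DEFAULT_FWHM_MS,
                    per_voc_starts: dict[str, float] | None = None,
                    bin_width: float = DEFAULT_BIN_S,
                    ) -> tuple[np.ndarray, np.ndarray]:
    """Stacked EPSP segments and labels for one unit across all stimuli.

    Rows are ordered stimulus-major, trial-minor, so trial pairing across
    units is positional (row i of unit A and row i of unit B are the same
    simultaneous trial).
    """
    segs = segment_starts(rec.stimuli.ids, segment, per_voc_starts)
    rows, labels = [], []
    for sid in rec.stimuli.ids:
        traces = epsp_matrix(rec, unit_id, sid, fwhm_ms, bin_width)
        sl = segs[sid].bin_slice(bin_width)
        if sl.stop > traces.shape[1]:
            raise ValueError(f"segment for {sid!r} extends past the trial")
        rows.append(traces[:, sl])
        labels.extend([sid] * traces.shape[0])
    return np.vstack(rows), np.asarray(labels)


def unit_classification(rec: RecordingSet, unit_id: str, segment: SegmentSpec,
                        clf: ClassifierSpec | None = None,
                        plan: CrossValPlan | None = None,
                        fwhm_ms: float = DEFAULT_FWHM_MS,
                        per_voc_starts: dict[str, float] | None = None,
                        ) -> ClassificationResult:
    """Cross-validated discrimination for one unit's EPSP segments."""
    x, labels = response_matrix(rec, unit_id, segment, fwhm_ms, per_voc_starts)
    return crossval_classify(x, labels, clf=clf, plan=plan)
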