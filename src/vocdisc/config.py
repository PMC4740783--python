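"""Run configuration: YAML schema, validation, seeding and provenance.

A single YAML document describes one reproducible experiment: stimulus
generation, population geometry, preprocessing parameters, classifier and
cross-validation settings, pooling and correlation options, and a master
seed from which every stochastic stage derives a stable sub-seed.  The
SHA-256 hash of the canonicalised config is recorded in every output file.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from ._utils import derive_seed
from .analysis import DEFAULT_PER_VOC_STARTS_S, spectral_match, \
    tonotopic_profile, window_sweep
from .correlations import classify_with_corr_features, pairwise_corr_matrix, \
    run_comparison_test, shuffle_trials
from .discrimination import ClassifierSpec, CrossValPlan
from .features import SegmentSpec
from .pipeline import unit_classification
from .pooling import PoolingSpec, pooling_curve
from .stimuli import compute_spectral_profile, generate_vocalization_set, \
    make_band_edges
from .synthetic import generate_population, simulate_responses

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "load_config", "run"]

EXPERIMENTS = ("window-sweep", "tonotopy", "pooling", "correlations")


@dataclass
class RunConfig:
    """Validated experiment configuration (see module docstring)."""

    experiment: str = "pooling"
    seed: int = 0
    out_dir: str = "results"
    # stimuli
    n_stimuli: int = 11
    intensity_db: float = 70.0
    trial_length: float = 1.0
    # population
    geometry: str = "linear_double_shank"
    n_units: int = 16
    bf_range: tuple[float, float] = (0.5, 23.0)
    shared_noise_c: float = 0.0
    n_trials: int = 20
    # preprocessing / features
    z: float = 3.0
    fwhm_ms: float = 3.0
    # analysis window
    segment_start: float = 0.1
    segment_length: float = 0.1
    use_per_voc_starts: bool = False
    # classification
    classifier: str = "corr-template"
    n_folds: int = 10
    # pooling
    pooling_method: str = "concatenate"
    pooling_order: str = "gradual"
    n_comb: int | None = None
    # correlations
    tau_max_ms: float = 10.0
    sweep_mode: str = "consecutive-100ms"

    def __post_init__(self) -> None:
        errors = []
        if self.experiment not in EXPERIMENTS:
            errors.append(f"experiment: {self.experiment!r} not in {EXPERIMENTS}")
        if self.n_trials < 2:
            errors.append("n_trials: must be >= 2")
        if self.n_units < 1:
            errors.append("n_units: must be >= 1")
        if not (0 <= self.shared_noise_c <= 1):
            errors.append("shared_noise_c: must be in [0, 1]")
        if self.segment_start < 0 or self.segment_length <= 0:
            errors.append("segment: start >= 0 and length > 0 required")
        if errors:
            raise ValueError("invalid configuration: " + "; ".join(errors))

    def config_hash(self) -> str:
        canon = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]

    def stage_seed(self, stage: str) -> int:
        return derive_seed(self.seed, stage)


def load_config(path: str | Path) -> RunConfig:
    """Load and validate a YAML config; unknown keys are rejected."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    valid = set(RunConfig.__dataclass_fields__)
    unknown = set(raw) - valid
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    if "bf_range" in raw:
        raw["bf_range"] = tuple(raw["bf_range"])
    return RunConfig(**raw)


# ---------------------------------------------------------------------------
# experiment driver


def _setup(cfg: RunConfig):
    stimuli = generate_vocalization_set(
        seed=cfg.stage_seed("stimuli"), trial_length=cfg.trial_length,
        intensity_db=cfg.intensity_db)
    if cfg.n_stimuli != stimuli.n_voc:
        stimuli = type(stimuli)(stimuli.stimuli[: cfg.n_stimuli],
                                cfg.trial_length, cfg.intensity_db)
    pop = generate_population(cfg.geometry, cfg.n_units, cfg.bf_range,
                              seed=cfg.stage_seed("population"),
                              shared_noise_c=cfg.shared_noise_c)
    rec = simulate_responses(pop, stimuli, cfg.n_trials,
                             seed=cfg.stage_seed("responses"))
    return stimuli, pop, rec


def _per_voc_starts(cfg: RunConfig, stimuli) -> dict[str, float] | None:
    if not cfg.use_per_voc_starts:
        return None
    return {sid: DEFAULT_PER_VOC_STARTS_S[i % len(DEFAULT_PER_VOC_STARTS_S)]
            for i, sid in enumerate(stimuli.ids)}


def run(cfg: RunConfig) -> dict:
    """Execute the configured experiment; write CSV/JSON outputs.

    Deterministic given the master seed.  Returns a summary dict (also
    written to ``<out_dir>/summary.json`` with the config hash).
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    chash = cfg.config_hash()
    stimuli, pop, rec = _setup(cfg)
    clf = ClassifierSpec(cfg.classifier)
    plan = CrossValPlan(cfg.n_folds, seed=cfg.stage_seed("folds"))
    segment = SegmentSpec(cfg.segment_start, cfg.segment_length)
    starts = _per_voc_starts(cfg, stimuli)
    summary: dict = {"experiment": cfg.experiment, "config_hash": chash,
                     "seed": cfg.seed}

    if cfg.experiment == "window-sweep":
        sweep = window_sweep(rec, None, cfg.sweep_mode, clf, plan,
                             per_voc_starts=starts)
        df = pd.DataFrame({
            "start": [w.start for w in sweep.windows],
            "length": [w.length for w in sweep.windows],
            "cc": sweep.cc_per_window,
            "se": sweep.sd_per_window,
            "config_hash": chash,
        })
        df.to_csv(out / "window_sweep.csv", index=False)
        summary["cc_max"] = float(sweep.cc_per_window.max())
        summary["cc_min"] = float(sweep.cc_per_window.min())

    elif cfg.experiment == "tonotopy":
        results = {u.unit_id: unit_classification(rec, u.unit_id, segment,
                                                  clf, plan, cfg.fwhm_ms, starts)
                   for u in pop.units}
        bfs = {u.unit_id: u.bf for u in pop.units}
        bands = make_band_edges()
        rows = []
        for stim in stimuli.stimuli:
            prof = tonotopic_profile(results, bfs, stim.id)
            score = spectral_match(prof, compute_spectral_profile(stim, bands))
            for c, v, e in zip(prof.bf_bin_centers, prof.cc_k, prof.se):
                rows.append({"vocalization": stim.id, "bf_khz": c, "cc_k": v,
                             "se": e, "match_pct": score.match_pct,
                             "config_hash": chash})
            summary.setdefault("match_pct", {})[stim.id] = score.match_pct
        pd.DataFrame(rows).to_csv(out / "tonotopic_profiles.csv", index=False)

    elif cfg.experiment == "pooling":
        spec = PoolingSpec(cfg.pooling_method, cfg.pooling_order,
                           n_comb=cfg.n_comb, window=segment,
                           seed=cfg.stage_seed("pooling"))
        curve = pooling_curve(rec, spec, clf, plan, cfg.fwhm_ms, starts)
        df = pd.DataFrame({
            "n_comb": curve.n_comb, "cc": curve.cc, "sd": curve.sd,
            "method": curve.method, "order": curve.order, "config_hash": chash,
        })
        df.to_csv(out / "pooling_curve.csv", index=False)
        summary["cc_by_n"] = curve.cc.tolist()

    elif cfg.experiment == "correlations":
        shuffled, plan_sh = shuffle_trials(rec, cfg.stage_seed("shuffle"))
        unit_ids = pop.unit_ids[: (cfg.n_comb or min(5, pop.n_units))]
        rows = []
        for stim in stimuli.stimuli:
            sim = pairwise_corr_matrix(rec, stim.id, "simultaneous",
                                       segment=segment,
                                       tau_max_ms=cfg.tau_max_ms)
            shuf = pairwise_corr_matrix(shuffled, stim.id, "simultaneous",
                                        segment=segment,
                                        tau_max_ms=cfg.tau_max_ms)
            test = run_comparison_test(sim.lower_half(), shuf.lower_half(),
                                       paired=True)
            rows.append({"vocalization": stim.id,
                         "corr_sim": sim.mean_pair_value(),
                         "corr_shuf": shuf.mean_pair_value(),
                         "p_value": test.p_value, "test": test.test_name,
                         "config_hash": chash})
        pd.DataFrame(rows).to_csv(out / "response_correlations.csv", index=False)
        res_sim = classify_with_corr_features(rec, unit_ids, segment, plan,
                                              cfg.tau_max_ms, cfg.fwhm_ms, starts)
        res_shuf = classify_with_corr_features(shuffled, unit_ids, segment,
                                               plan, cfg.tau_max_ms,
                                               cfg.fwhm_ms, starts)
        summary["cc_simultaneous"] = res_sim.cc
        summary["cc_shuffled"] = res_shuf.cc
        summary["mean_corr_sim"] = float(np.mean([r["corr_sim"] for r in rows]))
        summary["mean_corr_shuf"] = float(np.mean([r["corr_shuf"] for r in rows]))

    (out / "summary.json").write_text(json.dumps(summary, indent=2))
    return summary
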