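"""End-to-end orchestration: simulate -> features -> reduce -> classify -> compare.

A single hierarchical config drives every stage; re-running with the same
config and master seed reproduces all numeric outputs exactly. Every output
table carries the config hash and master seed in a comment header.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import classify, features, paired, synthetic
from .config import default_profiles, manifest_from_dict, profiles_from_dict
from .errors import ConfigError
from .types import ExperimentDesign, SessionManifest

log = logging.getLogger(__name__)

LEDGER_VARIABLES = ("mean_dv", "skew", "kurt", "pdf_mu", "ac_lag_s",
                    "psd_beta", "apen")

#: Desk-scale demo design: same four treatments, shrunk series and counts.
DEMO_CONFIG = {
    "design": {
        "rate": 62.5,
        "duration_s": 720.0,      # 12 min -> 45,000 samples
        "experiments": [
            {"name": "water", "n_plants": 8, "n_reference": 2},
            {"name": "nutrient", "n_plants": 8, "n_reference": 2},
            {"name": "peg", "n_plants": 8, "n_reference": 2},
            {"name": "nacl", "n_plants": 8, "n_reference": 2},
        ],
    },
    "features": {"apen_max_points": 2000, "max_scale": 10},
    "reduction": {"window_size": 3000},
    "harness": {"classifiers": ["KNN", "DT", "Bayes"],
                "fractions": [0.3, 0.5, 0.7, 0.9], "repetitions": 20},
    "seed": 0,
}


@dataclass
class RunReport:
    """What a pipeline run produced, with stage timings."""

    out_dir: Path
    config_hash: str
    seed: int
    n_series: int
    tables: dict = field(default_factory=dict)
    timings_s: dict = field(default_factory=dict)


def _config_hash(config: dict) -> str:
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def _write_table(df: pd.DataFrame, path: Path, config_hash: str,
                 seed: int) -> None:
    with path.open("w") as fh:
        fh.write(f"# config_hash = {config_hash}\n# seed = {seed}\n")
        df.to_csv(fh, index=False)


def validate_config(config: dict) -> None:
    """Reject invalid configs before any computation."""
    harness = config.get("harness", {})
    reps = harness.get("repetitions", 20)
    if reps < 1:
        raise ConfigError(f"harness.repetitions must be >= 1, got {reps}")
    fractions = harness.get("fractions", list(classify.DEFAULT_FRACTIONS))
    if any(not 0 < f < 1 for f in fractions):
        raise ConfigError("harness.fractions must lie in (0, 1)")
    for name in harness.get("classifiers", classify.CLASSIFIER_ROSTER):
        if name not in classify.CLASSIFIER_ROSTER:
            raise ConfigError(f"unknown classifier {name!r}")
    window = config.get("reduction", {}).get("window_size",
                                             classify.DEFAULT_WINDOW)
    if window < 1:
        raise ConfigError("reduction.window_size must be >= 1")
    design = config.get("design")
    if design is not None:
        manifest = manifest_from_dict({"design": design})
        if manifest.samples_per_series < window:
            raise ConfigError(
                f"series of {manifest.samples_per_series} samples shorter "
                f"than one reduction window ({window})")


def run_pipeline(config: dict, out_dir: Optional[Path] = None,
                 seed: Optional[int] = None) -> RunReport:
    """Run the full pipeline from one config mapping.

    Stages: manifest enumeration, per-series synthesis, nine-statistic
    ledgers, interval-arithmetic reduction, learning curves + confusion
    matrices (before vs after per experiment, and the four treatments
    against each other on post-stimulus data), and paired before/after
    ledger statistics. Writes one delimited table per product.
    """
    validate_config(config)
    if seed is None:
        seed = int(config.get("seed", 0))
    out_dir = Path(out_dir if out_dir is not None
                   else config.get("out", "electrome_run"))
    out_dir.mkdir(parents=True, exist_ok=True)
    chash = _config_hash({**config, "seed": seed})
    report = RunReport(out_dir=out_dir, config_hash=chash, seed=seed,
                       n_series=0)

    design = config.get("design")
    manifest = (manifest_from_dict({"design": design}) if design
                else synthetic.default_session_manifest())
    if config.get("treatments"):
        profiles = profiles_from_dict({"treatments": config["treatments"]})
    else:
        profiles = default_profiles()

    t0 = time.perf_counter()
    entries, make_series = synthetic.generate_manifest(manifest,
                                                       profiles=profiles,
                                                       seed=seed)
    manifest_df = pd.DataFrame(entries)
    manifest_df["n_samples"] = manifest.samples_per_series
    _write_table(manifest_df, out_dir / "manifest.csv", chash, seed)
    report.tables["manifest"] = out_dir / "manifest.csv"
    report.timings_s["manifest"] = time.perf_counter() - t0

    fcfg = features.FeatureConfig(**config.get("features", {}))
    window = config.get("reduction", {}).get("window_size",
                                             classify.DEFAULT_WINDOW)
    center = config.get("reduction", {}).get("center", "mean")

    t0 = time.perf_counter()
    rows, vectors, vec_meta = [], [], []
    for entry in entries:
        try:
            series = make_series(entry)
        except Exception as exc:
            raise RuntimeError(
                f"stage 'simulate' failed for series {entry}: {exc}") from exc
        if not entry["is_reference"]:
            led = features.feature_ledger(series, fcfg)
            rows.append(led.to_row())
            vec = classify.interval_reduce(series, window_size=window,
                                           center=center)
            vectors.append(vec)
            vec_meta.append(entry)
    report.n_series = len(rows)
    ledger_df = pd.DataFrame(rows)
    _write_table(ledger_df, out_dir / "ledger.csv", chash, seed)
    report.tables["ledger"] = out_dir / "ledger.csv"

    triplet_rows = []
    for entry, vec in zip(vec_meta, vectors):
        for wi, (mn, md, mx) in enumerate(vec.triplets):
            triplet_rows.append({**{k: entry[k] for k in
                                    ("experiment", "plant_id", "phase")},
                                 "window": wi, "min": mn, "center": md,
                                 "max": mx})
    _write_table(pd.DataFrame(triplet_rows), out_dir / "triplets.csv",
                 chash, seed)
    report.tables["triplets"] = out_dir / "triplets.csv"
    report.timings_s["features"] = time.perf_counter() - t0

    harness = config.get("harness", {})
    classifiers = harness.get("classifiers", list(classify.CLASSIFIER_ROSTER))
    fractions = harness.get("fractions", list(classify.DEFAULT_FRACTIONS))
    repetitions = harness.get("repetitions", 20)

    t0 = time.perf_counter()
    curve_rows, confusion_rows, compare_rows = [], [], []

    def evaluate(task_name: str, idx_mask, label_key):
        sel = [i for i, keep in enumerate(idx_mask) if keep]
        labels = [vec_meta[i][label_key] for i in sel]
        if len(set(labels)) < 2:
            return
        X, y = classify.feature_matrix([vectors[i] for i in sel], labels)
        evals = classify.run_learning_curve(
            X, y, classifiers=classifiers, fractions=fractions,
            repetitions=repetitions, seed=seed)
        for ev in evals:
            for fi, frac in enumerate(ev.training_fractions):
                for rep in range(repetitions):
                    curve_rows.append({"task": task_name,
                                       "classifier": ev.classifier_name,
                                       "fraction": frac, "repetition": rep,
                                       "accuracy": ev.accuracies[fi, rep]})
            for i, ci in enumerate(ev.classes):
                for j, cj in enumerate(ev.classes):
                    confusion_rows.append({"task": task_name,
                                           "classifier": ev.classifier_name,
                                           "fraction": ev.confusion_fraction,
                                           "true": ci, "predicted": cj,
                                           "rate": ev.confusion[i, j]})
        best_fi = {ev.classifier_name:
                   int(np.argmax(ev.accuracies.mean(axis=1)))
                   for ev in evals}
        for i, ev_a in enumerate(evals):
            for ev_b in evals[i + 1:]:
                cmp_ = classify.compare_classifiers(
                    ev_a.accuracies[best_fi[ev_a.classifier_name]],
                    ev_b.accuracies[best_fi[ev_b.classifier_name]])
                compare_rows.append({"task": task_name,
                                     "classifier_a": ev_a.classifier_name,
                                     "classifier_b": ev_b.classifier_name,
                                     "statistic": cmp_.statistic,
                                     "p_value": cmp_.p_value,
                                     "no_difference": cmp_.no_difference})

    for exp in manifest.experiments:
        mask = [m["experiment"] == exp.name for m in vec_meta]
        evaluate(f"{exp.name}:before_vs_after", mask, "phase")
    evaluate("all:after_by_treatment",
             [m["phase"] == "after" for m in vec_meta], "experiment")

    _write_table(pd.DataFrame(curve_rows), out_dir / "learning_curves.csv",
                 chash, seed)
    _write_table(pd.DataFrame(confusion_rows), out_dir / "confusion.csv",
                 chash, seed)
    _write_table(pd.DataFrame(compare_rows), out_dir / "comparisons.csv",
                 chash, seed)
    report.tables["learning_curves"] = out_dir / "learning_curves.csv"
    report.tables["confusion"] = out_dir / "confusion.csv"
    report.tables["comparisons"] = out_dir / "comparisons.csv"
    report.timings_s["classification"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    stats_df = paired.comparison_table(ledger_df, LEDGER_VARIABLES)
    _write_table(stats_df, out_dir / "before_after.csv", chash, seed)
    report.tables["before_after"] = out_dir / "before_after.csv"
    report.timings_s["paired_stats"] = time.perf_counter() - t0

    for stage, dt in report.timings_s.items():
        log.info("stage %-14s %.2f s", stage, dt)
    return report
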