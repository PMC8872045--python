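"""End-to-end orchestration: simulate -> preprocess -> extract -> select -> benchmark.

Every output CSV carries a leading ``# config_hash=...`` comment naming the
configuration that produced it; reading them back therefore uses
``pd.read_csv(..., comment="#")``. All stage seeds are derived from the
single master seed.
"""

from __future__ import annotations

import logging
import sys
from pathlib import Path

import numpy as np
import pandas as pd

from .config import RunConfig
from .evaluation import ClassifierSpec, default_specs, run_full_benchmark
from .features import extract_table
from .preprocess import EpochSet, ica_clean, preprocess_recording, retention_report
from .selection import SelectionResult, select_features, selection_report
from .synth import Recording, make_cohort

logger = logging.getLogger("eegemo")


def stage_seeds(master_seed: int, n: int = 4) -> list[int]:
    """Derive independent per-stage seeds (< 2**31) from one master seed."""
    ss = np.random.SeedSequence(master_seed)
    return [int(child.generate_state(1)[0] % (2**31)) for child in ss.spawn(n)]


def _write_csv(df: pd.DataFrame, path: Path, config_hash: str) -> None:
    with open(path, "w") as fh:
        fh.write(f"# config_hash={config_hash}\n")
        df.to_csv(fh, index=False)


def read_artifact_csv(path: str | Path) -> pd.DataFrame:
    """Read any pipeline-written CSV (skips the config-hash comment line)."""
    return pd.read_csv(path, comment="#")


def simulate_stage(config: RunConfig, seed: int) -> list[Recording]:
    recordings = make_cohort(
        config.profiles(),
        config.artifact_spec(),
        n_participants=config.n_participants,
        fs=config.fs,
        duration=config.duration,
        seed=seed,
        participant_sigma=config.participant_sigma,
        noise_rms=config.noise_rms,
    )
    logger.info("simulate: %d recordings (%d participants x 4 conditions)",
                len(recordings), config.n_participants)
    return recordings


def preprocess_stage(
    config: RunConfig, recordings: list[Recording], seed: int
) -> list[EpochSet]:
    epoch_sets = []
    criteria = config.rejection_criteria()
    for rec in recordings:
        es = preprocess_recording(
            rec,
            low_hz=config.band_low_hz,
            high_hz=config.band_high_hz,
            epoch_length=config.epoch_length,
            criteria=criteria,
        )
        if config.use_ica:
            es = ica_clean(es, {}, threshold=config.ica_threshold, seed=seed)
        epoch_sets.append(es)
    total = sum(es.n_epochs for es in epoch_sets)
    kept = sum(es.n_retained for es in epoch_sets)
    logger.info("preprocess: %d/%d epochs retained (%.1f%%)",
                kept, total, 100 * kept / total)
    return epoch_sets


def run_all(config: RunConfig, out_dir: str | Path) -> Path:
    """Execute the full pipeline and persist all artifacts under ``out_dir``."""
    config.validate()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    chash = config.hash()

    handler = logging.FileHandler(out / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    if not any(isinstance(h, logging.StreamHandler) for h in logger.handlers[:-1]):
        logger.addHandler(logging.StreamHandler(sys.stderr))

    try:
        config.to_yaml(out / "config.yaml")
        s_sim, s_ica, s_sel, s_eval = stage_seeds(config.seed)

        recordings = simulate_stage(config, s_sim)
        epoch_sets = preprocess_stage(config, recordings, s_ica)

        retention = pd.concat(
            [
                retention_report(es).assign(
                    participant_id=es.participant_id, condition=es.condition
                )
                for es in epoch_sets
            ],
            ignore_index=True,
        )
        _write_csv(retention, out / "epoch_retention.csv", chash)

        table = extract_table(epoch_sets)
        _write_csv(table, out / "features.csv", chash)
        logger.info("extract: %d rows x %d feature columns",
                    len(table), table.shape[1] - 2)

        selection = select_features(table, k=config.top_k, seed=s_sel)
        _write_csv(selection_report(selection), out / "selection.csv", chash)
        logger.info("select: %d common features in both top-%d rankings",
                    len(selection.selected), config.top_k)

        specs = [
            ClassifierSpec(kind, config.classifier_overrides.get(kind, {}))
            for kind in [s.kind for s in default_specs()]
        ]
        report = run_full_benchmark(
            table, selection, seed=s_eval, specs=specs, n_folds=config.n_folds
        )
        _write_csv(report.metrics_frame(), out / "metrics.csv", chash)
        _write_csv(report.importance_frame(), out / "importance.csv", chash)
        (out / "report.json").write_text(
            '{"config_hash": "%s", "cells": %s}' % (chash, report.to_json())
        )
        roc_rows = []
        for (contrast, clf), cell in report.cells.items():
            for fpr, tpr in cell.roc_points:
                roc_rows.append(
                    {"condition": " vs ".join(contrast), "classifier": clf,
                     "fpr": fpr, "tpr": tpr}
                )
        _write_csv(pd.DataFrame(roc_rows), out / "roc_points.csv", chash)
        logger.info("benchmark: %d report cells", len(report.cells))
    except Exception:
        logger.exception("pipeline aborted")
        raise
    finally:
        logger.removeHandler(handler)
        handler.close()
    return out
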