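"""End-to-end pipeline: segment -> features -> cross-validated evaluation."""

from __future__ import annotations

import logging
import time
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from . import features as feat
from . import segmentation as seg
from .classification import CVResult, LabeledCohort, repeated_kfold_cv
from .config import PipelineConfig
from .core import FEATURE_NAMES, OCTVolume, RetoctError

logger = logging.getLogger(__name__)


def extract_feature_table(volumes: Sequence[Tuple[str, OCTVolume, Optional[str]]],
                          config: PipelineConfig = PipelineConfig(),
                          boundaries_dir=None) -> pd.DataFrame:
    """Segment every volume and extract its feature vector.

    A volume whose segmentation or feature extraction fails is skipped with
    a logged warning; the failure count is reported at the end.  When
    ``boundaries_dir`` is given, the intermediate boundary sets are persisted
    there as ``<id>.json``.
    """
    rows: List[Dict] = []
    failures: List[str] = []
    for vid, volume, label in volumes:
        t0 = time.perf_counter()
        try:
            boundaries = seg.segment_volume(volume, config.segmentation)
            fv = feat.extract_features(volume, boundaries, config.features)
        except RetoctError as exc:
            logger.warning("volume %s skipped: %s", vid, exc)
            failures.append(vid)
            continue
        if boundaries_dir is not None:
            from . import volio
            volio.write_boundaries(
                Path(boundaries_dir) / f"{vid}.json", boundaries,
                meta={"volume_hash": volio.volume_hash(volume),
                      "config_hash": config.hash})
        rec = {"id": vid, **fv.to_dict()}
        if label is not None:
            rec["label"] = label
        rows.append(rec)
        logger.info("volume %s done in %.1fs", vid, time.perf_counter() - t0)
    if failures:
        logger.warning("%d/%d volumes skipped: %s", len(failures),
                       len(volumes), failures)
    return pd.DataFrame(rows)


def evaluate_feature_table(table: pd.DataFrame,
                           config: PipelineConfig = PipelineConfig()) -> CVResult:
    """Run the repeated stratified k-fold protocol on a labeled feature table."""
    if "label" not in table.columns:
        raise RetoctError("feature table has no 'label' column")
    labels = table["label"].to_numpy()
    classes, counts = np.unique(labels, return_counts=True)
    if len(classes) < 2:
        raise RetoctError(
            f"cross-validation needs at least 2 classes, got only {classes[0]!r}")
    cv = config.cv
    if counts.min() < cv.k:
        raise RetoctError(
            f"class {classes[np.argmin(counts)]!r} has {counts.min()} subjects; "
            f"k={cv.k} is infeasible (max k = {counts.min()})")
    cohort = LabeledCohort(table[list(FEATURE_NAMES)].to_numpy(dtype=float),
                           labels, ids=table["id"].tolist())
    return repeated_kfold_cv(cohort, k=cv.k, repeats=cv.repeats,
                             algorithm=cv.algorithm, grids=cv.grids,
                             seed=cv.seed, n_classes=cv.n_classes,
                             positive_class=cv.positive_class)


def run_pipeline(volumes: Sequence[Tuple[str, OCTVolume, Optional[str]]],
                 config: PipelineConfig = PipelineConfig(),
                 boundaries_dir=None) -> Tuple[pd.DataFrame, CVResult]:
    """Full run: per-volume features, then cross-validated classification."""
    t0 = time.perf_counter()
    logger.info("pipeline start: %d volumes, config %s", len(volumes), config.hash)
    table = extract_feature_table(volumes, config, boundaries_dir)
    if table.empty:
        raise RetoctError("no volume survived feature extraction")
    result = evaluate_feature_table(table, config)
    logger.info("pipeline done in %.1fs", time.perf_counter() - t0)
    return table, result


def format_cv_table(result: CVResult) -> str:
    """Human-readable mean (SD) metric summary."""
    lines = [f"{'metric':<12} mean (SD)"]
    for key, (mean, sd) in result.aggregate.items():
        if key == "auc":
            lines.append(f"{key:<12} {mean:.3f} ({sd:.3f})")
        else:
            lines.append(f"{key:<12} {mean:.2f} ({sd:.2f})")
    return "\n".join(lines)
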