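"""End-to-end orchestration: read -> QC -> subsample -> features -> stats -> report.

A run loads keypoint files and a metadata CSV (or a freshly simulated
cohort), detects foot strikes, excludes untracked and too-short bouts,
optionally keeps one bout per participant-day, extracts the 2D or 3D
feature set, then performs the univariate screen, collinearity pruning
and multivariate proportional-odds fit, and writes every table the
analysis produces along with a QC accounting log.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from gaitscore.config import METRIC_STEP_DETECTION, RunConfig
from gaitscore.io_types import (
    WalkingBout,
    qc_bout,
    read_keypoints_2d,
    read_keypoints_3d,
    read_metadata,
    subsample_one_per_day,
)
from gaitscore.gait2d import FEATURES_2D, detect_foot_strikes, extract_features_2d
from gaitscore.gait3d import FEATURES_3D, detect_foot_strikes_3d, extract_features_3d
from gaitscore.ordinal_stats import (
    EvaluationResult,
    OrdinalFit,
    SelectionReport,
    evaluate,
    fit_multivariate,
    select_features,
)

log = logging.getLogger(__name__)

__all__ = ["RunReport", "load_bouts", "extract_feature_table", "run_pipeline"]


@dataclass
class RunReport:
    """Everything a pipeline run produced, plus the QC accounting."""

    config: RunConfig
    qc_log: pd.DataFrame  # bout_id, n_steps, included, reason
    features: pd.DataFrame  # one row per included bout, features + ids + outcome columns
    selection: SelectionReport
    fit: OrdinalFit | None
    evaluation: EvaluationResult | None

    @property
    def qc_counts(self) -> dict[str, int]:
        counts = self.qc_log["reason"].value_counts().to_dict()
        return {
            "total": int(len(self.qc_log)),
            "included": int(counts.get("ok", 0)),
            "too_short": int(counts.get("too_short", 0)),
            "untracked": int(counts.get("untracked", 0)),
        }


def load_bouts(input_dir: str | Path, dimensionality: str) -> list[WalkingBout]:
    """Read every keypoint file in a directory (2D: .json/.csv; 3D: .csv)."""
    input_dir = Path(input_dir)
    bouts = []
    if dimensionality == "2d":
        for path in sorted(input_dir.glob("*.json")):
            bouts.append(read_keypoints_2d(path))
        for path in sorted(input_dir.glob("*_2d.csv")):
            bouts.append(read_keypoints_2d(path))
    else:
        for path in sorted(input_dir.glob("*.csv")):
            if path.name.endswith("_2d.csv") or path.name == "metadata.csv":
                continue
            bouts.append(read_keypoints_3d(path))
    return bouts


def extract_feature_table(
    bouts: list[WalkingBout],
    cfg: RunConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, list[WalkingBout]]:
    """QC, daily subsampling and feature extraction.

    Returns (feature table over included bouts, QC log over all bouts,
    included bouts).
    """
    det = cfg.step_detection if cfg.dimensionality == "2d" else (
        cfg.step_detection
        if cfg.step_detection != RunConfig().step_detection
        else METRIC_STEP_DETECTION
    )
    detect = detect_foot_strikes if cfg.dimensionality == "2d" else detect_foot_strikes_3d

    strikes_by_id = {}
    qc_rows = []
    included: list[WalkingBout] = []
    for bout in bouts:
        try:
            strikes = detect(bout, det)
        except (KeyError, ValueError) as exc:
            log.warning("bout %s: strike detection failed (%s)", bout.bout_id, exc)
            from gaitscore.io_types import FootStrikeSeries

            strikes = FootStrikeSeries.empty()
        verdict = qc_bout(bout, strikes, min_steps=cfg.min_steps)
        qc_rows.append(
            {
                "bout_id": bout.bout_id,
                "participant_id": bout.participant_id,
                "n_steps": verdict.n_steps,
                "included": verdict.included,
                "reason": verdict.reason,
            }
        )
        if verdict.included:
            strikes_by_id[bout.bout_id] = strikes
            included.append(bout)
    qc_log = pd.DataFrame(qc_rows)

    if cfg.subsample_daily:
        included = subsample_one_per_day(included, cfg.seed)

    feat_rows = []
    for bout in included:
        strikes = strikes_by_id[bout.bout_id]
        if cfg.dimensionality == "2d":
            feats = extract_features_2d(bout, det, cfg.xcom, strikes=strikes)
        else:
            feats = extract_features_3d(bout, det, strikes=strikes)
        row = {"bout_id": bout.bout_id, "participant_id": bout.participant_id}
        row.update(feats.as_dict())
        feat_rows.append(row)
    columns = ["bout_id", "participant_id"] + list(
        FEATURES_2D if cfg.dimensionality == "2d" else FEATURES_3D
    )
    features = pd.DataFrame(feat_rows, columns=columns)
    return features, qc_log, included


def _write_confusion_plot(confusion: pd.DataFrame, path: Path, title: str) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(4.2, 3.8))
    mat = confusion.to_numpy()
    ax.imshow(mat, cmap="Blues")
    for (i, j), val in np.ndenumerate(mat):
        ax.text(j, i, str(int(val)), ha="center", va="center", fontsize=9)
    ax.set_xlabel("predicted score")
    ax.set_ylabel("annotated score")
    ax.set_xticks(range(5))
    ax.set_yticks(range(5))
    ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def run_pipeline(
    cfg: RunConfig,
    bouts: list[WalkingBout] | None = None,
    metadata: pd.DataFrame | None = None,
    write_outputs: bool = True,
) -> RunReport:
    """Execute the full analysis and (optionally) write all artifacts.

    ``bouts``/``metadata`` can be passed directly (e.g. fresh from the
    simulator); otherwise they are read from ``cfg.input_dir`` and
    ``cfg.metadata_path``.  Aborts with a QC summary if no bout survives
    quality control.
    """
    if bouts is None:
        if cfg.input_dir is None:
            raise ValueError("either pass bouts or set cfg.input_dir")
        bouts = load_bouts(cfg.input_dir, cfg.dimensionality)
    if metadata is None:
        if cfg.metadata_path is None:
            raise ValueError("either pass metadata or set cfg.metadata_path")
        metadata = read_metadata(cfg.metadata_path)

    features, qc_log, _ = extract_feature_table(bouts, cfg)
    if features.empty:
        raise RuntimeError(
            "no bout passed quality control: "
            + json.dumps(qc_log["reason"].value_counts().to_dict())
        )
    feature_names = list(FEATURES_2D if cfg.dimensionality == "2d" else FEATURES_3D)
    table = features.merge(
        metadata[["bout_id", "age", "sex", "updrs_gait", "sas_gait"]], on="bout_id", how="inner"
    )
    table = table.dropna(subset=[cfg.outcome])

    selection = select_features(
        table, feature_names, cfg.outcome, alpha=cfg.alpha, r_threshold=cfg.r_threshold
    )
    # the multivariate model always carries age and sex, so it is defined even
    # when the screen selects no gait feature
    fit = fit_multivariate(table, selection.final_features, cfg.outcome)
    evaluation = evaluate(table, fit, cfg.outcome) if fit.converged else None

    report = RunReport(
        config=cfg,
        qc_log=qc_log,
        features=table,
        selection=selection,
        fit=fit,
        evaluation=evaluation,
    )
    if write_outputs:
        _write_artifacts(report)
    return report


def _write_artifacts(report: RunReport) -> None:
    cfg = report.config
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    stamp = {"config_hash": cfg.config_hash(), "seed": cfg.seed}

    report.features.to_csv(out / "features.csv", index=False)
    report.qc_log.to_csv(out / "qc_log.csv", index=False)
    report.selection.univariate.to_csv(out / "univariate.csv")
    with open(out / "selection.json", "w") as fh:
        json.dump(
            {
                **stamp,
                "selected_by_p": report.selection.selected_by_p,
                "dropped_by_correlation": [
                    {"kept": k, "dropped": d, "r": r}
                    for k, d, r in report.selection.dropped_by_correlation
                ],
                "final_features": report.selection.final_features,
                "failed": report.selection.failed,
                "qc_counts": report.qc_counts,
            },
            fh,
            indent=2,
        )
    if report.fit is not None:
        report.fit.summary_frame().to_csv(out / "multivariate.csv")
    if report.evaluation is not None:
        ev = report.evaluation
        ev.confusion.to_csv(out / "confusion_matrix.csv")
        ev.per_participant.to_csv(out / "per_participant_accuracy.csv")
        with open(out / "accuracy.json", "w") as fh:
            json.dump(
                {
                    **stamp,
                    "accuracy_percent": ev.accuracy,
                    "adjacent_agreement_percent": ev.adjacent_agreement,
                },
                fh,
                indent=2,
            )
        try:
            _write_confusion_plot(
                ev.confusion,
                out / "confusion_matrix.png",
                f"{cfg.outcome} ({cfg.dimensionality})",
            )
        except Exception as exc:  # plotting must never sink a run
            log.warning("confusion-matrix plot failed: %s", exc)
    with open(out / "run_config.json", "w") as fh:
        json.dump({**stamp, "config": dataclasses.asdict(cfg)}, fh, indent=2, default=str)
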