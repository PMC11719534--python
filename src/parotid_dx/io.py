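"""Readers, writers and the end-to-end pipeline.

The on-disk formats are plain text: lesion feature tables as CSV with a
fixed header, DCE series as two-column ``time_s,signal`` CSVs, and run
summaries as JSON.  Every file written carries a provenance header (tool
version, seed, config hash) in ``#``-prefixed comment lines so results are
traceable to the exact configuration that produced them.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .classifier import DxThresholds, classify_values
from .cohort_sim import (
    FEATURE_COLUMNS,
    CohortConfig,
    DceTiming,
    generate_cohort,
    generate_dce_series,
)
from .dce_analysis import CurveClassifierConfig, SignalTimeCurve, type_curve
from .evaluate import (
    confusion_from_predictions,
    metrics_from_confusion,
    per_class_metrics,
)

__all__ = [
    "RunConfig",
    "read_feature_table",
    "write_feature_table",
    "read_curve_csv",
    "write_curve_csv",
    "classify_table",
    "run_pipeline",
]

_BOOL_COLUMNS = FEATURE_COLUMNS[2:10]
_FLOAT_COLUMNS = ("norm_t2_si", "norm_t1_si", "adc", "peak_time_s", "washout_pct")


@dataclass(frozen=True)
class RunConfig:
    """Configuration of an end-to-end pipeline run."""

    outdir: Path
    seed: int = 0
    n_per_group: dict[str, int] = field(
        default_factory=lambda: {"PA": 14, "WT": 10, "OBT": 4, "MT": 8})
    thresholds: DxThresholds = field(default_factory=DxThresholds)
    curve_config: CurveClassifierConfig = field(default_factory=CurveClassifierConfig)
    dce_noise_sd: float = 2.0
    dce_baseline_si: float = 100.0
    dce_amplitude: float = 200.0


def _config_hash(obj) -> str:
    payload = json.dumps(obj, sort_keys=True, default=str).encode()
    return hashlib.sha256(payload).hexdigest()[:12]


def _provenance_lines(seed: int, config_hash: str) -> list[str]:
    return [
        f"# parotid-dx v{__version__}",
        f"# seed={seed}",
        f"# config_sha={config_hash}",
    ]


def write_feature_table(df: pd.DataFrame, path, *, seed: int = 0,
                        config_hash: str = "na") -> None:
    """Write a lesion feature table CSV with a provenance header.

    Booleans are written as 0/1, missing values as empty fields, floats
    with full repr precision.
    """
    path = Path(path)
    out = df.copy()
    for col in _BOOL_COLUMNS:
        out[col] = out[col].astype("boolean").astype("Int64")
    with open(path, "w", newline="\n") as fh:
        for line in _provenance_lines(seed, config_hash):
            fh.write(line + "\n")
        out.to_csv(fh, index=False, lineterminator="\n")


def read_feature_table(path) -> pd.DataFrame:
    """Read a lesion feature table CSV, validating the schema.

    ``#`` comment lines are skipped; booleans are parsed from 0/1; empty
    fields become NaN.  A malformed row raises with its line number.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        df = pd.read_csv(path, comment="#", dtype={"lesion_id": str, "group": str,
                                                   "curve_type": str})
    except pd.errors.ParserError as exc:
        raise ValueError(f"malformed CSV {path}: {exc}") from exc
    missing = set(FEATURE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(
            f"{path}: header missing required columns {sorted(missing)}")
    df = df[list(FEATURE_COLUMNS)]
    for col in _BOOL_COLUMNS:
        bad = df[col].dropna()[~df[col].dropna().isin([0, 1, True, False])]
        if len(bad):
            line = int(bad.index[0]) + 2  # +1 header, +1 one-based
            raise ValueError(
                f"{path}: non-boolean value {bad.iloc[0]!r} in column "
                f"{col!r} near line {line}")
        df[col] = df[col].astype("boolean")
    for col in _FLOAT_COLUMNS:
        try:
            df[col] = pd.to_numeric(df[col])
        except (ValueError, TypeError) as exc:
            raise ValueError(f"{path}: column {col!r} not numeric: {exc}") from exc
    return df


def write_curve_csv(curve: SignalTimeCurve, path, *, seed: int = 0,
                    config_hash: str = "na") -> None:
    """Write one DCE series as a ``time_s,signal`` CSV."""
    path = Path(path)
    with open(path, "w", newline="\n") as fh:
        for line in _provenance_lines(seed, config_hash):
            fh.write(line + "\n")
        fh.write(f"# n_baseline={curve.n_baseline}\n")
        fh.write("time_s,signal\n")
        for t, s in zip(curve.times, curve.signals):
            fh.write(f"{t:.6g},{s:.8g}\n")


def read_curve_csv(path, n_baseline: int | None = None) -> SignalTimeCurve:
    """Read a ``time_s,signal`` CSV; n_baseline from header unless given."""
    path = Path(path)
    if n_baseline is None:
        with open(path) as fh:
            for line in fh:
                if line.startswith("# n_baseline="):
                    n_baseline = int(line.split("=", 1)[1])
                    break
                if not line.startswith("#"):
                    break
    if n_baseline is None:
        raise ValueError(f"{path}: n_baseline not in header and not given")
    df = pd.read_csv(path, comment="#")
    if list(df.columns) != ["time_s", "signal"]:
        raise ValueError(f"{path}: expected columns time_s,signal")
    return SignalTimeCurve(df["time_s"].to_numpy(), df["signal"].to_numpy(),
                           n_baseline)


def classify_table(df: pd.DataFrame,
                   thresholds: DxThresholds = DxThresholds()) -> pd.DataFrame:
    """Apply the diagnostic decision tree to every row of a feature table.

    Returns ``lesion_id, dx_class, malignant, rule_path`` with the rule
    path serialized as ``" | "``-joined steps.
    """
    rows = []
    for _, rec in df.iterrows():
        pred = classify_values(bool(rec["ghosting"]),
                               float(rec["norm_t1_si"]),
                               float(rec["norm_t2_si"]), thresholds)
        rows.append({
            "lesion_id": rec["lesion_id"],
            "dx_class": pred.dx_class,
            "malignant": pred.malignant,
            "rule_path": " | ".join(pred.rule_path),
        })
    return pd.DataFrame(rows, columns=["lesion_id", "dx_class", "malignant",
                                       "rule_path"])


def _metrics_dict(m) -> dict:
    return {
        name: {
            "numerator": getattr(m, name).numerator,
            "denominator": getattr(m, name).denominator,
            "percent": getattr(m, name).percent,
        }
        for name in ("sens", "spec", "ppv", "npv", "acc")
    }


def run_pipeline(config: RunConfig) -> dict:
    """Simulate, type curves, classify, evaluate; write per-stage outputs.

    Stages: (1) draw a cohort at the configured per-group counts; (2) for
    every lesion with DCE parameters, synthesize its S(t) series, re-extract
    features and assign a measured curve type; (3) run the decision tree;
    (4) score malignant-vs-benign and per-class performance against the
    ground-truth groups.  Writes ``cohort.csv``, ``curve_types.csv``,
    ``predictions.csv`` and ``summary.json`` under ``config.outdir`` and
    returns the summary dict.  Fully deterministic under a fixed seed.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cfg_hash = _config_hash({
        "seed": config.seed,
        "n_per_group": config.n_per_group,
        "thresholds": dataclasses.asdict(config.thresholds),
        "curve_config": dataclasses.asdict(config.curve_config),
        "dce_noise_sd": config.dce_noise_sd,
        "dce_baseline_si": config.dce_baseline_si,
        "dce_amplitude": config.dce_amplitude,
    })

    # stage 1: cohort simulation
    try:
        cohort_cfg = CohortConfig(n_per_group=config.n_per_group,
                                  seed=config.seed)
        cohort = generate_cohort(cohort_cfg)
    except Exception as exc:
        raise RuntimeError(f"stage 'simulate' failed: {exc}") from exc
    write_feature_table(cohort, outdir / "cohort.csv", seed=config.seed,
                        config_hash=cfg_hash)

    # stage 2: DCE synthesis + curve typing
    timing = cohort_cfg.dce_timing
    curve_rng = np.random.Generator(np.random.PCG64(
        np.random.SeedSequence(config.seed).spawn(10)[-1]))
    curve_rows = []
    try:
        for _, rec in cohort.iterrows():
            curve = generate_dce_series(
                rec["curve_type"], rec["peak_time_s"], rec["washout_pct"],
                config.dce_baseline_si, config.dce_amplitude, timing,
                config.dce_noise_sd, curve_rng)
            label, feats = type_curve(curve, config.curve_config)
            curve_rows.append({
                "lesion_id": rec["lesion_id"],
                "peak_time_s": round(feats.peak_time_s, 6),
                "washout_pct": (round(feats.washout_pct, 6)
                                if feats.washout_defined else ""),
                "curve_type": label,
            })
    except Exception as exc:
        raise RuntimeError(f"stage 'dce-type' failed: {exc}") from exc
    curve_df = pd.DataFrame(curve_rows, columns=["lesion_id", "peak_time_s",
                                                 "washout_pct", "curve_type"])
    with open(outdir / "curve_types.csv", "w", newline="\n") as fh:
        for line in _provenance_lines(config.seed, cfg_hash):
            fh.write(line + "\n")
        curve_df.to_csv(fh, index=False, lineterminator="\n")

    # stage 3: decision tree
    try:
        preds = classify_table(cohort, config.thresholds)
    except Exception as exc:
        raise RuntimeError(f"stage 'classify' failed: {exc}") from exc
    with open(outdir / "predictions.csv", "w", newline="\n") as fh:
        for line in _provenance_lines(config.seed, cfg_hash):
            fh.write(line + "\n")
        preds.to_csv(fh, index=False, lineterminator="\n")

    # stage 4: evaluation against ground truth
    try:
        truth_bin = np.where(cohort["group"] == "MT", "malignant", "benign")
        pred_bin = np.where(preds["malignant"], "malignant", "benign")
        conf = confusion_from_predictions(truth_bin, pred_bin)
        summary = {
            "provenance": {
                "tool": "parotid-dx",
                "version": __version__,
                "seed": config.seed,
                "config_sha": cfg_hash,
            },
            "n_lesions": int(len(cohort)),
            "confusion": dataclasses.asdict(conf),
            "malignant_vs_benign": _metrics_dict(metrics_from_confusion(conf)),
            "per_class": {
                cls: _metrics_dict(per_class_metrics(
                    cohort["group"].to_numpy(), preds["dx_class"].to_numpy(), cls))
                for cls in ("PA", "WT", "OBT", "MT")
            },
            "curve_type_agreement": float(
                (curve_df["curve_type"].to_numpy()
                 == cohort["curve_type"].to_numpy()).mean())
            if len(cohort) else math.nan,
        }
    except Exception as exc:
        raise RuntimeError(f"stage 'evaluate' failed: {exc}") from exc
    with open(outdir / "summary.json", "w", newline="\n") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return summary
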