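"""End-to-end orchestration: simulate -> quantify -> classify -> evaluate.

Each stage is a plain function over in-memory objects plus a writer of its
CSV/JSON artifact, so the CLI subcommands compose to exactly the same outputs
as :func:`run_pipeline`.  All report numbers are stored as exact fractions
alongside printed-style rounded strings (percentages to one decimal,
p-values to two decimals), making downstream rounding unambiguous.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path
from typing import Mapping, Optional, Union

import numpy as np
import pandas as pd

from . import __version__
from .cohort import CohortConfig, sample_cohort
from .io import (
    PipelineConfig,
    cohort_config_to_dict,
    pipeline_config_to_dict,
    read_cohort,
    rule_table_from_json,
    write_cohort,
)
from .lesions import LesionRecord, type_match
from .stats import (
    auroc,
    compare_groups,
    confusion_metrics,
    counts_from_predictions,
    detection_rate,
    linear_regression,
    roc_curve,
    youden_cutoff,
)
from .tree import BDTCResult, classify_cohort, default_rule_table
from .washout import TICSeries, fit_washout

logger = logging.getLogger("mpus")

FIT_COLUMNS = [
    "lesion_id",
    "roi",
    "A",
    "B",
    "k",
    "gradient0",
    "t_to_peak",
    "area",
    "mse",
    "converged",
]


def quantify_series(
    series: list[TICSeries], area_source: str = "fit"
) -> pd.DataFrame:
    """Fit the washout model to every series; one row per (lesion, ROI)."""
    rows = []
    for s in series:
        f = fit_washout(s, area_source=area_source)
        rows.append(
            {
                "lesion_id": s.lesion_id,
                "roi": s.roi,
                "A": f.A,
                "B": f.B,
                "k": f.k,
                "gradient0": f.gradient0,
                "t_to_peak": f.t_to_peak,
                "area": f.area,
                "mse": f.mse,
                "converged": f.converged,
            }
        )
    return pd.DataFrame(rows, columns=FIT_COLUMNS)


def results_frame(results: list[BDTCResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "lesion_id": [r.lesion_id for r in results],
            "washout": [int(r.washout) for r in results],
            "predicted_malignant": [int(r.predicted_malignant) for r in results],
            "predicted_type": [r.predicted_type for r in results],
            "path": [">".join(r.path) for r in results],
        }
    )


def _pct(x: Optional[float]) -> Optional[dict]:
    if x is None:
        return None
    return {"fraction": x, "printed": f"{100.0 * x:.1f}%"}


def _pval(p: float) -> dict:
    return {"p": p, "printed": f"{p:.2f}"}


def evaluate_cohort(
    records: list[LesionRecord],
    results: list[BDTCResult],
    areas: Mapping[str, float],
    parenchyma_areas: Optional[Mapping[str, float]] = None,
) -> dict:
    """Score predictions against reference diagnoses and build the report dict.

    ``areas`` maps lesion_id -> lesion AREA (dB); ``parenchyma_areas`` enables
    the lesion~parenchyma regression section.
    """
    by_id = {r.lesion_id: r for r in results}
    recs = [r for r in records if r.truth_malignant is not None]
    if len(recs) == 0:
        raise ValueError("no lesions with reference diagnoses to evaluate")
    truth = [bool(r.truth_malignant) for r in recs]
    pred = [by_id[r.lesion_id].predicted_malignant for r in recs]
    counts = counts_from_predictions(pred, truth)
    metrics = confusion_metrics(counts)

    n_mal_correct = sum(int(p == t) for p, t in zip(pred, truth))
    n_type_correct = sum(
        int(
            p == t
            and r.truth_type is not None
            and type_match(by_id[r.lesion_id].predicted_type, r.truth_type)
        )
        for p, t, r in zip(pred, truth, recs)
    )
    det = detection_rate(n_type_correct, n_mal_correct) if n_mal_correct else None

    score = np.array([areas[r.lesion_id] for r in recs], dtype=float)
    lab = np.array(truth, dtype=bool)
    report: dict = {
        "n": len(recs),
        "confusion": {"tp": counts.tp, "fp": counts.fp, "tn": counts.tn, "fn": counts.fn},
        "metrics": {
            "sensitivity": _pct(metrics.sensitivity),
            "specificity": _pct(metrics.specificity),
            "ppv": _pct(metrics.ppv),
            "npv": _pct(metrics.npv),
            "accuracy": _pct(metrics.accuracy),
            "f1": _pct(metrics.f1),
        },
        "detection": None
        if det is None
        else {
            "n_type_correct": det.n_type_correct,
            "n_malignancy_correct": det.n_malignancy_correct,
            "rate": _pct(det.fraction),
            "percent": det.percent,
        },
    }
    if lab.any() and (~lab).any():
        roc = roc_curve(score, lab)
        report["roc"] = {
            "auroc": roc.auroc,
            "youden_cutoff_db": youden_cutoff(roc),
        }
        report["area_group_comparison"] = _pval(
            compare_groups(score[lab], score[~lab]).pvalue
        )
    if parenchyma_areas is not None:
        x = np.array([parenchyma_areas[r.lesion_id] for r in recs], dtype=float)
        if np.ptp(x) > 0:
            reg = linear_regression(x, score)
            report["regression_lesion_on_parenchyma"] = {
                "intercept_db": reg.intercept,
                "slope": reg.slope,
                "p_slope": _pval(reg.p_slope),
            }
    return report


def _dump_json(obj: dict, path: Path) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n", encoding="utf-8")


def _sha256_of(obj) -> str:
    return hashlib.sha256(json.dumps(obj, sort_keys=True, default=str).encode()).hexdigest()


def run_pipeline(
    config: Union[PipelineConfig, str, Path],
    out_dir: Union[str, Path],
    seed: Optional[int] = None,
) -> dict:
    """Simulate a cohort, quantify every TIC, classify, and evaluate.

    Writes cohort.csv, tic.csv, tic_params.csv, results.csv, roc.csv,
    report.json and run_log.json into ``out_dir`` and returns the report
    dict.  ``seed`` overrides the config's cohort seed.  Deterministic:
    identical config and seed give byte-identical outputs.
    """
    if not isinstance(config, PipelineConfig):
        from .io import load_config

        config = load_config(config)
    config.validate()
    if seed is not None:
        import dataclasses

        config = dataclasses.replace(config, cohort=dataclasses.replace(config.cohort, seed=seed))
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    logger.info("simulate: n=%d seed=%d", config.cohort.n, config.cohort.seed)
    records = sample_cohort(config.cohort, include_tics=True)
    write_cohort(records, out / "cohort.csv", tic_path=out / "tic.csv")

    logger.info("quantify: fitting %d TIC series", 2 * len(records))
    # fit from the serialized series so staged CLI runs reproduce this exactly
    from .io import read_tic_series

    series = list(read_tic_series(out / "tic.csv").values())
    params = quantify_series(series, area_source=config.area_source)
    params.to_csv(out / "tic_params.csv", index=False, float_format="%.12g")
    params = pd.read_csv(out / "tic_params.csv", dtype={"lesion_id": str})

    rule_table = (
        rule_table_from_json(config.rules_path) if config.rules_path else default_rule_table()
    )
    areas = {
        row.lesion_id: row.area for row in params.itertuples(index=False) if row.roi == "lesion"
    }
    par_areas = {
        row.lesion_id: row.area for row in params.itertuples(index=False) if row.roi == "parenchyma"
    }
    logger.info("classify: cutoff=%.3f dB", config.cutoff)
    results = classify_cohort(records, cutoff=config.cutoff, rule_table=rule_table, areas=areas)
    results_frame(results).to_csv(out / "results.csv", index=False)

    logger.info("evaluate: scoring %d lesions", len(records))
    report = evaluate_cohort(records, results, areas, parenchyma_areas=par_areas)
    report["cutoff_db"] = config.cutoff
    report["area_source"] = config.area_source
    _dump_json(report, out / "report.json")

    score = np.array([areas[r.lesion_id] for r in records])
    lab = np.array([bool(r.truth_malignant) for r in records])
    if lab.any() and (~lab).any():
        roc = roc_curve(score, lab)
        pd.DataFrame(
            {"threshold_db": roc.thresholds, "se": roc.se, "sp": roc.sp}
        ).to_csv(out / "roc.csv", index=False, float_format="%.12g")

    rule_hash = _sha256_of({"|".join(map(str, k)): v for k, v in rule_table.items()})
    log = {
        "seed": config.cohort.seed,
        "config_sha256": _sha256_of(pipeline_config_to_dict(config)),
        "rule_table_sha256": rule_hash,
        "cutoff_db": config.cutoff,
        "area_source": config.area_source,
        "mpus_version": __version__,
        "numpy_version": np.__version__,
        "pandas_version": pd.__version__,
    }
    _dump_json(log, out / "run_log.json")
    return report
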