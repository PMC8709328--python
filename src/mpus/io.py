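"""File formats: cohort tables, long-format TIC series, rule tables, configs.

Everything is plain text.  Cohort tables and TIC series are CSV (UTF-8, "."
decimal separator, floats printed to 12 significant digits so write/read
round-trips are exact at that precision); rule tables and run configurations
are JSON.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, fields
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd

from .cohort import CohortConfig
from .lesions import EnhancementPattern, LesionRecord, LesionType
from .tree import RuleTable
from .washout import DEFAULT_WASHOUT_CUTOFF_DB, TICSeries

FLOAT_FMT = "%.12g"

COHORT_COLUMNS = ["lesion_id", "true_type", "true_malignant", "cirrhotic", "pattern"]
COHORT_OPTIONAL = ["area_lesion_true", "area_parenchyma_true"]
TIC_COLUMNS = ["lesion_id", "roi", "t_seconds", "intensity_db"]


class SchemaError(ValueError):
    """A CSV/JSON input does not match the expected schema."""


def _g(x: Optional[float]) -> str:
    return "" if x is None else FLOAT_FMT % x


def write_cohort(
    records: list[LesionRecord],
    path: Union[str, Path],
    tic_path: Union[str, Path, None] = None,
) -> None:
    """Write the cohort table; optionally also the TIC series in long format."""
    rows = []
    for r in records:
        rows.append(
            {
                "lesion_id": r.lesion_id,
                "true_type": "" if r.truth_type is None else r.truth_type.value,
                "true_malignant": "" if r.truth_malignant is None else int(r.truth_malignant),
                "cirrhotic": int(r.cirrhotic),
                "pattern": "" if r.pattern is None else r.pattern.value,
                "area_lesion_true": _g(r.area_lesion_true),
                "area_parenchyma_true": _g(r.area_parenchyma_true),
            }
        )
    pd.DataFrame(rows, columns=COHORT_COLUMNS + COHORT_OPTIONAL).to_csv(path, index=False)
    if tic_path is not None:
        series = []
        for r in records:
            for s in (r.lesion_series, r.parenchyma_series):
                if s is not None:
                    series.append(s)
        write_tic_series(series, tic_path)


def read_cohort(
    path: Union[str, Path], tic_path: Union[str, Path, None] = None
) -> list[LesionRecord]:
    """Read a cohort table, attaching TIC series from ``tic_path`` if given."""
    df = pd.read_csv(path, dtype={"lesion_id": str, "pattern": str, "true_type": str})
    for col in COHORT_COLUMNS:
        if col not in df.columns:
            raise SchemaError(f"cohort file is missing required column '{col}'")
    if df["lesion_id"].duplicated().any():
        dup = df.loc[df["lesion_id"].duplicated(), "lesion_id"].iloc[0]
        raise SchemaError(f"duplicate lesion_id '{dup}'")
    valid_patterns = {p.value for p in EnhancementPattern}
    series_map = read_tic_series(tic_path) if tic_path is not None else {}
    records = []
    for row in df.itertuples(index=False):
        pattern_raw = getattr(row, "pattern")
        pattern = None
        if isinstance(pattern_raw, str) and pattern_raw != "":
            if pattern_raw not in valid_patterns:
                raise SchemaError(f"unknown pattern label '{pattern_raw}'")
            pattern = EnhancementPattern(pattern_raw)
        ttype_raw = getattr(row, "true_type")
        ttype = (
            LesionType(ttype_raw) if isinstance(ttype_raw, str) and ttype_raw != "" else None
        )
        tmal = getattr(row, "true_malignant")
        tmal = None if pd.isna(tmal) else bool(int(tmal))

        def _f(name: str) -> Optional[float]:
            v = getattr(row, name, None)
            return None if v is None or pd.isna(v) else float(v)

        lid = str(getattr(row, "lesion_id"))
        records.append(
            LesionRecord(
                lesion_id=lid,
                cirrhotic=bool(int(getattr(row, "cirrhotic"))),
                pattern=pattern,
                lesion_series=series_map.get((lid, "lesion")),
                parenchyma_series=series_map.get((lid, "parenchyma")),
                truth_type=ttype,
                truth_malignant=tmal,
                area_lesion_true=_f("area_lesion_true"),
                area_parenchyma_true=_f("area_parenchyma_true"),
            )
        )
    return records


def write_tic_series(series: list[TICSeries], path: Union[str, Path]) -> None:
    frames = []
    for s in series:
        frames.append(
            pd.DataFrame(
                {
                    "lesion_id": s.lesion_id,
                    "roi": s.roi,
                    "t_seconds": s.times,
                    "intensity_db": s.intensities,
                }
            )
        )
    df = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(columns=TIC_COLUMNS)
    df.to_csv(path, index=False, float_format=FLOAT_FMT)


def read_tic_series(path: Union[str, Path]) -> dict[tuple[str, str], TICSeries]:
    """Long-format TIC CSV -> {(lesion_id, roi): TICSeries}, samples ordered by time."""
    df = pd.read_csv(path, dtype={"lesion_id": str, "roi": str})
    for col in TIC_COLUMNS:
        if col not in df.columns:
            raise SchemaError(f"TIC file is missing required column '{col}'")
    out: dict[tuple[str, str], TICSeries] = {}
    for (lid, roi), grp in df.groupby(["lesion_id", "roi"], sort=True):
        grp = grp.sort_values("t_seconds")
        if grp["t_seconds"].duplicated().any():
            raise SchemaError(f"duplicate time point for lesion '{lid}' roi '{roi}'")
        out[(str(lid), str(roi))] = TICSeries(
            lesion_id=str(lid),
            roi=str(roi),
            times=grp["t_seconds"].to_numpy(dtype=float),
            intensities=grp["intensity_db"].to_numpy(dtype=float),
        )
    return out


# ---------------------------------------------------------------------------
# rule tables
# ---------------------------------------------------------------------------


def _rule_key_str(key: tuple[bool, bool, EnhancementPattern]) -> str:
    cirrhotic, washout, pattern = key
    return "|".join(
        [
            "cirrhotic" if cirrhotic else "non_cirrhotic",
            "washout" if washout else "no_washout",
            pattern.value,
        ]
    )


def rule_table_to_json(table: RuleTable, path: Union[str, Path]) -> None:
    data = {_rule_key_str(k): v for k, v in sorted(table.items(), key=lambda kv: _rule_key_str(kv[0]))}
    Path(path).write_text(json.dumps(data, indent=2, sort_keys=True) + "\n", encoding="utf-8")


def rule_table_from_json(path: Union[str, Path]) -> dict[tuple[bool, bool, EnhancementPattern], str]:
    data = json.loads(Path(path).read_text(encoding="utf-8"))
    table: dict[tuple[bool, bool, EnhancementPattern], str] = {}
    for key, value in data.items():
        parts = key.split("|")
        if len(parts) != 3 or parts[0] not in ("cirrhotic", "non_cirrhotic") or parts[1] not in (
            "washout",
            "no_washout",
        ):
            raise SchemaError(f"malformed rule-table key '{key}'")
        try:
            pattern = EnhancementPattern(parts[2])
        except ValueError as exc:
            raise SchemaError(f"unknown pattern in rule-table key '{key}'") from exc
        table[(parts[0] == "cirrhotic", parts[1] == "washout", pattern)] = str(value)
    return table


def example_rule_table_path(name: str = "rules_hyper_washout_adenoma.json") -> Path:
    """Path of a bundled example rule-table JSON (alternative tree readings)."""
    return Path(__file__).parent / "data" / name


# ---------------------------------------------------------------------------
# run configuration
# ---------------------------------------------------------------------------


@dataclass
class PipelineConfig:
    """Everything one end-to-end run needs."""

    cohort: CohortConfig = field(default_factory=CohortConfig)
    cutoff: float = DEFAULT_WASHOUT_CUTOFF_DB
    area_source: str = "fit"  # "fit" | "samples"
    rules_path: Optional[str] = None  # None -> built-in default table

    def validate(self) -> None:
        self.cohort.validate()
        if self.area_source not in ("fit", "samples"):
            raise SchemaError(f"area_source must be 'fit' or 'samples', got {self.area_source!r}")


def cohort_config_to_dict(cfg: CohortConfig) -> dict:
    d = {}
    for f in fields(cfg):
        v = getattr(cfg, f.name)
        if f.name in ("composition", "malignant_overrides"):
            v = {k.value: val for k, val in v.items()}
        d[f.name] = v
    return d


def cohort_config_from_dict(d: dict) -> CohortConfig:
    known = {f.name for f in fields(CohortConfig)}
    unknown = set(d) - known
    if unknown:
        raise SchemaError(f"unknown cohort config keys: {sorted(unknown)}")
    kw = dict(d)
    if "composition" in kw:
        kw["composition"] = {LesionType(k): v for k, v in kw["composition"].items()}
    if "malignant_overrides" in kw:
        kw["malignant_overrides"] = {
            LesionType(k): bool(v) for k, v in kw["malignant_overrides"].items()
        }
    return CohortConfig(**kw)


def pipeline_config_to_dict(cfg: PipelineConfig) -> dict:
    return {
        "cohort": cohort_config_to_dict(cfg.cohort),
        "cutoff": cfg.cutoff,
        "area_source": cfg.area_source,
        "rules_path": cfg.rules_path,
    }


def load_config(path: Union[str, Path]) -> PipelineConfig:
    raw = json.loads(Path(path).read_text(encoding="utf-8"))
    if not isinstance(raw, dict):
        raise SchemaError("config must be a JSON object")
    cfg = PipelineConfig(
        cohort=cohort_config_from_dict(raw.get("cohort", {})),
        cutoff=float(raw.get("cutoff", DEFAULT_WASHOUT_CUTOFF_DB)),
        area_source=str(raw.get("area_source", "fit")),
        rules_path=raw.get("rules_path"),
    )
    cfg.validate()
    return cfg


def save_config(cfg: PipelineConfig, path: Union[str, Path]) -> None:
    Path(path).write_text(
        json.dumps(pipeline_config_to_dict(cfg), indent=2, sort_keys=True) + "\n",
        encoding="utf-8",
    )
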