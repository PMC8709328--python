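"""Three-step binary decision tree for inconclusive focal liver lesions.

The multiparametric-ultrasound (MPUS) rule set proceeds through three
decisions in a fixed order:

1. **Fibrosis** -- is the liver background cirrhotic (elastography stage F4)?
2. **TIC** -- does the lesion show washout, i.e. is its late-phase AREA at or
   below the operating cutoff (-19.3 dB by default)?
3. **Pattern** -- which arterial-phase enhancement pattern does parametric
   imaging show?

The malignancy call is driven by the TIC step (washout => malignant); the
fibrosis and pattern steps refine the lesion-type call through a lookup table
keyed by (cirrhotic, washout, pattern).  The table is data, not code, so
alternative readings of the tree are injectable; a high-sensitivity
screening rule (cirrhotic OR washout) is provided separately.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional

from .lesions import (
    INDETERMINATE,
    MALIGNANT_PREDICTIONS,
    PREDICTED_FFC,
    PREDICTED_FNH,
    EnhancementPattern,
    LesionRecord,
    LesionType,
    type_match,
)
from .washout import DEFAULT_WASHOUT_CUTOFF_DB, fit_washout, washout_flag

RuleTable = Mapping[tuple[bool, bool, EnhancementPattern], str]


@dataclass(frozen=True)
class BDTCResult:
    """Outcome of the decision tree for one lesion."""

    lesion_id: str
    washout: bool
    predicted_malignant: bool
    predicted_type: str
    path: tuple[str, ...]


def default_rule_table() -> dict[tuple[bool, bool, EnhancementPattern], str]:
    """The reconstructed (cirrhotic, washout, pattern) -> lesion-type table.

    Washout-side branches yield malignant types, no-washout branches benign
    ones; hyper-enhancement with washout routes to HCC regardless of
    cirrhosis, and iso-enhancement without washout splits on the fibrosis
    step (regenerative nodule in cirrhosis, focal fatty change otherwise).
    Keys absent from the table are classified "indeterminate".
    """
    table: dict[tuple[bool, bool, EnhancementPattern], str] = {}
    for cirrhotic in (False, True):
        table[(cirrhotic, True, EnhancementPattern.HYPER)] = LesionType.HCC.value
        table[(cirrhotic, True, EnhancementPattern.RIM)] = LesionType.METASTASIS.value
        table[(cirrhotic, True, EnhancementPattern.RIM_CENTRAL_HYPO)] = (
            LesionType.CHOLANGIOCARCINOMA.value
        )
        table[(cirrhotic, False, EnhancementPattern.PERIPHERAL_NODULAR)] = (
            LesionType.HAEMANGIOMA.value
        )
        table[(cirrhotic, False, EnhancementPattern.CENTRIFUGAL)] = PREDICTED_FNH
        table[(cirrhotic, False, EnhancementPattern.PERIPHERAL_SEPTA)] = LesionType.ABSCESS.value
    table[(True, False, EnhancementPattern.ISO)] = LesionType.REGENERATIVE_NODULE.value
    table[(False, False, EnhancementPattern.ISO)] = PREDICTED_FFC
    return table


def _lesion_area(record: LesionRecord, area: Optional[float]) -> float:
    if area is not None:
        return area
    if record.lesion_series is None:
        raise ValueError(f"lesion {record.lesion_id}: no AREA given and no lesion TIC to fit")
    return fit_washout(record.lesion_series).area


def mpus_malignancy(
    record: LesionRecord,
    cutoff: float = DEFAULT_WASHOUT_CUTOFF_DB,
    area: Optional[float] = None,
) -> bool:
    """High-sensitivity screening rule: cirrhotic OR washout => malignant.

    Combining the elastography dichotomy with the TIC cutoff by OR trades
    specificity for sensitivity; it is the screening companion of the full
    tree, not the tree itself.
    """
    return record.cirrhotic or washout_flag(_lesion_area(record, area), cutoff)


def bdtc_classify(
    record: LesionRecord,
    cutoff: float = DEFAULT_WASHOUT_CUTOFF_DB,
    rule_table: Optional[RuleTable] = None,
    area: Optional[float] = None,
) -> BDTCResult:
    """Run the three-step tree on one lesion.

    ``area`` short-circuits the TIC fit when the lesion AREA is already
    known (e.g. from a precomputed parameter table).  The decision path
    records, in order, the fibrosis branch, the TIC branch, and -- when a
    pattern is available -- the pattern branch.
    """
    if rule_table is None:
        rule_table = default_rule_table()
    lesion_area = _lesion_area(record, area)
    washout = washout_flag(lesion_area, cutoff)
    path = ["F4" if record.cirrhotic else "<F4", "washout" if washout else "no_washout"]
    if record.pattern is None:
        predicted_type = INDETERMINATE
    else:
        if not isinstance(record.pattern, EnhancementPattern):
            raise ValueError(f"invalid enhancement pattern {record.pattern!r}")
        path.append(f"pattern:{record.pattern.value}")
        predicted_type = rule_table.get((record.cirrhotic, washout, record.pattern), INDETERMINATE)
    return BDTCResult(
        lesion_id=record.lesion_id,
        washout=washout,
        predicted_malignant=washout,
        predicted_type=predicted_type,
        path=tuple(path),
    )


def classify_cohort(
    records: list[LesionRecord],
    cutoff: float = DEFAULT_WASHOUT_CUTOFF_DB,
    rule_table: Optional[RuleTable] = None,
    areas: Optional[Mapping[str, float]] = None,
) -> list[BDTCResult]:
    """Classify every record; ``areas`` maps lesion_id -> precomputed lesion AREA."""
    out = []
    for rec in records:
        area = None if areas is None else areas[rec.lesion_id]
        out.append(bdtc_classify(rec, cutoff=cutoff, rule_table=rule_table, area=area))
    return out


__all__ = [
    "BDTCResult",
    "RuleTable",
    "bdtc_classify",
    "classify_cohort",
    "default_rule_table",
    "mpus_malignancy",
    "type_match",
    "MALIGNANT_PREDICTIONS",
]
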