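"""Domain vocabulary: lesion types, arterial enhancement patterns, lesion records.

The cohort under study is a set of focal liver lesions (FLLs) that remained
inconclusive after contrast-enhanced ultrasound (CEUS).  Each lesion carries a
reference diagnosis (one of twelve categories), a binary fibrosis flag
(cirrhotic, i.e. elastography stage F4, versus below F4), an arterial-phase
enhancement pattern read from parametric imaging, and a pair of late-phase
time-intensity curves (lesion ROI and adjacent parenchyma ROI).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Optional

from .washout import TICSeries


class LesionType(str, Enum):
    """The twelve reference diagnoses present in the cohort."""

    HCC = "hcc"
    METASTASIS = "metastasis"
    HAEMANGIOMA = "haemangioma"
    REGENERATIVE_NODULE = "regenerative_nodule"
    FOCAL_FATTY_ALTERATION = "focal_fatty_alteration"
    FATTY_FREE_AREA = "fatty_free_area"
    CHOLANGIOCARCINOMA = "cholangiocarcinoma"
    ABSCESS = "abscess"
    ADENOMA = "adenoma"
    COMPLEX_BILIARY_CYST = "complex_biliary_cyst"
    PARENCHYMAL_INFARCTION = "parenchymal_infarction"
    VASCULAR_ABNORMALITY = "vascular_abnormality"


#: Standard oncological reading: primary and secondary liver cancers are
#: malignant, everything else (including adenoma, a benign tumour with
#: malignant potential) is scored benign.  Overridable per cohort config.
DEFAULT_MALIGNANCY: dict[LesionType, bool] = {
    LesionType.HCC: True,
    LesionType.METASTASIS: True,
    LesionType.CHOLANGIOCARCINOMA: True,
    LesionType.HAEMANGIOMA: False,
    LesionType.REGENERATIVE_NODULE: False,
    LesionType.FOCAL_FATTY_ALTERATION: False,
    LesionType.FATTY_FREE_AREA: False,
    LesionType.ABSCESS: False,
    LesionType.ADENOMA: False,
    LesionType.COMPLEX_BILIARY_CYST: False,
    LesionType.PARENCHYMAL_INFARCTION: False,
    LesionType.VASCULAR_ABNORMALITY: False,
}


class EnhancementPattern(str, Enum):
    """Arterial-phase (10-45 s) enhancement patterns read from parametric imaging.

    These are the seven canonical CEUS arterial patterns used to discriminate
    the common focal liver lesions.
    """

    PERIPHERAL_NODULAR = "peripheral_nodular"  # haemangioma-like
    CENTRIFUGAL = "centrifugal"  # hyper-enhancement spreading outward, feeding artery
    PERIPHERAL_SEPTA = "peripheral_septa"  # peripheral, septated, no central enhancement
    RIM = "rim"  # rim or hyper, metastasis-like
    HYPER = "hyper"  # homogeneous hyper-enhancement
    RIM_CENTRAL_HYPO = "rim_central_hypo"  # rim-like hyper with central hypo
    ISO = "iso"  # iso-enhancement


#: Canonical arterial pattern of each reference diagnosis.  The first seven
#: rows are the textbook associations (haemangioma, FNH-like, abscess,
#: metastasis, HCC, cholangiocarcinoma, focal fatty change); the remaining
#: five cohort categories have no textbook row and are assigned the clinically
#: nearest pattern: adenomas hyper-enhance, complex biliary cysts show
#: septated peripheral enhancement, infarction areas a non-enhancing centre,
#: vascular abnormalities a feeding-vessel (centrifugal) pattern, and the two
#: fat-distribution pseudo-lesions plus regenerative nodules iso-enhance.
DEFAULT_TYPE_PATTERN: dict[LesionType, EnhancementPattern] = {
    LesionType.HAEMANGIOMA: EnhancementPattern.PERIPHERAL_NODULAR,
    LesionType.ABSCESS: EnhancementPattern.PERIPHERAL_SEPTA,
    LesionType.METASTASIS: EnhancementPattern.RIM,
    LesionType.HCC: EnhancementPattern.HYPER,
    LesionType.CHOLANGIOCARCINOMA: EnhancementPattern.RIM_CENTRAL_HYPO,
    LesionType.FOCAL_FATTY_ALTERATION: EnhancementPattern.ISO,
    LesionType.FATTY_FREE_AREA: EnhancementPattern.ISO,
    LesionType.REGENERATIVE_NODULE: EnhancementPattern.ISO,
    LesionType.ADENOMA: EnhancementPattern.HYPER,
    LesionType.COMPLEX_BILIARY_CYST: EnhancementPattern.PERIPHERAL_SEPTA,
    LesionType.PARENCHYMAL_INFARCTION: EnhancementPattern.RIM_CENTRAL_HYPO,
    LesionType.VASCULAR_ABNORMALITY: EnhancementPattern.CENTRIFUGAL,
}

#: Predicted-type labels that are not reference diagnoses.  Focal nodular
#: hyperplasia is a possible decision-tree output but never a truth label in
#: this cohort; "focal_fatty_change" is the tree's iso-enhancement benign call.
PREDICTED_FNH = "fnh"
PREDICTED_FFC = "focal_fatty_change"
INDETERMINATE = "indeterminate"

#: Predicted-type labels implying a malignant call.
MALIGNANT_PREDICTIONS = frozenset(
    {LesionType.HCC.value, LesionType.METASTASIS.value, LesionType.CHOLANGIOCARCINOMA.value}
)


def type_match(predicted: str, truth: LesionType) -> bool:
    """Whether a predicted lesion-type label counts as a correct typing.

    Exact label match, except that the "focal_fatty_change" call covers both
    fat-distribution pseudo-lesions (focal fatty alteration and fatty-free
    area): on imaging they are the same entity, fat deposition versus sparing.
    """
    if predicted == INDETERMINATE:
        return False
    if predicted == PREDICTED_FFC:
        return truth in (LesionType.FOCAL_FATTY_ALTERATION, LesionType.FATTY_FREE_AREA)
    return predicted == truth.value


@dataclass
class LesionRecord:
    """One focal liver lesion with everything the decision pipeline consumes."""

    lesion_id: str
    cirrhotic: bool
    pattern: Optional[EnhancementPattern] = None
    lesion_series: Optional[TICSeries] = None
    parenchyma_series: Optional[TICSeries] = None
    truth_type: Optional[LesionType] = None
    truth_malignant: Optional[bool] = None
    #: AREA values the generator drew (before TIC synthesis / refitting);
    #: absent for real cohorts.
    area_lesion_true: Optional[float] = None
    area_parenchyma_true: Optional[float] = None
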