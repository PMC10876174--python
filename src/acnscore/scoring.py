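"""The four diagnostic classification rules for pediatric ACNs.

Each rule is a pure function from a :class:`~acnscore.cohort.CaseRecord`
to a class label, returning ``None`` when required inputs are missing:

* ``wieneke_score`` / ``wieneke_classify`` — the 9-criterion Wieneke
  score (WC): weight > 400 g, size > 10.5 cm, extra-adrenal extension,
  vena cava invasion, venous (vascular) invasion, capsular invasion,
  necrosis, > 15 mitoses / 20 HPF, atypical mitoses; < 3 benign, = 3
  indeterminate (uncertain malignant potential), > 3 malignant.
* ``mwc_microscopic_score`` / ``mwc_classify`` — the modified Wieneke
  5-item microscopic score (necrosis, > 15 mitoses / 20 HPF, atypical
  mitoses, vascular invasion, capsular invasion) with a Ki67-based
  second step, yielding favorable vs unfavorable histology.
* ``ra_classify`` — the reticulin algorithm: reticulin framework
  disruption (any non-intact category) AND at least one of necrosis,
  vascular (venous) invasion, or a high mitotic rate.  The adult variant
  (aRA) uses > 5 / 50 HPF, the pediatric variant (pRA) > 15 / 20 HPF.

``score_panel`` evaluates everything at once with partial evaluation:
each sub-score is emitted when its inputs allow, missing otherwise.  The
Wieneke class is additionally emitted when it is decided by the known
criteria alone (e.g. four criteria already satisfied forces MALIGNANT
regardless of missing items), which maximizes usable cases under
per-analysis deletion of incomplete records.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Optional

from .cohort import CaseRecord, MitoticCount, Tristate
from .rules import DEFAULT_RULES, ScoringRules


class WCClass(enum.Enum):
    BENIGN = "benign"
    INDETERMINATE = "indeterminate"
    MALIGNANT = "malignant"


class MWCClass(enum.Enum):
    FAVORABLE = "favorable"
    UNFAVORABLE = "unfavorable"


class RAClass(enum.Enum):
    BENIGN = "benign"
    MALIGNANT = "malignant"


class RAVariant(enum.Enum):
    ADULT = "adult"
    PEDIATRIC = "pediatric"


WC_CRITERIA = (
    "weight", "size", "extra_adrenal_extension", "vena_cava_invasion",
    "vascular_invasion", "capsular_invasion", "necrosis",
    "high_mitotic_count", "atypical_mitoses",
)


def _mitoses_exceed(count: Optional[MitoticCount], cutoff: int,
                    denominator: int, rules: ScoringRules) -> Tristate:
    if count is None:
        return None
    return count.exceeds(cutoff, denominator,
                         allow_rescale=rules.allow_mitotic_rescale)


def wieneke_criteria(case: CaseRecord,
                     rules: ScoringRules = DEFAULT_RULES) -> dict[str, Tristate]:
    """Evaluate each of the nine Wieneke criteria (True/False/None)."""
    return {
        "weight": None if case.weight_g is None else case.weight_g > rules.wc_weight_g,
        "size": None if case.size_cm is None else case.size_cm > rules.wc_size_cm,
        "extra_adrenal_extension": case.extra_adrenal_extension,
        "vena_cava_invasion": case.vena_cava_invasion,
        "vascular_invasion": case.vascular_invasion,
        "capsular_invasion": case.capsular_invasion,
        "necrosis": case.necrosis,
        "high_mitotic_count": _mitoses_exceed(
            case.mitoses_per_20hpf, rules.wc_mitoses_per_20hpf, 20, rules),
        "atypical_mitoses": case.atypical_mitoses,
    }


def wieneke_score(case: CaseRecord,
                  rules: ScoringRules = DEFAULT_RULES) -> Optional[int]:
    """Count of satisfied Wieneke criteria (0..9), or None if any
    criterion is unevaluable."""
    criteria = wieneke_criteria(case, rules)
    if any(value is None for value in criteria.values()):
        return None
    return sum(criteria.values())


def wieneke_score_bounds(case: CaseRecord,
                         rules: ScoringRules = DEFAULT_RULES) -> tuple[int, int]:
    """(known-true count, known-true + unevaluable count): the attainable
    score range given the missing criteria."""
    criteria = wieneke_criteria(case, rules)
    low = sum(1 for v in criteria.values() if v is True)
    high = low + sum(1 for v in criteria.values() if v is None)
    return low, high


def wieneke_classify(score: int,
                     rules: ScoringRules = DEFAULT_RULES) -> WCClass:
    """Map a Wieneke score to its class band."""
    if not 0 <= score <= len(WC_CRITERIA):
        raise ValueError(f"Wieneke score out of range: {score}")
    if score <= rules.wc_benign_max:
        return WCClass.BENIGN
    if score == rules.wc_indeterminate:
        return WCClass.INDETERMINATE
    return WCClass.MALIGNANT


def wieneke_class(case: CaseRecord,
                  rules: ScoringRules = DEFAULT_RULES) -> Optional[WCClass]:
    """Wieneke class, emitted whenever decidable.

    If some criteria are missing but every attainable score falls in one
    band, that band is returned; otherwise None.
    """
    low, high = wieneke_score_bounds(case, rules)
    lo_class, hi_class = wieneke_classify(low, rules), wieneke_classify(high, rules)
    if lo_class is hi_class:
        return lo_class
    return None


MWC_ITEMS = ("necrosis", "high_mitotic_count", "atypical_mitoses",
             "vascular_invasion", "capsular_invasion")


def mwc_microscopic_score(case: CaseRecord,
                          rules: ScoringRules = DEFAULT_RULES) -> Optional[int]:
    """5-item microscopic score (0..5); None if any item is unevaluable."""
    items = {
        "necrosis": case.necrosis,
        "high_mitotic_count": _mitoses_exceed(
            case.mitoses_per_20hpf, rules.wc_mitoses_per_20hpf, 20, rules),
        "atypical_mitoses": case.atypical_mitoses,
        "vascular_invasion": case.vascular_invasion,
        "capsular_invasion": case.capsular_invasion,
    }
    if any(value is None for value in items.values()):
        return None
    return sum(items.values())


def mwc_classify(case: CaseRecord,
                 rules: ScoringRules = DEFAULT_RULES) -> Optional[MWCClass]:
    """Two-step modified Wieneke classification.

    Unfavorable at microscopic score >= 3, favorable at <= 1; a score in
    between is decided by the Ki67 proliferative index (>= 15% cutoff by
    default).  Returns None when the score or a needed Ki67 is missing.
    """
    score = mwc_microscopic_score(case, rules)
    if score is None:
        return None
    if score >= rules.mwc_unfavorable_min:
        return MWCClass.UNFAVORABLE
    if score <= rules.mwc_favorable_max:
        return MWCClass.FAVORABLE
    if case.ki67_percent is None:
        return None
    if case.ki67_percent >= rules.mwc_ki67_cutoff_percent:
        return MWCClass.UNFAVORABLE
    return MWCClass.FAVORABLE


def ra_classify(case: CaseRecord, variant: RAVariant,
                rules: ScoringRules = DEFAULT_RULES) -> Optional[RAClass]:
    """Reticulin algorithm, adult or pediatric mitotic cutoff.

    Step 1: reticulin framework disruption (any non-intact category).
    Step 2: at least one of necrosis, vascular (venous) invasion, or
    mitoses above the variant's cutoff.  Malignant iff both steps hold.
    An intact framework is benign regardless of the other features.
    """
    if case.reticulin is None:
        return None
    if not case.reticulin.altered:
        return RAClass.BENIGN
    if variant is RAVariant.ADULT:
        mitotic = _mitoses_exceed(case.mitoses_per_50hpf, rules.ra_adult_cutoff,
                                  rules.ra_adult_denominator_hpf, rules)
    else:
        mitotic = _mitoses_exceed(case.mitoses_per_20hpf, rules.ra_pediatric_cutoff,
                                  rules.ra_pediatric_denominator_hpf, rules)
    criteria = (case.necrosis, case.vascular_invasion, mitotic)
    if any(c is True for c in criteria):
        return RAClass.MALIGNANT
    if any(c is None for c in criteria):
        return None
    return RAClass.BENIGN


@dataclass(frozen=True)
class ScorePanel:
    """The four classifications (plus raw scores) for one case."""

    case_id: str
    wc_score: Optional[int]
    wc_class: Optional[WCClass]
    mwc_microscopic_score: Optional[int]
    mwc_class: Optional[MWCClass]
    ara_class: Optional[RAClass]
    pra_class: Optional[RAClass]


def score_panel(case: CaseRecord,
                rules: ScoringRules = DEFAULT_RULES) -> ScorePanel:
    """Evaluate all four scores with partial evaluation (missing inputs
    yield missing sub-scores, never an exception)."""
    return ScorePanel(
        case_id=case.case_id,
        wc_score=wieneke_score(case, rules),
        wc_class=wieneke_class(case, rules),
        mwc_microscopic_score=mwc_microscopic_score(case, rules),
        mwc_class=mwc_classify(case, rules),
        ara_class=ra_classify(case, RAVariant.ADULT, rules),
        pra_class=ra_classify(case, RAVariant.PEDIATRIC, rules),
    )


def panel_frame(cohort, rules: ScoringRules = DEFAULT_RULES):
    """Score every case in a cohort; returns a tidy pandas DataFrame with
    one row per case (enum labels as strings, missing as NA)."""
    import pandas as pd

    rows = []
    for case in cohort:
        panel = score_panel(case, rules)
        rows.append({
            "case_id": panel.case_id,
            "wc_score": panel.wc_score,
            "wc_class": None if panel.wc_class is None else panel.wc_class.value,
            "mwc_microscopic_score": panel.mwc_microscopic_score,
            "mwc_class": None if panel.mwc_class is None else panel.mwc_class.value,
            "ara_class": None if panel.ara_class is None else panel.ara_class.value,
            "pra_class": None if panel.pra_class is None else panel.pra_class.value,
            "outcome": None if case.outcome.value == "unknown" else case.outcome.value,
            "followup_months": case.followup_months,
        })
    return pd.DataFrame(rows)
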