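"""Scoring-rule configuration.

Every numeric threshold used by the classification rules lives here as
data, not code, and can be overridden from a plain ``key = value`` text
file.  The shipped defaults are the published conventions:

* Wieneke criteria macroscopic cutoffs: weight > 400 g, size > 10.5 cm,
  mitotic cutoff > 15 per 20 HPF; class bands < 3 benign, = 3
  indeterminate, > 3 malignant.
* Modified Wieneke two-step rule: 5-item microscopic score, unfavorable
  at >= 3, favorable at <= 1, and Ki67 >= 15% deciding a score of 2.
  The two-step rule is a reconstruction of the published description and
  is configurable precisely because the original rule table is not fully
  specified in the validation literature.
* Reticulin algorithm mitotic cutoffs: adult > 5 per 50 HPF (Weiss
  convention), pediatric > 15 per 20 HPF (Wieneke convention).

All cutoffs are strict inequalities except the Ki67 cutoff (>= 15%).
"""

from __future__ import annotations

from dataclasses import dataclass, asdict, replace
from pathlib import Path


@dataclass(frozen=True)
class ScoringRules:
    # Wieneke criteria
    wc_weight_g: float = 400.0
    wc_size_cm: float = 10.5
    wc_mitoses_per_20hpf: int = 15
    wc_benign_max: int = 2       # score <= 2 -> benign
    wc_indeterminate: int = 3    # score == 3 -> indeterminate; > 3 malignant
    # Modified Wieneke (5-item microscopic score + Ki67 second step)
    mwc_unfavorable_min: int = 3
    mwc_favorable_max: int = 1
    mwc_ki67_cutoff_percent: float = 15.0
    # Reticulin algorithm mitotic cutoffs
    ra_adult_cutoff: int = 5
    ra_adult_denominator_hpf: int = 50
    ra_pediatric_cutoff: int = 15
    ra_pediatric_denominator_hpf: int = 20
    # Cross-denominator rescaling of mitotic counts (off by default: HPF
    # area and counting protocol differ between conventions)
    allow_mitotic_rescale: bool = False

    def replace(self, **kwargs) -> "ScoringRules":
        return replace(self, **kwargs)


DEFAULT_RULES = ScoringRules()

_BOOL_FIELDS = {"allow_mitotic_rescale"}
_INT_FIELDS = {
    "wc_mitoses_per_20hpf", "wc_benign_max", "wc_indeterminate",
    "mwc_unfavorable_min", "mwc_favorable_max",
    "ra_adult_cutoff", "ra_adult_denominator_hpf",
    "ra_pediatric_cutoff", "ra_pediatric_denominator_hpf",
}


def load_rules(path: str | Path) -> ScoringRules:
    """Read rules from a ``key = value`` file; unlisted keys keep defaults."""
    overrides = {}
    valid = set(asdict(DEFAULT_RULES))
    for raw in Path(path).read_text().splitlines():
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ValueError(f"malformed rules line: {raw!r}")
        key, value = (part.strip() for part in line.split("=", 1))
        if key not in valid:
            raise ValueError(f"unknown rule key: {key!r}")
        if key in _BOOL_FIELDS:
            overrides[key] = value.lower() in ("true", "1", "yes")
        elif key in _INT_FIELDS:
            overrides[key] = int(value)
        else:
            overrides[key] = float(value)
    return DEFAULT_RULES.replace(**overrides)


def save_rules(rules: ScoringRules, path: str | Path) -> None:
    lines = [f"{key} = {value}" for key, value in asdict(rules).items()]
    Path(path).write_text("\n".join(lines) + "\n")
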