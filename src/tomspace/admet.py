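"""Rule-based ADMET triage of herbal compounds.

Compounds predicted mutagenic (AMES "toxic"), carcinogenic ("danger") or
hERG-blocking ("inhibitor" / "strong inhibitor") are excluded before any
target space is built.  Exclusion acts at compound level: an herb keeps
contributing through its remaining clean compounds.  Every rule a compound
triggers is recorded, so the exclusion log is auditable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from .model import AdmetAnnotation

logger = logging.getLogger(__name__)

RULE_AMES = "AMES"
RULE_CARCINOGENICITY = "Carcinogenicity"
RULE_HERG = "hERG"


@dataclass
class FilterRuleSet:
    """Which of the three exclusion rules are active, and how to treat
    compounds without any annotation row.

    The default keeps unannotated compounds: only a positive toxicity
    prediction is evidence for exclusion.
    """

    exclude_ames: bool = True
    exclude_carcinogenicity: bool = True
    exclude_herg: bool = True
    unknown_policy: str = "keep"  # "keep" | "drop"

    def __post_init__(self) -> None:
        if self.unknown_policy not in ("keep", "drop"):
            raise ValueError(f"unknown_policy must be 'keep' or 'drop', got {self.unknown_policy!r}")

    def as_dict(self) -> dict:
        return {
            "exclude_ames": self.exclude_ames,
            "exclude_carcinogenicity": self.exclude_carcinogenicity,
            "exclude_herg": self.exclude_herg,
            "unknown_policy": self.unknown_policy,
        }


RULE_UNANNOTATED = "unannotated"


def triggered_rules(annotation: AdmetAnnotation, rules: FilterRuleSet) -> list[str]:
    """All active rules this annotation trips (may be empty)."""
    hits: list[str] = []
    if rules.exclude_ames and annotation.ames_risk:
        hits.append(RULE_AMES)
    if rules.exclude_carcinogenicity and annotation.carcinogenicity_risk:
        hits.append(RULE_CARCINOGENICITY)
    if rules.exclude_herg and annotation.herg_risk:
        hits.append(RULE_HERG)
    return hits


def apply_admet_filter(
    compounds: set[str],
    annotations: list[AdmetAnnotation],
    rules: FilterRuleSet | None = None,
) -> tuple[set[str], list[tuple[str, str]]]:
    """Partition ``compounds`` into kept ids and excluded (id, rule) records.

    A compound is excluded iff it triggers at least one active rule; a
    compound with no annotation row follows ``rules.unknown_policy`` (kept
    by default, with a warning).  Kept and excluded ids always partition
    the input set, and each exclusion lists every rule it triggered.
    """
    rules = rules or FilterRuleSet()
    by_id = {a.compound_id: a for a in annotations}
    kept: set[str] = set()
    excluded: list[tuple[str, str]] = []
    for cid in sorted(compounds):
        ann = by_id.get(cid)
        if ann is None:
            if rules.unknown_policy == "drop":
                excluded.append((cid, RULE_UNANNOTATED))
            else:
                logger.warning("compound %s has no ADMET annotation; kept (unknown_policy=keep)", cid)
                kept.add(cid)
            continue
        hits = triggered_rules(ann, rules)
        if hits:
            excluded.extend((cid, rule) for rule in hits)
        else:
            kept.add(cid)
    return kept, excluded
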