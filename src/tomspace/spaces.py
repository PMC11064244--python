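"""Construction of target spaces.

A formula's target space is the union of the targets of the surviving
compounds of its herbs; a drug module's space is the union of its drugs'
targets.  Cytochrome P450 isozymes (symbols matching ``CYP`` followed by a
digit, e.g. CYP3A4) are excluded from both sides by default: they report
drug metabolism, not therapeutic action.  Exclusion is symmetric so the
support denominator stays consistent.
"""

from __future__ import annotations

import logging
import re

from .model import AssociationTable, ModuleDefinition, TargetSpace

logger = logging.getLogger(__name__)

# CYP isozyme symbols are CYP + family number (+ subfamily letter + number),
# e.g. CYP3A4, CYP2D6, CYP1A2.  Requiring a digit after the prefix avoids
# catching unrelated symbols that merely start with "CYP".
_CYP_PATTERN = re.compile(r"^CYP\d")

TAG_CYP_EXCLUDED = "cyp_excluded"
TAG_ADMET_FILTERED = "admet_filtered"


def is_cyp(gene: str) -> bool:
    """True iff the normalized symbol names a cytochrome P450 isozyme."""
    return bool(_CYP_PATTERN.match(gene))


def remove_cyp(genes: set[str]) -> set[str]:
    return {g for g in genes if not is_cyp(g)}


def build_formula_space(
    formula_id: str,
    formula_herb: AssociationTable,
    herb_compound: AssociationTable,
    compound_target: AssociationTable,
    kept_compounds: set[str] | None = None,
    exclude_cyp: bool = True,
    admet_filtered: bool = False,
) -> TargetSpace:
    """Union the targets of the formula's herbs' (kept) compounds.

    ``kept_compounds`` is the post-ADMET compound set; ``None`` means no
    compound filtering.  A formula with no herbs is an error; a formula
    whose compounds were all filtered out yields an empty space with a
    warning so batch runs complete.
    """
    herbs = formula_herb.targets_of(formula_id)
    if not herbs:
        raise ValueError(f"formula {formula_id!r} has no herbs in the formula-herb table")
    herb_to_compounds = herb_compound.as_mapping()
    compound_to_targets = compound_target.as_mapping()

    compounds: set[str] = set()
    for herb in herbs:
        compounds |= herb_to_compounds.get(herb, set())
    if kept_compounds is not None:
        compounds &= kept_compounds

    genes: set[str] = set()
    for c in compounds:
        genes |= compound_to_targets.get(c, set())

    tags: list[str] = []
    if admet_filtered or kept_compounds is not None:
        tags.append(TAG_ADMET_FILTERED)
    if exclude_cyp:
        genes = remove_cyp(genes)
        tags.append(TAG_CYP_EXCLUDED)
    if not genes:
        logger.warning("formula %s has an empty target space after filtering", formula_id)
    return TargetSpace(owner_id=formula_id, owner_kind="formula", genes=frozenset(genes), filters_applied=tuple(tags))


def build_module_space(
    module: ModuleDefinition,
    drug_target: AssociationTable,
    exclude_cyp: bool = True,
) -> TargetSpace:
    """Union the targets of the module's drugs; error on an empty union
    (support against an empty drug space is undefined)."""
    drug_to_targets = drug_target.as_mapping()
    genes: set[str] = set()
    for drug in module.drug_ids:
        genes |= drug_to_targets.get(drug, set())
    tags: list[str] = []
    if exclude_cyp:
        genes = remove_cyp(genes)
        tags.append(TAG_CYP_EXCLUDED)
    if not genes:
        raise ValueError(
            f"drug module {module.module_id!r} has an empty target space; support is undefined"
        )
    return TargetSpace(
        owner_id=module.module_id,
        owner_kind="drug_module",
        genes=frozenset(genes),
        filters_applied=tuple(tags),
    )
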