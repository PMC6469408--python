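"""Genetic-logic classification of candidate hybrid-male-sterility genes.

A gene assayed in fertile backcross (BC) and introgression (IG) males is
*misregulated* in a fertile class when its expression differs significantly
from both parental species.  Misregulation that also appears in fertile
males cannot by itself explain F1 hybrid male sterility, so a gene is
*excluded* when at least one of its misregulated fertile classes is not
significantly different from sterile F1 males — the misexpression is then
reproduced in a fertile genotype at F1-like levels.  Genes never
misregulated in fertile males (or misregulated only at levels unlike
sterile F1, an edge case annotated for review) are retained as candidates.

A separate comparison of the sepia (se, carrying the D. p. pseudoobscura
allele at the Overdrive-linked marker) versus non-sepia (se+) introgression
classes flags genes whose expression responds to the introgressed Ovd
region ("Ovd targets").
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import pandas as pd

__all__ = [
    "FERTILE_BC_CLASSES",
    "FERTILE_IG_CLASSES",
    "FERTILE_CLASSES",
    "ClassComparisonFlags",
    "CandidateStatus",
    "flag_fertile_misregulation",
    "apply_exclusion_rule",
    "identify_ovd_targets",
]

FERTILE_BC_CLASSES = ("BC1p", "BC1b", "BC4")
# F8se+ males are sterile and never count toward fertile misregulation
FERTILE_IG_CLASSES = ("F8y", "F8y+", "F8se")
FERTILE_CLASSES = FERTILE_BC_CLASSES + FERTILE_IG_CLASSES

FLAG_COLUMNS = ("gene", "sample_class", "diff_from_both_parents", "diff_from_sterile_f1")


@dataclass(frozen=True)
class ClassComparisonFlags:
    gene: str
    sample_class: str
    diff_from_both_parents: bool
    diff_from_sterile_f1: bool


@dataclass
class CandidateStatus:
    gene: str
    misregulated_in_fertile: list[str] = field(default_factory=list)
    excluded: bool = False
    exclusion_reason: str = ""
    retained_candidate: bool = True
    review: bool = False
    ovd_target: bool = False
    rule_trace: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.excluded and self.retained_candidate:
            raise ValueError("excluded genes cannot be retained candidates")


def _validated(flags: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in FLAG_COLUMNS if c not in flags.columns]
    if missing:
        raise ValueError(f"flags table lacks columns: {missing}")
    return flags


def flag_fertile_misregulation(flags: pd.DataFrame) -> dict[str, dict[str, list[str]]]:
    """Per-gene lists of misregulated fertile classes, split by BC vs IG.

    A (gene, class) pair is misregulated iff ``diff_from_both_parents`` is
    True.  Every fertile class must be present for every gene.
    """
    flags = _validated(flags)
    by_gene: dict[str, dict[str, list[str]]] = {}
    indexed = flags.set_index(["gene", "sample_class"])
    for gene in flags["gene"].unique():
        bc, ig = [], []
        for cls in FERTILE_CLASSES:
            try:
                row = indexed.loc[(gene, cls)]
            except KeyError:
                raise ValueError(f"missing flag for (gene, class) = ({gene}, {cls})")
            if bool(row["diff_from_both_parents"]):
                (bc if cls in FERTILE_BC_CLASSES else ig).append(cls)
        by_gene[gene] = {"bc": bc, "ig": ig}
    return by_gene


def apply_exclusion_rule(flags: pd.DataFrame) -> list[CandidateStatus]:
    """Classify every gene as excluded or retained candidate.

    A gene is excluded iff it is misregulated in >= 1 fertile class AND at
    least one of those classes is not significantly different from sterile
    F1 males.  A gene misregulated in fertile classes that ALL differ from
    sterile F1 is retained by the letter of the rule but annotated for
    review.  Each status carries an audit trace of the rule firings.
    """
    flags = _validated(flags)
    misreg = flag_fertile_misregulation(flags)
    indexed = flags.set_index(["gene", "sample_class"])
    statuses = []
    for gene, groups in misreg.items():
        classes = groups["bc"] + groups["ig"]
        status = CandidateStatus(gene=gene, misregulated_in_fertile=classes)
        if not classes:
            status.rule_trace.append("no fertile misregulation; retained")
            statuses.append(status)
            continue
        matching_f1 = []
        for cls in classes:
            row = indexed.loc[(gene, cls)]
            if pd.isna(row["diff_from_sterile_f1"]):
                raise ValueError(
                    f"({gene}, {cls}) misregulated but missing the sterile-F1 comparison"
                )
            if not bool(row["diff_from_sterile_f1"]):
                matching_f1.append(cls)
        if matching_f1:
            status.excluded = True
            status.retained_candidate = False
            status.exclusion_reason = (
                "misregulated in fertile class(es) "
                + ",".join(classes)
                + " with F1-like levels in "
                + ",".join(matching_f1)
            )
            status.rule_trace.append(
                f"fertile misregulation in {classes}; F1-matching in {matching_f1}; excluded"
            )
        else:
            status.review = True
            status.rule_trace.append(
                f"fertile misregulation in {classes} but every class differs from "
                "sterile F1; retained (review)"
            )
        statuses.append(status)
    return statuses


def identify_ovd_targets(se_comparison: Mapping[str, bool]) -> set[str]:
    """Genes with a significant se vs se+ introgression contrast (q < alpha).

    ``se_comparison`` maps gene -> whether the F8se vs F8se+ Scheffé
    comparison is significant; returns the set of flagged genes.
    """
    return {gene for gene, sig in se_comparison.items() if bool(sig)}


def annotate_ovd(statuses: Iterable[CandidateStatus], ovd: set[str]) -> list[CandidateStatus]:
    """Set the ``ovd_target`` flag on an existing classification."""
    out = list(statuses)
    for st in out:
        st.ovd_target = st.gene in ovd
    return out
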