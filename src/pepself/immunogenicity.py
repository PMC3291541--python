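"""Immunogenicity labels and the self-overlap contingency analysis.

Experimentally assayed peptide-MHC combinations are classified as
immunogenic when at least one positive T-cell response was recorded, and
non-immunogenic when every record is negative (IEDB-style outcome strings).
Each classified peptide is then flagged for overlap with the presented self
repertoire under a recognition model, and the association between
immunogenicity and self-overlap is tested on the resulting 2x2 table.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from .overlap import SelfIndex
from .presentation import PresentedSet
from .recognition import RecognitionModel
from .stats import ContingencyTable2x2, chi_square_2x2

logger = logging.getLogger(__name__)

#: Default mapping from assay outcome strings (lowercased) to classes.
IEDB_OUTCOME_RULES: Mapping[str, str] = {
    "positive": "positive",
    "positive-high": "positive",
    "positive(-high)": "positive",
    "positive-intermediate": "positive",
    "positive-low": "positive",
    "negative": "negative",
}


@dataclass(frozen=True)
class LabeledPeptide:
    peptide: str
    allele: str
    label: str  # "immunogenic" | "non-immunogenic"
    source: str = ""


def classify_labels(
    table: pd.DataFrame | str | Path,
    outcome_rules: Mapping[str, str] = IEDB_OUTCOME_RULES,
) -> list[LabeledPeptide]:
    """Label (peptide, allele) pairs from assay outcome records.

    Input: TSV or frame with columns peptide, allele, assay_outcome (and
    optionally source).  A pair with any positive record is immunogenic;
    a pair whose records are all negative is non-immunogenic.  Records with
    outcome strings outside ``outcome_rules`` are excluded with a warning,
    and a pair left with no classifiable record is dropped.
    """
    if not isinstance(table, pd.DataFrame):
        table = pd.read_csv(table, sep="\t")
    required = {"peptide", "allele", "assay_outcome"}
    if not required <= set(table.columns):
        raise ValueError(f"label table must have columns {sorted(required)}")
    if "source" not in table.columns:
        table = table.assign(source="")
    labeled = []
    for (pep, allele), grp in table.groupby(["peptide", "allele"]):
        classes = []
        for outcome in grp["assay_outcome"]:
            key = str(outcome).strip().lower()
            if key not in outcome_rules:
                logger.warning(
                    "excluding record with unknown assay outcome %r for %s/%s",
                    outcome, pep, allele,
                )
                continue
            classes.append(outcome_rules[key])
        if not classes:
            continue
        label = "immunogenic" if "positive" in classes else "non-immunogenic"
        labeled.append(
            LabeledPeptide(
                peptide=str(pep).upper(),
                allele=str(allele),
                label=label,
                source=str(grp["source"].iloc[0]),
            )
        )
    return labeled


def overlap_table(
    labeled: Sequence[LabeledPeptide],
    self_presented: PresentedSet | set[str],
    model: RecognitionModel,
) -> ContingencyTable2x2:
    """Cross-classify immunogenicity against self-overlap into a 2x2 table.

    A peptide is self-overlapping when at least one presented self peptide
    is recognised as the same under ``model``.  Rows: immunogenic /
    non-immunogenic; columns: overlapping / not overlapping.
    """
    self_peptides = (
        self_presented.peptides
        if isinstance(self_presented, PresentedSet)
        else self_presented
    )
    if any(len(lp.peptide) != 9 for lp in labeled):
        raise ValueError("all labeled peptides must be 9mers")
    n_imm = sum(1 for lp in labeled if lp.label == "immunogenic")
    n_non = len(labeled) - n_imm
    if n_imm == 0 or n_non == 0:
        raise ValueError("both immunogenic and non-immunogenic peptides are required")
    index = SelfIndex(self_peptides, model)
    a = b = c = d = 0
    for lp in labeled:
        overlapping = index.overlaps(lp.peptide)
        if lp.label == "immunogenic":
            if overlapping:
                a += 1
            else:
                b += 1
        else:
            if overlapping:
                c += 1
            else:
                d += 1
    return ContingencyTable2x2(a=a, b=b, c=c, d=d)


def association_report(table: ContingencyTable2x2) -> dict[str, float]:
    """Chi-square test plus the odds ratio for one contingency table."""
    stat, p = chi_square_2x2(table)
    return {
        "chi2": stat,
        "p_value": p,
        "odds_ratio": table.odds_ratio,
        "n": table.total,
    }
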