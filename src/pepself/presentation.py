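"""MHC class I presentation: pluggable binding scores and thresholds.

Binding predictors (NetMHC-style tools) are represented by a minimal
contract — ``score(peptide) -> predicted IC50 in nM`` — with two concrete
implementations: a position-weight *motif* model useful for simulation, and
a lookup model backed by an imported table of precomputed scores.
Proteasomal cleavage + TAP transport are a second contract
(``passes(peptide)``), pass-through by default.

Two threshold modes select the presented set: a *fixed* cutoff (500 nM, the
conventional binder threshold) and a *scaled* cutoff calibrated per allele
so that a common fraction of self peptides (2.3%, the HLA-A*0201 specificity
at 500 nM) is presented.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Protocol, runtime_checkable

import numpy as np
import pandas as pd

from .peptidome import AMINO_ACIDS

_AA_INDEX = {aa: i for i, aa in enumerate(AMINO_ACIDS)}

FIXED_THRESHOLD_NM = 500.0
#: Fraction of self 9mers presented by HLA-A*0201 at 500 nM.
DEFAULT_TARGET_SPECIFICITY = 0.023


@runtime_checkable
class BindingModel(Protocol):
    """Anything with an allele name and a deterministic IC50 score."""

    allele_name: str

    def score(self, peptide: str) -> float: ...


@runtime_checkable
class ProcessingModel(Protocol):
    def passes(self, peptide: str) -> bool: ...


class PassThroughProcessing:
    """Default processing stage: every peptide reaches the ER."""

    def passes(self, peptide: str) -> bool:  # noqa: ARG002
        return True


class CTerminalCleavageModel:
    """Toy proteasomal C-terminal cleavage preference.

    Scores the C-terminal residue against a preference table in [0,1] and
    passes peptides whose preference meets the threshold.  A stand-in for
    the cleavage/TAP stage of the presentation pathway.
    """

    def __init__(self, preference: dict[str, float], threshold: float = 0.5):
        missing = set(AMINO_ACIDS) - set(preference)
        if missing:
            raise ValueError(f"preference table missing residues {sorted(missing)}")
        self.preference = dict(preference)
        self.threshold = threshold

    def passes(self, peptide: str) -> bool:
        return self.preference[peptide[-1]] >= self.threshold


class MotifBindingModel:
    """Position-weight-matrix binding model on the log-IC50 scale.

    ``weights[p, a]`` is the additive log-IC50 contribution of residue ``a``
    at position p+1; the predicted IC50 is ``exp(sum of contributions)`` nM.
    Anchor positions carry wider weight dispersion, so the presented set is
    residue-restricted there (low entropy), as for real alleles.
    """

    def __init__(self, allele_name: str, weights: np.ndarray):
        weights = np.asarray(weights, dtype=float)
        if weights.shape != (9, 20):
            raise ValueError(f"weights must be 9x20, got {weights.shape}")
        self.allele_name = allele_name
        self.weights = weights

    def score(self, peptide: str) -> float:
        if len(peptide) != 9:
            raise ValueError("peptide must have length 9")
        total = sum(self.weights[p, _AA_INDEX[aa]] for p, aa in enumerate(peptide))
        return float(np.exp(total))

    def score_many(self, peptides: Iterable[str]) -> np.ndarray:
        """Vectorised scoring of many 9mers."""
        peps = list(peptides)
        if not peps:
            return np.zeros(0)
        idx = np.array([[_AA_INDEX[aa] for aa in p] for p in peps])
        total = self.weights[np.arange(9)[None, :], idx].sum(axis=1)
        return np.exp(total)

    def to_table(self, path: str | Path) -> None:
        """Serialise as a 9x20 whitespace table with an amino-acid header."""
        with open(path, "w") as fh:
            fh.write(" ".join(AMINO_ACIDS) + "\n")
            for row in self.weights:
                fh.write(" ".join(f"{v:.8g}" for v in row) + "\n")

    @classmethod
    def from_table(cls, path: str | Path, allele_name: str | None = None) -> "MotifBindingModel":
        lines = [ln.split() for ln in Path(path).read_text().splitlines() if ln.strip()]
        header = [t.upper() for t in lines[0]]
        if header != list(AMINO_ACIDS):
            raise ValueError("motif table header must list the 20 amino acids in order")
        if len(lines) != 10:
            raise ValueError("motif table must have 9 weight rows")
        weights = np.array([[float(t) for t in row] for row in lines[1:]])
        return cls(allele_name or Path(path).stem, weights)


class TableBindingModel:
    """Lookup-backed binding model over precomputed (peptide, IC50) scores."""

    def __init__(self, allele_name: str, scores: dict[str, float]):
        self.allele_name = allele_name
        self._scores = dict(scores)

    def score(self, peptide: str) -> float:
        try:
            return self._scores[peptide]
        except KeyError:
            raise KeyError(
                f"no stored score for peptide {peptide!r} on allele {self.allele_name}"
            ) from None

    def __len__(self) -> int:
        return len(self._scores)


def import_score_table(path: str | Path) -> dict[str, TableBindingModel]:
    """Read a TSV with columns peptide, allele, ic50_nm into lookup models.

    Emulates ingesting NetMHC/NetMHCpan/SMM output.  Duplicate
    (peptide, allele) rows with conflicting scores are an error; exact
    duplicates collapse silently.
    """
    df = pd.read_csv(path, sep="\t")
    required = {"peptide", "allele", "ic50_nm"}
    if not required <= set(df.columns):
        raise ValueError(f"score table must have columns {sorted(required)}")
    df["peptide"] = df["peptide"].str.upper()
    conflicts = (
        df.groupby(["peptide", "allele"])["ic50_nm"].nunique().pipe(lambda s: s[s > 1])
    )
    if len(conflicts):
        pep, allele = conflicts.index[0]
        raise ValueError(
            f"conflicting scores for peptide {pep!r} on allele {allele!r}"
        )
    models = {}
    for allele, grp in df.groupby("allele"):
        scores = dict(zip(grp["peptide"], grp["ic50_nm"].astype(float)))
        models[str(allele)] = TableBindingModel(str(allele), scores)
    return models


def export_score_table(
    models: Iterable[BindingModel], peptides: Iterable[str], path: str | Path
) -> None:
    """Write model scores for the given peptides as a peptide/allele/ic50 TSV."""
    peps = sorted(set(peptides))
    rows = [
        {"peptide": p, "allele": m.allele_name, "ic50_nm": m.score(p)}
        for m in models
        for p in peps
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Thresholds and the presented set
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ThresholdSpec:
    """Fixed (500 nM) or scaled (matched self-specificity) threshold mode."""

    mode: str = "scaled"
    fixed_value: float = FIXED_THRESHOLD_NM
    target_specificity: float = DEFAULT_TARGET_SPECIFICITY

    def __post_init__(self) -> None:
        if self.mode not in ("fixed", "scaled"):
            raise ValueError("mode must be 'fixed' or 'scaled'")
        if not 0 < self.target_specificity <= 1:
            raise ValueError("target_specificity must be in (0,1]")


@dataclass
class PresentedSet:
    """Unique 9mers predicted presented by one allele at one threshold."""

    allele_name: str
    threshold_nm: float
    peptides: set[str]
    species_id: str = ""
    kingdom: str = "self"
    achieved_specificity: float | None = None

    def __len__(self) -> int:
        return len(self.peptides)

    def __contains__(self, peptide: str) -> bool:
        return peptide in self.peptides


def calibrate_scaled_threshold(
    model: BindingModel,
    self_peptides: Iterable[str],
    target_specificity: float = DEFAULT_TARGET_SPECIFICITY,
) -> tuple[float, float]:
    """Per-allele IC50 cutoff presenting a target fraction of self peptides.

    The threshold is the k-th smallest self score with k = floor(target * N)
    (an empirical quantile); peptides scoring exactly the threshold are all
    counted, and the achieved specificity is returned alongside, rather than
    forced to the target.  Returns ``(threshold_nm, achieved_specificity)``.
    """
    scores = _scores_array(model, list(self_peptides))
    n = scores.size
    if n == 0:
        raise ValueError("self_peptides must be non-empty")
    if np.all(scores == scores[0]):
        raise ValueError(
            "degenerate score distribution (all self scores equal); "
            "use a fixed threshold instead"
        )
    k = int(np.floor(target_specificity * n))
    if k == 0:
        # target below 1/N resolution: no threshold presents a non-empty,
        # small-enough fraction; report a cutoff below the minimum score
        return float(np.min(scores)) - 1.0, 0.0
    threshold = float(np.sort(scores, kind="stable")[k - 1])
    achieved = float(np.count_nonzero(scores <= threshold) / n)
    return threshold, achieved


def _scores_array(model: BindingModel, peptides: list[str]) -> np.ndarray:
    if hasattr(model, "score_many"):
        return np.asarray(model.score_many(peptides), dtype=float)
    return np.array([model.score(p) for p in peptides], dtype=float)


def presented_set(
    model: BindingModel,
    peptides: Iterable[str],
    threshold_spec: ThresholdSpec | float = ThresholdSpec(),
    processing: ProcessingModel | None = None,
    self_peptides: Iterable[str] | None = None,
    species_id: str = "",
    kingdom: str = "self",
) -> PresentedSet:
    """Filter peptides to those presented by ``model``.

    A peptide is presented when the processing stage passes it and its
    predicted IC50 is <= the threshold (inclusive: a score exactly at
    500 nM counts as a binder).  In scaled mode the threshold is calibrated
    on ``self_peptides`` (or on ``peptides`` themselves when screening
    self).
    """
    peps = sorted(set(peptides))
    if any(len(p) != 9 for p in peps):
        raise ValueError("presented_set operates on 9mers")
    processing = processing or PassThroughProcessing()
    achieved: float | None = None
    if isinstance(threshold_spec, (int, float)):
        threshold = float(threshold_spec)
    elif threshold_spec.mode == "fixed":
        threshold = threshold_spec.fixed_value
    else:
        calibration_set = list(self_peptides) if self_peptides is not None else peps
        threshold, achieved = calibrate_scaled_threshold(
            model, calibration_set, threshold_spec.target_specificity
        )
    passed = [p for p in peps if processing.passes(p)]
    scores = _scores_array(model, passed)
    kept = {p for p, s in zip(passed, scores) if s <= threshold}
    return PresentedSet(
        allele_name=model.allele_name,
        threshold_nm=threshold,
        peptides=kept,
        species_id=species_id,
        kingdom=kingdom,
        achieved_specificity=achieved,
    )
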