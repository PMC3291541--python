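"""Self/nonself overlap enumeration across proteomes.

The overlap of a recognition model is the chance that a randomly chosen
nonself peptide is indistinguishable (to a T-cell behaving per the model)
from at least one self peptide.  Fractions are pooled per kingdom — total
overlapping nonself peptides divided by total nonself peptides over all
species of that kingdom — and the headline number is the unweighted mean of
the viral and bacterial pooled fractions.

Degenerate overlaps are computed with a key index: self peptides are keyed
by their recognised-position projection, and each nonself peptide probes the
index with its enumerated recognition keys (~25 probes under the default
PMBEC-style rule), which scales linearly instead of all-pairs.
"""

from __future__ import annotations

import logging
import random
from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd

from .peptidome import (
    PeptideSet,
    ProteinRecord,
    ProteomeSet,
    extract_kmers,
    iter_kmers,
    shuffle_records,
)
from .recognition import (
    RecognitionModel,
    SimilarityScoreSpec,
    peptide_similarity_score,
)

logger = logging.getLogger(__name__)


@dataclass
class SpeciesOverlap:
    species_id: str
    kingdom: str
    n_peptides: int
    n_overlapping: int

    @property
    def fraction(self) -> float:
        return self.n_overlapping / self.n_peptides if self.n_peptides else float("nan")


@dataclass
class OverlapResult:
    """Per-species counts plus pooled and kingdom-averaged fractions."""

    allele: str
    model: str
    species: list[SpeciesOverlap]

    def pooled_fraction(self, kingdom: str) -> float:
        n = sum(s.n_peptides for s in self.species if s.kingdom == kingdom)
        o = sum(s.n_overlapping for s in self.species if s.kingdom == kingdom)
        return o / n if n else float("nan")

    @property
    def kingdom_average(self) -> float:
        """Unweighted mean of the viral and bacterial pooled fractions
        (falls back to whichever kingdoms are present)."""
        fracs = []
        for kingdom in ("virus", "bacterium"):
            n = sum(s.n_peptides for s in self.species if s.kingdom == kingdom)
            if n:
                fracs.append(self.pooled_fraction(kingdom))
        if not fracs:
            return float("nan")
        return sum(fracs) / len(fracs)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "species": s.species_id,
                    "kingdom": s.kingdom,
                    "n_peptides": s.n_peptides,
                    "n_overlap": s.n_overlapping,
                    "fraction": s.fraction,
                }
                for s in self.species
            ]
        )


class SelfIndex:
    """Self peptides keyed by recognised-position projection."""

    def __init__(self, self_peptides: Iterable[str], model: RecognitionModel):
        self.model = model
        self.projections = {model.project(p) for p in self_peptides}

    def overlaps(self, nonself_peptide: str) -> bool:
        keys = self.model.enumerate_recognized_keys(nonself_peptide)
        return not keys.isdisjoint(self.projections)


def count_overlaps(
    nonself_peptides: Iterable[str], self_peptides: set[str], model: RecognitionModel
) -> int:
    index = SelfIndex(self_peptides, model)
    return sum(1 for p in nonself_peptides if index.overlaps(p))


def count_overlaps_bruteforce(
    nonself_peptides: Iterable[str], self_peptides: set[str], model: RecognitionModel
) -> int:
    """All-pairs oracle for the key-index computation (O(n*m))."""
    selfs = list(self_peptides)
    return sum(
        1
        for p in nonself_peptides
        if any(model.is_recognized(p, s) for s in selfs)
    )


def count_overlaps_simscore(
    nonself_peptides: Iterable[str], self_peptides: set[str], spec: SimilarityScoreSpec
) -> int:
    """Overlaps under the min-max-scaled peptide similarity score.

    A nonself peptide overlaps when its similarity score with some self
    peptide exceeds the threshold; the nonself peptide is the reference of
    the scaling.  All-pairs — use on presented (not whole-proteome) sets.
    """
    selfs = list(self_peptides)
    n = 0
    for pep in nonself_peptides:
        for s in selfs:
            if peptide_similarity_score(s, pep, spec.matrix) > spec.threshold:
                n += 1
                break
    return n


def overlap_fraction(
    nonself_sets: Sequence[PeptideSet],
    self_set: PeptideSet | set[str],
    model: RecognitionModel,
    allele: str = "no-MHC",
) -> OverlapResult:
    """Overlap of each nonself peptide set with self, under one model."""
    self_peptides = self_set.peptides if isinstance(self_set, PeptideSet) else self_set
    if not self_peptides:
        logger.warning("empty self set: all overlap fractions are 0")
    index = SelfIndex(self_peptides, model)
    species = []
    for ns in nonself_sets:
        n_overlap = sum(1 for p in ns.peptides if index.overlaps(p))
        species.append(
            SpeciesOverlap(
                species_id=ns.species_id,
                kingdom=ns.kingdom,
                n_peptides=len(ns.peptides),
                n_overlapping=n_overlap,
            )
        )
    return OverlapResult(allele=allele, model=model.name, species=species)


def subsample_self(
    records: Sequence[ProteinRecord], fraction: float, seed: int
) -> list[ProteinRecord]:
    """Uniformly subsample self proteins (the "50% of self" analysis)."""
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0,1]")
    rng = random.Random(seed)
    n = max(1, round(fraction * len(records)))
    return rng.sample(list(records), n)


def length_scan(
    self_records: Sequence[ProteinRecord],
    nonself_proteomes: Sequence[ProteomeSet],
    k_range: Iterable[int] = range(1, 21),
    shuffle_seed: int | None = 0,
) -> pd.DataFrame:
    """Exact full-length overlap of nonself k-mers with self, per length k.

    Returns a tidy frame with one row per (k, kingdom, control) where
    ``control`` is False for the real proteomes and True for the
    within-protein shuffled versions.  Lengths with no nonself window are
    reported absent (no row).
    """
    k_range = sorted(set(k_range))
    if any(k < 1 or k > 20 for k in k_range):
        raise ValueError("k_range must lie within [1, 20]")
    variants: list[tuple[bool, Sequence[ProteomeSet]]] = [(False, nonself_proteomes)]
    if shuffle_seed is not None:
        shuffled = [
            ProteomeSet(
                species_id=p.species_id,
                kingdom=p.kingdom,
                records=shuffle_records(p.records, seed=shuffle_seed + i),
            )
            for i, p in enumerate(nonself_proteomes)
        ]
        variants.append((True, shuffled))
    rows = []
    for k in k_range:
        self_kmers = extract_kmers(self_records, k).peptides
        for control, proteomes in variants:
            per_kingdom: dict[str, list[int]] = {}
            for prot in proteomes:
                kmers = extract_kmers(prot, k).peptides
                n_total = len(kmers)
                n_overlap = len(kmers & self_kmers)
                per_kingdom.setdefault(prot.kingdom, [0, 0])
                per_kingdom[prot.kingdom][0] += n_total
                per_kingdom[prot.kingdom][1] += n_overlap
            for kingdom, (n_total, n_overlap) in per_kingdom.items():
                if n_total == 0:
                    continue  # undefined: no nonself window of this length
                rows.append(
                    {
                        "k": k,
                        "kingdom": kingdom,
                        "control": control,
                        "n_peptides": n_total,
                        "n_overlap": n_overlap,
                        "fraction": n_overlap / n_total,
                    }
                )
    return pd.DataFrame(rows)


@dataclass
class PerProteinOverlapCount:
    """How many pathogen species share >=1 9mer with one self protein."""

    protein_id: str
    length: int
    n_species_overlapping: int


def per_protein_species_counts(
    self_records: Sequence[ProteinRecord],
    nonself_proteomes: Sequence[ProteomeSet],
    k: int = 9,
) -> list[PerProteinOverlapCount]:
    """Per self protein, the number of species with an identical k-mer."""
    species_kmers = [extract_kmers(p, k).peptides for p in nonself_proteomes]
    counts = []
    for rec in self_records:
        protein_kmers = set(iter_kmers(rec.sequence, k))
        n = sum(1 for kmers in species_kmers if not protein_kmers.isdisjoint(kmers))
        counts.append(
            PerProteinOverlapCount(
                protein_id=rec.id, length=len(rec.sequence), n_species_overlapping=n
            )
        )
    return counts
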