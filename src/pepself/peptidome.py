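"""Proteome reading, k-mer peptide extraction and proteome-level utilities.

A "peptidome" here is the set of unique length-k windows (k-mers) over a
proteome.  Proteins are kept whole even when they contain ambiguous residues
(X, B, Z, U or stop characters): any k-mer window touching such a residue is
simply excluded from the peptide set, mirroring how presentation predictors
treat ambiguous positions.
"""

from __future__ import annotations

import logging
import random
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO

logger = logging.getLogger(__name__)

#: The 20 canonical amino-acid one-letter codes, alphabetical.
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
_CANONICAL = frozenset(AMINO_ACIDS)

#: Residue codes tolerated in input sequences but excluded from k-mers.
AMBIGUOUS = frozenset("XBZUJO*")

KINGDOMS = ("self", "virus", "bacterium")


@dataclass(frozen=True)
class ProteinRecord:
    """A single protein sequence with its provenance."""

    id: str
    sequence: str
    species_id: str = ""
    kingdom: str = "self"

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"protein {self.id!r}: empty sequence")
        bad = set(self.sequence) - _CANONICAL - AMBIGUOUS
        if bad:
            raise ValueError(
                f"protein {self.id!r}: non amino-acid characters {sorted(bad)!r}"
            )
        if self.kingdom not in KINGDOMS:
            raise ValueError(f"unknown kingdom {self.kingdom!r}")


@dataclass
class ProteomeSet:
    """All proteins of one species."""

    species_id: str
    kingdom: str
    records: list[ProteinRecord]

    def __post_init__(self) -> None:
        if not self.records:
            raise ValueError(f"proteome {self.species_id!r} has no records")

    def __len__(self) -> int:
        return len(self.records)


@dataclass
class PeptideSet:
    """Unique k-mers from one source (species + kingdom)."""

    k: int
    peptides: set[str]
    species_id: str = ""
    kingdom: str = "self"

    def __post_init__(self) -> None:
        if any(len(p) != self.k for p in self.peptides):
            raise ValueError("peptide length inconsistent with k")

    def __len__(self) -> int:
        return len(self.peptides)

    def __contains__(self, peptide: str) -> bool:
        return peptide in self.peptides


def read_fasta(
    path: str | Path, species_id: str = "", kingdom: str = "self"
) -> list[ProteinRecord]:
    """Read a protein FASTA file into :class:`ProteinRecord` objects.

    Sequences are uppercased; records whose sequence is empty after
    sanitization are dropped with a warning.  Ambiguous residues are kept
    (downstream k-mer extraction skips windows containing them).
    """
    path = Path(path)
    records: list[ProteinRecord] = []
    for entry in SeqIO.parse(str(path), "fasta"):
        seq = str(entry.seq).upper().replace(" ", "").replace("-", "")
        if not seq:
            logger.warning("dropping empty-sequence FASTA entry %r", entry.id)
            continue
        bad = set(seq) - _CANONICAL - AMBIGUOUS
        if bad:
            raise ValueError(
                f"FASTA entry {entry.id!r}: unexpected characters {sorted(bad)!r}"
            )
        records.append(
            ProteinRecord(id=entry.id, sequence=seq, species_id=species_id, kingdom=kingdom)
        )
    if not records:
        raise ValueError(f"no FASTA records in {path}")
    return records


def write_fasta(records: Iterable[ProteinRecord], path: str | Path) -> None:
    """Write records as plain FASTA (60-column wrapped)."""
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.sequence), 60):
                fh.write(rec.sequence[i : i + 60] + "\n")


def iter_kmers(sequence: str, k: int) -> Iterable[str]:
    """Yield canonical-only k-mer windows of a single sequence (stride 1)."""
    # track the most recent ambiguous residue so windows overlapping it skip fast
    last_bad = -1
    for i, ch in enumerate(sequence):
        if ch not in _CANONICAL:
            last_bad = i
        if i >= k - 1 and last_bad <= i - k:
            yield sequence[i - k + 1 : i + 1]


def extract_kmers(
    records: Iterable[ProteinRecord] | ProteomeSet,
    k: int,
    species_id: str | None = None,
    kingdom: str | None = None,
) -> PeptideSet:
    """Unique set of all length-``k`` windows over the given proteins.

    Windows containing non-canonical residues are excluded.  ``k`` larger
    than every sequence yields an empty set.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if isinstance(records, ProteomeSet):
        if species_id is None:
            species_id = records.species_id
        if kingdom is None:
            kingdom = records.kingdom
        records = records.records
    records = list(records)
    if species_id is None:
        species_id = records[0].species_id if records else ""
    if kingdom is None:
        kingdom = records[0].kingdom if records else "self"
    peptides: set[str] = set()
    for rec in records:
        peptides.update(iter_kmers(rec.sequence, k))
    return PeptideSet(k=k, peptides=peptides, species_id=species_id, kingdom=kingdom)


def shuffle_records(
    records: Iterable[ProteinRecord], seed: int
) -> list[ProteinRecord]:
    """Permute the residues of every protein independently (composition kept).

    Used as the shuffled control: within-protein permutation destroys
    homology-driven k-mer sharing while conserving amino-acid composition.
    Deterministic for a given seed.
    """
    rng = random.Random(seed)
    out = []
    for rec in records:
        letters = list(rec.sequence)
        rng.shuffle(letters)
        out.append(
            ProteinRecord(
                id=rec.id,
                sequence="".join(letters),
                species_id=rec.species_id,
                kingdom=rec.kingdom,
            )
        )
    return out


def kmer_sharing(a: set[str], b: set[str]) -> float:
    """Shared unique-k-mer fraction, relative to the smaller set."""
    if not a or not b:
        return 0.0
    return len(a & b) / min(len(a), len(b))


def reduce_redundancy(
    proteomes: Sequence[ProteomeSet], max_similarity: float = 0.8, k: int = 9
) -> list[ProteomeSet]:
    """Greedy redundancy reduction between proteomes.

    Proteomes are visited in order of decreasing size (total residues); a
    candidate is discarded when its shared unique-9mer fraction — normalised
    by the smaller proteome of the pair — exceeds ``max_similarity`` against
    any proteome already retained.
    """
    if not 0 < max_similarity <= 1:
        raise ValueError("max_similarity must be in (0, 1]")
    proteomes = list(proteomes)
    if not proteomes:
        raise ValueError("no proteomes given")
    sized = sorted(
        proteomes,
        key=lambda p: (-sum(len(r.sequence) for r in p.records), p.species_id),
    )
    kept: list[ProteomeSet] = []
    kept_kmers: list[set[str]] = []
    for prot in sized:
        kmers = extract_kmers(prot, k).peptides
        if any(kmer_sharing(kmers, other) > max_similarity for other in kept_kmers):
            logger.info("discarding redundant proteome %s", prot.species_id)
            continue
        kept.append(prot)
        kept_kmers.append(kmers)
    return kept


def write_peptides(peptides: Iterable[str], path: str | Path) -> None:
    """One peptide per line, sorted for reproducibility."""
    with open(path, "w") as fh:
        for pep in sorted(peptides):
            fh.write(pep + "\n")


def read_peptides(path: str | Path, k: int | None = None) -> set[str]:
    """Read a one-peptide-per-line file; optionally enforce a uniform length."""
    peptides = set()
    with open(path) as fh:
        for line in fh:
            pep = line.strip().upper()
            if not pep:
                continue
            if k is not None and len(pep) != k:
                raise ValueError(f"peptide {pep!r} does not have length {k}")
            peptides.add(pep)
    return peptides
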