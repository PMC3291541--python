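"""Synthetic inputs with known ground truth.

Generates every input the pipeline consumes: host/pathogen proteome pairs
with a planted shared-9mer (homology) rate, allele binding motifs with
anchor positions, immunogenicity labels with a planted dependence on
self-overlap, substitution matrices whose thresholded similarity rule has a
controlled mean set size, and toy pMHC-TCR structures with hand-placed
contact geometry.  All generators are deterministic under their seed and
emit their ground-truth parameters alongside the data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import gemmi
import numpy as np
import pandas as pd

from .peptidome import AMINO_ACIDS, ProteinRecord, ProteomeSet
from .presentation import MotifBindingModel
from .recognition import SubstitutionMatrix

_UNIFORM = np.full(20, 1 / 20)


def _random_sequence(rng: np.random.Generator, length: int, aa_freqs: np.ndarray) -> str:
    idx = rng.choice(20, size=length, p=aa_freqs)
    return "".join(AMINO_ACIDS[i] for i in idx)


@dataclass
class SyntheticProteomes:
    """A self proteome, nonself proteomes, and where homology was planted."""

    self_proteome: ProteomeSet
    nonself_proteomes: list[ProteomeSet]
    #: species_id -> protein id -> (start, length) of the planted self chunk
    planted: dict[str, dict[str, tuple[int, int]]]
    shared_kmer_rate: float


def make_proteomes(
    n_self_proteins: int = 100,
    n_species: int = 10,
    protein_length_range: tuple[int, int] = (200, 500),
    aa_freqs: Sequence[float] | None = None,
    shared_kmer_rate: float = 0.0,
    n_proteins_per_species: int = 10,
    kingdoms: Sequence[str] = ("virus", "bacterium"),
    nonself_length_range: tuple[int, int] | None = None,
    seed: int = 0,
) -> SyntheticProteomes:
    """Host + pathogen proteomes with a planted shared-9mer rate.

    Background residues are i.i.d. from ``aa_freqs`` (uniform by default).
    Homology is planted by overwriting, in each nonself protein, one
    contiguous chunk with a copy of a self subsequence sized so that the
    fraction of the protein's 9mer windows lying inside the chunk equals
    ``shared_kmer_rate`` (rate 1 copies the whole protein, which therefore
    must be no longer than the longest self protein).  Nonself species
    alternate between the given kingdoms.
    """
    if not 0 <= shared_kmer_rate <= 1:
        raise ValueError("shared_kmer_rate must be in [0,1]")
    rng = np.random.default_rng(seed)
    freqs = _UNIFORM if aa_freqs is None else np.asarray(aa_freqs, dtype=float)
    if freqs.shape != (20,) or not math.isclose(freqs.sum(), 1.0, rel_tol=1e-6):
        raise ValueError("aa_freqs must be 20 probabilities summing to 1")
    lo, hi = protein_length_range
    ns_lo, ns_hi = nonself_length_range or protein_length_range
    if lo < 9 or ns_lo < 9:
        raise ValueError("proteins must be at least 9 residues long")

    self_records = [
        ProteinRecord(
            id=f"self_{i:04d}",
            sequence=_random_sequence(rng, int(rng.integers(lo, hi + 1)), freqs),
            species_id="self",
            kingdom="self",
        )
        for i in range(n_self_proteins)
    ]
    max_self_len = max(len(r.sequence) for r in self_records)

    nonself: list[ProteomeSet] = []
    planted: dict[str, dict[str, tuple[int, int]]] = {}
    for s in range(n_species):
        kingdom = kingdoms[s % len(kingdoms)]
        species_id = f"{kingdom}_{s:03d}"
        records = []
        planted[species_id] = {}
        for j in range(n_proteins_per_species):
            length = int(rng.integers(ns_lo, ns_hi + 1))
            seq = _random_sequence(rng, length, freqs)
            if shared_kmer_rate > 0:
                n_windows = length - 8
                chunk = int(round(shared_kmer_rate * n_windows)) + 8
                if chunk < 9:
                    chunk = 0  # rate too small to plant a single 9mer here
                if chunk > length:
                    chunk = length
                if chunk:
                    if chunk > max_self_len:
                        raise ValueError(
                            f"shared_kmer_rate {shared_kmer_rate} needs a planted chunk of "
                            f"{chunk} residues but the longest self protein has {max_self_len}"
                        )
                    donor = self_records[int(rng.integers(0, n_self_proteins))]
                    while len(donor.sequence) < chunk:
                        donor = self_records[int(rng.integers(0, n_self_proteins))]
                    src = int(rng.integers(0, len(donor.sequence) - chunk + 1))
                    dst = int(rng.integers(0, length - chunk + 1))
                    seq = seq[:dst] + donor.sequence[src : src + chunk] + seq[dst + chunk :]
                    planted[species_id][f"{species_id}_p{j:03d}"] = (dst, chunk)
            records.append(
                ProteinRecord(
                    id=f"{species_id}_p{j:03d}",
                    sequence=seq,
                    species_id=species_id,
                    kingdom=kingdom,
                )
            )
        nonself.append(ProteomeSet(species_id=species_id, kingdom=kingdom, records=records))
    return SyntheticProteomes(
        self_proteome=ProteomeSet(species_id="self", kingdom="self", records=self_records),
        nonself_proteomes=nonself,
        planted=planted,
        shared_kmer_rate=shared_kmer_rate,
    )


def chance_overlap_probability(n_self_kmers: int, k: int = 9) -> float:
    """Chance that one random k-mer occurs in a set of n random self k-mers:
    1 - (1 - 20^-k)^n."""
    return 1.0 - (1.0 - 20.0**-k) ** n_self_kmers


def make_allele(
    name: str = "SYN-A01",
    anchor_positions: Sequence[int] = (2, 9),
    anchor_strength: float = 2.0,
    background_sd: float = 0.05,
    median_ic50_nm: float = 5000.0,
    seed: int = 0,
) -> MotifBindingModel:
    """A motif binding model with strong residue preferences at anchors.

    Weights are additive log-IC50 contributions: anchors draw per-residue
    weights from N(0, anchor_strength), other positions from
    N(0, background_sd); a constant offset sets the median predicted IC50.
    Stronger anchors concentrate the presented set on few residues there,
    yielding the low anchor entropy real alleles show.
    """
    if any(p < 1 or p > 9 for p in anchor_positions):
        raise ValueError("anchor positions must be in P1..P9")
    rng = np.random.default_rng(seed)
    weights = rng.normal(0.0, background_sd, size=(9, 20))
    for p in anchor_positions:
        weights[p - 1] = rng.normal(0.0, anchor_strength, size=20)
    weights -= weights.mean(axis=1, keepdims=True)
    weights += math.log(median_ic50_nm) / 9
    return MotifBindingModel(allele_name=name, weights=weights)


def random_peptides(n: int, k: int = 9, seed: int = 0,
                    aa_freqs: Sequence[float] | None = None) -> list[str]:
    """n random k-mers with i.i.d. residues (uniform by default)."""
    rng = np.random.default_rng(seed)
    freqs = _UNIFORM if aa_freqs is None else np.asarray(aa_freqs, dtype=float)
    idx = rng.choice(20, size=(n, k), p=freqs)
    return ["".join(AMINO_ACIDS[i] for i in row) for row in idx]


def make_immunogenicity_labels(
    peptides: Sequence[str],
    self_overlap_flags: Sequence[bool],
    base_rate: float = 0.25,
    odds_ratio: float = 3.5,
    allele: str = "SYN-A01",
    seed: int = 0,
) -> pd.DataFrame:
    """Assay outcomes with a planted overlap -> immunogenicity effect.

    Immunogenicity is Bernoulli with log-odds logit(base_rate) +
    log(odds_ratio) * (1 - overlap_flag): overlapping peptides stay at the
    base rate while non-overlapping ones are ``odds_ratio`` times more
    likely (in odds) to be immunogenic — the direction in which
    self-tolerance censors responses.  Returns a frame with columns
    peptide, allele, assay_outcome, overlap (ground truth).
    """
    if odds_ratio <= 0:
        raise ValueError("odds_ratio must be > 0")
    if not 0 <= base_rate <= 1:
        raise ValueError("base_rate must be in [0,1]")
    if len(peptides) != len(self_overlap_flags):
        raise ValueError("peptides and flags must align")
    rng = np.random.default_rng(seed)
    rows = []
    for pep, flag in zip(peptides, self_overlap_flags):
        if base_rate in (0.0, 1.0):
            p = base_rate
        else:
            logodds = math.log(base_rate / (1 - base_rate)) + math.log(odds_ratio) * (
                1 - bool(flag)
            )
            p = 1 / (1 + math.exp(-logodds))
        immunogenic = rng.random() < p
        rows.append(
            {
                "peptide": pep,
                "allele": allele,
                "assay_outcome": "Positive" if immunogenic else "Negative",
                "overlap": bool(flag),
            }
        )
    return pd.DataFrame(rows)


def make_similarity_matrix(
    mean_similar_partners: float, seed: int = 0, cutoff: float = 0.05
) -> SubstitutionMatrix:
    """A symmetric covariance-style matrix with a controlled similarity rule.

    Randomly selects round(mean * 20 / 2) unordered residue pairs and gives
    them |value| > cutoff (others below), so the ``abs_covariance_gt``
    rule at ``cutoff`` has mean similar-set size within 0.1 of the closest
    achievable value (multiples of 0.1; always within the ±0.2 calibration
    band of the request).
    """
    if not 0 <= mean_similar_partners <= 19:
        raise ValueError("mean_similar_partners must be in [0,19]")
    rng = np.random.default_rng(seed)
    n_pairs = int(round(mean_similar_partners * 20 / 2))
    pairs = [(i, j) for i in range(20) for j in range(i + 1, 20)]
    chosen = rng.choice(len(pairs), size=n_pairs, replace=False) if n_pairs else []
    mat = rng.uniform(-cutoff * 0.8, cutoff * 0.8, size=(20, 20))
    mat = (mat + mat.T) / 2
    np.fill_diagonal(mat, 1.0)
    for idx in chosen:
        i, j = pairs[int(idx)]
        v = rng.uniform(cutoff * 1.2, cutoff * 10) * (1 if rng.random() < 0.5 else -1)
        mat[i, j] = mat[j, i] = v
    return SubstitutionMatrix(name=f"synthetic-{mean_similar_partners:g}", values=mat)


# ---------------------------------------------------------------------------
# Toy pMHC-TCR structures
# ---------------------------------------------------------------------------

#: spacing of peptide residues along x, wide enough that a TCR residue
#: placed near one peptide position cannot also contact its neighbours
_PEPTIDE_SPACING = 12.0


@dataclass(frozen=True)
class ContactSpec:
    """One requested contact: n TCR residues at a distance from a position."""

    position: int  # 1-based peptide position
    n_residues: int
    distance: float

    def __post_init__(self) -> None:
        if not 1 <= self.position <= 9:
            raise ValueError("position must be in P1..P9")
        if self.n_residues < 1:
            raise ValueError("n_residues must be >= 1")
        if self.distance <= 0:
            raise ValueError("distance must be positive")


def make_toy_structure(
    contact_spec: Sequence[ContactSpec | tuple[int, int, float]],
    path: str | Path,
    seed: int = 0,
) -> Path:
    """Write a minimal PDB with a 9-residue peptide and a TCR chain.

    Peptide chain ``P`` holds 9 glycine CA atoms spaced 12 Å apart on the
    x-axis; TCR chain ``T`` holds one CA atom per requested contact, placed
    at exactly the requested distance from the target peptide position in
    the y-z plane (so it stays > 10 Å from every other peptide residue).
    Distances are realised exactly: a residue asked for at 5.0 Å is *not*
    within a strict 5.0 Å cutoff.
    """
    specs = [c if isinstance(c, ContactSpec) else ContactSpec(*c) for c in contact_spec]
    if any(s.distance >= _PEPTIDE_SPACING / 2 for s in specs):
        raise ValueError(
            f"contact distances must be < {_PEPTIDE_SPACING / 2} to keep the "
            "geometry unambiguous"
        )
    st = gemmi.Structure()
    st.name = "toy-pmhc-tcr"
    model = gemmi.Model("1")

    pep_chain = gemmi.Chain("P")
    for i in range(9):
        res = gemmi.Residue()
        res.name = "GLY"
        res.seqid = gemmi.SeqId(i + 1, " ")
        atom = gemmi.Atom()
        atom.name = "CA"
        atom.element = gemmi.Element("C")
        atom.occ = 1.0
        atom.pos = gemmi.Position(i * _PEPTIDE_SPACING, 0.0, 0.0)
        res.add_atom(atom)
        pep_chain.add_residue(res)
    model.add_chain(pep_chain)

    tcr_chain = gemmi.Chain("T")
    res_no = 0
    for spec in specs:
        for j in range(spec.n_residues):
            res_no += 1
            theta = j * (math.pi / max(spec.n_residues, 2)) / 2  # fan out in y-z
            y = spec.distance * math.sin(theta)
            z = spec.distance * math.cos(theta)
            res = gemmi.Residue()
            res.name = "ALA"
            res.seqid = gemmi.SeqId(res_no, " ")
            atom = gemmi.Atom()
            atom.name = "CA"
            atom.element = gemmi.Element("C")
            atom.occ = 1.0
            atom.pos = gemmi.Position((spec.position - 1) * _PEPTIDE_SPACING, y, z)
            res.add_atom(atom)
            tcr_chain.add_residue(res)
    if res_no == 0:  # keep the chain valid even with no requested contacts
        res = gemmi.Residue()
        res.name = "ALA"
        res.seqid = gemmi.SeqId(1, " ")
        atom = gemmi.Atom()
        atom.name = "CA"
        atom.element = gemmi.Element("C")
        atom.occ = 1.0
        atom.pos = gemmi.Position(0.0, 0.0, 100.0)
        res.add_atom(atom)
        tcr_chain.add_residue(res)
    model.add_chain(tcr_chain)

    st.add_model(model)
    st.setup_entities()
    path = Path(path)
    st.write_pdb(str(path))
    return path
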