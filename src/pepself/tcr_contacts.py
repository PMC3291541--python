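"""TCR contacts with presented peptides from pMHC-TCR crystal structures.

For each position of the 9mer in the MHC groove, the number of TCR residues
with at least one non-hydrogen atom strictly within a distance cutoff
(5.0 Å by default) of any non-hydrogen atom of that peptide residue is
counted, and normalised per structure to fractions of the total
peptide-TCR contacts.  Chain assignment is explicit via an annotation, not
guessed; a helper suggests the length-9 chain.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import gemmi
import numpy as np
from scipy import stats as sps

logger = logging.getLogger(__name__)

DEFAULT_CUTOFF = 5.0


@dataclass(frozen=True)
class StructureAnnotation:
    """Which chains are the peptide, the TCR and the MHC in one structure."""

    structure_id: str
    peptide_chain: str
    tcr_chains: tuple[str, ...]
    mhc_chains: tuple[str, ...] = ()


@dataclass(frozen=True)
class ContactProfile:
    """Per-position TCR contact counts and per-structure fractions."""

    structure_id: str
    counts: tuple[int, ...]  # P1..P9

    def __post_init__(self) -> None:
        if len(self.counts) != 9:
            raise ValueError("profile must cover P1..P9")
        if any(c < 0 for c in self.counts):
            raise ValueError("counts must be >= 0")

    @property
    def total(self) -> int:
        return sum(self.counts)

    @property
    def fractions(self) -> tuple[float, ...]:
        total = self.total
        if total == 0:
            return (0.0,) * 9
        return tuple(c / total for c in self.counts)


def _residue_heavy_atoms(residue: gemmi.Residue) -> list[gemmi.Atom]:
    """Non-hydrogen atoms, highest-occupancy conformer only for altlocs."""
    by_name: dict[str, gemmi.Atom] = {}
    for atom in residue:
        if atom.is_hydrogen():
            continue
        prev = by_name.get(atom.name)
        if prev is None or atom.occ > prev.occ:
            by_name[atom.name] = atom
    return list(by_name.values())


def _chain_or_error(model: gemmi.Model, name: str, structure_id: str) -> gemmi.Chain:
    for chain in model:
        if chain.name == name:
            return chain
    raise ValueError(f"structure {structure_id}: chain {name!r} not found")


def suggest_peptide_chain(path: str | Path) -> str | None:
    """Name of a chain with exactly 9 amino-acid residues, if unique."""
    structure = gemmi.read_structure(str(path))
    structure.setup_entities()
    candidates = [
        chain.name
        for chain in structure[0]
        if sum(1 for r in chain if gemmi.find_tabulated_residue(r.name)
               and gemmi.find_tabulated_residue(r.name).is_amino_acid()) == 9
    ]
    return candidates[0] if len(candidates) == 1 else None


def count_contacts(
    path: str | Path,
    annotation: StructureAnnotation,
    cutoff: float = DEFAULT_CUTOFF,
) -> ContactProfile:
    """Count TCR residues strictly within ``cutoff`` Å of each peptide position.

    A TCR residue counts for a peptide position when any of its heavy atoms
    lies < cutoff from any heavy atom of that peptide residue.  The peptide
    chain must contain exactly 9 residues.
    """
    structure = gemmi.read_structure(str(path))
    model = structure[0]
    pep_chain = _chain_or_error(model, annotation.peptide_chain, annotation.structure_id)
    pep_residues = list(pep_chain)
    if len(pep_residues) != 9:
        raise ValueError(
            f"structure {annotation.structure_id}: peptide chain "
            f"{annotation.peptide_chain!r} has {len(pep_residues)} residues, expected 9"
        )
    tcr_residues: list[gemmi.Residue] = []
    for chain_name in annotation.tcr_chains:
        tcr_residues.extend(_chain_or_error(model, chain_name, annotation.structure_id))

    pep_atoms = [
        np.array([[a.pos.x, a.pos.y, a.pos.z] for a in _residue_heavy_atoms(res)])
        for res in pep_residues
    ]
    counts = [0] * 9
    for tcr_res in tcr_residues:
        atoms = _residue_heavy_atoms(tcr_res)
        if not atoms:
            continue
        coords = np.array([[a.pos.x, a.pos.y, a.pos.z] for a in atoms])
        for i, pa in enumerate(pep_atoms):
            if pa.size == 0:
                continue
            d2 = ((coords[:, None, :] - pa[None, :, :]) ** 2).sum(axis=2)
            if (d2 < cutoff**2).any():
                counts[i] += 1
    profile = ContactProfile(structure_id=annotation.structure_id, counts=tuple(counts))
    if profile.total == 0:
        warnings.warn(
            f"structure {annotation.structure_id}: no peptide-TCR contact within "
            f"{cutoff} Å; fractions reported as zeros",
            stacklevel=2,
        )
    return profile


def compare_position_groups(
    profiles: Sequence[ContactProfile],
    group_a_positions: Sequence[int],
    group_b_positions: Sequence[int],
) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sums test on pooled per-structure contact
    fractions of two position groups (e.g. P4-8 vs P1-3 + P9)."""
    if len(profiles) < 2:
        raise ValueError("need at least two structures")
    if not group_a_positions or not group_b_positions:
        raise ValueError("position groups must be non-empty")
    a = [p.fractions[pos - 1] for p in profiles for pos in group_a_positions]
    b = [p.fractions[pos - 1] for p in profiles for pos in group_b_positions]
    res = sps.ranksums(a, b)
    return float(res.statistic), float(res.pvalue)
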