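"""Models of what "the same T-cell sees both peptides" means.

Three notions of overlap between a presented nonself peptide and a presented
self peptide are implemented:

* **exact position-mask overlap** — the two 9mers are identical on a chosen
  subset of positions (all of P1–P9, the TCR-exposed middle P3–P8, or the
  non-anchor positions P1 + P3–P8);
* **degenerate overlap** — the TCR is assumed to read only the middle
  positions, to demand identity at the most stringently recognised position
  P5, and to tolerate at most one conservative substitution in the region
  N-terminal of P5 and one in the region C-terminal of P5.  Conservative
  means the residue pair is linked by a :class:`SimilarityRule` derived from
  a substitution/covariance matrix (PMBEC-style absolute covariance > 0.05,
  or a positive BLOSUM score);
* **peptide similarity score** — a min–max-scaled substitution-matrix score
  over all positions; two peptides overlap when the score exceeds a
  threshold (0.85 by convention).

Positions are 1-based P1..P9 throughout the public API.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .peptidome import AMINO_ACIDS

_AA_INDEX = {aa: i for i, aa in enumerate(AMINO_ACIDS)}

#: Matrix names resolvable without a user-supplied file (via biopython).
BUNDLED_MATRICES = ("BLOSUM45", "BLOSUM50", "BLOSUM62", "BLOSUM80", "BLOSUM90")


@dataclass(frozen=True)
class SubstitutionMatrix:
    """A symmetric 20x20 amino-acid pair score/covariance table."""

    name: str
    values: np.ndarray  # shape (20, 20), indexed by AMINO_ACIDS order

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (20, 20):
            raise ValueError(f"matrix {self.name!r}: expected 20x20, got {v.shape}")
        if not np.allclose(v, v.T, atol=1e-9):
            raise ValueError(f"matrix {self.name!r} is not symmetric")
        object.__setattr__(self, "values", v)

    def score(self, a: str, b: str) -> float:
        return float(self.values[_AA_INDEX[a], _AA_INDEX[b]])


def load_matrix(path: str | Path, name: str | None = None) -> SubstitutionMatrix:
    """Read a whitespace-delimited 20x20 matrix file.

    Format: first non-comment row lists the 20 amino-acid letters; each of
    the following 20 rows holds an optional row label plus 20 numbers.
    This accepts PMBEC- and NCBI-BLOSUM-style text tables restricted to the
    canonical alphabet.
    """
    path = Path(path)
    rows: list[list[str]] = []
    for line in path.read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        rows.append(line.split())
    if not rows:
        raise ValueError(f"empty matrix file {path}")
    header = [t.upper() for t in rows[0]]
    if sorted(header) != sorted(AMINO_ACIDS):
        raise ValueError(
            f"matrix file {path}: header must list the 20 amino acids, got {header}"
        )
    if len(rows) != 21:
        raise ValueError(f"matrix file {path}: expected 20 data rows, got {len(rows) - 1}")
    order = header
    mat = np.zeros((20, 20))
    row_letters = []
    for r, toks in enumerate(rows[1:]):
        if len(toks) == 21:  # leading row label
            row_letters.append(toks[0].upper())
            toks = toks[1:]
        elif len(toks) == 20:
            row_letters.append(order[r])
        else:
            raise ValueError(f"matrix file {path}: row {r + 1} has {len(toks)} fields")
        for c, tok in enumerate(toks):
            mat[_AA_INDEX[row_letters[r]], _AA_INDEX[order[c]]] = float(tok)
    return SubstitutionMatrix(name=name or path.stem, values=mat)


def write_matrix(matrix: SubstitutionMatrix, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(" ".join(AMINO_ACIDS) + "\n")
        for i, aa in enumerate(AMINO_ACIDS):
            fh.write(aa + " " + " ".join(f"{v:g}" for v in matrix.values[i]) + "\n")


def bundled_matrix(name: str) -> SubstitutionMatrix:
    """A standard BLOSUM matrix restricted to the 20 canonical residues."""
    from Bio.Align import substitution_matrices

    loaded = substitution_matrices.load(name)
    mat = np.zeros((20, 20))
    for i, a in enumerate(AMINO_ACIDS):
        for j, b in enumerate(AMINO_ACIDS):
            mat[i, j] = loaded[a, b]
    return SubstitutionMatrix(name=name, values=mat)


def get_matrix(source: str | Path | SubstitutionMatrix) -> SubstitutionMatrix:
    """Resolve a matrix from an object, a bundled name, or a file path."""
    if isinstance(source, SubstitutionMatrix):
        return source
    if isinstance(source, str) and source.upper() in BUNDLED_MATRICES:
        return bundled_matrix(source.upper())
    return load_matrix(source)


# ---------------------------------------------------------------------------
# Similarity rules
# ---------------------------------------------------------------------------

RULE_KINDS = ("abs_covariance_gt", "value_gt", "positive_score")


@dataclass(frozen=True)
class SimilarityRule:
    """Per-residue sets of tolerated (conservative) substitutions.

    ``similar[a]`` is the set of residues b != a deemed interchangeable with
    a.  The relation is symmetric and irreflexive.
    """

    similar: Mapping[str, frozenset[str]]
    provenance: str = ""

    def __post_init__(self) -> None:
        sim = {aa: frozenset(self.similar.get(aa, ())) for aa in AMINO_ACIDS}
        for a in AMINO_ACIDS:
            if a in sim[a]:
                raise ValueError(f"residue {a} is in its own similar-set")
            for b in sim[a]:
                if a not in sim[b]:
                    raise ValueError(f"similarity rule not symmetric for ({a},{b})")
        object.__setattr__(self, "similar", sim)

    def __call__(self, a: str) -> frozenset[str]:
        return self.similar[a]

    def allows(self, a: str, b: str) -> bool:
        return b in self.similar[a]

    @property
    def mean_set_size(self) -> float:
        return float(np.mean([len(self.similar[a]) for a in AMINO_ACIDS]))

    @classmethod
    def empty(cls) -> "SimilarityRule":
        return cls(similar={aa: frozenset() for aa in AMINO_ACIDS}, provenance="empty")


def build_similarity_rule(
    matrix: SubstitutionMatrix, rule_kind: str, cutoff: float = 0.05
) -> SimilarityRule:
    """Derive a :class:`SimilarityRule` from a matrix.

    ``abs_covariance_gt``: |M(a,b)| > cutoff (the PMBEC convention);
    ``value_gt``: M(a,b) > cutoff; ``positive_score``: M(a,b) > 0 (the
    BLOSUM convention).  Diagonal entries never count.
    """
    if rule_kind not in RULE_KINDS:
        raise ValueError(f"rule_kind must be one of {RULE_KINDS}")
    sim: dict[str, set[str]] = {aa: set() for aa in AMINO_ACIDS}
    for a, b in itertools.combinations(AMINO_ACIDS, 2):
        v = matrix.score(a, b)
        if rule_kind == "abs_covariance_gt":
            hit = abs(v) > cutoff
        elif rule_kind == "value_gt":
            hit = v > cutoff
        else:
            hit = v > 0
        if hit:
            sim[a].add(b)
            sim[b].add(a)
    return SimilarityRule(
        similar={a: frozenset(s) for a, s in sim.items()},
        provenance=f"{matrix.name}:{rule_kind}:{cutoff:g}",
    )


# ---------------------------------------------------------------------------
# Recognition models
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class RecognitionModel:
    """Which peptide positions a T-cell reads, and how forgivingly.

    ``recognized_positions`` are 1-based positions the TCR reads;
    ``fixed_positions`` must match exactly; the remaining recognised
    positions are partitioned into ``regions``, each with a mismatch budget,
    and every tolerated mismatch must additionally be a conservative
    substitution under ``similarity_rule``.  An empty similarity rule makes
    the model an exact position-mask match.
    """

    recognized_positions: tuple[int, ...]
    fixed_positions: frozenset[int] = frozenset()
    regions: tuple[tuple[frozenset[int], int], ...] = ()
    similarity_rule: SimilarityRule = field(default_factory=SimilarityRule.empty)
    name: str = ""

    def __post_init__(self) -> None:
        rec = tuple(sorted(self.recognized_positions))
        object.__setattr__(self, "recognized_positions", rec)
        if not rec:
            raise ValueError("at least one recognized position required")
        if any(p < 1 or p > 9 for p in rec):
            raise ValueError("positions must be in P1..P9")
        if not self.fixed_positions <= set(rec):
            raise ValueError("fixed_positions must be recognized")
        free = set(rec) - self.fixed_positions
        covered: set[int] = set()
        for positions, budget in self.regions:
            if budget < 0:
                raise ValueError("mismatch budget must be >= 0")
            if positions & covered:
                raise ValueError("regions overlap")
            covered |= positions
        if covered != free:
            raise ValueError("regions must partition recognized minus fixed positions")

    # -- constructors ------------------------------------------------------

    @classmethod
    def exact(cls, positions: Sequence[int], name: str = "") -> "RecognitionModel":
        """Exact match on a position mask (e.g. complete P1-9, middle P3-8)."""
        pos = tuple(sorted(positions))
        return cls(
            recognized_positions=pos,
            fixed_positions=frozenset(pos),
            regions=(),
            name=name or f"exact-{'+'.join(map(str, pos))}",
        )

    @classmethod
    def complete(cls) -> "RecognitionModel":
        return cls.exact(range(1, 10), name="complete")

    @classmethod
    def middle(cls) -> "RecognitionModel":
        return cls.exact(range(3, 9), name="middle")

    @classmethod
    def nonanchor(cls) -> "RecognitionModel":
        return cls.exact((1, 3, 4, 5, 6, 7, 8), name="nonanchor")

    @classmethod
    def degenerate(
        cls, similarity_rule: SimilarityRule, name: str = "degenerate"
    ) -> "RecognitionModel":
        """The default degenerate model: P3-8 read, P5 fixed, one
        conservative mismatch allowed on each side of P5."""
        return cls(
            recognized_positions=tuple(range(3, 9)),
            fixed_positions=frozenset({5}),
            regions=(
                (frozenset({3, 4}), 1),
                (frozenset({6, 7, 8}), 1),
            ),
            similarity_rule=similarity_rule,
            name=name,
        )

    @classmethod
    def degenerate_adjacent(
        cls, similarity_rule: SimilarityRule
    ) -> "RecognitionModel":
        """Variant permitting the two mismatches to fall next to each other:
        one region {P3,P4,P6,P7,P8} with budget 2, P5 still fixed."""
        return cls(
            recognized_positions=tuple(range(3, 9)),
            fixed_positions=frozenset({5}),
            regions=((frozenset({3, 4, 6, 7, 8}), 2),),
            similarity_rule=similarity_rule,
            name="degenerate-adjacent",
        )

    @classmethod
    def allele_specific(
        cls, positions: Sequence[int], most_specific: int, similarity_rule: SimilarityRule
    ) -> "RecognitionModel":
        """Degenerate model over an allele's six least specific positions.

        ``most_specific`` (the most selective of the recognised positions)
        is fixed, and the remaining positions split into an N-terminal and a
        C-terminal region around it, each with budget 1 — the same anatomy
        as the default model around P5.
        """
        pos = tuple(sorted(positions))
        if most_specific not in pos:
            raise ValueError("most_specific must be among the recognized positions")
        left = frozenset(p for p in pos if p < most_specific)
        right = frozenset(p for p in pos if p > most_specific)
        regions = tuple((r, 1) for r in (left, right) if r)
        return cls(
            recognized_positions=pos,
            fixed_positions=frozenset({most_specific}),
            regions=regions,
            similarity_rule=similarity_rule,
            name=f"allele-specific-{'+'.join(map(str, pos))}",
        )

    # -- core predicates ---------------------------------------------------

    def project(self, peptide: str) -> str:
        """The peptide's residues at the recognised positions, in order."""
        return "".join(peptide[p - 1] for p in self.recognized_positions)

    def is_recognized(self, peptide_a: str, peptide_b: str) -> bool:
        """True when the same T-cell would see both peptides."""
        if len(peptide_a) != 9 or len(peptide_b) != 9:
            raise ValueError("peptides must have length 9")
        rule = self.similarity_rule
        for p in self.fixed_positions:
            if peptide_a[p - 1] != peptide_b[p - 1]:
                return False
        for positions, budget in self.regions:
            mismatches = 0
            for p in positions:
                a, b = peptide_a[p - 1], peptide_b[p - 1]
                if a != b:
                    if not rule.allows(a, b):
                        return False
                    mismatches += 1
                    if mismatches > budget:
                        return False
        return True

    def enumerate_recognized_keys(self, peptide: str) -> set[str]:
        """All recognised-position projections this peptide's T-cell accepts.

        A peptide b is recognised by a's T-cell iff ``project(b)`` is in
        ``enumerate_recognized_keys(a)``; with a symmetric similarity rule
        this is the index-lookup form of :meth:`is_recognized`.
        """
        if len(peptide) != 9:
            raise ValueError("peptide must have length 9")
        rule = self.similarity_rule
        pos_order = self.recognized_positions
        # per-region variants: original residues, or <=budget positions
        # substituted by similar residues
        region_variants: list[list[dict[int, str]]] = []
        for positions, budget in self.regions:
            pos_list = sorted(positions)
            variants: list[dict[int, str]] = [{}]
            for m in range(1, budget + 1):
                for subset in itertools.combinations(pos_list, m):
                    choices = [sorted(rule(peptide[p - 1])) for p in subset]
                    for combo in itertools.product(*choices):
                        variants.append(dict(zip(subset, combo)))
            region_variants.append(variants)
        keys: set[str] = set()
        for combo in itertools.product(*region_variants) if region_variants else [()]:
            subst: dict[int, str] = {}
            for d in combo:
                subst.update(d)
            keys.add(
                "".join(subst.get(p, peptide[p - 1]) for p in pos_order)
            )
        return keys

    def n_recognized_keys(self, residues_by_position: Mapping[int, str]) -> int:
        """Closed-form key count for given residues at recognised positions.

        For per-region budget c over positions with similar-set sizes s_i the
        region contributes sum over subsets of size <= c of the product of
        s_i; with c = 1 this is 1 + sum(s_i).  Fixed positions contribute a
        factor of 1.
        """
        rule = self.similarity_rule
        total = 1
        for positions, budget in self.regions:
            sizes = [len(rule(residues_by_position[p])) for p in sorted(positions)]
            region_total = 0
            for m in range(0, budget + 1):
                for subset in itertools.combinations(sizes, m):
                    term = 1
                    for s in subset:
                        term *= s
                    region_total += term
            total *= region_total
        return total


# ---------------------------------------------------------------------------
# Peptide similarity score (min-max scaled substitution-matrix similarity)
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SimilarityScoreSpec:
    """Parameters of the min-max-scaled peptide similarity overlap model.

    By convention the matrix is BLOSUM35 and two peptides overlap when the
    scaled score exceeds 0.85; the scaling is anchored on the reference
    peptide (the nonself/query peptide when screening nonself against self).
    """

    matrix: SubstitutionMatrix
    threshold: float = 0.85

    def __post_init__(self) -> None:
        if not 0 <= self.threshold <= 1:
            raise ValueError("threshold must be in [0,1]")


def peptide_similarity_score(
    query: str, reference: str, matrix: SubstitutionMatrix
) -> float:
    """Min-max-scaled similarity of ``query`` to ``reference``.

    raw = sum_i M(ref_i, query_i); the score is (raw - min) / (max - min)
    where min/max are the lowest/highest raw scores any peptide can reach
    against the reference.  A query identical to the reference scores 1
    whenever the matrix diagonal dominates its column.
    """
    if len(query) != len(reference):
        raise ValueError("peptides must have equal length")
    vals = matrix.values
    ref_idx = [_AA_INDEX[a] for a in reference]
    raw = sum(vals[i, _AA_INDEX[b]] for i, b in zip(ref_idx, query))
    lo = sum(vals[i].min() for i in ref_idx)
    hi = sum(vals[i].max() for i in ref_idx)
    if hi == lo:
        raise ValueError("degenerate matrix: min and max similarity coincide")
    return float((raw - lo) / (hi - lo))


def scale_similarity(raw: float, lo: float, hi: float) -> float:
    """The bare min-max scaling step, exposed for worked examples."""
    if hi == lo:
        raise ValueError("degenerate scaling bounds")
    return (raw - lo) / (hi - lo)
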