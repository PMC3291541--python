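"""Statistical procedures: contingency tests, permutation enrichment,
positional entropy / anchor selectivity, and rank correlation.

The chi-square test on 2x2 tables defaults to the uncorrected statistic
n(ad-bc)^2 / [(a+b)(c+d)(a+c)(b+d)] with 1 df; Yates continuity correction
is available behind a flag.  The permutation enrichment test identifies
self proteins sharing 9mers with more pathogen species than expected from a
length-proportional null.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy import stats as sps

from .overlap import PerProteinOverlapCount

LOG2_20 = math.log2(20)
ANCHOR_POSITIONS = (2, 9)
NON_ANCHOR_POSITIONS = (1, 3, 4, 5, 6, 7, 8)


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Counts: rows = immunogenic / non-immunogenic, columns =
    self-overlapping / not overlapping."""

    a: int  # immunogenic, overlapping
    b: int  # immunogenic, not overlapping
    c: int  # non-immunogenic, overlapping
    d: int  # non-immunogenic, not overlapping

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("counts must be non-negative")
        if self.total == 0:
            raise ValueError("table is empty")

    @property
    def total(self) -> int:
        return self.a + self.b + self.c + self.d

    @property
    def odds_ratio(self) -> float:
        if self.b * self.c == 0:
            return float("inf") if self.a * self.d > 0 else float("nan")
        return (self.a * self.d) / (self.b * self.c)


def chi_square_2x2(
    table: ContingencyTable2x2 | tuple[int, int, int, int],
    continuity_correction: bool = False,
) -> tuple[float, float]:
    """Chi-square test of association on a 2x2 table, 1 df.

    Uncorrected by default.  Returns ``(statistic, p_value)``; raises on a
    zero marginal (the statistic is undefined there).
    """
    if not isinstance(table, ContingencyTable2x2):
        table = ContingencyTable2x2(*table)
    a, b, c, d = table.a, table.b, table.c, table.d
    n = table.total
    margins = {"row1": a + b, "row2": c + d, "col1": a + c, "col2": b + d}
    for name, m in margins.items():
        if m == 0:
            raise ValueError(f"degenerate margin: {name} sums to zero")
    diff = abs(a * d - b * c)
    if continuity_correction:
        diff = max(0.0, diff - n / 2)
    stat = n * diff**2 / (margins["row1"] * margins["row2"] * margins["col1"] * margins["col2"])
    p = float(sps.chi2.sf(stat, df=1))
    return float(stat), p


def permutation_enrichment(
    counts: Sequence[PerProteinOverlapCount],
    n_species: int,
    n_perm: int = 1000,
    seed: int = 0,
) -> list[str]:
    """Self proteins overlapping more species than any of n_perm null draws.

    The null assumes overlaps accrue proportionally to protein length:
    with the global per-residue rate lambda = sum(counts) / sum(lengths),
    protein i draws Binomial(n_species, min(1, lambda * length_i /
    n_species)) per permutation.  A protein is flagged when its observed
    species count strictly exceeds all ``n_perm`` draws (empirical
    p < 1/(n_perm + 1)).
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    counts = list(counts)
    total = sum(c.n_species_overlapping for c in counts)
    if total == 0:
        return []
    total_length = sum(c.length for c in counts)
    lam = total / total_length
    rng = np.random.default_rng(seed)
    flagged = []
    for c in counts:
        if c.n_species_overlapping == 0:
            continue
        p_i = min(1.0, lam * c.length / n_species)
        draws = rng.binomial(n_species, p_i, size=n_perm)
        if c.n_species_overlapping > draws.max():
            flagged.append(c.protein_id)
    return flagged


@dataclass(frozen=True)
class PositionProfile:
    """Per-position Shannon entropy (bits) of an allele's presented set."""

    allele: str
    entropy: tuple[float, ...]  # P1..P9

    def __post_init__(self) -> None:
        if len(self.entropy) != 9:
            raise ValueError("profile must cover P1..P9")
        if any(h < -1e-12 or h > LOG2_20 + 1e-9 for h in self.entropy):
            raise ValueError("entropies must lie in [0, log2 20]")

    def information(self, position: int) -> float:
        """Information content (selectivity) at a 1-based position."""
        return LOG2_20 - self.entropy[position - 1]


def position_entropy(
    presented_peptides: Iterable[str], allele: str = ""
) -> PositionProfile:
    """Shannon entropy per position over a set of presented 9mers."""
    peps = list(presented_peptides)
    if not peps:
        raise ValueError("empty peptide set")
    if any(len(p) != 9 for p in peps):
        raise ValueError("peptides must have length 9")
    entropies = []
    for pos in range(9):
        _, freq = np.unique([p[pos] for p in peps], return_counts=True)
        f = freq / freq.sum()
        entropies.append(float(-(f * np.log2(f)).sum()))
    return PositionProfile(allele=allele, entropy=tuple(entropies))


def additional_anchor_assessment(
    profile: PositionProfile,
    threshold: float = 0.25,
    use_information: bool = True,
) -> tuple[float, bool]:
    """Does this allele restrict residues at TCR-exposed positions?

    Selectivity per position defaults to information content (log2 20 - H):
    low entropy = high selectivity, so the non-anchor sum rises exactly when
    additional anchors are present.  ``use_information=False`` sums raw
    entropy instead.  The allele is flagged when the non-anchor (P1, P3-8)
    selectivity sum exceeds ``threshold`` (25%) of the all-position sum.
    Returns ``(non_anchor_selectivity_sum, flag)``.
    """
    if use_information:
        values = [profile.information(p) for p in range(1, 10)]
    else:
        values = list(profile.entropy)
    non_anchor = sum(values[p - 1] for p in NON_ANCHOR_POSITIONS)
    total = sum(values)
    flag = total > 0 and non_anchor > threshold * total
    return non_anchor, flag


def least_specific_positions(profile: PositionProfile, n: int = 6) -> tuple[int, ...]:
    """The n positions with the highest entropy (lowest selectivity).

    Ties break toward the lower (more N-terminal) position.  Used for the
    allele-specific degenerate recognition mask.
    """
    if not 1 <= n <= 9:
        raise ValueError("n must be in 1..9")
    order = sorted(range(1, 10), key=lambda p: (-profile.entropy[p - 1], p))
    return tuple(sorted(order[:n]))


def spearman_rank(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Spearman rank correlation with tie-aware ranks, p via the
    t-distribution approximation."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 3:
        raise ValueError("x and y must be equal-length vectors of length >= 3")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ValueError("constant vector: rank correlation undefined")
    res = sps.spearmanr(x, y)
    return float(res.statistic), float(res.pvalue)
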