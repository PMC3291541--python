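"""The recognition footprint of a single T-cell clone.

Under a degenerate recognition model a T-cell raised against one middle
region 6mer also recognises every variant reachable by tolerated
conservative substitutions.  The number of *other* recognised combinations,
averaged over all possible middle 6mers, measures cross-reactivity; its
reciprocal against the 20^6 possible combinations is the "1 in N" form
(1 in ~2.7 million under a PMBEC-like rule averaging ~24 other variants).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np

from .peptidome import AMINO_ACIDS
from .recognition import RecognitionModel


def recognized_variant_count(middle_residues: str, model: RecognitionModel) -> int:
    """Number of *other* residue combinations the same T-cell recognises.

    ``middle_residues`` supplies, in order, the residues at the model's
    recognised positions.  Closed form: product over regions of
    (sum over subsets within budget of the product of similar-set sizes),
    minus 1 for the peptide's own combination.
    """
    positions = model.recognized_positions
    if len(middle_residues) != len(positions):
        raise ValueError(
            f"expected {len(positions)} residues for positions {positions}"
        )
    by_pos = dict(zip(positions, middle_residues))
    return model.n_recognized_keys(by_pos) - 1


def recognized_variant_count_exhaustive(
    middle_residues: str, model: RecognitionModel, alphabet: str = AMINO_ACIDS
) -> int:
    """Brute-force oracle: scan every combination over ``alphabet``.

    Exponential in the number of recognised positions — intended for
    reduced alphabets in tests.
    """
    positions = model.recognized_positions
    by_pos = dict(zip(positions, middle_residues))
    template = ["A"] * 9
    for p, aa in by_pos.items():
        template[p - 1] = aa
    own = "".join(template)
    free = [p for p in positions if p not in model.fixed_positions]
    count = 0
    for combo in itertools.product(alphabet, repeat=len(free)):
        candidate = list(template)
        for p, aa in zip(free, combo):
            candidate[p - 1] = aa
        cand = "".join(candidate)
        if cand != own and model.is_recognized(own, cand):
            count += 1
    return count


@dataclass(frozen=True)
class Footprint:
    """Population-average cross-reactivity of one recognition model."""

    mean_other_count: float
    reciprocal: float            # alphabet^n_variable / mean_other_count
    reciprocal_inclusive: float  # denominator includes the self combination
    n_combinations: int

    @property
    def one_in_millions(self) -> float:
        return self.reciprocal / 1e6


def average_footprint(
    model: RecognitionModel, alphabet_size: int = 20
) -> Footprint:
    """Mean recognised-variant count over uniform independent residues.

    With residues i.i.d. uniform, the expectation factorises over regions:
    for budget-1 regions, E = prod_regions (1 + sum_i E[s]) - 1 where E[s]
    is the mean similar-set size; general budgets use the subset expansion.
    The reciprocal is alphabet_size^(#recognised positions) divided by the
    mean count of *other* combinations (an inclusive variant, dividing by
    mean + 1, is also reported).
    """
    rule = model.similarity_rule
    sizes = np.array([len(rule(aa)) for aa in AMINO_ACIDS], dtype=float)
    mean_s = float(sizes.mean())
    total = 1.0
    for positions, budget in model.regions:
        m = len(positions)
        region_total = 0.0
        for c in range(0, budget + 1):
            # E[sum over c-subsets of prod s_i] = C(m, c) * E[s]^c
            region_total += _comb(m, c) * mean_s**c
        total *= region_total
    mean_other = total - 1.0
    n_positions = len(model.recognized_positions)
    n_comb = alphabet_size**n_positions
    reciprocal = n_comb / mean_other if mean_other > 0 else float(n_comb)
    return Footprint(
        mean_other_count=mean_other,
        reciprocal=reciprocal,
        reciprocal_inclusive=n_comb / (mean_other + 1.0),
        n_combinations=n_comb,
    )


def monte_carlo_footprint(
    model: RecognitionModel, n_draws: int = 100_000, seed: int = 0
) -> tuple[float, float]:
    """Monte-Carlo estimate of the mean other-variant count (mean, stderr)."""
    rng = np.random.default_rng(seed)
    positions = model.recognized_positions
    draws = rng.integers(0, 20, size=(n_draws, len(positions)))
    counts = np.empty(n_draws)
    cache: dict[tuple[int, ...], int] = {}
    for i, row in enumerate(draws):
        key = tuple(row)
        if key not in cache:
            residues = "".join(AMINO_ACIDS[j] for j in row)
            cache[key] = recognized_variant_count(residues, model)
        counts[i] = cache[key]
    return float(counts.mean()), float(counts.std(ddof=1) / np.sqrt(n_draws))


def _comb(n: int, k: int) -> int:
    import math

    return math.comb(n, k)
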