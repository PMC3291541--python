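import numpy as np
import pytest

from pepself.peptidome import AMINO_ACIDS
from pepself.recognition import (
    RecognitionModel,
    SimilarityRule,
    SubstitutionMatrix,
    build_similarity_rule,
    bundled_matrix,
    load_matrix,
    peptide_similarity_score,
    scale_similarity,
    write_matrix,
)
from pepself.synthetic import make_similarity_matrix, random_peptides

from conftest import make_random_rule


# -- matrices ---------------------------------------------------------------


def test_matrix_file_round_trip(tmp_path):
    mat = make_similarity_matrix(1.6, seed=4)
    path = tmp_path / "mat.txt"
    write_matrix(mat, path)
    back = load_matrix(path)
    assert np.allclose(back.values, mat.values)


def test_asymmetric_matrix_rejected():
    values = np.zeros((20, 20))
    values[0, 1] = 1.0  # not mirrored
    with pytest.raises(ValueError, match="symmetric"):
        SubstitutionMatrix(name="bad", values=values)


# -- similarity rules -------------------------------------------------------


def test_identity_matrix_yields_empty_rule():
    rule = build_similarity_rule(
        SubstitutionMatrix("identity", np.eye(20)), "abs_covariance_gt", 0.05
    )
    assert all(not rule(aa) for aa in AMINO_ACIDS)


def test_single_pair_rule():
    values = np.eye(20)
    i, l = AMINO_ACIDS.index("I"), AMINO_ACIDS.index("L")
    values[i, l] = values[l, i] = 0.2
    rule = build_similarity_rule(
        SubstitutionMatrix("pair", values), "abs_covariance_gt", 0.05
    )
    assert rule("I") == frozenset("L")
    assert rule("L") == frozenset("I")
    assert all(not rule(aa) for aa in AMINO_ACIDS if aa not in "IL")


def test_blosum62_positive_rule_matches_column_scan():
    matrix = bundled_matrix("BLOSUM62")
    rule = build_similarity_rule(matrix, "positive_score")
    for a in AMINO_ACIDS:
        expected = {b for b in AMINO_ACIDS if b != a and matrix.score(a, b) > 0}
        assert rule(a) == expected
        for b in rule(a):
            assert a in rule(b)  # symmetry


def test_negative_covariance_counts_as_similar_only_in_abs_mode():
    values = np.eye(20)
    a, b = 0, 1
    values[a, b] = values[b, a] = -0.2
    mat = SubstitutionMatrix("neg", values)
    abs_rule = build_similarity_rule(mat, "abs_covariance_gt", 0.05)
    signed_rule = build_similarity_rule(mat, "value_gt", 0.05)
    aa, bb = AMINO_ACIDS[a], AMINO_ACIDS[b]
    assert bb in abs_rule(aa)
    assert bb not in signed_rule(aa)


# -- recognition models -----------------------------------------------------


def test_is_recognized_reflexive(degenerate_model, random_9mers):
    for pep in random_9mers[:50]:
        assert degenerate_model.is_recognized(pep, pep)
        assert RecognitionModel.complete().is_recognized(pep, pep)


def test_unrecognized_positions_ignored(degenerate_model):
    # P1 and P2 are invisible to the TCR in the default model
    a = "ACDEFGHIK"
    b = "WWDEFGHIK"
    assert degenerate_model.is_recognized(a, b)
    assert RecognitionModel.middle().is_recognized(a, b)
    assert not RecognitionModel.complete().is_recognized(a, b)


def test_two_mismatches_in_one_region_rejected():
    # rule that allows everything, so only the budgets can reject
    rule = make_random_rule(seed=0, p_edge=1.0)
    model = RecognitionModel.degenerate(rule)
    a = "AADEFGHIK"
    b_one = "AAWEFGHIK"   # P3 only
    b_two = "AAWWFGHIK"   # P3 and P4: two mismatches in the N-terminal region
    assert model.is_recognized(a, b_one)
    assert not model.is_recognized(a, b_two)


def test_fixed_position_must_match(degenerate_model):
    a = "ACDEFGHIK"
    b = a[:4] + "W" + a[5:]  # P5 differs
    assert not degenerate_model.is_recognized(a, b)


def test_length_errors(degenerate_model):
    with pytest.raises(ValueError):
        degenerate_model.is_recognized("ACDEFGHI", "ACDEFGHIK")
    with pytest.raises(ValueError):
        degenerate_model.enumerate_recognized_keys("ACDEFGHI")


def test_symmetry_on_random_pairs(degenerate_model, rng):
    peptides = random_peptides(100, seed=21)
    for _ in range(1000):
        a, b = rng.choice(peptides, 2)
        b = _perturb(a, rng) if rng.random() < 0.5 else b
        assert degenerate_model.is_recognized(a, b) == degenerate_model.is_recognized(b, a)


def _perturb(peptide, rng, n_changes=2):
    letters = list(peptide)
    for pos in rng.choice(9, size=n_changes, replace=False):
        letters[pos] = AMINO_ACIDS[rng.integers(20)]
    return "".join(letters)


# -- key enumeration --------------------------------------------------------


def test_empty_rule_single_key():
    model = RecognitionModel.degenerate(SimilarityRule.empty())
    keys = model.enumerate_recognized_keys("ACDEFGHIK")
    assert keys == {model.project("ACDEFGHIK")}


def test_one_partner_rule_key_count():
    # every residue has exactly one partner: regions of size 2 and 3 give
    # (1+2)(1+3) = 12 keys
    letters = list(AMINO_ACIDS)  # pair adjacent letters into an involution
    similar = {}
    for i in range(0, 20, 2):
        similar[letters[i]] = frozenset({letters[i + 1]})
        similar[letters[i + 1]] = frozenset({letters[i]})
    rule = SimilarityRule(similar=similar)
    model = RecognitionModel.degenerate(rule)
    keys = model.enumerate_recognized_keys("ACDEFGHIK")
    assert len(keys) == 12


def test_key_count_matches_closed_form(rng):
    for seed in range(20):
        rule = make_random_rule(seed=seed, p_edge=0.12)
        model = RecognitionModel.degenerate(rule)
        for pep in random_peptides(50, seed=seed + 100):
            keys = model.enumerate_recognized_keys(pep)
            by_pos = {p: pep[p - 1] for p in model.recognized_positions}
            assert len(keys) == model.n_recognized_keys(by_pos)


def test_key_membership_equals_pairwise_oracle(rng):
    rule = make_random_rule(seed=3, p_edge=0.15)
    model = RecognitionModel.degenerate(rule)
    peptides = random_peptides(100, seed=33)
    for i in range(500):
        a = peptides[i % len(peptides)]
        b = _perturb(a, rng, n_changes=int(rng.integers(1, 4)))
        keys = model.enumerate_recognized_keys(a)
        assert (model.project(b) in keys) == model.is_recognized(a, b)


def test_adjacent_variant_allows_neighbouring_mismatches():
    rule = make_random_rule(seed=0, p_edge=1.0)
    strict = RecognitionModel.degenerate(rule)
    relaxed = RecognitionModel.degenerate_adjacent(rule)
    a = "AADEFGHIK"
    b = "AAWWFGHIK"  # two mismatches at P3, P4
    assert not strict.is_recognized(a, b)
    assert relaxed.is_recognized(a, b)


def test_model_nesting_property(rng):
    small = make_random_rule(seed=5, p_edge=0.08)
    # supersets of the similarity pairs with larger budgets must recognize more
    big_similar = {
        a: frozenset(small(a) | make_random_rule(seed=6, p_edge=0.08)(a))
        for a in AMINO_ACIDS
    }
    big_rule = SimilarityRule(similar=big_similar)
    model_b = RecognitionModel.degenerate(small)
    model_a = RecognitionModel.degenerate_adjacent(big_rule)  # budget 2 >= 1,1
    peptides = random_peptides(80, seed=55)
    for i in range(400):
        a = peptides[i % len(peptides)]
        b = _perturb(a, rng, n_changes=int(rng.integers(1, 3)))
        if model_b.is_recognized(a, b):
            assert model_a.is_recognized(a, b)


def test_allele_specific_model_anatomy():
    rule = make_random_rule(seed=7, p_edge=0.1)
    model = RecognitionModel.allele_specific(
        positions=(1, 3, 4, 6, 7, 8), most_specific=4, similarity_rule=rule
    )
    assert model.fixed_positions == {4}
    region_sets = {frozenset(r) for r, _ in model.regions}
    assert region_sets == {frozenset({1, 3}), frozenset({6, 7, 8})}


# -- similarity score -------------------------------------------------------


def test_similarity_score_worked_example():
    # raw 3 against scaling bounds [1, 11] -> 0.2
    assert scale_similarity(3, 1, 11) == pytest.approx(0.2)


def test_similarity_score_identity_is_one():
    matrix = bundled_matrix("BLOSUM62")
    for pep in random_peptides(20, seed=8):
        assert peptide_similarity_score(pep, pep, matrix) == pytest.approx(1.0)


def test_similarity_score_matches_recomputation():
    matrix = bundled_matrix("BLOSUM50")
    peptides = random_peptides(100, seed=9)
    refs = random_peptides(100, seed=10)
    for q, r in zip(peptides, refs):
        raw = sum(matrix.score(a, b) for a, b in zip(r, q))
        lo = sum(min(matrix.score(a, x) for x in AMINO_ACIDS) for a in r)
        hi = sum(max(matrix.score(a, x) for x in AMINO_ACIDS) for a in r)
        expected = (raw - lo) / (hi - lo)
        score = peptide_similarity_score(q, r, matrix)
        assert score == pytest.approx(expected)
        assert 0.0 <= score <= 1.0


def test_similarity_score_degenerate_matrix_errors():
    flat = SubstitutionMatrix("flat", np.ones((20, 20)))
    with pytest.raises(ValueError):
        peptide_similarity_score("ACDEFGHIK", "ACDEFGHIK", flat)
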