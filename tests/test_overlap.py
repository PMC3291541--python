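import math

import numpy as np
import pytest

from pepself.overlap import (
    SelfIndex,
    count_overlaps,
    count_overlaps_bruteforce,
    count_overlaps_simscore,
    length_scan,
    overlap_fraction,
    per_protein_species_counts,
    subsample_self,
)
from pepself.peptidome import PeptideSet, ProteinRecord, ProteomeSet, extract_kmers
from pepself.recognition import (
    RecognitionModel,
    SimilarityRule,
    SimilarityScoreSpec,
    bundled_matrix,
)
from pepself.synthetic import (
    chance_overlap_probability,
    make_proteomes,
    random_peptides,
)

from conftest import make_random_rule


def _pepset(peptides, species_id="v", kingdom="virus"):
    return PeptideSet(k=9, peptides=set(peptides), species_id=species_id,
                      kingdom=kingdom)


def test_subset_gives_total_overlap(degenerate_model):
    selfs = set(random_peptides(100, seed=1))
    nonself = _pepset(list(selfs)[:30])
    result = overlap_fraction([nonself], selfs, degenerate_model)
    assert result.pooled_fraction("virus") == 1.0


def test_disjoint_projections_give_zero():
    model = RecognitionModel.degenerate(SimilarityRule.empty())
    selfs = {"A" * 9}
    nonself = _pepset({"C" * 9, "D" * 9})
    result = overlap_fraction([nonself], selfs, model)
    assert result.pooled_fraction("virus") == 0.0


def test_empty_self_warns_and_zeroes(degenerate_model):
    nonself = _pepset(random_peptides(10, seed=2))
    result = overlap_fraction([nonself], set(), degenerate_model)
    assert result.pooled_fraction("virus") == 0.0


def test_key_index_equals_bruteforce_small(degenerate_model):
    selfs = set(random_peptides(300, seed=3))
    nonself = random_peptides(300, seed=4)
    # salt in peptides similar to self so the overlap is non-trivial
    rng = np.random.default_rng(5)
    salted = nonself + [_mutate(p, rng) for p in list(selfs)[:100]]
    fast = count_overlaps(salted, selfs, degenerate_model)
    slow = count_overlaps_bruteforce(salted, selfs, degenerate_model)
    assert fast == slow
    assert fast > 0


def _mutate(peptide, rng):
    from pepself.peptidome import AMINO_ACIDS

    pos = int(rng.integers(9))
    letters = list(peptide)
    letters[pos] = AMINO_ACIDS[int(rng.integers(20))]
    return "".join(letters)


def test_model_monotonicity_chain(degenerate_model):
    data = make_proteomes(n_self_proteins=40, n_species=4,
                          shared_kmer_rate=0.03, seed=6)
    selfs = extract_kmers(data.self_proteome, 9).peptides
    nonself_sets = [extract_kmers(p, 9) for p in data.nonself_proteomes]
    fractions = {}
    for name, model in {
        "complete": RecognitionModel.complete(),
        "nonanchor": RecognitionModel.nonanchor(),
        "middle": RecognitionModel.middle(),
        "degenerate": degenerate_model,
    }.items():
        fractions[name] = overlap_fraction(nonself_sets, selfs, model).kingdom_average
    assert fractions["complete"] <= fractions["nonanchor"] <= fractions["middle"]
    assert fractions["middle"] <= fractions["degenerate"]


def test_simscore_overlap_counts():
    matrix = bundled_matrix("BLOSUM62")
    spec = SimilarityScoreSpec(matrix, threshold=0.85)
    selfs = set(random_peptides(50, seed=7))
    identical = list(selfs)[:5]
    distant = random_peptides(20, seed=8)
    n = count_overlaps_simscore(identical, selfs, spec)
    assert n == 5  # identical peptides always exceed the threshold
    assert count_overlaps_simscore(distant, selfs, spec) <= len(distant)


def test_length_scan_single_letter_saturates():
    data = make_proteomes(n_self_proteins=10, n_species=2,
                          protein_length_range=(200, 300), seed=9)
    scan = length_scan(data.self_proteome.records, data.nonself_proteomes,
                       k_range=[1, 9], shuffle_seed=None)
    k1 = scan[scan.k == 1]
    assert (k1.fraction == 1.0).all()  # all 20 letters occur in self
    k9 = scan[scan.k == 9]
    assert (k9.fraction < 0.01).all()  # unrelated proteomes barely overlap


def test_length_scan_absent_when_k_exceeds_proteins():
    selfs = [ProteinRecord(id="s", sequence="ACDEFGHIKLMNPQRSTVWY")]
    nonself = [ProteomeSet("v", "virus",
                           [ProteinRecord(id="v1", sequence="ACDEFGHIKL",
                                          species_id="v", kingdom="virus")])]
    scan = length_scan(selfs, nonself, k_range=[5, 15], shuffle_seed=None)
    assert set(scan.k) == {5}  # k=15 has no nonself window: row absent


def test_length_scan_recovers_planted_rate():
    rate = 0.05
    data = make_proteomes(n_self_proteins=100, n_species=4,
                          shared_kmer_rate=rate, seed=10)
    scan = length_scan(data.self_proteome.records, data.nonself_proteomes,
                       k_range=[9], shuffle_seed=None)
    n_self = len(extract_kmers(data.self_proteome, 9).peptides)
    chance = chance_overlap_probability(n_self)
    for row in scan.itertuples():
        expected = rate + chance
        sigma = math.sqrt(expected * (1 - expected) / row.n_peptides)
        assert abs(row.fraction - expected) <= 3 * sigma


def test_shuffled_control_reduces_overlap():
    data = make_proteomes(n_self_proteins=30, n_species=2,
                          shared_kmer_rate=0.1, seed=11)
    scan = length_scan(data.self_proteome.records, data.nonself_proteomes,
                       k_range=[9], shuffle_seed=0)
    real = scan[~scan.control].fraction.to_numpy()
    control = scan[scan.control].fraction.to_numpy()
    assert (control < real).all()


def test_per_protein_species_counts_bruteforce():
    data = make_proteomes(n_self_proteins=50, n_species=20,
                          protein_length_range=(60, 120),
                          n_proteins_per_species=2,
                          shared_kmer_rate=0.02, seed=12)
    counts = per_protein_species_counts(data.self_proteome.records,
                                        data.nonself_proteomes)
    by_id = {c.protein_id: c for c in counts}
    for rec in data.self_proteome.records:
        protein_kmers = {rec.sequence[i:i + 9]
                         for i in range(len(rec.sequence) - 8)}
        expected = 0
        for prot in data.nonself_proteomes:
            species_kmers = set()
            for r in prot.records:
                species_kmers.update(r.sequence[i:i + 9]
                                     for i in range(len(r.sequence) - 8))
            if protein_kmers & species_kmers:
                expected += 1
        got = by_id[rec.id]
        assert got.n_species_overlapping == expected
        assert got.n_species_overlapping <= len(data.nonself_proteomes)
        assert got.length == len(rec.sequence)


def test_verbatim_pathogen_copy_is_counted():
    data = make_proteomes(n_self_proteins=10, n_species=2, seed=13)
    copied = data.nonself_proteomes[0].records[0]
    selfs = data.self_proteome.records + [
        ProteinRecord(id="planted", sequence=copied.sequence,
                      species_id="self", kingdom="self")
    ]
    counts = per_protein_species_counts(selfs, data.nonself_proteomes)
    assert {c.protein_id: c for c in counts}["planted"].n_species_overlapping >= 1


def test_subsample_self_is_seeded_uniform_fraction():
    records = make_proteomes(n_self_proteins=40, n_species=1, seed=14
                             ).self_proteome.records
    half = subsample_self(records, 0.5, seed=1)
    assert len(half) == 20
    assert subsample_self(records, 0.5, seed=1) == half
    assert set(r.id for r in half) <= set(r.id for r in records)


def test_kingdom_average_is_unweighted_mean(degenerate_model):
    selfs = set(random_peptides(200, seed=15))
    virus = _pepset(list(selfs)[:10] + random_peptides(10, seed=16), "v", "virus")
    bact = _pepset(random_peptides(40, seed=17), "b", "bacterium")
    result = overlap_fraction([virus, bact], selfs, degenerate_model)
    expected = (result.pooled_fraction("virus")
                + result.pooled_fraction("bacterium")) / 2
    assert result.kingdom_average == pytest.approx(expected)
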