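"""Allele frequencies, diversity statistics and probability-of-identity oracles."""

import itertools
import math

import numpy as np
import pytest

from scatsurvey.individual_matching import IndividualCluster
from scatsurvey.popgen_stats import (
    allele_frequencies,
    cumulative_pid,
    locus_stats,
    pid_locus,
    stats_from_clusters,
    summary_table,
)
from scatsurvey.survey_io import LocusGenotype, Status


def pid_unrelated_by_enumeration(freqs):
    """Independent oracle: sum over all genotypes g of P(g)^2 under HWE."""
    alleles = sorted(freqs)
    total = 0.0
    for a, b in itertools.combinations_with_replacement(alleles, 2):
        p = freqs[a] ** 2 if a == b else 2 * freqs[a] * freqs[b]
        total += p * p
    return total


def pid_sibling_by_mendelian_simulation(freqs, n_pairs, rng):
    """Independent oracle: Mendelian sibling pairs from random HWE parents."""
    alleles = np.array(sorted(freqs))
    probs = np.array([freqs[a] for a in alleles])
    idx = rng.choice(len(alleles), size=(n_pairs, 4), p=probs)  # m1 m2 f1 f2
    pick = rng.integers(0, 2, size=(n_pairs, 4))  # maternal/paternal picks per sib
    sib1_m = idx[np.arange(n_pairs), pick[:, 0]]
    sib1_f = idx[np.arange(n_pairs), 2 + pick[:, 1]]
    sib2_m = idx[np.arange(n_pairs), pick[:, 2]]
    sib2_f = idx[np.arange(n_pairs), 2 + pick[:, 3]]
    g1 = np.sort(np.stack([sib1_m, sib1_f], axis=1), axis=1)
    g2 = np.sort(np.stack([sib2_m, sib2_f], axis=1), axis=1)
    return float(np.mean(np.all(g1 == g2, axis=1)))


def test_allele_frequencies_from_unique_individuals(clustering, genotype_table):
    table = allele_frequencies(clustering.clusters, genotype_table.loci)
    pun894 = table["PUN894"]
    assert pun894.n_individuals == 9
    assert pun894.freqs == {110: 16 / 18, 118: 2 / 18}
    # three individuals ambiguous at PUN1157 are excluded entirely
    assert table["PUN1157"].n_individuals == 6
    # the missing-locus individual drops out at PUN124
    assert table["PUN124"].n_individuals == 8
    for locus in genotype_table.loci:
        assert sum(table[locus].freqs.values()) == pytest.approx(1.0, abs=1e-12)


def test_single_homozygous_individual():
    cluster = IndividualCluster(
        1, ["S"], {"L": LocusGenotype("L", Status.OK, alleles=(110, 110))}
    )
    table = allele_frequencies([cluster], ["L"])
    assert table["L"].freqs == {110: 1.0}


def test_empty_locus_flagged_not_zero_filled():
    cluster = IndividualCluster(
        1, ["S"], {"L": LocusGenotype("L", Status.MISSING)}
    )
    table = allele_frequencies([cluster], ["L"])
    assert table["L"].empty
    assert table.flagged_empty() == ["L"]
    with pytest.raises(ValueError):
        locus_stats("L", {}, 0, [])


EXPECTED_TABLE = {
    # locus: (N, Na, Ne, Ho, He, UHe) as printed after rounding
    "PUN124": (8, 6, 3.2, 0.750, 0.688, 0.733),
    "PUN229": (8, 4, 3.5, 0.875, 0.711, 0.758),
    "PUN935": (7, 4, 3.3, 0.714, 0.694, 0.747),
    "PUN1157": (6, 3, 2.6, 0.667, 0.611, 0.667),
    "PUN132": (9, 4, 2.3, 0.556, 0.574, 0.608),
    "PUN894": (9, 2, 1.2, 0.222, 0.198, 0.209),
}


def test_per_locus_stats_reproduce_survey_table(locus_stats_list):
    assert len(locus_stats_list) == 6
    for s in locus_stats_list:
        n, na, ne, ho, he, uhe = EXPECTED_TABLE[s.locus]
        assert (s.n, s.na) == (n, na)
        assert round(s.ne, 1) == ne
        assert round(s.ho, 3) == ho
        assert round(s.he, 3) == he
        assert round(s.uhe, 3) == uhe


def test_locus_stats_degenerate_frequencies():
    gt = LocusGenotype("L", Status.OK, alleles=(100, 100))
    s = locus_stats("L", {100: 1.0}, 1, [gt])
    assert (s.na, s.ne, s.ho, s.he, s.uhe) == (1, 1.0, 0.0, 0.0, 0.0)
    het = LocusGenotype("L", Status.OK, alleles=(100, 102))
    s2 = locus_stats("L", {100: 0.5, 102: 0.5}, 1, [het])
    assert s2.ne == pytest.approx(2.0)
    assert s2.he == pytest.approx(0.5)


def test_he_equals_one_minus_inverse_ne(locus_stats_list):
    """Algebraic identity He = 1 - 1/Ne, asserted to 1e-12."""
    for s in locus_stats_list:
        assert abs(s.he - (1.0 - 1.0 / s.ne)) < 1e-12


def test_uhe_small_sample_correction(locus_stats_list):
    for s in locus_stats_list:
        assert s.uhe == pytest.approx(s.he * 2 * s.n / (2 * s.n - 1), rel=1e-12)
        assert s.uhe >= s.he


def test_pid_closed_forms():
    assert pid_locus({1: 1.0}) == (pytest.approx(1.0), pytest.approx(1.0))
    pid_u, pid_sib = pid_locus({1: 0.5, 2: 0.5})
    assert pid_u == pytest.approx(0.375)
    assert pid_sib == pytest.approx(0.59375)


def test_pid_rejects_unnormalised_frequencies():
    with pytest.raises(ValueError):
        pid_locus({1: 0.5, 2: 0.4})


def test_pid_unrelated_matches_enumeration_on_survey_frequencies(
    clustering, genotype_table
):
    table = allele_frequencies(clustering.clusters, genotype_table.loci)
    for locus in genotype_table.loci:
        freqs = table[locus].freqs
        pid_u, pid_sib = pid_locus(freqs)
        assert pid_u == pytest.approx(
            pid_unrelated_by_enumeration(freqs), abs=1e-12
        )
        assert pid_u <= pid_sib <= 1.0
        assert pid_sib >= 0.25


def test_pid_unrelated_matches_enumeration_fuzz():
    rng = np.random.default_rng(5)
    for _ in range(100):
        k = int(rng.integers(1, 9))
        probs = rng.dirichlet(np.ones(k) * rng.uniform(0.2, 5.0))
        freqs = {100 + 2 * i: float(p) for i, p in enumerate(probs)}
        pid_u, _ = pid_locus(freqs)
        assert pid_u == pytest.approx(pid_unrelated_by_enumeration(freqs), abs=1e-12)


def test_pid_sibling_matches_mendelian_simulation():
    rng = np.random.default_rng(17)
    for _ in range(3):
        k = int(rng.integers(2, 7))
        probs = rng.dirichlet(np.ones(k) * 2.0)
        freqs = {100 + 2 * i: float(p) for i, p in enumerate(probs)}
        _, pid_sib = pid_locus(freqs)
        n_pairs = 50_000
        observed = pid_sibling_by_mendelian_simulation(freqs, n_pairs, rng)
        se = math.sqrt(pid_sib * (1 - pid_sib) / n_pairs)
        assert abs(observed - pid_sib) <= 3 * se


def test_cumulative_pid_properties(locus_stats_list):
    pairs = [(s.pid_u, s.pid_sib) for s in locus_stats_list]
    total_u, total_sib = cumulative_pid(pairs)
    # hand-multiplied oracle
    assert total_u == pytest.approx(math.prod(p for p, _ in pairs), rel=1e-12)
    assert total_sib == pytest.approx(math.prod(p for _, p in pairs), rel=1e-12)
    # single locus is the identity
    assert cumulative_pid(pairs[:1]) == pairs[0]
    # order invariance
    assert cumulative_pid(list(reversed(pairs))) == pytest.approx(
        (total_u, total_sib)
    )
    # non-increasing as loci accumulate
    running_u = 1.0
    for u, _ in pairs:
        assert running_u * u <= running_u
        running_u *= u
    assert cumulative_pid([(0.1, 0.3), (0.1, 0.3)]) == (
        pytest.approx(0.01), pytest.approx(0.09),
    )
    with pytest.raises(ValueError):
        cumulative_pid([])


def test_summary_table_overall_means(locus_stats_list):
    frame = summary_table(locus_stats_list)
    overall = frame[frame["Locus"] == "Overall"].iloc[0]
    assert overall["He"] == 0.579
    assert overall["Ho"] == 0.631


def test_summary_table_single_locus(locus_stats_list):
    frame = summary_table(locus_stats_list[:1])
    overall = frame[frame["Locus"] == "Overall"].iloc[0]
    assert overall["He"] == round(locus_stats_list[0].he, 3)


def test_summary_table_unweighted_mean():
    gt = LocusGenotype("A", Status.OK, alleles=(1, 2))
    hom = LocusGenotype("B", Status.OK, alleles=(1, 1))
    a = locus_stats("A", {1: 0.9, 2: 0.1}, 1, [gt])  # He = 0.18 -> 0.2 rounded
    assert a.he == pytest.approx(0.18)
    b = locus_stats("B", {1: 0.8, 3: 0.2}, 1, [hom])  # He = 0.32
    frame = summary_table([a, b])
    overall = frame[frame["Locus"] == "Overall"].iloc[0]
    assert overall["He"] == round((0.18 + 0.32) / 2, 3)


def test_stats_skip_empty_loci(clustering):
    stats = stats_from_clusters(clustering.clusters, ["PUN124", "GHOST"])
    assert [s.locus for s in stats] == ["PUN124"]
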