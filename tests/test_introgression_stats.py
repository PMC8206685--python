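"""Statistic family vs exhaustive brute-force oracles, plus the algebraic
identities (antisymmetry, additivity, conditioning monotonicity)."""

import numpy as np
import pytest

from archstats.genotype_io import MISSING
from archstats.introgression_stats import (classify_archaic_state,
                                           classify_site_pattern, compute_AFD,
                                           compute_D, compute_FST, compute_f4,
                                           compute_heterozygosity, compute_nd,
                                           heterozygosity_loss,
                                           nd_to_genomic_fraction)

from conftest import make_table, random_table


# ---------------------------------------------------------------------------
# brute-force oracles: explicit per-site loops, independent of the vectorized
# implementations


def oracle_D(table, s1, s2, archaic):
    abba = baba = 0.0
    for _, row in table.df.iterrows():
        if row[f"state_{archaic}"] != 1:
            continue
        g1, g2 = row[f"gt_{s1}"], row[f"gt_{s2}"]
        if g1 < 0 or g2 < 0:
            continue
        x1, x2 = g1 / 2, g2 / 2
        abba += (1 - x1) * x2
        baba += x1 * (1 - x2)
    if abba + baba == 0:
        return None
    return (abba - baba) / (abba + baba)


def oracle_nd(table, pop, focal, conditioned, mclass, panel):
    num = 0.0
    N = 0
    singular = {"transitions": "transition", "transversions": "transversion"}
    for _, row in table.df.iterrows():
        if mclass != "both" and row.mutation_class != singular[mclass]:
            continue
        N += 1
        nea, den = row.state_neanderthal, row.state_denisovan
        if focal == "neanderthal":
            ok = nea == 1 and den == 0
        else:
            ok = den == 1 and nea == 0
        if not ok:
            continue
        if conditioned:
            b = sum(row[f"bcount_{p}"] for p in panel)
            n = sum(row[f"ncalled_{p}"] for p in panel)
            if b > 0 or n == 0:
                continue
        if row[f"ncalled_{pop}"] == 0:
            continue
        num += row[f"bcount_{pop}"] / row[f"ncalled_{pop}"]
    return num / N if N else 0.0


def freq_of(table, row, name):
    if name in table.populations:
        n = row[f"ncalled_{name}"]
        return row[f"bcount_{name}"] / n if n > 0 else None
    if name in table.taxa:
        s = row[f"state_{name}"]
        return None if s < 0 else float(s)
    g = row[f"gt_{name}"]
    return None if g < 0 else g / 2


def oracle_f4(table, p1, p2, p3, p4):
    prods = []
    for _, row in table.df.iterrows():
        fs = [freq_of(table, row, p) for p in (p1, p2, p3, p4)]
        if any(f is None for f in fs):
            continue
        prods.append((fs[0] - fs[1]) * (fs[2] - fs[3]))
    return float(np.mean(prods)) if prods else None


def oracle_afd(table, a, b):
    diffs = []
    for _, row in table.df.iterrows():
        fa, fb = freq_of(table, row, a), freq_of(table, row, b)
        if fa is None or fb is None:
            continue
        diffs.append(abs(fa - fb))
    return float(np.mean(diffs))


def oracle_fst(table, a, b):
    num = den = 0.0
    for _, row in table.df.iterrows():
        na, nb = row[f"ncalled_{a}"], row[f"ncalled_{b}"]
        if na < 2 or nb < 2:
            continue
        pa, pb = row[f"bcount_{a}"] / na, row[f"bcount_{b}"] / nb
        num += (pa - pb) ** 2 - pa * (1 - pa) / (na - 1) - pb * (1 - pb) / (nb - 1)
        den += pa * (1 - pb) + pb * (1 - pa)
    return num / den if den else None


def oracle_het(table, pop):
    hs = []
    for _, row in table.df.iterrows():
        n = row[f"ncalled_{pop}"]
        if n == 0:
            continue
        p = row[f"bcount_{pop}"] / n
        hs.append(2 * p * (1 - p))
    return float(np.mean(hs))


@pytest.mark.parametrize("seed", [0, 1, 2, 3])
def test_all_statistics_match_brute_force(seed):
    rng = np.random.default_rng(seed)
    table = random_table(rng, n_sites=50)
    panel = ("P3",)

    d = compute_D(table, "s0", "s1", "neanderthal")
    expected = oracle_D(table, "s0", "s1", "neanderthal")
    if expected is None:
        assert not d.defined
    else:
        assert d.D == pytest.approx(expected, abs=1e-12)

    for focal in ("neanderthal", "denisovan"):
        for conditioned in (False, True):
            for mclass in ("both", "transitions", "transversions"):
                res = compute_nd(table, "P1", focal, conditioned=conditioned,
                                 mutation_class=mclass, conditioning_panel=panel)
                assert res.nd == pytest.approx(
                    oracle_nd(table, "P1", focal, conditioned, mclass, panel),
                    abs=1e-12)

    f4 = compute_f4(table, "P1", "P2", "neanderthal", "chimpanzee")
    assert f4.f4 == pytest.approx(
        oracle_f4(table, "P1", "P2", "neanderthal", "chimpanzee"), abs=1e-12)

    afd = compute_AFD(table, "P1", "P2")
    assert afd.value == pytest.approx(oracle_afd(table, "P1", "P2"), abs=1e-12)

    fst = compute_FST(table, "P1", "P2")
    assert fst.value == pytest.approx(oracle_fst(table, "P1", "P2"), abs=1e-12)

    assert compute_heterozygosity(table, "P1") == pytest.approx(
        oracle_het(table, "P1"), abs=1e-12)


# ---------------------------------------------------------------------------
# site-pattern classification


class TestPatterns:
    def test_abba_baba_definitions(self):
        assert classify_site_pattern(0, 2, 1) == "ABBA"
        assert classify_site_pattern(2, 0, 1) == "BABA"

    def test_equal_humans_uninformative(self):
        for g in (0, 1, 2):
            assert classify_site_pattern(g, g, 1) == "uninformative"

    def test_archaic_ancestral_or_missing_uninformative(self):
        assert classify_site_pattern(0, 2, 0) == "uninformative"
        assert classify_site_pattern(0, 2, MISSING) == "uninformative"
        assert classify_site_pattern(MISSING, 2, 1) == "uninformative"

    def test_archaic_state_configurations(self):
        assert classify_archaic_state(1, 0) == "XXBAA"
        assert classify_archaic_state(0, 1) == "XXABA"
        assert classify_archaic_state(1, 1) == "XXBBA"
        assert classify_archaic_state(0, 0) == "other"
        assert classify_archaic_state(MISSING, 1) == "other"


# ---------------------------------------------------------------------------
# D


class TestD:
    def test_arithmetic_105_95(self):
        """ABBA=105, BABA=95 -> D = 0.05 (fixed opposite-homozygote sites)."""
        n = 200
        nea = np.ones(n, dtype=int)
        den = np.zeros(n, dtype=int)
        s1 = np.array([0] * 105 + [2] * 95)
        s2 = 2 - s1
        table = make_table(nea, den, {"P1": s1}, {"P1": np.full(n, 2)},
                           {"a": s1, "b": s2})
        res = compute_D(table, "a", "b", "neanderthal")
        assert res.abba == 105 and res.baba == 95
        assert res.D == pytest.approx(0.05)

    def test_antisymmetry(self):
        rng = np.random.default_rng(11)
        table = random_table(rng)
        d12 = compute_D(table, "s0", "s1", "neanderthal")
        d21 = compute_D(table, "s1", "s0", "neanderthal")
        assert d12.D == pytest.approx(-d21.D, abs=1e-12)

    def test_same_individual_undefined(self):
        rng = np.random.default_rng(3)
        table = random_table(rng)
        assert not compute_D(table, "s0", "s0", "neanderthal").defined

    def test_zero_informative_flagged_not_raised(self):
        table = make_table([0, 0], [0, 0], {"P1": [1, 1]}, {"P1": [2, 2]},
                           {"a": [0, 2], "b": [2, 0]})
        assert not compute_D(table, "a", "b", "neanderthal").defined

    def test_conditioning_restricts_to_zygosity(self):
        nea = [1, 1, 1, 1]
        table = make_table(nea, [0] * 4, {"P1": [1] * 4}, {"P1": [2] * 4},
                           {"a": [1, 0, 2, 1], "b": [2, 2, 0, 0]})
        het = compute_D(table, "a", "b", "neanderthal", conditioning="het-p1")
        full = compute_D(table, "a", "b", "neanderthal")
        # only sites 1 and 4 (a heterozygous) contribute
        assert het.abba + het.baba == pytest.approx(
            (0.5 * 1 + 0.5 * 0) + (0.5 * 0 + 0.5 * 1))
        assert full.abba + full.baba > het.abba + het.baba

    def test_haplotype_mode_is_seeded_and_agrees_on_fixed_sites(self):
        n = 100
        s1 = np.repeat([0, 2], 50)
        s2 = 2 - s1
        table = make_table(np.ones(n, int), np.zeros(n, int),
                           {"P1": s1}, {"P1": np.full(n, 2)}, {"a": s1, "b": s2})
        d1 = compute_D(table, "a", "b", "neanderthal", mode="haplotype", seed=9)
        d2 = compute_D(table, "a", "b", "neanderthal", mode="haplotype", seed=9)
        assert d1 == d2
        # all sites homozygous: haplotype sampling changes nothing
        assert d1.D == compute_D(table, "a", "b", "neanderthal").D


# ---------------------------------------------------------------------------
# nd


class TestNd:
    def test_arithmetic_example(self):
        """Two qualifying sites with focal frequencies 0.25 and 0.75 among 10
        callable sites -> nd = 0.10."""
        nea = [1, 1] + [0] * 8
        den = [0] * 10
        table = make_table(nea, den,
                           {"P": [1, 3] + [0] * 8, "AFR": [0] * 10},
                           {"P": [4] * 10, "AFR": [6] * 10})
        res = compute_nd(table, "P", "neanderthal", conditioned=True,
                         conditioning_panel=("AFR",))
        assert res.numerator == pytest.approx(1.0)
        assert res.N == 10
        assert res.nd == pytest.approx(0.10)

    def test_panel_population_has_zero_conditioned_nd(self, small_sim_table):
        res = compute_nd(small_sim_table, "african", "neanderthal",
                         conditioned=True, conditioning_panel=("african",))
        assert res.nd == 0.0

    def test_conditioned_at_most_unconditioned(self):
        rng = np.random.default_rng(21)
        for _ in range(5):
            table = random_table(rng)
            for focal in ("neanderthal", "denisovan"):
                cond = compute_nd(table, "P1", focal, conditioned=True,
                                  conditioning_panel=("P3",))
                unc = compute_nd(table, "P1", focal, conditioned=False)
                assert cond.nd <= unc.nd + 1e-15

    def test_ts_tv_numerators_are_additive(self):
        rng = np.random.default_rng(8)
        table = random_table(rng)
        parts = [compute_nd(table, "P2", "denisovan", conditioned=False,
                            mutation_class=m).numerator
                 for m in ("transitions", "transversions")]
        total = compute_nd(table, "P2", "denisovan", conditioned=False,
                           mutation_class="both").numerator
        assert sum(parts) == pytest.approx(total, abs=1e-12)

    def test_empty_panel_is_configuration_error(self):
        rng = np.random.default_rng(2)
        table = random_table(rng)
        with pytest.raises(ValueError):
            compute_nd(table, "P1", "neanderthal", conditioned=True,
                       conditioning_panel=())

    def test_xxbba_sites_count_in_N_but_not_numerator(self):
        nea = [1, 1]
        den = [1, 0]  # first site XXBBA, second XXBAA
        table = make_table(nea, den, {"P": [2, 2], "AFR": [0, 0]},
                           {"P": [4, 4], "AFR": [4, 4]})
        res = compute_nd(table, "P", "neanderthal", conditioned=True,
                         conditioning_panel=("AFR",))
        assert res.n_qualifying == 1
        assert res.N == 2

    def test_genomic_fraction_rescaling(self):
        assert nd_to_genomic_fraction(0.03, 0.02, 0.02) == pytest.approx(0.03)


# ---------------------------------------------------------------------------
# f4 / AFD / FST / heterozygosity


class TestF4:
    def test_zero_when_p1_equals_p2(self):
        table = make_table([1, 0, 1], [0, 1, 0],
                           {"P1": [1, 2, 0], "P2": [1, 2, 0]},
                           {"P1": [4, 4, 4], "P2": [4, 4, 4]})
        assert compute_f4(table, "P1", "P2", "neanderthal", "chimpanzee").f4 == 0.0

    def test_antisymmetry_in_both_pairs(self):
        rng = np.random.default_rng(13)
        table = random_table(rng)
        base = compute_f4(table, "P1", "P2", "neanderthal", "chimpanzee").f4
        swapped = compute_f4(table, "P2", "P1", "neanderthal", "chimpanzee").f4
        swapped2 = compute_f4(table, "P1", "P2", "chimpanzee", "neanderthal").f4
        assert base == pytest.approx(-swapped, abs=1e-12)
        assert base == pytest.approx(-swapped2, abs=1e-12)

    def test_same_genome_in_second_pair_is_exactly_zero(self):
        rng = np.random.default_rng(14)
        table = random_table(rng)
        assert compute_f4(table, "P1", "P2", "neanderthal", "neanderthal").f4 == 0.0

    def test_no_shared_sites_flagged(self):
        table = make_table([MISSING], [0], {"P1": [1], "P2": [0]},
                           {"P1": [2], "P2": [2]})
        res = compute_f4(table, "P1", "P2", "neanderthal", "chimpanzee")
        assert not res.defined


class TestDistances:
    def test_afd_identity_and_fixed_difference(self):
        table = make_table([1, 0], [0, 1], {"A": [4, 0], "B": [0, 4]},
                           {"A": [4, 4], "B": [4, 4]})
        assert compute_AFD(table, "A", "A").value == 0.0
        assert compute_AFD(table, "A", "B").value == 1.0

    def test_fst_fixed_difference_is_one(self):
        table = make_table([1, 0], [0, 1], {"A": [6, 0], "B": [0, 6]},
                           {"A": [6, 6], "B": [6, 6]})
        assert compute_FST(table, "A", "B").value == pytest.approx(1.0)

    def test_fst_monomorphic_everywhere_flagged(self):
        table = make_table([1], [0], {"A": [0], "B": [0]},
                           {"A": [4], "B": [4]})
        assert not compute_FST(table, "A", "B").defined


class TestHeterozygosity:
    def test_fixed_sites_give_zero(self):
        table = make_table([1, 0], [0, 0], {"A": [0, 4]}, {"A": [4, 4]})
        assert compute_heterozygosity(table, "A") == 0.0

    def test_single_half_frequency_site(self):
        """p=0.5 at one of ten sites -> mean H = 0.5/10 = 0.05."""
        b = [2] + [0] * 9
        table = make_table([0] * 10, [0] * 10, {"A": b}, {"A": [4] * 10})
        assert compute_heterozygosity(table, "A") == pytest.approx(0.05)

    def test_loss_is_relative_deficit(self):
        b_ref = [2, 2, 0, 4]
        b_foc = [0, 4, 0, 4]   # focal has no heterozygosity
        table = make_table([0] * 4, [0] * 4, {"R": b_ref, "F": b_foc},
                           {"R": [4] * 4, "F": [4] * 4})
        assert heterozygosity_loss(table, "R", "F") == pytest.approx(1.0)
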