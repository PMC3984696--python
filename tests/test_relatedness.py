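import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from matekin.genotype_io import Individual, MicrosatGenotype, Population
from matekin.relatedness import (
    AlleleFrequencyTable,
    allele_frequencies,
    hwe_exact_test,
    internal_relatedness,
    locus_summaries,
    mhc_allele_sharing,
    pairwise_relatedness,
)

from conftest import make_population


# ---------------------------------------------------------------------------
# independent brute-force oracles
# ---------------------------------------------------------------------------

def ir_brute(calls, freqs):
    """Reference IR: (2H - sum f) / (2N - sum f) over typed loci, summing the
    frequency of every allele copy."""
    H = N = 0
    S = 0.0
    for locus, (a, b) in calls.items():
        if a == 0:
            continue
        N += 1
        H += a == b
        S += freqs[locus][a] + freqs[locus][b]
    return (2 * H - S) / (2 * N - S)


def qg_brute(x, y, pop):
    """Reference Queller-Goodnight: explicit per-locus sums with frequencies
    recounted from scratch excluding the dyad."""
    nx = dx = ny = dy = 0.0
    for locus in pop.locus_names:
        a, b = x.genotype.calls[locus]
        c, d = y.genotype.calls[locus]
        if a == 0 or c == 0:
            continue
        cnt: dict[int, int] = {}
        for ind in pop.individuals.values():
            if ind.id in (x.id, y.id):
                continue
            aa, bb = ind.genotype.calls[locus]
            if aa != 0:
                cnt[aa] = cnt.get(aa, 0) + 1
                cnt[bb] = cnt.get(bb, 0) + 1
        tot = sum(cnt.values())
        p = lambda al: cnt.get(al, 0) / tot  # noqa: E731
        I = lambda u, v: float(u == v)  # noqa: E731
        cross = 0.5 * (I(a, c) + I(a, d) + I(b, c) + I(b, d))
        numx, denx = cross - p(a) - p(b), 1 + I(a, b) - p(a) - p(b)
        numy, deny = cross - p(c) - p(d), 1 + I(c, d) - p(c) - p(d)
        if denx == 0 and deny == 0:
            continue
        nx, dx, ny, dy = nx + numx, dx + denx, ny + numy, dy + deny
    return 0.5 * (nx / dx + ny / dy)


# ---------------------------------------------------------------------------
# allele frequencies
# ---------------------------------------------------------------------------

class TestAlleleFrequencies:
    def test_counting_and_exclusion(self):
        pop = make_population(
            {"x": {"L1": (1, 1)}, "y": {"L1": (1, 2)}}, ["L1"]
        )
        ft = allele_frequencies(pop)
        assert ft.freqs["L1"] == {1: 0.75, 2: 0.25}
        assert ft.sample_sizes["L1"] == 4
        ft2 = allele_frequencies(pop, exclude={"y"})
        assert ft2.freqs["L1"] == {1: 1.0}

    def test_zero_typed_copies_raises(self):
        pop = make_population({"x": {"L1": (0, 0)}}, ["L1"])
        with pytest.raises(ValueError, match="L1"):
            allele_frequencies(pop)

    def test_estimates_near_generator_truth(self, three_year_pop):
        pop, truth = three_year_pop
        ft = allele_frequencies(pop)
        for locus, fs in truth.locus_freqs.items():
            n = ft.sample_sizes[locus]
            for allele, p in fs.items():
                phat = ft.freqs[locus].get(allele, 0.0)
                # 4 sigma binomial sampling band
                assert abs(phat - p) < 4 * np.sqrt(p * (1 - p) / n) + 1e-9


# ---------------------------------------------------------------------------
# internal relatedness
# ---------------------------------------------------------------------------

class TestInternalRelatedness:
    def test_forced_values_single_locus(self):
        ft = AlleleFrequencyTable({"L1": {1: 0.5, 2: 0.5}}, {"L1": 4})
        assert internal_relatedness(MicrosatGenotype({"L1": (1, 1)}), ft) == 1.0
        assert internal_relatedness(MicrosatGenotype({"L1": (1, 2)}), ft) == -1.0

    def test_matches_brute_force(self, rng):
        loci = [f"L{i}" for i in range(12)]
        genos = {
            f"a{i}": {
                l: (int(rng.integers(1, 15)), int(rng.integers(1, 15))) for l in loci
            }
            for i in range(100)
        }
        pop = make_population(genos, loci)
        ft = allele_frequencies(pop)
        for g in genos.values():
            got = internal_relatedness(MicrosatGenotype(g), ft)
            assert got == pytest.approx(ir_brute(g, ft.freqs), abs=1e-12)

    def test_fully_homozygous_is_one(self, rng):
        loci = [f"L{i}" for i in range(5)]
        g = {l: (3, 3) for l in loci}
        pop = make_population({"a": g, "b": {l: (1, 3) for l in loci}}, loci)
        ft = allele_frequencies(pop)
        assert internal_relatedness(MicrosatGenotype(g), ft) == pytest.approx(1.0)

    def test_errors(self):
        ft = AlleleFrequencyTable({"L1": {1: 1.0}}, {"L1": 2})
        with pytest.raises(ValueError):
            internal_relatedness(MicrosatGenotype({"L1": (0, 0)}), ft)
        with pytest.raises(KeyError):
            internal_relatedness(MicrosatGenotype({"L1": (2, 2)}), ft)

    def test_homozygous_swap_increases_ir(self):
        # replacing one heterozygous locus by a homozygous one raises IR
        loci = ["L1", "L2", "L3"]
        ft = AlleleFrequencyTable(
            {l: {1: 0.4, 2: 0.3, 3: 0.3} for l in loci},
            {l: 10 for l in loci},
        )
        het = {l: (1, 2) for l in loci}
        hom = dict(het, L2=(1, 1))
        assert internal_relatedness(
            MicrosatGenotype(hom), ft
        ) > internal_relatedness(MicrosatGenotype(het), ft)

    def test_near_zero_mean_at_hwe(self, rng):
        loci = [f"L{i}" for i in range(12)]
        genos = {
            f"a{i}": {
                l: (int(rng.integers(1, 11)), int(rng.integers(1, 11))) for l in loci
            }
            for i in range(500)
        }
        pop = make_population(genos, loci)
        ft = allele_frequencies(pop)
        irs = [internal_relatedness(pop[i].genotype, ft) for i in genos]
        assert abs(np.mean(irs)) < 0.02

    @given(st.permutations(list(range(6))), st.integers(1, 1000))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_invariant_to_locus_order_and_relabeling(self, perm, shift):
        loci = [f"L{i}" for i in range(6)]
        base = {l: (i % 3 + 1, (i + 1) % 3 + 1) for i, l in enumerate(loci)}
        freqs = {l: {1: 0.5, 2: 0.3, 3: 0.2} for l in loci}
        ft = AlleleFrequencyTable(freqs, {l: 10 for l in loci})
        ref = internal_relatedness(MicrosatGenotype(base), ft)
        # permute locus order
        permuted = {loci[j]: base[loci[j]] for j in perm}
        assert internal_relatedness(MicrosatGenotype(permuted), ft) == ref
        # relabel alleles by an order-preserving shift
        shifted = {l: (a + shift, b + shift) for l, (a, b) in base.items()}
        ft2 = AlleleFrequencyTable(
            {l: {a + shift: f for a, f in fs.items()} for l, fs in freqs.items()},
            {l: 10 for l in loci},
        )
        assert internal_relatedness(MicrosatGenotype(shifted), ft2) == ref


# ---------------------------------------------------------------------------
# pairwise relatedness
# ---------------------------------------------------------------------------

class TestPairwiseRelatedness:
    def test_self_relatedness_is_one(self, rng):
        loci = ["L1", "L2"]
        pop = make_population(
            {
                "a": {l: (1, 2) for l in loci},
                "b": {l: (2, 3) for l in loci},
                "c": {l: (1, 3) for l in loci},
            },
            loci,
        )
        assert pairwise_relatedness(pop["a"], pop["a"], pop) == 1.0

    def test_matches_brute_force_small_instances(self, rng):
        loci = ["L1", "L2", "L3"]
        genos = {
            f"a{i}": {
                l: (int(rng.integers(1, 5)), int(rng.integers(1, 5))) for l in loci
            }
            for i in range(20)
        }
        pop = make_population(genos, loci)
        ids = list(genos)
        for i in range(0, 18, 2):
            x, y = pop[ids[i]], pop[ids[i + 1]]
            assert pairwise_relatedness(x, y, pop) == pytest.approx(
                qg_brute(x, y, pop), abs=1e-12
            )

    def test_symmetry(self, rng):
        loci = ["L1", "L2", "L3"]
        genos = {
            f"a{i}": {
                l: (int(rng.integers(1, 6)), int(rng.integers(1, 6))) for l in loci
            }
            for i in range(16)
        }
        pop = make_population(genos, loci)
        for i in range(0, 14, 2):
            x, y = pop[f"a{i}"], pop[f"a{i + 1}"]
            assert pairwise_relatedness(x, y, pop) == pytest.approx(
                pairwise_relatedness(y, x, pop), abs=1e-12
            )

    def test_parent_offspring_and_unrelated_calibration(self):
        # smaller version of the full calibration (acceptance runs n=500)
        rng = np.random.default_rng(5)
        loci = [f"L{i}" for i in range(12)]
        inds, pairs = {}, []
        for i in range(150):
            p1 = {l: (int(rng.integers(1, 11)), int(rng.integers(1, 11))) for l in loci}
            p2 = {l: (int(rng.integers(1, 11)), int(rng.integers(1, 11))) for l in loci}
            child = {l: (p1[l][rng.integers(0, 2)], p2[l][rng.integers(0, 2)]) for l in loci}
            inds[f"x{i}"] = Individual(f"x{i}", "male", "adult", genotype=MicrosatGenotype(p1))
            inds[f"y{i}"] = Individual(f"y{i}", "female", "adult", genotype=MicrosatGenotype(child))
            pairs.append((f"x{i}", f"y{i}"))
        pop = Population(individuals=inds, locus_names=loci)
        rs = [pairwise_relatedness(pop[a], pop[b], pop) for a, b in pairs]
        assert np.mean(rs) == pytest.approx(0.5, abs=0.05)
        unrel = [
            pairwise_relatedness(pop[pairs[i][0]], pop[pairs[i + 1][1]], pop)
            for i in range(0, 148, 2)
        ]
        assert np.mean(unrel) == pytest.approx(0.0, abs=0.05)

    def test_all_loci_dropped_raises(self):
        pop = make_population({"a": {"L1": (1, 1)}, "b": {"L1": (0, 0)}}, ["L1"])
        with pytest.raises(ValueError, match="undefined"):
            pairwise_relatedness(pop["a"], pop["b"], pop)


# ---------------------------------------------------------------------------
# MHC allele sharing
# ---------------------------------------------------------------------------

class TestAlleleSharing:
    @pytest.mark.parametrize(
        "a, b, expect",
        [
            ({1, 2}, {2, 3}, 0.5),
            ({1, 2, 3}, {1, 2, 3}, 1.0),
            ({1, 2}, {3, 4}, 0.0),
            ({1}, {1, 2, 3}, 0.5),
        ],
    )
    def test_forced_values(self, a, b, expect):
        assert mhc_allele_sharing(a, b) == pytest.approx(expect)

    def test_empty_profile_raises(self):
        with pytest.raises(ValueError):
            mhc_allele_sharing(set(), {1})

    @given(
        st.sets(st.integers(1, 40), min_size=1, max_size=6),
        st.sets(st.integers(1, 40), min_size=1, max_size=6),
    )
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_symmetric_and_bounded(self, a, b):
        d = mhc_allele_sharing(a, b)
        assert d == mhc_allele_sharing(b, a)
        assert 0.0 <= d <= 1.0


# ---------------------------------------------------------------------------
# locus summaries and HWE
# ---------------------------------------------------------------------------

class TestLocusSummaries:
    def test_forced_small_cases(self, rng):
        pop = make_population(
            {"a": {"L1": (1, 2), "L2": (1, 1)}, "b": {"L1": (1, 2), "L2": (1, 1)}},
            ["L1", "L2"],
        )
        s = {x.locus: x for x in locus_summaries(pop, rng=rng, n_perm=200)}
        assert s["L1"].Hobs == 1.0 and s["L1"].k == 2 and s["L1"].N == 2
        assert s["L2"].Hexp == 0.0 and s["L2"].hwe_p == 1.0 and s["L2"].k == 1

    def test_hexp_unbiased_formula(self, rng):
        pop = make_population(
            {"a": {"L1": (1, 1)}, "b": {"L1": (2, 2)}}, ["L1"]
        )
        (s,) = locus_summaries(pop, rng=rng, n_perm=200)
        # n=2, p=(0.5,0.5): 2n/(2n-1) * (1 - 0.5) = 4/3 * 0.5
        assert s.Hexp == pytest.approx(2 / 3)

    def test_hwe_detects_heterozygote_deficit(self, rng):
        # strongly inbred sample: all homozygotes at a 2-allele locus
        genos = {f"a{i}": {"L1": (1 + i % 2, 1 + i % 2)} for i in range(60)}
        pop = make_population(genos, ["L1"])
        (s,) = locus_summaries(pop, rng=rng, n_perm=500)
        assert s.hwe_p < 0.01

    def test_hwe_p_uniform_under_null(self):
        # smaller version of the full calibration (acceptance runs 500 loci)
        rng = np.random.default_rng(77)
        ps = []
        for _ in range(150):
            k = int(rng.integers(4, 13))
            p = rng.dirichlet(np.ones(k))
            codes = rng.choice(k, size=(200, 2), p=p)
            ps.append(hwe_exact_test(codes, n_perm=500, rng=rng))
        assert stats.kstest(ps, "uniform").pvalue > 0.01
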