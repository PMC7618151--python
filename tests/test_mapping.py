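"""Rate model, posteriors, filters, map construction, EM, bootstrap."""

import numpy as np
import pytest

from xovermap.model import (
    CoverageProfile,
    CrossoverMapModel,
    MapWithCI,
    RateModel,
    RecombinationMap,
    correction_factor,
    delta_r_regions,
    double_crossover_adjust,
    edge_trim,
    effective_coverage,
    em_refine,
    estimate_baseline_rate,
    filter_imbalanced_snps,
    initial_map,
    map_length_cM,
    posterior_crossover,
    read_map_tsv,
)

from conftest import build_pair, random_pairs


def model(r_star=1e-8, f=0.0):
    return RateModel("chr1", r_star, f)


class TestBaselineRate:
    def test_hand_countable_ratio(self):
        pairs = [
            build_pair(left=1, right=2_000_001, status="C" if i < 2 else "N")
            for i in range(10)
        ]
        assert estimate_baseline_rate(pairs) == pytest.approx(2 / 2e7)

    def test_no_crossovers_gives_zero(self):
        pairs = [build_pair(left=1, right=2_000_001, status="N")] * 4
        assert estimate_baseline_rate(pairs) == 0.0

    def test_doubling_insert_halves_rate(self):
        short = [build_pair(left=1, right=2_000_001, status="C")]
        long = [build_pair(left=1, right=4_000_001, status="C")]
        assert estimate_baseline_rate(long) == pytest.approx(
            estimate_baseline_rate(short) / 2
        )

    def test_no_long_pairs_errors(self):
        with pytest.raises(ValueError, match="long_threshold"):
            estimate_baseline_rate([build_pair(left=1, right=500)])


class TestCorrectionFactor:
    def test_direct_arithmetic(self):
        pairs = [build_pair(left=1, right=501, status="C") for _ in range(5)]
        f = correction_factor(pairs, r_star=1e-8)
        assert f == pytest.approx((5 - 5 * 500 * 1e-8) / 5)
        assert f == pytest.approx(0.9999950)

    def test_no_short_pairs_gives_zero(self):
        assert correction_factor([build_pair(left=1, right=5_000)], 1e-8) == 0.0

    def test_denominator_counts_all_short_pairs(self):
        """n_short counts N pairs too: one false-positive C among many
        short N pairs estimates a small error rate, not ~1."""
        pairs = [build_pair(left=1, right=501, status="C")]
        pairs += [build_pair(left=1, right=501, status="N") for _ in range(99)]
        assert correction_factor(pairs, r_star=0.0) == pytest.approx(0.01)


class TestPosterior:
    def test_certain_crossover(self, pair_factory):
        pair = pair_factory(left=1, right=1_000_001, status="C")
        assert posterior_crossover(pair, model(r_star=1e-8)) == pytest.approx(1.0)

    def test_numerator_vanishes_at_lc_equals_f(self, pair_factory):
        import dataclasses

        pair = dataclasses.replace(
            pair_factory(left=1, right=1_000_001, status="C"), lc=0.3, ln=0.7
        )
        assert posterior_crossover(pair, model(r_star=1e-8, f=0.3)) == 0.0

    def test_worked_example(self, pair_factory):
        import dataclasses

        pair = dataclasses.replace(
            pair_factory(left=1, right=1_000_001, status="C"), lc=0.97, ln=0.03
        )
        m = model(r_star=1e-8, f=0.01)  # pc = 0.01
        expected = (0.96 * 0.01) / (0.96 * 0.01 + 0.04 * 0.99)
        p = posterior_crossover(pair, m)
        assert p == pytest.approx(expected) == pytest.approx(0.1951, abs=1e-4)

    def test_monotone_in_d_and_f(self, pair_factory):
        ps = [
            posterior_crossover(
                pair_factory(left=1, right=1 + d, status="C", b1=0.01, b2=0.01),
                model(r_star=1e-8, f=0.005),
            )
            for d in (10_000, 100_000, 1_000_000)
        ]
        assert ps == sorted(ps)
        pf = [
            posterior_crossover(
                pair_factory(left=1, right=1_000_001, status="C", b1=0.01, b2=0.01),
                model(r_star=1e-8, f=f),
            )
            for f in (0.0, 0.01, 0.05)
        ]
        assert pf == sorted(pf, reverse=True)

    def test_plain_noncrossover_posterior_zero(self, pair_factory):
        pair = pair_factory(left=1, right=500_000, status="N")
        assert posterior_crossover(pair, model(r_star=1e-8, f=0.01)) == 0.0


class TestImbalancedSnps:
    def test_two_c_zero_n_removed(self):
        pairs = [build_pair(left=100, right=900, status="C"),
                 build_pair(left=100, right=700, status="C")]
        kept, removed = filter_imbalanced_snps(pairs)
        assert kept == [] and ("chr1", 100) in removed

    def test_two_c_one_n_kept(self):
        pairs = [build_pair(left=100, right=900, status="C"),
                 build_pair(left=100, right=700, status="C"),
                 build_pair(left=100, right=800, status="N")]
        kept, removed = filter_imbalanced_snps(pairs)
        assert len(kept) == 3 and removed == []

    def test_single_c_kept(self):
        pairs = [build_pair(left=100, right=900, status="C")]
        kept, removed = filter_imbalanced_snps(pairs)
        assert len(kept) == 1 and removed == []

    def test_iterates_until_stable(self):
        """Removing one bad SNP's pairs can strip the N support of a
        second SNP, which must then fall too."""
        pairs = [
            build_pair(left=100, right=900, status="C"),
            build_pair(left=100, right=500, status="C"),
            build_pair(left=500, right=700, status="N"),  # bounds 500, dies with SNP 100? no: with 500
            build_pair(left=700, right=950, status="C"),
            build_pair(left=700, right=960, status="C"),
        ]
        # SNP 700 bounds: 1 N + 2 C -> kept initially; SNP 100 bounds 2 C,
        # 0 N -> removed with its pairs; SNP 500 loses its C pair but keeps
        # its N pair; SNP 700 still has the N pair, stays.
        kept, removed = filter_imbalanced_snps(pairs)
        assert ("chr1", 100) in removed
        # now drop the N pair's support instead: make it bound SNP 100
        pairs[2] = build_pair(left=100, right=700, status="N")
        kept2, removed2 = filter_imbalanced_snps(pairs)
        # first pass: SNP 700 has 2 C + 1 N -> kept; SNP 100 has 2 C + 1 N -> kept
        assert removed2 == [] and len(kept2) == 5


class TestDoubleCrossover:
    def test_zero_lambda_no_change(self, pair_factory):
        pair = pair_factory(left=1, right=2_000_001, status="N")
        adj = double_crossover_adjust(pair, model(r_star=0.0))
        assert (adj.lc, adj.ln) == (0.0, 1.0)

    def test_poisson_closed_form(self, pair_factory):
        pair = pair_factory(left=1, right=2_000_001, status="N")
        adj = double_crossover_adjust(pair, model(r_star=0.05e-6))  # lambda=0.1
        assert adj.lc == pytest.approx(0.01 * np.exp(-0.1) / 2)
        assert adj.lc == pytest.approx(0.0045242, abs=1e-7)
        assert adj.ln == pytest.approx(1 - adj.lc)

    def test_short_pair_untouched(self, pair_factory):
        pair = pair_factory(left=1, right=500_001, status="N")
        adj = double_crossover_adjust(pair, model(r_star=1e-7))
        assert (adj.lc, adj.ln) == (0.0, 1.0)

    def test_crossover_pair_untouched(self, pair_factory):
        pair = pair_factory(left=1, right=2_000_001, status="C")
        adj = double_crossover_adjust(pair, model(r_star=1e-7))
        assert (adj.lc, adj.ln) == (pair.lc, pair.ln)


def brute_force_coverage(pairs, chrom_len):
    """Per-bp spanning count; pair covers [left, right)."""
    cov = np.zeros(chrom_len + 2)
    for p in pairs:
        cov[p.left.pos : p.right.pos] += 1
    return cov


class TestEffectiveCoverage:
    def test_single_pair(self):
        prof = effective_coverage([build_pair(left=100, right=900)])
        assert prof.at(100) == 1 and prof.at(899) == 1
        assert prof.at(99) == 0 and prof.at(900) == 0

    def test_nested_pairs(self):
        prof = effective_coverage(
            [build_pair(left=100, right=900), build_pair(left=300, right=600)]
        )
        assert prof.at(400) == 2 and prof.at(200) == 1 and prof.at(700) == 1

    def test_matches_brute_force(self, rng):
        pairs = random_pairs(rng, n=20, chrom_len=10_000)
        prof = effective_coverage(pairs)
        cov = brute_force_coverage(pairs, 10_000)
        bp = np.arange(1, 10_001)
        assert np.array_equal(prof.at(bp), cov[1:10_001])


class TestEdgeTrim:
    def test_uniform_retains_all(self):
        prof = CoverageProfile("chr1", np.array([1.0, 1000.0]), np.array([5.0]))
        assert edge_trim(prof, 3) == (1, 1000)

    def test_ramp_trims_tails_not_interior_dips(self):
        bounds = np.array([1, 100, 200, 300, 400, 500.0])
        count = np.array([1.0, 8.0, 2.0, 9.0, 1.0])  # interior dip at [200,300)
        prof = CoverageProfile("chr1", bounds, count)
        assert edge_trim(prof, 5) == (100, 400)

    def test_zero_cutoff_spans_all_pairs(self):
        prof = effective_coverage([build_pair(left=50, right=700)])
        assert edge_trim(prof, 0) == (50, 700)

    def test_unreachable_cutoff(self):
        prof = CoverageProfile("chr1", np.array([1.0, 100.0]), np.array([2.0]))
        assert edge_trim(prof, 10) is None


def brute_force_initial_map(pairs, posteriors, chrom_len, span):
    """Per-bp rate: sum of P_i/d_i over spanning pairs / coverage."""
    dens = np.zeros(chrom_len + 2)
    for p, post in zip(pairs, posteriors):
        dens[p.left.pos : p.right.pos] += post / p.d
    cov = brute_force_coverage(pairs, chrom_len)
    with np.errstate(invalid="ignore", divide="ignore"):
        rate = np.where(cov > 0, dens / cov, 0.0)
    rate[: span[0]] = 0.0
    rate[span[1] :] = 0.0
    return rate * 100.0  # cM/bp


class TestInitialMap:
    def test_single_pair_rate_and_mass(self):
        pairs = [build_pair(left=1000, right=2000, status="C")]
        prof = effective_coverage(pairs)
        m = initial_map(pairs, np.array([1.0]), prof, (1000, 2000))
        # P=1 spread over 1000 bp at coverage 1: 1e-3 M/bp = 0.1 cM/bp
        assert np.allclose(m.rate, 0.1)
        assert m.total_cM() == pytest.approx(100.0)  # mass = P = 1 Morgan

    def test_stacked_identical_pairs_same_rate(self):
        one = [build_pair(left=1000, right=2000, status="C")]
        two = one * 2
        m1 = initial_map(one, np.ones(1), effective_coverage(one), (1000, 2000))
        m2 = initial_map(two, np.ones(2), effective_coverage(two), (1000, 2000))
        assert np.allclose(m1.rate, m2.rate)

    def test_no_crossovers_zero_map(self, rng):
        pairs = random_pairs(rng, n=10, p_c=0.0)
        prof = effective_coverage(pairs)
        span = edge_trim(prof, 0)
        m = initial_map(pairs, np.zeros(len(pairs)), prof, span)
        assert np.all(m.rate == 0)

    def test_matches_brute_force(self, rng):
        pairs = random_pairs(rng, n=20, chrom_len=10_000)
        post = rng.uniform(0, 1, size=len(pairs)) * np.array(
            [p.status == "C" for p in pairs]
        )
        prof = effective_coverage(pairs)
        span = edge_trim(prof, 0)
        m = initial_map(pairs, post, prof, span)
        oracle = brute_force_initial_map(pairs, post, 10_000, span)
        mids = []
        for i in range(len(m.rate)):
            mids.append(int(m.boundaries[i]))
        got = m.rate
        exp = oracle[np.array(mids)]
        assert np.allclose(got, exp)


def brute_force_em_step(rate_bp, pairs, posteriors, cov_bp):
    """One EM pass on per-bp arrays (rate in Morgans/bp, loops, no
    vectorised tricks shared with the implementation)."""
    dens = np.zeros_like(rate_bp)
    for p, post in zip(pairs, posteriors):
        if post <= 0:
            continue
        span = slice(p.left.pos, p.right.pos)
        mass = rate_bp[span].sum()
        if mass > 0:
            w = rate_bp[span] / mass * post
        else:
            w = np.full(p.d, post / p.d)
        dens[span] += w
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(cov_bp > 0, dens / cov_bp, 0.0)


class TestEmRefine:
    def test_single_pair_is_fixed_point(self):
        pairs = [build_pair(left=1000, right=2000, status="C")]
        prof = effective_coverage(pairs)
        m0 = initial_map(pairs, np.ones(1), prof, (1000, 2000))
        m1, n = em_refine(m0, pairs, np.ones(1), prof, max_iter=1, tol=0.0)
        assert np.allclose(m1.rate, m0.rate)

    def test_matches_per_bp_oracle(self, rng):
        """Two EM passes on a random toy equal the brute-force per-bp EM."""
        pairs = random_pairs(rng, n=15, chrom_len=5_000, p_c=0.5)
        post = np.array([1.0 if p.status == "C" else 0.0 for p in pairs])
        prof = effective_coverage(pairs)
        span = edge_trim(prof, 0)
        m0 = initial_map(pairs, post, prof, span)
        refined, _ = em_refine(m0, pairs, post, prof, max_iter=2, tol=0.0)
        # oracle on per-bp arrays
        L = 5_001
        cov = brute_force_coverage(pairs, L)[:L]
        rate_bp = np.zeros(L)
        for i in range(len(m0.rate)):
            rate_bp[int(m0.boundaries[i]) : int(m0.boundaries[i + 1])] = m0.rate[i] / 100.0
        for _ in range(2):
            rate_bp = brute_force_em_step(rate_bp, pairs, post, cov)
        sample = np.array([int(b) for b in refined.boundaries[:-1]])
        assert np.allclose(refined.rate / 100.0, rate_bp[sample], rtol=1e-9, atol=1e-15)

    def test_mass_conserved_every_iteration(self, rng):
        """Coverage-weighted map mass equals the summed posteriors after
        every EM pass; with uniform coverage the genetic length itself is
        conserved to 1e-9 relative."""
        pairs = random_pairs(rng, n=30, chrom_len=8_000, p_c=0.4)
        post = rng.uniform(0.2, 1.0, len(pairs)) * np.array(
            [p.status == "C" for p in pairs]
        )
        prof = effective_coverage(pairs)
        span = edge_trim(prof, 0)
        flat = CoverageProfile(prof.chrom, prof.boundaries, np.ones_like(prof.count))
        m = initial_map(pairs, post, flat, span)
        total_post = post.sum() * 100.0  # cM
        assert m.total_cM() == pytest.approx(total_post, rel=1e-12)
        for _ in range(8):
            m, _ = em_refine(m, pairs, post, flat, max_iter=1, tol=0.0)
            assert m.total_cM() == pytest.approx(total_post, rel=1e-9)

    def test_two_pair_em_matches_hand_solution(self):
        """Two overlapping certain crossovers: the coverage-normalised EM
        has the flat map as its exact fixed point (hand-solved: the
        doubled density in the overlap is cancelled by doubled coverage),
        so the intervals [100,200) [200,300) [300,400) all settle at
        P/d / 1 = 0.005 M/bp = 0.5 cM/bp."""
        pairs = [
            build_pair(left=100, right=300, status="C"),
            build_pair(left=200, right=400, status="C"),
        ]
        post = np.ones(2)
        prof = effective_coverage(pairs)
        m0 = initial_map(pairs, post, prof, (100, 400))
        refined, _ = em_refine(m0, pairs, post, prof, max_iter=50, tol=1e-12)
        assert len(refined.rate) == 3
        assert np.allclose(refined.rate, 0.5)
        # and EM shifts mass away from an interval whose coverage is
        # inflated by a non-crossover pair
        pairs_n = pairs + [build_pair(left=100, right=200, status="N")]
        prof_n = effective_coverage(pairs_n)
        m0n = initial_map(pairs_n, np.array([1.0, 1.0, 0.0]), prof_n, (100, 400))
        ref_n, _ = em_refine(
            m0n, pairs_n, np.array([1.0, 1.0, 0.0]), prof_n, max_iter=50, tol=1e-12
        )
        assert ref_n.rate[0] < ref_n.rate[1]


class TestMapLength:
    def test_zero_and_unit(self):
        zero = RecombinationMap("c", [1, 1_000_001], [0.0])
        assert map_length_cM(zero) == (0.0, 0.0)
        unit = RecombinationMap("c", [1, 1_000_001], [1e-6])  # 1 cM/Mb
        cm, morgans = map_length_cM(unit)
        assert cm == pytest.approx(1.0) and morgans == pytest.approx(0.01)

    def test_matches_per_bp_sum(self, rng):
        bounds = np.sort(rng.choice(np.arange(1, 5_000), 10, replace=False)).astype(float)
        rates = rng.uniform(0, 1e-4, len(bounds) - 1)
        m = RecombinationMap("c", bounds, rates)
        per_bp = sum(
            rates[i] * (bounds[i + 1] - bounds[i]) for i in range(len(rates))
        )
        assert map_length_cM(m)[0] == pytest.approx(per_bp)

    def test_tsv_round_trip(self, tmp_path, rng):
        bounds = np.array([1.0, 500.0, 1500.0, 4000.0])
        rates = np.array([1e-6, 5e-6, 0.0])
        m = RecombinationMap("chr9", bounds, rates)
        m.to_tsv(tmp_path / "m.tsv")
        back = read_map_tsv(tmp_path / "m.tsv")["chr9"]
        assert np.allclose(back.boundaries, bounds)
        assert np.allclose(back.rate, rates)


def _sim_model(rng, n=400, chrom_len=2_000_000, p_short_c=0.02):
    """Pair set rich enough for the full pipeline (long + short inserts)."""
    pairs = []
    for _ in range(n):
        if rng.uniform() < 0.3:
            d = int(rng.integers(1_100_000, 1_800_000))
        else:
            d = int(rng.integers(200, 50_000))
        left = int(rng.integers(1, chrom_len - d))
        is_c = rng.uniform() < (0.3 if d > 1_000_000 else p_short_c)
        pairs.append(build_pair(left=left, right=left + d, status="C" if is_c else "N"))
    return CrossoverMapModel(pairs, min_cov=0)


class TestBootstrap:
    def test_single_replicate_degenerate_envelope(self, rng):
        res = _sim_model(rng).fit()
        ci = res.bootstrap(n_boot=1, seed=1)
        assert np.allclose(ci.lo95, ci.mean_map.rate)
        assert np.allclose(ci.hi95, ci.mean_map.rate)

    def test_seed_determinism(self, rng):
        res = _sim_model(rng).fit()
        a = res.bootstrap(n_boot=5, seed=42)
        b = res.bootstrap(n_boot=5, seed=42)
        assert np.array_equal(a.mean_map.rate, b.mean_map.rate)
        assert np.array_equal(a.lo95, b.lo95) and np.array_equal(a.hi95, b.hi95)

    def test_duplication_narrows_envelope(self, rng):
        base = _sim_model(rng)
        thin = CrossoverMapModel(base.pairs, min_cov=0)
        fat = CrossoverMapModel(base.pairs * 8, min_cov=0)
        w = []
        for mdl in (thin, fat):
            ci = mdl.fit().bootstrap(n_boot=15, seed=7)
            lens = np.diff(ci.mean_map.boundaries)
            w.append(np.sum((ci.hi95 - ci.lo95) * lens))
        assert w[1] < w[0]


def _ci(chrom, bounds, rate, half_width):
    rate = np.asarray(rate, dtype=float)
    m = RecombinationMap(chrom, bounds, rate)
    return MapWithCI(m, rate - half_width, rate + half_width, 10)


class TestDeltaR:
    def test_identical_maps_no_regions(self):
        a = _ci("c", [1, 1000, 2000], [1e-5, 2e-5], 1e-6)
        regions, bp, frac = delta_r_regions(a, a)
        assert regions == [] and bp == 0 and frac == 0.0

    def test_scaled_maps_full_span_then_normalized_empty(self):
        a = _ci("c", [1, 1000, 2000], [1e-5, 2e-5], 1e-7)
        b = _ci("c", [1, 1000, 2000], [1e-4, 2e-4], 1e-6)
        regions, bp, frac = delta_r_regions(a, b)
        assert frac == pytest.approx(1.0) and bp == 1999
        regions_n, _, frac_n = delta_r_regions(a, b, normalize=True)
        assert regions_n == [] and frac_n == 0.0

    def test_touching_envelopes_intersect(self):
        a = _ci("c", [1, 1000], [1e-5], 1e-6)  # hi = 1.1e-5
        b = _ci("c", [1, 1000], [1.2e-5], 1e-6)  # lo = 1.1e-5
        regions, _, _ = delta_r_regions(a, b)
        assert regions == []

    def test_disjoint_spans_empty(self):
        a = _ci("c", [1, 1000], [1e-5], 1e-6)
        b = _ci("c", [2000, 3000], [1e-5], 1e-6)
        assert delta_r_regions(a, b) == ([], 0, 0.0)


class TestModelSurface:
    def test_summary_mentions_key_quantities(self, rng):
        res = _sim_model(rng).fit()
        s = res.summary()
        assert "r*" in s and "error rate f" in s and "cM" in s

    def test_multi_chromosome_rejected(self):
        with pytest.raises(ValueError, match="chromosome"):
            CrossoverMapModel(
                [build_pair(chrom="chr1"), build_pair(chrom="chr2")]
            )

    def test_from_pairs_file(self, tmp_path, rng):
        from xovermap.infopairs import write_pairs_tsv

        mdl = _sim_model(rng)
        write_pairs_tsv(mdl.pairs, tmp_path / "p.tsv")
        res = CrossoverMapModel.from_pairs_file(tmp_path / "p.tsv", min_cov=0).fit()
        assert res.total_cM == pytest.approx(mdl.fit().total_cM)
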