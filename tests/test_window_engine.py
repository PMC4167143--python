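import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from alidrift.msa_io import Alignment, GapMode, InputError
from alidrift.scoring import ScoreTable, ScoringScheme
from alidrift.window_engine import (
    WindowParams,
    _window_rng,
    exact_null_distribution,
    exact_verdict,
    null_scores,
    pair_profile,
    window_verdict,
    windows,
)

SCHEME = ScoringScheme()


class TestWindows:
    def test_step_one_intervals(self):
        assert windows(5, 3) == [(0, 3), (1, 4), (2, 5)]

    def test_degenerate_single_window(self):
        assert windows(4, 4) == [(0, 4)]

    def test_unit_window(self):
        assert len(windows(10, 1)) == 10

    def test_window_larger_than_alignment(self):
        with pytest.raises(InputError):
            windows(3, 4)


class TestWindowParams:
    def test_permutations_must_resolve_alpha(self):
        with pytest.raises(InputError):
            WindowParams(n_permutations=10, alpha=0.05)

    def test_default_flank_equals_window(self):
        assert WindowParams(window_size=8).effective_flank == 8


class TestNullScores:
    def test_single_state_pool_gives_constant_nulls(self):
        x = np.array(list("AAAAAAAA"), dtype="U1")
        params = WindowParams(window_size=3, n_permutations=50, alpha=0.05, seed=1)
        nulls = null_scores(x, x, (2, 5), params, SCHEME)
        assert np.all(nulls == 3.0)  # w * match_score

    def test_fixed_seed_reproducible(self):
        rng_args = dict(seed=7, pair_index=(0, 1), start=2)
        x = np.array(list("ACGTACGT"), dtype="U1")
        y = np.array(list("ACGAACGA"), dtype="U1")
        params = WindowParams(window_size=3, n_permutations=40, seed=7)
        a = null_scores(x, y, (2, 5), params, SCHEME, rng=_window_rng(**rng_args))
        b = null_scores(x, y, (2, 5), params, SCHEME, rng=_window_rng(**rng_args))
        assert np.array_equal(a, b)

    def test_null_distribution_matches_enumeration(self):
        # small pools: empirical MC frequencies ~ exhaustive enumeration
        x = np.array(list("ACACAC"), dtype="U1")
        y = np.array(list("GGGGGG"), dtype="U1")
        w = 2
        params = WindowParams(window_size=w, flank=6, n_permutations=20000, seed=3)
        table = ScoreTable(SCHEME, "nucleotide", GapMode.FIFTH_STATE)
        cx, cy = table.encode(x), table.encode(y)
        nulls = null_scores(cx, cy, (2, 4), params, SCHEME,
                            rng=_window_rng(3, (0, 1), 2), table=table)
        # exhaustive oracle over all draw combinations (pool = whole row here)
        draws = []
        for xw in itertools.product(cx, repeat=w):
            for yw in itertools.product(cy, repeat=w):
                draws.append(sum(table.table[a, b] for a, b in zip(xw, yw)))
        vals, counts = np.unique(draws, return_counts=True)
        expected = counts / counts.sum()
        observed = np.array([(nulls == v).mean() for v in vals])
        assert np.allclose(observed, expected, atol=0.02)
        assert observed.sum() == 1.0  # no scores outside the enumerated support


class TestWindowVerdict:
    def test_clearly_non_random(self):
        assert window_verdict(10.0, np.zeros(100), 0.05) == 1

    def test_all_ties_are_random(self):
        assert window_verdict(5.0, np.full(100, 5.0), 0.05) == -1

    def test_threshold_is_sharp(self):
        nulls = np.concatenate([np.full(94, -1.0), np.full(6, 10.0)])
        assert window_verdict(0.0, nulls, 0.05) == -1  # beats only 94 of 100
        nulls = np.concatenate([np.full(95, -1.0), np.full(5, 10.0)])
        assert window_verdict(0.0, nulls, 0.05) == 1

    def test_empty_nulls_rejected(self):
        with pytest.raises(InputError):
            window_verdict(0.0, np.array([]), 0.05)


class TestExactNull:
    def test_convolution_matches_brute_force(self):
        table = ScoreTable(SCHEME, "nucleotide", GapMode.FIFTH_STATE)
        x_pool = table.encode(np.array(list("AACG"), dtype="U1"))
        y_pool = table.encode(np.array(list("AT"), dtype="U1"))
        w = 3
        vals, probs = exact_null_distribution(x_pool, y_pool, w, table)
        brute = {}
        for xw in itertools.product(x_pool, repeat=w):
            for yw in itertools.product(y_pool, repeat=w):
                s = sum(table.table[a, b] for a, b in zip(xw, yw))
                brute[s] = brute.get(s, 0) + 1
        total = sum(brute.values())
        assert set(np.round(vals, 6)) == set(np.round(list(brute), 6))
        for v, p in zip(vals, probs):
            assert p == pytest.approx(brute[v] / total, abs=1e-12)

    def test_exact_verdict_tie_rule(self):
        vals = np.array([0.0, 2.0])
        probs = np.array([0.96, 0.04])
        assert exact_verdict(2.0, vals, probs, 0.05) == 1
        assert exact_verdict(0.0, vals, probs, 0.05) == -1  # tie with mass 0.96


class TestPairProfile:
    def test_symmetry_exact(self, random_pair_alignment):
        aln = random_pair_alignment(n_sites=120, seed=4)
        params = WindowParams(window_size=4, n_permutations=40, alpha=0.05, seed=9)
        p1 = pair_profile(aln, "X", "Y", params)
        p2 = pair_profile(aln, "Y", "X", params)
        assert np.array_equal(p1.values, p2.values)
        assert p1.taxon_pair == p2.taxon_pair

    def test_bounds_and_edge_attenuation(self, random_pair_alignment):
        aln = random_pair_alignment(n_sites=80, seed=5)
        w = 6
        prof = pair_profile(aln, "X", "Y", WindowParams(seed=2))
        assert np.all(np.abs(prof.values) <= 1.0)
        for k in range(1, w):  # edge sites covered by k < w windows
            assert abs(prof.values[k - 1]) <= k / w + 1e-12
            assert abs(prof.values[-k]) <= k / w + 1e-12

    def test_identical_diverse_sequences_score_plus_one(self):
        rng = np.random.default_rng(0)
        row = rng.choice(list("ACGT"), size=200)
        aln = Alignment(["X", "Y"], np.vstack([row, row]))
        w = 6
        prof = pair_profile(aln, "X", "Y", WindowParams(seed=1))
        assert np.all(prof.values[w - 1:200 - w + 1] == 1.0)
        assert prof.values[0] == pytest.approx(1 / w)

    def test_constant_pair_scores_minus_one(self):
        aln = Alignment(["X", "Y"], np.array([list("A" * 50), list("A" * 50)]))
        prof = pair_profile(aln, "X", "Y", WindowParams(seed=1))
        w = 6
        assert np.all(prof.values[w - 1:50 - w + 1] == -1.0)

    def test_edge_normalize_coverage_restores_unit_edges(self):
        rng = np.random.default_rng(0)
        row = rng.choice(list("ACGT"), size=100)
        aln = Alignment(["X", "Y"], np.vstack([row, row]))
        prof = pair_profile(
            aln, "X", "Y", WindowParams(seed=1, edge_normalize_coverage=True)
        )
        assert np.all(prof.values == 1.0)

    def test_random_pair_profile_mostly_negative(self, random_pair_alignment):
        means = []
        for seed in range(5):
            aln = random_pair_alignment(n_sites=2000, seed=100 + seed)
            prof = pair_profile(aln, "X", "Y", WindowParams(seed=seed))
            means.append(prof.values.mean())
        assert all(m < 0 for m in means)
        # expected site value about alpha - (1 - alpha) = -0.9
        assert np.mean(means) < -0.8

    def test_unknown_taxon_rejected(self, random_pair_alignment):
        aln = random_pair_alignment()
        with pytest.raises(InputError):
            pair_profile(aln, "X", "Z", WindowParams(seed=0))

    @given(st.integers(min_value=0, max_value=10_000))
    @settings(max_examples=25, deadline=None)
    def test_profile_bounds_any_seed(self, seed):
        rng = np.random.default_rng(seed)
        grid = rng.choice(list("ACGT-N"), size=(2, 30))
        aln = Alignment(["X", "Y"], grid)
        prof = pair_profile(
            aln, "X", "Y",
            WindowParams(window_size=3, n_permutations=20, alpha=0.05, seed=seed),
        )
        assert np.all(prof.values <= 1.0) and np.all(prof.values >= -1.0)


class TestMonteCarloVsExact:
    def test_verdict_agreement_on_random_alignments(self):
        """MC verdicts (large n) agree with the exact enumeration null on
        nearly all windows of random two-taxon alignments."""
        agree = total = 0
        scheme = SCHEME
        table = ScoreTable(scheme, "nucleotide", GapMode.FIFTH_STATE)
        for a in range(20):
            rng = np.random.default_rng(a)
            grid = rng.choice(list("ACGT"), size=(2, 60))
            params = WindowParams(window_size=3, n_permutations=2000, seed=a)
            cx = table.encode(grid[0])
            cy = table.encode(grid[1])
            sites = table.table[cx, cy]
            f = params.effective_flank
            for start, stop in windows(60, 3):
                obs = sites[start:stop].sum()
                nulls = null_scores(cx, cy, (start, stop), params, scheme,
                                    rng=_window_rng(a, (0, 1), start), table=table)
                mc = window_verdict(obs, nulls, params.alpha)
                lo, hi = max(0, start - f), min(60, stop + f)
                vals, probs = exact_null_distribution(cx[lo:hi], cy[lo:hi], 3, table)
                ex = exact_verdict(obs, vals, probs, params.alpha)
                total += 1
                agree += mc == ex
        assert agree / total >= 0.99
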