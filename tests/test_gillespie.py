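import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from evorescue import (derived_quantities, heterozygosity, make_params,
                       mc_establishment_probability, replicate_seeds, run_batch,
                       simulate)


class TestSingleReplicate:
    def test_no_mutation_guarantees_extinction(self):
        p = make_params(w0=500, K=5000, alpha=0.3, bm=1.3, mu=0.0)
        res = simulate(p, seed=1)
        assert res.outcome == "extinction"
        assert res.n_mutations == 0
        assert res.wild_count == 0 and res.lineage_sizes == ()

    def test_bit_for_bit_reproducibility(self, high_density_params):
        a = simulate(high_density_params, seed=12345)
        b = simulate(high_density_params, seed=12345)
        assert a == b

    def test_different_seeds_differ(self, high_density_params):
        a = simulate(high_density_params, seed=1)
        b = simulate(high_density_params, seed=2)
        assert a.final_time != b.final_time

    def test_outcome_classification_invariants(self, high_density_params):
        m_eq = derived_quantities(high_density_params).m_eq
        for s in replicate_seeds(42, 40):
            res = simulate(high_density_params, int(s))
            if res.outcome == "extinction":
                assert res.wild_count == 0 and not res.lineage_sizes
            else:
                n = len(res.lineage_sizes)
                assert res.outcome == ("hard" if n == 1 else "soft")
                assert res.total_mutants >= 0.99 * m_eq
                assert len(res.lineage_origins) == n
                assert all(0 <= o <= res.final_time for o in res.lineage_origins)
                assert res.n_mutations >= n

    def test_event_cap_raises(self, high_density_params):
        with pytest.raises(RuntimeError, match="event cap"):
            simulate(high_density_params, seed=1, max_events=10)

    def test_mean_trajectory_matches_deterministic_decay(self):
        """With K effectively infinite and mu = 0 the wild type is a linear
        birth-death process: its mean must follow w0 exp(-alpha t)."""
        p = make_params(w0=800, K=1e12, alpha=0.5, bm=1.3, mu=0.0)
        chk = np.array([1.0, 2.0, 4.0, 6.0, 9.0])
        W = np.empty((1000, chk.size))
        for i, s in enumerate(replicate_seeds(99, 1000)):
            _, W[i] = simulate(p, int(s), _checkpoints=chk)
        expected = 800 * np.exp(-0.5 * chk)
        se = W.std(0, ddof=1) / math.sqrt(1000)
        assert np.all(np.abs(W.mean(0) - expected) < 3 * se)


def _enumeration_heterozygosity(sizes, n):
    """Brute force: label every individual by lineage, enumerate all
    n-subsets, count those drawn from more than one lineage."""
    labels = [i for i, m in enumerate(sizes) for _ in range(m)]
    combos = list(itertools.combinations(range(len(labels)), n))
    multi = sum(1 for c in combos if len({labels[i] for i in c}) > 1)
    return multi / len(combos)


class TestHeterozygosity:
    def test_single_lineage_is_zero(self):
        assert heterozygosity([42], 2) == 0.0
        assert heterozygosity([42], 10) == 0.0

    def test_two_singletons_must_straddle(self):
        assert heterozygosity([1, 1], 2) == 1.0

    def test_three_one_split(self):
        # 1 - C(3,2)/C(4,2) = 1 - 3/6
        assert heterozygosity([3, 1], 2) == pytest.approx(0.5, abs=1e-12)

    @pytest.mark.parametrize("sizes", [
        [2, 1], [4, 2], [3, 3, 2], [5, 1, 1], [2, 2, 2, 2], [6, 2], [8]])
    def test_matches_exhaustive_enumeration(self, sizes):
        for n in range(2, sum(sizes) + 1):
            assert heterozygosity(sizes, n) == pytest.approx(
                _enumeration_heterozygosity(sizes, n), abs=1e-12)

    def test_oversized_sample_uses_whole_population(self):
        assert heterozygosity([3, 1], 100) == heterozygosity([3, 1], 4)
        assert heterozygosity([3, 1], 4) == 1.0  # whole sample spans lineages

    def test_large_population_numerically_stable(self):
        h = heterozygosity([9000, 900], 100)
        assert 0.0 <= h <= 1.0
        # chance of missing the 9% lineage in 100 draws is tiny
        assert h > 0.999

    def test_rejects_bad_inputs(self):
        with pytest.raises(ValueError):
            heterozygosity([3, 1], 1)
        with pytest.raises(ValueError):
            heterozygosity([], 2)

    @given(sizes=st.lists(st.integers(1, 6), min_size=1, max_size=4),
           n=st.integers(2, 8))
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_bounded_and_nondecreasing_in_sample_size(self, sizes, n):
        h = heterozygosity(sizes, n)
        assert 0.0 <= h <= 1.0
        if n > 2:
            assert h >= heterozygosity(sizes, n - 1) - 1e-12


class TestBatches:
    def test_no_mutation_batch(self):
        p = make_params(w0=200, K=2000, alpha=0.3, bm=1.3, mu=0.0)
        b = run_batch(p, 50, base_seed=1)
        assert b.prop_extinction == 1.0
        assert math.isnan(b.mean_het[2])

    def test_proportions_sum_to_one_and_seeds_logged(self, high_density_params):
        b = run_batch(high_density_params, 60, base_seed=3)
        assert b.prop_extinction + b.prop_hard + b.prop_soft == pytest.approx(1.0)
        assert len(b.seeds) == 60 and len(set(b.seeds)) == 60
        assert b.n_rescued == round((b.prop_hard + b.prop_soft) * 60)

    def test_heterozygosity_nondecreasing_in_sample_size(self, high_density_params):
        b = run_batch(high_density_params, 60, base_seed=3)
        assert b.mean_het[2] <= b.mean_het[100] + 1e-12

    def test_batch_reproducible(self, high_density_params):
        a = run_batch(high_density_params, 30, base_seed=8)
        b = run_batch(high_density_params, 30, base_seed=8)
        assert a == b

    def test_near_certain_extinction_corner(self):
        """Fast decline, rare mutation: Poisson mean ~ 0.01, so nearly every
        replicate goes extinct, matching the analytic rescue probability."""
        from evorescue import rescue_probabilities

        p = make_params(w0=10000, K=110000, alpha=1.0, bm=1.1, mu=1e-5)
        pr = rescue_probabilities(p).p_rescue
        assert pr < 0.01
        b = run_batch(p, 200, base_seed=5)
        se = math.sqrt(pr * (1 - pr) / 200)
        assert abs(b.prop_extinction - (1.0 - pr)) <= 3 * se

    def test_replicate_tsv_log(self, tmp_path, high_density_params):
        from evorescue import append_replicate_log

        path = tmp_path / "reps.tsv"
        results = [simulate(high_density_params, s) for s in (1, 2)]
        for r in results:
            append_replicate_log(path, r)
        lines = path.read_text().splitlines()
        assert lines[0].startswith("seed\toutcome")
        assert len(lines) == 3
        assert lines[1].split("\t")[1] == results[0].outcome

    def test_json_serialization(self, tmp_path, high_density_params):
        import json
        b = run_batch(high_density_params, 20, base_seed=2)
        path = tmp_path / "batch.json"
        b.to_json(path)
        data = json.loads(path.read_text())
        assert data["n_reps"] == 20
        assert data["prop_extinction"] == b.prop_extinction
        assert len(data["seeds"]) == 20


class TestMonteCarloOracle:
    def test_high_density_onset_establishment_is_rare(self):
        p = make_params(w0=10000, K=10000, alpha=0.1, bm=1.1, mu=1e-4)
        p_hat, se = mc_establishment_probability(p, 0.0, 20_000, seed=17)
        assert p_hat < 1e-3

    def test_reproducible(self, low_density_params):
        a = mc_establishment_probability(low_density_params, 0.0, 5000, seed=9)
        b = mc_establishment_probability(low_density_params, 0.0, 5000, seed=9)
        assert a == b
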