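"""Rank regression with eigenvector escalation, Stouffer, FDR, gene lists."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

import gxmap as gx
from gxmap.association import RankDeficientError, default_schedule


def _empty_basis(n):
    return gx.EigenvectorBasis(vectors=np.empty((n, 0)), eigenvalues=np.empty(0))


def _chain_graph(n, k=3):
    d = np.abs(np.subtract.outer(np.arange(float(n)), np.arange(float(n))))
    return gx.build_knn_graph(d, k=k)


class TestRankTransform:
    def test_examples(self):
        np.testing.assert_array_equal(gx.rank_transform([10, 20, 30]), [1, 2, 3])
        np.testing.assert_array_equal(gx.rank_transform([5, 5, 9]), [1.5, 1.5, 3])

    @settings(max_examples=50, deadline=None)
    @given(st.integers(min_value=0, max_value=2**31 - 1))
    def test_rank_pearson_equals_spearman(self, seed):
        rng = np.random.default_rng(seed)
        x, y = rng.normal(size=40), rng.normal(size=40)
        rho_via_ranks = np.corrcoef(gx.rank_transform(x), gx.rank_transform(y))[0, 1]
        assert rho_via_ranks == pytest.approx(stats.spearmanr(x, y).statistic, abs=1e-12)


class TestFitWithSevm:
    def test_schedule_shape(self):
        assert default_schedule(150) == [0, 1] + list(range(5, 151, 5))
        assert default_schedule(150)[-1] == 150

    def test_no_escalation_matches_plain_spearman_test(self):
        rng = np.random.default_rng(0)
        n = 60
        y, x = rng.normal(size=n), rng.normal(size=n)
        fit = gx.fit_with_sevm(y, x, _empty_basis(n), _chain_graph(n), schedule=[0])
        rho, p = stats.spearmanr(x, y)
        t_expected = rho * np.sqrt((n - 2) / (1 - rho**2))
        assert fit.n_eigenvectors == 0
        assert fit.coef_t == pytest.approx(t_expected, abs=1e-10)
        assert fit.p == pytest.approx(p, abs=1e-10)

    def test_independent_data_rarely_escalates(self):
        # spatially white response and predictor: residual Moran should
        # almost never trigger, so m stays 0 and the fit is the plain test
        rng = np.random.default_rng(1)
        g = _chain_graph(80)
        basis = gx.compute_mem(g)
        stayed = 0
        for _ in range(50):
            y, x = rng.normal(size=80), rng.normal(size=80)
            fit = gx.fit_with_sevm(y, x, basis, g)
            stayed += fit.n_eigenvectors == 0
        assert stayed >= 40

    def test_cap_behaviour_when_autocorrelation_persists(self):
        # alpha=1 makes the residual test impossible to satisfy: the fit
        # must stop at the largest scheduled value within the cap
        rng = np.random.default_rng(2)
        n, cap = 80, 20
        g = _chain_graph(n)
        basis = gx.compute_mem(g)
        fit = gx.fit_with_sevm(rng.normal(size=n), rng.normal(size=n), basis, g, alpha=1.0, cap=cap)
        assert fit.n_eigenvectors == 20
        assert 0 < fit.residual_moran_p < 1

    def test_exit_condition_invariant(self, recovery_outcome):
        donor = recovery_outcome.result.donor_results
        ok = (donor["residual_moran_p"] >= 0.05) | (donor["n_eigenvectors"] == 150)
        assert ok.all()
        assert set(donor["n_eigenvectors"].unique()) <= set(default_schedule(150))

    def test_rank_deficient_predictor_raises(self):
        # put the *ranked, centered* predictor into the basis span, so the
        # design loses rank as soon as the first eigenvector enters
        g = _chain_graph(40)
        x = np.random.default_rng(3).normal(size=40)
        xc = gx.rank_transform(x) - gx.rank_transform(x).mean()
        ev = (xc / np.linalg.norm(xc))[:, None]
        basis = gx.EigenvectorBasis(vectors=ev, eigenvalues=np.array([1.0]))
        y = np.random.default_rng(4).normal(size=40)
        with pytest.raises(RankDeficientError, match="m=1"):
            gx.fit_with_sevm(y, x, basis, g, alpha=1.0, schedule=[1])

    def test_constant_predictor_raises(self):
        g = _chain_graph(30)
        with pytest.raises(RankDeficientError):
            gx.fit_with_sevm(np.arange(30.0), np.ones(30), _empty_basis(30), g)


class TestStouffer:
    def test_six_equal_positive_donors(self):
        p = 2 * stats.norm.sf(2.0)
        z, pm = gx.stouffer_combine([p] * 6, [1.0] * 6)
        assert z == pytest.approx(12 / np.sqrt(6), abs=1e-10)
        assert pm == pytest.approx(2 * stats.norm.sf(12 / np.sqrt(6)), abs=1e-12)

    def test_balanced_signs_cancel(self):
        p = 2 * stats.norm.sf(1.7)
        z, pm = gx.stouffer_combine([p] * 6, [1, 1, 1, -1, -1, -1])
        assert z == pytest.approx(0.0, abs=1e-12)
        assert pm == pytest.approx(1.0)

    @settings(max_examples=100, deadline=None)
    @given(st.integers(min_value=0, max_value=2**31 - 1))
    def test_matches_quantile_oracle(self, seed):
        rng = np.random.default_rng(seed)
        ps = rng.uniform(1e-6, 1.0, size=6)
        signs = rng.choice([-1.0, 1.0], size=6)
        z, pm = gx.stouffer_combine(ps, signs)
        zs = np.array([stats.norm.ppf(1 - p / 2) for p in ps])
        z_expected = float((signs * zs).sum() / np.sqrt(6))
        assert z == pytest.approx(z_expected, abs=1e-10)
        assert pm == pytest.approx(min(2 * stats.norm.sf(abs(z_expected)), 1.0), abs=1e-12)

    def test_fewer_than_two_donors_rejected(self):
        with pytest.raises(ValueError, match="2 donors"):
            gx.stouffer_combine([0.05], [1.0])

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            gx.stouffer_combine([0.0, 0.5], [1.0, 1.0])

    def test_extreme_p_clamped_finite(self):
        z, pm = gx.stouffer_combine([1e-310, 0.5], [1.0, 1.0])
        assert np.isfinite(z) and 0 <= pm <= 1


class TestBhFdr:
    def test_single_p(self):
        assert gx.bh_fdr([0.03])[0] == pytest.approx(0.03)

    def test_hand_applied_step_up(self):
        np.testing.assert_allclose(gx.bh_fdr([0.01, 0.02, 0.03, 0.04]), [0.04] * 4)

    def test_all_equal(self):
        np.testing.assert_allclose(gx.bh_fdr([0.2, 0.2, 0.2]), [0.2] * 3)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            gx.bh_fdr([0.5, 1.2])

    def test_step_up_oracle_random(self):
        rng = np.random.default_rng(4)
        p = rng.uniform(size=25)
        q = gx.bh_fdr(p)
        m = len(p)
        order = np.argsort(p)
        expected = np.empty(m)
        running = 1.0
        for rank_idx in range(m - 1, -1, -1):
            i = order[rank_idx]
            running = min(running, m * p[i] / (rank_idx + 1))
            expected[i] = running
        np.testing.assert_allclose(q, expected, atol=1e-12)


class TestGeneLists:
    def _assoc(self, rows):
        return pd.DataFrame(rows, columns=["probe_id", "q", "z_meta"])

    def test_single_significant_positive(self):
        gl = gx.probe_to_gene_lists(
            self._assoc([("p1", 0.01, 3.0)]), {"p1": "A"}
        )
        assert gl.positive == {"A"} and gl.negative == frozenset()

    def test_nonsignificant_in_neither(self):
        gl = gx.probe_to_gene_lists(
            self._assoc([("p1", 0.2, 3.0), ("p2", 0.8, -1.0)]), {"p1": "A", "p2": "A"}
        )
        assert gl.positive == frozenset() and gl.negative == frozenset()

    def test_discordant_probes_put_gene_in_both(self):
        gl = gx.probe_to_gene_lists(
            self._assoc([("p1", 0.01, 3.0), ("p2", 0.02, -4.0)]), {"p1": "A", "p2": "A"}
        )
        assert gl.positive == {"A"} and gl.negative == {"A"}

    def test_unmapped_probe_rejected(self):
        with pytest.raises(ValueError, match="p1"):
            gx.probe_to_gene_lists(self._assoc([("p1", 0.01, 3.0)]), {})


class TestConsensus:
    def test_intersection(self):
        per_map = {
            m: gx.GeneLists(positive=frozenset(p), negative=frozenset())
            for m, p in [("a", {"A", "B", "C"}), ("b", {"B", "C"}), ("c", {"B", "C", "D"})]
        }
        pos, neg = gx.consensus_lists(per_map)
        assert pos == {"B", "C"} and neg == frozenset()

    def test_empty_map_gives_empty_consensus(self):
        per_map = {
            "a": gx.GeneLists(positive=frozenset({"A"}), negative=frozenset({"X"})),
            "b": gx.GeneLists(positive=frozenset(), negative=frozenset({"X"})),
            "c": gx.GeneLists(positive=frozenset({"A"}), negative=frozenset({"X", "Y"})),
        }
        pos, neg = gx.consensus_lists(per_map)
        assert pos == frozenset() and neg == {"X"}

    def test_wrong_map_count_rejected(self):
        with pytest.raises(ValueError, match="3 maps"):
            gx.consensus_lists({"a": gx.GeneLists(frozenset(), frozenset())})


class TestPipeline:
    def test_sign_coherence(self, recovery_outcome):
        """z_meta sign equals the sign of the sum of signed donor |Z| values."""
        donor = recovery_outcome.result.donor_results
        probe = recovery_outcome.result.probe_results
        merged = donor.merge(probe, on=["map_id", "probe_id"])
        p_clamped = merged["p"].clip(1e-300, 1 - 1e-16)
        z_mag = stats.norm.isf(p_clamped / 2)
        merged["signed_z"] = np.sign(merged["coef_t"]) * z_mag
        agg = merged.groupby(["map_id", "probe_id"]).agg(
            total=("signed_z", "sum"), z_meta=("z_meta", "first")
        )
        assert (np.sign(agg["total"]) == np.sign(agg["z_meta"])).all()

    def test_probe_results_contract(self, recovery_outcome):
        probe = recovery_outcome.result.probe_results
        assert probe["q"].between(0, 1).all()
        assert probe["direction"].isin([-1, 0, 1]).all()
        assert (probe["n_donors"] >= 2).all()
        assert set(probe["map_id"]) == {"C9orf72", "GRN", "MAPT"}
        summary = recovery_outcome.result.eigenvector_summary
        assert {"min", "median", "max", "map_id"} <= set(summary.columns)

    def test_fdr_control_on_fully_null_data(self):
        """With no planted genes, essentially nothing passes q < 0.05."""
        out = gx.recovery_study(seed=7, n_donors=3, n_samples=100, n_genes=150, n_planted=0)
        probe = out.result.probe_results
        frac = float((probe["q"] < 0.05).mean())
        se = np.sqrt(0.05 * 0.95 / len(probe))
        assert frac <= 0.05 + 3 * se

    def test_zero_variance_probe_skipped_not_fatal(self, small_geometry):
        geom = small_geometry
        _, t_vals = gx.atrophy_for_geometry(geom)
        truth = gx.GroundTruth(effect_rho={}, seed=0)
        bundles = []
        for s in (1, 2):
            b = gx.generate_expression(geom, 3, 1, truth, t_vals, seed=s)
            bundles.append(b)
        bundles[0].expression.iloc[0, :] = 1.0  # constant probe in donor 1 only
        tables = {
            b.donor_id: pd.DataFrame({"m": t_vals}, index=b.samples["sample_id"])
            for b in bundles
        }
        # both bundles share donor_id (same geometry); rename the second
        bundles[1].donor_id = "donor2"
        bundles[1].samples = bundles[1].samples.assign(donor_id="donor2")
        tables = {
            b.donor_id: pd.DataFrame(
                {"m": t_vals}, index=b.samples["sample_id"]
            )
            for b in bundles
        }
        res = gx.run_association(bundles, tables, k=10)
        skipped = res.donor_results.query("donor_id == 'donor1'")["probe_id"]
        assert "G00001_p1" not in set(skipped)
        # the probe still gets combined over the remaining donor only if >= 2
        assert "G00001_p1" not in set(res.probe_results["probe_id"])
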