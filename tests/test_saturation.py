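import numpy as np
import pytest

from charsat.dissimilarity import mord_dissimilarity, patristic_distances
from charsat.matrix import MISSING
from charsat.saturation import (
    MichaelisMentenFit,
    NullVmaxDistribution,
    _fit_mm_arrays,
    _fit_mm_batch,
    ci_overlap_calibration,
    classify_constraint,
    fit_michaelis_menten,
    null_vmax_distribution,
    simulate_null_matrix,
)
from charsat.trees import read_changes_tree

from conftest import make_matrix


class TestMichaelisMentenFit:
    def test_noiseless_recovery_to_1e6(self):
        P = np.arange(0.1, 2.01, 0.1)
        D = 1.0 * P / (0.5 + P)
        fit = fit_michaelis_menten((P, D))
        assert fit.converged
        assert fit.vmax == pytest.approx(1.0, abs=1e-6)
        assert fit.km == pytest.approx(0.5, abs=1e-6)
        assert fit.vmax_ci84[0] <= fit.vmax <= fit.vmax_ci84[1]

    def test_flat_zero_data_gives_zero_vmax(self):
        P = np.linspace(0.1, 2, 10)
        fit = fit_michaelis_menten((P, np.zeros(10)))
        assert fit.converged and fit.vmax == 0.0

    def test_below_min_pairs_is_untestable(self):
        fit = fit_michaelis_menten((np.array([0.1, 0.4]), np.array([0.2, 0.5])))
        assert not fit.converged

    def test_fewer_than_three_distinct_abscissae_untestable(self):
        P = np.array([0.5] * 4 + [1.0] * 4)
        D = 0.8 * P / (0.3 + P)
        assert not fit_michaelis_menten((P, D)).converged

    def test_scale_equivariance(self):
        rng = np.random.default_rng(1)
        P = rng.uniform(0.05, 3, 60)
        D = 0.9 * P / (0.4 + P) + rng.normal(0, 0.02, 60)
        base = _fit_mm_arrays(P, D)
        scaled_d = _fit_mm_arrays(P, 3.0 * D)
        assert scaled_d.vmax == pytest.approx(3.0 * base.vmax, rel=1e-6)
        scaled_p = _fit_mm_arrays(5.0 * P, D)
        assert scaled_p.vmax == pytest.approx(base.vmax, rel=1e-6)
        assert scaled_p.km == pytest.approx(5.0 * base.km, rel=1e-6)

    def test_unbiased_on_noisy_data(self):
        rng = np.random.default_rng(7)
        estimates = []
        for _ in range(150):
            P = rng.uniform(0.05, 3, 60)
            D = 0.8 * P / (0.3 + P) + rng.normal(0, 0.05, 60)
            fit = _fit_mm_arrays(P, D)
            if fit.converged:
                estimates.append(fit.vmax)
        mean = np.mean(estimates)
        se = np.std(estimates) / np.sqrt(len(estimates))
        assert abs(mean - 0.8) < 4 * se + 0.01

    def test_batch_fitter_matches_scipy_route(self):
        rng = np.random.default_rng(3)
        P = rng.uniform(0.05, 3, 50)
        Ds = np.stack([0.5 + 0.8 * P / (0.3 + P) * f + rng.normal(0, 0.03, 50)
                       for f in rng.uniform(0.3, 1.5, 12)])
        batch_v, conv = _fit_mm_batch(P, Ds)
        for row, bv, ok in zip(Ds, batch_v, conv):
            single = _fit_mm_arrays(P, row)
            if single.converged and ok:
                assert bv == pytest.approx(single.vmax, rel=1e-3, abs=1e-4)


class TestNullSimulation:
    def test_zero_length_tree_inherits_root_state(self):
        ct = read_changes_tree(data="((A:0,B:0):0,C:0);")
        template = make_matrix([[0, 1], [1, 0], [0, 0]], taxa=list("ABC"))
        sim = simulate_null_matrix(ct, template, seed=5)
        for j in range(2):
            states = {next(iter(sim.row(t)[j])) for t in "ABC"}
            assert len(states) == 1

    def test_missing_mask_preserved_exactly(self):
        ct = read_changes_tree(data="((A:1,B:1):1,C:2);")
        template = make_matrix([[0, MISSING, 1], [MISSING, 1, 0], [0, 1, MISSING]],
                               taxa=list("ABC"))
        sim = simulate_null_matrix(ct, template, seed=2)
        assert np.array_equal(sim.missing_mask(), template.missing_mask())

    def test_long_branch_three_state_difference_near_two_thirds(self):
        # stationary closed form: expected per-character difference (k-1)/k
        ct = read_changes_tree(data="((A:50,B:50):1,C:50);")
        template = make_matrix([[0] * 1200, [1] * 1200, [2] * 1200],
                               taxa=["A", "B", "C"])
        sim = simulate_null_matrix(ct, template, seed=3)
        D = mord_dissimilarity(sim).value("A", "B")
        assert D == pytest.approx(2 / 3, abs=0.03)

    def test_determinism_under_fixed_seed(self):
        ct = read_changes_tree(data="((A:1,B:1):1,C:2);")
        template = make_matrix([[0, 1, 1], [1, 0, 0], [0, 1, 0]], taxa=list("ABC"))
        assert simulate_null_matrix(ct, template, seed=9) == \
            simulate_null_matrix(ct, template, seed=9)


class TestNullVmaxDistribution:
    @staticmethod
    def ladder_newick(n, length, inner):
        s = f"T{n - 1}:{length}"
        for i in range(n - 2, 0, -1):
            s = f"(T{i}:{length},{s}):{inner}"
        return f"(T0:{length},{s});"

    def build(self, n_taxa=12, n_chars=120, length=3.0):
        rng = np.random.default_rng(0)
        ct = read_changes_tree(data=self.ladder_newick(n_taxa, length, length / 2))
        template = make_matrix(rng.integers(0, 2, size=(n_taxa, n_chars)).tolist(),
                               taxa=[f"T{i}" for i in range(n_taxa)])
        return ct, template

    def test_binary_long_tree_null_median_near_half(self):
        ct, template = self.build()
        null = null_vmax_distribution(ct, template, n_sims=120, seed=4)
        assert null.median == pytest.approx(0.5, abs=0.05)

    def test_reproducible_under_seed(self):
        ct, template = self.build(n_taxa=8, n_chars=60)
        a = null_vmax_distribution(ct, template, n_sims=100, seed=11)
        b = null_vmax_distribution(ct, template, n_sims=100, seed=11)
        assert np.array_equal(a.values, b.values)
        assert a.central84 == b.central84


class TestClassification:
    def null_band(self):
        values = np.concatenate([np.linspace(0.76, 0.87, 50)])
        return NullVmaxDistribution.from_values(values)

    def obs(self, lo, hi):
        return MichaelisMentenFit((lo + hi) / 2, 0.3, (lo, hi), 50, True, 0.1)

    def test_rule_application(self):
        null = NullVmaxDistribution(np.full(100, 0.8), 100, (0.76, 0.87), 0.81)
        assert classify_constraint(self.obs(0.90, 1.10), null).call == "relaxed"
        assert classify_constraint(self.obs(0.40, 0.50), null).call == "strengthened"
        assert classify_constraint(self.obs(0.70, 0.85), null).call == "none"

    def test_unconverged_observed_untestable(self):
        null = NullVmaxDistribution(np.full(100, 0.8), 100, (0.76, 0.87), 0.81)
        call = classify_constraint(MichaelisMentenFit.untestable(3), null)
        assert call.call == "untestable"

    def test_unidentifiable_asymptote_reported_unconverged(self):
        # near-linear data: the curve never bends, Vmax runs away
        P = np.linspace(0.01, 0.1, 30)
        D = 0.05 * P + np.random.default_rng(0).normal(0, 1e-5, 30)
        fit = _fit_mm_arrays(P, D)
        assert not fit.converged


class TestScanExport:
    def test_tsv_and_annotated_tree_round_out_scan_results(self, tmp_path):
        import pandas as pd

        from charsat.saturation import scan_all_nodes, scan_annotations, scan_to_tsv
        from charsat.trees import read_annotated_tree, write_tree
        from charsat import synthetic as syn

        sc = syn.SyntheticScenario(seed=44, tree=syn.TreeConfig(n_tips=16),
                                   characters=syn.CharacterConfig(
                                       n_chars=80, base_rate=0.05,
                                       rate_profile="constant"))
        tt = syn.simulate_tree(sc)
        matrix, ct, _ = syn.simulate_constrained_matrix(tt, sc)
        calls = scan_all_nodes(tt, ct, matrix, n_sims=100, seed=1)
        scan_to_tsv(calls, tmp_path / "scan.tsv")
        df = pd.read_csv(tmp_path / "scan.tsv", sep="\t")
        assert len(df) == len(calls)
        assert {"node_id", "vmax", "call", "n_pairs"} <= set(df.columns)
        write_tree(tt, tmp_path / "scan.nwk", annotations=scan_annotations(calls))
        text = (tmp_path / "scan.nwk").read_text()
        assert "call=" in text


class TestCiOverlapCalibration:
    def test_separated_estimators_never_overlap(self):
        rng = np.random.default_rng(0)
        # direct construction: two estimators 1000 SE apart
        z = 1.4051
        a = rng.standard_normal(5000)
        b = rng.standard_normal(5000) + 1000.0
        overlap = np.mean(np.abs(a - b) <= 2 * z)
        assert overlap == 0.0

    def test_level_bounds_validated(self):
        with pytest.raises(ValueError):
            ci_overlap_calibration(0, 100, seed=1)
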