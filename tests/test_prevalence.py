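"""EAR cut-point prevalence, sensitivity curves, and BRR standard errors."""

import numpy as np
import pytest
from scipy import stats

from intakevar import (
    SyntheticConfig,
    TransformSpec,
    brr_se,
    decompose,
    default_beta_grid,
    ear_cutpoint,
    generate,
    model_distribution,
    sensitivity_grid,
    EAR_REGISTRY,
)
from intakevar.prevalence import hadamard_matrix, brr_replicate_weights


def _weighted_mean(data, w):
    return float(np.sum(w * data["intake"]) / np.sum(w))


class TestEarCutpoint:
    def test_symmetric_half(self, identity_spec):
        dist = model_distribution(mu=9.0, s_b2=4.0, s_w2=0.0,
                                  transform=identity_spec)
        est = ear_cutpoint(dist, 10.0)
        assert est.prevalence == pytest.approx(0.5, abs=0.01)

    def test_closed_form_normal(self, identity_spec):
        """EAR one SD below the mean: prevalence = Phi(-1)."""
        dist = model_distribution(mu=9.0, s_b2=4.0, s_w2=0.0,
                                  transform=identity_spec, grid_size=400)
        est = ear_cutpoint(dist, 8.0)
        assert est.prevalence == pytest.approx(stats.norm.cdf(-1), abs=0.005)

    def test_point_mass_flags(self, identity_spec):
        dist = model_distribution(mu=4.0, s_b2=0.0, s_w2=0.0,
                                  transform=identity_spec)  # point at 5
        est = ear_cutpoint(dist, 10.0)
        assert est.prevalence == 1.0
        assert "degenerate_distribution" in est.flags
        assert "near_one_bound" in est.flags

    def test_validity_flags(self, identity_spec):
        dist = model_distribution(mu=9.0, s_b2=4.0, s_w2=0.0,
                                  transform=identity_spec)
        low = ear_cutpoint(dist, 10.0 - 2 * 1.7)   # ~ 4.5%
        high = ear_cutpoint(dist, 10.0 + 2 * 1.7)
        assert "near_zero_bound" in low.flags
        assert "near_one_bound" in high.flags
        mid = ear_cutpoint(dist, 10.0)
        assert not mid.flags

    def test_monotone_in_ear(self, log_spec):
        dist = model_distribution(mu=2.0, s_b2=0.2, s_w2=0.3,
                                  transform=log_spec)
        ears = np.linspace(2, 20, 25)
        prev = [ear_cutpoint(dist, e).prevalence for e in ears]
        assert np.all(np.diff(prev) >= 0)

    def test_bad_ear(self, identity_spec):
        dist = model_distribution(mu=9.0, s_b2=1.0, s_w2=0.0,
                                  transform=identity_spec)
        with pytest.raises(ValueError):
            ear_cutpoint(dist, 0.0)


class TestSensitivityGrid:
    def test_default_grid(self):
        grid = default_beta_grid()
        assert grid[0] == 0.05 and grid[-1] == 0.99
        assert len(grid) == 20
        assert np.allclose(np.diff(grid)[:-1], 0.05)

    def test_mean_above_ear_nonincreasing(self, zinc_like_recalls):
        """Adequate population: raising the assumed within share drains the
        lower tail; prevalence falls toward 0 at the 0.99 endpoint."""
        data, _ = zinc_like_recalls
        day1 = data[data["sequence"] == 1].reset_index(drop=True)
        curve = sensitivity_grid(day1, ear=6.0,
                                 transform=TransformSpec(lam=0.0))
        prev = [p.prevalence for p in curve.prevalences]
        assert np.all(np.diff(prev) <= 1e-12)
        assert prev[-1] <= 0.02

    def test_mean_below_ear_nondecreasing(self, zinc_like_recalls):
        data, _ = zinc_like_recalls
        day1 = data[data["sequence"] == 1].reset_index(drop=True)
        curve = sensitivity_grid(day1, ear=16.0,
                                 transform=TransformSpec(lam=0.0))
        prev = [p.prevalence for p in curve.prevalences]
        assert np.all(np.diff(prev) >= -1e-12)
        assert prev[-1] >= 0.98

    def test_reference_close_at_true_beta(self, zinc_like_recalls, log_spec):
        """The 1-d curve evaluated at the true ratio reproduces the 2-d
        reference prevalence within 2 percentage points."""
        data, truth = zinc_like_recalls
        comp = decompose(data, log_spec)
        day1 = data[data["sequence"] == 1].reset_index(drop=True)
        curve = sensitivity_grid(
            day1, ear=6.0, beta_grid=[truth["beta_true"]],
            transform=log_spec, reference_components=comp)
        assert curve.reference is not None
        diff = abs(curve.prevalences[0].prevalence
                   - curve.reference.prevalence)
        assert diff <= 0.02

    def test_guard_rejects_degenerate_beta(self, zinc_like_recalls):
        data, _ = zinc_like_recalls
        day1 = data[data["sequence"] == 1].reset_index(drop=True)
        with pytest.raises(ValueError, match="degenerate"):
            sensitivity_grid(day1, ear=6.0, beta_grid=[0.5, 1.0],
                             transform=TransformSpec(lam=0.0))

    def test_prevalence_range_reported(self, zinc_like_recalls):
        data, _ = zinc_like_recalls
        day1 = data[data["sequence"] == 1].reset_index(drop=True)
        curve = sensitivity_grid(day1, ear=6.0, beta_grid=[0.5, 0.7, 0.9],
                                 transform=TransformSpec(lam=0.0))
        lo, hi = curve.prevalence_range
        assert lo <= hi
        frame = curve.to_frame()
        assert list(frame.columns) == ["beta", "prevalence", "se", "flags"]

    def test_ear_registry_entries(self):
        assert EAR_REGISTRY["folate"]["ear"] == 320.0
        assert EAR_REGISTRY["vitamin_a"]["ear"] == 500.0
        assert EAR_REGISTRY["zinc"]["ear"] == 6.0


class TestHadamard:
    @pytest.mark.parametrize("order", [1, 2, 4, 8, 12, 20, 24, 44, 48, 96])
    def test_orthogonality(self, order):
        H = hadamard_matrix(order)
        assert np.array_equal(H @ H.T, order * np.eye(order, dtype=int))

    def test_impossible_order(self):
        with pytest.raises(ValueError):
            hadamard_matrix(6)


class TestBrr:
    def test_se_within_20pct_of_monte_carlo(self, survey_design):
        """Mean BRR SE over independent survey realizations tracks the
        empirical SD of the weighted mean over many realizations."""
        def make(seed):
            cfg = SyntheticConfig(n_subjects=240, n_days=1, s_b2=0.25,
                                  s_w2=0.5, lambda_true=0.0,
                                  design=survey_design, seed=seed)
            return generate(cfg)[0]

        means = [_weighted_mean(d, d["weight"].to_numpy())
                 for d in (make(50_000 + s) for s in range(300))]
        emp_sd = np.std(means, ddof=1)
        ses = [brr_se(make(50_000 + s), _weighted_mean, n_replicates=48,
                      fay=0.7, seed=s) for s in range(20)]
        assert np.mean(ses) == pytest.approx(emp_sd, rel=0.20)

    def test_fay_one_rejected(self, survey_design):
        data, _ = generate(SyntheticConfig(
            n_subjects=96, n_days=1, design=survey_design, seed=1))
        with pytest.raises(ValueError, match="fay"):
            brr_se(data, _weighted_mean, fay=1.0)

    def test_constant_statistic_zero_se(self, survey_design):
        data, _ = generate(SyntheticConfig(
            n_subjects=96, n_days=1, design=survey_design, seed=1))
        se = brr_se(data, lambda d, w: 42.0)
        assert se == 0.0

    def test_single_cluster_stratum_named(self):
        import pandas as pd

        data = pd.DataFrame({
            "intake": [1.0, 2.0, 3.0],
            "stratum": ["a", "a", "b"],
            "cluster": ["a1", "a2", "b1"],
            "weight": [1.0, 1.0, 1.0],
        })
        with pytest.raises(ValueError, match="'b'"):
            brr_se(data, _weighted_mean)

    def test_missing_design_columns(self, lognormal_recalls):
        data, _ = lognormal_recalls
        with pytest.raises(ValueError, match="analytic"):
            brr_se(data, _weighted_mean)

    def test_replicate_weights_structure(self, survey_design):
        data, _ = generate(SyntheticConfig(
            n_subjects=96, n_days=1, design=survey_design, seed=4))
        W = brr_replicate_weights(data, n_replicates=48, fay=0.7)
        assert W.shape == (48, len(data))
        base = data["weight"].to_numpy()
        ratio = W / base
        assert np.allclose(np.sort(np.unique(np.round(ratio, 10))),
                           [0.7, 1.3])

    def test_se_trend_increases_with_beta(self, survey_design):
        """Design-based SEs of the cut-point prevalence tend to grow as the
        assumed within share rises, provided the prevalence stays off the
        0/1 boundary (directional, averaged over seeds)."""
        from intakevar import (partition_external, total_variance_1d,
                               ear_cutpoint)
        spec = TransformSpec(lam=0.0)

        def prevalence_at(beta):
            def stat(data, w):
                d = data.assign(weight=w)
                tvw = total_variance_1d(d, spec, weight_col="weight")
                parts = partition_external(tvw["s_total2"], beta)
                dist = model_distribution(
                    mu=tvw["mu"], s_b2=parts["s_b2"], s_w2=parts["s_w2"],
                    transform=spec, grid_size=200)
                return ear_cutpoint(dist, 8.0).prevalence
            return stat

        ses = {0.3: [], 0.6: [], 0.9: []}
        for seed in range(4):
            cfg = SyntheticConfig(n_subjects=240, n_days=1, mu=2.0,
                                  s_b2=0.25, s_w2=0.5, lambda_true=0.0,
                                  design=survey_design, seed=700 + seed)
            data, _ = generate(cfg)
            for beta in ses:
                ses[beta].append(brr_se(data, prevalence_at(beta), seed=seed))
        assert np.mean(ses[0.9]) >= np.mean(ses[0.3])
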