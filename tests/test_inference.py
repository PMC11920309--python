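import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import aucpower as ap
from aucpower.data import DegenerateDataError
from conftest import random_rating_data


def _binormal(mu, m, n, rng, continuous=False):
    spec = ap.BinormalSpec(
        mu_signal=mu, n_participants=1, items_signal=m, items_noise=n, continuous=continuous
    )
    return ap.generate_ratings(spec, rng)


class TestDelong:
    def test_worked_example_ci_rounds_to_published_bounds(self, alcohol):
        est = ap.auc_ci(alcohol)
        assert round(est.auc, 2) == 0.61
        assert round(est.ci95[0], 2) == 0.59
        assert round(est.ci95[1], 2) == 0.64

    @settings(max_examples=100, derandomize=True)
    @given(seed=st.integers(0, 10_000))
    def test_auc_identical_to_rank_statistic(self, seed):
        data = random_rating_data(np.random.default_rng(seed))
        if data.n_signal < 2 or data.n_noise < 2:
            return
        assert ap.delong_components(data).auc == ap.rank_auc(data)

    def test_perfect_separation_gives_zero_variance(self):
        data = ap.RatingData(
            labels=np.array([1, 1, 1, 0, 0, 0]), scores=np.array([6, 6, 6, 1, 1, 1.0])
        )
        res = ap.delong_components(data)
        assert res.auc == 1.0 and res.variance == 0.0
        est = ap.auc_ci(data)
        assert est.degenerate
        assert est.ci95 == (1.0, 1.0)

    def test_single_observation_class_is_degenerate(self):
        data = ap.RatingData(labels=np.array([1, 0, 0]), scores=np.array([3.0, 1, 2]))
        with pytest.raises(DegenerateDataError):
            ap.delong_components(data)

    def test_se_agrees_with_stratified_bootstrap(self):
        rng = np.random.default_rng(5)
        data = _binormal(0.5, 250, 250, rng)
        delong_se = np.sqrt(ap.delong_components(data).variance)
        xs, ys = data.signal_scores, data.noise_scores
        reps = np.empty(2000)
        for b in range(reps.size):
            bd = ap.RatingData(
                labels=data.labels,
                scores=np.concatenate([rng.choice(xs, xs.size), rng.choice(ys, ys.size)]),
            )
            reps[b] = ap.rank_auc(bd)
        assert delong_se == pytest.approx(reps.std(ddof=1), rel=0.15)

    def test_ci_width_shrinks_like_root_n(self):
        widths = {}
        for n in (200, 400):
            w = []
            for s in range(150):
                data = _binormal(0.38, n, n, np.random.default_rng(1000 + s))
                est = ap.auc_ci(data)
                w.append(est.ci95[1] - est.ci95[0])
            widths[n] = np.mean(w)
        assert 0.65 <= widths[400] / widths[200] <= 0.75

    def test_ci90_nested_in_ci95(self, alcohol):
        est = ap.auc_ci(alcohol)
        assert est.ci95[0] < est.ci90[0] < est.auc < est.ci90[1] < est.ci95[1]


class TestUnpairedDelta:
    def test_identical_groups_center_on_zero(self, alcohol):
        est = ap.unpaired_delta_ci(alcohol, alcohol)
        assert est.delta == 0.0
        assert est.ci95[0] == pytest.approx(-est.ci95[1], abs=1e-12)

    def test_worked_example_difference(self, alcohol, placebo):
        est = ap.unpaired_delta_ci(alcohol, placebo)
        assert est.delta == pytest.approx(-0.12, abs=1e-12)
        assert est.ci95[1] < 0  # significantly worse under alcohol

    def test_se_agrees_with_two_group_bootstrap(self):
        rng = np.random.default_rng(9)
        d1 = _binormal(0.38, 200, 200, rng)
        d2 = _binormal(0.78, 200, 200, rng)
        est = ap.unpaired_delta_ci(d1, d2)
        reps = np.empty(2000)
        for b in range(reps.size):
            deltas = []
            for d in (d1, d2):
                xs, ys = d.signal_scores, d.noise_scores
                bd = ap.RatingData(
                    labels=d.labels,
                    scores=np.concatenate([rng.choice(xs, xs.size), rng.choice(ys, ys.size)]),
                )
                deltas.append(ap.rank_auc(bd))
            reps[b] = deltas[0] - deltas[1]
        assert est.se == pytest.approx(reps.std(ddof=1), rel=0.15)


class TestPairedDelta:
    def _paired(self, rho, seed, mu2=0.38):
        s1 = ap.BinormalSpec(mu_signal=0.38, rho=rho, n_participants=100)
        s2 = ap.BinormalSpec(mu_signal=mu2, rho=rho, n_participants=100)
        return ap.generate_paired_ratings(s1, s2, seed)

    def test_exact_copy_has_zero_delta_and_se(self):
        d1, _ = self._paired(0.5, 3)
        est = ap.paired_delta_ci(d1, d1)
        assert est.delta == 0.0 and est.se == 0.0 and est.degenerate

    def test_missing_pairing_rejected(self, alcohol, placebo):
        with pytest.raises(ValueError, match="pairing"):
            ap.paired_delta_ci(alcohol, placebo)

    def test_broken_pairing_rejected(self):
        d1, d2 = self._paired(0.5, 4)
        d2.pairing_id = d2.pairing_id + 1
        with pytest.raises(ValueError, match="one-to-one"):
            ap.paired_delta_ci(d1, d2)

    def test_independent_conditions_match_unpaired_se(self):
        ratios = []
        for s in range(30):
            d1, d2 = self._paired(0.0, 100 + s)
            ratios.append(ap.paired_delta_ci(d1, d2).se / ap.unpaired_delta_ci(d1, d2).se)
        assert np.mean(ratios) == pytest.approx(1.0, abs=0.05)

    def test_positive_correlation_shrinks_se(self):
        smaller = 0
        for s in range(40):
            d1, d2 = self._paired(0.8, 200 + s)
            if ap.paired_delta_ci(d1, d2).se < ap.unpaired_delta_ci(d1, d2).se:
                smaller += 1
        assert smaller >= 38  # ≥95% of datasets


class TestBootstrap:
    def test_perfectly_separated_data_give_zero_width(self):
        data = ap.RatingData(
            labels=np.concatenate([np.ones(20), np.zeros(20)]),
            scores=np.concatenate([np.full(20, 6.0), np.full(20, 1.0)]),
        )
        est = ap.bootstrap_pauc_ci(data, n_boot=200, seed=0)
        assert est.ci95 == (1.0, 1.0) and est.degenerate

    def test_full_range_brackets_delong_estimate(self):
        data = _binormal(0.5, 300, 300, np.random.default_rng(12))
        boot = ap.bootstrap_pauc_ci(data, fpr_range=(0.0, 1.0), n_boot=1000, seed=1)
        delong = ap.auc_ci(data)
        assert boot.ci95[0] < delong.auc < boot.ci95[1]
        assert boot.auc == pytest.approx(delong.auc, abs=1e-12)

    def test_identical_groups_delta_interval_contains_zero(self, alcohol):
        est = ap.bootstrap_pauc_ci(alcohol, alcohol, fpr_range=(0.0, 0.167), n_boot=300, seed=2)
        assert est.ci95[0] <= 0.0 <= est.ci95[1]

    def test_reproducible_given_seed(self, alcohol):
        a = ap.bootstrap_pauc_ci(alcohol, fpr_range=(0.0, 0.5), n_boot=300, seed=7)
        b = ap.bootstrap_pauc_ci(alcohol, fpr_range=(0.0, 0.5), n_boot=300, seed=7)
        assert a.ci95 == b.ci95 and a.ci90 == b.ci90

    def test_invalid_inputs_rejected(self, alcohol):
        with pytest.raises(ValueError):
            ap.bootstrap_pauc_ci(alcohol, fpr_range=(0.5, 0.2), n_boot=300, seed=0)
        with pytest.raises(ValueError):
            ap.bootstrap_pauc_ci(alcohol, n_boot=50, seed=0)


class TestCoverage:
    def test_delong_95_interval_covers_binormal_truth(self):
        # continuous binormal data, true AUC 0.6, 200 observations per class
        from scipy.stats import norm

        mu = np.sqrt(2) * norm.ppf(0.6)
        hits = 0
        n_sims = 1000
        for s in range(n_sims):
            data = _binormal(mu, 200, 200, np.random.default_rng(50_000 + s), continuous=True)
            est = ap.auc_ci(data)
            hits += est.ci95[0] <= 0.6 <= est.ci95[1]
        assert 0.92 <= hits / n_sims <= 0.975
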