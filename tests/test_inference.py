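"""Tests for cross summaries and pairing-mixture estimation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from xyypairing import datasets
from xyypairing.inference import (
    PairingFrequencyModel,
    complementary_covariance,
    estimate_mixture_bootstrap,
    estimate_mixture_moments,
    nondisjunction_rate,
    summarize_cross,
)
from xyypairing.pairing import (
    CLASS_ORDER,
    PairingMixture,
    ViabilityVector,
    zygote_distribution,
)
from xyypairing.simulate import VialDesign, simulate_xyy_vials

mixtures = st.tuples(
    st.floats(0.01, 10), st.floats(0.01, 10), st.floats(0.01, 10)
).map(lambda t: PairingMixture(*(x / sum(t) for x in t)))


def lstsq_mixture_oracle(freqs):
    """Independent oracle: least-squares solve of the 6x3 linear system
    freq = A @ (pL, pM, pN) with A built by enumerating gamete classes."""
    A = np.zeros((6, 3))
    pairings = {"L": {"X", "Y1"}, "M": {"X", "Y2"}, "N": {"Y1", "Y2"}}
    content = {
        "X": {"X"}, "12": {"Y1", "Y2"}, "X1": {"X", "Y1"},
        "2": {"Y2"}, "X2": {"X", "Y2"}, "1": {"Y1"},
    }
    for j, (label, paired) in enumerate(pairings.items()):
        (unpaired,) = {"X", "Y1", "Y2"} - paired
        for anchor in paired:
            for joins in (True, False):
                sperm = {anchor} | ({unpaired} if joins else set())
                i = [k for k, c in enumerate(CLASS_ORDER) if content[c] == sperm][0]
                A[i, j] += 0.25
    sol, *_ = np.linalg.lstsq(A, np.asarray(freqs), rcond=None)
    return sol


class TestSummarizeCross:
    @pytest.mark.parametrize(
        "y, female, aneuploid",
        [("B", 53.4, 0.5), ("ROMA", 48.3, 0.2), ("10B", 50.1, 0.6), ("473", 50.0, 0.8)],
    )
    def test_control_cross_fixture_rows(self, table1, y, female, aneuploid):
        row = table1[table1.y_chromosome.astype(str) == y]
        s = summarize_cross(row)
        assert round(s.percent_female, 1) == female
        assert round(s.percent_aneuploid, 1) == aneuploid

    def test_pooled_equals_frequency_of_summed_counts(self, rng):
        counts = pd.DataFrame(
            rng.integers(0, 60, size=(6, 6)) + 1, columns=list(CLASS_ORDER)
        )
        s = summarize_cross(counts)
        arr = counts.to_numpy()
        np.testing.assert_allclose(
            s.pooled_freq.to_numpy(), 100 * arr.sum(0) / arr.sum(), rtol=0, atol=1e-12
        )
        # pooled is NOT the mean of per-vial ratios in general
        assert s.n_flies == arr.sum()

    def test_single_vial_pooled_equals_mean_and_sd_flagged(self):
        counts = pd.DataFrame([[10, 12, 8, 9, 11, 10]], columns=list(CLASS_ORDER))
        s = summarize_cross(counts)
        pd.testing.assert_series_equal(s.pooled_freq, s.vial_mean, check_names=False)
        assert s.vial_sd is None
        assert s.sd_flies_per_vial is None

    def test_xyy_aneuploid_sums_xxy_daughters_and_xyy_sons(self):
        counts = pd.DataFrame([[10, 5, 6, 10, 7, 12]], columns=list(CLASS_ORDER))
        s = summarize_cross(counts)
        assert s.percent_aneuploid == pytest.approx(100 * (5 + 6 + 7) / 50)
        assert s.percent_female == pytest.approx(100 * (10 + 6 + 7) / 50)

    def test_empty_and_unknown_labels_rejected(self):
        with pytest.raises(ValueError, match="must contain"):
            summarize_cross(pd.DataFrame({"A": [1]}))
        with pytest.raises(ValueError, match="empty"):
            summarize_cross(pd.DataFrame(columns=list(CLASS_ORDER)))

    def test_vial_sd_uses_unbiased_denominator(self):
        counts = pd.DataFrame(
            [[20, 10, 10, 10, 10, 10], [10, 20, 10, 10, 10, 10]],
            columns=list(CLASS_ORDER),
        )
        s = summarize_cross(counts)
        freqs = counts.to_numpy() / counts.to_numpy().sum(1, keepdims=True)
        np.testing.assert_allclose(
            s.vial_sd.to_numpy(), 100 * freqs.std(0, ddof=1), atol=1e-12
        )


class TestMomentsEstimator:
    def test_uniform_frequencies_give_uniform_mixture(self):
        est = estimate_mixture_moments(np.full(6, 1 / 6))
        np.testing.assert_allclose(est.point.as_array(), 1 / 3, atol=1e-12)
        assert not est.projected
        assert est.assumes_unit_viability

    @given(mixtures)
    def test_roundtrip_identity_with_forward_model(self, mixture):
        freqs = zygote_distribution(mixture)
        est = estimate_mixture_moments(freqs)
        np.testing.assert_allclose(
            est.point.as_array(), mixture.as_array(), atol=1e-12
        )

    def test_fixture_cross_matches_least_squares_oracle(self):
        freqs = datasets.table2_pooled_frequencies("B", "10B")
        est = estimate_mixture_moments(freqs)
        np.testing.assert_allclose(est.point.as_array(), (0.196, 0.288, 0.516), atol=5e-4)
        np.testing.assert_allclose(
            est.point.as_array(), lstsq_mixture_oracle(freqs), atol=1e-10
        )

    def test_out_of_simplex_estimates_projected_and_flagged(self):
        # heavy X/12 excess pushes pN negative before projection
        est = estimate_mixture_moments([0.4, 0.4, 0.05, 0.05, 0.05, 0.05])
        assert est.projected
        p = est.point.as_array()
        assert np.all(p >= 0) and p.sum() == pytest.approx(1.0)

    def test_invalid_frequencies_rejected(self):
        with pytest.raises(ValueError, match="sum to 1"):
            estimate_mixture_moments([0.3] * 6)
        with pytest.raises(ValueError, match="nonnegative"):
            estimate_mixture_moments([-0.1, 0.3, 0.2, 0.2, 0.2, 0.2])


class TestBootstrap:
    def test_degenerate_identical_vials_give_zero_width(self):
        # exact model frequencies for mixture (0.5, 0.3, 0.2), 400 flies/vial
        row = (zygote_distribution(PairingMixture(0.5, 0.3, 0.2)) * 400).astype(int)
        counts = pd.DataFrame([row.to_dict()] * 5)
        est = estimate_mixture_bootstrap(counts, n_boot=200, seed=0)
        iv = est.intervals
        np.testing.assert_allclose(iv["lower"], iv["upper"], atol=1e-12)
        np.testing.assert_allclose(iv["point"], (0.5, 0.3, 0.2), atol=1e-12)

    def test_fixed_seed_reproducible(self):
        counts = simulate_xyy_vials(
            PairingMixture(0.2, 0.3, 0.5), None, VialDesign(n_vials=10), seed=5
        )
        a = estimate_mixture_bootstrap(counts, n_boot=300, seed=11)
        b = estimate_mixture_bootstrap(counts, n_boot=300, seed=11)
        pd.testing.assert_frame_equal(a.intervals, b.intervals)

    def test_single_vial_rejected_and_small_nboot_warns(self):
        counts = simulate_xyy_vials(
            PairingMixture.uniform(), None, VialDesign(n_vials=1), seed=0
        )
        with pytest.raises(ValueError, match="at least 2 vials"):
            estimate_mixture_bootstrap(counts)
        two = simulate_xyy_vials(
            PairingMixture.uniform(), None, VialDesign(n_vials=2), seed=0
        )
        with pytest.warns(UserWarning, match="n_boot"):
            estimate_mixture_bootstrap(two, n_boot=50, seed=0)

    def test_interval_coverage_near_nominal(self):
        true = np.array([0.2, 0.3, 0.5])
        design = VialDesign(n_vials=50, mean_vial_size=150, size_dispersion=0)
        hits = np.zeros(3)
        n_rep = 100
        for i in range(n_rep):
            counts = simulate_xyy_vials(
                PairingMixture(*true), None, design, seed=40_000 + i
            )
            iv = estimate_mixture_bootstrap(counts, n_boot=400, level=0.95, seed=i).intervals
            hits += (iv["lower"].to_numpy() <= true) & (true <= iv["upper"].to_numpy())
        coverage = hits / n_rep
        # percentile bootstrap on 50 vials: within ~3 binomial SE of 95%
        assert np.all(coverage >= 0.88) and np.all(coverage <= 1.0)


class TestNondisjunctionRate:
    def test_isogenised_x_stock_rate(self):
        r = nondisjunction_rate(datasets.X_STOCK_FEMALE_NDJ)
        assert round(r.percent, 2) == 0.06
        assert r.lower < r.percent < r.upper

    def test_zero_numerator_has_positive_upper_bound(self):
        r = nondisjunction_rate((0, 2000))
        assert r.percent == 0.0
        assert r.lower == 0.0
        assert r.upper > 0.0

    def test_control_cross_table_rate(self, table1):
        row = table1[table1.y_chromosome == "B"]
        r = nondisjunction_rate(row)
        assert r.n_exceptional == 19 and r.n_total == 4191
        assert round(r.percent, 1) == 0.5

    def test_clopper_pearson_matches_beta_quantiles(self):
        from scipy.stats import beta

        r = nondisjunction_rate((5, 8220), level=0.95)
        assert r.lower == pytest.approx(100 * beta.ppf(0.025, 5, 8216), rel=1e-9)
        assert r.upper == pytest.approx(100 * beta.ppf(0.975, 6, 8215), rel=1e-9)

    def test_zero_total_rejected(self):
        with pytest.raises(ValueError, match="no progeny"):
            nondisjunction_rate((0, 0))


class TestComplementaryCovariance:
    def test_positive_when_mixture_varies_between_vials(self, rng):
        medians = []
        for _ in range(20):
            rows = []
            for _ in range(30):
                m = PairingMixture(*rng.dirichlet([8 / 3] * 3))
                rows.append(rng.multinomial(200, zygote_distribution(m).to_numpy()))
            df = pd.DataFrame(rows, columns=list(CLASS_ORDER))
            medians.append(complementary_covariance(df).to_numpy())
        assert np.all(np.median(medians, axis=0) > 0)

    def test_multinomial_sampling_gives_non_positive_correlations(self):
        medians = []
        for rep in range(20):
            df = simulate_xyy_vials(
                PairingMixture.uniform(), None,
                VialDesign(n_vials=30, mean_vial_size=150, size_dispersion=0),
                seed=50_000 + rep,
            )
            medians.append(complementary_covariance(df).to_numpy())
        # multinomial covariance -p_i p_j / n is slightly negative
        assert np.all(np.median(medians, axis=0) <= 0)

    def test_constant_vials_flagged_undefined(self):
        df = pd.DataFrame([[10, 10, 10, 10, 10, 10]] * 4, columns=list(CLASS_ORDER))
        out = complementary_covariance(df)
        assert out.isna().all()

    def test_too_few_vials_rejected(self):
        df = pd.DataFrame([[10] * 6] * 2, columns=list(CLASS_ORDER))
        with pytest.raises(ValueError, match="at least 3"):
            complementary_covariance(df)


class TestModelResults:
    def test_fit_recovers_generating_mixture(self):
        true = PairingMixture(0.2, 0.3, 0.5)
        counts = simulate_xyy_vials(
            true, None, VialDesign(n_vials=40, mean_vial_size=200, size_dispersion=0),
            seed=8,
        )
        res = PairingFrequencyModel(counts).fit(n_boot=500, seed=8)
        np.testing.assert_allclose(res.params.to_numpy(), true.as_array(), atol=0.05)
        ci = res.conf_int()
        assert (ci["lower"] <= res.params.to_numpy()).all()
        assert (ci["upper"] >= res.params.to_numpy()).all()
        assert res.bse is not None and (res.bse > 0).all()

    def test_viability_bias_is_surfaced_not_hidden(self):
        # XYY sons (12 sperm) at 60% viability biases the unit-viability estimator
        true = PairingMixture.uniform()
        counts = simulate_xyy_vials(
            true, ViabilityVector({"12": 0.6}),
            VialDesign(n_vials=60, mean_vial_size=1000, size_dispersion=0),
            seed=9,
        )
        res = PairingFrequencyModel(counts).fit(n_boot=300, seed=9)
        assert res.estimate.assumes_unit_viability
        assert abs(res.params["N"] - 1 / 3) > 0.02  # bias detectable
        # the diagnostic shows the X ~ 12 asymmetry the bias comes from
        assert res.diagnostics.loc["X~12", "freq_diff_pct"] > 1.0

    def test_summary_reports_fit_and_diagnostics(self):
        counts = simulate_xyy_vials(
            PairingMixture.uniform(), None, VialDesign(n_vials=6), seed=3
        )
        text = PairingFrequencyModel(counts).fit(n_boot=200, seed=3).summary()
        for token in ("vials: 6", "unit zygote viability", "L", "M", "N", "X~12"):
            assert token in text

    def test_control_table_rejected(self, table1):
        with pytest.raises(ValueError, match="six XYY class columns"):
            PairingFrequencyModel(table1)
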