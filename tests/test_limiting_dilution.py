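"""Single-hit limiting-dilution inference: oracles and invariants."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.optimize import minimize_scalar

from parityomics.limiting_dilution import (
    DilutionAssay,
    SingleHitModel,
    classify_outgrowths,
    compare_frequencies,
    fit_single_hit,
    goodness_of_fit,
    _log_likelihood,
)
from parityomics.simulate import simulate_dilution_assay


def random_table(rng):
    k = rng.integers(2, 5)
    doses = np.sort(rng.choice([25, 50, 100, 250, 500, 1000, 2000], size=k, replace=False))[::-1]
    n = rng.integers(3, 12, size=k)
    f = np.exp(rng.uniform(np.log(1e-4), np.log(2e-2)))
    r = rng.binomial(n, 1 - np.exp(-f * doses))
    if r.sum() == 0 or (r == n).all():
        return None
    return DilutionAssay(tuple(map(float, doses)), tuple(map(int, n)), tuple(map(int, r)))


def grid_search_logf(assay, lo=-14.0, hi=-1.0, n=20001):
    d = np.asarray(assay.doses)
    nn = np.asarray(assay.n_injected, float)
    r = np.asarray(assay.n_positive, float)
    grid = np.linspace(lo, hi, n)
    f = np.exp(grid)[:, None]
    with np.errstate(divide="ignore"):
        lls = (r * np.log1p(-np.exp(-f * d))).sum(axis=1) - ((nn - r) * f * d).sum(axis=1)
    i = int(np.argmax(lls))
    # refine with bounded scalar optimization around the best grid point
    res = minimize_scalar(
        lambda x: -_log_likelihood(x, d, nn, r),
        bounds=(grid[max(i - 1, 0)], grid[min(i + 1, n - 1)]),
        method="bounded",
        options={"xatol": 1e-12},
    )
    return float(res.x)


class TestSingleHitMLE:
    def test_single_dose_closed_form(self):
        # one dose group: f = -ln(1 - r/n) / d exactly
        est = fit_single_hit(DilutionAssay((100.0,), (10,), (5,)))
        assert est.f_hat == pytest.approx(np.log(2) / 100.0, rel=1e-8)

    def test_matches_grid_search_oracle_on_random_tables(self):
        rng = np.random.default_rng(42)
        checked = 0
        while checked < 100:
            assay = random_table(rng)
            if assay is None:
                continue
            est = fit_single_hit(assay)
            assert abs(np.log(est.f_hat) - grid_search_logf(assay)) < 1e-6
            checked += 1

    def test_matches_statsmodels_cloglog_glm(self, transplant_tables):
        # independent route: binomial GLM with complementary log-log link
        # and offset log(dose); the intercept is log f
        import statsmodels.api as sm

        for assay in transplant_tables.values():
            df = assay.to_frame()
            endog = np.column_stack([df["n_positive"], df["n_injected"] - df["n_positive"]])
            glm = sm.GLM(
                endog,
                np.ones((len(df), 1)),
                family=sm.families.Binomial(sm.families.links.CLogLog()),
                offset=np.log(df["dose"].to_numpy(float)),
            ).fit()
            est = fit_single_hit(assay)
            assert np.log(est.f_hat) == pytest.approx(glm.params[0], abs=5e-6)
            assert est.log_f_se == pytest.approx(glm.bse[0], rel=1e-3)

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(c=st.floats(min_value=0.1, max_value=10.0))
    def test_dose_rescaling_divides_frequency(self, c):
        base = DilutionAssay((1000.0, 500.0, 250.0), (9, 11, 6), (8, 8, 2))
        scaled = DilutionAssay((1000.0 * c, 500.0 * c, 250.0 * c), (9, 11, 6), (8, 8, 2))
        f0 = fit_single_hit(base).f_hat
        fc = fit_single_hit(scaled).f_hat
        assert fc == pytest.approx(f0 / c, rel=1e-6)

    def test_more_positives_never_decrease_frequency(self):
        rng = np.random.default_rng(7)
        for _ in range(30):
            assay = random_table(rng)
            if assay is None:
                continue
            f0 = fit_single_hit(assay).f_hat
            r = list(assay.n_positive)
            bump = [i for i in range(len(r)) if r[i] < assay.n_injected[i]]
            if not bump:
                continue
            i = bump[0]
            r[i] += 1
            if sum(r) == sum(assay.n_injected):
                continue
            f1 = fit_single_hit(
                DilutionAssay(assay.doses, assay.n_injected, tuple(r))
            ).f_hat
            assert f1 >= f0 - 1e-12

    def test_boundary_tables_flagged(self):
        zero = fit_single_hit(DilutionAssay((100.0, 50.0), (5, 5), (0, 0)))
        assert zero.boundary_flag == "zero" and zero.f_hat == 0.0
        assert zero.ci_high > 0  # one-sided exact upper bound
        full = fit_single_hit(DilutionAssay((100.0, 50.0), (5, 5), (5, 5)))
        assert full.boundary_flag == "infinite" and np.isinf(full.f_hat)

    def test_profile_ci_contains_mle_and_brackets_wald(self, transplant_tables):
        assay = transplant_tables["virgin_c"]
        wald = SingleHitModel(ci_method="wald").fit(assay)
        prof = SingleHitModel(ci_method="profile").fit(assay)
        for model in (wald, prof):
            assert model.ci_[0] < model.frequency_ < model.ci_[1]
        assert prof.ci_[0] == pytest.approx(wald.ci_[0], rel=0.15)

    def test_ci_coverage_at_table_design(self):
        # 95% Wald CI on log f covers the true frequency in 93-97% of
        # simulated assays with the published dose ladder and f=1/500
        doses, n = (1000, 500, 250, 100, 50), (9, 11, 6, 6, 7)
        f_true = 1 / 500
        rng = np.random.default_rng(2024)
        covered = total = 0
        for _ in range(1000):
            r = rng.binomial(n, 1 - np.exp(-f_true * np.asarray(doses, float)))
            if r.sum() == 0 or (r == np.asarray(n)).all():
                continue
            est = fit_single_hit(DilutionAssay(tuple(map(float, doses)), n, tuple(map(int, r))))
            total += 1
            covered += est.ci_low <= f_true <= est.ci_high
        assert 0.93 <= covered / total <= 0.97


class TestGroupComparison:
    def test_identical_groups_give_p_one(self, transplant_tables):
        a = transplant_tables["virgin_c"]
        cmp = compare_frequencies(a, a)
        assert cmp.chi2 == pytest.approx(0.0, abs=1e-8)
        assert cmp.p_value == pytest.approx(1.0, abs=1e-6)

    def test_published_tables_p_values(self, transplant_tables):
        # highly significant drop after parity at stringent scoring,
        # non-significant when rudimentary outgrowths count as positive
        p_c = compare_frequencies(
            transplant_tables["virgin_c"], transplant_tables["parous_c"]
        ).p_value
        p_d = compare_frequencies(
            transplant_tables["virgin_d"], transplant_tables["parous_d"]
        ).p_value
        p_e = compare_frequencies(
            transplant_tables["virgin_e"], transplant_tables["parous_e"]
        ).p_value
        assert p_c == pytest.approx(4e-4, rel=0.25)
        assert p_d == pytest.approx(4e-4, rel=0.25)
        assert p_e == pytest.approx(0.076, rel=0.05)

    def test_boundary_group_flagged_not_fatal(self):
        a = DilutionAssay((100.0, 50.0), (5, 5), (3, 1))
        b = DilutionAssay((100.0, 50.0), (5, 5), (0, 0))
        cmp = compare_frequencies(a, b)
        assert cmp.boundary_flag
        assert 0 <= cmp.p_value <= 1


class TestGoodnessOfFit:
    def test_single_group_raises(self):
        with pytest.raises(ValueError, match="2 dose groups"):
            goodness_of_fit(DilutionAssay((100.0,), (10,), (5,)))

    def test_null_p_roughly_uniform_under_single_hit(self):
        doses, n = np.array([1000.0, 500.0, 100.0]), np.array([30, 30, 30])
        rng = np.random.default_rng(5)
        ps = []
        for _ in range(300):
            r = rng.binomial(n, 1 - np.exp(-0.002 * doses))
            if r.sum() == 0 or (r == n).all():
                continue
            assay = DilutionAssay(tuple(doses), tuple(map(int, n)), tuple(map(int, r)))
            ps.append(goodness_of_fit(assay).p_value)
        ps = np.asarray(ps)
        # calibrated: mean near 0.5 and roughly nominal 5% tail
        assert abs(ps.mean() - 0.5) < 0.06
        assert abs((ps < 0.05).mean() - 0.05) < 0.05

    def test_detects_two_hit_shaped_data(self):
        # P(pos) rising as the square of dose (two-hit-like), far from
        # the single-hit saturation curve, many replicates
        doses = np.array([2000.0, 1000.0, 500.0, 100.0])
        p_two_hit = np.array([0.99, 0.55, 0.10, 0.001])
        rng = np.random.default_rng(6)
        rejected = 0
        reps = 40
        for _ in range(reps):
            r = rng.binomial(60, p_two_hit)
            assay = DilutionAssay(tuple(doses), (60,) * 4, tuple(map(int, r)))
            rejected += goodness_of_fit(assay).p_value < 0.05
        assert rejected > reps / 2


class TestClassifyOutgrowths:
    @pytest.mark.parametrize(
        "fractions, threshold, expected",
        [
            ([0.02, 0.05, 0.30], 0.03, 2),
            ([0.02, 0.05, 0.30], 0.10, 1),
            ([], 0.10, 0),
        ],
    )
    def test_counts(self, fractions, threshold, expected):
        assert classify_outgrowths(fractions, threshold) == expected

    def test_rejects_bad_inputs(self):
        with pytest.raises(ValueError):
            classify_outgrowths([1.2], 0.1)
        with pytest.raises(ValueError):
            classify_outgrowths([0.5], 0.0)


class TestSimulatedAssay:
    def test_zero_frequency_forces_no_outgrowths(self):
        assay = simulate_dilution_assay(0.0, [1000, 100], [50, 50], seed=1)
        assert sum(assay.n_positive) == 0

    def test_positive_fraction_matches_binomial_probability(self):
        # dose 1000 at f=1/500: P(positive) = 1 - e^-2
        assay = simulate_dilution_assay(1 / 500, [1000], [20000], seed=2)
        p = 1 - np.exp(-2)
        se = np.sqrt(p * (1 - p) / 20000)
        assert abs(assay.n_positive[0] / 20000 - p) < 3 * se

    def test_seeded_determinism(self):
        a = simulate_dilution_assay(1 / 500, [1000, 500], [9, 11], seed=3)
        b = simulate_dilution_assay(1 / 500, [1000, 500], [9, 11], seed=3)
        assert a == b

    def test_negative_inputs_rejected(self):
        with pytest.raises(ValueError):
            simulate_dilution_assay(-0.1, [100], [5], seed=0)
        with pytest.raises(ValueError):
            simulate_dilution_assay(0.1, [-100], [5], seed=0)
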