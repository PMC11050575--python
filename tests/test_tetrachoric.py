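"""Bivariate-normal CDF and tetrachoric correlation estimation."""

import math
import warnings

import numpy as np
import pytest
from scipy.integrate import dblquad
from scipy.special import ndtr
from scipy.stats import multivariate_normal

from screendca import (
    CohortError,
    TwoByTwoTable,
    band_of,
    bvn_cdf,
    correlation_matrix,
    tetrachoric_rho,
)
from screendca.simulate import SyntheticConfig, generate


class TestBvnCdf:
    def test_zero_thresholds_independence(self):
        assert bvn_cdf(0.0, 0.0, 0.0) == pytest.approx(0.25, abs=1e-12)

    def test_zero_thresholds_arcsin_closed_form(self):
        # orthant probability 1/4 + arcsin(rho)/(2 pi)
        for rho in (-0.9, -0.5, 0.3, 0.5, 0.6, 0.95):
            expected = 0.25 + math.asin(rho) / (2 * math.pi)
            assert bvn_cdf(0.0, 0.0, rho) == pytest.approx(expected, abs=1e-10)
        assert bvn_cdf(0.0, 0.0, 0.5) == pytest.approx(1 / 3, abs=1e-10)

    def test_independence_factorizes(self):
        for h, k in [(-1.3, 0.7), (2.0, -0.4), (0.3, 0.3)]:
            assert bvn_cdf(h, k, 0.0) == pytest.approx(
                float(ndtr(h) * ndtr(k)), abs=1e-12
            )

    def test_rho_bound(self):
        with pytest.raises(ValueError):
            bvn_cdf(0.0, 0.0, 1.0)

    def test_monotone_in_each_argument(self):
        grid = [-1.5, -0.5, 0.5, 1.5]
        rhos = [-0.8, -0.3, 0.0, 0.4, 0.8]
        for k in grid:
            for rho in rhos:
                vals = [bvn_cdf(h, k, rho) for h in grid]
                assert all(b >= a - 1e-12 for a, b in zip(vals, vals[1:]))
        for h in grid:
            for k in grid:
                vals = [bvn_cdf(h, k, rho) for rho in rhos]
                assert all(b >= a - 1e-12 for a, b in zip(vals, vals[1:]))

    def test_against_2d_quadrature_oracle(self):
        # brute-force double integral of the bivariate normal density
        pts = [-1.2, 0.0, 1.0, 1.8, -0.6]
        rhos = [-0.85, -0.4, 0.0, 0.45, 0.9]
        for h in pts:
            for k in pts[:3]:
                for rho in rhos:
                    cov = [[1.0, rho], [rho, 1.0]]
                    dens = multivariate_normal(mean=[0, 0], cov=cov).pdf
                    oracle, _ = dblquad(
                        lambda y, x: dens([x, y]), -8.5, h,
                        lambda x: -8.5, lambda x: k,
                        epsabs=1e-11,
                    )
                    assert bvn_cdf(h, k, rho) == pytest.approx(oracle, abs=1e-8)

    def test_against_scipy_mvn(self):
        for h, k, rho in [(-0.7, 1.1, 0.6), (0.2, 0.2, -0.75), (1.5, -1.5, 0.3)]:
            oracle = multivariate_normal(
                mean=[0, 0], cov=[[1, rho], [rho, 1]]
            ).cdf([h, k])
            assert bvn_cdf(h, k, rho) == pytest.approx(float(oracle), abs=1e-7)


class TestTetrachoricRho:
    def test_exact_independence(self):
        est = tetrachoric_rho(TwoByTwoTable(25, 25, 25, 25))
        assert est.rho == pytest.approx(0.0, abs=1e-10)
        assert est.converged
        assert est.band == "negligible"

    def test_orthant_inversion_recovers_rho(self):
        # cells from Phi2(0, 0; 0.6): both-pos = 1/4 + asin(0.6)/(2 pi)
        p = 0.25 + math.asin(0.6) / (2 * math.pi)
        n = 100_000
        a = d = round(p * n)
        b = c = round((0.5 - p) * n)
        est = tetrachoric_rho(TwoByTwoTable(a, b, c, d))
        assert est.rho == pytest.approx(0.6, abs=1e-3)

    @pytest.mark.parametrize("rho", [-0.7, -0.2, 0.35, 0.8])
    @pytest.mark.parametrize("taus", [(0.0, 0.0), (-0.5, 0.8)])
    def test_inverse_property_on_exact_tables(self, rho, taus):
        # build cell probabilities exactly from Phi2, scale to large counts
        tr, tc = taus
        p_nn = bvn_cdf(tr, tc, rho)
        p_rn = float(ndtr(tr))  # row-negative marginal
        p_cn = float(ndtr(tc))
        scale = 10_000_000
        d = p_nn * scale
        c = (p_rn - p_nn) * scale
        b = (p_cn - p_nn) * scale
        a = scale - b - c - d
        t = TwoByTwoTable.__new__(TwoByTwoTable)  # float cells, bypass int validation
        object.__setattr__(t, "tp", a)
        object.__setattr__(t, "fp", b)
        object.__setattr__(t, "fn", c)
        object.__setattr__(t, "tn", d)
        est = tetrachoric_rho(t)
        assert est.converged
        assert est.rho == pytest.approx(rho, abs=1e-6)
        assert est.tau_row == pytest.approx(tr, abs=1e-9)
        assert est.tau_col == pytest.approx(tc, abs=1e-9)

    def test_simulation_recovery(self):
        rng = np.random.default_rng(11)
        n, rho = 60_000, 0.5
        z = rng.multivariate_normal([0, 0], [[1, rho], [rho, 1]], size=n)
        x, y = z[:, 0] > 0, z[:, 1] > 0
        t = TwoByTwoTable(
            int((x & y).sum()), int((x & ~y).sum()),
            int((~x & y).sum()), int((~x & ~y).sum()),
        )
        # MC standard error of tetrachoric rho at these margins ~ pi/(2 sqrt(n))
        assert tetrachoric_rho(t).rho == pytest.approx(rho, abs=3 * 1.6 / math.sqrt(n))

    def test_sign_matches_log_odds_ratio(self):
        rng = np.random.default_rng(3)
        for _ in range(50):
            cells = rng.integers(1, 200, size=4)
            t = TwoByTwoTable(*map(int, cells))
            log_or = math.log((t.tp * t.tn) / (t.fp * t.fn))
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                est = tetrachoric_rho(t)
            if abs(log_or) > 1e-6:
                assert math.copysign(1, est.rho) == math.copysign(1, log_or)

    def test_zero_cell_triggers_correction(self):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            est = tetrachoric_rho(TwoByTwoTable(30, 10, 0, 25))
        assert est.corrected

    def test_zero_margin_errors(self):
        with pytest.raises(CohortError, match="margin"):
            tetrachoric_rho(TwoByTwoTable(0, 0, 10, 20))


class TestBanding:
    @pytest.mark.parametrize(
        "rho,band",
        [(0.1, "negligible"), (0.3, "fair"), (-0.45, "fair"), (0.59, "fair"),
         (0.6, "moderate"), (-0.75, "moderate"), (0.8, "very_strong"),
         (-0.95, "very_strong")],
    )
    def test_half_open_bands(self, rho, band):
        assert band_of(rho) == band


@pytest.fixture(scope="module")
def shifted_cohort():
    # spleen anomalies strongly enriched in the heterotaxy class
    cfg = SyntheticConfig(
        n=20_000, seed=77, class_type_shift={("Heterotaxy", "Spleen"): 2.0}
    )
    return generate(cfg)


class TestCorrelationMatrix:
    def test_class_specific_enrichment_detected(self, shifted_cohort):
        m = correlation_matrix(shifted_cohort, subset="all")
        rho = m.to_frame().loc["Spleen", "Heterotaxy"]
        assert rho > 0.3  # banded fair or higher
        assert band_of(rho) in ("fair", "moderate", "very_strong")

    def test_diagnosed_only_subsets(self, shifted_cohort):
        m = correlation_matrix(shifted_cohort, subset="diagnosed_only")
        n_dx = sum(1 for r in shifted_cohort if r.diagnosis_identified)
        assert m.n == n_dx
        assert m.subset == "diagnosed_only"

    def test_absent_label_is_missing_with_reason(self):
        cohort = generate(SyntheticConfig(
            n=2000, seed=5, eca_labels=("Eye", "Renal"),
            eca_marginal_prev=(0.3, 0.3),
        ))
        m = correlation_matrix(cohort, subset="all")
        assert np.isnan(m.to_frame().loc["Skull"]).all()
        assert any(lbl == "Skull" for (lbl, _c) in m.failures)
        assert "zero margin" in set(m.failures.values())

    def test_invalid_subset(self, shifted_cohort):
        with pytest.raises(ValueError):
            correlation_matrix(shifted_cohort, subset="bogus")
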