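"""Design construction, Gibbs sampler recovery, prediction and R-squared."""

import numpy as np
import pandas as pd
import pytest

from ppmr.errors import (
    InvalidDesignError,
    InvalidResponseError,
    UnknownGroupError,
)
from ppmr.hier_model import (
    LEVELS,
    McmcSettings,
    PosteriorFit,
    PredictorScaler,
    R2_LEVEL_SETS,
    bayesian_r2_sequence,
    build_design,
    fit,
    hpd,
)
from ppmr.synthetic import SimConfig, simulate_group_table


def _group_row(species="sp1", family="fam1", order="ord1", region="reg1",
               subregion="reg1_sub1", bin_lo=2.0, mass=150.0, R_bio=50.0,
               R_num=120.0):
    return {
        "species": species, "family": family, "order": order,
        "region": region, "subregion": subregion, "bin_lo_log10g": bin_lo,
        "n_pred": 12, "mean_mass_numw_g": mass, "mean_mass_biow_g": mass,
        "R_num": R_num, "R_bio": R_bio,
        "fish_prop_mass": 0.5, "fish_prop_count": 0.5,
    }


def _small_table():
    rows = []
    for sp, fam in [("sp1", "fam1"), ("sp2", "fam1"), ("sp3", "fam2")]:
        for b, m in [(1.0, 12.0), (2.0, 150.0), (3.0, 1500.0)]:
            rows.append(_group_row(species=sp, family=fam, bin_lo=b, mass=m,
                                   R_bio=40.0 + 10 * b, R_num=100.0 + 30 * b))
    return pd.DataFrame(rows)


class TestScaler:
    def test_two_point_standardisation(self):
        df = pd.DataFrame([
            _group_row(bin_lo=1.0, mass=10.0),
            _group_row(species="sp2", bin_lo=3.0, mass=1000.0),
        ])
        d = build_design(df, "R_bio")
        assert d.X[:, 1] == pytest.approx([-np.sqrt(0.5), np.sqrt(0.5)])
        assert d.X[:, 2] == pytest.approx([-np.sqrt(0.5), np.sqrt(0.5)])

    def test_raw_coef_polynomial_identity(self, rng):
        sc = PredictorScaler(mean_x=2.1, sd_x=0.8, mean_x2=5.0, sd_x2=3.3)
        beta = rng.normal(size=(7, 3))
        raw = sc.raw_coefs(beta)
        for u in [0.5, 1.7, 4.2]:
            x, x2 = sc.transform(u)
            scaled = beta @ np.array([1.0, x, x2])
            direct = raw @ np.array([1.0, u, u * u])
            assert scaled == pytest.approx(direct, rel=1e-12)


class TestBuildDesign:
    def test_quadratic_column_is_standardised_square_of_raw(self):
        d = build_design(_small_table(), "R_bio")
        u = d.log10_mass
        expect = (u ** 2 - (u ** 2).mean()) / (u ** 2).std(ddof=1)
        assert d.X[:, 2] == pytest.approx(expect, rel=1e-12)
        # and explicitly NOT the square of the standardised linear column
        assert not np.allclose(d.X[:, 2], d.X[:, 1] ** 2)

    def test_response_selects_matching_mass_column(self):
        df = _small_table()
        df["mean_mass_numw_g"] = df["mean_mass_biow_g"] * 2.0
        d_bio = build_design(df, "R_bio")
        d_num = build_design(df, "R_num")
        assert d_num.log10_mass == pytest.approx(d_bio.log10_mass + np.log10(2))

    def test_row_order_invariance(self, rng):
        df = _small_table()
        shuffled = df.sample(frac=1.0, random_state=7).reset_index(drop=True)
        d1 = build_design(df, "R_bio")
        d2 = build_design(shuffled, "R_bio")
        assert np.array_equal(d1.y, d2.y)
        assert np.array_equal(d1.X, d2.X)
        for level in LEVELS:
            assert np.array_equal(d1.codes[level], d2.codes[level])
            assert d1.labels[level] == d2.labels[level]

    def test_nested_codes(self):
        d = build_design(_small_table(), "R_bio")
        assert len(d.labels["order"]) == 1
        assert len(d.labels["family"]) == 2
        assert len(d.labels["species"]) == 3
        # species paths carry family and order prefixes
        assert d.labels["species"][0] == ("ord1", "fam1", "sp1")

    def test_errors(self):
        with pytest.raises(InvalidResponseError):
            build_design(_small_table(), "R_median")
        bad = _small_table()
        bad.loc[0, "R_bio"] = -1.0
        with pytest.raises(InvalidResponseError):
            build_design(bad, "R_bio")
        one_mass = pd.DataFrame([
            _group_row(), _group_row(species="sp2"),
        ])
        with pytest.raises(InvalidDesignError):
            build_design(one_mass, "R_bio")


def _manual_fit(beta=(1.0, 0.5, -0.2), sigma=0.1, S=200, species_effect=None):
    """A PosteriorFit with constant draws and identity-like scaling."""
    labels = {
        "order": [("ord1",)],
        "family": [("ord1", "fam1")],
        "species": [("ord1", "fam1", "sp1")],
        "region": [("ord1", "fam1", "sp1", "reg1")],
        "subregion": [("ord1", "fam1", "sp1", "reg1", "reg1_sub1")],
    }
    b = {l: np.zeros((S, 1, 3)) for l in LEVELS}
    if species_effect is not None:
        b["species"][:, 0, :] = species_effect
    return PosteriorFit(
        response="R_bio",
        beta=np.tile(np.asarray(beta, dtype=float), (S, 1)),
        b=b,
        sd={l: np.full((S, 3), 0.1) for l in LEVELS},
        sigma=np.full(S, sigma),
        scaler=PredictorScaler(mean_x=0.0, sd_x=1.0, mean_x2=0.0, sd_x2=1.0),
        labels=labels,
        chains=1,
        mass_range_log10=(0.0, 4.0),
    )


class TestPredict:
    def test_fixed_level_closed_form(self):
        f = _manual_fit(beta=(1.0, 0.5, -0.2))
        u = 2.0
        expect = 10.0 ** (1.0 + 0.5 * u - 0.2 * u * u)
        draws = f.predict_R(mass_log10=u, level="fixed")
        assert draws == pytest.approx(np.full(200, expect))

    def test_random_effects_accumulate(self):
        f = _manual_fit(beta=(1.0, 0.0, 0.0), species_effect=(0.3, 0.1, 0.0))
        u = 2.0
        at_fixed = f.predict_R(mass_log10=u, level="fixed")[0]
        at_species = f.predict_R(species="sp1", mass_log10=u, level="species")[0]
        assert at_species == pytest.approx(at_fixed * 10.0 ** (0.3 + 0.1 * u))
        # order and family effects are zero, so species == subregion here
        at_sub = f.predict_R(species="sp1", region="reg1",
                             subregion="reg1_sub1", mass_log10=u)[0]
        assert at_sub == pytest.approx(at_species)

    def test_bin_midpoint_convention(self):
        f = _manual_fit()
        via_bin = f.predict_R(species="sp1", region="reg1",
                              subregion="reg1_sub1", mass_bin_lo=2.0)
        via_mass = f.predict_R(species="sp1", region="reg1",
                               subregion="reg1_sub1", mass_log10=2.05)
        assert via_bin == pytest.approx(via_mass)

    def test_bias_correction_factor(self):
        f = _manual_fit(sigma=0.2)
        plain = f.predict_R(mass_log10=1.0, level="fixed")
        corr = f.predict_R(mass_log10=1.0, level="fixed", bias_correct=True)
        assert corr / plain == pytest.approx(
            np.full(200, 10.0 ** (0.5 * 0.2 ** 2 * np.log(10.0)))
        )

    def test_unknown_group_raises(self):
        with pytest.raises(UnknownGroupError):
            _manual_fit().predict_R(species="ghost", region="reg1",
                                    subregion="reg1_sub1", mass_log10=1.0)

    def test_extrapolation_warns(self):
        with pytest.warns(UserWarning, match="outside the trained range"):
            _manual_fit().predict_R(mass_log10=9.0, level="fixed")


class TestHpd:
    def test_normal_interval(self, rng):
        draws = rng.normal(3.0, 2.0, 200_000)
        lo, hi = hpd(draws, prob=0.95)
        assert lo == pytest.approx(3.0 - 1.96 * 2.0, abs=0.1)
        assert hi == pytest.approx(3.0 + 1.96 * 2.0, abs=0.1)


class TestR2Sequence:
    def test_closed_form_with_constant_draws(self):
        table, _ = simulate_group_table(_zero_sd_config(), seed=3)
        design = build_design(table, "R_bio")
        f = _manual_fit(beta=(1.0, 0.5, -0.2), sigma=0.3)
        f.scaler = design.scaler
        # one unit per level in the manual fit will not match the design's
        # codes, so zero out everything but fixed effects by reusing shapes
        f.b = {l: np.zeros((200, len(design.labels[l]), 3)) for l in LEVELS}
        f.labels = design.labels
        out = bayesian_r2_sequence(f, design)
        yhat = design.X @ np.array([1.0, 0.5, -0.2])
        expect = yhat.var() / (yhat.var() + 0.09)
        assert list(out["level_set"]) == list(R2_LEVEL_SETS)
        assert out["median"].to_numpy() == pytest.approx(np.full(6, expect))
        # constant draws: the HPD interval collapses onto the value
        assert out["hpd_lo"].to_numpy() == pytest.approx(out["median"].to_numpy())

    def test_sigma_to_zero_gives_r2_one(self):
        table, _ = simulate_group_table(_zero_sd_config(), seed=3)
        design = build_design(table, "R_bio")
        f = _manual_fit(beta=(1.0, 0.5, -0.2), sigma=1e-9)
        f.scaler = design.scaler
        f.b = {l: np.zeros((200, len(design.labels[l]), 3)) for l in LEVELS}
        f.labels = design.labels
        out = bayesian_r2_sequence(f, design)
        assert out["median"].to_numpy() == pytest.approx(np.ones(6))


def _zero_sd_config(**kw):
    zero = (0.0, 0.0, 0.0)
    base = dict(
        order_effect_sds=zero, family_effect_sds=zero, species_effect_sds=zero,
        region_effect_sds=zero, subregion_effect_sds=zero, resid_sd=0.05,
    )
    base.update(kw)
    return SimConfig(**base)


class TestFit:
    def test_too_few_draws_rejected(self):
        table = _small_table()
        design = build_design(table, "R_bio")
        with pytest.raises(InvalidDesignError):
            fit(design, McmcSettings(chains=2, iterations=200, burn_in=100))

    def test_recovers_fixed_curve_when_no_group_structure(self):
        cfg = _zero_sd_config()
        table, truth = simulate_group_table(cfg, seed=11)
        design = build_design(table, "R_bio")
        f = fit(design, "default", seed=5)
        raw_hat = np.median(f.fixed_draws_raw(), axis=0)
        raw_true = truth.fixed_coefs_raw("R_bio")
        assert raw_hat == pytest.approx(raw_true, abs=0.15)
        # no structure was simulated, so every level sd should sit near zero
        for level in LEVELS:
            assert np.median(f.sd[level][:, 0]) < 0.1
        # residual sd close to the generating value
        assert np.median(f.sigma) == pytest.approx(cfg.resid_sd, abs=0.02)

    def test_species_level_variation_detected(self):
        cfg = SimConfig()   # species-dominant random-effect structure
        table, _ = simulate_group_table(cfg, seed=21)
        f = fit(build_design(table, "R_bio"), "default", seed=9)
        sd_species = np.median(f.sd["species"][:, 0])
        assert 0.25 <= sd_species <= 0.75
        assert sd_species > np.median(f.sd["region"][:, 0])
        assert sd_species > np.median(f.sd["subregion"][:, 0])
        assert np.median(f.sigma) < 0.2

    def test_exchangeability_bit_identical(self):
        table, _ = simulate_group_table(_zero_sd_config(), seed=2)
        shuffled = table.sample(frac=1.0, random_state=13).reset_index(drop=True)
        f1 = fit(build_design(table, "R_bio"), "default", seed=4)
        f2 = fit(build_design(shuffled, "R_bio"), "default", seed=4)
        assert np.array_equal(f1.beta, f2.beta)
        assert np.array_equal(f1.sigma, f2.sigma)
        for level in LEVELS:
            assert np.array_equal(f1.b[level], f2.b[level])

    def test_roundtrip_through_directory(self, tmp_path):
        table, _ = simulate_group_table(_zero_sd_config(), seed=2)
        f1 = fit(build_design(table, "R_bio"), "default", seed=4)
        f1.to_dir(tmp_path / "fit")
        f2 = PosteriorFit.from_dir(tmp_path / "fit")
        assert f2.response == f1.response
        assert f2.labels == f1.labels
        assert np.allclose(f2.beta, f1.beta, rtol=0, atol=1e-12)
        assert np.allclose(f2.sigma, f1.sigma, rtol=0, atol=1e-12)
        p1 = f1.predict_R(species=f1.labels["species"][0][2], region="reg1",
                          subregion="reg1_sub1", mass_bin_lo=2.0)
        p2 = f2.predict_R(species=f1.labels["species"][0][2], region="reg1",
                          subregion="reg1_sub1", mass_bin_lo=2.0)
        assert np.allclose(p1, p2, rtol=1e-10)

    def test_diagnostics_present_and_converged(self):
        table, _ = simulate_group_table(_zero_sd_config(), seed=2)
        f = fit(build_design(table, "R_bio"), "default", seed=4)
        assert f.diagnostics["max_rhat"] < 1.2
        assert f.n_draws >= 500
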