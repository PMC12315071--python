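"""Mixed-model engine: frozen lme4/lmerTest reference values, OLS
reduction, parameter recovery, Nakagawa R2 and type-I calibration."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from hetstab import fit_lmm, nakagawa_r2, transform_response, zscore
from hetstab._reml import fit_mixed, fit_ols
from hetstab.lmm import build_design, residual_diagnostics

FIXED = ["het", "emersion", "het:emersion"]

# Reference fits from R lme4 1.1-37 / lmerTest 3.1-3 (REML, Satterthwaite)
# on the conftest ``lmm_fixture`` table.
LMER_NESTED = {
    #            beta        se        df        t        p
    "Intercept": (-0.8706, 0.4991, 8.2496, -1.7445, 0.1181),
    "het": (1.1589, 0.3792, 49.2360, 3.0563, 0.0036),
    "emersion": (1.0309, 0.5221, 50.8918, 1.9747, 0.0537),
    "het:emersion": (-0.8068, 0.6952, 53.2891, -1.1605, 0.2510),
}
LMER_NESTED_VC = (0.7677492, 0.3860192, 0.4674968)  # transect, station, resid

LMER_BOUNDARY = {
    "Intercept": (0.1566, 0.3575, 51.0008),
    "het": (0.3065, 0.4672, 65.8499),
    "emersion": (-0.4966, 0.6159, 64.5480),
    "het:emersion": (1.0319, 0.8178, 65.9976),
}
LMER_BOUNDARY_VC = (0.002467214, 0.0, 0.9899907)


class TestZscoreTransforms:
    def test_two_point_zscore(self):
        assert np.allclose(zscore([0.0, 1.0]), [-np.sqrt(0.5), np.sqrt(0.5)])

    def test_idempotent_and_centred(self, rng):
        v = rng.normal(2, 7, 40)
        z = zscore(v)
        assert abs(z.mean()) < 1e-12 and z.std(ddof=1) == pytest.approx(1.0)
        assert np.allclose(zscore(z), z, atol=1e-12)

    def test_constant_rejected(self):
        with pytest.raises(ValueError):
            zscore([3.0, 3.0, 3.0])

    def test_transform_policies(self):
        v, label = transform_response([0.0, 4.0, 16.0], "sqrt")
        assert np.allclose(v, [0, 2, 4]) and label == "sqrt"
        v, _ = transform_response([0.0], "log1p")
        assert v[0] == 0.0
        assert np.allclose(transform_response([1.0, 2.0], "identity")[0], [1, 2])
        with pytest.raises(ValueError):
            transform_response([0.0, 1.0], "log")
        with pytest.raises(ValueError):
            transform_response([1.0], "cube")


class TestAgainstLmerTest:
    def test_nested_fixture_matches_reference(self, lmm_fixture):
        lf = fit_lmm(lmm_fixture, "y_nested", fixed=FIXED, zscore_predictors=False)
        f = lf.fit
        for name, (b, se, df, t, p) in LMER_NESTED.items():
            j = f.names.index(name)
            assert f.beta[j] == pytest.approx(b, abs=2e-4)
            assert f.se[j] == pytest.approx(se, abs=2e-4)
            assert f.df[j] == pytest.approx(df, abs=0.05)
            assert f.tvalues[j] == pytest.approx(t, abs=2e-3)
            assert f.pvalues[j] == pytest.approx(p, abs=2e-4)
        assert f.vc_transect == pytest.approx(LMER_NESTED_VC[0], abs=1e-4)
        assert f.vc_station == pytest.approx(LMER_NESTED_VC[1], abs=1e-4)
        assert f.sigma2 == pytest.approx(LMER_NESTED_VC[2], abs=1e-4)
        assert not f.singular

    def test_boundary_fixture_matches_reference(self, lmm_fixture):
        """Station variance collapses to the boundary here; estimates and
        SEs still match lmerTest tightly, Satterthwaite df only loosely
        (the approximation is ill-defined at a boundary)."""
        f = fit_lmm(lmm_fixture, "y_boundary", fixed=FIXED, zscore_predictors=False).fit
        for name, (b, se, df) in LMER_BOUNDARY.items():
            j = f.names.index(name)
            assert f.beta[j] == pytest.approx(b, abs=2e-4)
            assert f.se[j] == pytest.approx(se, abs=2e-4)
            assert f.df[j] == pytest.approx(df, abs=12.0)
        assert f.vc_transect == pytest.approx(LMER_BOUNDARY_VC[0], abs=1e-4)
        assert f.vc_station == pytest.approx(LMER_BOUNDARY_VC[1], abs=1e-4)
        assert f.singular

    def test_statsmodels_agrees_on_nested_fixture(self, lmm_fixture):
        """Independent cross-check with statsmodels MixedLM (REML)."""
        smf = pytest.importorskip("statsmodels.formula.api")
        m = smf.mixedlm(
            "y_nested ~ het * emersion", lmm_fixture, groups="transect_id",
            re_formula="1", vc_formula={"station": "0 + C(station_id)"},
        ).fit(reml=True)
        f = fit_lmm(lmm_fixture, "y_nested", fixed=FIXED, zscore_predictors=False).fit
        assert f.coef("het") == pytest.approx(m.params["het"], abs=5e-3)
        assert f.coef("het:emersion") == pytest.approx(m.params["het:emersion"], abs=5e-3)


class TestFitBehaviour:
    def test_reduces_to_ols_without_cluster_variance(self, rng):
        """In the balanced paired design, within-station contrasts always
        equal ordinary least squares; when the variance-component
        estimates hit the zero boundary, every estimate does."""
        df = pd.DataFrame({
            "transect_id": np.repeat(np.arange(5), 14),
            "station_id": np.repeat(np.arange(35), 2),
            "het": np.tile([0, 1], 35),
            "emersion": np.repeat(rng.uniform(0, 1, 35), 2),
        })
        X, names, _ = build_design(df, FIXED, zscore_numeric=False)
        found_boundary = False
        for _ in range(20):
            y = 1.0 + 0.8 * df.het - 0.5 * df.emersion + rng.normal(0, 1, 70)
            mixed = fit_mixed(y.to_numpy(), X, df.transect_id, df.station_id, names)
            ols = fit_ols(y.to_numpy(), X, names)
            for term in ("het", "het:emersion"):  # orthogonal to stations
                j = names.index(term)
                assert mixed.beta[j] == pytest.approx(ols.beta[j], abs=1e-6)
            if mixed.vc_transect < 1e-8 and mixed.vc_station < 1e-8:
                found_boundary = True
                assert np.allclose(mixed.beta, ols.beta, atol=1e-6)
        assert found_boundary

    def test_recovers_known_slope(self, rng):
        rows = []
        for t in range(5):
            for s in range(7):
                e = rng.uniform(0, 1)
                for h in (0, 1):
                    rows.append((f"t{t}", f"t{t}s{s}", h, e))
        df = pd.DataFrame(rows, columns=["transect_id", "station_id", "het", "emersion"])
        hits = 0
        for _ in range(40):
            df["y"] = 2.0 * df.het + rng.normal(0, 1, len(df))
            f = fit_lmm(df, "y", fixed=FIXED, zscore_predictors=False).fit
            j = f.names.index("het")
            lo = f.beta[j] - 1.96 * f.se[j]
            hi = f.beta[j] + 1.96 * f.se[j]
            hits += lo <= 2.0 <= hi
        assert hits >= 33  # ~95% coverage

    def test_row_order_invariance(self, lmm_fixture):
        a = fit_lmm(lmm_fixture, "y_nested", fixed=FIXED).fit
        shuffled = lmm_fixture.sample(frac=1.0, random_state=3)
        b = fit_lmm(shuffled, "y_nested", fixed=FIXED).fit
        assert np.allclose(a.beta, b.beta, atol=1e-8)
        assert np.allclose(a.se, b.se, atol=1e-8)

    def test_zscoring_preserves_t_statistics(self, lmm_fixture):
        """Affine rescaling of predictors leaves t statistics unchanged.

        Exact for main-effect models (z-scoring is affine); with an
        interaction the model itself changes, so there the invariance is
        checked against an affine rescale of the inputs instead."""
        raw = fit_lmm(lmm_fixture, "y_nested", fixed=["het", "emersion"],
                      zscore_predictors=False).fit
        std = fit_lmm(lmm_fixture, "y_nested", fixed=["het", "emersion"],
                      zscore_predictors=True).fit
        for name in ("het", "emersion"):
            i, j = raw.names.index(name), std.names.index(name)
            assert std.tvalues[j] == pytest.approx(raw.tvalues[i], abs=1e-6)
        rescaled = lmm_fixture.assign(emersion=10 * lmm_fixture.emersion + 3)
        a = fit_lmm(lmm_fixture, "y_nested", fixed=FIXED, zscore_predictors=True).fit
        b = fit_lmm(rescaled, "y_nested", fixed=FIXED, zscore_predictors=True).fit
        assert np.allclose(a.tvalues, b.tvalues, atol=1e-6)

    def test_rank_deficient_design_rejected(self, lmm_fixture):
        df = lmm_fixture.assign(dup=lmm_fixture.het)
        with pytest.raises(ValueError, match="rank-deficient"):
            fit_lmm(df, "y_nested", fixed=["het", "dup"], zscore_predictors=False)

    def test_type_one_error_calibrated(self, rng):
        """Null heterogeneity term rejects at ~5% across replicate fits."""
        rows = []
        for t in range(5):
            for s in range(7):
                e = rng.uniform(0, 1)
                for h in (0, 1):
                    rows.append((f"t{t}", f"t{t}s{s}", h, e))
        df = pd.DataFrame(rows, columns=["transect_id", "station_id", "het", "emersion"])
        n_rep, rej = 500, 0
        for i in range(n_rep):
            tr = dict(zip(df.transect_id.unique(), rng.normal(0, 0.5, 5)))
            st_ = dict(zip(df.station_id.unique(), rng.normal(0, 0.5, 35)))
            df["y"] = (
                df.transect_id.map(tr) + df.station_id.map(st_) + rng.normal(0, 1, len(df))
            )
            f = fit_lmm(df, "y", fixed=FIXED).fit
            rej += f.pvalue("het") < 0.05
        assert 0.03 <= rej / n_rep <= 0.08


class TestNakagawaR2:
    def test_null_and_saturated_limits(self, lmm_fixture):
        f = fit_lmm(lmm_fixture, "y_nested", fixed=FIXED).fit
        r2m, r2c = nakagawa_r2(f)
        assert 0 <= r2m <= r2c <= 1

    def test_recovers_known_variance_shares(self, rng):
        """Fixed 0.4 / random 0.3 / residual 0.3 variance shares are
        recovered on average across replicates."""
        rows = []
        for t in range(6):
            for s in range(8):
                for h in (0, 1):
                    rows.append((f"t{t}", f"t{t}s{s}", h))
        df = pd.DataFrame(rows, columns=["transect_id", "station_id", "het"])
        x = df.het.to_numpy() - 0.5  # variance 0.25
        r2ms, r2cs = [], []
        for _ in range(150):
            tr = dict(zip(df.transect_id.unique(), rng.normal(0, np.sqrt(0.15), 6)))
            st_ = dict(zip(df.station_id.unique(), rng.normal(0, np.sqrt(0.15), 48)))
            y = (
                np.sqrt(0.4 / 0.25) * x
                + df.transect_id.map(tr).to_numpy()
                + df.station_id.map(st_).to_numpy()
                + rng.normal(0, np.sqrt(0.3), len(df))
            )
            f = fit_lmm(df.assign(y=y), "y", fixed=["het"]).fit
            m, c = nakagawa_r2(f)
            r2ms.append(m)
            r2cs.append(c)
        assert np.mean(r2ms) == pytest.approx(0.4, abs=0.05)
        assert np.mean(r2cs) == pytest.approx(0.7, abs=0.05)


def test_residual_diagnostics_sane(lmm_fixture):
    f = fit_lmm(lmm_fixture, "y_nested", fixed=FIXED).fit
    d = residual_diagnostics(f)
    assert d["qq_corr"] > 0.95
    assert abs(d["scale_location_slope"]) < 1.0
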