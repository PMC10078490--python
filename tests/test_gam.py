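"""Penalized-spline community GAMs: fits, adjusted R2, F tests."""

import subprocess
import tempfile
from pathlib import Path

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit

import metapart as mp
from metapart.gam import build_design


@pytest.fixture(scope="module")
def smooth_data():
    rng = np.random.default_rng(8)
    n = 100
    data = pd.DataFrame(
        {
            "PC1": np.sort(rng.uniform(-2, 2, n)),
            "PC2": rng.standard_normal(n),
            "PC3": rng.standard_normal(n),
            "lon": rng.uniform(0, 1, n),
            "lat": rng.uniform(0, 1, n),
        }
    )
    P = expit(np.sin(2.0 * data["PC1"].to_numpy()))[:, None] * np.ones((1, 6))
    return P, data


class TestCommunityFit:
    def test_constant_response_explains_nothing(self, smooth_data):
        _, data = smooth_data
        P = np.full((100, 4), 0.5)
        fit = mp.fit_gam_community(P, [mp.SmoothSpec("PC1")], data)
        assert fit.pooled_r2 == 0.0
        assert fit.adj_r2 <= 0.0

    def test_noise_free_smooth_signal_recovered(self, smooth_data):
        P, data = smooth_data
        fit = mp.fit_gam_community(P, [mp.SmoothSpec("PC1")], data)
        assert fit.pooled_r2 > 0.95

    def test_matches_mgcv_penalized_spline_fit(self, smooth_data):
        """Independent oracle: mgcv's quasibinomial P-spline on the same input."""
        P, data = smooth_data
        fit = mp.fit_gam_community(P, [mp.SmoothSpec("PC1")], data)
        with tempfile.TemporaryDirectory() as td:
            csv = Path(td) / "in.csv"
            out = Path(td) / "out.csv"
            pd.DataFrame({"x": data["PC1"], "y": P[:, 0]}).to_csv(csv, index=False)
            script = (
                f"d <- read.csv('{csv}'); library(mgcv);"
                "m <- gam(y ~ s(x, k=9, bs='ps'), data=d, family=quasibinomial());"
                f"write.csv(data.frame(mu=fitted(m)), '{out}', row.names=FALSE)"
            )
            try:
                subprocess.run(
                    ["Rscript", "-e", script], check=True, capture_output=True, timeout=120
                )
            except (FileNotFoundError, subprocess.CalledProcessError) as exc:
                pytest.skip(f"mgcv oracle unavailable: {exc}")
            mu_mgcv = pd.read_csv(out)["mu"].to_numpy()
        corr = np.corrcoef(fit.fitted[:, 0], mu_mgcv)[0, 1]
        assert corr > 0.999
        r2_mgcv = 1 - np.sum((P[:, 0] - mu_mgcv) ** 2) / np.sum((P[:, 0] - P[:, 0].mean()) ** 2)
        assert fit.pooled_r2 == pytest.approx(r2_mgcv, abs=0.02)

    def test_null_predictor_adjusted_r2_centered_near_zero(self):
        """Calibration: a pure-noise smooth contributes ~0 adjusted R2."""
        adj = []
        for seed in range(60):
            rng = np.random.default_rng(seed)
            data = pd.DataFrame({"PC1": rng.standard_normal(40)})
            P = expit(0.5 * rng.standard_normal((40, 8)))
            adj.append(mp.fit_gam_community(P, [mp.SmoothSpec("PC1")], data).adj_r2)
        assert -0.05 < np.mean(adj) < 0.05

    def test_saturated_model_rejected(self):
        rng = np.random.default_rng(0)
        data = pd.DataFrame({c: rng.standard_normal(12) for c in ("PC1", "PC2", "PC3")})
        P = expit(rng.standard_normal((12, 3)))
        with pytest.raises(ValueError, match="saturated"):
            mp.fit_gam_community(
                P, [mp.SmoothSpec(c) for c in ("PC1", "PC2", "PC3")], data
            )

    def test_more_than_three_variables_rejected(self, smooth_data):
        P, data = smooth_data
        specs = [mp.SmoothSpec(c) for c in ("PC1", "PC2", "PC3")] + [mp.SmoothSpec("lon")]
        with pytest.raises(ValueError, match="three variables"):
            mp.fit_gam_community(P, specs, data)

    def test_non_finite_response_rejected(self, smooth_data):
        _, data = smooth_data
        P = np.full((100, 2), 0.4)
        P[0, 0] = np.nan
        with pytest.raises(ValueError, match="non-finite"):
            mp.fit_gam_community(P, [mp.SmoothSpec("PC1")], data)

    def test_empty_specs_rejected(self, smooth_data):
        P, data = smooth_data
        with pytest.raises(ValueError, match="non-empty"):
            mp.fit_gam_community(P, [], data)

    def test_surface_term_fits_joint_coordinate_signal(self):
        rng = np.random.default_rng(5)
        n = 90
        data = pd.DataFrame({"lon": rng.uniform(0, 1, n), "lat": rng.uniform(0, 1, n)})
        signal = np.sin(3 * data["lon"]) * np.cos(3 * data["lat"])
        P = expit(2 * signal.to_numpy())[:, None] * np.ones((1, 4))
        fit = mp.fit_gam_community(P, [mp.SmoothSpec(("lon", "lat"))], data)
        assert fit.pooled_r2 > 0.8
        assert fit.n_coef == 15  # 16-function tensor minus identifiability constraint

    def test_basis_budget_enforced(self, smooth_data):
        _, data = smooth_data
        with pytest.raises(ValueError, match="basis"):
            build_design([mp.SmoothSpec("PC1", basis_size=28)], data)


class TestAdjustedR2AndTests:
    def test_adjusted_never_exceeds_raw(self, smooth_data):
        P, data = smooth_data
        fit = mp.fit_gam_community(P, [mp.SmoothSpec("PC1"), mp.SmoothSpec("PC2")], data)
        assert fit.adj_r2 <= fit.pooled_r2
        assert 0.0 <= fit.pooled_r2 <= 1.0

    def test_joint_model_nests_single_models(self, chain):
        """adjR2(E+S) >= max(adjR2(E), adjR2(S)) - 0.02 for penalized fits."""
        for seed in (0, 1, 2):
            part, _, _, _ = chain("mixed", seed, n_sites=50, n_species=12)
            assert part.adj_r2_ES >= max(part.adj_r2_E, part.adj_r2_S) - 0.02

    def test_f_test_detects_strong_signal(self, smooth_data):
        P, data = smooth_data
        null = mp.intercept_fit(P)
        fit = mp.fit_gam_community(P, [mp.SmoothSpec("PC1")], data)
        f_stat, p = mp.pooled_f_test(null, fit)
        assert f_stat > 50
        assert p < 1e-6

    def test_f_test_ignores_pure_noise(self):
        rng = np.random.default_rng(44)
        data = pd.DataFrame({"PC1": rng.standard_normal(50)})
        P = expit(0.5 * rng.standard_normal((50, 6)))
        null = mp.intercept_fit(P)
        fit = mp.fit_gam_community(P, [mp.SmoothSpec("PC1")], data)
        _, p = mp.pooled_f_test(null, fit)
        assert p > 0.05

    def test_constant_response_gives_p_one(self):
        data = pd.DataFrame({"PC1": np.linspace(-1, 1, 30)})
        P = np.full((30, 3), 0.5)
        null = mp.intercept_fit(P)
        fit = mp.fit_gam_community(P, [mp.SmoothSpec("PC1")], data)
        _, p = mp.pooled_f_test(null, fit)
        assert p == 1.0
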