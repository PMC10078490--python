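"""Variable transforms, correlation PCA, derived environmental indices."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import skew

import metapart as mp
from metapart.io import default_metadata


def make_env(values: pd.DataFrame, **meta_updates) -> mp.EnvironmentTable:
    meta = default_metadata(values.columns)
    for col, updates in meta_updates.items():
        for key, val in updates.items():
            meta.loc[col, key] = val
    return mp.EnvironmentTable(values, meta)


class TestTransforms:
    def test_arcsine_square_root_endpoints(self):
        env = make_env(
            pd.DataFrame({"p": [0.0, 1.0, 0.25]}, index=["a", "b", "c"]),
            p={"transform": "asin_sqrt"},
        )
        out = mp.transform_variables(env).values["p"]
        assert out["a"] == 0.0
        assert out["b"] == pytest.approx(np.pi / 2)
        assert out["c"] == pytest.approx(np.arcsin(0.5))

    def test_percent_scale_divided_first(self):
        env = make_env(
            pd.DataFrame({"cover": [0.0, 100.0, 25.0]}, index=list("abc")),
            cover={"transform": "asin_sqrt", "percent": True},
        )
        out = mp.transform_variables(env).values["cover"]
        assert out["b"] == pytest.approx(np.pi / 2)

    def test_log_offset_convention_with_zeros(self):
        env = make_env(
            pd.DataFrame({"x": [0.0, 9.0, 99.0]}, index=list("abc")), x={"transform": "log"}
        )
        out = mp.transform_variables(env).values["x"]
        assert out["a"] == 0.0  # log10(0 + 1)
        assert out["b"] == pytest.approx(1.0)

    def test_log_without_zeros_has_no_offset(self):
        env = make_env(
            pd.DataFrame({"x": [1.0, 10.0, 100.0]}, index=list("abc")), x={"transform": "log"}
        )
        out = mp.transform_variables(env).values["x"]
        assert np.allclose(out, [0.0, 1.0, 2.0])

    def test_out_of_domain_arcsine_rejected(self):
        env = make_env(
            pd.DataFrame({"p": [0.5, 1.5]}, index=list("ab")), p={"transform": "asin_sqrt"}
        )
        with pytest.raises(ValueError, match="asin_sqrt"):
            mp.transform_variables(env)

    def test_negative_log_input_rejected(self):
        env = make_env(pd.DataFrame({"x": [-1.0, 2.0]}, index=list("ab")), x={"transform": "log"})
        with pytest.raises(ValueError, match="negative"):
            mp.transform_variables(env)

    def test_double_arcsine_application_fails_out_of_domain(self):
        """Transforms are not idempotent: arcsin(sqrt(p)) can exceed 1, so a
        second application must raise rather than silently distort."""
        vals = pd.DataFrame({"p": [0.9, 0.95, 0.99]}, index=list("abc"))
        env = make_env(vals, p={"transform": "asin_sqrt"})
        once = mp.transform_variables(env)
        again = mp.EnvironmentTable(
            once.values, once.metadata.assign(transform="asin_sqrt")
        )
        with pytest.raises(ValueError, match="asin_sqrt"):
            mp.transform_variables(again)

    def test_auto_assignment_log_reduces_skewness(self):
        rng = np.random.default_rng(77)
        raw = pd.DataFrame({"x": rng.lognormal(0.0, 1.5, 200)})
        raw.index = [f"s{i}" for i in range(200)]
        env = make_env(raw)
        out = mp.transform_variables(env, auto=True)
        assert abs(skew(out.values["x"])) < abs(skew(raw["x"]))

    def test_auto_assignment_chooses_asin_sqrt_for_proportions(self):
        rng = np.random.default_rng(3)
        raw = pd.DataFrame({"p": rng.uniform(0, 1, 50)}, index=[f"s{i}" for i in range(50)])
        from metapart.env_processing import auto_assign_transforms

        meta = auto_assign_transforms(raw, default_metadata(raw.columns))
        assert meta.loc["p", "transform"] == "asin_sqrt"


class TestPCA:
    def test_three_variables_explain_everything(self, rng):
        tbl = pd.DataFrame(rng.standard_normal((20, 3)), columns=list("abc"))
        pcs = mp.reduce_environment(tbl)
        assert pcs.cumulative_explained == pytest.approx(1.0, abs=1e-10)

    def test_explained_matches_correlation_eigenvalues(self, rng):
        """Oracle: independent eigen-decomposition of the correlation matrix."""
        tbl = pd.DataFrame(rng.standard_normal((10, 6)), columns=list("abcdef"))
        pcs = mp.reduce_environment(tbl)
        z = (tbl - tbl.mean()) / tbl.std(ddof=1)
        eigval = np.sort(np.linalg.eigvalsh(np.corrcoef(z.T)))[::-1]
        assert np.allclose(pcs.explained, eigval[:3] / 6.0, atol=1e-10)

    def test_variable_order_invariance(self, rng):
        tbl = pd.DataFrame(rng.standard_normal((15, 5)), columns=list("abcde"))
        forward = mp.reduce_environment(tbl)
        permuted = mp.reduce_environment(tbl[["d", "b", "e", "a", "c"]])
        assert np.allclose(forward.explained, permuted.explained, atol=1e-10)
        assert np.allclose(
            forward.loadings.loc[list("abcde")].to_numpy(),
            permuted.loadings.loc[list("abcde")].to_numpy(),
            atol=1e-8,
        )

    def test_reconstruction_residual_equals_unexplained_variance(self, rng):
        tbl = pd.DataFrame(rng.standard_normal((12, 5)), columns=list("abcde"))
        pcs = mp.reduce_environment(tbl)
        z = ((tbl - tbl.mean()) / tbl.std(ddof=1)).to_numpy()
        recon = pcs.scores.to_numpy() @ pcs.loadings.to_numpy().T
        resid_var = np.sum((z - recon) ** 2) / np.sum(z**2)
        assert resid_var == pytest.approx(1.0 - pcs.cumulative_explained, abs=1e-8)

    def test_component_scores_orthogonal(self, rng):
        tbl = pd.DataFrame(rng.standard_normal((25, 7)))
        tbl.columns = [f"v{i}" for i in range(7)]
        pcs = mp.reduce_environment(tbl)
        s = pcs.scores.to_numpy()
        off = s.T @ s - np.diag(np.diag(s.T @ s))
        assert np.abs(off).max() < 1e-8

    def test_sign_convention_largest_loading_positive(self, rng):
        tbl = pd.DataFrame(rng.standard_normal((20, 4)), columns=list("abcd"))
        pcs = mp.reduce_environment(tbl)
        loadings = pcs.loadings.to_numpy()
        assert all(loadings[np.argmax(np.abs(loadings[:, j])), j] > 0 for j in range(3))

    def test_constant_variable_dropped_with_warning(self, rng):
        tbl = pd.DataFrame(rng.standard_normal((10, 4)), columns=list("abcd"))
        tbl["const"] = 1.0
        with pytest.warns(UserWarning, match="constant"):
            pcs = mp.reduce_environment(tbl)
        assert pcs.dropped == ["const"]
        assert "const" not in pcs.loadings.index

    def test_too_few_variables_rejected(self, rng):
        tbl = pd.DataFrame(rng.standard_normal((10, 2)), columns=list("ab"))
        with pytest.raises(ValueError, match="3"):
            mp.reduce_environment(tbl)


class TestDerivedIndices:
    def test_circle_has_shoreline_development_one(self):
        r = 3.7
        assert mp.shoreline_development(2 * np.pi * r, np.pi * r**2) == pytest.approx(1.0)

    def test_unit_square(self):
        assert mp.shoreline_development(4.0, 1.0) == pytest.approx(4.0 / (2 * np.sqrt(np.pi)))

    def test_nonpositive_inputs_rejected(self):
        with pytest.raises(ValueError):
            mp.shoreline_development(0.0, 1.0)
        with pytest.raises(ValueError):
            mp.shoreline_development(1.0, -2.0)

    @pytest.mark.parametrize(
        "proportions, expected",
        [
            ([1.0], 0.0),
            ([0.25, 0.25, 0.25, 0.25], np.log(4)),
            ([0.5, 0.3, 0.2], 1.0297),
            ([2.0, 2.0], np.log(2)),  # renormalized
            ([0.5, 0.0, 0.5], np.log(2)),  # zero class contributes nothing
        ],
    )
    def test_landcover_shannon(self, proportions, expected):
        assert mp.landcover_shannon(proportions) == pytest.approx(expected, abs=1e-4)

    def test_all_zero_cover_rejected(self):
        with pytest.raises(ValueError, match="all-zero"):
            mp.landcover_shannon([0.0, 0.0])
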