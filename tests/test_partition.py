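"""Forward selection, fraction decomposition, spectral-randomization null."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy.special import expit

import metapart as mp


@pytest.fixture(scope="module")
def pc1_driven():
    rng = np.random.default_rng(21)
    n = 70
    data = pd.DataFrame(
        {
            "PC1": rng.standard_normal(n),
            "PC2": rng.standard_normal(n),
            "PC3": rng.standard_normal(n),
            "lon": rng.uniform(0, 1, n),
            "lat": rng.uniform(0, 1, n),
        }
    )
    P = expit(2.0 * np.tanh(data["PC1"].to_numpy()))[:, None] * np.ones((1, 8))
    P = np.clip(P + 0.01 * rng.standard_normal(P.shape), 1e-6, 1 - 1e-6)
    return P, data


class TestForwardSelection:
    def test_empty_candidates_give_empty_selection(self, pc1_driven):
        P, data = pc1_driven
        assert mp.forward_select(P, [], data) == []

    def test_constructed_pc1_signal_selected_first(self, pc1_driven):
        P, data = pc1_driven
        selected = mp.forward_select(
            P, [mp.SmoothSpec(c) for c in ("PC1", "PC2", "PC3")], data
        )
        assert selected
        assert selected[0].predictor == "PC1"

    def test_lon_lat_merge_into_surface(self):
        specs = [mp.SmoothSpec("lon"), mp.SmoothSpec("lat")]
        merged = mp.partition.merge_space_specs(specs)
        assert len(merged) == 1
        assert merged[0].is_surface

    def test_variable_cap_drops_weakest(self, pc1_driven):
        P, data = pc1_driven
        env_sel = [mp.SmoothSpec(c) for c in ("PC1", "PC2", "PC3")]
        space_sel = [mp.SmoothSpec("lon"), mp.SmoothSpec("lat")]
        env_capped, space_capped = mp.enforce_variable_cap(P, data, env_sel, space_sel)
        total = sum(
            s.n_variables for s in mp.partition.merge_space_specs(env_capped + space_capped)
        )
        assert total <= 3
        assert any(s.predictor == "PC1" for s in env_capped)  # the true driver survives


class TestPartitionIdentity:
    def test_empty_space_side_reduces_identity(self, pc1_driven):
        P, data = pc1_driven
        part = mp.partition_variation(P, [mp.SmoothSpec("PC1")], [], data)
        assert part.frac_pure_space == 0.0
        assert part.frac_shared == 0.0
        assert part.frac_pure_env == pytest.approx(part.adj_r2_E, abs=1e-12)

    def test_both_sides_empty_flagged(self, pc1_driven):
        P, data = pc1_driven
        part = mp.partition_variation(P, [], [], data)
        assert part.note == "no predictors selected"
        assert part.residual == 1.0

    def test_identity_exact_for_fitted_groups(self, chain):
        for preset, seed in [("mixed", 0), ("env_only", 1), ("space_only", 2)]:
            part, _, _, _ = chain(preset, seed, n_sites=50, n_species=12)
            total = part.frac_pure_env + part.frac_shared + part.frac_pure_space
            assert total == pytest.approx(part.adj_r2_ES, abs=1e-10)
            assert part.residual == pytest.approx(1 - part.adj_r2_ES, abs=1e-10)


class TestRelativeProportions:
    def test_simple_arithmetic(self):
        (rel, defined) = mp.relative_proportions(0.2, 0.1, 0.1)
        assert defined
        assert rel == pytest.approx((0.5, 0.25, 0.25))

    def test_negative_fraction_floored(self):
        (rel, defined) = mp.relative_proportions(0.3, -0.05, 0.05)
        assert defined
        assert rel == pytest.approx((0.857, 0.0, 0.143), abs=1e-3)

    def test_all_zero_undefined(self):
        (rel, defined) = mp.relative_proportions(0.0, 0.0, 0.0)
        assert not defined
        assert all(np.isnan(v) for v in rel)

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(
        st.tuples(
            st.floats(-1, 1, allow_nan=False),
            st.floats(-1, 1, allow_nan=False),
            st.floats(-1, 1, allow_nan=False),
        )
    )
    def test_proportions_sum_to_one_when_defined(self, fractions):
        (rel, defined) = mp.relative_proportions(*fractions)
        if defined:
            assert sum(rel) == pytest.approx(1.0, abs=1e-10)
            assert all(v >= 0 for v in rel)


class TestMSRCorrection:
    def test_too_few_replicates_rejected(self, landscape30):
        with pytest.raises(ValueError, match="null too small"):
            mp.MSRConfig(mem_basis=landscape30.mem_basis, n_replicates=10)

    def test_requires_environmental_selection(self, pc1_driven, landscape30):
        P, data = pc1_driven
        cfg = mp.MSRConfig(mem_basis=np.eye(70, 69), n_replicates=19)
        with pytest.raises(ValueError, match="non-empty environmental"):
            mp.msr_correct(P, [], [], data, cfg)

    def test_surrogates_preserve_morans_i(self, landscape30):
        """The defining spectral property: surrogate variables keep the
        observed Moran's I exactly (sign flips preserve per-MEM power)."""
        basis = landscape30.mem_basis
        rng = np.random.default_rng(3)
        z = basis[:, :5] @ rng.standard_normal(5) + 0.3 * rng.standard_normal(30)
        coeffs = basis.T @ (z - z.mean())
        i_obs = mp.morans_i(z, landscape30.connectivity)
        for _ in range(5):
            signs = rng.choice((-1.0, 1.0), size=(29, 1))
            z_r = basis @ (coeffs[:, None] * signs)[:, 0] + z.mean()
            assert mp.morans_i(z_r, landscape30.connectivity) == pytest.approx(i_obs, abs=1e-10)

    def test_nonspatial_environment_needs_no_correction(self):
        """White-noise environment: the spectral null has nothing to remove,
        so corrected ~ uncorrected within Monte-Carlo error."""
        import pandas as pd

        diffs = []
        for seed in range(50):
            lan, env, meta, cm, truth = mp.simulate_metacommunity(
                "env_only", n_sites=60, n_species=12, seed=seed
            )
            latent = mp.select_latent_dimension(cm, (0, 1, 2), seed=seed)
            P = mp.predicted_response(latent, allow_nonconverged=True)
            pcs = mp.reduce_environment(env)
            data = pd.concat(
                [pcs.scores, pd.DataFrame(lan.coords, index=env.index, columns=["lon", "lat"])],
                axis=1,
            )
            msr = mp.MSRConfig(mem_basis=lan.mem_basis, n_replicates=39, seed=seed + 999)
            part = mp.partition_variation(
                P, [mp.SmoothSpec("PC1"), mp.SmoothSpec("PC2")], [], data, msr=msr
            )
            diffs.append(part.corrected_adj_r2_E - part.adj_r2_E)
        assert np.mean(np.abs(diffs)) < 0.02

    def test_corrected_fractions_follow_identity(self):
        import pandas as pd

        lan, env, meta, cm, truth = mp.simulate_metacommunity(
            "mixed", n_sites=50, n_species=12, seed=3
        )
        latent = mp.select_latent_dimension(cm, (0, 1, 2), seed=3)
        P = mp.predicted_response(latent, allow_nonconverged=True)
        pcs = mp.reduce_environment(env)
        data = pd.concat(
            [pcs.scores, pd.DataFrame(lan.coords, index=env.index, columns=["lon", "lat"])],
            axis=1,
        )
        msr = mp.MSRConfig(mem_basis=lan.mem_basis, n_replicates=19, seed=5)
        part = mp.partition_variation(
            P, [mp.SmoothSpec("PC1")], [mp.SmoothSpec("lon"), mp.SmoothSpec("lat")], data, msr=msr
        )
        assert part.corrected_adj_r2_E is not None
        total = (
            part.corrected_frac_pure_env
            + part.corrected_frac_shared
            + part.corrected_frac_pure_space
        )
        assert total == pytest.approx(part.corrected_adj_r2_ES, abs=1e-10)
        env_total = part.corrected_frac_pure_env + part.corrected_frac_shared
        assert env_total == pytest.approx(part.corrected_adj_r2_E, abs=1e-10)
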