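"""Shared fixtures: small landscapes and the per-community analysis chain."""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
import pytest

import metapart as mp

warnings.filterwarnings("ignore", message="GLLVM did not converge")


@pytest.fixture(scope="session")
def landscape30():
    return mp.simulate_landscape(30, seed=42)


@pytest.fixture(scope="session")
def chain():
    """The per-community analysis chain as one callable.

    simulate -> GLLVM (AIC dimension) -> predicted response -> forward
    selection (env PCs and coordinates separately) -> cap -> partition.
    Returns (PartitionResult, LatentFit, Landscape, predictor table).
    """

    def run(
        preset: str,
        seed: int,
        n_sites: int = 60,
        n_species: int = 20,
        d_candidates=(0, 1, 2, 3),
        msr_replicates: int = 0,
        alpha: float = 0.05,
        **truth_overrides,
    ):
        lan, env, meta, cm, truth = mp.simulate_metacommunity(
            preset, n_sites=n_sites, n_species=n_species, seed=seed, **truth_overrides
        )
        latent = mp.select_latent_dimension(cm, d_candidates, seed=seed)
        P = mp.predicted_response(latent, allow_nonconverged=True)
        pcs = mp.reduce_environment(env)
        data = pd.concat(
            [pcs.scores, pd.DataFrame(lan.coords, index=env.index, columns=["lon", "lat"])],
            axis=1,
        )
        env_sel = mp.forward_select(
            P, [mp.SmoothSpec(c) for c in ("PC1", "PC2", "PC3")], data, alpha=alpha
        )
        space_sel = mp.forward_select(
            P, [mp.SmoothSpec(c) for c in ("lon", "lat")], data, alpha=alpha
        )
        env_sel, space_sel = mp.enforce_variable_cap(P, data, env_sel, space_sel)
        msr = None
        if msr_replicates and env_sel:
            msr = mp.MSRConfig(
                mem_basis=lan.mem_basis, n_replicates=msr_replicates, seed=seed + 10_000
            )
        part = mp.partition_variation(P, env_sel, space_sel, data, msr=msr)
        return part, latent, lan, data

    return run


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
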