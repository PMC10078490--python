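"""Synthetic metacommunities with known environmental and spatial structure.

The generator mirrors the structure of a two-region temporary-pond survey:
~30 sites per region, dozens of mixed-type environmental variables of which a
subset is spatially autocorrelated, and binary species matrices whose
occurrences are driven by environmental gradients, broad-scale spatial
gradients (Moran eigenvector combinations), and a shared latent site effect.
Because the generating effect sizes are known, downstream variation
partitioning can be tested for calibration (no signal -> fractions near zero)
and recovery (the dominant fraction matches the dominant process).

Species occurrence model, site i, species j:

    logit p_ij = alpha_j + beta_env[j] * g_env(i, j) + beta_space[j] * g_spc(i, j)
                 + lambda_j * u_i

where g_env/g_spc are unit-variance shared gradients (environmental columns,
or combinations of broad-scale MEMs), u_i ~ N(0,1) is a latent site effect
with species loadings lambda_j ~ N(0, sigma_latent^2), and alpha_j is solved
so that each species' mean occurrence probability equals prevalence_target.
Occurrences are then independent Bernoulli draws.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import expit

from .community import CommunityMatrix
from .landscape import Landscape, simulate_landscape

__all__ = [
    "SyntheticTruth",
    "simulate_environment",
    "simulate_community",
    "preset_truth",
    "simulate_metacommunity",
    "PRESETS",
]

PRESETS = ("env_only", "space_only", "mixed", "null", "confounded")


@dataclass
class SyntheticTruth:
    """Generating parameters of a synthetic metacommunity.

    Effect sizes are on the logit scale and multiply unit-variance gradients,
    so beta = 2 moves a site one logit per gradient standard deviation.
    ``autocorr_scale`` is the fraction of the broad-scale (positive-eigenvalue)
    MEM spectrum used to build spatial structure; small values give the
    broadest patterns only.
    """

    n_sites: int = 30
    n_species: int = 40
    beta_env: float | np.ndarray = 0.0
    beta_space: float | np.ndarray = 0.0
    n_env_spatial: int = 3
    n_env_nonspatial: int = 3
    autocorr_scale: float = 0.5
    sigma_latent: float = 0.5
    prevalence_target: float = 0.35
    seed: int = 0
    env_noise: float = 0.5
    env_targets: str = "all"  # which env columns species respond to
    n_active_gradients: int = 2  # shared gradients per process

    def __post_init__(self) -> None:
        if not 0.0 < self.prevalence_target < 1.0:
            raise ValueError("prevalence_target must be in (0, 1)")
        if not 0.0 < self.autocorr_scale <= 1.0:
            raise ValueError("autocorr_scale must be in (0, 1]")
        self.beta_env = np.broadcast_to(
            np.asarray(self.beta_env, dtype=float), (self.n_species,)
        ).copy()
        self.beta_space = np.broadcast_to(
            np.asarray(self.beta_space, dtype=float), (self.n_species,)
        ).copy()


def _broad_scale_columns(landscape: Landscape, autocorr_scale: float) -> np.ndarray:
    n_pos = landscape.n_positive_mem
    if n_pos == 0:
        raise ValueError("landscape has no broad-scale MEM columns")
    k = max(1, int(round(autocorr_scale * n_pos)))
    return landscape.mem_basis[:, :k]


def _standardize(x: np.ndarray) -> np.ndarray:
    sd = x.std(axis=0, ddof=0)
    return (x - x.mean(axis=0)) / np.where(sd == 0, 1.0, sd)


def _make_environment(landscape: Landscape, truth: SyntheticTruth):
    """Build latent environmental gradients and the observed variable table.

    A small number of unit-variance latent gradients (``truth.n_active_gradients``
    per type) underlie the measured variables: spatial gradients are linear
    combinations of broad-scale MEM columns, nonspatial gradients are white
    noise. Each observed variable measures one gradient with relative noise
    ``truth.env_noise`` — this correlation structure is what makes a
    three-component PCA of the table meaningful, as in field data where many
    measured variables reflect few underlying gradients.

    Returns (table, metadata, gradients dict). Deterministic in truth.seed.
    """
    if landscape.n_sites != truth.n_sites:
        raise ValueError("landscape and truth disagree on n_sites")
    rng = np.random.default_rng([truth.seed, 10_001])
    n = truth.n_sites
    g = truth.n_active_gradients
    grad_spatial = np.zeros((n, 0))
    if truth.n_env_spatial > 0:
        basis = _broad_scale_columns(landscape, truth.autocorr_scale)
        grad_spatial = _standardize(basis @ rng.standard_normal((basis.shape[1], g)))
    grad_nonspatial = (
        _standardize(rng.standard_normal((n, g))) if truth.n_env_nonspatial > 0 else np.zeros((n, 0))
    )

    columns: dict[str, np.ndarray] = {}
    meta_rows = []
    for v in range(truth.n_env_spatial):
        signal = grad_spatial[:, v % grad_spatial.shape[1]]
        x = signal + truth.env_noise * rng.standard_normal(n)
        columns[f"env_sp_{v:02d}"] = _standardize(x)
        meta_rows.append((f"env_sp_{v:02d}", "none", "macroclimatic", "z-score", True))
    for v in range(truth.n_env_nonspatial):
        signal = grad_nonspatial[:, v % grad_nonspatial.shape[1]]
        x = signal + truth.env_noise * rng.standard_normal(n)
        columns[f"env_ns_{v:02d}"] = _standardize(x)
        meta_rows.append((f"env_ns_{v:02d}", "none", "limnological", "z-score", False))
    env = pd.DataFrame(columns, index=pd.Index(landscape.site_id, name="site_id"))
    meta = pd.DataFrame(
        meta_rows, columns=["variable", "transform", "set", "units", "spatial"]
    ).set_index("variable")
    gradients = {"spatial": grad_spatial, "nonspatial": grad_nonspatial}
    return env, meta, gradients


def simulate_environment(
    landscape: Landscape, truth: SyntheticTruth
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate an environment table with a spatially structured subset.

    Spatially structured variables measure latent gradients built from
    broad-scale MEM columns (plus white noise, sd ``truth.env_noise``);
    nonspatial variables measure white-noise gradients the same way. All
    columns are standardized to zero mean, unit variance.

    Returns the table and a metadata frame (variable, transform, set, units,
    spatial flag). Spatial variables are labeled ``macroclimatic`` and
    nonspatial ones ``limnological``, mirroring the field expectation that
    climate varies regionally and local limnology does not.
    """
    env, meta, _ = _make_environment(landscape, truth)
    return env, meta


def simulate_community(
    landscape: Landscape,
    environment: pd.DataFrame,
    truth: SyntheticTruth,
    env_meta: pd.DataFrame | None = None,
    return_details: bool = False,
):
    """Draw a presence-absence matrix from the occurrence model.

    Species are assigned cyclically to a small number of shared gradients
    (``truth.n_active_gradients`` per process): environmental gradients are
    the latent gradients underlying the observed environment table
    (restricted by ``truth.env_targets`` to 'all', 'spatial' or 'nonspatial'
    gradients), spatial gradients are random unit-variance combinations of
    broad-scale MEMs independent of the environment. Degenerate (all-0/all-1)
    species are retained and flagged on the returned matrix.
    """
    env_values = environment.to_numpy(dtype=float)
    n, m = truth.n_sites, truth.n_species
    if env_values.shape[0] != n or landscape.n_sites != n:
        raise ValueError("dimensions of landscape, environment and truth disagree")
    rng = np.random.default_rng([truth.seed, 20_002])

    # --- environmental gradients: species respond to the latent gradients the
    # observed variables measure (regenerated deterministically from the seed) ---
    _, _, gradients = _make_environment(landscape, truth)
    if truth.env_targets == "all":
        env_gradients = np.hstack([gradients["spatial"], gradients["nonspatial"]])
    elif truth.env_targets in ("spatial", "nonspatial"):
        env_gradients = gradients[truth.env_targets]
    else:
        raise ValueError(f"unknown env_targets {truth.env_targets!r}")
    if env_gradients.shape[1] == 0:
        if np.any(truth.beta_env != 0.0):
            raise ValueError(f"no environmental gradients match env_targets={truth.env_targets!r}")
        env_gradients = np.zeros((n, 1))
    k_env = env_gradients.shape[1]
    env_assign = np.arange(m) % k_env

    # --- spatial gradients ---
    basis = _broad_scale_columns(landscape, truth.autocorr_scale)
    k_spc = truth.n_active_gradients
    spc_gradients = _standardize(basis @ rng.standard_normal((basis.shape[1], k_spc)))
    spc_assign = np.arange(m) % k_spc

    signs_env = rng.choice([-1.0, 1.0], size=m)
    signs_spc = rng.choice([-1.0, 1.0], size=m)
    u = rng.standard_normal(n)
    lam = truth.sigma_latent * rng.standard_normal(m)

    eta0 = (
        env_gradients[:, env_assign] * (truth.beta_env * signs_env)
        + spc_gradients[:, spc_assign] * (truth.beta_space * signs_spc)
        + np.outer(u, lam)
    )
    alpha = _solve_intercepts(eta0, truth.prevalence_target)
    prob = expit(alpha + eta0)
    occurrence = (rng.uniform(size=(n, m)) < prob).astype(int)

    cm = CommunityMatrix(
        pd.DataFrame(
            occurrence,
            index=pd.Index(landscape.site_id, name="site_id"),
            columns=[f"sp_{j:03d}" for j in range(m)],
        )
    )
    if not return_details:
        return cm
    details = {
        "alpha": alpha,
        "prob": prob,
        "env_gradients": env_gradients,
        "env_assign": env_assign,
        "spc_gradients": spc_gradients,
        "spc_assign": spc_assign,
        "signs_env": signs_env,
        "signs_spc": signs_spc,
        "u": u,
        "lam": lam,
    }
    return cm, details


def _solve_intercepts(eta0: np.ndarray, target: float) -> np.ndarray:
    """Per-species intercept so that mean occurrence probability hits target."""
    lo = np.full(eta0.shape[1], -30.0)
    hi = np.full(eta0.shape[1], 30.0)
    for _ in range(60):
        mid = (lo + hi) / 2.0
        mean_p = expit(mid + eta0).mean(axis=0)
        lo = np.where(mean_p < target, mid, lo)
        hi = np.where(mean_p < target, hi, mid)
    return (lo + hi) / 2.0


def preset_truth(
    name: str,
    n_sites: int = 30,
    n_species: int = 40,
    seed: int = 0,
    **overrides,
) -> SyntheticTruth:
    """Named generating scenarios used throughout testing and calibration.

    - ``null``: no environmental or spatial signal; a latent site effect only,
      so the community has structure that neither predictor set explains.
    - ``env_only``: strong response to nonspatial environmental variables.
    - ``space_only``: strong response to broad-scale spatial gradients; the
      environment is pure noise.
    - ``mixed``: moderate responses to both, with part of the environment
      spatially structured.
    - ``confounded``: spatially structured environment and spatially
      structured species that do not respond to the environment — the
      scenario the spectral-randomization correction exists for.
    """
    base = dict(n_sites=n_sites, n_species=n_species, seed=seed)
    if name == "null":
        cfg = dict(beta_env=0.0, beta_space=0.0, sigma_latent=1.0,
                   n_env_spatial=3, n_env_nonspatial=3)
    elif name == "env_only":
        cfg = dict(beta_env=2.0, beta_space=0.0, sigma_latent=0.5,
                   n_env_spatial=0, n_env_nonspatial=6, env_targets="nonspatial")
    elif name == "space_only":
        cfg = dict(beta_env=0.0, beta_space=2.0, sigma_latent=0.5,
                   n_env_spatial=0, n_env_nonspatial=6)
    elif name == "mixed":
        # half the taxa track the environment, half track space — the
        # heterogeneity the multi-taxon design is about
        j = np.arange(n_species)
        cfg = dict(beta_env=np.where(j % 2 == 0, 2.5, 0.0),
                   beta_space=np.where(j % 2 == 1, 2.0, 0.0),
                   sigma_latent=0.3,
                   n_env_spatial=3, n_env_nonspatial=3, env_targets="all",
                   n_active_gradients=1)
    elif name == "confounded":
        cfg = dict(beta_env=0.0, beta_space=2.0, sigma_latent=0.5,
                   n_env_spatial=4, n_env_nonspatial=2, autocorr_scale=0.4)
    else:
        raise ValueError(f"unknown preset {name!r}; choose from {PRESETS}")
    cfg.update(base)
    cfg.update(overrides)
    return SyntheticTruth(**cfg)


def simulate_metacommunity(
    preset: str,
    n_sites: int = 30,
    n_species: int = 40,
    seed: int = 0,
    extent: float = 1.0,
    geographic: bool = False,
    **overrides,
):
    """One-call generator: landscape + environment + community for a preset.

    Returns ``(landscape, environment, env_meta, community, truth)``.
    """
    truth = preset_truth(preset, n_sites=n_sites, n_species=n_species, seed=seed, **overrides)
    landscape = simulate_landscape(n_sites, extent=extent, seed=seed, geographic=geographic)
    env, meta = simulate_environment(landscape, truth)
    community = simulate_community(landscape, env, truth, env_meta=meta)
    return landscape, env, meta, community, truth
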