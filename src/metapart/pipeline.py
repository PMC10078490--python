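"""The per-group analysis chain and the multi-group pipeline driver.

For each community matrix the chain is: latent-variable reduction of the
binary matrix (binomial GLLVM, dimension by AIC) -> predicted-probability
response -> forward selection of environmental principal components and of
spatial coordinates (separately) -> variation partitioning with the
spectral-randomization correction -> relative proportions.

Groups are isolated: an error in one (a 5-taxon matrix with no signal, say)
marks that group failed and the rest continue. All randomness derives
deterministically from the master seed and the group label.
"""

from __future__ import annotations

import hashlib
import json
import zlib
from dataclasses import dataclass, field as dc_field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .community import CommunityMatrix
from .env_processing import EnvironmentTable, PCScores, reduce_environment, transform_variables
from .gam import SmoothSpec
from .gllvm import LatentFit, predicted_response, select_latent_dimension
from .io import read_tables
from .landscape import build_mem_basis
from .partition import (
    MSRConfig,
    PartitionResult,
    enforce_variable_cap,
    forward_select,
    partition_variation,
)

__all__ = ["PipelineConfig", "GroupResult", "analyze_group", "run_pipeline", "derive_seed"]


def derive_seed(master_seed: int, label: str, stage: str) -> int:
    """Deterministic per-(group, stage) seed below 2^31."""
    digest = zlib.crc32(f"{label}:{stage}".encode())
    return (int(master_seed) * 1_000_003 + digest) % (2**31 - 1)


@dataclass
class PipelineConfig:
    """Settings of the full multi-group run (see module docstring)."""

    community_paths: dict = dc_field(default_factory=dict)
    environment_path: str | None = None
    metadata_path: str | None = None
    coordinates_path: str | None = None
    geographic: bool = True
    auto_transform: bool = True
    d_candidates: tuple = (0, 1, 2, 3)
    alpha: float = 0.05
    basis_size: int = 9
    msr_replicates: int = 199
    master_seed: int = 0
    output_dir: str | None = None
    pooling: str = "response"

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh)
        raw["d_candidates"] = tuple(raw.get("d_candidates", (0, 1, 2, 3)))
        return cls(**raw)

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


@dataclass
class GroupResult:
    group: str
    latent: LatentFit | None
    partition: PartitionResult | None
    error: str | None = None

    @property
    def failed(self) -> bool:
        return self.error is not None


def analyze_group(
    community: CommunityMatrix,
    pc_scores: pd.DataFrame,
    coords: pd.DataFrame,
    mem_basis: np.ndarray,
    group: str = "group",
    d_candidates=(0, 1, 2, 3),
    alpha: float = 0.05,
    basis_size: int = 9,
    msr_replicates: int = 199,
    master_seed: int = 0,
    apply_msr: bool = True,
) -> GroupResult:
    """Run the full chain for one community matrix.

    ``pc_scores`` holds columns PC1..PC3; ``coords`` holds lon/lat (or x/y,
    renamed to lon/lat for modeling purposes).
    """
    xy = coords.rename(columns={"x": "lon", "y": "lat"})
    data = pd.concat([pc_scores, xy[["lon", "lat"]]], axis=1)

    latent = select_latent_dimension(
        community, d_candidates=d_candidates, seed=derive_seed(master_seed, group, "gllvm")
    )
    P = predicted_response(latent, allow_nonconverged=True)

    env_candidates = [SmoothSpec(c, basis_size) for c in ("PC1", "PC2", "PC3")]
    space_candidates = [SmoothSpec(c, basis_size) for c in ("lon", "lat")]
    env_sel = forward_select(P, env_candidates, data, alpha=alpha)
    space_sel = forward_select(P, space_candidates, data, alpha=alpha)
    env_sel, space_sel = enforce_variable_cap(P, data, env_sel, space_sel)

    msr = None
    if apply_msr and env_sel:
        msr = MSRConfig(
            mem_basis=mem_basis,
            n_replicates=msr_replicates,
            seed=derive_seed(master_seed, group, "msr"),
        )
    part = partition_variation(P, env_sel, space_sel, data, msr=msr)
    return GroupResult(group=group, latent=latent, partition=part)


def _summary_row(res: GroupResult) -> dict:
    row = {"group": res.group, "failed": res.failed, "error": res.error}
    if res.latent is not None:
        row.update(
            n_latent=res.latent.n_latent,
            gllvm_aic=res.latent.aic,
            gllvm_converged=res.latent.converged,
        )
    if res.partition is not None:
        p = res.partition
        row.update(
            selected_env="+".join(p.selected_env),
            selected_space="+".join(p.selected_space),
            adj_r2_E=p.adj_r2_E,
            adj_r2_S=p.adj_r2_S,
            adj_r2_ES=p.adj_r2_ES,
            frac_pure_env=p.frac_pure_env,
            frac_shared=p.frac_shared,
            frac_pure_space=p.frac_pure_space,
            residual=p.residual,
            corrected_adj_r2_E=p.corrected_adj_r2_E,
            corrected_frac_pure_env=p.corrected_frac_pure_env,
            corrected_frac_shared=p.corrected_frac_shared,
            rel_pure_env=p.rel_pure_env,
            rel_shared=p.rel_shared,
            rel_pure_space=p.rel_pure_space,
            msr_replicates=p.msr_replicates,
        )
    return row


def run_pipeline(
    config: PipelineConfig,
    communities: dict | None = None,
    environment: EnvironmentTable | None = None,
    coordinates: pd.DataFrame | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Run every group through the chain; return (summary table, results).

    Inputs may be given in memory (``communities`` as a dict of
    CommunityMatrix, plus ``environment`` and ``coordinates``) or read from
    the paths in ``config``. A failed group yields a summary row with its
    error message; other groups are unaffected. When ``config.output_dir``
    is set, the summary CSV and a run manifest (package version, seeds,
    config hash) are written there.
    """
    if communities is None:
        communities, environment, coordinates = read_tables(
            config.community_paths,
            config.environment_path,
            config.coordinates_path,
            config.metadata_path,
        )
    env = transform_variables(environment, auto=config.auto_transform)
    pcs: PCScores = reduce_environment(env)
    coord_cols = ["lon", "lat"] if "lon" in coordinates.columns else ["x", "y"]
    coord_array = coordinates[coord_cols].to_numpy(dtype=float)
    mem_basis, _, _ = build_mem_basis(coord_array, geographic=config.geographic)

    results: dict[str, GroupResult] = {}
    for group, cm in communities.items():
        try:
            results[group] = analyze_group(
                cm,
                pcs.scores,
                coordinates,
                mem_basis,
                group=group,
                d_candidates=config.d_candidates,
                alpha=config.alpha,
                basis_size=config.basis_size,
                msr_replicates=config.msr_replicates,
                master_seed=config.master_seed,
            )
        except Exception as exc:  # per-group isolation
            results[group] = GroupResult(group=group, latent=None, partition=None, error=str(exc))
    summary = pd.DataFrame([_summary_row(r) for r in results.values()])

    if config.output_dir:
        out = Path(config.output_dir)
        out.mkdir(parents=True, exist_ok=True)
        summary.to_csv(out / "partition_summary.csv", index=False)
        manifest = {
            "package_version": __version__,
            "master_seed": config.master_seed,
            "config_hash": config.config_hash(),
            "pca_cumulative_explained": pcs.cumulative_explained,
            "groups": list(communities),
        }
        (out / "run_manifest.json").write_text(json.dumps(manifest, indent=2))
    return summary, results
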