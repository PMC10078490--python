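"""CSV readers/writers and cross-table validation.

All tables are plain CSV with a header row and ``site_id`` as the first
column: community matrices (sites x taxa, binary), the environment table
(sites x variables, numeric) with a companion metadata CSV (variable,
transform, set, units[, percent]), and site coordinates (lon, lat in decimal
degrees, or x, y planar).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .community import CommunityMatrix
from .env_processing import EnvironmentTable

__all__ = [
    "read_community",
    "read_environment",
    "read_coordinates",
    "read_tables",
    "write_community",
    "write_environment",
    "write_coordinates",
    "default_metadata",
]


def _read_indexed_csv(path) -> pd.DataFrame:
    frame = pd.read_csv(path)
    if frame.columns[0] != "site_id":
        raise ValueError(f"{path}: first column must be 'site_id', got {frame.columns[0]!r}")
    return frame.set_index("site_id")


def read_community(path) -> CommunityMatrix:
    frame = _read_indexed_csv(path)
    values = frame.to_numpy()
    bad = np.argwhere(~np.isin(values, (0, 1)))
    if bad.size:
        i, j = bad[0]
        raise ValueError(
            f"{path}: non-binary entry {values[i, j]!r} at site {frame.index[i]!r}, "
            f"taxon {frame.columns[j]!r}"
        )
    return CommunityMatrix(frame.astype(int))


def default_metadata(variables) -> pd.DataFrame:
    return pd.DataFrame(
        {"transform": "none", "set": "other", "units": "", "percent": False},
        index=pd.Index(list(variables), name="variable"),
    )


def read_environment(path, metadata_path=None) -> EnvironmentTable:
    values = _read_indexed_csv(path).astype(float)
    if metadata_path is None:
        meta = default_metadata(values.columns)
    else:
        meta = pd.read_csv(metadata_path).set_index("variable")
    return EnvironmentTable(values=values, metadata=meta)


def read_coordinates(path) -> pd.DataFrame:
    coords = _read_indexed_csv(path).astype(float)
    cols = set(coords.columns)
    if not ({"lon", "lat"} <= cols or {"x", "y"} <= cols):
        raise ValueError(f"{path}: coordinate columns must be lon/lat or x/y")
    if coords.isna().any().any():
        missing = coords.index[coords.isna().any(axis=1)].tolist()
        raise ValueError(f"{path}: missing coordinates for sites {missing}")
    return coords


def read_tables(
    community_paths: dict, environment_path, coordinates_path, metadata_path=None
) -> tuple[dict, EnvironmentTable, pd.DataFrame]:
    """Read and cross-validate all pipeline inputs.

    ``community_paths`` maps group names to community CSV paths. Site sets
    must match exactly between every community matrix, the environment table
    and the coordinates; mismatches raise with the offending sites listed.
    """
    env = read_environment(environment_path, metadata_path)
    coords = read_coordinates(coordinates_path)
    ref = set(env.values.index)
    _check_sites(set(coords.index), ref, "coordinates", "environment")
    communities = {}
    for name, path in community_paths.items():
        cm = read_community(path)
        _check_sites(set(cm.occurrence.index), ref, f"community {name!r}", "environment")
        communities[name] = cm
    return communities, env, coords


def _check_sites(found: set, expected: set, what: str, reference: str) -> None:
    extra = sorted(found - expected)
    missing = sorted(expected - found)
    if extra or missing:
        parts = []
        if missing:
            parts.append(f"absent from {what}: {missing}")
        if extra:
            parts.append(f"absent from {reference}: {extra}")
        raise ValueError(f"site mismatch between {what} and {reference}; " + "; ".join(parts))


def write_community(cm: CommunityMatrix, path) -> None:
    cm.occurrence.rename_axis("site_id").to_csv(path)


def write_environment(env: EnvironmentTable, path, metadata_path=None) -> None:
    env.values.rename_axis("site_id").to_csv(path)
    if metadata_path is not None:
        env.metadata.rename_axis("variable").to_csv(metadata_path)


def write_coordinates(coords: pd.DataFrame, path) -> None:
    coords.rename_axis("site_id").to_csv(path)
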