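"""The site-by-taxon presence-absence matrix, the unit of analysis."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["CommunityMatrix"]


@dataclass
class CommunityMatrix:
    """Binary site-by-taxon occurrence table.

    ``occurrence`` is indexed by site_id with one column per taxon; entries are
    0/1. Taxa present everywhere or nowhere are retained (as in real data,
    where ubiquitous taxa occur) and flagged via :meth:`degenerate_taxa`;
    operations whose preconditions require variation exclude them explicitly.
    """

    occurrence: pd.DataFrame

    def __post_init__(self) -> None:
        values = self.occurrence.to_numpy()
        if values.ndim != 2 or values.shape[0] < 2 or values.shape[1] < 1:
            raise ValueError("community matrix must be at least 2 sites x 1 taxon")
        if not np.isin(values, (0, 1)).all():
            bad = np.argwhere(~np.isin(values, (0, 1)))[0]
            raise ValueError(
                "non-binary community entry at site "
                f"{self.occurrence.index[bad[0]]!r}, taxon {self.occurrence.columns[bad[1]]!r}"
            )
        if self.occurrence.index.duplicated().any():
            dupes = self.occurrence.index[self.occurrence.index.duplicated()].tolist()
            raise ValueError(f"duplicated site ids: {dupes}")

    @property
    def site_id(self) -> list:
        return list(self.occurrence.index)

    @property
    def taxon_id(self) -> list:
        return list(self.occurrence.columns)

    @property
    def values(self) -> np.ndarray:
        return self.occurrence.to_numpy(dtype=float)

    @property
    def n_sites(self) -> int:
        return self.occurrence.shape[0]

    @property
    def n_taxa(self) -> int:
        return self.occurrence.shape[1]

    def degenerate_taxa(self) -> list:
        """Taxa with no variation (all absent or all present)."""
        prevalence = self.occurrence.mean(axis=0)
        mask = (prevalence == 0.0) | (prevalence == 1.0)
        return list(self.occurrence.columns[mask])
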