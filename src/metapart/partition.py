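"""Variation partitioning of community structure into environment and space.

Three community GAMs — environment-only (E), space-only (S), and joint (E+S)
— decompose the adjusted explained variation by the standard identity

    E|S  = adjR2(E+S) - adjR2(S)     (pure environment)
    S|E  = adjR2(E+S) - adjR2(E)     (pure space)
    E&S  = adjR2(E) + adjR2(S) - adjR2(E+S)   (spatially structured environment)
    residual = 1 - adjR2(E+S)

Predictors enter each side through forward selection with a double-stopping
criterion: a candidate is added only while (i) its addition is significant at
``alpha`` and (ii) the cumulative adjusted R-squared stays below that of the
model with the whole candidate set; selection does not start at all unless
the whole-set model is itself significant. If the stepwise pass selects
nothing despite a significant whole-set model, the single most significant
candidate is kept, provided it passes ``alpha``.

Because a spatially autocorrelated environment can explain spatially
autocorrelated communities by chance, the environmental component is also
reported with a Moran-spectral-randomization (MSR) correction: surrogate
environments that preserve each variable's spatial power spectrum (random
sign-flips of its Moran-eigenvector coefficients) provide the null level of
environmental R-squared, and the adjusted environmental contribution becomes

    adjR2_MSR(E) = 1 - (1 - R2(E)) / (1 - mean_r R2(E_r)).

The E+S model is MSR-adjusted the same way (surrogate environment + observed
space), the S-only model keeps its classical adjustment, and corrected
fractions follow the partition identity on the corrected quantities.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .gam import GamFit, SmoothSpec, fit_gam_community, intercept_fit, pooled_f_test

__all__ = [
    "MSRConfig",
    "PartitionResult",
    "forward_select",
    "enforce_variable_cap",
    "partition_variation",
    "msr_correct",
    "relative_proportions",
    "merge_space_specs",
]

SPACE_PREDICTORS = ("lon", "lat")


@dataclass
class MSRConfig:
    """Settings for the spectral-randomization null of the environment."""

    mem_basis: np.ndarray
    n_replicates: int = 199
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_replicates < 19:
            raise ValueError("null too small for correction: need at least 19 replicates")


@dataclass
class PartitionResult:
    """Adjusted-R2 fractions of community variation, raw and MSR-corrected."""

    adj_r2_E: float
    adj_r2_S: float
    adj_r2_ES: float
    frac_pure_env: float
    frac_shared: float
    frac_pure_space: float
    residual: float
    selected_env: list
    selected_space: list
    corrected_adj_r2_E: float | None = None
    corrected_adj_r2_ES: float | None = None
    corrected_frac_pure_env: float | None = None
    corrected_frac_shared: float | None = None
    corrected_frac_pure_space: float | None = None
    rel_pure_env: float = np.nan
    rel_shared: float = np.nan
    rel_pure_space: float = np.nan
    rel_defined: bool = False
    msr_replicates: int = 0
    seed: int | None = None
    note: str = ""

    def fractions(self, corrected: bool | None = None) -> tuple[float, float, float]:
        """(pure env, shared, pure space), corrected if available by default."""
        use_corr = self.corrected_frac_pure_env is not None if corrected is None else corrected
        if use_corr:
            if self.corrected_frac_pure_env is None:
                raise ValueError("no MSR-corrected fractions on this result")
            return (
                self.corrected_frac_pure_env,
                self.corrected_frac_shared,
                self.corrected_frac_pure_space,
            )
        return (self.frac_pure_env, self.frac_shared, self.frac_pure_space)


def merge_space_specs(specs: list[SmoothSpec]) -> list[SmoothSpec]:
    """Replace separately selected lon and lat smooths with one 2-D surface.

    Longitude and latitude are candidates individually, but when both are
    selected the spatial trend is modeled as a joint smooth surface (tensor
    basis, 16 <= 18 functions) rather than two additive marginal smooths.
    """
    names = [s.predictor for s in specs if not s.is_surface]
    if "lon" in names and "lat" in names:
        out = [s for s in specs if s.predictor not in SPACE_PREDICTORS]
        out.append(SmoothSpec(("lon", "lat"), basis_size=9))
        return out
    return list(specs)


def _model_specs(selected: list[SmoothSpec]) -> list[SmoothSpec]:
    return merge_space_specs(selected)


def forward_select(
    P: np.ndarray,
    candidates: list[SmoothSpec],
    data: pd.DataFrame,
    alpha: float = 0.05,
    global_gate: bool = True,
    fallback: bool = True,
    max_vars: int = 3,
) -> list[SmoothSpec]:
    """Forward selection with the double-stopping criterion.

    Returns the selected candidates (original univariate specs; lon+lat
    merging into a surface happens at fit time). An empty list means the
    candidate set explains nothing beyond chance.
    """
    if not candidates:
        return []
    null_fit = intercept_fit(P)
    global_fit = fit_gam_community(P, _model_specs(candidates), data)
    _, p_global = pooled_f_test(null_fit, global_fit)
    if global_gate and not (p_global < alpha):
        return []

    selected: list[SmoothSpec] = []
    current = null_fit
    remaining = list(candidates)
    while remaining:
        if sum(s.n_variables for s in selected) >= max_vars:
            break
        trials = []
        for cand in remaining:
            try:
                fit = fit_gam_community(P, _model_specs(selected + [cand]), data)
            except ValueError:
                continue
            _, p_add = pooled_f_test(current, fit)
            trials.append((cand, fit, p_add))
        qualified = [t for t in trials if t[2] < alpha]
        if not qualified:
            break
        cand, fit, _ = max(qualified, key=lambda t: t[1].adj_r2)
        if fit.adj_r2 > global_fit.adj_r2 + 1e-10:
            break  # second stopping rule: global-model adjusted R2 is the cap
        selected.append(cand)
        current = fit
        remaining.remove(cand)

    if not selected and fallback:
        best = None
        for cand in candidates:
            fit = fit_gam_community(P, [cand], data)
            _, p_single = pooled_f_test(null_fit, fit)
            if best is None or p_single < best[1]:
                best = (cand, p_single)
        if best is not None and best[1] < alpha:
            selected = [best[0]]
    return selected


def enforce_variable_cap(
    P: np.ndarray,
    data: pd.DataFrame,
    env_sel: list[SmoothSpec],
    space_sel: list[SmoothSpec],
    max_vars: int = 3,
) -> tuple[list[SmoothSpec], list[SmoothSpec]]:
    """Drop lowest-contribution selected variables until at most ``max_vars``
    remain across both sets combined (a lon x lat surface counts as two)."""
    env_sel, space_sel = list(env_sel), list(space_sel)

    def total() -> int:
        return sum(s.n_variables for s in _model_specs(env_sel + space_sel))

    while total() > max_vars and (env_sel or space_sel):
        # drop the weakest contributor, ranked by single-variable adjusted R2
        # (the over-limit joint model cannot be fitted within the basis budget)
        singles = []
        for pool, spec in [("env", s) for s in env_sel] + [("space", s) for s in space_sel]:
            adj_single = fit_gam_community(P, [spec], data).adj_r2
            singles.append((adj_single, pool, spec))
        _, pool, spec = min(singles, key=lambda t: t[0])
        (env_sel if pool == "env" else space_sel).remove(spec)
    return env_sel, space_sel


def partition_variation(
    P: np.ndarray,
    env_sel: list[SmoothSpec],
    space_sel: list[SmoothSpec],
    data: pd.DataFrame,
    msr: MSRConfig | None = None,
) -> PartitionResult:
    """Decompose adjusted explained variation into E|S, E&S, S|E, residual.

    An empty side contributes adjusted R2 = 0, so the whole explained
    fraction loads on the other pure component. With ``msr`` given and a
    non-empty environmental side, MSR-corrected fractions are filled in and
    the relative proportions are computed from them; otherwise from the raw
    fractions.
    """
    if not env_sel and not space_sel:
        return PartitionResult(
            adj_r2_E=0.0, adj_r2_S=0.0, adj_r2_ES=0.0,
            frac_pure_env=0.0, frac_shared=0.0, frac_pure_space=0.0,
            residual=1.0, selected_env=[], selected_space=[],
            note="no predictors selected",
        )
    fit_E = fit_gam_community(P, env_sel, data) if env_sel else None
    space_specs = _model_specs(space_sel)
    fit_S = fit_gam_community(P, space_specs, data) if space_sel else None
    if env_sel and space_sel:
        fit_ES = fit_gam_community(P, env_sel + space_specs, data)
    else:
        fit_ES = fit_E if env_sel else fit_S

    adj_E = fit_E.adj_r2 if fit_E else 0.0
    adj_S = fit_S.adj_r2 if fit_S else 0.0
    adj_ES = fit_ES.adj_r2
    result = PartitionResult(
        adj_r2_E=adj_E,
        adj_r2_S=adj_S,
        adj_r2_ES=adj_ES,
        frac_pure_env=adj_ES - adj_S,
        frac_shared=adj_E + adj_S - adj_ES,
        frac_pure_space=adj_ES - adj_E,
        residual=1.0 - adj_ES,
        selected_env=[s.label for s in env_sel],
        selected_space=[s.label for s in space_specs],
    )
    if msr is not None and env_sel:
        msr_correct(P, env_sel, space_sel, data, msr, result=result,
                    fit_E=fit_E, fit_S=fit_S, fit_ES=fit_ES)
    pure_env, shared, pure_space = result.fractions()
    rel, defined = relative_proportions(pure_env, shared, pure_space)
    result.rel_pure_env, result.rel_shared, result.rel_pure_space = rel
    result.rel_defined = defined
    return result


def msr_correct(
    P: np.ndarray,
    env_sel: list[SmoothSpec],
    space_sel: list[SmoothSpec],
    data: pd.DataFrame,
    msr: MSRConfig,
    result: PartitionResult | None = None,
    fit_E: GamFit | None = None,
    fit_S: GamFit | None = None,
    fit_ES: GamFit | None = None,
) -> PartitionResult:
    """Moran-spectral-randomization correction of the environmental component.

    Each selected environmental column is decomposed on the complete MEM
    basis and rebuilt with independently randomized coefficient signs, which
    preserves its spatial power spectrum (and hence its Moran's I) exactly.
    Per replicate, the E-only and E+S community R2 are recomputed with the
    surrogate environment (including GCV smoothness selection, so the null
    statistic matches the observed one); the means of these null R2 replace
    the Ezekiel parameter-count penalty in the adjustment of the observed R2.
    """
    if not env_sel:
        raise ValueError("MSR correction needs a non-empty environmental selection")
    basis = np.asarray(msr.mem_basis, dtype=float)
    n = P.shape[0]
    if basis.shape[0] != n:
        raise ValueError("MEM basis does not match the number of sites")
    if fit_E is None:
        fit_E = fit_gam_community(P, env_sel, data)
    space_specs = _model_specs(space_sel)
    if space_sel and fit_S is None:
        fit_S = fit_gam_community(P, space_specs, data)
    if fit_ES is None:
        fit_ES = (
            fit_gam_community(P, env_sel + space_specs, data) if space_sel else fit_E
        )

    env_cols = [s.predictor for s in env_sel]
    Z = data[env_cols].to_numpy(dtype=float)
    Z_centered = Z - Z.mean(axis=0, keepdims=True)
    coeffs = basis.T @ Z_centered  # (n-1) x k, exact: basis spans the centered space

    rng = np.random.default_rng(msr.seed)
    r2_E_null = np.empty(msr.n_replicates)
    r2_ES_null = np.empty(msr.n_replicates) if space_sel else None
    data_r = data.copy()
    for r in range(msr.n_replicates):
        # one sign per eigenvector, shared across variables: preserves every
        # variable's power spectrum AND the exact cross-product structure of
        # the predictor block (independent per-variable flips would decorrelate
        # an orthogonal PC block and understate the null R2)
        signs = rng.choice((-1.0, 1.0), size=(coeffs.shape[0], 1))
        Z_r = basis @ (coeffs * signs) + Z.mean(axis=0, keepdims=True)
        data_r[env_cols] = Z_r
        # the null statistic must include GCV smoothness selection: freezing
        # the smoothing parameter at the observed fit's value understates the
        # null R2 (the observed flexibility is tuned to the observed data)
        fit_E_r = fit_gam_community(P, env_sel, data_r)
        r2_E_null[r] = fit_E_r.pooled_r2
        if space_sel:
            fit_ES_r = fit_gam_community(P, env_sel + space_specs, data_r)
            r2_ES_null[r] = fit_ES_r.pooled_r2

    adj_E_msr = _msr_adjust(fit_E.pooled_r2, r2_E_null.mean())
    adj_S = fit_S.adj_r2 if fit_S else 0.0
    if space_sel:
        adj_ES_msr = _msr_adjust(fit_ES.pooled_r2, r2_ES_null.mean())
    else:
        adj_ES_msr = adj_E_msr

    if result is None:
        result = partition_variation(P, env_sel, space_sel, data, msr=None)
    result.corrected_adj_r2_E = adj_E_msr
    result.corrected_adj_r2_ES = adj_ES_msr
    result.corrected_frac_pure_env = adj_ES_msr - adj_S
    result.corrected_frac_shared = adj_E_msr + adj_S - adj_ES_msr
    result.corrected_frac_pure_space = adj_ES_msr - adj_E_msr
    result.msr_replicates = msr.n_replicates
    result.seed = msr.seed
    return result


def _msr_adjust(r2_obs: float, r2_null_mean: float) -> float:
    denom = 1.0 - r2_null_mean
    if denom <= 0.0:
        return 0.0
    return float(1.0 - (1.0 - r2_obs) / denom)


def relative_proportions(
    pure_env: float, shared: float, pure_space: float
) -> tuple[tuple[float, float, float], bool]:
    """Fractions as shares of the total explained variation E + S.

    Negative fractions are floored at zero; the survivors are divided by
    their sum. If everything floors to zero the proportions are undefined and
    the flag is False.
    """
    floored = np.maximum([pure_env, shared, pure_space], 0.0)
    total = floored.sum()
    if total <= 0.0:
        return (np.nan, np.nan, np.nan), False
    rel = floored / total
    return (float(rel[0]), float(rel[1]), float(rel[2])), True
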