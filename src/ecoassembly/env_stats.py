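"""Environment/space/turnover statistics: Mantel-family tests, PCNM,
factor selection (VIF + permutation vector fitting), variation
partitioning, and zonal environmental heterogeneity.

Conventions: Mantel tests are one-sided (greater), permutation p-values
use the (1 + count)/(1 + n_perm) estimator and are therefore never exactly
zero, and all randomized routines are reproducible for a fixed seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.sparse.csgraph import minimum_spanning_tree
from scipy.spatial.distance import pdist

from ecoassembly.core_data import (
    CommunityTable,
    PairwiseMatrix,
    SampleMetadata,
    ValidationError,
)

log = logging.getLogger("ecoassembly")


# ---------------------------------------------------------------------------
# transforms and environmental distances
# ---------------------------------------------------------------------------


def log1p_env(meta: SampleMetadata, variables: list[str]) -> SampleMetadata:
    """ln(x + 1)-transform the listed environmental variables.

    Negative values are rejected (the transform is meant for concentrations
    and other non-negative quantities).
    """
    df = meta.df.copy()
    for v in variables:
        if v not in df.columns:
            raise ValidationError(f"unknown variable {v!r}")
        col = df[v].astype(float)
        neg = col < 0
        if neg.any():
            sample = df.index[neg][0]
            raise ValidationError(
                f"negative value for {v!r} at sample {sample!r}; "
                "log1p requires non-negative input"
            )
        df[v] = np.log1p(col)
    return SampleMetadata(df)


def env_distance(
    meta: SampleMetadata,
    variables: list[str],
    normalize: bool = False,
) -> PairwiseMatrix:
    """Euclidean distance between samples over environmental variables.

    With ``normalize``, each variable is first rescaled to [0, 1] by
    (x - min)/(max - min); constant variables are dropped with a warning.
    The single-variable case reduces to |x_a - x_b|.
    """
    E = meta.env_matrix(variables)
    X = E.to_numpy(dtype=float)
    cols = list(E.columns)
    if normalize:
        rng_ = X.max(axis=0) - X.min(axis=0)
        keep = rng_ > 0
        if (~keep).any():
            dropped = [c for c, k in zip(cols, keep) if not k]
            log.warning("env_distance: dropping constant variables %s", dropped)
        if not keep.any():
            raise ValidationError("all variables constant after normalization")
        X = (X[:, keep] - X[:, keep].min(axis=0)) / rng_[keep]
    d = pdist(X, metric="euclidean")
    from ecoassembly.core_data import pairwise_from_condensed

    return pairwise_from_condensed([str(s) for s in E.index], d, name="env_distance")


def zonal_heterogeneity(
    meta: SampleMetadata,
    variables: list[str],
    group_col: str = "zone",
    normalize: bool = True,
) -> pd.DataFrame:
    """Within-group pairwise environmental-distance distribution.

    Normalization (max-min over *all* samples) happens before grouping so
    groups share a scale. Returns a long DataFrame (group, sample_a,
    sample_b, distance).
    """
    dm = env_distance(meta, variables, normalize=normalize)
    groups = meta.df.loc[dm.sample_ids, group_col]
    rows = []
    for g in groups.unique():
        ids = [s for s in dm.sample_ids if groups[s] == g]
        if len(ids) < 2:
            continue
        sub = dm.submatrix(ids)
        for (a, b), v in zip(sub.pair_index(), sub.condensed()):
            rows.append((g, a, b, float(v)))
    return pd.DataFrame(rows, columns=["group", "sample_a", "sample_b", "distance"])


# ---------------------------------------------------------------------------
# Mantel family
# ---------------------------------------------------------------------------


@dataclass
class MantelResult:
    r: float
    p: float
    n_perm: int
    adjusted: bool = False  # True for partial Mantel


def _condensed_checked(m: PairwiseMatrix) -> np.ndarray:
    v = m.condensed()
    if np.isnan(v).any():
        raise ValidationError("Mantel input matrix contains NaN pairs")
    if v.std() == 0:
        raise ValidationError("Mantel input matrix has zero variance")
    return v


def mantel(
    dA: PairwiseMatrix,
    dB: PairwiseMatrix,
    n_perm: int = 999,
    seed: int = 0,
) -> MantelResult:
    """Mantel test: Pearson r over unfolded upper triangles.

    One-sided (greater) permutation test with simultaneous row/column
    permutation of dB; p = (1 + #{r_perm >= r_obs}) / (1 + n_perm).
    """
    if dA.sample_ids != dB.sample_ids:
        raise ValidationError("Mantel matrices cover different samples")
    a = _condensed_checked(dA)
    b = _condensed_checked(dB)
    r_obs = float(stats.pearsonr(a, b)[0])
    n = dA.n
    iu = np.triu_indices(n, k=1)
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        bp = dB.values[np.ix_(perm, perm)][iu]
        if stats.pearsonr(a, bp)[0] >= r_obs - 1e-12:
            count += 1
    return MantelResult(r=r_obs, p=(1 + count) / (1 + n_perm), n_perm=n_perm)


def _partial_r(rab: float, rac: float, rbc: float) -> float:
    denom = np.sqrt(max((1 - rac**2) * (1 - rbc**2), 0.0))
    num = rab - rac * rbc
    if denom < 1e-12:
        if abs(num) < 1e-10:
            # controlling a matrix for itself: 0/0 limit is 0
            return 0.0
        raise ValidationError("partial Mantel undefined: |r| with control = 1")
    return num / denom


def partial_mantel(
    dA: PairwiseMatrix,
    dB: PairwiseMatrix,
    dC: PairwiseMatrix,
    n_perm: int = 999,
    seed: int = 0,
) -> MantelResult:
    """Partial Mantel: correlation of dA and dB controlling for dC.

    r_AB.C from the three triangle correlations; significance by jointly
    permuting rows/columns of dA (one-sided greater).
    """
    for m in (dB, dC):
        if m.sample_ids != dA.sample_ids:
            raise ValidationError("partial Mantel matrices cover different samples")
    a = _condensed_checked(dA)
    b = _condensed_checked(dB)
    c = _condensed_checked(dC)
    rab = stats.pearsonr(a, b)[0]
    rac = stats.pearsonr(a, c)[0]
    rbc = stats.pearsonr(b, c)[0]
    r_obs = float(_partial_r(rab, rac, rbc))
    n = dA.n
    iu = np.triu_indices(n, k=1)
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        ap = dA.values[np.ix_(perm, perm)][iu]
        r_p = _partial_r(
            stats.pearsonr(ap, b)[0], stats.pearsonr(ap, c)[0], rbc
        )
        if r_p >= r_obs - 1e-12:
            count += 1
    return MantelResult(
        r=r_obs, p=(1 + count) / (1 + n_perm), n_perm=n_perm, adjusted=True
    )


def bnti_env_correlation(
    bnti: PairwiseMatrix,
    meta: SampleMetadata,
    variables: list[str],
    n_perm: int = 999,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-variable Mantel and partial Mantel of betaNTI vs |delta variable|.

    For each variable: plain Mantel of the betaNTI matrix against the
    between-sample absolute difference, and partial Mantel controlling the
    Euclidean distance over all remaining (standardized) variables.
    Constant variables are skipped with a warning.
    """
    E = meta.env_matrix(variables)
    samples = [s for s in bnti.sample_ids if s in E.index]
    if len(samples) < 4:
        raise ValidationError("bnti_env_correlation needs >= 4 samples")
    sub_bnti = bnti.submatrix(samples)
    E = E.loc[samples]
    usable = [v for v in variables if E[v].std() > 0]
    skipped = sorted(set(variables) - set(usable))
    if skipped:
        log.warning("bnti_env_correlation: skipping constant variables %s", skipped)
    Z = (E[usable] - E[usable].mean()) / E[usable].std()
    rows = []
    from ecoassembly.core_data import pairwise_from_condensed

    for k, v in enumerate(usable):
        dv = pairwise_from_condensed(
            samples, pdist(E[[v]].to_numpy(dtype=float)), name=v
        )
        plain = mantel(sub_bnti, dv, n_perm=n_perm, seed=seed + k)
        others = [u for u in usable if u != v]
        if others:
            dC = pairwise_from_condensed(
                samples, pdist(Z[others].to_numpy(dtype=float)), name="others"
            )
            part = partial_mantel(sub_bnti, dv, dC, n_perm=n_perm, seed=seed + k)
            adj_r, adj_p = part.r, part.p
        else:
            adj_r, adj_p = np.nan, np.nan
        rows.append((v, plain.r, plain.p, adj_r, adj_p))
    return pd.DataFrame(
        rows, columns=["variable", "mantel_r", "mantel_p", "adj_r", "adj_p"]
    )


# ---------------------------------------------------------------------------
# PCNM
# ---------------------------------------------------------------------------


def pcnm(
    geo: PairwiseMatrix, truncation: float | None = None
) -> tuple[np.ndarray, pd.DataFrame]:
    """Principal coordinates of neighbour matrices (spatial eigenvectors).

    Distances above the truncation threshold (default: the longest edge of
    the minimum spanning tree) are replaced by 4x the threshold; the
    truncated matrix is Gower-centered and eigen-decomposed. Returns the
    positive eigenvalues (descending) and the matching eigenvectors as a
    samples-by-PCNM DataFrame.
    """
    n = geo.n
    if n < 3:
        raise ValidationError("pcnm needs at least 3 samples")
    D = geo.values.copy()
    if truncation is None:
        mst = minimum_spanning_tree(D).toarray()
        truncation = float(mst[mst > 0].max())
    if truncation <= 0:
        raise ValidationError("pcnm truncation threshold must be positive")
    Dt = np.where(D <= truncation, D, 4.0 * truncation)
    np.fill_diagonal(Dt, 0.0)
    A = -0.5 * Dt**2
    J = np.eye(n) - np.ones((n, n)) / n
    B = J @ A @ J
    vals, vecs = np.linalg.eigh((B + B.T) / 2.0)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    tol = max(1e-10, abs(vals).max() * 1e-10)
    keep = vals > tol
    vals = vals[keep]
    vecs = vecs[:, keep]
    cols = [f"PCNM{i + 1}" for i in range(vals.size)]
    return vals, pd.DataFrame(vecs, index=pd.Index(geo.sample_ids, name="sample_id"),
                              columns=cols)


# ---------------------------------------------------------------------------
# factor selection: VIF + permutation vector fitting
# ---------------------------------------------------------------------------


def variance_inflation(X: pd.DataFrame) -> pd.Series:
    """VIF per column: 1/(1 - R^2) regressing each factor on the others."""
    out = {}
    arr = X.to_numpy(dtype=float)
    n, k = arr.shape
    for j, name in enumerate(X.columns):
        if k == 1:
            out[name] = 1.0
            continue
        y = arr[:, j]
        others = np.column_stack([np.ones(n), np.delete(arr, j, axis=1)])
        beta, *_ = np.linalg.lstsq(others, y, rcond=None)
        resid = y - others @ beta
        ss_tot = ((y - y.mean()) ** 2).sum()
        r2 = 1.0 - resid @ resid / ss_tot if ss_tot > 0 else 0.0
        out[name] = np.inf if r2 >= 1.0 - 1e-12 else 1.0 / (1.0 - r2)
    return pd.Series(out, name="vif")


def _pcoa_axes(dist: PairwiseMatrix, n_axes: int = 2) -> np.ndarray:
    D = dist.values
    n = D.shape[0]
    A = -0.5 * D**2
    J = np.eye(n) - np.ones((n, n)) / n
    B = J @ A @ J
    vals, vecs = np.linalg.eigh((B + B.T) / 2.0)
    order = np.argsort(vals)[::-1][:n_axes]
    return vecs[:, order] * np.sqrt(np.maximum(vals[order], 0.0))


def _vector_fit_r2(scores: np.ndarray, x: np.ndarray) -> float:
    X = np.column_stack([np.ones(scores.shape[0]), scores])
    beta, *_ = np.linalg.lstsq(X, x, rcond=None)
    resid = x - X @ beta
    ss_tot = ((x - x.mean()) ** 2).sum()
    return 1.0 - resid @ resid / ss_tot if ss_tot > 0 else 0.0


def select_factors(
    table: CommunityTable,
    meta: SampleMetadata,
    factors: list[str],
    vif_threshold: float = 10.0,
    n_perm: int = 999,
    alpha: float = 0.05,
    seed: int = 0,
) -> list[str]:
    """Collinearity and significance screening of candidate factors.

    Step 1 iteratively drops the worst-VIF factor until all VIF <
    ``vif_threshold``. Step 2 keeps factors whose vector fit onto the
    first two principal-coordinate axes of the Bray-Curtis matrix is
    significant by permutation of the factor values (a deterministic
    substitute for NMDS-based vector fitting).
    """
    if len(factors) < 2:
        raise ValidationError("select_factors needs at least 2 candidate factors")
    E = meta.env_matrix(factors)
    samples = [s for s in table.sample_ids if s in E.index]
    E = E.loc[samples]
    sub = table.select_samples(samples)
    X = E.copy()
    while X.shape[1] > 1:
        vif = variance_inflation(X)
        if vif.max() < vif_threshold:
            break
        worst = vif.idxmax()
        log.warning("select_factors: dropping %s (VIF=%.3g)", worst, vif[worst])
        X = X.drop(columns=[worst])
    if X.shape[1] == 0:
        raise ValidationError("all factors dropped by VIF screening")

    from ecoassembly.diversity import bray_curtis

    scores = _pcoa_axes(bray_curtis(sub), n_axes=2)
    rng = np.random.default_rng(seed)
    retained = []
    for name in X.columns:
        x = X[name].to_numpy(dtype=float)
        r2_obs = _vector_fit_r2(scores, x)
        count = 0
        for _ in range(n_perm):
            if _vector_fit_r2(scores, rng.permutation(x)) >= r2_obs - 1e-12:
                count += 1
        p = (1 + count) / (1 + n_perm)
        if p < alpha:
            retained.append(name)
    if not retained:
        log.warning("select_factors: no factor significant at alpha=%.3g", alpha)
    return retained


# ---------------------------------------------------------------------------
# variation partitioning (RDA on Hellinger-transformed counts)
# ---------------------------------------------------------------------------


@dataclass
class VPAResult:
    pure_x1: float
    pure_x2: float
    shared: float
    residual: float
    adj_r2_x1: float
    adj_r2_x2: float
    adj_r2_both: float

    @property
    def fractions(self) -> dict[str, float]:
        return {
            "pure_X1": self.pure_x1,
            "pure_X2": self.pure_x2,
            "shared": self.shared,
            "residual": self.residual,
        }


def hellinger(counts: np.ndarray) -> np.ndarray:
    """Hellinger transform: sqrt of within-sample relative abundances."""
    totals = counts.sum(axis=0, keepdims=True)
    if (totals == 0).any():
        raise ValidationError("Hellinger transform: empty sample")
    return np.sqrt(counts / totals)


def _rda_r2(Y: np.ndarray, X: np.ndarray) -> float:
    """Fraction of total variance of (centered) Y explained by X."""
    n = Y.shape[0]
    Yc = Y - Y.mean(axis=0)
    Xd = np.column_stack([np.ones(n), X])
    beta, *_ = np.linalg.lstsq(Xd, Yc, rcond=None)
    fitted = Xd @ beta
    ss_tot = (Yc**2).sum()
    if ss_tot == 0:
        raise ValidationError("community matrix has zero variance")
    return float((fitted**2).sum() / ss_tot)


def _adjust_r2(r2: float, n: int, k: int) -> float:
    """Ezekiel adjustment."""
    if n - k - 1 <= 0:
        raise ValidationError("too many predictors for adjusted R^2")
    return 1.0 - (1.0 - r2) * (n - 1) / (n - k - 1)


def vpa(
    table: CommunityTable,
    meta: SampleMetadata,
    x1: list[str],
    x2: list[str],
    use_hellinger: bool = True,
) -> VPAResult:
    """Variation partitioning of community composition between two factor sets.

    Redundancy analysis on Hellinger-transformed counts (raw proportions
    behind ``use_hellinger=False``). Components use Ezekiel-adjusted R^2:
    pure_X1 = adjR2(X1 u X2) - adjR2(X2) (and symmetrically), shared =
    adjR2(X1) + adjR2(X2) - adjR2(X1 u X2), residual = 1 - adjR2(X1 u X2).
    The shared fraction may be negative and is reported as computed.
    """
    all_vars = list(dict.fromkeys(list(x1) + list(x2)))
    E = meta.env_matrix(all_vars)
    samples = [s for s in table.sample_ids if s in E.index]
    sub = table.select_samples(samples)
    E = E.loc[samples]
    n = len(samples)
    k_both = len(all_vars)
    if n <= k_both + 1:
        raise ValidationError(
            f"vpa needs more samples ({n}) than predictors ({k_both}) + 1"
        )
    rel = sub.counts / sub.counts.sum(axis=0, keepdims=True)
    Y = hellinger(sub.counts).T if use_hellinger else rel.T
    Z = ((E - E.mean()) / E.std(ddof=0).replace(0.0, 1.0)).to_numpy(dtype=float)
    cols = {v: i for i, v in enumerate(all_vars)}

    def adj(names: list[str]) -> float:
        X = Z[:, [cols[v] for v in names]]
        return _adjust_r2(_rda_r2(Y, X), n, len(names))

    a1 = adj(list(x1))
    a2 = adj(list(x2))
    a12 = adj(all_vars)
    return VPAResult(
        pure_x1=a12 - a2,
        pure_x2=a12 - a1,
        shared=a1 + a2 - a12,
        residual=1.0 - a12,
        adj_r2_x1=a1,
        adj_r2_x2=a2,
        adj_r2_both=a12,
    )
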