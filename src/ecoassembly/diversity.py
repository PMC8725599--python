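"""Rarefaction, alpha/beta diversity, ANOSIM, distance decay, zone assignment."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import pdist, squareform

from ecoassembly.core_data import (
    CommunityTable,
    PairwiseMatrix,
    SampleMetadata,
    ValidationError,
    pairwise_from_condensed,
)

EARTH_RADIUS_KM = 6371.0088


def rarefy(table: CommunityTable, depth: int | None = None, seed: int = 0) -> CommunityTable:
    """Subsample each sample without replacement to a common depth.

    ``depth`` defaults to the minimum sample total. Each rarefied column is
    a multivariate-hypergeometric draw from the sample's counts and sums
    exactly to ``depth``. Reproducible for a fixed ``seed``.
    """
    totals = table.sample_totals
    if depth is None:
        depth = int(totals.min())
    depth = int(depth)
    if depth <= 0:
        raise ValidationError("rarefaction depth must be positive")
    short = np.flatnonzero(totals < depth)
    if short.size:
        raise ValidationError(
            f"sample {table.sample_ids[short[0]]!r} has total "
            f"{int(totals[short[0]])} < depth {depth}"
        )
    rng = np.random.default_rng(seed)
    out = np.empty_like(table.counts)
    for j in range(table.n_samples):
        out[:, j] = rng.multivariate_hypergeometric(table.counts[:, j], depth)
    return CommunityTable(list(table.taxon_ids), list(table.sample_ids), out)


def alpha_diversity(table: CommunityTable) -> pd.DataFrame:
    """Per-sample richness, Chao1, Shannon H (nats) and Gini-Simpson.

    Shannon H = -sum p ln p; Gini-Simpson = 1 - sum p^2;
    Chao1 = S_obs + F1(F1-1)/(2(F2+1)) with F1/F2 the within-sample
    singleton/doubleton counts.
    """
    totals = table.sample_totals
    if (totals == 0).any():
        empty = table.sample_ids[int(np.argmax(totals == 0))]
        raise ValidationError(f"sample {empty!r} is empty")
    rows = []
    for j, sid in enumerate(table.sample_ids):
        x = table.counts[:, j]
        p = x[x > 0] / totals[j]
        richness = int((x > 0).sum())
        f1 = int((x == 1).sum())
        f2 = int((x == 2).sum())
        chao1 = richness + f1 * (f1 - 1) / (2.0 * (f2 + 1))
        shannon = float(-(p * np.log(p)).sum())
        gini = float(1.0 - (p**2).sum())
        rows.append((sid, richness, chao1, shannon, gini))
    return pd.DataFrame(
        rows, columns=["sample_id", "richness", "chao1", "shannon_H", "gini_simpson"]
    ).set_index("sample_id")


def bray_curtis(table: CommunityTable) -> PairwiseMatrix:
    """Bray-Curtis dissimilarity between samples, on counts.

    BC(j,k) = sum|x_ij - x_ik| / sum(x_ij + x_ik). Pairs of two all-zero
    samples are undefined and stored as NaN. Community similarity is
    ``1 - BC``.
    """
    if table.n_samples < 2:
        raise ValidationError("bray_curtis needs at least 2 samples")
    X = table.counts.T.astype(float)
    with np.errstate(invalid="ignore"):
        d = pdist(X, metric="braycurtis")
    return pairwise_from_condensed(table.sample_ids, d, name="bray_curtis")


def anosim(
    dist: PairwiseMatrix,
    groups: "pd.Series | dict | list",
    n_perm: int = 999,
    seed: int = 0,
) -> tuple[float, float]:
    """Analysis of similarities on a distance matrix.

    R = (mean between-group rank - mean within-group rank) / (M/2),
    M = n(n-1)/2. Significance by permutation of group labels, p =
    (1 + #{R_perm >= R_obs}) / (1 + n_perm).
    """
    labels = _resolve_labels(dist.sample_ids, groups)
    uniq, counts = np.unique(labels, return_counts=True)
    if len(uniq) < 2:
        raise ValidationError("anosim needs at least 2 groups")
    if (counts < 2).any():
        small = uniq[counts < 2][0]
        raise ValidationError(f"group {small!r} has fewer than 2 samples")
    d = dist.condensed()
    if np.isnan(d).any():
        raise ValidationError("distance matrix has NaN pairs")
    ranks = stats.rankdata(d)
    n = dist.n
    iu, ju = np.triu_indices(n, k=1)
    m = d.size

    def r_stat(lab: np.ndarray) -> float:
        within = lab[iu] == lab[ju]
        return (ranks[~within].mean() - ranks[within].mean()) / (m / 2.0)

    r_obs = r_stat(labels)
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(labels)
        if r_stat(perm) >= r_obs:
            count += 1
    p = (1 + count) / (1 + n_perm)
    return float(r_obs), float(p)


def _resolve_labels(sample_ids: list[str], groups) -> np.ndarray:
    if isinstance(groups, pd.Series):
        return np.asarray([groups[s] for s in sample_ids])
    if isinstance(groups, dict):
        return np.asarray([groups[s] for s in sample_ids])
    labels = np.asarray(groups)
    if labels.shape[0] != len(sample_ids):
        raise ValidationError("group labels do not match sample count")
    return labels


def geographic_distance(meta: SampleMetadata) -> PairwiseMatrix:
    """Great-circle (haversine) distance in km, Earth radius 6371.0088 km."""
    lat = np.radians(meta.df["latitude"].to_numpy(dtype=float))
    lon = np.radians(meta.df["longitude"].to_numpy(dtype=float))
    dlat = lat[:, None] - lat[None, :]
    dlon = lon[:, None] - lon[None, :]
    a = np.sin(dlat / 2) ** 2 + np.cos(lat[:, None]) * np.cos(lat[None, :]) * np.sin(dlon / 2) ** 2
    d = 2 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(a, 0.0, 1.0)))
    np.fill_diagonal(d, 0.0)
    d = (d + d.T) / 2.0
    return PairwiseMatrix(meta.sample_ids, d, name="geographic_km")


@dataclass
class DDRFit:
    """Distance-decay regression of community similarity on geographic distance."""

    slope: float  # per km
    intercept: float
    r: float
    p_value: float  # matrix-permutation p
    p_parametric: float
    n_pairs: int


def distance_decay(
    similarity: PairwiseMatrix,
    geo: PairwiseMatrix,
    n_perm: int = 999,
    seed: int = 0,
) -> DDRFit:
    """OLS of pairwise similarity on geographic distance.

    Significance is assessed by Mantel-style joint row/column permutation
    of the similarity matrix (pairs are not independent); the parametric
    OLS p-value is reported alongside.
    """
    if similarity.sample_ids != geo.sample_ids:
        raise ValidationError("similarity and geo matrices have different samples")
    x = geo.condensed()
    y = similarity.condensed()
    if x.size < 3:
        raise ValidationError("distance decay needs at least 3 pairs")
    res = stats.linregress(x, y)
    r_obs = res.rvalue
    rng = np.random.default_rng(seed)
    n = similarity.n
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        yp = similarity.values[np.ix_(perm, perm)][np.triu_indices(n, k=1)]
        if abs(stats.pearsonr(x, yp)[0]) >= abs(r_obs):
            count += 1
    p_perm = (1 + count) / (1 + n_perm)
    return DDRFit(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r=float(r_obs),
        p_value=float(p_perm),
        p_parametric=float(res.pvalue),
        n_pairs=int(x.size),
    )


def assign_zone(latitude: float) -> str:
    """Climatic zone from latitude.

    tropic: |lat| <= 23.5; subtropic: 23.5 < |lat| <= 40; subarctic:
    lat > 40. Latitudes below -40 are outside the study design and raise.
    """
    lat = float(latitude)
    if not -90 <= lat <= 90:
        raise ValidationError(f"latitude {lat} outside [-90, 90]")
    if lat < -40:
        raise ValidationError(
            f"latitude {lat} below -40 degrees: southern subarctic is outside "
            "the supported zone scheme"
        )
    a = abs(lat)
    if a <= 23.5:
        return "tropic"
    if a <= 40:
        return "subtropic"
    return "subarctic"
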