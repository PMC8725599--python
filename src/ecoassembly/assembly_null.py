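"""Phylogenetic and taxonomic null models for community-assembly inference.

The inference chain:

1. :func:`phylo_signal` — Mantel correlogram of between-taxon niche
   distance against patristic distance; phylogenetic signal at short
   distances licenses nearest-taxon turnover metrics.
2. :func:`beta_mntd` / :func:`bnti` — abundance-weighted between-sample
   mean nearest-taxon distance and its standardized effect size against a
   tip-shuffling null (999 randomizations). |bNTI| > 2 indicates
   selection; the sign separates heterogeneous (+) from homogeneous (-).
3. :func:`rc_bray` — Raup-Crick standardized Bray-Curtis against a
   probabilistic assembly null (9,999 randomizations), rescaled to
   [-1, 1]; |RC| > 0.95 separates dispersal processes from drift.
4. :func:`partition_processes` — per-pair classification and the five-way
   fraction table.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from ecoassembly.core_data import (
    CommunityTable,
    PairwiseMatrix,
    PhylogeneticTree,
    SampleMetadata,
    ValidationError,
)

log = logging.getLogger("ecoassembly")

BNTI_THRESHOLD = 2.0
RC_THRESHOLD = 0.95

PROCESSES = (
    "heterogeneous_selection",
    "homogeneous_selection",
    "dispersal_limitation",
    "homogenizing_dispersal",
    "drift",
)


# ---------------------------------------------------------------------------
# betaMNTD / betaNTI
# ---------------------------------------------------------------------------


def _weights(counts: np.ndarray, abundance_weighted: bool) -> np.ndarray:
    totals = counts.sum(axis=0)
    if (totals == 0).any():
        raise ValidationError("sample with zero total count in betaMNTD input")
    if abundance_weighted:
        return counts / totals
    present = (counts > 0).astype(float)
    return present / present.sum(axis=0)


def _beta_mntd_matrix(D: np.ndarray, F: np.ndarray, present: np.ndarray) -> np.ndarray:
    """All-pairs betaMNTD given patristic matrix D, weight matrix F (taxa x
    samples) and presence mask.

    For each sample k, M[i, k] = min over taxa i' present in k of D[i, i'];
    then bMNTD[j, k] = 0.5 * (sum_i F[i,j] M[i,k] + sum_i F[i,k] M[i,j]).
    A taxon present in both samples matches itself at distance 0 via the
    zero diagonal of D.
    """
    n_taxa, n_samples = F.shape
    M = np.empty((n_taxa, n_samples))
    for k in range(n_samples):
        idx = np.flatnonzero(present[:, k])
        M[:, k] = D[:, idx].min(axis=1)
    half = F.T @ M  # half[j, k] = sum_i F[i,j] * M[i,k]
    out = 0.5 * (half + half.T)
    np.fill_diagonal(out, 0.0)
    return out


def beta_mntd(
    table: CommunityTable,
    tree: PhylogeneticTree,
    abundance_weighted: bool = True,
) -> PairwiseMatrix:
    """Between-sample mean nearest-taxon phylogenetic distance.

    For a pair of samples, each taxon contributes the patristic distance to
    its closest relative in the other sample, weighted by its within-sample
    relative abundance (or equally, if unweighted); the two directed means
    are averaged. Taxa present in both samples are their own nearest
    neighbour (distance 0).
    """
    sub = table.drop_zero_taxa() if (table.taxon_totals == 0).any() else table
    tree.align_taxa(sub.taxon_ids)
    D = tree.patristic(sub.taxon_ids)
    F = _weights(sub.counts, abundance_weighted)
    present = sub.counts > 0
    values = _beta_mntd_matrix(D, F, present)
    return PairwiseMatrix(sub.sample_ids, values, name="beta_mntd")


@dataclass
class BetaMNTDResult:
    """Observed betaMNTD, its null distribution summary, and betaNTI."""

    observed: PairwiseMatrix
    null_mean: PairwiseMatrix
    null_sd: PairwiseMatrix
    bnti: PairwiseMatrix
    n_null: int
    seed: int
    n_degenerate: int = 0


def bnti(
    table: CommunityTable,
    tree: PhylogeneticTree,
    n_null: int = 999,
    seed: int = 0,
    abundance_weighted: bool = True,
    shuffle_within_pool: bool = True,
) -> BetaMNTDResult:
    """betaNTI: standardized effect size of betaMNTD against a tip-shuffle null.

    The null shuffles taxon identities across the tree tips restricted to
    the taxa of the analysis pool (equivalent to jointly permuting the rows
    and columns of the pooled patristic matrix), holding the community
    matrix fixed; betaMNTD is recomputed for each of ``n_null``
    randomizations. bNTI = (observed - null mean) / null sd per pair.
    With ``shuffle_within_pool=False`` the pool's taxa are instead mapped
    to random distinct tips drawn from the *full* tree (sensitivity
    variant).

    Pairs with null sd = 0 are flagged degenerate (NaN) and counted.
    """
    if table.n_samples < 2:
        raise ValidationError("bnti needs at least 2 samples in the pool")
    sub = table.drop_zero_taxa() if (table.taxon_totals == 0).any() else table
    tree.align_taxa(sub.taxon_ids)
    D = tree.patristic(sub.taxon_ids)
    F = _weights(sub.counts, abundance_weighted)
    present = sub.counts > 0
    obs = _beta_mntd_matrix(D, F, present)

    n = sub.n_samples
    iu = np.triu_indices(n, k=1)
    nulls = np.empty((n_null, iu[0].size))
    rng = np.random.default_rng(seed)
    n_taxa = sub.n_taxa
    if shuffle_within_pool:
        D_source, n_source = D, n_taxa
    else:
        D_source = tree.patristic(tree.tip_names)
        n_source = len(tree.tip_names)
    for r in range(n_null):
        if shuffle_within_pool:
            perm = rng.permutation(n_taxa)
        else:
            perm = rng.choice(n_source, size=n_taxa, replace=False)
        Dp = D_source[np.ix_(perm, perm)]
        nulls[r] = _beta_mntd_matrix(Dp, F, present)[iu]

    mean_c = nulls.mean(axis=0)
    sd_c = nulls.std(axis=0, ddof=1)
    obs_c = obs[iu]
    with np.errstate(invalid="ignore", divide="ignore"):
        bnti_c = np.where(sd_c > 0, (obs_c - mean_c) / sd_c, np.nan)
    n_degenerate = int((sd_c == 0).sum())
    if n_degenerate:
        log.warning("bnti: %d degenerate pairs (null sd = 0) flagged", n_degenerate)

    from ecoassembly.core_data import pairwise_from_condensed

    ids = sub.sample_ids
    return BetaMNTDResult(
        observed=PairwiseMatrix(ids, obs, name="beta_mntd"),
        null_mean=pairwise_from_condensed(ids, mean_c, "null_mean", diagonal=np.nan),
        null_sd=pairwise_from_condensed(ids, sd_c, "null_sd", diagonal=np.nan),
        bnti=pairwise_from_condensed(ids, bnti_c, "bnti", diagonal=np.nan),
        n_null=n_null,
        seed=seed,
        n_degenerate=n_degenerate,
    )


# ---------------------------------------------------------------------------
# Raup-Crick (Bray-Curtis)
# ---------------------------------------------------------------------------


@dataclass
class RCBrayResult:
    rc: PairwiseMatrix  # in [-1, 1]
    n_null: int
    seed: int


def _null_community_counts(
    rng: np.random.Generator,
    n_reps: int,
    occ_w: np.ndarray,
    abund_p: np.ndarray,
    richness: int,
    total: int,
) -> np.ndarray:
    """Assemble ``n_reps`` null communities for one sample.

    Taxa are drawn without replacement with probability proportional to
    pool occupancy (Gumbel top-k trick), then ``total`` individuals are
    distributed among the drawn taxa with probability proportional to
    pool-wide relative abundance (sequential conditional binomials).
    Returns an (n_reps, n_taxa) integer matrix with rows summing to
    ``total``.
    """
    S = occ_w.size
    keys = np.log(occ_w)[None, :] + rng.gumbel(size=(n_reps, S))
    sel = np.argpartition(-keys, richness - 1, axis=1)[:, :richness]
    P = np.zeros((n_reps, S))
    rows = np.arange(n_reps)[:, None]
    P[rows, sel] = abund_p[sel]
    P /= P.sum(axis=1, keepdims=True)
    # suffix sums for the conditional-binomial chain
    T = np.flip(np.cumsum(np.flip(P, axis=1), axis=1), axis=1)
    counts = np.zeros((n_reps, S), dtype=np.int64)
    n_rem = np.full(n_reps, total, dtype=np.int64)
    for s in range(S):
        ps = P[:, s]
        ts = T[:, s]
        active = (ps > 0) & (n_rem > 0)
        if not active.any():
            continue
        ratio = np.zeros(n_reps)
        # last remaining mass for a row -> take everything left
        last = active & (ts <= ps * (1 + 1e-12))
        ratio[active] = np.clip(ps[active] / ts[active], 0.0, 1.0)
        ratio[last] = 1.0
        draw = rng.binomial(n_rem, ratio)
        draw[~active] = 0
        counts[:, s] = draw
        n_rem -= draw
    if (n_rem > 0).any():
        # numerical leftovers land on each row's last selected taxon
        for r in np.flatnonzero(n_rem > 0):
            counts[r, sel[r].max()] += n_rem[r]
    return counts


def rc_bray(
    table: CommunityTable,
    n_null: int = 9999,
    seed: int = 0,
) -> RCBrayResult:
    """Raup-Crick metric on Bray-Curtis against a probabilistic assembly null.

    For each sample pair, null communities preserve each sample's observed
    richness and total count; taxa enter with probability proportional to
    their occupancy across the pool, and individuals are allocated
    proportionally to pool-wide relative abundance. With ties at half
    weight,

        RC_raw = (#{null BC < obs BC} + 0.5 #{null BC = obs BC}) / n_null
        RC     = 2 (RC_raw - 0.5)  in [-1, 1].

    Values above 0.95 indicate dispersal limitation, below -0.95
    homogenizing dispersal. Random streams are derived per pair from
    (seed, i, j), so results do not depend on evaluation order.
    """
    sub = table.drop_zero_taxa() if (table.taxon_totals == 0).any() else table
    if sub.n_taxa < 2:
        raise ValidationError("rc_bray pool needs at least 2 taxa")
    if sub.n_samples < 2:
        raise ValidationError("rc_bray needs at least 2 samples")
    counts = sub.counts
    occ_w = (counts > 0).sum(axis=1).astype(float)
    abund_p = counts.sum(axis=1).astype(float)
    abund_p /= abund_p.sum()
    richness = (counts > 0).sum(axis=0)
    totals = counts.sum(axis=0)
    if (totals == 0).any():
        raise ValidationError("rc_bray: sample with zero total count")

    n = sub.n_samples
    rc = np.full((n, n), np.nan)
    for i in range(n):
        for j in range(i + 1, n):
            xi = counts[:, i].astype(float)
            xj = counts[:, j].astype(float)
            obs = np.abs(xi - xj).sum() / (xi + xj).sum()
            rng = np.random.default_rng(np.random.SeedSequence([seed, i, j]))
            A = _null_community_counts(
                rng, n_null, occ_w, abund_p, int(richness[i]), int(totals[i])
            )
            B = _null_community_counts(
                rng, n_null, occ_w, abund_p, int(richness[j]), int(totals[j])
            )
            null_bc = np.abs(A - B).sum(axis=1) / (A + B).sum(axis=1)
            less = (null_bc < obs - 1e-12).sum()
            equal = (np.abs(null_bc - obs) <= 1e-12).sum()
            rc_raw = (less + 0.5 * equal) / n_null
            rc[i, j] = rc[j, i] = 2.0 * (rc_raw - 0.5)
    return RCBrayResult(
        rc=PairwiseMatrix(sub.sample_ids, rc, name="rc_bray"),
        n_null=n_null,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# Process partition
# ---------------------------------------------------------------------------


@dataclass
class ProcessPartition:
    """Five-way ecological-process fractions for one sample group."""

    group_id: str
    n_pairs: int
    counts: dict[str, int]
    fractions: dict[str, float]
    n_excluded: int = 0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "group": self.group_id,
                "process": list(PROCESSES),
                "fraction": [self.fractions[p] for p in PROCESSES],
                "n_pairs": self.n_pairs,
            }
        )


def classify_pair(bnti_value: float, rc_value: float) -> str:
    """Classify one sample pair from its betaNTI and RC_Bray values."""
    if bnti_value > BNTI_THRESHOLD:
        return "heterogeneous_selection"
    if bnti_value < -BNTI_THRESHOLD:
        return "homogeneous_selection"
    if rc_value > RC_THRESHOLD:
        return "dispersal_limitation"
    if rc_value < -RC_THRESHOLD:
        return "homogenizing_dispersal"
    return "drift"


def partition_processes(
    bnti_matrix: PairwiseMatrix,
    rc_matrix: PairwiseMatrix,
    group_id: str = "all",
    pairs: list[tuple[str, str]] | None = None,
) -> ProcessPartition:
    """Fraction of sample pairs assigned to each of the five processes.

    |bNTI| > 2 assigns selection (sign separates heterogeneous from
    homogeneous); otherwise RC_Bray beyond +/-0.95 assigns dispersal
    limitation / homogenizing dispersal, and the remainder is drift.
    Degenerate (NaN) pairs are excluded with a logged count; fractions are
    exact counts over the retained pairs and sum to 1.
    """
    if bnti_matrix.sample_ids != rc_matrix.sample_ids:
        raise ValidationError("bnti and rc matrices cover different samples")
    if pairs is None:
        pairs = bnti_matrix.pair_index()
    if not pairs:
        raise ValidationError("partition_processes: no pairs to classify")
    pos = {s: i for i, s in enumerate(bnti_matrix.sample_ids)}
    counts = {p: 0 for p in PROCESSES}
    n_excluded = 0
    for a, b in pairs:
        i, j = pos[a], pos[b]
        bv = bnti_matrix.values[i, j]
        rv = rc_matrix.values[i, j]
        if np.isnan(bv) or (abs(bv) <= BNTI_THRESHOLD and np.isnan(rv)):
            n_excluded += 1
            continue
        counts[classify_pair(bv, rv)] += 1
    n_pairs = sum(counts.values())
    if n_excluded:
        log.warning("partition_processes[%s]: %d pairs excluded", group_id, n_excluded)
    if n_pairs == 0:
        raise ValidationError("partition_processes: all pairs degenerate")
    fractions = {p: counts[p] / n_pairs for p in PROCESSES}
    return ProcessPartition(group_id, n_pairs, counts, fractions, n_excluded)


# ---------------------------------------------------------------------------
# Phylogenetic signal (Mantel correlogram)
# ---------------------------------------------------------------------------


@dataclass
class PhyloSignalCorrelogram:
    """Mantel correlogram of niche distance over phylogenetic distance classes."""

    class_midpoints: np.ndarray
    mantel_r: np.ndarray
    p_values: np.ndarray
    p_corrected: np.ndarray  # progressive Holm
    n_pairs_per_class: np.ndarray
    n_perm: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "class_midpoint": self.class_midpoints,
                "mantel_r": self.mantel_r,
                "p_value": self.p_values,
                "p_corrected": self.p_corrected,
                "n_pairs": self.n_pairs_per_class,
            }
        )


def niche_optima(
    table: CommunityTable, env: pd.DataFrame, min_occurrences: int = 2
) -> pd.DataFrame:
    """Abundance-weighted mean environment per taxon ("niche optimum").

    ``env`` is samples x variables with complete values. Taxa present in
    fewer than ``min_occurrences`` samples are excluded with a warning.
    """
    samples = [s for s in table.sample_ids if s in env.index]
    if len(samples) < 2:
        raise ValidationError("niche_optima needs >= 2 samples with environment data")
    sub = table.select_samples(samples)
    E = env.loc[samples].to_numpy(dtype=float)
    if np.isnan(E).any():
        raise ValidationError("environment matrix contains missing values")
    X = sub.counts.astype(float)
    occ = (X > 0).sum(axis=1)
    keep = occ >= min_occurrences
    if (~keep).any():
        log.warning(
            "niche_optima: excluding %d taxa present in < %d samples",
            int((~keep).sum()),
            min_occurrences,
        )
    X = X[keep]
    W = X / X.sum(axis=1, keepdims=True)
    optima = W @ E  # taxa x variables
    return pd.DataFrame(
        optima,
        index=pd.Index([t for t, k in zip(sub.taxon_ids, keep) if k], name="taxon_id"),
        columns=env.columns,
    )


def phylo_signal(
    table: CommunityTable,
    tree: PhylogeneticTree,
    env: "pd.DataFrame | SampleMetadata",
    variables: list[str] | None = None,
    n_classes: int = 10,
    n_perm: int = 999,
    seed: int = 0,
    standardize: bool = True,
) -> PhyloSignalCorrelogram:
    """Mantel correlogram of between-taxon niche distance vs patristic distance.

    Niche distance is the Euclidean distance between (optionally
    standardized) abundance-weighted niche optima. Distance classes are
    ``n_classes`` equal-width bins of the patristic range; per class the
    Mantel statistic is the sign-flipped Pearson correlation between the
    niche-distance matrix and the class-membership indicator, so positive
    values at short distances mean close relatives have similar optima.
    P-values are two-sided permutation tests with progressive Holm
    correction.
    """
    if isinstance(env, SampleMetadata):
        env = env.env_matrix(variables or env.env_variables)
    elif variables is not None:
        env = env[list(variables)]
    optima = niche_optima(table, env)
    taxa = list(optima.index)
    if len(taxa) < 4:
        raise ValidationError("phylo_signal needs >= 4 taxa with niche optima")
    vals = optima.to_numpy(dtype=float)
    if standardize:
        sd = vals.std(axis=0, ddof=1)
        keep_var = sd > 0
        vals = (vals[:, keep_var] - vals[:, keep_var].mean(axis=0)) / sd[keep_var]
    from scipy.spatial.distance import pdist

    niche_d = pdist(vals)
    phylo_d = tree.patristic(taxa)[np.triu_indices(len(taxa), k=1)]

    edges = np.linspace(0.0, phylo_d.max(), n_classes + 1)
    mid = 0.5 * (edges[:-1] + edges[1:])
    which = np.clip(np.digitize(phylo_d, edges[1:-1]), 0, n_classes - 1)

    nt = len(taxa)
    niche_sq = np.zeros((nt, nt))
    iu = np.triu_indices(nt, k=1)
    niche_sq[iu] = niche_d
    niche_sq.T[iu] = niche_d

    rng = np.random.default_rng(seed)
    perms = [rng.permutation(nt) for _ in range(n_perm)]
    perm_niche = np.empty((n_perm, niche_d.size))
    for r, p in enumerate(perms):
        perm_niche[r] = niche_sq[np.ix_(p, p)][iu]

    r_out = np.full(n_classes, np.nan)
    p_out = np.full(n_classes, np.nan)
    n_out = np.zeros(n_classes, dtype=int)
    for c in range(n_classes):
        ind = (which == c).astype(float)
        n_out[c] = int(ind.sum())
        if n_out[c] < 2 or ind.std() == 0:
            continue
        r_obs = -stats.pearsonr(niche_d, ind)[0]
        # vectorized permutation correlations
        ic = ind - ind.mean()
        denom_i = np.sqrt((ic**2).sum())
        pm = perm_niche - perm_niche.mean(axis=1, keepdims=True)
        denom_p = np.sqrt((pm**2).sum(axis=1))
        r_perm = -(pm @ ic) / (denom_p * denom_i)
        count = int((np.abs(r_perm) >= abs(r_obs) - 1e-12).sum())
        r_out[c] = r_obs
        p_out[c] = (1 + count) / (1 + n_perm)

    # progressive Holm: class k corrected within the first k tests
    p_corr = np.full(n_classes, np.nan)
    tested = np.flatnonzero(~np.isnan(p_out))
    for rank, c in enumerate(tested, start=1):
        sub_p = p_out[tested[:rank]]
        order = np.argsort(sub_p)
        adj = np.maximum.accumulate((rank - np.arange(rank)) * sub_p[order])
        holm = np.empty(rank)
        holm[order] = np.minimum(adj, 1.0)
        p_corr[c] = holm[rank - 1]  # current class is last in the progressive set
    return PhyloSignalCorrelogram(
        class_midpoints=mid,
        mantel_r=r_out,
        p_values=p_out,
        p_corrected=p_corr,
        n_pairs_per_class=n_out,
        n_perm=n_perm,
    )
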