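"""Synthetic metacommunities with known ground-truth assembly processes.

Generates the three inputs every inference stage consumes — a rarefied-style
count table, an ultrametric tree with phylogenetic signal in niche optima,
and transect metadata spanning climatic zones — under three modes:

- ``selection``: Gaussian environmental filtering along a gradient; taxon
  optima evolve by Brownian motion on the tree, so phylogenetic turnover
  carries signal.
- ``neutral``: Sloan-style drift/immigration; per-sample compositions are
  Dirichlet-multinomial around a fixed source pool, whose marginals are
  exactly the Beta form the neutral community model assumes.
- ``mixed``: selection-determined expected compositions perturbed by the
  same Dirichlet drift.

All generators are pure functions of (config, seed).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from skbio import TreeNode

from ecoassembly.core_data import (
    CommunityTable,
    PhylogeneticTree,
    SampleMetadata,
    ValidationError,
)

import pandas as pd


@dataclass
class ScenarioConfig:
    """Knobs for one synthetic metacommunity."""

    n_taxa: int = 100
    n_samples: int = 24
    reads_per_sample: int = 1000
    birth_rate: float = 1.0
    sigma2: float = 1.0  # Brownian rate for niche optima
    root_value: float = 15.0
    gradient_min: float = 2.0
    gradient_max: float = 28.0
    sigma_w: float = 2.0  # Gaussian niche width; smaller = stronger selection
    m: float = 0.3  # immigration rate (neutral / mixed)
    mode: str = "selection"  # selection | neutral | mixed
    seed: int = 0
    lat_min: float = -35.0
    lat_max: float = 70.0
    longitude: float = -170.0

    def __post_init__(self) -> None:
        if self.mode not in ("selection", "neutral", "mixed"):
            raise ValidationError(f"unknown mode {self.mode!r}")
        if self.sigma_w <= 0:
            raise ValidationError("sigma_w must be positive")
        if not 0 < self.m <= 1:
            raise ValidationError("m must be in (0, 1]")
        for fname in ("n_taxa", "n_samples", "reads_per_sample"):
            if getattr(self, fname) <= 0:
                raise ValidationError(f"{fname} must be positive")


def simulate_tree(n_taxa: int, birth_rate: float = 1.0, seed: int = 0) -> PhylogeneticTree:
    """Yule pure-birth tree with ``n_taxa`` extant tips, ultrametric.

    Tips are labelled ``OTU_0001`` ... in tip-traversal order. Mean pairwise
    patristic distance scales like 1/birth_rate.
    """
    if n_taxa < 3:
        raise ValidationError("simulate_tree needs n_taxa >= 3")
    rng = np.random.default_rng(seed)
    root = TreeNode()
    t = 0.0
    active: list[tuple[TreeNode, float]] = [(root, 0.0)]
    while len(active) < n_taxa:
        k = len(active)
        t += rng.exponential(1.0 / (birth_rate * k))
        i = int(rng.integers(k))
        node, birth = active.pop(i)
        node.length = t - birth if node.parent is not None else None
        c1, c2 = TreeNode(), TreeNode()
        node.extend([c1, c2])
        active.extend([(c1, t), (c2, t)])
    # extend all open lineages to the present
    t_end = t + rng.exponential(1.0 / (birth_rate * n_taxa))
    for node, birth in active:
        node.length = t_end - birth
    width = max(4, len(str(n_taxa)))
    for i, tip in enumerate(root.tips(), start=1):
        tip.name = f"OTU_{i:0{width}d}"
    return PhylogeneticTree(root)


def evolve_optima(
    tree: PhylogeneticTree, sigma2: float, root_value: float, seed: int = 0
) -> pd.Series:
    """Brownian-motion niche optima along the tree; one value per tip."""
    rng = np.random.default_rng(seed)
    values: dict[int, float] = {id(tree.tree): float(root_value)}
    for node in tree.tree.preorder(include_self=False):
        step = rng.normal(0.0, np.sqrt(max(sigma2, 0.0) * (node.length or 0.0)))
        values[id(node)] = values[id(node.parent)] + step
    tips = {t.name: values[id(t)] for t in tree.tree.tips()}
    return pd.Series(tips, name="optimum")


def _transect_metadata(config: ScenarioConfig, env_values: np.ndarray, rng) -> SampleMetadata:
    """Metadata along a meridional transect with the driver variable plus nuisance columns."""
    n = config.n_samples
    lats = np.linspace(config.lat_min, config.lat_max, n)
    sample_ids = [f"S{i + 1:03d}" for i in range(n)]
    layers = ["surface" if i % 2 == 0 else "DCM" for i in range(n)]
    from ecoassembly.diversity import assign_zone

    df = pd.DataFrame(
        {
            "latitude": lats,
            "longitude": np.full(n, config.longitude),
            "layer": layers,
            "zone": [assign_zone(lat) for lat in lats],
            "temperature": env_values,
            # nuisance variables uncorrelated with the driving gradient
            "salinity": 33.0 + rng.normal(0.0, 0.5, n),
            "nitrate": np.round(np.abs(rng.normal(2.0, 1.0, n)), 6),
        },
        index=pd.Index(sample_ids, name="sample_id"),
    )
    return SampleMetadata(df)


def simulate_selection(
    config: ScenarioConfig,
    tree: PhylogeneticTree,
    optima: pd.Series,
) -> tuple[CommunityTable, SampleMetadata]:
    """Gaussian environmental filtering along the transect gradient.

    Expected relative abundance of taxon i in sample s is proportional to
    exp(-(E_s - o_i)^2 / (2 sigma_w^2)); counts are multinomial draws at
    ``reads_per_sample``.
    """
    rng = np.random.default_rng(config.seed)
    env = np.linspace(config.gradient_max, config.gradient_min, config.n_samples)
    meta = _transect_metadata(config, env, rng)
    o = optima.loc[tree.tip_names].to_numpy(dtype=float)
    # taxa x samples fitness kernel
    w = np.exp(-((env[None, :] - o[:, None]) ** 2) / (2.0 * config.sigma_w**2))
    w = np.maximum(w, 1e-300)
    p = w / w.sum(axis=0, keepdims=True)
    counts = np.empty((config.n_taxa, config.n_samples), dtype=np.int64)
    for j in range(config.n_samples):
        counts[:, j] = rng.multinomial(config.reads_per_sample, p[:, j])
    table = CommunityTable(list(tree.tip_names), meta.sample_ids, counts)
    return table, meta


def simulate_neutral(
    source_p: np.ndarray,
    m: float,
    N: int,
    n_samples: int,
    seed: int = 0,
    taxon_ids: list[str] | None = None,
    sample_ids: list[str] | None = None,
) -> CommunityTable:
    """Dirichlet-multinomial neutral sampler around a fixed source pool.

    Per sample the composition is Dirichlet with concentration
    ``N * m * source_p`` and counts are multinomial(N). The marginal of
    each taxon's relative abundance is Beta(N m p, N m (1-p)) — exactly the
    stationary form the Sloan neutral model predicts, so parameter recovery
    by ``ncm_fit`` is a sharp test.
    """
    source_p = np.asarray(source_p, dtype=float)
    if abs(source_p.sum() - 1.0) > 1e-8:
        raise ValidationError("source_p must sum to 1")
    if not 0 < m <= 1:
        raise ValidationError("m must be in (0, 1]")
    rng = np.random.default_rng(seed)
    S = source_p.size
    alpha = N * m * source_p
    counts = np.empty((S, n_samples), dtype=np.int64)
    for j in range(n_samples):
        comp = rng.dirichlet(alpha)
        counts[:, j] = rng.multinomial(N, comp)
    if taxon_ids is None:
        width = max(4, len(str(S)))
        taxon_ids = [f"OTU_{i + 1:0{width}d}" for i in range(S)]
    if sample_ids is None:
        sample_ids = [f"S{j + 1:03d}" for j in range(n_samples)]
    return CommunityTable(list(taxon_ids), list(sample_ids), counts)


def lognormal_source(n_taxa: int, sigma: float = 1.0, seed: int = 0) -> np.ndarray:
    """Lognormal relative-abundance pool, a standard SAD shape."""
    rng = np.random.default_rng(seed)
    x = rng.lognormal(0.0, sigma, n_taxa)
    return x / x.sum()


def simulate_scenario(
    config: ScenarioConfig,
) -> tuple[CommunityTable, PhylogeneticTree, SampleMetadata, dict]:
    """Generate the full (table, tree, metadata) bundle for a config.

    Returns the ground-truth parameters alongside, for downstream recovery
    checks.
    """
    tree = simulate_tree(config.n_taxa, config.birth_rate, seed=config.seed)
    # scale optima spread to the gradient so selection bites
    optima = evolve_optima(tree, config.sigma2, config.root_value, seed=config.seed + 1)
    rng = np.random.default_rng(config.seed + 2)
    if config.mode == "selection":
        table, meta = simulate_selection(config, tree, optima)
    elif config.mode == "neutral":
        env = np.linspace(config.gradient_max, config.gradient_min, config.n_samples)
        meta = _transect_metadata(config, env, rng)
        source = lognormal_source(config.n_taxa, sigma=1.0, seed=config.seed + 3)
        table = simulate_neutral(
            source,
            config.m,
            config.reads_per_sample,
            config.n_samples,
            seed=config.seed + 4,
            taxon_ids=list(tree.tip_names),
            sample_ids=None,
        )
        meta = SampleMetadata(meta.df.loc[table.sample_ids])
    else:  # mixed: selection kernel + Dirichlet drift
        env = np.linspace(config.gradient_max, config.gradient_min, config.n_samples)
        meta = _transect_metadata(config, env, rng)
        o = optima.loc[tree.tip_names].to_numpy(dtype=float)
        w = np.exp(-((env[None, :] - o[:, None]) ** 2) / (2.0 * config.sigma_w**2))
        w = np.maximum(w, 1e-300)
        p = w / w.sum(axis=0, keepdims=True)
        counts = np.empty((config.n_taxa, config.n_samples), dtype=np.int64)
        N = config.reads_per_sample
        for j in range(config.n_samples):
            comp = rng.dirichlet(np.maximum(N * config.m * p[:, j], 1e-8))
            counts[:, j] = rng.multinomial(N, comp)
        table = CommunityTable(list(tree.tip_names), meta.sample_ids, counts)
    truth = {
        "mode": config.mode,
        "sigma_w": config.sigma_w,
        "m": config.m,
        "seed": config.seed,
        "optima": {k: float(v) for k, v in optima.items()},
    }
    return table, tree, meta, truth


def make_fixtures(out_dir, configs: dict[str, ScenarioConfig] | None = None) -> dict:
    """Write selection/neutral/mixed bundles (TSV + Newick + CSV) plus a manifest.

    Regenerating with the manifest's recorded configs is byte-identical.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if configs is None:
        configs = {
            "selection": ScenarioConfig(
                n_taxa=50, n_samples=18, reads_per_sample=500, mode="selection",
                sigma_w=1.5, seed=11,
            ),
            "neutral": ScenarioConfig(
                n_taxa=50, n_samples=18, reads_per_sample=500, mode="neutral",
                m=0.3, seed=12,
            ),
            "mixed": ScenarioConfig(
                n_taxa=50, n_samples=18, reads_per_sample=500, mode="mixed",
                sigma_w=3.0, m=0.3, seed=13,
            ),
        }
    manifest: dict = {"bundles": {}}
    for name, config in configs.items():
        table, tree, meta, truth = simulate_scenario(config)
        table.write_tsv(out / f"{name}_table.tsv")
        tree.write_newick(out / f"{name}_tree.nwk")
        meta.write_csv(out / f"{name}_meta.csv")
        manifest["bundles"][name] = {
            "config": asdict(config),
            "ground_truth": {k: v for k, v in truth.items() if k != "optima"},
            "files": {
                "table": f"{name}_table.tsv",
                "tree": f"{name}_tree.nwk",
                "meta": f"{name}_meta.csv",
            },
        }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
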