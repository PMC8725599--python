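"""End-to-end orchestration: rarefy -> diversity -> null models -> process
partition -> NCM -> niche breadth -> environmental statistics, per sample
group, with deterministic seeding and a JSON manifest.

Output is a pure function of (inputs, config, seed): no timestamps are
written, CSV reals use 6 significant digits, and every stage's parameters
are recorded in ``manifest.json``.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from ecoassembly import (
    alpha_diversity,
    anosim,
    beta_mntd,
    bnti,
    bnti_env_correlation,
    bray_curtis,
    community_niche_breadth,
    distance_decay,
    geographic_distance,
    levins_b,
    ncm_fit,
    partition_processes,
    phylo_signal,
    rarefy,
    rc_bray,
    read_community_table,
    read_metadata,
    read_tree,
    remove_singletons,
    vpa,
    log1p_env,
    zonal_heterogeneity,
)
from ecoassembly.core_data import FLOAT_FORMAT, ValidationError

log = logging.getLogger("ecoassembly")

DEFAULT_PHYSICAL = ["temperature", "salinity", "PAR", "MLD", "ELD"]
DEFAULT_NUTRIENT = ["nitrate", "phosphate", "silicate", "ammonia", "iron"]


@dataclass
class RunConfig:
    table: str = ""
    tree: str = ""
    meta: str = ""
    out_dir: str = "results"
    grouping: str = "zonal_combined"  # basin_by_layer | zonal_combined | all | <column>
    rarefy_depth: int | None = None  # None = minimum sample total
    n_null: int = 999
    n_rc: int = 9999
    n_perm: int = 999
    seed: int = 42
    remove_singletons: bool = True
    physical_factors: list[str] = field(default_factory=lambda: list(DEFAULT_PHYSICAL))
    nutrient_factors: list[str] = field(default_factory=lambda: list(DEFAULT_NUTRIENT))
    run_env_stats: bool = True
    run_phylo_signal: bool = True

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)


def _groups(config: RunConfig, meta) -> dict[str, list[str]]:
    df = meta.df
    if config.grouping == "all":
        return {"all": list(map(str, df.index))}
    if config.grouping == "basin_by_layer":
        col = "layer"
    elif config.grouping == "zonal_combined":
        col = "zone"
    else:
        col = config.grouping
    if col not in df.columns:
        raise ValidationError(f"grouping column {col!r} not in metadata")
    out: dict[str, list[str]] = {}
    for g, sub in df.groupby(col, sort=True):
        out[str(g)] = [str(s) for s in sub.index]
    return out


def _write(df: pd.DataFrame, path: Path, index: bool = True) -> None:
    df.to_csv(path, float_format=FLOAT_FORMAT, index=index)


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full analysis and write per-stage CSVs + manifest.

    Any stage failure aborts with the stage name; outputs written so far
    are kept next to a ``.partial`` marker.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    marker = out / ".partial"
    marker.write_text("run in progress\n")
    manifest: dict = {
        "config": asdict(config),
        "stages": [],
        "groups": {},
        "warnings": [],
    }
    stage = "load"
    try:
        table = read_community_table(config.table)
        tree = read_tree(config.tree) if config.tree else None
        meta = read_metadata(config.meta)
        meta = meta.select_samples([s for s in table.sample_ids])

        stage = "filter"
        if config.remove_singletons:
            table = remove_singletons(table)
        else:
            table = table.drop_zero_taxa()

        stage = "rarefy"
        table = rarefy(table, depth=config.rarefy_depth, seed=config.seed)
        depth = int(table.sample_totals[0])
        manifest["stages"].append({"stage": "rarefy", "depth": depth, "seed": config.seed})
        table.write_tsv(out / "rarefied_table.tsv")

        stage = "alpha_diversity"
        alpha = alpha_diversity(table)
        _write(alpha, out / "alpha.csv")
        manifest["stages"].append({"stage": "alpha_diversity"})

        stage = "beta_diversity"
        bc = bray_curtis(table)
        bc.write_csv(out / "bray_curtis.csv")
        geo = geographic_distance(meta)
        geo.write_csv(out / "geographic_km.csv")
        manifest["stages"].append({"stage": "beta_diversity"})

        stage = "anosim"
        anosim_rows = []
        for col in ("layer", "zone"):
            if col in meta.df.columns and meta.df[col].nunique() >= 2:
                sizes = meta.df[col].value_counts()
                if (sizes >= 2).all():
                    r, p = anosim(bc, meta.df[col], n_perm=config.n_perm, seed=config.seed)
                    anosim_rows.append((col, r, p, config.n_perm))
        _write(
            pd.DataFrame(anosim_rows, columns=["grouping", "R", "p", "n_perm"]),
            out / "anosim.csv",
            index=False,
        )
        manifest["stages"].append({"stage": "anosim"})

        stage = "distance_decay"
        sim = type(bc)(bc.sample_ids, 1.0 - bc.values, name="similarity")
        ddr = distance_decay(sim, geo, n_perm=config.n_perm, seed=config.seed)
        _write(
            pd.DataFrame([asdict(ddr) | {"slope_percent_per_km": ddr.slope * 100.0}]),
            out / "ddr.csv",
            index=False,
        )
        manifest["stages"].append({"stage": "distance_decay"})

        if tree is not None and config.run_phylo_signal:
            stage = "phylo_signal"
            env_vars = meta.env_variables
            if env_vars:
                cor = phylo_signal(
                    table, tree, meta, variables=env_vars,
                    n_perm=config.n_perm, seed=config.seed,
                )
                _write(cor.to_frame(), out / "phylo_signal.csv", index=False)
                manifest["stages"].append({"stage": "phylo_signal", "n_perm": config.n_perm})

        groups = _groups(config, meta)
        manifest["groups"] = {g: len(ids) for g, ids in groups.items()}

        partition_frames = []
        bnti_frames = []
        rc_frames = []
        ncm_rows = []
        niche_rows = []
        for gname, sample_ids in groups.items():
            if len(sample_ids) < 3:
                manifest["warnings"].append(
                    f"group {gname}: fewer than 3 samples, null models skipped"
                )
                continue
            gtable = table.select_samples(sample_ids).drop_zero_taxa()
            if tree is not None:
                stage = f"bnti[{gname}]"
                bres = bnti(gtable, tree, n_null=config.n_null, seed=config.seed)
                stage = f"rc_bray[{gname}]"
                rres = rc_bray(gtable, n_null=config.n_rc, seed=config.seed)
                stage = f"partition[{gname}]"
                part = partition_processes(bres.bnti, rres.rc, group_id=gname)
                partition_frames.append(part.to_frame())
                bdf = bres.bnti.to_dataframe().stack().rename("bnti").reset_index()
                bdf.insert(0, "group", gname)
                bnti_frames.append(bdf)
                rdf = rres.rc.to_dataframe().stack().rename("rc_bray").reset_index()
                rdf.insert(0, "group", gname)
                rc_frames.append(rdf)
                manifest["stages"].append(
                    {
                        "stage": "null_models",
                        "group": gname,
                        "n_null": config.n_null,
                        "n_rc": config.n_rc,
                        "n_pairs": part.n_pairs,
                        "n_excluded_pairs": part.n_excluded,
                        "seed": config.seed,
                    }
                )
            stage = f"ncm[{gname}]"
            try:
                fit = ncm_fit(gtable)
                ncm_rows.append(
                    (gname, fit.m, fit.N, fit.r_squared, len(fit.taxa), fit.n_samples)
                )
                per_taxon = fit.taxa.copy()
                per_taxon.insert(0, "group", gname)
                _write(per_taxon, out / f"ncm_taxa_{gname}.csv")
            except ValidationError as exc:
                manifest["warnings"].append(f"ncm[{gname}]: {exc}")
            stage = f"niche[{gname}]"
            b = levins_b(gtable)
            bcom = community_niche_breadth(b, gtable)
            for sid, v in bcom.items():
                niche_rows.append((gname, sid, float(v)))

        if partition_frames:
            _write(
                pd.concat(partition_frames, ignore_index=True),
                out / "process_partition.csv",
                index=False,
            )
            _write(pd.concat(bnti_frames, ignore_index=True), out / "bnti.csv", index=False)
            _write(pd.concat(rc_frames, ignore_index=True), out / "rcbray.csv", index=False)
        _write(
            pd.DataFrame(
                ncm_rows, columns=["group", "m", "N", "r_squared", "n_taxa", "n_samples"]
            ),
            out / "ncm.csv",
            index=False,
        )
        _write(
            pd.DataFrame(niche_rows, columns=["group", "sample_id", "b_com"]),
            out / "niche.csv",
            index=False,
        )
        manifest["stages"].append({"stage": "ncm"})
        manifest["stages"].append({"stage": "niche"})

        if config.run_env_stats and tree is not None:
            stage = "env_stats"
            env_vars = [v for v in meta.env_variables]
            usable = [v for v in env_vars if meta.df[v].notna().all()]
            if len(usable) >= 2 and len(meta.sample_ids) >= 4:
                tmeta = log1p_env(meta, [v for v in usable if (meta.df[v] >= 0).all()])
                bres_all = bnti(table.drop_zero_taxa(), tree, n_null=config.n_null,
                                seed=config.seed)
                mt = bnti_env_correlation(
                    bres_all.bnti, tmeta, usable, n_perm=config.n_perm, seed=config.seed
                )
                _write(mt, out / "mantel_table.csv", index=False)
                phys = [v for v in config.physical_factors if v in usable]
                nutr = [v for v in config.nutrient_factors if v in usable]
                if phys and nutr and len(meta.sample_ids) > len(phys) + len(nutr) + 1:
                    res = vpa(table, tmeta, phys, nutr)
                    _write(
                        pd.DataFrame(
                            [
                                {
                                    "pure_physical": res.pure_x1,
                                    "pure_nutrient": res.pure_x2,
                                    "shared": res.shared,
                                    "residual": res.residual,
                                }
                            ]
                        ),
                        out / "vpa.csv",
                        index=False,
                    )
                if "zone" in meta.df.columns:
                    het = zonal_heterogeneity(tmeta, usable)
                    _write(het, out / "heterogeneity.csv", index=False)
                manifest["stages"].append({"stage": "env_stats"})

        manifest["complete"] = True
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
        marker.unlink(missing_ok=True)
        return manifest
    except Exception as exc:
        manifest["complete"] = False
        manifest["failed_stage"] = stage
        manifest["error"] = str(exc)
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc
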