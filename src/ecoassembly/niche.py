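"""Levins' niche breadth per taxon and community-level means."""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from ecoassembly.core_data import CommunityTable, ValidationError

log = logging.getLogger("ecoassembly")


def levins_b(table: CommunityTable) -> pd.Series:
    """Levins' niche breadth B_j = 1 / sum_i P_ij^2 per taxon.

    P_ij is taxon j's proportion of its own total found in community i
    (taxon-normalized, so P sums to 1 over communities and 1 <= B <= N).
    B equals the number of communities for a perfectly even taxon and 1
    for a single-site taxon. Zero-total taxa are excluded with a warning.
    """
    totals = table.taxon_totals
    keep = totals > 0
    if (~keep).any():
        log.warning("levins_b: excluding %d zero-total taxa", int((~keep).sum()))
    x = table.counts[keep].astype(float)
    P = x / x.sum(axis=1, keepdims=True)
    b = 1.0 / (P**2).sum(axis=1)
    return pd.Series(
        b,
        index=pd.Index([t for t, k in zip(table.taxon_ids, keep) if k], name="taxon_id"),
        name="levins_b",
    )


def community_niche_breadth(
    b: pd.Series, table: CommunityTable, weighted: bool = False
) -> pd.Series:
    """Per-sample mean niche breadth (B_com) over taxa present in the sample.

    Default is the unweighted mean of B_j over present taxa; ``weighted``
    averages with within-sample relative abundances instead.
    """
    out = {}
    pos = {t: i for i, t in enumerate(table.taxon_ids)}
    bvals = b.to_dict()
    for j, sid in enumerate(table.sample_ids):
        present = [t for t in table.taxon_ids if table.counts[pos[t], j] > 0 and t in bvals]
        if not present:
            raise ValidationError(f"sample {sid!r} has no taxa with niche breadth")
        vals = np.array([bvals[t] for t in present])
        if weighted:
            w = np.array([table.counts[pos[t], j] for t in present], dtype=float)
            out[sid] = float((vals * w).sum() / w.sum())
        else:
            out[sid] = float(vals.mean())
    return pd.Series(out, name="b_com").rename_axis("sample_id")
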