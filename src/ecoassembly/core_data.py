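"""Domain types and file I/O shared by every analysis stage.

The central objects are:

- :class:`CommunityTable` — integer OTU counts, taxa (rows) x samples
  (columns).
- :class:`PhylogeneticTree` — rooted tree with branch lengths; the source
  of patristic distances.
- :class:`SampleMetadata` — per-sample coordinates, depth layer, climatic
  zone, and environmental variables.
- :class:`PairwiseMatrix` — a symmetric sample-by-sample matrix
  (dissimilarity, turnover index, geographic distance ...).

File formats are deliberately plain: TSV for the count table (first column
``#OTU_ID``), Newick for the tree, CSV for metadata. Writers emit reals
with 6 significant digits.
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skbio import TreeNode

log = logging.getLogger("ecoassembly")

FLOAT_FORMAT = "%.6g"

LAYERS = ("surface", "DCM")
ZONES = ("subarctic", "subtropic", "tropic")


class ValidationError(ValueError):
    """Raised when an input violates a structural invariant."""


# ---------------------------------------------------------------------------
# CommunityTable
# ---------------------------------------------------------------------------


@dataclass
class CommunityTable:
    """Taxa-by-samples table of non-negative integer counts.

    Parameters
    ----------
    taxon_ids : list of str
        Unique row identifiers (OTU IDs), in file order.
    sample_ids : list of str
        Unique column identifiers.
    counts : ndarray of int, shape (n_taxa, n_samples)
    """

    taxon_ids: list[str]
    sample_ids: list[str]
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.taxon_ids = list(map(str, self.taxon_ids))
        self.sample_ids = list(map(str, self.sample_ids))
        counts = np.asarray(self.counts)
        if counts.ndim != 2:
            raise ValidationError("counts must be a 2-D array")
        if counts.shape != (len(self.taxon_ids), len(self.sample_ids)):
            raise ValidationError(
                f"counts shape {counts.shape} does not match "
                f"{len(self.taxon_ids)} taxa x {len(self.sample_ids)} samples"
            )
        if np.issubdtype(counts.dtype, np.floating):
            if np.isnan(counts).any():
                i, j = np.argwhere(np.isnan(counts))[0]
                raise ValidationError(
                    f"NaN count at taxon {self.taxon_ids[i]!r}, "
                    f"sample {self.sample_ids[j]!r}"
                )
            if not np.all(counts == np.round(counts)):
                i, j = np.argwhere(counts != np.round(counts))[0]
                raise ValidationError(
                    f"non-integer count {counts[i, j]} at taxon "
                    f"{self.taxon_ids[i]!r}, sample {self.sample_ids[j]!r}"
                )
            counts = counts.astype(np.int64)
        if not np.issubdtype(counts.dtype, np.integer):
            raise ValidationError(f"counts must be integer, got {counts.dtype}")
        if (counts < 0).any():
            i, j = np.argwhere(counts < 0)[0]
            raise ValidationError(
                f"negative count at taxon {self.taxon_ids[i]!r}, "
                f"sample {self.sample_ids[j]!r}"
            )
        for name, ids in (("taxon", self.taxon_ids), ("sample", self.sample_ids)):
            seen: set[str] = set()
            for x in ids:
                if x in seen:
                    raise ValidationError(f"duplicate {name} ID: {x!r}")
                seen.add(x)
        self.counts = counts.astype(np.int64)

    # -- basic views --------------------------------------------------------

    @property
    def n_taxa(self) -> int:
        return len(self.taxon_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def sample_totals(self) -> np.ndarray:
        return self.counts.sum(axis=0)

    @property
    def taxon_totals(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    def relative_abundance(self) -> np.ndarray:
        """Within-sample relative abundances, shape (n_taxa, n_samples).

        Raises if any sample is empty.
        """
        totals = self.sample_totals
        if (totals == 0).any():
            empty = self.sample_ids[int(np.argmax(totals == 0))]
            raise ValidationError(f"sample {empty!r} has zero total count")
        return self.counts / totals

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.counts, index=pd.Index(self.taxon_ids, name="#OTU_ID"),
            columns=self.sample_ids,
        )

    # -- subsetting ---------------------------------------------------------

    def select_samples(self, sample_ids: list[str]) -> "CommunityTable":
        """Return the sub-table over ``sample_ids`` (order as given)."""
        missing = [s for s in sample_ids if s not in self.sample_ids]
        if missing:
            raise ValidationError(f"unknown sample IDs: {missing}")
        idx = [self.sample_ids.index(s) for s in sample_ids]
        return CommunityTable(self.taxon_ids, list(sample_ids), self.counts[:, idx])

    def select_taxa(self, taxon_ids: list[str]) -> "CommunityTable":
        missing = [t for t in taxon_ids if t not in self.taxon_ids]
        if missing:
            raise ValidationError(f"unknown taxon IDs: {missing}")
        pos = {t: i for i, t in enumerate(self.taxon_ids)}
        idx = [pos[t] for t in taxon_ids]
        return CommunityTable(list(taxon_ids), self.sample_ids, self.counts[idx, :])

    def drop_zero_taxa(self) -> "CommunityTable":
        """Drop all-zero taxa (they break relative-abundance math)."""
        keep = self.taxon_totals > 0
        n_dropped = int((~keep).sum())
        if n_dropped:
            log.warning("dropping %d all-zero taxa", n_dropped)
        return CommunityTable(
            [t for t, k in zip(self.taxon_ids, keep) if k],
            self.sample_ids,
            self.counts[keep],
        )

    def write_tsv(self, path) -> None:
        self.to_dataframe().to_csv(path, sep="\t")


def read_community_table(path) -> CommunityTable:
    """Read an OTU table from TSV (first column = OTU ID, header present)."""
    df = pd.read_csv(path, sep="\t", header=0, index_col=0, dtype=str)
    taxa = [str(t) for t in df.index]
    samples = [str(s) for s in df.columns]
    try:
        values = df.to_numpy(dtype=float)
    except ValueError as exc:
        raise ValidationError(f"non-numeric cell in {path}: {exc}") from exc
    return CommunityTable(taxa, samples, values)


def remove_singletons(table: CommunityTable) -> CommunityTable:
    """Drop taxa whose total count across all samples is <= 1.

    Taxa with a total of exactly 1 (singletons) are removed; all-zero taxa
    are dropped as degenerate with a warning. Row order is otherwise
    preserved and retained counts are untouched.
    """
    totals = table.taxon_totals
    n_zero = int((totals == 0).sum())
    if n_zero:
        log.warning("remove_singletons: dropping %d all-zero taxa", n_zero)
    keep = totals > 1
    return CommunityTable(
        [t for t, k in zip(table.taxon_ids, keep) if k],
        table.sample_ids,
        table.counts[keep],
    )


def occupancy(table: CommunityTable) -> pd.DataFrame:
    """Per-taxon site-occupation frequency and mean relative abundance.

    Returns a DataFrame indexed by taxon with columns ``occupancy``
    (#samples with count > 0 divided by n_samples) and
    ``mean_relative_abundance`` (mean of within-sample relative
    abundances).
    """
    if table.n_samples < 1:
        raise ValidationError("occupancy requires at least one sample")
    freq = (table.counts > 0).mean(axis=1)
    rel = table.relative_abundance().mean(axis=1)
    return pd.DataFrame(
        {"occupancy": freq, "mean_relative_abundance": rel},
        index=pd.Index(table.taxon_ids, name="taxon_id"),
    )


# ---------------------------------------------------------------------------
# PhylogeneticTree
# ---------------------------------------------------------------------------


class PhylogeneticTree:
    """Rooted tree with non-negative branch lengths, tips labelled by OTU ID.

    Thin wrapper over :class:`skbio.TreeNode` that validates the structure
    once and exposes patristic (tip-to-tip path length) distances.
    """

    def __init__(self, tree: TreeNode):
        self.tree = tree
        tips = list(tree.tips())
        names = [t.name for t in tips]
        if any(n is None or n == "" for n in names):
            raise ValidationError("tree has unlabeled tips")
        if len(set(names)) != len(names):
            dup = sorted({n for n in names if names.count(n) > 1})
            raise ValidationError(f"duplicate tip labels: {dup}")
        for node in tree.traverse(include_self=False):
            if node.length is None:
                node.length = 0.0
            if node.length < 0:
                raise ValidationError(
                    f"negative branch length {node.length} above "
                    f"{node.name or 'internal node'}"
                )
        self.tip_names: list[str] = names
        self._dm = None

    @property
    def n_tips(self) -> int:
        return len(self.tip_names)

    def _distance_matrix(self):
        if self._dm is None:
            self._dm = self.tree.tip_tip_distances()
        return self._dm

    def patristic(self, taxa: list[str]) -> np.ndarray:
        """Patristic distance matrix over ``taxa`` in the given order."""
        self.align_taxa(taxa)
        dm = self._distance_matrix()
        idx = [dm.index(t) for t in taxa]
        return dm.data[np.ix_(idx, idx)].copy()

    def align_taxa(self, taxa: list[str]) -> None:
        """Raise listing the taxa absent from the tree's tip set."""
        missing = sorted(set(taxa) - set(self.tip_names))
        if missing:
            raise ValidationError(
                f"{len(missing)} taxa missing from tree tips: {missing[:10]}"
            )

    def write_newick(self, path) -> None:
        self.tree.write(str(path), format="newick")

    def to_newick(self) -> str:
        buf = io.StringIO()
        self.tree.write(buf, format="newick")
        return buf.getvalue()


def read_tree(path) -> PhylogeneticTree:
    """Read a rooted Newick tree with branch lengths.

    Underscores in tip labels are kept verbatim (no Newick space
    conversion), since OTU IDs routinely contain them.
    """
    tree = TreeNode.read(str(path), format="newick", convert_underscores=False)
    return PhylogeneticTree(tree)


def tree_from_newick(newick: str) -> PhylogeneticTree:
    return PhylogeneticTree(
        TreeNode.read(io.StringIO(newick), format="newick", convert_underscores=False)
    )


# ---------------------------------------------------------------------------
# SampleMetadata
# ---------------------------------------------------------------------------

_MANDATORY_META = ["sample_id", "latitude", "longitude", "layer"]
_NON_ENV = {"sample_id", "latitude", "longitude", "layer", "zone"}


@dataclass
class SampleMetadata:
    """Per-sample coordinates, layer, zone and environmental variables.

    Backed by a DataFrame indexed by sample ID. Environmental variables are
    every numeric column other than latitude/longitude. Missing values are
    allowed and mean "sample excluded from analyses requiring that
    variable" — they are never imputed.
    """

    df: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.df
        if df.index.has_duplicates:
            dup = df.index[df.index.duplicated()].tolist()
            raise ValidationError(f"duplicate sample IDs in metadata: {dup}")
        for col in ("latitude", "longitude", "layer"):
            if col not in df.columns:
                raise ValidationError(f"metadata missing mandatory column {col!r}")
        lat = df["latitude"].astype(float)
        lon = df["longitude"].astype(float)
        if ((lat < -90) | (lat > 90)).any():
            bad = df.index[(lat < -90) | (lat > 90)].tolist()
            raise ValidationError(f"latitude out of [-90, 90] for samples {bad}")
        if ((lon < -180) | (lon > 180)).any():
            bad = df.index[(lon < -180) | (lon > 180)].tolist()
            raise ValidationError(f"longitude out of [-180, 180] for samples {bad}")
        self.df = df

    @property
    def sample_ids(self) -> list[str]:
        return [str(s) for s in self.df.index]

    @property
    def env_variables(self) -> list[str]:
        return [
            c
            for c in self.df.columns
            if c not in _NON_ENV and pd.api.types.is_numeric_dtype(self.df[c])
        ]

    def select_samples(self, sample_ids: list[str]) -> "SampleMetadata":
        missing = [s for s in sample_ids if s not in self.df.index]
        if missing:
            raise ValidationError(f"samples missing from metadata: {missing}")
        return SampleMetadata(self.df.loc[list(sample_ids)].copy())

    def env_matrix(self, variables: list[str], dropna: bool = True) -> pd.DataFrame:
        """Environmental variables as samples-by-variables DataFrame.

        With ``dropna``, samples with a missing value in any requested
        variable are excluded (with a warning).
        """
        missing = [v for v in variables if v not in self.df.columns]
        if missing:
            raise ValidationError(f"unknown environmental variables: {missing}")
        sub = self.df[list(variables)].astype(float)
        if dropna and sub.isna().any().any():
            excluded = sub.index[sub.isna().any(axis=1)].tolist()
            log.warning(
                "excluding %d samples with missing values in %s",
                len(excluded),
                variables,
            )
            sub = sub.dropna()
        return sub

    def write_csv(self, path) -> None:
        self.df.to_csv(path, index_label="sample_id", float_format=FLOAT_FORMAT)


def read_metadata(path, derive_zone: bool = True) -> SampleMetadata:
    """Read sample metadata from CSV.

    Mandatory columns: ``sample_id, latitude, longitude, layer``. A ``zone``
    column is derived from latitude when absent.
    """
    df = pd.read_csv(path)
    missing = [c for c in _MANDATORY_META if c not in df.columns]
    if missing:
        raise ValidationError(f"metadata missing mandatory columns: {missing}")
    df["sample_id"] = df["sample_id"].astype(str)
    df = df.set_index("sample_id")
    meta = SampleMetadata(df)
    if derive_zone and "zone" not in df.columns:
        from ecoassembly.diversity import assign_zone

        df["zone"] = [assign_zone(lat) for lat in df["latitude"].astype(float)]
    return meta


# ---------------------------------------------------------------------------
# PairwiseMatrix
# ---------------------------------------------------------------------------


@dataclass
class PairwiseMatrix:
    """Symmetric sample-by-sample matrix (distance or turnover index).

    The diagonal is 0 for distances; for standardized indices whose
    diagonal is undefined it holds NaN. Off-diagonal NaN marks a pair
    flagged degenerate.
    """

    sample_ids: list[str]
    values: np.ndarray
    name: str = field(default="")

    def __post_init__(self) -> None:
        self.sample_ids = list(map(str, self.sample_ids))
        v = np.asarray(self.values, dtype=float)
        n = len(self.sample_ids)
        if v.shape != (n, n):
            raise ValidationError(f"matrix shape {v.shape} != ({n}, {n})")
        if len(set(self.sample_ids)) != n:
            raise ValidationError("duplicate sample IDs in pairwise matrix")
        off = ~np.eye(n, dtype=bool)
        finite = np.isfinite(v) | np.isnan(v)
        if not finite.all():
            raise ValidationError("pairwise matrix contains +/-inf")
        asym = np.abs(np.where(np.isnan(v), 0.0, v) - np.where(np.isnan(v.T), 0.0, v.T))
        if off.any() and np.nanmax(asym) > 1e-9:
            raise ValidationError("pairwise matrix is not symmetric")
        self.values = v

    @property
    def n(self) -> int:
        return len(self.sample_ids)

    def condensed(self) -> np.ndarray:
        """Upper-triangle values in scipy condensed (row-major) order."""
        iu = np.triu_indices(self.n, k=1)
        return self.values[iu]

    def pair_index(self) -> list[tuple[str, str]]:
        iu = np.triu_indices(self.n, k=1)
        return [(self.sample_ids[i], self.sample_ids[j]) for i, j in zip(*iu)]

    def submatrix(self, sample_ids: list[str]) -> "PairwiseMatrix":
        pos = {s: i for i, s in enumerate(self.sample_ids)}
        missing = [s for s in sample_ids if s not in pos]
        if missing:
            raise ValidationError(f"samples not in matrix: {missing}")
        idx = [pos[s] for s in sample_ids]
        return PairwiseMatrix(
            list(sample_ids), self.values[np.ix_(idx, idx)].copy(), self.name
        )

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values,
            index=pd.Index(self.sample_ids, name="sample_id"),
            columns=self.sample_ids,
        )

    def write_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, float_format=FLOAT_FORMAT)


def pairwise_from_condensed(
    sample_ids: list[str], condensed: np.ndarray, name: str = "", diagonal: float = 0.0
) -> PairwiseMatrix:
    """Build a PairwiseMatrix from condensed upper-triangle values."""
    n = len(sample_ids)
    v = np.full((n, n), float(diagonal))
    iu = np.triu_indices(n, k=1)
    v[iu] = condensed
    v.T[iu] = condensed
    return PairwiseMatrix(list(sample_ids), v, name)


def read_pairwise_csv(path, name: str = "") -> PairwiseMatrix:
    df = pd.read_csv(path, index_col=0)
    return PairwiseMatrix([str(s) for s in df.index], df.to_numpy(dtype=float), name)
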