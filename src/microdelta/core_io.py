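"""Data model and file I/O shared by every analysis stage.

The central container is :class:`FeatureTable`, a samples x ASVs matrix of
non-negative integer counts with stable, unique identifiers on both axes.
Taxonomic lineages, the rooted phylogeny, and per-sample covariates are held
in light wrappers around pandas / scikit-bio objects so that each stage can
lean on those libraries for the heavy lifting.

On-disk dialect: dense tab-separated text with features as rows (the layout
exported by ``biom convert --to-tsv``); an orientation flag accepts the
transposed form.  Trees are newick; metadata is a TSV with a header naming
the cohort fields.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from skbio import TreeNode

__all__ = [
    "FeatureTable",
    "TaxonomyMap",
    "CohortMetadata",
    "RANKS",
    "read_feature_table",
    "write_feature_table",
    "read_taxonomy",
    "write_taxonomy",
    "read_tree",
    "read_metadata",
    "prevalence_filter",
    "collapse_taxonomy",
]

#: Canonical seven taxonomic ranks, Greengenes-style prefixes.
RANKS = ("kingdom", "phylum", "class", "order", "family", "genus", "species")
_RANK_PREFIX = ("k__", "p__", "c__", "o__", "f__", "g__", "s__")


class FeatureTableError(ValueError):
    """Raised for malformed feature-table input."""


@dataclass(frozen=True)
class FeatureTable:
    """Samples x features matrix of non-negative integer counts.

    Parameters
    ----------
    data : pandas.DataFrame
        Rows are samples, columns are features.  Coerced to int64.

    Notes
    -----
    Identifiers must be unique on both axes and counts non-negative; the
    constructor enforces both.  Row/column order is preserved exactly, so a
    write/read round-trip is the identity.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data
        if df.index.has_duplicates:
            dupes = df.index[df.index.duplicated()].unique().tolist()
            raise FeatureTableError(f"duplicate sample id(s): {dupes}")
        if df.columns.has_duplicates:
            dupes = df.columns[df.columns.duplicated()].unique().tolist()
            raise FeatureTableError(f"duplicate feature id(s): {dupes}")
        arr = df.to_numpy()
        if arr.size and not np.issubdtype(arr.dtype, np.number):
            raise FeatureTableError("non-numeric counts in feature table")
        if arr.size and (arr < 0).any():
            i, j = np.argwhere(arr < 0)[0]
            raise FeatureTableError(
                f"negative count at sample {df.index[i]!r}, feature {df.columns[j]!r}"
            )
        if arr.size and not np.allclose(arr, np.round(arr)):
            i, j = np.argwhere(~np.isclose(arr, np.round(arr)))[0]
            raise FeatureTableError(
                f"non-integer count at sample {df.index[i]!r}, feature {df.columns[j]!r}"
            )
        object.__setattr__(self, "data", df.astype(np.int64))

    # -- basic accessors -------------------------------------------------
    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def feature_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def counts(self) -> np.ndarray:
        """Counts as an (n_samples, n_features) int array (a copy)."""
        return self.data.to_numpy(copy=True)

    @property
    def n_samples(self) -> int:
        return self.data.shape[0]

    @property
    def n_features(self) -> int:
        return self.data.shape[1]

    def depths(self) -> pd.Series:
        """Per-sample sequencing depth (row sums)."""
        return self.data.sum(axis=1)

    def relative_abundance(self, pseudocount: float = 0.0) -> pd.DataFrame:
        """Row-normalised fractions, optionally after adding a pseudocount."""
        x = self.data.to_numpy(dtype=float) + pseudocount
        with np.errstate(invalid="ignore"):
            frac = x / x.sum(axis=1, keepdims=True)
        return pd.DataFrame(frac, index=self.data.index, columns=self.data.columns)

    def select_samples(self, ids: Sequence[str]) -> "FeatureTable":
        missing = [s for s in ids if s not in self.data.index]
        if missing:
            raise KeyError(f"unknown sample id(s): {missing}")
        return FeatureTable(self.data.loc[list(ids)])

    def select_features(self, ids: Sequence[str]) -> "FeatureTable":
        missing = [f for f in ids if f not in self.data.columns]
        if missing:
            raise KeyError(f"unknown feature id(s): {missing}")
        return FeatureTable(self.data[list(ids)])


@dataclass(frozen=True)
class TaxonomyMap:
    """Feature id -> taxonomic lineage (ordered ranks, possibly truncated).

    Lineages are stored as tuples of rank strings without prefixes; a missing
    or unknown rank is an empty string.  ``collapse_taxonomy`` groups features
    whose lineages agree through the requested rank, grouping unknowns under
    their most specific known prefix.
    """

    lineages: Mapping[str, tuple[str, ...]]

    def __post_init__(self) -> None:
        clean: dict[str, tuple[str, ...]] = {}
        for fid, lin in dict(self.lineages).items():
            lin = tuple(str(x).strip() for x in lin)[: len(RANKS)]
            lin = lin + ("",) * (len(RANKS) - len(lin))
            clean[str(fid)] = lin
        object.__setattr__(self, "lineages", clean)

    def lineage(self, feature_id: str) -> tuple[str, ...]:
        return self.lineages[feature_id]

    def at_rank(self, feature_id: str, rank: str) -> str:
        """Label of ``feature_id`` at ``rank`` ('' if unknown at that rank)."""
        return self.lineages[feature_id][RANKS.index(rank)]

    def group_label(self, feature_id: str, rank: str) -> str:
        """Collapsing label: lineage prefix through ``rank``.

        Features unknown at ``rank`` are labelled by their most specific
        known prefix with a trailing ``?`` so they stay distinguishable from
        features genuinely resolved at that prefix.
        """
        depth = RANKS.index(rank) + 1
        lin = self.lineages[feature_id]
        prefix = lin[:depth]
        known = [f"{_RANK_PREFIX[i]}{v}" for i, v in enumerate(prefix) if v]
        if not known:
            return "unclassified"
        if not prefix[-1]:  # unknown at requested rank
            return ";".join(known) + ";?"
        return ";".join(known)

    @classmethod
    def from_strings(cls, mapping: Mapping[str, str]) -> "TaxonomyMap":
        """Parse Greengenes-style strings ``k__Bacteria; p__Firmicutes; ...``."""
        out = {}
        for fid, s in mapping.items():
            parts = [p.strip() for p in str(s).split(";")]
            lin = []
            for p in parts:
                for pref in _RANK_PREFIX:
                    if p.startswith(pref):
                        p = p[len(pref):]
                        break
                lin.append(p.strip())
            out[fid] = tuple(lin)
        return cls(out)

    def to_strings(self) -> dict[str, str]:
        return {
            fid: "; ".join(
                f"{_RANK_PREFIX[i]}{v}" for i, v in enumerate(lin)
            )
            for fid, lin in self.lineages.items()
        }


#: Required metadata columns and their dtypes/levels.
_META_COLUMNS = {
    "subject_id": None,
    "arm": {"UDCA", "placebo"},
    "timepoint": {"baseline", "end"},
    "sex": {"M", "F"},
    "age": None,
    "aspirin": {0, 1},
    "batch_mismatch": {0, 1},
    "storage_years": None,
    "outcome_any": {0, 1},
    "outcome_advanced": {0, 1},
}


@dataclass(frozen=True)
class CohortMetadata:
    """Per-sample covariates and the baseline/end pairing structure.

    The underlying frame is indexed by sample id and carries subject id,
    treatment arm, timepoint, sex, age, aspirin use, a batch-mismatch
    indicator, freezer storage time in years, and the two adenoma outcomes.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data.copy()
        missing = [c for c in _META_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"metadata missing column(s): {missing}")
        for col, levels in _META_COLUMNS.items():
            if levels is not None:
                bad = set(df[col].dropna().unique()) - set(levels)
                if bad:
                    raise ValueError(f"metadata column {col!r}: invalid value(s) {bad}")
        # at most one sample per subject per timepoint
        dup = df.groupby(["subject_id", "timepoint"]).size()
        if (dup > 1).any():
            offender = dup[dup > 1].index[0]
            raise ValueError(
                f"subject {offender[0]!r} has multiple {offender[1]!r} samples"
            )
        object.__setattr__(self, "data", df)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    def subjects(self) -> list[str]:
        return list(pd.unique(self.data["subject_id"]))

    def paired_subjects(self) -> list[str]:
        """Subjects with both a baseline and an end-of-study sample."""
        tp = self.data.groupby("subject_id")["timepoint"].agg(set)
        return [s for s, v in tp.items() if {"baseline", "end"} <= v]

    def sample_for(self, subject_id: str, timepoint: str) -> str:
        sel = self.data[
            (self.data["subject_id"] == subject_id)
            & (self.data["timepoint"] == timepoint)
        ]
        if len(sel) != 1:
            raise KeyError(f"no unique {timepoint} sample for subject {subject_id}")
        return sel.index[0]

    def subject_info(self) -> pd.DataFrame:
        """One row per subject with the subject-level covariates."""
        cols = ["arm", "sex", "age", "aspirin", "batch_mismatch",
                "outcome_any", "outcome_advanced"]
        return self.data.groupby("subject_id")[cols].first()

    def select(self, sample_ids: Sequence[str]) -> "CohortMetadata":
        return CohortMetadata(self.data.loc[list(sample_ids)])


# ---------------------------------------------------------------------------
# File I/O
# ---------------------------------------------------------------------------

def read_feature_table(path, orientation: str = "features") -> FeatureTable:
    """Read a dense TSV count matrix.

    Parameters
    ----------
    path : str or file-like
        Tab-separated matrix with a header row of ids; first column holds
        the ids of the other axis.
    orientation : {'features', 'samples'}
        ``'features'`` (canonical dialect): rows are features, columns are
        samples.  ``'samples'``: rows are samples.

    Raises
    ------
    FeatureTableError
        On duplicate ids (naming the id) or negative / non-numeric cells
        (naming the position).
    """
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str,
                     comment=None, skip_blank_lines=True)
    if df.index.has_duplicates:
        dupes = df.index[df.index.duplicated()].unique().tolist()
        raise FeatureTableError(f"duplicate id(s) in first column: {dupes}")
    if df.columns.has_duplicates:
        dupes = df.columns[df.columns.duplicated()].unique().tolist()
        raise FeatureTableError(f"duplicate id(s) in header: {dupes}")
    try:
        num = df.astype(float)
    except ValueError:
        for j, col in enumerate(df.columns):
            for i, v in enumerate(df[col]):
                try:
                    float(v)
                except (TypeError, ValueError):
                    raise FeatureTableError(
                        f"non-numeric cell {v!r} at row {df.index[i]!r}, "
                        f"column {col!r}"
                    ) from None
        raise
    if orientation == "features":
        num = num.T
    elif orientation != "samples":
        raise ValueError("orientation must be 'features' or 'samples'")
    num.index.name = None
    num.columns.name = None
    return FeatureTable(num)


def write_feature_table(table: FeatureTable, path, orientation: str = "features") -> None:
    """Write the canonical dense TSV dialect (features as rows by default)."""
    df = table.data.T if orientation == "features" else table.data
    df = df.copy()
    df.index.name = "#id"
    df.to_csv(path, sep="\t", lineterminator="\n")


def read_taxonomy(path) -> TaxonomyMap:
    """Read a two-column TSV ``feature_id <tab> lineage-string``."""
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    col = df.columns[0]
    return TaxonomyMap.from_strings(df[col].to_dict())


def write_taxonomy(tax: TaxonomyMap, path) -> None:
    s = pd.Series(tax.to_strings(), name="lineage")
    s.index.name = "#feature_id"
    s.to_csv(path, sep="\t", lineterminator="\n")


def read_tree(path) -> TreeNode:
    """Read a rooted newick tree whose tips are feature ids."""
    tree = TreeNode.read(str(path) if not hasattr(path, "read") else path)
    for node in tree.traverse(include_self=False):
        if node.length is None:
            node.length = 0.0
        if node.length < 0:
            raise ValueError(f"negative branch length at node {node.name!r}")
    return tree


def read_metadata(path) -> CohortMetadata:
    """Read the per-sample metadata TSV (first column = sample id)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    return CohortMetadata(df)


def write_metadata(meta: CohortMetadata, path) -> None:
    df = meta.data.copy()
    df.index.name = "#sample_id"
    df.to_csv(path, sep="\t", lineterminator="\n")


# ---------------------------------------------------------------------------
# Deterministic table manipulation
# ---------------------------------------------------------------------------

def prevalence_filter(
    table: FeatureTable, min_fraction: float
) -> tuple[FeatureTable, int]:
    """Drop features observed in fewer than ``floor(min_fraction * n)`` samples.

    "Observed" means a count of at least 1.  With ``min_fraction = 0.33`` and
    802 samples the integer threshold is 264.  Returns the filtered table and
    the threshold actually applied; samples are never dropped or reordered.
    """
    if not (0 < min_fraction <= 1):
        raise ValueError("min_fraction must be in (0, 1]")
    if table.n_samples == 0:
        raise ValueError("empty table")
    threshold = int(np.floor(min_fraction * table.n_samples))
    prevalence = (table.data > 0).sum(axis=0)
    keep = prevalence[prevalence >= threshold].index
    if len(keep) == 0:
        warnings.warn("prevalence filter removed every feature", stacklevel=2)
    return FeatureTable(table.data[list(keep)]), threshold


def collapse_taxonomy(
    table: FeatureTable, tax: TaxonomyMap, rank: str
) -> FeatureTable:
    """Sum features whose lineages agree through ``rank``.

    Features unresolved at ``rank`` collapse under their most specific known
    prefix (labelled with a trailing ``?``), mirroring the convention of
    showing unknown genera with their best-known parent.  Per-sample totals
    are conserved.
    """
    if rank not in RANKS:
        raise ValueError(f"rank must be one of {RANKS}")
    labels = {}
    for fid in table.feature_ids:
        if fid not in tax.lineages:
            raise KeyError(f"feature {fid!r} missing from taxonomy")
        labels[fid] = tax.group_label(fid, rank)
    grouped = table.data.T.groupby(
        pd.Series(labels), sort=True
    ).sum().T
    grouped.columns.name = None
    return FeatureTable(grouped)
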