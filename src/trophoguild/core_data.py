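"""Domain types, file I/O and gut-content standardization.

The analysis starts from individual-level gut-content records
(one row per individual x prey item, with the fraction of gut
volume/frequency that item represents), maps heterogeneous raw prey
labels onto a canonical set of 38 ecologically informative prey
groups, drops species with too few sampled guts, and averages
per-individual proportions into a consumer x prey-group diet matrix
whose rows sum to one.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from ._phylo import prune_to, read_tree, read_trees, tree_from_string  # noqa: F401

logger = logging.getLogger(__name__)

__all__ = [
    "PREY_GROUPS",
    "SchemaError",
    "ValidationError",
    "GUT_RECORD_COLUMNS",
    "read_gut_contents",
    "write_gut_records",
    "validate_gut_records",
    "PreyCrosswalk",
    "apply_crosswalk",
    "filter_min_guts",
    "DietMatrix",
    "build_diet_matrix",
    "read_diet_matrix",
    "read_species_attributes",
    "read_tree",
    "read_trees",
    "prune_to",
]

#: Canonical prey groups (38). Synthetic analog of the study's prey-group
#: table, reconstructed at the granularity described in the methods:
#: phylum/class for most taxa, order/superorder for crustaceans, plus the
#: non-taxonomic groups "detritus", "inorganic" and "zooplankton".
PREY_GROUPS: tuple[str, ...] = (
    "Actinopterygii", "Annelida", "Anthozoa", "Arachnida", "Asteroidea",
    "benthic autotroph", "Bivalvia", "Bryozoa", "Cephalopoda", "Cirripedia",
    "Crinoidea", "cyanobacteria", "Decapoda", "detritus", "Echinoidea",
    "Elasmobranchii", "Foraminifera", "Gastropoda", "Harpacticoida",
    "Hemichordata", "Holothuroidea", "inorganic", "Insecta", "Medusozoa",
    "Nematoda", "Nemertea", "Ophiuroidea", "Peracarida", "phytoplankton",
    "Platyhelminthes", "Polyplacophora", "Porifera", "Pycnogonida",
    "Scaphopoda", "Sipuncula", "Stomatopoda", "Tunicata", "zooplankton",
)

GUT_RECORD_COLUMNS = ("individual_id", "species", "location", "prey_item", "value")

_RAW_SUM_TOL = 1e-6


class SchemaError(ValueError):
    """A required column is missing or a table has the wrong shape."""


class ValidationError(ValueError):
    """Row-level contents violate an invariant."""


# ----------------------------------------------------------------------
# Gut-content records
# ----------------------------------------------------------------------

def read_gut_contents(path: str | Path, dialect: dict | None = None) -> pd.DataFrame:
    """Read a delimited gut-content table into the canonical record layout.

    ``dialect`` may override the separator (``sep``), map file column
    names onto the canonical ones (``columns: {canonical: file_name}``),
    and declare percentage-scaled values (``percent: true``), which are
    rescaled to fractions.
    """
    dialect = dict(dialect or {})
    sep = dialect.get("sep")
    df = pd.read_csv(path, sep=sep, engine="python" if sep is None else "c")
    if df.empty:
        raise SchemaError(f"empty gut-content table: {path}")
    colmap = dialect.get("columns", {})
    rename = {v: k for k, v in colmap.items()}
    df = df.rename(columns=rename)
    missing = [c for c in GUT_RECORD_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing required column(s): {missing}")
    df = df.loc[:, list(GUT_RECORD_COLUMNS)].copy()
    df["value"] = pd.to_numeric(df["value"])
    if dialect.get("percent", False):
        df["value"] = df["value"] / 100.0
    validate_gut_records(df)
    return df


def validate_gut_records(records: pd.DataFrame) -> None:
    missing = [c for c in GUT_RECORD_COLUMNS if c not in records.columns]
    if missing:
        raise SchemaError(f"missing required column(s): {missing}")
    neg = records.index[records["value"] < 0]
    if len(neg):
        raise ValidationError(f"negative value at row(s) {list(neg[:5])}")
    sums = records.groupby("individual_id")["value"].sum()
    bad = sums[sums > 1.0 + _RAW_SUM_TOL]
    if len(bad):
        raise ValidationError(
            f"per-individual values exceed 1: {dict(bad.head())}"
        )


def write_gut_records(records: pd.DataFrame, path: str | Path) -> None:
    records.loc[:, list(GUT_RECORD_COLUMNS)].to_csv(path, index=False)


# ----------------------------------------------------------------------
# Prey crosswalk
# ----------------------------------------------------------------------

@dataclass
class PreyCrosswalk:
    """Mapping from raw prey labels to canonical prey groups.

    A raw label maps to one or two groups with split weights summing
    to 1 (e.g. the historical "Algae & Detritus" label, divided equally
    between "detritus" and "benthic autotroph"), or is flagged for
    discard when non-informative or redundant.
    """

    mapping: dict[str, list[tuple[str, float]]] = field(default_factory=dict)
    discard: set[str] = field(default_factory=set)
    groups: tuple[str, ...] = PREY_GROUPS

    def __post_init__(self) -> None:
        known = set(self.groups)
        for label, targets in self.mapping.items():
            bad = [g for g, _ in targets if g not in known]
            if bad:
                raise ValidationError(f"crosswalk target(s) not canonical: {bad}")
            w = sum(w for _, w in targets)
            if abs(w - 1.0) > _RAW_SUM_TOL:
                raise ValidationError(
                    f"split weights for {label!r} sum to {w}, expected 1"
                )

    @classmethod
    def identity(cls) -> "PreyCrosswalk":
        """Crosswalk mapping each canonical group name to itself."""
        return cls(mapping={g: [(g, 1.0)] for g in PREY_GROUPS})

    @classmethod
    def read(cls, path: str | Path) -> "PreyCrosswalk":
        """Read a crosswalk CSV with columns prey_item, group, weight.

        An empty group (or the literal ``DISCARD``) flags the label for
        removal; repeated prey_item rows express splits.
        """
        df = pd.read_csv(path)
        for col in ("prey_item", "group"):
            if col not in df.columns:
                raise SchemaError(f"crosswalk missing column {col!r}")
        if "weight" not in df.columns:
            df["weight"] = 1.0
        df["weight"] = df["weight"].fillna(1.0)
        mapping: dict[str, list[tuple[str, float]]] = {}
        discard: set[str] = set()
        for label, sub in df.groupby("prey_item", sort=False):
            groups = sub["group"].fillna("DISCARD")
            if (groups == "DISCARD").any():
                discard.add(str(label))
            else:
                mapping[str(label)] = list(zip(groups, sub["weight"].astype(float)))
        return cls(mapping=mapping, discard=discard)

    def write(self, path: str | Path) -> None:
        rows = [
            {"prey_item": label, "group": g, "weight": w}
            for label, targets in self.mapping.items()
            for g, w in targets
        ]
        rows += [{"prey_item": label, "group": "DISCARD", "weight": 1.0}
                 for label in sorted(self.discard)]
        pd.DataFrame(rows).to_csv(path, index=False)


def apply_crosswalk(records: pd.DataFrame, xwalk: PreyCrosswalk) -> pd.DataFrame:
    """Map raw prey labels to canonical groups, expanding split labels.

    Discarded labels are dropped (downstream renormalization restores
    per-individual sums); any label neither mapped nor discarded is an
    error listing the offenders.
    """
    labels = set(records["prey_item"].unique())
    unknown = sorted(labels - set(xwalk.mapping) - xwalk.discard)
    if unknown:
        raise ValidationError(f"unmapped prey label(s): {unknown}")
    n_discarded = int(records["prey_item"].isin(xwalk.discard).sum())
    if n_discarded:
        logger.info("discarding %d record(s) with non-informative labels", n_discarded)
    kept = records[~records["prey_item"].isin(xwalk.discard)]
    out_rows = []
    for label, targets in xwalk.mapping.items():
        sub = kept[kept["prey_item"] == label]
        if sub.empty:
            continue
        for group, weight in targets:
            part = sub.copy()
            part["prey_item"] = group
            part["value"] = part["value"] * weight
            out_rows.append(part)
    if not out_rows:
        return kept.iloc[0:0].copy()
    out = pd.concat(out_rows, ignore_index=True)
    # merge duplicate (individual, group) rows created by many-to-one maps
    out = (
        out.groupby(["individual_id", "species", "location", "prey_item"],
                    as_index=False, sort=False)["value"].sum()
    )
    return out.loc[:, list(GUT_RECORD_COLUMNS)]


def filter_min_guts(records: pd.DataFrame, min_guts: int = 10) -> pd.DataFrame:
    """Keep only species sampled with at least ``min_guts`` individuals."""
    if min_guts < 1:
        raise ValueError("min_guts must be >= 1")
    counts = records.groupby("species")["individual_id"].nunique()
    keep = counts.index[counts >= min_guts]
    dropped = sorted(set(counts.index) - set(keep))
    if dropped:
        logger.info("dropping %d species below %d guts: %s",
                    len(dropped), min_guts, dropped[:10])
    out = records[records["species"].isin(keep)].reset_index(drop=True)
    if out.empty:
        logger.warning("no species retained at min_guts=%d", min_guts)
    return out


# ----------------------------------------------------------------------
# Diet matrix
# ----------------------------------------------------------------------

@dataclass
class DietMatrix:
    """Consumer x prey-group proportion matrix with row metadata.

    ``matrix`` rows are consumer nodes (species, or "species@location"
    when built per location) over the 38 canonical prey groups, each row
    summing to 1. ``meta`` records the number of guts behind each row
    and the location(s) pooled into it.
    """

    matrix: pd.DataFrame
    meta: pd.DataFrame

    def __post_init__(self) -> None:
        sums = self.matrix.sum(axis=1)
        if len(sums) and np.abs(sums - 1.0).max() > 1e-6:
            raise ValidationError("diet matrix rows must sum to 1")

    @property
    def consumers(self) -> list[str]:
        return list(self.matrix.index)

    def write(self, path: str | Path) -> None:
        out = self.matrix.copy()
        out.insert(0, "n_guts", self.meta["n_guts"])
        out.insert(1, "locations", self.meta["locations"])
        out.to_csv(path, index_label="consumer")


def read_diet_matrix(path: str | Path) -> DietMatrix:
    df = pd.read_csv(path, index_col="consumer")
    meta = df[["n_guts", "locations"]].copy()
    matrix = df.drop(columns=["n_guts", "locations"])
    return DietMatrix(matrix=matrix, meta=meta)


def build_diet_matrix(records: pd.DataFrame, by_location: bool = False) -> DietMatrix:
    """Average renormalized per-individual proportions into a diet matrix.

    Each individual's proportions are first renormalized to sum to 1
    (empty guts are excluded with a log note), then averaged with equal
    weight per individual within each consumer node. ``by_location``
    keys consumer nodes as species@location; otherwise individuals are
    pooled globally per species.
    """
    rec = records.copy()
    bad_groups = sorted(set(rec["prey_item"]) - set(PREY_GROUPS))
    if bad_groups:
        raise ValidationError(
            f"records contain non-canonical prey groups: {bad_groups[:5]}; "
            "run apply_crosswalk first"
        )
    totals = rec.groupby("individual_id")["value"].transform("sum")
    empty = totals <= 0
    if empty.any():
        n_empty = rec.loc[empty, "individual_id"].nunique()
        logger.info("excluding %d empty gut(s)", n_empty)
        rec = rec[~empty]
        totals = totals[~empty]
    rec["value"] = rec["value"] / totals

    if by_location:
        rec["consumer"] = rec["species"].astype(str) + "@" + rec["location"].astype(str)
    else:
        rec["consumer"] = rec["species"].astype(str)

    # per-individual vectors, then equal-weight mean per consumer
    indiv = rec.pivot_table(index=["consumer", "individual_id"],
                            columns="prey_item", values="value",
                            aggfunc="sum", fill_value=0.0)
    mat = indiv.groupby(level="consumer").mean()
    mat = mat.reindex(columns=list(PREY_GROUPS), fill_value=0.0)
    mat = mat.div(mat.sum(axis=1), axis=0)  # exact renormalization

    mat.index.name = "consumer"
    mat.columns.name = None

    n_guts = indiv.groupby(level="consumer").size().rename("n_guts")
    locs = (rec.groupby("consumer")["location"]
            .agg(lambda s: ";".join(sorted(set(map(str, s)))))
            .rename("locations"))
    meta = pd.concat([n_guts, locs], axis=1).loc[mat.index]
    return DietMatrix(matrix=mat, meta=meta)


# ----------------------------------------------------------------------
# Species attributes
# ----------------------------------------------------------------------

def read_species_attributes(path: str | Path) -> pd.DataFrame:
    """Read a species attribute table (species, max_size_cm, family)."""
    df = pd.read_csv(path)
    for col in ("species", "max_size_cm", "family"):
        if col not in df.columns:
            raise SchemaError(f"species attributes missing column {col!r}")
    if (df["max_size_cm"] <= 0).any():
        raise ValidationError("max_size_cm must be positive")
    return df.set_index("species")
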