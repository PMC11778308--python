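"""Reading, validating and aggregating taxonomic profile collections.

A *profile collection* is the tabular output of a marker-gene read profiler
(SingleM/Sandpiper style) condensed to one row per (metagenomic dataset,
taxon lineage) with a relative-abundance percentage, together with a map
from dataset accession to one of seven habitat categories. Detection of a
taxon in a dataset is encoded by the presence of a row with strictly
positive abundance; zero-abundance rows are dropped at load time.

Lineages follow the GTDB convention of rank-prefixed names
(``d__Bacteria; p__Acidobacteriota; ...``) from domain down to genus.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, fields, replace
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

logger = logging.getLogger(__name__)

#: Taxonomic ranks handled, shallowest first.
RANKS = ("domain", "phylum", "class", "order", "family", "genus")

_RANK_PREFIX = {
    "domain": "d__",
    "phylum": "p__",
    "class": "c__",
    "order": "o__",
    "family": "f__",
    "genus": "g__",
}
_PREFIX_RANK = {v: k for k, v in _RANK_PREFIX.items()}

# attribute names on TaxonLineage, same order as RANKS ("class" is reserved)
_RANK_ATTR = {
    "domain": "domain",
    "phylum": "phylum",
    "class": "class_",
    "order": "order",
    "family": "family",
    "genus": "genus",
}

#: The seven habitat categories over which distribution patterns are scored.
HABITATS = (
    "soil",
    "engineered",
    "freshwater",
    "host-associated",
    "marine",
    "non-marine saline and alkaline",
    "terrestrial non-soil",
)

#: Habitats pooled as "non-soil" in soil-vs-non-soil comparisons.
#: Host-associated datasets are excluded from these comparisons because of
#: their extreme overrepresentation in public archives.
NON_SOIL_COMPARATIVE_HABITATS = (
    "engineered",
    "freshwater",
    "marine",
    "non-marine saline and alkaline",
    "terrestrial non-soil",
)


class LineageError(ValueError):
    """Malformed or internally inconsistent lineage string."""


class ProfileValidationError(ValueError):
    """Profile collection violates a structural invariant."""


@dataclass(frozen=True)
class TaxonLineage:
    """A ranked lineage; empty string means unresolved at that rank.

    Ranks must be filled left to right: a resolved rank may never follow an
    unresolved one.
    """

    domain: str = ""
    phylum: str = ""
    class_: str = ""
    order: str = ""
    family: str = ""
    genus: str = ""

    def __post_init__(self) -> None:
        seen_empty = False
        for rank in RANKS:
            name = getattr(self, _RANK_ATTR[rank])
            if name == "":
                seen_empty = True
            elif seen_empty:
                raise LineageError(
                    f"rank '{rank}' is filled but a shallower rank is empty: {self!r}"
                )

    @classmethod
    def parse(cls, text: str) -> "TaxonLineage":
        """Parse a prefixed lineage string such as ``d__Bacteria; p__Foo``."""
        values: dict[str, str] = {}
        last_idx = -1
        for part in text.split(";"):
            part = part.strip()
            if part == "":
                continue
            prefix = part[:3]
            if prefix not in _PREFIX_RANK:
                raise LineageError(f"unknown rank prefix in field {part!r}")
            rank = _PREFIX_RANK[prefix]
            idx = RANKS.index(rank)
            if idx <= last_idx:
                raise LineageError(f"rank {rank!r} out of order or duplicated in {text!r}")
            last_idx = idx
            values[_RANK_ATTR[rank]] = part[3:].strip()
        if not values:
            raise LineageError(f"no rank fields found in {text!r}")
        return cls(**values)

    def render(self) -> str:
        """Canonical prefixed string; round-trips through :meth:`parse`."""
        parts = []
        for rank in RANKS:
            name = getattr(self, _RANK_ATTR[rank])
            if name == "":
                break
            parts.append(f"{_RANK_PREFIX[rank]}{name}")
        return "; ".join(parts)

    def depth(self) -> int:
        """Number of resolved ranks."""
        n = 0
        for rank in RANKS:
            if getattr(self, _RANK_ATTR[rank]) == "":
                break
            n += 1
        return n

    def resolved_at(self, rank: str) -> bool:
        _check_rank(rank)
        return getattr(self, _RANK_ATTR[rank]) != ""

    def truncate(self, rank: str) -> "TaxonLineage":
        """Drop all ranks deeper than ``rank``."""
        _check_rank(rank)
        keep = RANKS.index(rank) + 1
        values = {
            _RANK_ATTR[r]: getattr(self, _RANK_ATTR[r]) if i < keep else ""
            for i, r in enumerate(RANKS)
        }
        return TaxonLineage(**values)

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.render()


def _check_rank(rank: str) -> None:
    if rank not in RANKS:
        raise ValueError(f"unknown rank {rank!r}; expected one of {RANKS}")


def _check_habitats(labels: Iterable[str]) -> None:
    bad = sorted(set(labels) - set(HABITATS))
    if bad:
        raise ProfileValidationError(
            f"unknown habitat label(s) {bad}; allowed: {list(HABITATS)}"
        )


@dataclass
class ProfileCollection:
    """Per-dataset, per-taxon relative abundances plus habitat labels.

    Parameters
    ----------
    records
        DataFrame with columns ``dataset``, ``lineage`` (canonical prefixed
        string) and ``abundance`` (percentage, strictly positive). Absence
        of a taxon from a dataset is encoded by absence of the row. Extra
        columns (e.g. an ``unresolved`` flag added by aggregation) are
        carried through.
    habitat_of
        Series mapping every dataset accession to a habitat category. May
        contain datasets with no profile rows; those still count toward
        habitat denominators.
    """

    records: pd.DataFrame
    habitat_of: pd.Series

    def __post_init__(self) -> None:
        required = {"dataset", "lineage", "abundance"}
        missing = required - set(self.records.columns)
        if missing:
            raise ProfileValidationError(f"records missing column(s) {sorted(missing)}")
        self.habitat_of = pd.Series(self.habitat_of)
        self.habitat_of.index = self.habitat_of.index.astype(str)
        _check_habitats(self.habitat_of.unique())
        unlabelled = sorted(
            set(self.records["dataset"].astype(str)) - set(self.habitat_of.index)
        )
        if unlabelled:
            raise ProfileValidationError(
                f"datasets without a habitat label: {unlabelled[:10]}"
                + ("..." if len(unlabelled) > 10 else "")
            )
        dup = self.records.duplicated(subset=["dataset", "lineage"])
        if dup.any():
            rows = self.records.loc[dup, ["dataset", "lineage"]].head(5)
            raise ProfileValidationError(
                f"duplicate (dataset, lineage) pairs, e.g.:\n{rows}"
            )
        ab = self.records["abundance"]
        if (ab <= 0).any():
            raise ProfileValidationError("abundances must be strictly positive")
        if (ab > 100).any():
            raise ProfileValidationError("abundances are percentages and must be <= 100")

    # -- convenience -----------------------------------------------------
    @property
    def n_datasets(self) -> int:
        return int(self.habitat_of.size)

    def datasets_per_habitat(self) -> pd.Series:
        """Dataset counts per habitat, including datasets with no records."""
        counts = self.habitat_of.value_counts()
        return counts.reindex(list(HABITATS), fill_value=0)

    def taxa(self) -> list[str]:
        return sorted(self.records["lineage"].unique())

    def copy(self) -> "ProfileCollection":
        return ProfileCollection(self.records.copy(), self.habitat_of.copy())


def read_profiles(
    profile_table: str | Path,
    habitat_table: str | Path,
    *,
    dataset_col: str = "dataset",
    lineage_col: str = "lineage",
    abundance_col: str = "relative_abundance_pct",
    habitat_col: str = "habitat",
) -> ProfileCollection:
    """Load a profile TSV and habitat TSV into a validated collection.

    Zero-abundance rows are dropped (with a logged count): presence is any
    strictly positive relative abundance. Lineage strings are parsed and
    re-rendered so the stored form is canonical.
    """
    prof = pd.read_csv(profile_table, sep="\t", dtype={dataset_col: str})
    hab = pd.read_csv(habitat_table, sep="\t", dtype=str)
    for col in (dataset_col, lineage_col, abundance_col):
        if col not in prof.columns:
            raise ProfileValidationError(f"profile table lacks column {col!r}")
    for col in (dataset_col, habitat_col):
        if col not in hab.columns:
            raise ProfileValidationError(f"habitat table lacks column {col!r}")

    n_zero = int((prof[abundance_col] == 0).sum())
    if n_zero:
        logger.info("dropping %d zero-abundance row(s); absence is encoded by absence", n_zero)
        prof = prof[prof[abundance_col] > 0]

    records = pd.DataFrame(
        {
            "dataset": prof[dataset_col].astype(str),
            "lineage": [TaxonLineage.parse(t).render() for t in prof[lineage_col]],
            "abundance": prof[abundance_col].astype(float),
        }
    ).reset_index(drop=True)
    habitat_of = pd.Series(
        hab[habitat_col].values, index=hab[dataset_col].astype(str).values, name="habitat"
    )
    if habitat_of.index.duplicated().any():
        raise ProfileValidationError("duplicate dataset accessions in habitat table")
    return ProfileCollection(records, habitat_of)


def write_profiles(
    collection: ProfileCollection,
    profile_table: str | Path,
    habitat_table: str | Path,
) -> None:
    """Write a collection back out in the same TSV dialect it is read from."""
    out = collection.records.rename(columns={"abundance": "relative_abundance_pct"})
    out[["dataset", "lineage", "relative_abundance_pct"]].to_csv(
        profile_table, sep="\t", index=False
    )
    hab = collection.habitat_of.rename_axis("dataset").rename("habitat").reset_index()
    hab.to_csv(habitat_table, sep="\t", index=False)


def aggregate_to_rank(collection: ProfileCollection, rank: str) -> ProfileCollection:
    """Sum abundances of sub-lineages up to ``rank`` within each dataset.

    Lineages unresolved at ``rank`` are retained under their deepest resolved
    prefix and flagged via the ``unresolved`` column, so per-dataset total
    abundance is conserved exactly.
    """
    _check_rank(rank)
    lineages = {t: TaxonLineage.parse(t) for t in collection.records["lineage"].unique()}
    truncated = {t: lin.truncate(rank).render() for t, lin in lineages.items()}
    unresolved = {t: not lin.resolved_at(rank) for t, lin in lineages.items()}

    df = collection.records.copy()
    df["lineage"] = df["lineage"].map(truncated)
    df["unresolved"] = collection.records["lineage"].map(unresolved)
    agg = (
        df.groupby(["dataset", "lineage"], as_index=False)
        .agg(abundance=("abundance", "sum"), unresolved=("unresolved", "any"))
    )
    return ProfileCollection(agg, collection.habitat_of.copy())
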