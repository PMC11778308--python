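"""Genome-level feature table and binary metabolic-trait matrix.

One row per genome: accession, taxonomic class, habitat of origin, and the
14 analysis features compared downstream — five general genomic features
(genome size, GC%, coding density, mean gene length, protein count), two
phage infection/immunity features (CRISPR count, viral contig count), three
secretory-arsenal features (CAZyme, peptidase, BGC counts), three predicted
physiological optima (growth temperature, pH, oxygen preference) and the
predicted life-history strategy. The metabolic-trait matrix is the 0/1
presence/absence output of an upstream annotator, consumed as a table.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .profile_io import HABITATS

logger = logging.getLogger(__name__)

#: The 12 continuous analysis features (column name -> human description).
CONTINUOUS_FEATURES = (
    "genome_size",
    "gc_pct",
    "coding_density",
    "mean_gene_length",
    "protein_count",
    "crispr_count",
    "viral_contig_count",
    "cazyme_count",
    "peptidase_count",
    "bgc_count",
    "pred_ogt",
    "pred_ph",
)

#: Categorical analysis features: oxygen preference (2-level) and
#: life-history strategy (3-level).
CATEGORICAL_FEATURES = ("pred_aerobe", "life_history")

ANALYSIS_FEATURES = CONTINUOUS_FEATURES + CATEGORICAL_FEATURES

AEROBE_LEVELS = ("aerobic", "anaerobic")
LIFE_HISTORY_LEVELS = ("ruderal", "competitor", "scarcity")

#: Default soil-preference grouping of classes, used for SPL-vs-NSPL
#: summaries; overridable wherever it is consumed.
DEFAULT_SPL_GROUPS: Mapping[str, str] = {
    "Terriglobia": "SPL",
    "Vicinamibacteria": "SPL",
    "Blastocatellia": "SPL",
    "Thermoanaerobaculia": "SPL",
    "Holophagae": "NSPL",
    "Aminicenantia": "NSPL",
}


class GenomeTableError(ValueError):
    """Structural problem in genome features or traits."""


@dataclass
class GenomeTable:
    """Validated genome records plus optional binary trait matrix.

    ``records`` is indexed by accession with at least ``class_`` and
    ``habitat`` columns; whichever analysis features are present are used
    downstream (missing values allowed, handled per-feature). ``traits`` is
    an accession x trait 0/1 DataFrame (may be empty).
    """

    records: pd.DataFrame
    traits: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        for col in ("class_", "habitat"):
            if col not in self.records.columns:
                raise GenomeTableError(f"genome records lack column {col!r}")
        if self.records.index.duplicated().any():
            dups = self.records.index[self.records.index.duplicated()].unique()[:5]
            raise GenomeTableError(f"duplicate genome accession(s): {list(dups)}")
        bad_hab = sorted(set(self.records["habitat"].dropna()) - set(HABITATS))
        if bad_hab:
            raise GenomeTableError(f"unknown habitat label(s) in genome table: {bad_hab}")
        if self.traits is not None and len(self.traits):
            extra = sorted(set(self.traits.index) - set(self.records.index))
            if extra:
                raise GenomeTableError(
                    f"trait matrix has accessions absent from records: {extra[:5]}"
                )
            vals = self.traits.to_numpy()
            ok = np.isin(vals[~pd.isna(vals)], [0, 1])
            if not ok.all():
                bad = np.argwhere(~np.isin(vals, [0, 1]) & ~pd.isna(vals))
                r, c = bad[0]
                raise GenomeTableError(
                    "trait values must be 0/1; first offending cell "
                    f"({self.traits.index[r]}, {self.traits.columns[c]}) = {vals[r, c]!r}"
                )

    @property
    def n_genomes(self) -> int:
        return int(len(self.records))

    def classes(self) -> list[str]:
        return sorted(self.records["class_"].unique())

    def copy(self) -> "GenomeTable":
        return GenomeTable(
            self.records.copy(), None if self.traits is None else self.traits.copy()
        )


def load_genome_table(
    features: str | Path,
    traits: str | Path | None = None,
    *,
    accession_col: str = "accession",
) -> GenomeTable:
    """Read a genome feature TSV and optional long-format trait TSV.

    The trait file has columns ``accession``, ``trait``, ``value`` with
    strictly binary values; it is pivoted to a wide 0/1 matrix. Rows with
    missing feature values are retained (missing markers) and logged.
    """
    df = pd.read_csv(features, sep="\t", dtype={accession_col: str})
    if accession_col not in df.columns:
        raise GenomeTableError(f"feature table lacks column {accession_col!r}")
    df = df.set_index(accession_col)
    present = [c for c in CONTINUOUS_FEATURES if c in df.columns]
    for col in present:
        df[col] = pd.to_numeric(df[col], errors="raise")
    n_missing = int(df[present].isna().sum().sum()) if present else 0
    if n_missing:
        logger.info("genome table has %d missing feature value(s); kept as NA", n_missing)
    _range_checks(df)

    trait_matrix = None
    if traits is not None:
        long = pd.read_csv(traits, sep="\t", dtype={"accession": str, "trait": str})
        for col in ("accession", "trait", "value"):
            if col not in long.columns:
                raise GenomeTableError(f"trait table lacks column {col!r}")
        bad = long[~long["value"].isin([0, 1])]
        if len(bad):
            row = bad.iloc[0]
            raise GenomeTableError(
                f"trait values must be 0/1; offending cell "
                f"({row['accession']}, {row['trait']}) = {row['value']!r}"
            )
        trait_matrix = long.pivot_table(
            index="accession", columns="trait", values="value", aggfunc="first"
        )
    return GenomeTable(df, trait_matrix)


def _range_checks(df: pd.DataFrame) -> None:
    checks = {
        "gc_pct": (0, 100),
        "coding_density": (0, 100),
        "pred_ph": (0, 14),
    }
    for col, (lo, hi) in checks.items():
        if col in df.columns:
            vals = df[col].dropna()
            if ((vals < lo) | (vals > hi)).any():
                raise GenomeTableError(f"column {col!r} outside [{lo}, {hi}]")
    count_cols = [
        c
        for c in (
            "genome_size",
            "protein_count",
            "crispr_count",
            "viral_contig_count",
            "cazyme_count",
            "peptidase_count",
            "bgc_count",
        )
        if c in df.columns
    ]
    for col in count_cols:
        vals = df[col].dropna()
        if (vals < 0).any():
            raise GenomeTableError(f"column {col!r} contains negative counts")


def filter_for_comparison(
    table: GenomeTable,
    min_genomes_per_class: int = 100,
    min_habitats_per_class: int = 5,
) -> tuple[GenomeTable, pd.DataFrame]:
    """Keep only genomes of classes meeting both sampling thresholds.

    A class is retained when it has at least ``min_genomes_per_class``
    genomes AND those genomes originate from at least
    ``min_habitats_per_class`` of the seven habitats. Returns the filtered
    table and a per-class audit frame (kept flag and reasons).
    """
    rec = table.records
    audit_rows = []
    kept_classes = []
    for cls, sub in rec.groupby("class_", sort=True):
        n = int(len(sub))
        n_hab = int(sub["habitat"].nunique())
        reasons = []
        if n < min_genomes_per_class:
            reasons.append(f"n_genomes {n} < {min_genomes_per_class}")
        if n_hab < min_habitats_per_class:
            reasons.append(f"n_habitats {n_hab} < {min_habitats_per_class}")
        kept = not reasons
        if kept:
            kept_classes.append(cls)
        audit_rows.append(
            {
                "class_": cls,
                "n_genomes": n,
                "n_habitats": n_hab,
                "kept": kept,
                "reason": "; ".join(reasons),
            }
        )
    audit = pd.DataFrame(audit_rows)
    if not kept_classes:
        raise GenomeTableError(
            "no class passes the comparison filter "
            f"(>= {min_genomes_per_class} genomes from >= {min_habitats_per_class} habitats)"
        )
    mask = rec["class_"].isin(kept_classes)
    new_records = rec[mask].copy()
    new_traits = None
    if table.traits is not None:
        new_traits = table.traits.loc[table.traits.index.isin(new_records.index)].copy()
    return GenomeTable(new_records, new_traits), audit


def summarize_by_class_habitat(table: GenomeTable) -> pd.DataFrame:
    """Class x habitat genome counts with a ``total`` column; row sums equal
    class totals and the grand sum equals the number of records."""
    rec = table.records
    if rec.empty:
        return pd.DataFrame(columns=list(HABITATS) + ["total"])
    counts = (
        rec.groupby(["class_", "habitat"]).size().unstack(fill_value=0)
        .reindex(columns=list(HABITATS), fill_value=0)
    )
    counts["total"] = counts.sum(axis=1)
    return counts
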