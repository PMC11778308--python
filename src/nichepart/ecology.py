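"""Habitat ubiquity, preference and abundance metrics, and the cutoff-based
soil-preference and generalist/specialist classifications.

Three criteria are scored per taxon:

1. **ubiquity** — the percentage of datasets within a habitat category in
   which the taxon is detected (any non-zero relative abundance);
2. **preference** — the ratio of soil ubiquity to pooled non-soil ubiquity
   (host-associated datasets excluded from both sides);
3. **relative abundance** — the mean relative-abundance percentage over the
   datasets in which the taxon is detected, compared between soil and
   pooled non-soil datasets.

A lineage passing strict cutoffs on all three (soil ubiquity > 75%,
preference ratio > 4, soil/non-soil abundance ratio > 1) is summarised as a
soil-preferring lineage (SPL); one failing all three as non-soil-preferring
(NSPL); mixtures are intermediate; lineages seen in fewer than a rare-taxon
cutoff of studies are reported as rare.

Habitat breadth is scored separately: a taxon detected in all seven habitat
categories (host-associated included) is a generalist, otherwise a
specialist; a genome-based variant calls a taxon generalist when its genomes
originate from two or more habitats.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .profile_io import (
    HABITATS,
    NON_SOIL_COMPARATIVE_HABITATS,
    ProfileCollection,
    aggregate_to_rank,
)

__all__ = [
    "HabitatStats",
    "EcologyMetrics",
    "PreferenceCutoffs",
    "PreferenceCall",
    "BreadthCall",
    "compute_metrics",
    "classify_preference",
    "classify_breadth",
    "classify_breadth_from_genomes",
    "generalist_fraction",
    "genus_richness_summary",
    "metrics_frame",
    "round_half_up",
    "ubiquity_pct",
]


def round_half_up(x: float, ndigits: int = 1) -> float:
    """Round with ties away from zero (0.05 -> 0.1), the convention used in
    reported percentages; ``float`` round() would round half to even."""
    if x is None:
        return x
    x = float(x)
    if math.isnan(x) or math.isinf(x):
        return x
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def ubiquity_pct(n_detected: int, n_datasets: int) -> float:
    """Percentage of datasets in which a taxon is detected.

    Returns NaN when there are no datasets (undefined, not zero).
    """
    if n_datasets < 0 or n_detected < 0 or n_detected > n_datasets:
        raise ValueError("need 0 <= n_detected <= n_datasets")
    if n_datasets == 0:
        return float("nan")
    return 100.0 * n_detected / n_datasets


@dataclass
class HabitatStats:
    n_datasets: int
    n_detected: int
    ubiquity_pct: float  # NaN when the habitat has no datasets
    mean_abundance_pct: float  # NaN when never detected


@dataclass
class EcologyMetrics:
    """Per-taxon distribution metrics over the seven habitat categories.

    Soil/non-soil comparative fields pool datasets (detections over datasets),
    never average per-habitat percentages, and exclude the host-associated
    category from the non-soil side.
    """

    taxon: str
    per_habitat: dict[str, HabitatStats]
    soil_ubiquity_pct: float
    nonsoil_ubiquity_pct: float
    preference_ratio: float  # inf when non-soil ubiquity is 0 but soil > 0
    soil_mean_abundance_pct: float
    nonsoil_mean_abundance_pct: float
    abundance_ratio: float
    n_studies_total: int
    flags: list[str] = field(default_factory=list)


@dataclass(frozen=True)
class PreferenceCutoffs:
    """Strict (>) cutoffs for the three soil-preference criteria."""

    ubiquity: float = 75.0
    ratio: float = 4.0
    abundance: float = 1.0
    abundance_ratio: float = 1.0


@dataclass
class PreferenceCall:
    taxon: str
    ubiquitous: bool
    soil_preferring: bool
    soil_enriched: bool
    abundant_in_soil: bool  # soil mean abundance above the abundance cutoff
    summary: str  # SPL | NSPL | intermediate | rare
    flags: list[str] = field(default_factory=list)


@dataclass
class BreadthCall:
    taxon: str
    n_habitats_detected: int
    n_studies_total: int
    call: str  # generalist | specialist | rare-excluded
    call_ignoring_rarity: str  # generalist | specialist


def _ratio(num: float, den: float, flags: list[str], flag: str) -> float:
    if math.isnan(num) or math.isnan(den):
        return float("nan")
    if den == 0:
        if num > 0:
            flags.append(flag)
            return float("inf")
        return float("nan")
    return num / den


def compute_metrics(
    collection: ProfileCollection,
    rank: str | None = None,
    *,
    detection_conditional_abundance: bool = True,
) -> list[EcologyMetrics]:
    """Compute ubiquity, preference and abundance metrics for every taxon.

    Parameters
    ----------
    collection
        Profile collection; aggregated to ``rank`` first when given.
    detection_conditional_abundance
        When True (default), mean abundance averages over datasets where the
        taxon is detected; when False, over all datasets of the habitat
        (absences counted as zero).
    """
    if collection.records.empty:
        raise ValueError("empty profile collection")
    if rank is not None:
        collection = aggregate_to_rank(collection, rank)

    hab_counts = collection.datasets_per_habitat()
    df = collection.records.copy()
    df["habitat"] = df["dataset"].map(collection.habitat_of)

    nonsoil = list(NON_SOIL_COMPARATIVE_HABITATS)
    n_soil = int(hab_counts["soil"])
    n_nonsoil = int(hab_counts[nonsoil].sum())

    out: list[EcologyMetrics] = []
    for taxon, sub in df.groupby("lineage", sort=True):
        per_habitat: dict[str, HabitatStats] = {}
        det = sub.groupby("habitat", sort=False)["abundance"].agg(["size", "mean", "sum"])
        for hab in HABITATS:
            n_d = int(hab_counts[hab])
            if hab in det.index:
                n_det = int(det.loc[hab, "size"])
                if detection_conditional_abundance:
                    mean_ab = float(det.loc[hab, "mean"])
                else:
                    mean_ab = float(det.loc[hab, "sum"]) / n_d if n_d else float("nan")
            else:
                n_det = 0
                mean_ab = float("nan") if detection_conditional_abundance else 0.0
                if n_d == 0:
                    mean_ab = float("nan")
            per_habitat[hab] = HabitatStats(n_d, n_det, ubiquity_pct(n_det, n_d), mean_ab)

        flags: list[str] = []
        soil = per_habitat["soil"]
        det_nonsoil = sum(per_habitat[h].n_detected for h in nonsoil)
        soil_ub = ubiquity_pct(soil.n_detected, n_soil)
        nonsoil_ub = ubiquity_pct(det_nonsoil, n_nonsoil)

        ns_mask = sub["habitat"].isin(nonsoil)
        if detection_conditional_abundance:
            soil_mean = soil.mean_abundance_pct
            ns_ab = sub.loc[ns_mask, "abundance"]
            nonsoil_mean = float(ns_ab.mean()) if len(ns_ab) else float("nan")
        else:
            soil_mean = soil.mean_abundance_pct
            nonsoil_mean = (
                float(sub.loc[ns_mask, "abundance"].sum()) / n_nonsoil
                if n_nonsoil
                else float("nan")
            )

        pref = _ratio(
            0.0 if math.isnan(soil_ub) else soil_ub,
            0.0 if math.isnan(nonsoil_ub) else nonsoil_ub,
            flags,
            "preference-denominator-zero",
        )
        ab_ratio = _ratio(
            soil_mean if not math.isnan(soil_mean) else float("nan"),
            nonsoil_mean if not math.isnan(nonsoil_mean) else 0.0,
            flags,
            "abundance-denominator-zero",
        )
        if sub["unresolved"].any() if "unresolved" in sub.columns else False:
            flags.append("unresolved-at-rank")

        out.append(
            EcologyMetrics(
                taxon=taxon,
                per_habitat=per_habitat,
                soil_ubiquity_pct=soil_ub,
                nonsoil_ubiquity_pct=nonsoil_ub,
                preference_ratio=pref,
                soil_mean_abundance_pct=soil_mean,
                nonsoil_mean_abundance_pct=nonsoil_mean,
                abundance_ratio=ab_ratio,
                n_studies_total=int(len(sub)),
                flags=flags,
            )
        )
    return out


def classify_preference(
    metrics: EcologyMetrics,
    cutoffs: PreferenceCutoffs = PreferenceCutoffs(),
    rare_cutoff: int = 250,
) -> PreferenceCall:
    """Apply the strict three-criterion soil-preference classification.

    SPL requires all three of: soil ubiquity > 75%, soil/non-soil ubiquity
    ratio > 4, and soil/non-soil mean-abundance ratio > 1; NSPL requires all
    three to fail. Taxa detected in fewer than ``rare_cutoff`` studies are
    summarised as rare regardless of the component calls.
    """
    flags = list(metrics.flags)
    soil_ub = metrics.soil_ubiquity_pct
    ubiquitous = (not math.isnan(soil_ub)) and soil_ub > cutoffs.ubiquity
    pref = metrics.preference_ratio
    soil_preferring = (not math.isnan(pref)) and pref > cutoffs.ratio
    ab_ratio = metrics.abundance_ratio
    soil_enriched = (not math.isnan(ab_ratio)) and ab_ratio > cutoffs.abundance_ratio
    soil_mean = metrics.soil_mean_abundance_pct
    abundant = (not math.isnan(soil_mean)) and soil_mean > cutoffs.abundance

    if metrics.n_studies_total < rare_cutoff:
        summary = "rare"
    elif ubiquitous and soil_preferring and soil_enriched:
        summary = "SPL"
    elif not (ubiquitous or soil_preferring or soil_enriched):
        summary = "NSPL"
    else:
        summary = "intermediate"
    return PreferenceCall(
        taxon=metrics.taxon,
        ubiquitous=ubiquitous,
        soil_preferring=soil_preferring,
        soil_enriched=soil_enriched,
        abundant_in_soil=abundant,
        summary=summary,
        flags=flags,
    )


def classify_breadth(
    collection: ProfileCollection,
    rank: str | None = None,
    min_studies: int = 250,
) -> list[BreadthCall]:
    """Profile-based habitat breadth: generalist iff detected in all seven
    habitat categories (host-associated included); taxa detected in fewer
    than ``min_studies`` datasets are reported as rare-excluded, with the
    unfiltered call alongside."""
    if rank is not None:
        collection = aggregate_to_rank(collection, rank)
    df = collection.records.copy()
    df["habitat"] = df["dataset"].map(collection.habitat_of)
    out = []
    for taxon, sub in df.groupby("lineage", sort=True):
        n_hab = int(sub["habitat"].nunique())
        n_total = int(len(sub))
        raw = "generalist" if n_hab == len(HABITATS) else "specialist"
        call = "rare-excluded" if n_total < min_studies else raw
        out.append(BreadthCall(taxon, n_hab, n_total, call, raw))
    return out


def classify_breadth_from_genomes(
    genomes,
    rank: str = "class",
    min_genomes: int = 5,
) -> list[BreadthCall]:
    """Genome-based habitat breadth: a taxon is a generalist when its genome
    representatives originate from two or more habitat categories.

    ``genomes`` is a :class:`~nichepart.genome_features.GenomeTable`. With
    the default ``rank='class'`` taxa are the genome classes; other ranks
    require a ``lineage`` column in the records.
    """
    from .profile_io import TaxonLineage  # local to avoid cycle at import

    records = genomes.records
    if rank == "class" and "lineage" not in records.columns:
        taxon_of = records["class_"]
    else:
        if "lineage" not in records.columns:
            raise ValueError(
                f"breadth at rank {rank!r} requires a 'lineage' column in the genome table"
            )
        taxon_of = records["lineage"].map(
            lambda t: TaxonLineage.parse(t).truncate(rank).render()
        )
    df = pd.DataFrame({"taxon": taxon_of, "habitat": records["habitat"]})
    out = []
    for taxon, sub in df.groupby("taxon", sort=True):
        n_hab = int(sub["habitat"].nunique())
        n = int(len(sub))
        raw = "generalist" if n_hab >= 2 else "specialist"
        call = "rare-excluded" if n < min_genomes else raw
        out.append(BreadthCall(str(taxon), n_hab, n, call, raw))
    return out


def generalist_fraction(calls: Sequence[BreadthCall], exclude_rare: bool = True) -> float:
    """Percentage of taxa called generalist, optionally dropping rare-excluded
    taxa from the denominator (NaN when no taxa remain)."""
    if exclude_rare:
        kept = [c for c in calls if c.call != "rare-excluded"]
        if not kept:
            return float("nan")
        return 100.0 * sum(c.call == "generalist" for c in kept) / len(kept)
    if not calls:
        return float("nan")
    return 100.0 * sum(c.call_ignoring_rarity == "generalist" for c in calls) / len(calls)


def genus_richness_summary(
    genus_counts: Mapping[str, int], groups: Mapping[str, str]
) -> pd.DataFrame:
    """Mean and sample (n-1) SD of genus counts per preference group.

    ``genus_counts`` maps taxon (e.g. class) name to its number of genera;
    ``groups`` maps taxon name to a group label (e.g. SPL / NSPL / moderate).
    """
    rows = []
    by_group: dict[str, list[int]] = {}
    for taxon, count in genus_counts.items():
        if taxon in groups:
            by_group.setdefault(groups[taxon], []).append(count)
    for group in sorted(by_group):
        vals = np.asarray(by_group[group], dtype=float)
        rows.append(
            {
                "group": group,
                "n": len(vals),
                "mean": float(vals.mean()),
                "sd": float(vals.std(ddof=1)) if len(vals) > 1 else float("nan"),
            }
        )
    return pd.DataFrame(rows)


def metrics_frame(metrics: Iterable[EcologyMetrics]) -> pd.DataFrame:
    """Flatten metrics into one row per taxon for TSV export."""
    rows = []
    for m in metrics:
        row: dict[str, object] = {
            "taxon": m.taxon,
            "soil_ubiquity_pct": m.soil_ubiquity_pct,
            "nonsoil_ubiquity_pct": m.nonsoil_ubiquity_pct,
            "preference_ratio": m.preference_ratio,
            "soil_mean_abundance_pct": m.soil_mean_abundance_pct,
            "nonsoil_mean_abundance_pct": m.nonsoil_mean_abundance_pct,
            "abundance_ratio": m.abundance_ratio,
            "n_studies_total": m.n_studies_total,
            "flags": ";".join(m.flags),
        }
        for hab, st in m.per_habitat.items():
            key = hab.replace(" ", "_")
            row[f"n_datasets[{key}]"] = st.n_datasets
            row[f"n_detected[{key}]"] = st.n_detected
            row[f"ubiquity_pct[{key}]"] = st.ubiquity_pct
            row[f"mean_abundance_pct[{key}]"] = st.mean_abundance_pct
        rows.append(row)
    return pd.DataFrame(rows)
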