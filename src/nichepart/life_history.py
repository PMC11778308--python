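"""Genomic-investment life-history classification.

Two investment indices summarise a genome's ecological strategy:

* **regulatory index** — transcription-factor count divided by total gene
  count (investment in regulatory flexibility);
* **acquisition index** — secreted CAZymes + secreted proteases + secreted
  lipases/hydrolases + biosynthetic gene clusters, divided by membrane
  transporter count (investment in resource acquisition).

A three-centroid model (ruderal / competitor / scarcity) is trained by
k-means on a small labelled training set in z-scored index space; new
genomes are assigned to the nearest trained centroid. The two indices
differ by orders of magnitude, so per-axis standardisation (fitted on the
training set) is applied before clustering and can be switched off.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

STRATEGIES = ("ruderal", "competitor", "scarcity")
#: Fixed tie-break order for equidistant assignments.
TIE_ORDER = ("competitor", "ruderal", "scarcity")


class TrainingError(ValueError):
    """Training set unsuitable for fitting the strategy model."""


@dataclass
class InvestmentProfile:
    accession: str
    tf_count: int
    total_genes: int
    secreted_cazymes: int
    secreted_proteases: int
    secreted_lipases: int
    bgc_count: int
    transporter_count: int
    regulatory_index: float = float("nan")
    acquisition_index: float = float("nan")
    flags: list[str] = field(default_factory=list)

    @property
    def defined(self) -> bool:
        return not self.flags


def compute_indices(
    accession: str,
    *,
    tf_count: int,
    total_genes: int,
    secreted_cazymes: int,
    secreted_proteases: int,
    secreted_lipases: int,
    bgc_count: int,
    transporter_count: int,
) -> InvestmentProfile:
    """Compute both investment indices from raw annotation counts.

    Zero denominators (no genes, no transporters) yield a flagged profile,
    never a silent zero; negative counts are rejected.
    """
    counts = {
        "tf_count": tf_count,
        "total_genes": total_genes,
        "secreted_cazymes": secreted_cazymes,
        "secreted_proteases": secreted_proteases,
        "secreted_lipases": secreted_lipases,
        "bgc_count": bgc_count,
        "transporter_count": transporter_count,
    }
    for name, v in counts.items():
        if v < 0:
            raise ValueError(f"{name} must be nonnegative, got {v}")
    flags = []
    if total_genes == 0:
        flags.append("zero-total-genes")
        reg = float("nan")
    else:
        reg = tf_count / total_genes
    if transporter_count == 0:
        flags.append("zero-transporters")
        acq = float("nan")
    else:
        acq = (secreted_cazymes + secreted_proteases + secreted_lipases + bgc_count) / (
            transporter_count
        )
    return InvestmentProfile(
        accession=accession,
        **counts,
        regulatory_index=reg,
        acquisition_index=acq,
        flags=flags,
    )


def compute_indices_table(counts: pd.DataFrame) -> pd.DataFrame:
    """Vectorised index computation over a counts table.

    Expects the raw count columns of :func:`compute_indices` plus an
    ``accession`` column; returns accession, both indices and a ``defined``
    flag column.
    """
    out = pd.DataFrame({"accession": counts["accession"].astype(str)})
    genes = counts["total_genes"].astype(float)
    transp = counts["transporter_count"].astype(float)
    out["regulatory_index"] = np.where(genes > 0, counts["tf_count"] / genes, np.nan)
    acq_num = (
        counts["secreted_cazymes"]
        + counts["secreted_proteases"]
        + counts["secreted_lipases"]
        + counts["bgc_count"]
    )
    out["acquisition_index"] = np.where(transp > 0, acq_num / transp, np.nan)
    out["defined"] = (genes > 0) & (transp > 0)
    return out


@dataclass
class StrategyModel:
    """Three labelled centroids in (regulatory, acquisition) index space.

    Centroids are stored in standardised coordinates together with the
    invertible per-axis scaling fitted on the training set.
    """

    centroids: np.ndarray  # (3, 2) in standardised space
    labels: tuple[str, str, str]
    scale_mean: np.ndarray  # (2,)
    scale_sd: np.ndarray  # (2,)
    seed: int
    standardise: bool = True

    def transform(self, points: np.ndarray) -> np.ndarray:
        points = np.atleast_2d(np.asarray(points, dtype=float))
        if self.standardise:
            return (points - self.scale_mean) / self.scale_sd
        return points

    def centroids_raw(self) -> np.ndarray:
        if self.standardise:
            return self.centroids * self.scale_sd + self.scale_mean
        return self.centroids

    def to_json(self, path: str | Path) -> None:
        payload = {
            "centroids": self.centroids.tolist(),
            "labels": list(self.labels),
            "scale_mean": self.scale_mean.tolist(),
            "scale_sd": self.scale_sd.tolist(),
            "seed": self.seed,
            "standardise": self.standardise,
        }
        Path(path).write_text(json.dumps(payload, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "StrategyModel":
        d = json.loads(Path(path).read_text())
        return cls(
            centroids=np.asarray(d["centroids"], dtype=float),
            labels=tuple(d["labels"]),
            scale_mean=np.asarray(d["scale_mean"], dtype=float),
            scale_sd=np.asarray(d["scale_sd"], dtype=float),
            seed=int(d["seed"]),
            standardise=bool(d["standardise"]),
        )


def train_model(
    training: pd.DataFrame, seed: int = 0, *, standardise: bool = True
) -> StrategyModel:
    """Fit the three-centroid model on a labelled training table.

    ``training`` needs columns ``regulatory_index``, ``acquisition_index``
    and ``label``. Rows are sorted canonically before fitting so the model
    is invariant to input row order; k-means uses multiple seeded restarts.
    Each centroid is labelled by the majority label of its members (ties
    broken by the label of the training point nearest the centroid); the
    three centroid labels must come out distinct.
    """
    required = {"regulatory_index", "acquisition_index", "label"}
    missing = required - set(training.columns)
    if missing:
        raise TrainingError(f"training table lacks column(s) {sorted(missing)}")
    df = training[["regulatory_index", "acquisition_index", "label"]].copy()
    if df[["regulatory_index", "acquisition_index"]].isna().any().any():
        raise TrainingError("training indices contain missing values")
    labels_present = sorted(df["label"].unique())
    unknown = set(labels_present) - set(STRATEGIES)
    if unknown:
        raise TrainingError(f"unknown strategy label(s) {sorted(unknown)}")
    if len(labels_present) < 3:
        raise TrainingError(
            f"training set must span all three strategies, got {labels_present}"
        )
    # canonical row order -> deterministic, order-invariant fit
    df = df.sort_values(
        ["regulatory_index", "acquisition_index", "label"], kind="mergesort"
    ).reset_index(drop=True)

    X = df[["regulatory_index", "acquisition_index"]].to_numpy(dtype=float)
    mean = X.mean(axis=0)
    sd = X.std(axis=0, ddof=0)
    if standardise:
        if (sd == 0).any():
            raise TrainingError("an index axis is constant; cannot standardise")
        Z = (X - mean) / sd
    else:
        Z = X.copy()

    km = KMeans(n_clusters=3, n_init=10, random_state=seed).fit(Z)
    assign = km.labels_
    centroid_labels: list[str] = []
    for c in range(3):
        members = df.loc[assign == c, "label"]
        if members.empty:
            raise TrainingError("k-means produced an empty cluster")
        counts = members.value_counts()
        top = counts[counts == counts.max()].index.tolist()
        if len(top) == 1:
            centroid_labels.append(top[0])
        else:
            # tie: take the label of the member point nearest the centroid
            member_idx = np.flatnonzero(assign == c)
            dists = np.linalg.norm(Z[member_idx] - km.cluster_centers_[c], axis=1)
            for i in np.argsort(dists, kind="stable"):
                lab = df.loc[member_idx[i], "label"]
                if lab in top:
                    centroid_labels.append(lab)
                    break
    if len(set(centroid_labels)) != 3:
        raise TrainingError(
            "clusters do not separate the three strategies "
            f"(centroid labels {centroid_labels}); provide a cleaner training set"
        )
    order = np.argsort([STRATEGIES.index(lab) for lab in centroid_labels])
    return StrategyModel(
        centroids=km.cluster_centers_[order],
        labels=tuple(centroid_labels[i] for i in order),
        scale_mean=mean,
        scale_sd=sd,
        seed=seed,
        standardise=standardise,
    )


def assign_strategy(
    model: StrategyModel, regulatory_index: float, acquisition_index: float
) -> tuple[str, bool]:
    """Nearest-centroid strategy for one genome; returns (label, tie_flag).

    Equidistant points break ties by the fixed order competitor < ruderal <
    scarcity and set the tie flag. Undefined indices are unassignable.
    """
    if math.isnan(regulatory_index) or math.isnan(acquisition_index):
        raise ValueError("profile has undefined indices; unassignable")
    z = model.transform([[regulatory_index, acquisition_index]])[0]
    d = np.linalg.norm(model.centroids - z, axis=1)
    dmin = d.min()
    tied = [model.labels[i] for i in range(3) if d[i] <= dmin * (1 + 1e-12) + 1e-15]
    if len(tied) > 1:
        label = min(tied, key=TIE_ORDER.index)
        return label, True
    return tied[0], False


def assign_strategies(model: StrategyModel, indices: pd.DataFrame) -> pd.DataFrame:
    """Assign every row of an index table; undefined rows get 'unassignable'."""
    rows = []
    for _, r in indices.iterrows():
        reg, acq = float(r["regulatory_index"]), float(r["acquisition_index"])
        if math.isnan(reg) or math.isnan(acq):
            rows.append(
                {"accession": r.get("accession", ""), "strategy": "unassignable",
                 "tie": False}
            )
            continue
        label, tie = assign_strategy(model, reg, acq)
        rows.append({"accession": r.get("accession", ""), "strategy": label, "tie": tie})
    return pd.DataFrame(rows)
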