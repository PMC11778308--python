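"""Synthetic input generators with planted, recoverable structure.

Every table the pipeline consumes can be generated here: profile
collections with planted per-habitat detection probabilities and log-normal
abundances; genome tables with planted class/habitat/interaction effects on
continuous features, planted logit terms on binary features and traits; and
labelled investment-index cohorts drawn from planted strategy clusters.
Each generator is a pure function of (config, seed) and emits a ground-truth
record sufficient to compute expected values of every downstream statistic.

The default genome design mirrors the unbalanced six-class x seven-habitat
cell counts of the real comparative cohort (1930 genomes, several empty
cells), so empty-cell handling is exercised by default.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .genome_features import GenomeTable
from .life_history import STRATEGIES
from .profile_io import HABITATS, ProfileCollection

_HABITAT_CODE = {
    "soil": "SO",
    "engineered": "EN",
    "freshwater": "FW",
    "host-associated": "HA",
    "marine": "MA",
    "non-marine saline and alkaline": "NS",
    "terrestrial non-soil": "TN",
}

#: Unbalanced six-class genome design (class -> habitat -> genome count);
#: totals 1930 with empty cells in the rarely sampled habitats.
DEFAULT_CLASS_HABITAT_DESIGN: dict[str, dict[str, int]] = {
    "Blastocatellia": {
        "soil": 64, "engineered": 103, "freshwater": 35, "host-associated": 8,
        "marine": 1, "non-marine saline and alkaline": 0, "terrestrial non-soil": 4,
    },
    "Terriglobia": {
        "soil": 537, "engineered": 179, "freshwater": 197, "host-associated": 50,
        "marine": 16, "non-marine saline and alkaline": 0, "terrestrial non-soil": 27,
    },
    "Thermoanaerobaculia": {
        "soil": 25, "engineered": 49, "freshwater": 22, "host-associated": 37,
        "marine": 17, "non-marine saline and alkaline": 0, "terrestrial non-soil": 3,
    },
    "Vicinamibacteria": {
        "soil": 44, "engineered": 35, "freshwater": 59, "host-associated": 47,
        "marine": 46, "non-marine saline and alkaline": 0, "terrestrial non-soil": 0,
    },
    "Aminicenantia": {
        "soil": 7, "engineered": 27, "freshwater": 49, "host-associated": 0,
        "marine": 35, "non-marine saline and alkaline": 1, "terrestrial non-soil": 0,
    },
    "Holophagae": {
        "soil": 16, "engineered": 30, "freshwater": 151, "host-associated": 4,
        "marine": 5, "non-marine saline and alkaline": 0, "terrestrial non-soil": 0,
    },
}

#: Planted (regulatory_index, acquisition_index) cluster centres and spreads
#: for the three life-history strategies. Regulatory indices are TF/genes
#: ratios (order 1e-2); acquisition indices are secreted-arsenal per
#: transporter (order 1e-1..1).
STRATEGY_CLUSTERS: dict[str, dict[str, tuple[float, float]]] = {
    "ruderal": {"mean": (0.055, 0.35), "sd": (0.004, 0.05)},
    "competitor": {"mean": (0.020, 1.80), "sd": (0.003, 0.15)},
    "scarcity": {"mean": (0.010, 0.25), "sd": (0.002, 0.04)},
}


def _spawn(seed: int, n: int) -> list[np.random.Generator]:
    """Fan one global seed out into independent substreams."""
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


# ---------------------------------------------------------------------------
# profile simulation
# ---------------------------------------------------------------------------


@dataclass
class TaxonSimSpec:
    """Planted distribution of one taxon across habitats."""

    lineage: str
    detection_prob: Mapping[str, float]
    abundance_mean: Mapping[str, float]
    abundance_dispersion: float = 1.0  # sigma of log-abundance

    def __post_init__(self) -> None:
        for h, p in self.detection_prob.items():
            if not 0 <= p <= 1:
                raise ValueError(f"detection probability for {h!r} outside [0,1]")


@dataclass
class ProfileSimConfig:
    n_datasets: Mapping[str, int]
    taxa: Sequence[TaxonSimSpec]
    seed: int = 0


def simulate_profiles(config: ProfileSimConfig) -> ProfileCollection:
    """Draw a profile collection from planted detection/abundance structure.

    Per dataset and taxon, detection is Bernoulli(detection_prob[habitat]);
    detected abundance is log-normal with the configured mean and
    log-dispersion, truncated to (0, 100].
    """
    rng_det, rng_ab = _spawn(config.seed, 2)
    datasets = []
    habitats = []
    for hab in HABITATS:
        n = int(config.n_datasets.get(hab, 0))
        code = _HABITAT_CODE[hab]
        for i in range(n):
            datasets.append(f"{code}{i:06d}")
            habitats.append(hab)
    habitat_of = pd.Series(habitats, index=datasets, name="habitat")

    rows = []
    for spec in config.taxa:
        sigma = spec.abundance_dispersion
        for ds, hab in habitat_of.items():
            p = spec.detection_prob.get(hab, 0.0)
            if p <= 0 or rng_det.random() >= p:
                continue
            m = spec.abundance_mean.get(hab, 0.1)
            mu = np.log(m) - sigma**2 / 2.0  # lognormal with mean m
            ab = float(np.exp(rng_ab.normal(mu, sigma)))
            rows.append((ds, spec.lineage, min(ab, 100.0)))
    records = pd.DataFrame(rows, columns=["dataset", "lineage", "abundance"])
    # relative abundances within a dataset cannot exceed 100% in total;
    # rescale the rare datasets where independent lognormal draws overshoot
    totals = records.groupby("dataset")["abundance"].transform("sum")
    over = totals > 100.0
    if over.any():
        records.loc[over, "abundance"] *= 100.0 / totals[over]
    return ProfileCollection(records, habitat_of)


def default_profile_config(seed: int = 0) -> ProfileSimConfig:
    """Small seven-habitat panel: 10 datasets per habitat, five taxa with
    planted soil-preferring, non-soil-preferring, generalist, single-habitat
    specialist and rare structure."""
    base = "d__Bacteria; p__Acidobacteriota"
    all_high = {h: 0.9 for h in HABITATS}
    all_low = {h: 0.1 for h in HABITATS}
    taxa = [
        TaxonSimSpec(  # planted SPL: near-certain in soil, rare elsewhere
            f"{base}; c__SoilPreferrer",
            {**all_low, "soil": 0.95},
            {**{h: 0.5 for h in HABITATS}, "soil": 8.0},
        ),
        TaxonSimSpec(  # planted NSPL
            f"{base}; c__WaterPreferrer",
            {**{h: 0.8 for h in HABITATS}, "soil": 0.1, "host-associated": 0.2},
            {**{h: 4.0 for h in HABITATS}, "soil": 0.3},
        ),
        TaxonSimSpec(f"{base}; c__Everywhere", all_high, {h: 2.0 for h in HABITATS}),
        TaxonSimSpec(
            f"{base}; c__MarineOnly",
            {h: (0.9 if h == "marine" else 0.0) for h in HABITATS},
            {"marine": 3.0},
        ),
        TaxonSimSpec(
            f"{base}; c__RareScattered",
            {h: 0.05 for h in HABITATS},
            {h: 0.2 for h in HABITATS},
        ),
    ]
    return ProfileSimConfig({h: 10 for h in HABITATS}, taxa, seed=seed)


# ---------------------------------------------------------------------------
# genome simulation
# ---------------------------------------------------------------------------


@dataclass
class ContinuousFeatureModel:
    grand_mean: float
    class_effects: Mapping[str, float] = field(default_factory=dict)
    habitat_effects: Mapping[str, float] = field(default_factory=dict)
    interaction_effects: Mapping[tuple[str, str], float] = field(default_factory=dict)
    noise_sd: float = 1.0

    def __post_init__(self) -> None:
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")


@dataclass
class BinaryFeatureModel:
    """Logit-scale terms for a Bernoulli feature/trait."""

    intercept: float = 0.0
    class_terms: Mapping[str, float] = field(default_factory=dict)
    habitat_terms: Mapping[str, float] = field(default_factory=dict)


@dataclass
class GenomeSimConfig:
    design: Mapping[str, Mapping[str, int]]  # class -> habitat -> n genomes
    feature_models: Mapping[str, ContinuousFeatureModel] = field(default_factory=dict)
    binary_models: Mapping[str, BinaryFeatureModel] = field(default_factory=dict)
    trait_models: Mapping[str, BinaryFeatureModel] = field(default_factory=dict)
    strategy_mixture: Mapping[str, float] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        for cls, cells in self.design.items():
            for hab, n in cells.items():
                if n < 0:
                    raise ValueError(f"negative cell count for ({cls}, {hab})")
        if self.strategy_mixture is not None:
            total = sum(self.strategy_mixture.values())
            if abs(total - 1.0) > 1e-9:
                raise ValueError("strategy mixture must sum to 1")


def _invlogit(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def simulate_genomes(config: GenomeSimConfig) -> tuple[GenomeTable, dict]:
    """Draw a genome table from planted effects; returns (table, truth).

    Continuous features are grand mean + class effect + habitat effect +
    interaction + Gaussian noise; binary features and traits are
    Bernoulli(inverse-logit of planted terms); life-history labels are drawn
    from the strategy mixture. The truth record carries every planted effect
    plus realised variance shares per continuous feature.
    """
    rngs = _spawn(config.seed, 4)
    rng_noise, rng_bin, rng_trait, rng_strat = rngs

    cls_col, hab_col, acc = [], [], []
    i = 0
    for cls in config.design:
        for hab, n in config.design[cls].items():
            for _ in range(int(n)):
                acc.append(f"GEN{i:06d}")
                cls_col.append(cls)
                hab_col.append(hab)
                i += 1
    rec = pd.DataFrame({"class_": cls_col, "habitat": hab_col}, index=pd.Index(acc, name="accession"))
    n_total = len(rec)

    truth: dict = {"design": {c: dict(h) for c, h in config.design.items()}, "n": n_total}
    truth["feature_models"] = {}
    for name, fm in config.feature_models.items():
        ce = rec["class_"].map(lambda c: fm.class_effects.get(c, 0.0)).to_numpy()
        he = rec["habitat"].map(lambda h: fm.habitat_effects.get(h, 0.0)).to_numpy()
        ie = np.array(
            [
                fm.interaction_effects.get((c, h), 0.0)
                for c, h in zip(rec["class_"], rec["habitat"])
            ]
        )
        noise = rng_noise.normal(0.0, fm.noise_sd, n_total)
        rec[name] = fm.grand_mean + ce + he + ie + noise
        var_signal = float(np.var(ce)) + float(np.var(he)) + float(np.var(ie))
        total_var = var_signal + fm.noise_sd**2
        truth["feature_models"][name] = {
            "grand_mean": fm.grand_mean,
            "class_effects": dict(fm.class_effects),
            "habitat_effects": dict(fm.habitat_effects),
            "noise_sd": fm.noise_sd,
            "planted_share_class": 100.0 * float(np.var(ce)) / total_var,
            "planted_share_habitat": 100.0 * float(np.var(he)) / total_var,
        }

    for name, bm in config.binary_models.items():
        logit = (
            bm.intercept
            + rec["class_"].map(lambda c: bm.class_terms.get(c, 0.0)).to_numpy()
            + rec["habitat"].map(lambda h: bm.habitat_terms.get(h, 0.0)).to_numpy()
        )
        draws = rng_bin.random(n_total) < _invlogit(logit)
        if name == "pred_aerobe":
            rec[name] = np.where(draws, "aerobic", "anaerobic")
        else:
            rec[name] = draws.astype(int)

    traits = None
    if config.trait_models:
        cols = {}
        for name, tm in config.trait_models.items():
            logit = (
                tm.intercept
                + rec["class_"].map(lambda c: tm.class_terms.get(c, 0.0)).to_numpy()
                + rec["habitat"].map(lambda h: tm.habitat_terms.get(h, 0.0)).to_numpy()
            )
            cols[name] = (rng_trait.random(n_total) < _invlogit(logit)).astype(int)
        traits = pd.DataFrame(cols, index=rec.index)
        truth["trait_models"] = {
            name: {
                "intercept": tm.intercept,
                "class_terms": dict(tm.class_terms),
                "habitat_terms": dict(tm.habitat_terms),
            }
            for name, tm in config.trait_models.items()
        }

    if config.strategy_mixture is not None:
        labels = list(config.strategy_mixture)
        probs = np.array([config.strategy_mixture[s] for s in labels])
        draws = rng_strat.choice(labels, size=n_total, p=probs)
        rec["life_history"] = draws
        truth["strategy_labels"] = dict(zip(rec.index, draws))

    return GenomeTable(rec, traits), truth


def least_confounded_class_effects(
    design: Mapping[str, Mapping[str, int]], target_var: float
) -> dict[str, float]:
    """Class-effect direction whose per-genome variance is least explainable
    by habitat on the given design, scaled to ``target_var``.

    On an unbalanced design, classes differ in habitat composition, so an
    arbitrary class effect leaks into the habitat margin and a partial-SS
    analysis attributes the shared part to neither factor. Planting the
    minimally confounded direction (smallest generalized eigenvalue of
    between-habitat vs total variance) keeps the planted lineage share
    identifiable.
    """
    from scipy.linalg import eigh

    classes = sorted(design)
    habitats = sorted({h for cells in design.values() for h in cells if cells[h] > 0})
    M = np.array([[design[c].get(h, 0) for h in habitats] for c in classes], dtype=float)
    n_total = M.sum()
    nc = M.sum(axis=1)
    nh = M.sum(axis=0)
    w = nc / n_total
    A = np.diag(nc / n_total) - np.outer(w, w)  # total variance form
    B = sum(
        np.outer(M[:, j], M[:, j]) / (n_total * nh[j])
        for j in range(len(habitats))
        if nh[j] > 0
    ) - np.outer(w, w)  # between-habitat variance form
    _, vecs = eigh(B, A)
    e = vecs[:, 0]
    e = e - float((w * e).sum())
    var = float((w * e**2).sum())
    e = e * np.sqrt(target_var / var)
    # fix overall sign for determinism
    if e[np.argmax(np.abs(e))] < 0:
        e = -e
    return dict(zip(classes, e))


def soil_contrast_habitat_effects(
    design: Mapping[str, Mapping[str, int]], target_var: float
) -> dict[str, float]:
    """Soil-vs-non-soil habitat shift with per-genome variance
    ``target_var``, weighted-centred over the design's habitat margin."""
    habitats = sorted({h for cells in design.values() for h in cells})
    n_total = sum(n for cells in design.values() for n in cells.values())
    n_soil = sum(cells.get("soil", 0) for cells in design.values())
    ws = n_soil / n_total
    if not 0 < ws < 1:
        raise ValueError("design needs both soil and non-soil genomes")
    a = np.sqrt(target_var * (1 - ws) / ws)
    b = -a * ws / (1 - ws)
    return {h: (a if h == "soil" else b) for h in habitats}


def make_variance_recovery_config(
    design: Mapping[str, Mapping[str, int]] | None = None,
    *,
    class_share: float = 40.0,
    habitat_share: float = 1.0,
    total_var: float = 100.0,
    feature: str = "feature",
    seed: int = 0,
) -> GenomeSimConfig:
    """Config with one continuous feature whose class/habitat effects are
    scaled so the planted variance shares (percent of total per-genome
    variance) hit the requested values on the given (unbalanced) design.

    The class effect follows the least habitat-confounded direction and the
    habitat effect is a soil-vs-non-soil contrast; see the respective
    helpers for rationale.
    """
    if design is None:
        design = DEFAULT_CLASS_HABITAT_DESIGN
    var_class = total_var * class_share / 100.0
    var_habitat = total_var * habitat_share / 100.0
    var_resid = total_var - var_class - var_habitat
    if var_resid <= 0:
        raise ValueError("shares leave no residual variance")
    fm = ContinuousFeatureModel(
        grand_mean=0.0,
        class_effects=least_confounded_class_effects(design, var_class)
        if var_class > 0
        else {},
        habitat_effects=soil_contrast_habitat_effects(design, var_habitat)
        if var_habitat > 0
        else {},
        noise_sd=float(np.sqrt(var_resid)),
    )
    return GenomeSimConfig(design=design, feature_models={feature: fm}, seed=seed)


def scaled_design(
    factor: float, design: Mapping[str, Mapping[str, int]] | None = None
) -> dict[str, dict[str, int]]:
    """Shrink the default design by ``factor``, rounding cell counts."""
    if design is None:
        design = DEFAULT_CLASS_HABITAT_DESIGN
    return {
        c: {h: int(round(n * factor)) for h, n in cells.items()}
        for c, cells in design.items()
    }


def default_genome_config(seed: int = 0) -> GenomeSimConfig:
    """Full 14-feature genome simulation on the unbalanced default design.

    Planted values are loosely realistic for soil bacteria: ~5 Mb genomes,
    GC around 60%, coding density ~88%, and SPL classes given larger
    genomes, more CAZymes/BGCs and a more aerobic, competitor-leaning
    profile than NSPL classes.
    """
    spl = ("Terriglobia", "Vicinamibacteria", "Blastocatellia", "Thermoanaerobaculia")
    nspl = ("Holophagae", "Aminicenantia")
    up = {c: (0.5 if c in spl else -1.0) for c in spl + nspl}

    def scaled(base: float, spread: float, sd: float) -> ContinuousFeatureModel:
        return ContinuousFeatureModel(
            grand_mean=base,
            class_effects={c: up[c] * spread for c in up},
            habitat_effects={"soil": -0.2 * spread},
            noise_sd=sd,
        )

    feature_models = {
        "genome_size": scaled(5.0e6, 8e5, 1.0e6),
        "gc_pct": scaled(60.0, 4.0, 3.0),
        "coding_density": scaled(88.0, -1.5, 2.0),
        "mean_gene_length": scaled(950.0, -40.0, 60.0),
        "protein_count": scaled(4500.0, 700.0, 900.0),
        "crispr_count": scaled(2.0, 0.3, 1.0),
        "viral_contig_count": scaled(3.0, 1.0, 1.5),
        "cazyme_count": scaled(120.0, 40.0, 30.0),
        "peptidase_count": scaled(90.0, 20.0, 20.0),
        "bgc_count": scaled(6.0, 1.5, 2.0),
        "pred_ogt": scaled(28.0, -2.0, 3.0),
        "pred_ph": scaled(6.5, 0.4, 0.6),
    }
    binary_models = {
        "pred_aerobe": BinaryFeatureModel(
            intercept=0.0, class_terms={c: (1.5 if c in spl else -1.5) for c in up}
        )
    }
    trait_models = {
        "o2_respiration": BinaryFeatureModel(
            0.0, class_terms={c: (2.0 if c in spl else -2.0) for c in up}
        ),
        "nitrate_to_ammonium": BinaryFeatureModel(
            0.0, class_terms={c: (-2.0 if c in spl else 2.0) for c in up}
        ),
        "n2_fixation": BinaryFeatureModel(-1.0, habitat_terms={"soil": 1.5}),
        "housekeeping_module": BinaryFeatureModel(2.0),
    }
    return GenomeSimConfig(
        design=DEFAULT_CLASS_HABITAT_DESIGN,
        feature_models=feature_models,
        binary_models=binary_models,
        trait_models=trait_models,
        strategy_mixture={"ruderal": 0.3, "competitor": 0.4, "scarcity": 0.3},
        seed=seed,
    )


# ---------------------------------------------------------------------------
# life-history cohorts
# ---------------------------------------------------------------------------


def simulate_investment_cohort(
    n: int,
    mixture: Mapping[str, float] | None = None,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.Series]:
    """Draw a labelled cohort of investment-index pairs from the planted
    strategy clusters; returns (index table, true labels)."""
    if mixture is None:
        mixture = {"ruderal": 1 / 3, "competitor": 1 / 3, "scarcity": 1 / 3}
    rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(1)[0])
    labels = list(mixture)
    probs = np.array([mixture[s] for s in labels])
    assigned = rng.choice(labels, size=n, p=probs)
    reg = np.empty(n)
    acq = np.empty(n)
    for i, lab in enumerate(assigned):
        (mr, ma) = STRATEGY_CLUSTERS[lab]["mean"]
        (sr, sa) = STRATEGY_CLUSTERS[lab]["sd"]
        reg[i] = max(rng.normal(mr, sr), 1e-5)
        acq[i] = max(rng.normal(ma, sa), 1e-4)
    df = pd.DataFrame(
        {
            "accession": [f"COH{i:05d}" for i in range(n)],
            "regulatory_index": reg,
            "acquisition_index": acq,
        }
    )
    return df, pd.Series(assigned, index=df["accession"].values, name="strategy")


def make_synthetic_training(seed: int = 0, n_per_label: int = 9) -> pd.DataFrame:
    """Synthetic stand-in for the 27-genome labelled training table: nine
    genomes per strategy drawn tightly around the planted cluster centres.
    The real labelled training set can be supplied in the same layout."""
    rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(2)[1])
    rows = []
    for lab in STRATEGIES:
        (mr, ma) = STRATEGY_CLUSTERS[lab]["mean"]
        (sr, sa) = STRATEGY_CLUSTERS[lab]["sd"]
        for i in range(n_per_label):
            rows.append(
                {
                    "accession": f"TRAIN_{lab[:4].upper()}{i:02d}",
                    "regulatory_index": max(rng.normal(mr, sr / 2), 1e-5),
                    "acquisition_index": max(rng.normal(ma, sa / 2), 1e-4),
                    "label": lab,
                }
            )
    return pd.DataFrame(rows)
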