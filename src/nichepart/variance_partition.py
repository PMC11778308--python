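"""Partition variation in genome features between phylogeny and habitat.

Continuous features are analysed with a two-factor (class x habitat) linear
model under sum-to-zero contrasts. Each term's type III sum of squares is
the increase in residual SS when that term's columns are removed from the
full model; F = (SS/df) / (SS_res/df_res), and the percentage contribution
of a term is its SS as a share of the total SS (all terms plus residual,
configurable to explained-SS only). Terms with F-test p < 1e-5 are tiered
"strong", 1e-5 <= p < 0.05 "weak", else "ns". Significant factors get
Tukey-Kramer post hoc pairwise comparisons via the studentized-range
distribution with pooled within-group variance.

Binary metabolic traits are analysed with a logistic regression of trait on
class + habitat (+ interaction where estimable). Model fit is summarised by
McFadden pseudo-R^2 = 1 - logL_full / logL_null, and each variable's
contribution is the pseudo-R^2 drop when the variable (main effect plus its
interactions) is removed; term p-values come from likelihood-ratio tests.

Unbalanced designs with empty class x habitat cells are the norm here:
unestimable interaction columns are dropped (rank-based) and the lost
degrees of freedom reported, never silently imputed.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

#: Fixed significance cutoffs for the strong/weak tiers (no FDR is applied;
#: an informational Benjamini-Hochberg column is available in batch output).
STRONG_P = 1e-5
WEAK_P = 0.05

__all__ = [
    "AnovaResult",
    "LogisticPartitionResult",
    "BatchPartitionResult",
    "fit_type3_anova",
    "tukey_hsd",
    "fit_logistic_partition",
    "batch_partition",
    "significance_tier",
]


def significance_tier(p: float) -> str:
    if np.isnan(p):
        return "ns"
    if p < STRONG_P:
        return "strong"
    if p < WEAK_P:
        return "weak"
    return "ns"


# ---------------------------------------------------------------------------
# design matrices
# ---------------------------------------------------------------------------


def _sum_code(labels: np.ndarray) -> tuple[np.ndarray, list]:
    """Sum-to-zero (deviation) coding: one column per non-reference level,
    +1 on the level, -1 on the last (reference) level."""
    levels = sorted(pd.unique(labels))
    if len(levels) < 2:
        raise ValueError(f"factor needs >= 2 levels, got {levels}")
    X = np.zeros((len(labels), len(levels) - 1))
    ref = levels[-1]
    for j, lev in enumerate(levels[:-1]):
        X[labels == lev, j] = 1.0
        X[labels == ref, j] = -1.0
    return X, levels


def _interaction(Xa: np.ndarray, Xb: np.ndarray) -> np.ndarray:
    cols = [Xa[:, i] * Xb[:, j] for i in range(Xa.shape[1]) for j in range(Xb.shape[1])]
    return np.column_stack(cols) if cols else np.empty((Xa.shape[0], 0))


def _rss_rank(X: np.ndarray, y: np.ndarray) -> tuple[float, int]:
    """Residual SS and column-space rank of a least-squares fit.

    Uses SVD-based lstsq with a rank-revealing cutoff so collinear columns
    (empty cells) cost nothing: the RSS is that of the projection onto the
    column space, whatever the parametrisation.
    """
    beta, _, rank, _ = np.linalg.lstsq(X, y, rcond=1e-12)
    resid = y - X @ beta
    return float(resid @ resid), int(rank)


def _prune_aliased(columns: list[np.ndarray], owners: list[str], tol: float = 1e-8):
    """Drop columns aliased with earlier ones, preserving term order.

    Mirrors how R's ``lm`` drops aliased coefficients before a type III
    test: with empty design cells some interaction columns are linear
    combinations of main effects and must be removed *in term order*
    (intercept, then main effects, then interaction) so the surviving
    design is full-rank and each term keeps an unambiguous column set.
    Incremental Gram-Schmidt; returns (kept column matrix, kept owners,
    dropped count per owner).
    """
    n = len(columns[0])
    Q: list[np.ndarray] = []
    kept_cols: list[np.ndarray] = []
    kept_owners: list[str] = []
    dropped: dict[str, int] = {}
    for v, owner in zip(columns, owners):
        r = v.astype(float).copy()
        for q in Q:
            r -= (q @ r) * q
        norm_v = np.linalg.norm(v)
        if np.linalg.norm(r) > tol * max(norm_v, 1.0):
            Q.append(r / np.linalg.norm(r))
            kept_cols.append(v)
            kept_owners.append(owner)
        else:
            dropped[owner] = dropped.get(owner, 0) + 1
    return np.column_stack(kept_cols), kept_owners, dropped


# ---------------------------------------------------------------------------
# type III ANOVA
# ---------------------------------------------------------------------------


@dataclass
class AnovaResult:
    feature: str
    terms: pd.DataFrame  # rows: class, habitat, interaction, residual
    pct_contribution: dict[str, float]
    tier: dict[str, str]
    tukey_pairs: pd.DataFrame
    n: int
    dropped_interaction_df: int = 0
    pct_denominator: str = "total"
    notes: list[str] = field(default_factory=list)

    def term(self, name: str) -> pd.Series:
        return self.terms.set_index("term").loc[name]


def fit_type3_anova(
    y: Sequence[float],
    class_labels: Sequence,
    habitat_labels: Sequence,
    *,
    feature: str = "feature",
    include_interaction: bool = True,
    pct_denominator: str = "total",
    tukey_when_significant: bool = True,
) -> AnovaResult:
    """Two-factor type III ANOVA of ``y`` on class, habitat and interaction.

    Missing ``y`` values are dropped pairwise (with their labels). Raises if
    either factor has a single level after dropping, or if the model is
    saturated (zero residual df).
    """
    y = np.asarray(y, dtype=float)
    cls = np.asarray(class_labels)
    hab = np.asarray(habitat_labels)
    if not (len(y) == len(cls) == len(hab)):
        raise ValueError("y, class_labels and habitat_labels must align")
    mask = np.isfinite(y)
    y, cls, hab = y[mask], cls[mask], hab[mask]
    n = len(y)

    Xc, c_levels = _sum_code(cls)
    Xh, h_levels = _sum_code(hab)
    notes: list[str] = []
    term_names = ["class", "habitat"] + (["interaction"] if include_interaction else [])

    columns: list[np.ndarray] = [np.ones(n)]
    owners: list[str] = ["intercept"]
    for name, block in (("class", Xc), ("habitat", Xh)):
        for j in range(block.shape[1]):
            columns.append(block[:, j])
            owners.append(name)
    if include_interaction:
        Xi = _interaction(Xc, Xh)
        for j in range(Xi.shape[1]):
            columns.append(Xi[:, j])
            owners.append("interaction")

    X_all, kept_owners, dropped = _prune_aliased(columns, owners)
    dropped_df = dropped.get("interaction", 0)
    if dropped_df:
        notes.append(f"{dropped_df} interaction df dropped (empty class x habitat cells)")
    for term in ("class", "habitat"):
        if dropped.get(term):
            notes.append(f"{dropped[term]} aliased '{term}' column(s) dropped")

    rss_full, rank_full = _rss_rank(X_all, y)
    df_res = n - rank_full
    if df_res <= 0:
        raise ValueError("saturated model: zero residual degrees of freedom")

    rows = []
    for term in term_names:
        idx = [i for i, o in enumerate(kept_owners) if o != term]
        df_term = len(kept_owners) - len(idx)
        if df_term == 0:
            notes.append(f"term '{term}' unestimable (no independent columns)")
            rows.append(
                {"term": term, "ss": 0.0, "df": 0, "f_stat": np.nan, "p_value": np.nan}
            )
            continue
        rss_red, _ = _rss_rank(X_all[:, idx], y)
        ss = max(rss_red - rss_full, 0.0)
        ms_res = rss_full / df_res
        if ms_res == 0:
            f_stat = float("inf") if ss > 0 else float("nan")
            p = 0.0 if ss > 0 else float("nan")
        else:
            f_stat = (ss / df_term) / ms_res
            p = float(stats.f.sf(f_stat, df_term, df_res))
        rows.append({"term": term, "ss": ss, "df": df_term, "f_stat": f_stat, "p_value": p})
    rows.append(
        {"term": "residual", "ss": rss_full, "df": df_res, "f_stat": np.nan, "p_value": np.nan}
    )
    terms = pd.DataFrame(rows)

    if pct_denominator == "total":
        denom = float(terms["ss"].sum())
    elif pct_denominator == "explained":
        denom = float(terms.loc[terms["term"] != "residual", "ss"].sum())
    else:
        raise ValueError("pct_denominator must be 'total' or 'explained'")
    pct = {
        row["term"]: (100.0 * row["ss"] / denom if denom > 0 else float("nan"))
        for _, row in terms.iterrows()
        if not (pct_denominator == "explained" and row["term"] == "residual")
    }
    tier = {
        row["term"]: significance_tier(row["p_value"])
        for _, row in terms.iterrows()
        if row["term"] != "residual"
    }

    tukey_frames = []
    if tukey_when_significant:
        for factor, labels in (("class", cls), ("habitat", hab)):
            p_term = float(terms.set_index("term").loc[factor, "p_value"])
            if np.isfinite(p_term) and p_term < WEAK_P:
                tk = tukey_hsd(y, labels)
                tk.insert(0, "factor", factor)
                tukey_frames.append(tk)
    tukey = (
        pd.concat(tukey_frames, ignore_index=True)
        if tukey_frames
        else pd.DataFrame(columns=["factor", "group_a", "group_b", "mean_diff", "p_adj"])
    )

    return AnovaResult(
        feature=feature,
        terms=terms,
        pct_contribution=pct,
        tier=tier,
        tukey_pairs=tukey,
        n=n,
        dropped_interaction_df=dropped_df,
        pct_denominator=pct_denominator,
        notes=notes,
    )


# ---------------------------------------------------------------------------
# Tukey-Kramer
# ---------------------------------------------------------------------------


def tukey_hsd(y: Sequence[float], group_labels: Sequence) -> pd.DataFrame:
    """Tukey-Kramer adjusted pairwise comparisons of group means.

    Uses the studentized-range distribution with pooled within-group
    variance; the Kramer correction handles unequal group sizes. With two
    groups this reduces to the pooled two-sided t-test.
    """
    y = np.asarray(y, dtype=float)
    g = np.asarray(group_labels)
    mask = np.isfinite(y)
    y, g = y[mask], g[mask]
    levels = sorted(pd.unique(g))
    k = len(levels)
    if k < 2:
        raise ValueError("need >= 2 groups")
    n = len(y)
    means = {lev: float(y[g == lev].mean()) for lev in levels}
    ns = {lev: int((g == lev).sum()) for lev in levels}
    df = n - k
    if df < 1:
        raise ValueError("pooled residual degrees of freedom < 1")
    sse = sum(float(((y[g == lev] - means[lev]) ** 2).sum()) for lev in levels)
    mse = sse / df

    rows = []
    for a, b in itertools.combinations(levels, 2):
        diff = means[a] - means[b]
        if mse == 0:
            p = 1.0 if diff == 0 else 0.0
        else:
            se = np.sqrt(mse / 2.0 * (1.0 / ns[a] + 1.0 / ns[b]))
            q = abs(diff) / se
            p = float(np.clip(stats.studentized_range.sf(q, k, df), 0.0, 1.0))
        rows.append({"group_a": a, "group_b": b, "mean_diff": diff, "p_adj": p})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# logistic partition (McFadden pseudo-R^2 drops)
# ---------------------------------------------------------------------------


@dataclass
class LogisticPartitionResult:
    trait: str
    term_p: dict[str, float]
    pseudo_r2_full: float
    contribution: dict[str, float]  # pseudo-R^2 drop on removing the variable
    direction: dict[str, str]  # class level -> higher/lower prevalence
    n: int
    flagged: bool = False
    notes: list[str] = field(default_factory=list)


def _independent_columns(X: np.ndarray, tol: float = 1e-9) -> np.ndarray:
    """Indices of a maximal linearly independent column subset (pivoted QR)."""
    if X.shape[1] == 0:
        return np.array([], dtype=int)
    from scipy.linalg import qr

    _, R, piv = qr(X, mode="economic", pivoting=True)
    diag = np.abs(np.diag(R))
    if diag.size == 0 or diag[0] == 0:
        return np.array([], dtype=int)
    rank = int((diag > tol * diag[0]).sum())
    return np.sort(piv[:rank])


def _bernoulli_ll(y: np.ndarray, p: np.ndarray) -> float:
    eps = 1e-12
    p = np.clip(p, eps, 1 - eps)
    return float(np.sum(y * np.log(p) + (1 - y) * np.log(1 - p)))


def _fit_logit(y: np.ndarray, X: np.ndarray) -> tuple[float, np.ndarray, bool]:
    """GLM/Binomial fit; returns (log-likelihood, params, converged)."""
    import statsmodels.api as sm

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = sm.GLM(y, X, family=sm.families.Binomial())
        try:
            res = model.fit(maxiter=100, tol=1e-10)
        except Exception as exc:  # pragma: no cover - defensive
            logger.warning("logistic fit failed: %s", exc)
            return float("nan"), np.full(X.shape[1], np.nan), False
    converged = bool(getattr(res, "converged", True))
    return float(res.llf), np.asarray(res.params), converged


def fit_logistic_partition(
    trait: Sequence[int],
    class_labels: Sequence,
    habitat_labels: Sequence,
    *,
    trait_name: str = "trait",
    include_interaction: bool = True,
) -> LogisticPartitionResult:
    """Attribute a binary trait to class and habitat via pseudo-R^2 drops.

    Fits trait ~ class + habitat (+ interaction where estimable) by maximum
    likelihood; McFadden pseudo-R^2 = 1 - logL_full/logL_null. The
    contribution of a variable is the pseudo-R^2 drop when its main-effect
    and interaction columns are removed; term p-values are likelihood-ratio
    tests. Complete separation or non-convergence flags the result rather
    than reporting a silent number.
    """
    y = np.asarray(trait, dtype=float)
    cls = np.asarray(class_labels)
    hab = np.asarray(habitat_labels)
    mask = np.isfinite(y)
    y, cls, hab = y[mask], cls[mask], hab[mask]
    n = len(y)
    if not ((y == 0) | (y == 1)).all():
        raise ValueError("trait must be binary 0/1")
    if y.min() == y.max():
        raise ValueError("trait must contain both 0s and 1s")

    def dummies(labels: np.ndarray) -> tuple[np.ndarray, list]:
        levels = sorted(pd.unique(labels))
        cols = [(labels == lev).astype(float) for lev in levels[1:]]
        X = np.column_stack(cols) if cols else np.empty((len(labels), 0))
        return X, levels

    Xc, c_levels = dummies(cls)
    Xh, h_levels = dummies(hab)
    Xi = _interaction(Xc, Xh) if include_interaction else np.empty((n, 0))

    intercept = np.ones((n, 1))
    # term membership of each column in the stacked design
    owners = (
        ["intercept"]
        + ["class"] * Xc.shape[1]
        + ["habitat"] * Xh.shape[1]
        + ["interaction"] * Xi.shape[1]
    )
    X_all = np.column_stack([intercept, Xc, Xh, Xi])
    keep = _independent_columns(X_all)
    owners = [owners[i] for i in keep]
    X_all = X_all[:, keep]

    notes: list[str] = []
    flagged = False

    def fit_subset(drop_terms: set[str]) -> tuple[float, int]:
        idx = [i for i, o in enumerate(owners) if o not in drop_terms]
        ll, params, conv = _fit_logit(y, X_all[:, idx])
        nonlocal flagged
        if not conv:
            flagged = True
            notes.append(f"non-convergence dropping {sorted(drop_terms) or 'nothing'}")
        if np.nanmax(np.abs(params)) > 20:
            flagged = True
            if "possible complete separation (divergent coefficients)" not in notes:
                notes.append("possible complete separation (divergent coefficients)")
        return ll, len(idx)

    ll_full, k_full = fit_subset(set())
    ll_null, _ = fit_subset({"class", "habitat", "interaction"})
    r2_full = 1.0 - ll_full / ll_null if ll_null != 0 else float("nan")

    term_p: dict[str, float] = {}
    contribution: dict[str, float] = {}
    for var, drop in (
        ("class", {"class", "interaction"}),
        ("habitat", {"habitat", "interaction"}),
    ):
        ll_red, k_red = fit_subset(drop)
        r2_red = 1.0 - ll_red / ll_null if ll_null != 0 else float("nan")
        contribution[var] = r2_full - r2_red
        lr = max(2.0 * (ll_full - ll_red), 0.0)
        df = k_full - k_red
        term_p[var] = float(stats.chi2.sf(lr, df)) if df > 0 else float("nan")
    if include_interaction and any(o == "interaction" for o in owners):
        ll_main, k_main = fit_subset({"interaction"})
        lr = max(2.0 * (ll_full - ll_main), 0.0)
        df = k_full - k_main
        term_p["interaction"] = float(stats.chi2.sf(lr, df)) if df > 0 else float("nan")

    overall = float(y.mean())
    direction = {
        lev: ("higher" if float(y[cls == lev].mean()) >= overall else "lower")
        for lev in c_levels
    }

    return LogisticPartitionResult(
        trait=trait_name,
        term_p=term_p,
        pseudo_r2_full=r2_full,
        contribution=contribution,
        direction=direction,
        n=n,
        flagged=flagged,
        notes=notes,
    )


# ---------------------------------------------------------------------------
# batch over a genome table
# ---------------------------------------------------------------------------


@dataclass
class BatchPartitionResult:
    anova: dict[str, AnovaResult]
    logistic: dict[str, LogisticPartitionResult]
    specificity: pd.DataFrame  # feature/trait -> lineage/habitat tiers + category
    tallies: dict[str, int]
    errors: dict[str, str]


def _specificity_category(class_tier: str, habitat_tier: str) -> str:
    c = class_tier == "strong"
    h = habitat_tier == "strong"
    if c and h:
        return "both"
    if c:
        return "lineage-specific"
    if h:
        return "habitat-specific"
    return "neither"


def batch_partition(
    table,
    *,
    include_interaction: bool = True,
    pct_denominator: str = "total",
) -> BatchPartitionResult:
    """Run the variance partition over every analysis feature and trait.

    The 12 continuous features go through the type III ANOVA; the 2-level
    oxygen preference is 0/1-encoded and run through the same ANOVA; the
    3-level life-history strategy is analysed as one-vs-rest indicators with
    the maximum-class-SS indicator reported for the feature. Every binary
    metabolic trait goes through the logistic partition. Per-feature failures
    are recorded and never abort the batch.
    """
    from .genome_features import CONTINUOUS_FEATURES, LIFE_HISTORY_LEVELS

    rec = table.records
    cls = rec["class_"].to_numpy()
    hab = rec["habitat"].to_numpy()

    anova: dict[str, AnovaResult] = {}
    logistic: dict[str, LogisticPartitionResult] = {}
    errors: dict[str, str] = {}
    spec_rows = []

    def run_anova(name: str, y: np.ndarray) -> None:
        try:
            res = fit_type3_anova(
                y,
                cls,
                hab,
                feature=name,
                include_interaction=include_interaction,
                pct_denominator=pct_denominator,
            )
        except Exception as exc:
            errors[name] = str(exc)
            spec_rows.append(
                {"name": name, "kind": "feature", "class_tier": "ns",
                 "habitat_tier": "ns", "category": "neither", "error": str(exc)}
            )
            return
        anova[name] = res
        spec_rows.append(
            {
                "name": name,
                "kind": "feature",
                "class_tier": res.tier.get("class", "ns"),
                "habitat_tier": res.tier.get("habitat", "ns"),
                "category": _specificity_category(
                    res.tier.get("class", "ns"), res.tier.get("habitat", "ns")
                ),
                "error": "",
            }
        )

    known = [c for c in CONTINUOUS_FEATURES if c in rec.columns]
    extra = [
        c
        for c in rec.select_dtypes(include=[np.number]).columns
        if c not in known and c not in ("class_", "habitat")
    ]
    for feat in known + extra:
        run_anova(feat, rec[feat].to_numpy(dtype=float))

    if "pred_aerobe" in rec.columns:
        y = np.where(
            rec["pred_aerobe"].isna(), np.nan, (rec["pred_aerobe"] == "aerobic").astype(float)
        )
        run_anova("pred_aerobe", y)

    if "life_history" in rec.columns and rec["life_history"].notna().any():
        # one-vs-rest indicators; report the indicator with the largest class SS
        best: AnovaResult | None = None
        for level in LIFE_HISTORY_LEVELS:
            y = np.where(
                rec["life_history"].isna(), np.nan,
                (rec["life_history"] == level).astype(float),
            )
            try:
                res = fit_type3_anova(
                    y, cls, hab,
                    feature=f"life_history[{level}]",
                    include_interaction=include_interaction,
                    pct_denominator=pct_denominator,
                )
            except Exception as exc:
                errors[f"life_history[{level}]"] = str(exc)
                continue
            ss_class = float(res.term("class")["ss"])
            if best is None or ss_class > float(best.term("class")["ss"]):
                best = res
        if best is not None:
            best.notes.append("max-class-SS one-vs-rest indicator of a 3-level feature")
            anova["life_history"] = best
            spec_rows.append(
                {
                    "name": "life_history",
                    "kind": "feature",
                    "class_tier": best.tier.get("class", "ns"),
                    "habitat_tier": best.tier.get("habitat", "ns"),
                    "category": _specificity_category(
                        best.tier.get("class", "ns"), best.tier.get("habitat", "ns")
                    ),
                    "error": "",
                }
            )

    if table.traits is not None and len(table.traits):
        traits = table.traits.reindex(rec.index)
        for trait in traits.columns:
            y = traits[trait].to_numpy(dtype=float)
            try:
                res = fit_logistic_partition(
                    y[np.isfinite(y)],
                    cls[np.isfinite(y)],
                    hab[np.isfinite(y)],
                    trait_name=trait,
                    include_interaction=include_interaction,
                )
            except Exception as exc:
                errors[trait] = str(exc)
                spec_rows.append(
                    {"name": trait, "kind": "trait", "class_tier": "ns",
                     "habitat_tier": "ns", "category": "neither", "error": str(exc)}
                )
                continue
            logistic[trait] = res
            ct = significance_tier(res.term_p.get("class", float("nan")))
            ht = significance_tier(res.term_p.get("habitat", float("nan")))
            spec_rows.append(
                {
                    "name": trait,
                    "kind": "trait",
                    "class_tier": ct,
                    "habitat_tier": ht,
                    "category": _specificity_category(ct, ht),
                    "error": "",
                }
            )

    specificity = pd.DataFrame(spec_rows)
    if len(specificity):
        # informational BH-adjusted class p-values across ANOVA features
        pvals = {
            name: float(res.term("class")["p_value"]) for name, res in anova.items()
        }
        if pvals:
            from statsmodels.stats.multitest import multipletests

            names = list(pvals)
            ps = np.array([pvals[nm] for nm in names])
            ok = np.isfinite(ps)
            adj = np.full_like(ps, np.nan)
            if ok.any():
                adj[ok] = multipletests(ps[ok], method="fdr_bh")[1]
            bh = dict(zip(names, adj))
            specificity["class_p_bh"] = specificity["name"].map(bh)
    tallies = (
        specificity["category"].value_counts().to_dict() if len(specificity) else {}
    )
    for cat in ("lineage-specific", "habitat-specific", "both", "neither"):
        tallies.setdefault(cat, 0)
    return BatchPartitionResult(anova, logistic, specificity, tallies, errors)
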