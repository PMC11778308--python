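import math

import numpy as np
import pandas as pd
import pytest

from nichepart.ecology import (
    BreadthCall,
    EcologyMetrics,
    PreferenceCutoffs,
    classify_breadth,
    classify_breadth_from_genomes,
    classify_preference,
    compute_metrics,
    generalist_fraction,
    round_half_up,
    ubiquity_pct,
)
from nichepart.genome_features import GenomeTable
from nichepart.profile_io import HABITATS, ProfileCollection
from nichepart.synthetic import ProfileSimConfig, TaxonSimSpec, simulate_profiles


def _metrics_for(taxon, metrics):
    return next(m for m in metrics if taxon in m.taxon)


class TestComputeMetrics:
    def test_counts_on_hand_built_collection(self, tiny_collection):
        metrics = compute_metrics(tiny_collection, "class")
        a = _metrics_for("c__A", metrics)
        # detected in 2 of 3 soil datasets, 1 of 2 marine
        assert a.per_habitat["soil"].n_detected == 2
        assert a.per_habitat["soil"].n_datasets == 3
        assert a.soil_ubiquity_pct == pytest.approx(100 * 2 / 3)
        # non-soil pool: marine (2 datasets) only habitat with datasets
        assert a.nonsoil_ubiquity_pct == pytest.approx(50.0)
        assert a.preference_ratio == pytest.approx((200 / 3) / 50)
        # detection-conditional means
        assert a.soil_mean_abundance_pct == pytest.approx(15.0)
        assert a.nonsoil_mean_abundance_pct == pytest.approx(2.0)
        assert a.abundance_ratio == pytest.approx(7.5)
        assert a.n_studies_total == 3

    def test_host_associated_excluded_from_comparative_fields(self, tiny_collection):
        metrics = compute_metrics(tiny_collection, "class")
        b = _metrics_for("c__B", metrics)  # host-associated only
        assert b.per_habitat["host-associated"].n_detected == 1
        assert b.soil_ubiquity_pct == 0.0
        assert b.nonsoil_ubiquity_pct == 0.0  # host pool not counted
        assert math.isnan(b.preference_ratio)

    def test_empty_habitat_reported_missing_not_zero(self, tiny_collection):
        metrics = compute_metrics(tiny_collection, "class")
        a = _metrics_for("c__A", metrics)
        assert a.per_habitat["freshwater"].n_datasets == 0
        assert math.isnan(a.per_habitat["freshwater"].ubiquity_pct)

    def test_nonsoil_pool_is_not_mean_of_percentages(self):
        # 10 engineered (all detected), 40 marine (none detected):
        # pooled = 10/50 = 20%, mean-of-percentages would be 50%
        habitat_of = pd.Series(
            {f"E{i}": "engineered" for i in range(10)}
            | {f"M{i}": "marine" for i in range(40)}
            | {"S0": "soil"}
        )
        records = pd.DataFrame(
            {
                "dataset": [f"E{i}" for i in range(10)],
                "lineage": ["d__B; p__P; c__X"] * 10,
                "abundance": [1.0] * 10,
            }
        )
        metrics = compute_metrics(ProfileCollection(records, habitat_of), "class")
        assert metrics[0].nonsoil_ubiquity_pct == pytest.approx(20.0)

    def test_ubiquity_pct_helper(self):
        assert ubiquity_pct(1, 4) == 25.0
        assert math.isnan(ubiquity_pct(0, 0))
        with pytest.raises(ValueError):
            ubiquity_pct(5, 4)

    def test_round_half_up_convention(self):
        assert round_half_up(95.649, 1) == 95.6
        assert round_half_up(95.65, 1) == 95.7
        assert round_half_up(0.125, 2) == 0.13


def _mk_metrics(soil_ub, nonsoil_ub, soil_ab=5.0, nonsoil_ab=1.0, n_total=1000):
    pref = float("inf") if nonsoil_ub == 0 and soil_ub > 0 else (
        soil_ub / nonsoil_ub if nonsoil_ub else float("nan")
    )
    return EcologyMetrics(
        taxon="t",
        per_habitat={},
        soil_ubiquity_pct=soil_ub,
        nonsoil_ubiquity_pct=nonsoil_ub,
        preference_ratio=pref,
        soil_mean_abundance_pct=soil_ab,
        nonsoil_mean_abundance_pct=nonsoil_ab,
        abundance_ratio=soil_ab / nonsoil_ab if nonsoil_ab else float("inf"),
        n_studies_total=n_total,
        flags=["preference-denominator-zero"] if nonsoil_ub == 0 and soil_ub > 0 else [],
    )


class TestClassifyPreference:
    def test_exact_boundary_is_strict(self):
        call = classify_preference(_mk_metrics(75.0, 10.0))
        assert not call.ubiquitous
        call = classify_preference(_mk_metrics(75.01, 10.0))
        assert call.ubiquitous

    def test_spl_requires_all_three(self):
        call = classify_preference(_mk_metrics(90.0, 10.0, soil_ab=5, nonsoil_ab=1))
        assert call.summary == "SPL"
        # fails the abundance-ratio criterion only -> intermediate
        call = classify_preference(_mk_metrics(90.0, 10.0, soil_ab=1, nonsoil_ab=2))
        assert call.summary == "intermediate"

    def test_nspl_requires_all_negative(self):
        call = classify_preference(_mk_metrics(10.0, 50.0, soil_ab=0.5, nonsoil_ab=2.0))
        assert call.summary == "NSPL"

    def test_rare_overrides(self):
        call = classify_preference(_mk_metrics(90.0, 10.0), rare_cutoff=250)
        assert call.summary == "SPL"
        rare = _mk_metrics(90.0, 10.0, n_total=249)
        assert classify_preference(rare).summary == "rare"

    def test_zero_denominator_is_positive_with_flag(self):
        call = classify_preference(_mk_metrics(90.0, 0.0))
        assert call.soil_preferring
        assert "preference-denominator-zero" in call.flags

    def test_monotone_in_soil_detection(self):
        """Increasing soil detections (all else fixed) never demotes a taxon."""
        rank = {"NSPL": 0, "intermediate": 1, "SPL": 2}
        prev = -1
        for soil_ub in np.linspace(0, 100, 41):
            m = _mk_metrics(soil_ub, 15.0, soil_ab=3.0, nonsoil_ab=1.0)
            call = classify_preference(m)
            assert rank[call.summary] >= prev
            prev = rank[call.summary]


class TestClassifyBreadth:
    def _panel(self, n_generalist=20, n_specialist=5, n_per_hab=10, seed=0):
        base = "d__B; p__P; c__"
        taxa = [
            TaxonSimSpec(f"{base}Gen{i}", {h: 1.0 for h in HABITATS}, {h: 1.0 for h in HABITATS})
            for i in range(n_generalist)
        ] + [
            TaxonSimSpec(
                f"{base}Spec{i}",
                {h: (1.0 if h == "soil" else 0.0) for h in HABITATS},
                {"soil": 1.0},
            )
            for i in range(n_specialist)
        ]
        return simulate_profiles(
            ProfileSimConfig({h: n_per_hab for h in HABITATS}, taxa, seed=seed)
        )

    def test_six_of_seven_is_specialist(self, tiny_collection):
        records = pd.DataFrame(
            {
                "dataset": [f"D{i}" for i in range(6)],
                "lineage": ["d__B; p__P; c__X"] * 6,
                "abundance": [1.0] * 6,
            }
        )
        habitat_of = pd.Series(
            {f"D{i}": h for i, h in enumerate(HABITATS[:6])}
            | {"D9": "terrestrial non-soil"}
        )
        calls = classify_breadth(ProfileCollection(records, habitat_of), "class", 0)
        assert calls[0].n_habitats_detected == 6
        assert calls[0].call == "specialist"

    def test_rare_exclusion_boundary(self):
        records = pd.DataFrame(
            {
                "dataset": [f"D{i}" for i in range(249)],
                "lineage": ["d__B"] * 249,
                "abundance": [1.0] * 249,
            }
        )
        habitat_of = pd.Series({f"D{i}": "soil" for i in range(249)})
        coll = ProfileCollection(records, habitat_of)
        calls = classify_breadth(coll, None, min_studies=250)
        assert calls[0].call == "rare-excluded"
        assert calls[0].call_ignoring_rarity == "specialist"

    def test_planted_panel_fractions_recovered(self):
        coll = self._panel()
        calls = classify_breadth(coll, "class", min_studies=0)
        frac = generalist_fraction(calls)
        assert frac == pytest.approx(100 * 20 / 25)
        by_call = {c.taxon: c for c in calls}
        assert all(
            by_call[t].call == "specialist" for t in by_call if "Spec" in t
        )


class TestBreadthFromGenomes:
    def _table(self, rows):
        rec = pd.DataFrame(
            rows, columns=["accession", "class_", "habitat"]
        ).set_index("accession")
        return GenomeTable(rec)

    def test_two_habitats_is_generalist(self):
        table = self._table(
            [(f"G{i}", "X", h) for i, h in enumerate(["soil"] * 3 + ["marine"] * 3)]
        )
        calls = classify_breadth_from_genomes(table, "class", 5)
        assert calls[0].call == "generalist"
        assert calls[0].n_habitats_detected == 2

    def test_four_genomes_rare_excluded(self):
        table = self._table([(f"G{i}", "X", "freshwater") for i in range(4)])
        calls = classify_breadth_from_genomes(table, "class", 5)
        assert calls[0].call == "rare-excluded"
        assert calls[0].call_ignoring_rarity == "specialist"

    def test_five_habitat_class_is_generalist(self):
        habs = ["soil", "engineered", "freshwater", "host-associated", "marine"]
        rows = [(f"G{i}", "Vicinamibacteria", habs[i % 5]) for i in range(231)]
        calls = classify_breadth_from_genomes(self._table(rows), "class", 5)
        assert calls[0].call == "generalist"
        assert calls[0].n_habitats_detected == 5

    def test_habitat_counts_agree_with_profile_based_calls(self):
        """With consistent planted presence, both routes see the same number
        of habitats per taxon."""
        presence = {"X": ["soil", "marine"], "Y": list(HABITATS), "Z": ["soil"]}
        rows, precords = [], []
        i = 0
        for cls, habs in presence.items():
            for h in habs:
                for _ in range(5):
                    rows.append((f"G{i}", cls, h))
                    i += 1
                precords.append((f"D_{cls}_{h}", f"d__B; p__P; c__{cls}", 1.0))
        table = self._table(rows)
        records = pd.DataFrame(precords, columns=["dataset", "lineage", "abundance"])
        habitat_of = pd.Series(
            {r[0]: r[0].split("_", 2)[2] for r in precords}
        )
        coll = ProfileCollection(records, habitat_of)
        from_profiles = {
            c.taxon.split("c__")[1]: c.n_habitats_detected
            for c in classify_breadth(coll, "class", 0)
        }
        from_genomes = {
            c.taxon: c.n_habitats_detected
            for c in classify_breadth_from_genomes(table, "class", 0)
        }
        assert from_profiles == from_genomes
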