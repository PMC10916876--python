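import numpy as np
import pandas as pd
import pytest
from sklearn.ensemble import RandomForestClassifier

import biomorph as bm
from biomorph.interpretation import forest_baseline
from conftest import make_term


class TestSelectImportant:
    def test_single_spike_at_tie_is_excluded(self):
        # (0,0,0,0,1): population SD 0.4, cut exactly 1.0; strict > excludes
        res = bm.select_important(pd.Series([0, 0, 0, 0, 1.0]))
        assert res.feature_names == set()
        assert res.threshold_value == pytest.approx(1.0)
        # sample convention: cut ~1.094, also empty
        res_s = bm.select_important(pd.Series([0, 0, 0, 0, 1.0]), sd_convention="sample")
        assert res_s.feature_names == set()

    def test_strong_spike_selected(self):
        # nine zeros and a 10: mean 1, population SD 3, cut 7 -> 10 selected
        vals = pd.Series([0.0] * 9 + [10.0], index=[f"f{i}" for i in range(10)])
        res = bm.select_important(vals)
        assert res.feature_names == {"f9"}
        assert res.threshold_value == pytest.approx(7.0)

    def test_uniform_importances_give_empty_set(self):
        res = bm.select_important(pd.Series([0.3] * 6))
        assert res.feature_names == set()

    def test_non_strict_mode_includes_boundary(self):
        res = bm.select_important(pd.Series([0, 0, 0, 0, 1.0]), strict=False)
        assert len(res.feature_names) == 1


@pytest.fixture(scope="module")
def fitted_forest():
    rng = np.random.default_rng(77)
    X = pd.DataFrame(
        rng.normal(size=(300, 8)), columns=[f"f{i}" for i in range(8)]
    )
    X["dead"] = 1.0  # constant: the forest can never split on it
    y = (X["f0"] + 0.5 * X["f1"] > 0).astype(int)
    model = RandomForestClassifier(n_estimators=100, random_state=0).fit(X, y)
    return model, X


class TestAttributeCompound:
    def test_local_accuracy_on_random_rows(self, fitted_forest):
        model, X = fitted_forest
        baseline = forest_baseline(model)
        for i in range(0, 50):
            row = X.iloc[i]
            attr = bm.attribute_compound(model, row)
            score = model.predict_proba(row.to_frame().T)[0, 1]
            assert attr.sum() == pytest.approx(score - baseline, abs=1e-6)

    def test_null_player_gets_zero(self, fitted_forest):
        model, X = fitted_forest
        attr = bm.attribute_compound(model, X.iloc[3])
        assert attr["dead"] == 0.0

    def test_unfitted_model_errors(self):
        with pytest.raises(ValueError, match="fitted"):
            bm.attribute_compound(RandomForestClassifier(), np.zeros(3))

    def test_planted_features_dominate_attributions(self):
        """For active, correctly predicted compounds the top positive
        attribution should sit on the planted activity features."""
        scenario = bm.default_scenario(seed=31)
        screen, labels = bm.generate_compound_screen(scenario)
        model = RandomForestClassifier(n_estimators=200, random_state=0)
        model.fit(screen.data, labels)
        planted = set(scenario.activity_subset)
        proba = model.predict_proba(screen.data)[:, 1]
        tp_rows = screen.data.index[(labels == 1) & (proba >= 0.5)][:10]
        hits = 0
        for r in tp_rows:
            attr = bm.attribute_compound(model, screen.data.loc[r])
            if attr.idxmax() in planted:
                hits += 1
        assert hits >= 0.8 * len(tp_rows)


def test_interpret_compound_report_is_bounded():
    """Per-compound enrichment from positive path attributions stays in
    percentage range and covers every registry term."""
    scenario = bm.default_scenario(seed=41)
    screen, labels = bm.generate_compound_screen(scenario)
    registry = bm.ground_truth_registry(scenario)
    model = RandomForestClassifier(n_estimators=100, random_state=1)
    model.fit(screen.data, labels)
    row = screen.data.index[(labels == 1).to_numpy()][0]
    report = bm.interpret_compound(model, screen.data.loc[row], registry)
    assert set(report.per_term_overlap) == set(registry.term_ids)
    for v in report.per_term_overlap.values():
        assert 0.0 <= v <= 100.0
    for v in report.level3_enrichment.values():
        assert 0.0 <= v <= 100.0


class TestTermOverlap:
    def test_half_overlap(self):
        term = make_term(["f1", "f2", "f3", "f4"])
        imp = bm.ImportantFeatureSet({"f1", "f3", "f9"}, "mean_plus_2sd",
                                     "model_importance", 0.0)
        assert bm.term_overlap(imp, term) == pytest.approx(50.0)

    def test_disjoint_and_superset(self):
        term = make_term(["f1", "f2"])
        none = bm.ImportantFeatureSet(set(), "mean_plus_2sd", "model_importance", 0.0)
        all_ = bm.ImportantFeatureSet({"f1", "f2", "f3"}, "mean_plus_2sd",
                                      "model_importance", 0.0)
        assert bm.term_overlap(none, term) == 0.0
        assert bm.term_overlap(all_, term) == 100.0

    def test_monotone_in_important_set(self, rng):
        feats = [f"f{i}" for i in range(10)]
        term = make_term(feats[:6])
        grow = set()
        last = 0.0
        for f in rng.permutation(feats):
            grow.add(f)
            ov = bm.term_overlap(
                bm.ImportantFeatureSet(set(grow), "mean_plus_2sd",
                                       "model_importance", 0.0),
                term,
            )
            assert ov >= last
            last = ov


class TestEnrichLevels:
    def _registry(self):
        terms = [
            make_term(["a", "b"], l3="vb_ros_mean_intensity", l4="ROS",
                      l1="viability", l2="ros"),
            make_term(["c", "d"], l3="cc_s_phase_fraction", l4="ROS",
                      l1="cell_cycle", l2="s_phase"),
            make_term(["e", "f"], l3="vb_percent_dead", l4="DNA Damage",
                      l1="viability", l2="cell_death"),
        ]
        return bm.TermRegistry(terms)

    def test_level4_mean_of_contributing_terms(self):
        reg = self._registry()
        # two ROS terms get overlaps 20 and 40 -> level-4 mean 30
        overlaps = {}
        for t in reg.terms:
            if t.level4_process == "ROS":
                overlaps[t.term_id] = 20.0 if t.level1_assay == "viability" else 40.0
            else:
                overlaps[t.term_id] = 5.0
        rep = bm.enrich_levels(reg, overlaps)
        assert rep.level4_enrichment["ROS"] == pytest.approx(30.0)
        assert rep.level4_enrichment["DNA Damage"] == pytest.approx(5.0)

    def test_hierarchical_percentage_rule(self):
        # three level-3 phenotypes under one measurement with enrichments
        # (5, 12, 50): two of three pass the >=10% rule -> 66.67
        terms = [
            make_term(["a"], l3=f"ph{i}", l4="G", l1="viability", l2="apoptosis")
            for i in range(3)
        ]
        reg = bm.TermRegistry(terms)
        overlaps = {t.term_id: v for t, v in zip(reg.terms, [5.0, 12.0, 50.0])}
        rep = bm.enrich_levels(reg, overlaps)
        assert rep.hierarchical[("level2", "apoptosis")] == pytest.approx(200 / 3)
        assert rep.hierarchical[("level1", "viability")] == pytest.approx(100.0)

    def test_singleton_registry_levels_equal_overlap(self):
        reg = bm.TermRegistry([make_term(["a", "b"])])
        rep = bm.enrich_levels(reg, {reg.term_ids[0]: 37.5})
        assert rep.level3_enrichment == {"vb_percent_dead": 37.5}
        assert rep.level4_enrichment == {"Chromatin Modifiers": 37.5}

    def test_means_bounded_by_contributions(self, rng):
        reg = self._registry()
        overlaps = {tid: float(v) for tid, v in
                    zip(reg.term_ids, rng.uniform(0, 100, len(reg)))}
        rep = bm.enrich_levels(reg, overlaps)
        for label, val in rep.level4_enrichment.items():
            contrib = [overlaps[t.term_id] for t in reg.terms
                       if t.level4_process == label]
            assert min(contrib) - 1e-9 <= val <= max(contrib) + 1e-9

    def test_missing_term_rejected(self):
        reg = self._registry()
        with pytest.raises(ValueError, match="missing"):
            bm.enrich_levels(reg, {})


class TestTopK:
    def _report(self, scores):
        return bm.EnrichmentReport({}, dict(scores), dict(scores), {})

    def test_tie_broken_alphabetically(self):
        rep = self._report({"B": 10.0, "A": 30.0, "C": 30.0})
        assert bm.top_k(rep, "level3", 2) == ["A", "C"]

    def test_k_larger_than_labels(self):
        rep = self._report({"A": 1.0, "B": 2.0})
        assert bm.top_k(rep, "level4", 10) == ["B", "A"]

    def test_ranking_invariant_under_scaling(self):
        scores = {"A": 5.0, "B": 50.0, "C": 20.0}
        rep1 = self._report(scores)
        rep2 = self._report({k: 3.7 * v for k, v in scores.items()})
        assert bm.top_k(rep1, "level3", 3) == bm.top_k(rep2, "level3", 3)
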