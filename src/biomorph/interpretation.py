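"""Mapping model importances and per-compound attributions into term space.

Given a fitted activity model on raw morphological features, interpretation
proceeds in three stages:

1. *Important features* — the features whose importance (model-level
   impurity importance, or per-compound additive attribution) exceeds the
   mean plus two standard deviations of the importance vector.
2. *Term overlap* — for every registry term, the percentage of its level-5
   feature subset present among the important features.
3. *Level enrichment* — per level-3 phenotype and level-4 process label, the
   arithmetic mean overlap of all terms carrying that label; and a
   hierarchical roll-up in which the enrichment of a level is the percentage
   of its immediate lower level's entries with enrichment >= 10%.

Per-compound attributions are additive decision-path contributions of the
forest's positive-class probability: walking each tree along the compound's
decision path, the change in the node-wise positive-class probability at
every split is credited to the split feature.  The attributions satisfy
local accuracy (they sum to the predicted score minus the forest's root
baseline) and give exactly zero to features the forest never splits on.
Per-compound reports use true positives only and keep positive
contributions, which push the prediction toward activity.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.exceptions import NotFittedError
from sklearn.utils.validation import check_is_fitted

from .term_builder import BioMorphTerm, TermRegistry

__all__ = [
    "ImportantFeatureSet",
    "EnrichmentReport",
    "select_important",
    "attribute_compound",
    "term_overlap",
    "enrich_levels",
    "top_k",
    "interpret_model",
    "interpret_compound",
]

logger = logging.getLogger("biomorph.interpret")

ENRICHMENT_CUTOFF = 10.0  # percent, for the hierarchical roll-up


@dataclass
class ImportantFeatureSet:
    feature_names: set[str]
    rule: str
    source: Literal["model_importance", "per_compound_attribution"]
    threshold_value: float


@dataclass
class EnrichmentReport:
    per_term_overlap: dict[str, float]
    level3_enrichment: dict[str, float]
    level4_enrichment: dict[str, float]
    hierarchical: dict[tuple[str, str], float]

    def write(self, prefix: str | Path) -> None:
        prefix = Path(prefix)
        pd.DataFrame(
            sorted(self.per_term_overlap.items()), columns=["term_id", "overlap_pct"]
        ).to_csv(prefix.with_suffix(".csv"), index=False)
        payload = {
            "level3_enrichment": self.level3_enrichment,
            "level4_enrichment": self.level4_enrichment,
            "hierarchical": {f"{lvl}:{lab}": v for (lvl, lab), v in self.hierarchical.items()},
        }
        prefix.with_suffix(".json").write_text(
            json.dumps(payload, indent=2, sort_keys=True) + "\n"
        )


def select_important(
    importances: pd.Series | np.ndarray,
    source: Literal["model_importance", "per_compound_attribution"] = "model_importance",
    sd_convention: Literal["population", "sample"] = "population",
    strict: bool = True,
) -> ImportantFeatureSet:
    """Features whose importance exceeds mean + 2·SD of the vector.

    Population SD and a strict inequality by default (both switchable): a
    constant vector has SD 0 and nothing strictly exceeds its mean, so the
    selection is empty.
    """
    if not isinstance(importances, pd.Series):
        importances = pd.Series(
            np.asarray(importances, dtype=float),
            index=[f"f{i}" for i in range(len(importances))],
        )
    if importances.size < 2:
        raise ValueError("need at least 2 features")
    ddof = 0 if sd_convention == "population" else 1
    cut = float(importances.mean() + 2 * importances.std(ddof=ddof))
    mask = importances > cut if strict else importances >= cut
    return ImportantFeatureSet(
        feature_names=set(importances.index[mask]),
        rule="mean_plus_2sd",
        source=source,
        threshold_value=cut,
    )


def _positive_class_index(model: RandomForestClassifier) -> int:
    classes = list(model.classes_)
    return classes.index(1) if 1 in classes else len(classes) - 1


def attribute_compound(
    model: RandomForestClassifier, x_row: pd.Series | np.ndarray
) -> pd.Series:
    """Additive per-feature attribution of one prediction.

    Decision-path contributions averaged over the forest's trees; the values
    sum to ``predict_proba(x)[positive] − baseline`` where the baseline is
    the mean root-node positive-class probability.
    """
    try:
        check_is_fitted(model)
    except NotFittedError as exc:
        raise ValueError("model must be fitted before attribution") from exc
    if isinstance(x_row, pd.Series):
        names = list(x_row.index)
        x = x_row.to_numpy(dtype=float)
    else:
        x = np.asarray(x_row, dtype=float).ravel()
        names = [f"f{i}" for i in range(x.size)]
    pos = _positive_class_index(model)
    contrib = np.zeros(x.size)
    for est in model.estimators_:
        t = est.tree_
        value = t.value[:, 0, :]
        prob = value[:, pos] / value.sum(axis=1)
        node = 0
        while t.children_left[node] != -1:
            f = t.feature[node]
            child = (
                t.children_left[node]
                if x[f] <= t.threshold[node]
                else t.children_right[node]
            )
            contrib[f] += prob[child] - prob[node]
            node = child
    contrib /= len(model.estimators_)
    return pd.Series(contrib, index=names)


def forest_baseline(model: RandomForestClassifier) -> float:
    """Mean root-node positive-class probability across the forest."""
    pos = _positive_class_index(model)
    roots = [
        est.tree_.value[0, 0, pos] / est.tree_.value[0, 0, :].sum()
        for est in model.estimators_
    ]
    return float(np.mean(roots))


def term_overlap(important: ImportantFeatureSet, term: BioMorphTerm) -> float:
    """Percentage of the term's level-5 features among the important set."""
    feats = term.level5_features
    return 100.0 * len(important.feature_names & feats) / len(feats)


def enrich_levels(
    registry: TermRegistry, per_term_overlap: dict[str, float]
) -> EnrichmentReport:
    """Aggregate per-term overlaps by annotation label and roll them upward.

    Label scores are arithmetic means over the terms carrying the label.
    The hierarchical block scores each level-2 measurement by the fraction
    of its level-3 phenotypes enriched >= 10%, and each level-1 assay by the
    fraction of its level-2 measurements that pass the same rule.
    """
    missing = [t.term_id for t in registry.terms if t.term_id not in per_term_overlap]
    if missing:
        raise ValueError(f"per_term_overlap missing terms: {missing[:5]}")

    by_l3: dict[str, list[float]] = {}
    by_l4: dict[str, list[float]] = {}
    l3_parent: dict[str, str] = {}  # level3 -> level2
    l2_parent: dict[str, str] = {}  # level2 -> level1
    for t in registry.terms:
        ov = per_term_overlap[t.term_id]
        by_l3.setdefault(t.level3_phenotype, []).append(ov)
        by_l4.setdefault(t.level4_process, []).append(ov)
        l3_parent[t.level3_phenotype] = t.level2_measurement
        l2_parent[t.level2_measurement] = t.level1_assay

    level3 = {k: float(np.mean(v)) for k, v in by_l3.items()}
    level4 = {k: float(np.mean(v)) for k, v in by_l4.items()}

    hierarchical: dict[tuple[str, str], float] = {}
    for l2 in sorted(set(l3_parent.values())):
        children = [l3 for l3, parent in l3_parent.items() if parent == l2]
        passed = sum(level3[c] >= ENRICHMENT_CUTOFF for c in children)
        hierarchical[("level2", l2)] = 100.0 * passed / len(children)
    for l1 in sorted(set(l2_parent.values())):
        children = [l2 for l2, parent in l2_parent.items() if parent == l1]
        passed = sum(
            hierarchical[("level2", c)] >= ENRICHMENT_CUTOFF for c in children
        )
        hierarchical[("level1", l1)] = 100.0 * passed / len(children)

    return EnrichmentReport(
        per_term_overlap=dict(per_term_overlap),
        level3_enrichment=level3,
        level4_enrichment=level4,
        hierarchical=hierarchical,
    )


def top_k(
    report: EnrichmentReport, level: Literal["level3", "level4"], k: int
) -> list[str]:
    """Labels ranked by descending enrichment, alphabetical on ties."""
    if k < 1:
        raise ValueError("k must be >= 1")
    scores = (
        report.level3_enrichment if level == "level3" else report.level4_enrichment
    )
    ranked = sorted(scores.items(), key=lambda kv: (-kv[1], kv[0]))
    return [label for label, _ in ranked[:k]]


# ---------------------------------------------------------------------------
# convenience drivers


def interpret_model(
    model: RandomForestClassifier,
    feature_names: list[str],
    registry: TermRegistry,
) -> EnrichmentReport:
    """Enrichment report from the model's impurity importances."""
    importances = pd.Series(model.feature_importances_, index=feature_names)
    important = select_important(importances, source="model_importance")
    overlaps = {t.term_id: term_overlap(important, t) for t in registry.terms}
    return enrich_levels(registry, overlaps)


def interpret_compound(
    model: RandomForestClassifier,
    x_row: pd.Series,
    registry: TermRegistry,
) -> EnrichmentReport:
    """Enrichment report for one compound from its positive attributions."""
    attr = attribute_compound(model, x_row)
    positive = attr.clip(lower=0.0)
    important = select_important(positive, source="per_compound_attribution")
    overlaps = {t.term_id: term_overlap(important, t) for t in registry.terms}
    return enrich_levels(registry, overlaps)
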