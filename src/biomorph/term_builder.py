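"""Construction of the annotated term registry from a paired CRISPR panel.

A *term* ties together five levels of annotation: the cell-health assay type
(level 1), the measurement type within it (level 2), one specific continuous
readout (level 3), one perturbed cell process — a group of CRISPR
perturbations (level 4) — and the subset of morphological features that
carries their joint signal (level 5).

The build walks every readout and every non-control perturbation group
through four gated steps:

  A. all-relevant feature selection of the profile features informative for
     the readout (regression task);
  B. a baseline linear-regression gate on that subset — keep the readout only
     if held-out R² > 0.25 on a random 80/20 split;
  C. within the step-A subset, all-relevant selection of the features that
     separate the perturbation group from the pooled negative controls
     (classification task, controls + group rows only);
  D. a baseline random-forest gate on the step-C subset — keep the
     (readout, group) pair only if held-out MCC > 0.50 on a stratified 80/20
     split.

Every quadruple that survives both gates becomes one term whose level-5
feature set is the step-C subset; by construction it is nested inside the
step-A subset of its readout.
"""

from __future__ import annotations

import hashlib
import json
import logging
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LinearRegression
from sklearn.metrics import matthews_corrcoef, r2_score
from sklearn.model_selection import train_test_split

from .profiles_io import HealthReadoutTable, MorphProfileTable, PerturbationMeta
from .selection import SelectionConfig, all_relevant_select

__all__ = [
    "GateResult",
    "BioMorphTerm",
    "TermRegistry",
    "TermBuildConfig",
    "gate_readout_regression",
    "gate_group_classifier",
    "build_registry",
    "write_registry",
    "read_registry",
    "RegistrySchemaError",
]

logger = logging.getLogger("biomorph.terms")

REGISTRY_SCHEMA_VERSION = 1

R2_GATE_THRESHOLD = 0.25
MCC_GATE_THRESHOLD = 0.50


class RegistrySchemaError(ValueError):
    """Registry file fails schema or invariant checks."""


@dataclass
class GateResult:
    metric_name: str  # "r_squared" | "mcc"
    value: float
    passed: bool
    split_seed: int

    def to_dict(self) -> dict:
        return {
            "metric_name": self.metric_name,
            "value": float(self.value),
            "passed": bool(self.passed),
            "split_seed": int(self.split_seed),
        }


@dataclass
class BioMorphTerm:
    """One registry entry; ``term_id`` concatenates the four label levels."""

    level1_assay: str
    level2_measurement: str
    level3_phenotype: str
    level4_process: str
    level5_features: frozenset[str]
    regression_gate: GateResult
    classifier_gate: GateResult

    def __post_init__(self) -> None:
        self.level5_features = frozenset(self.level5_features)
        if not self.level5_features:
            raise ValueError("level5 feature set must be non-empty")

    @property
    def term_id(self) -> str:
        return "_".join(
            [
                self.level1_assay,
                self.level2_measurement,
                self.level3_phenotype,
                self.level4_process,
            ]
        )

    def to_dict(self) -> dict:
        return {
            "term_id": self.term_id,
            "level1_assay": self.level1_assay,
            "level2_measurement": self.level2_measurement,
            "level3_phenotype": self.level3_phenotype,
            "level4_process": self.level4_process,
            "level5_features": sorted(self.level5_features),
            "regression_gate": self.regression_gate.to_dict(),
            "classifier_gate": self.classifier_gate.to_dict(),
        }


@dataclass
class TermRegistry:
    terms: list[BioMorphTerm]
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        ids = [t.term_id for t in self.terms]
        if len(ids) != len(set(ids)):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise RegistrySchemaError(f"duplicate term_ids: {dupes}")
        self.terms = sorted(self.terms, key=lambda t: t.term_id)

    def __len__(self) -> int:
        return len(self.terms)

    def __iter__(self):
        return iter(self.terms)

    @property
    def term_ids(self) -> list[str]:
        return [t.term_id for t in self.terms]

    def feature_universe(self) -> set[str]:
        out: set[str] = set()
        for t in self.terms:
            out |= t.level5_features
        return out


@dataclass
class TermBuildConfig:
    """Configuration for a registry build.

    ``readout_annotations`` maps each readout name to its (level-1 assay,
    level-2 measurement) labels, mirroring the readout-annotation CSV
    ``readout_name,level1_assay,level2_measurement``.
    """

    readout_annotations: dict[str, tuple[str, str]]
    selection: SelectionConfig = field(default_factory=SelectionConfig)
    r2_threshold: float = R2_GATE_THRESHOLD
    mcc_threshold: float = MCC_GATE_THRESHOLD
    seed: int = 0


# ---------------------------------------------------------------------------
# gates


def gate_readout_regression(
    X_subset: pd.DataFrame | np.ndarray,
    y_readout: np.ndarray | pd.Series,
    split_seed: int,
    threshold: float = R2_GATE_THRESHOLD,
) -> GateResult:
    """Hold-out R² gate: OLS on a random 80/20 split, pass iff R² > threshold."""
    X = np.asarray(X_subset, dtype=float)
    if X.ndim != 2 or X.shape[1] == 0:
        return GateResult("r_squared", -math.inf, False, split_seed)
    y = np.asarray(y_readout, dtype=float)
    if X.shape[0] < 10:
        raise ValueError("need >= 10 rows for the regression gate")
    X_tr, X_te, y_tr, y_te = train_test_split(
        X, y, test_size=0.2, random_state=split_seed
    )
    model = LinearRegression().fit(X_tr, y_tr)
    r2 = float(r2_score(y_te, model.predict(X_te)))
    return GateResult("r_squared", r2, r2 > threshold, split_seed)


def gate_group_classifier(
    X_subset: pd.DataFrame | np.ndarray,
    y_group: np.ndarray | pd.Series,
    split_seed: int,
    threshold: float = MCC_GATE_THRESHOLD,
) -> GateResult:
    """Hold-out MCC gate: random forest on a stratified 80/20 split.

    Predictions use the 0.5 probability cut; pass iff MCC > threshold.
    ``y_group`` is the binary group-membership vector (controls = 0).
    """
    X = np.asarray(X_subset, dtype=float)
    y = np.asarray(y_group).astype(int)
    if X.ndim != 2 or X.shape[1] == 0:
        return GateResult("mcc", -1.0, False, split_seed)
    if np.unique(y).size < 2:
        return GateResult("mcc", -1.0, False, split_seed)
    X_tr, X_te, y_tr, y_te = train_test_split(
        X, y, test_size=0.2, random_state=split_seed, stratify=y
    )
    if np.unique(y_tr).size < 2 or np.unique(y_te).size < 2:
        return GateResult("mcc", -1.0, False, split_seed)
    clf = RandomForestClassifier(random_state=split_seed, n_jobs=1).fit(X_tr, y_tr)
    proba = clf.predict_proba(X_te)[:, list(clf.classes_).index(1)]
    mcc = float(matthews_corrcoef(y_te, (proba >= 0.5).astype(int)))
    return GateResult("mcc", mcc, mcc > threshold, split_seed)


# ---------------------------------------------------------------------------
# registry build


def _digest(df: pd.DataFrame) -> str:
    return hashlib.sha256(
        df.to_csv(float_format="%.10g").encode()
    ).hexdigest()[:16]


def build_registry(
    profiles: MorphProfileTable,
    readouts: HealthReadoutTable,
    meta: PerturbationMeta,
    config: TermBuildConfig,
) -> TermRegistry:
    """Run the four-step gated build over every readout × perturbation group.

    Tables must be row-aligned (readouts/meta are reindexed to the profile
    rows).  Gate split seeds derive from the master seed plus the readout and
    group indices so each gate is independently reproducible.
    """
    readouts = readouts.align_to(profiles)
    meta.validate_for_terms(profiles)
    unmapped = [r for r in readouts.readout_names if r not in config.readout_annotations]
    if unmapped:
        raise ValueError(f"readouts missing level-1/2 annotations: {unmapped}")

    row_ids = profiles.row_ids
    ctrl_mask = meta.control_mask(row_ids)
    groups = meta.group_labels(row_ids)
    group_names = sorted(set(groups[~ctrl_mask]))

    terms: list[BioMorphTerm] = []
    for i, readout in enumerate(readouts.readout_names):
        y = readouts.data[readout].to_numpy()
        sel_cfg_a = SelectionConfig(
            max_iter=config.selection.max_iter,
            alpha=config.selection.alpha,
            estimator_max_depth=config.selection.estimator_max_depth,
            estimator_trees=config.selection.estimator_trees,
            task="regression",
            seed=config.seed + 7919 * (i + 1),
        )
        step_a = sorted(all_relevant_select(profiles, y, sel_cfg_a).confirmed)
        if not step_a:
            logger.info("readout %s: empty step-A subset, skipped", readout)
            continue
        gate_b = gate_readout_regression(
            profiles.data[step_a], y, split_seed=config.seed + 1000 * (i + 1),
            threshold=config.r2_threshold,
        )
        if not gate_b.passed:
            logger.info("readout %s: R²=%.3f failed gate", readout, gate_b.value)
            continue
        l1, l2 = config.readout_annotations[readout]
        for j, group in enumerate(group_names):
            pick = ctrl_mask | (groups == group).to_numpy()
            y_grp = (~ctrl_mask[pick]).astype(int)
            X_pair = profiles.data.loc[pick, step_a]
            sel_cfg_c = SelectionConfig(
                max_iter=config.selection.max_iter,
                alpha=config.selection.alpha,
                estimator_max_depth=config.selection.estimator_max_depth,
                estimator_trees=config.selection.estimator_trees,
                task="classification",
                seed=config.seed + 7919 * (i + 1) + 104729 * (j + 1),
            )
            step_c = sorted(all_relevant_select(X_pair, y_grp, sel_cfg_c).confirmed)
            if not step_c:
                continue
            gate_d = gate_group_classifier(
                X_pair[step_c], y_grp,
                split_seed=config.seed + 1000 * (i + 1) + (j + 1),
                threshold=config.mcc_threshold,
            )
            if not gate_d.passed:
                continue
            terms.append(
                BioMorphTerm(
                    level1_assay=l1,
                    level2_measurement=l2,
                    level3_phenotype=readout,
                    level4_process=group,
                    level5_features=frozenset(step_c),
                    regression_gate=gate_b,
                    classifier_gate=gate_d,
                )
            )
            logger.info(
                "term %s: |level5|=%d, R²=%.3f, MCC=%.3f",
                terms[-1].term_id, len(step_c), gate_b.value, gate_d.value,
            )

    provenance = {
        "seed": config.seed,
        "r2_threshold": config.r2_threshold,
        "mcc_threshold": config.mcc_threshold,
        "selection": asdict(config.selection),
        "profiles_digest": _digest(profiles.data),
        "readouts_digest": _digest(readouts.data),
        "n_profiles": len(row_ids),
        "n_features": len(profiles.feature_names),
        "n_readouts": len(readouts.readout_names),
    }
    registry = TermRegistry(terms, provenance)
    logger.info("registry built: %d terms", len(registry))
    return registry


# ---------------------------------------------------------------------------
# serialization


def write_registry(registry: TermRegistry, path: str | Path) -> None:
    """Write the registry as schema-versioned JSON, byte-stable for equal inputs."""
    payload = {
        "schema_version": REGISTRY_SCHEMA_VERSION,
        "provenance": registry.provenance,
        "terms": [t.to_dict() for t in registry.terms],
    }
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")


def read_registry(path: str | Path) -> TermRegistry:
    try:
        payload = json.loads(Path(path).read_text())
    except json.JSONDecodeError as exc:
        raise RegistrySchemaError(f"{path}: not valid JSON ({exc})") from None
    version = payload.get("schema_version")
    if version != REGISTRY_SCHEMA_VERSION:
        raise RegistrySchemaError(
            f"{path}: schema version {version!r}, expected {REGISTRY_SCHEMA_VERSION}"
        )
    terms = []
    for t in payload.get("terms", []):
        terms.append(
            BioMorphTerm(
                level1_assay=t["level1_assay"],
                level2_measurement=t["level2_measurement"],
                level3_phenotype=t["level3_phenotype"],
                level4_process=t["level4_process"],
                level5_features=frozenset(t["level5_features"]),
                regression_gate=GateResult(**t["regression_gate"]),
                classifier_gate=GateResult(**t["classifier_gate"]),
            )
        )
    return TermRegistry(terms, payload.get("provenance", {}))
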