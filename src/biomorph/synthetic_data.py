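"""Synthetic paired CRISPR panels and compound screens with planted structure.

The generator emulates the statistical shape the pipeline assumes, at a
scale small enough for routine testing:

* a CRISPR-style panel — standardized morphological features with a
  standard-normal baseline; a pooled negative-control arm; perturbation
  groups whose members share a mean shift of δ feature-SD units on a
  group-specific feature subset; and continuous cell-health readouts, each a
  noisy linear function of a small planted feature subset (weights drawn
  once per scenario);
* a compound screen on the same feature universe in which *active*
  compounds shift a designated planted subset by ±β with a per-compound
  sign.  Profiles are control-subtracted, so a phenotypically active
  compound moves morphology coherently in a compound-specific direction;
  the magnitude, not the sign, of the deviation marks activity.

Ground truth — which (readout, group) pairs share a feature subset, and
which subset drives activity — is exposed so recovery can be scored.

All randomness flows from one master seed through named child streams
(baseline features, readout weights, readout noise, labels, compound
features), so adding a stage never perturbs earlier draws.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .profiles_io import (
    HealthReadoutTable,
    MorphProfileTable,
    PerturbationMeta,
    write_metadata,
    write_table,
)
from .term_builder import BioMorphTerm, GateResult, TermRegistry

__all__ = [
    "SimScenario",
    "default_scenario",
    "all_noise_scenario",
    "generate_crispr_panel",
    "generate_compound_screen",
    "planted_pairs",
    "ground_truth_registry",
    "simulate_to_dir",
]

_STREAM_BASELINE = 0
_STREAM_WEIGHTS = 1
_STREAM_NOISE = 2
_STREAM_LABELS = 3
_STREAM_COMPOUNDS = 4

_CELL_LINES = ["A549", "ES2", "HCC44"]
_COMPARTMENTS = ["Cells", "Nuclei", "Cytoplasm"]
_CHANNELS = ["DNA", "RNA", "ER", "AGP", "Mito"]


def feature_universe(n_features: int) -> list[str]:
    """Deterministic CellProfiler-flavoured feature names."""
    names = []
    for i in range(n_features):
        comp = _COMPARTMENTS[i % len(_COMPARTMENTS)]
        chan = _CHANNELS[(i // len(_COMPARTMENTS)) % len(_CHANNELS)]
        names.append(f"{comp}_Intensity_{chan}_{i:03d}")
    return names


@dataclass
class SimScenario:
    """Full description of one simulated study.

    ``planted_map`` gives each planted readout its driving feature subset;
    ``group_effect_map`` gives each perturbation group the subset it shifts
    and the shift δ (in baseline-SD units).  ``activity_subset`` is the
    subset whose coherent ±β deviation defines compound activity.
    """

    n_features: int
    n_readouts: int
    n_groups: int
    controls_per_dataset: int
    profiles_per_group: int
    planted_map: dict[str, list[str]]
    group_effect_map: dict[str, tuple[list[str], float]]
    readout_annotations: dict[str, tuple[str, str]]
    readout_names: list[str]
    group_names: list[str]
    readout_noise: float = 0.5
    feature_noise: float = 1.0
    activity_effect: float = 1.5
    activity_subset: list[str] = field(default_factory=list)
    n_compounds: int = 200
    activity_prevalence: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_features, self.n_readouts, self.n_groups,
               self.controls_per_dataset, self.profiles_per_group) < 1:
            raise ValueError("all scenario counts must be >= 1")
        if self.activity_effect < 0:
            raise ValueError("activity effect must be >= 0")
        universe = set(feature_universe(self.n_features))
        for name, subset in self.planted_map.items():
            unknown = set(subset) - universe
            if unknown:
                raise ValueError(f"planted subset of {name} references {unknown}")
        for name, (subset, delta) in self.group_effect_map.items():
            if delta < 0:
                raise ValueError(f"group shift for {name} must be >= 0")
            unknown = set(subset) - universe
            if unknown:
                raise ValueError(f"group subset of {name} references {unknown}")
        if set(self.activity_subset) - universe:
            raise ValueError("activity subset references unknown features")

    @property
    def n_profiles(self) -> int:
        return self.controls_per_dataset + self.n_groups * self.profiles_per_group

    def _rng(self, stream: int) -> np.random.Generator:
        return np.random.default_rng(
            np.random.SeedSequence((abs(self.seed) % (2**31), stream))
        )


_DEFAULT_READOUTS = [
    ("vb_percent_dead", ("viability", "cell_death")),
    ("cc_g2_plus_m_fraction", ("cell_cycle", "g2_phase")),
    ("vb_ros_mean_intensity", ("viability", "ros")),
    ("cc_s_phase_fraction", ("cell_cycle", "s_phase")),
    ("vb_percent_apoptotic", ("viability", "apoptosis")),
]

_DEFAULT_GROUPS = [
    "Chromatin Modifiers",
    "DNA Damage",
    "Metabolism",
    "Kinases",
]


def default_scenario(seed: int = 0) -> SimScenario:
    """The study conditions used throughout the test harness.

    200 features; five readouts of which three are planted on disjoint
    8-feature subsets (noise SD 0.5); four perturbation groups of 20
    profiles each plus 30 pooled negative controls, the first three groups
    shifting the corresponding planted subset by δ = 1.5 SD.  Compound
    activity (prevalence 0.5, 200 compounds) lives on the first planted
    subset with effect β = 1.5.
    """
    n_features = 200
    names = feature_universe(n_features)
    subset_size = 8
    readout_names = [r for r, _ in _DEFAULT_READOUTS]
    annotations = dict(_DEFAULT_READOUTS)
    planted = {
        readout_names[k]: names[k * subset_size:(k + 1) * subset_size]
        for k in range(3)
    }
    effects = {
        _DEFAULT_GROUPS[k]: (planted[readout_names[k]], 1.5) for k in range(3)
    }
    return SimScenario(
        n_features=n_features,
        n_readouts=len(readout_names),
        n_groups=len(_DEFAULT_GROUPS),
        controls_per_dataset=30,
        profiles_per_group=20,
        planted_map=planted,
        group_effect_map=effects,
        readout_annotations=annotations,
        readout_names=readout_names,
        group_names=list(_DEFAULT_GROUPS),
        readout_noise=0.5,
        activity_effect=1.5,
        activity_subset=list(planted[readout_names[0]]),
        n_compounds=200,
        activity_prevalence=0.5,
        seed=seed,
    )


def all_noise_scenario(seed: int = 0) -> SimScenario:
    """Null study: no planted readouts, no group shifts, no activity signal."""
    readouts = _DEFAULT_READOUTS[:3]
    return SimScenario(
        n_features=150,
        n_readouts=len(readouts),
        n_groups=3,
        controls_per_dataset=30,
        profiles_per_group=20,
        planted_map={},
        group_effect_map={},
        readout_annotations=dict(readouts),
        readout_names=[r for r, _ in readouts],
        group_names=_DEFAULT_GROUPS[:3],
        activity_effect=0.0,
        activity_subset=feature_universe(150)[:8],
        seed=seed,
    )


def _slug(label: str) -> str:
    return label.lower().replace(" ", "-")


def generate_crispr_panel(
    scenario: SimScenario,
) -> tuple[MorphProfileTable, HealthReadoutTable, PerturbationMeta]:
    """Simulate the paired profile / readout / metadata tables."""
    names = feature_universe(scenario.n_features)
    col = {f: i for i, f in enumerate(names)}
    n = scenario.n_profiles

    X = scenario._rng(_STREAM_BASELINE).normal(
        0.0, scenario.feature_noise, size=(n, scenario.n_features)
    )
    row_ids = [f"control_{i:03d}" for i in range(scenario.controls_per_dataset)]
    group_of_row: list[str | None] = [None] * scenario.controls_per_dataset
    for g in scenario.group_names:
        for i in range(scenario.profiles_per_group):
            row_ids.append(f"{_slug(g)}_{i:03d}")
            group_of_row.append(g)

    for g, (subset, delta) in scenario.group_effect_map.items():
        rows = [i for i, gg in enumerate(group_of_row) if gg == g]
        cols = [col[f] for f in subset]
        X[np.ix_(rows, cols)] += delta

    profiles = MorphProfileTable(pd.DataFrame(X, index=row_ids, columns=names))

    w_rng = scenario._rng(_STREAM_WEIGHTS)
    noise_rng = scenario._rng(_STREAM_NOISE)
    readouts = {}
    for r in scenario.readout_names:
        if r in scenario.planted_map:
            subset = scenario.planted_map[r]
            w = w_rng.normal(0.0, 1.0, size=len(subset))
            y = X[:, [col[f] for f in subset]] @ w
            y = y + noise_rng.normal(0.0, scenario.readout_noise, size=n)
        else:
            w_rng.normal(0.0, 1.0, size=1)  # keep stream alignment stable
            y = noise_rng.normal(0.0, 1.0, size=n)
        readouts[r] = y
    readout_table = HealthReadoutTable(pd.DataFrame(readouts, index=row_ids))

    meta = PerturbationMeta(
        pd.DataFrame(
            {
                "row_id": row_ids,
                "perturbation_id": [f"pert_{i:03d}" for i in range(n)],
                "cell_line": [_CELL_LINES[i % len(_CELL_LINES)] for i in range(n)],
                "group_label": [
                    g if g is not None else "negative_control" for g in group_of_row
                ],
                "is_negative_control": [g is None for g in group_of_row],
            }
        )
    )
    return profiles, readout_table, meta


def generate_compound_screen(
    scenario: SimScenario,
) -> tuple[MorphProfileTable, pd.Series]:
    """Simulate a compound screen and its binary activity labels.

    Active compounds deviate by ±β (per-compound sign, coherent across the
    activity subset) from the control-subtracted baseline.
    """
    names = feature_universe(scenario.n_features)
    col = {f: i for i, f in enumerate(names)}
    n = scenario.n_compounds
    rng_x = scenario._rng(_STREAM_COMPOUNDS)
    rng_y = scenario._rng(_STREAM_LABELS)

    X = rng_x.normal(0.0, 1.0, size=(n, scenario.n_features))
    labels = (rng_y.random(n) < scenario.activity_prevalence).astype(int)
    minority = min(labels.sum(), n - labels.sum())
    if minority < 8:
        raise ValueError(
            f"activity prevalence {scenario.activity_prevalence} leaves only "
            f"{minority} minority compounds (< 8); increase n_compounds"
        )
    if scenario.activity_effect > 0 and scenario.activity_subset:
        signs = np.where(rng_y.random(n) < 0.5, -1.0, 1.0)
        cols = [col[f] for f in scenario.activity_subset]
        active = np.flatnonzero(labels == 1)
        X[np.ix_(active, cols)] += (
            scenario.activity_effect * signs[active][:, None]
        )

    row_ids = [f"CPD-{i:05d}" for i in range(n)]
    profiles = MorphProfileTable(pd.DataFrame(X, index=row_ids, columns=names))
    return profiles, pd.Series(labels, index=row_ids, name="active")


def planted_pairs(scenario: SimScenario) -> set[tuple[str, str]]:
    """(readout, group) pairs that truly share planted features."""
    pairs = set()
    for r, subset in scenario.planted_map.items():
        for g, (g_subset, delta) in scenario.group_effect_map.items():
            if delta > 0 and set(subset) & set(g_subset):
                pairs.add((r, g))
    return pairs


def ground_truth_registry(scenario: SimScenario) -> TermRegistry:
    """The scenario's defining terms, built from ground truth (synthetic).

    One term per planted (readout, group) pair with the shared feature
    subset as level 5 and sentinel gate results; a harness object for
    testing the scoring and interpretation stages in isolation from the
    registry build.
    """
    terms = []
    for r, g in sorted(planted_pairs(scenario)):
        shared = sorted(set(scenario.planted_map[r]) & set(scenario.group_effect_map[g][0]))
        l1, l2 = scenario.readout_annotations[r]
        terms.append(
            BioMorphTerm(
                level1_assay=l1,
                level2_measurement=l2,
                level3_phenotype=r,
                level4_process=g,
                level5_features=frozenset(shared),
                regression_gate=GateResult("r_squared", 1.0, True, scenario.seed),
                classifier_gate=GateResult("mcc", 1.0, True, scenario.seed),
            )
        )
    return TermRegistry(terms, {"synthetic_ground_truth": True, "seed": scenario.seed})


def simulate_to_dir(scenario: SimScenario, outdir: str | Path) -> dict[str, Path]:
    """Write the simulated tables plus a ground-truth JSON for harness use."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    profiles, readouts, meta = generate_crispr_panel(scenario)
    screen, labels = generate_compound_screen(scenario)
    paths = {
        "profiles": outdir / "crispr_profiles.csv",
        "readouts": outdir / "cell_health_readouts.csv",
        "meta": outdir / "perturbation_meta.csv",
        "annotations": outdir / "readout_annotations.csv",
        "screen": outdir / "compound_profiles.csv",
        "labels": outdir / "activity_labels.csv",
        "ground_truth": outdir / "ground_truth.json",
    }
    write_table(profiles, paths["profiles"])
    write_table(readouts, paths["readouts"])
    write_metadata(meta, paths["meta"])
    pd.DataFrame(
        [(r, l1, l2) for r, (l1, l2) in scenario.readout_annotations.items()],
        columns=["readout_name", "level1_assay", "level2_measurement"],
    ).to_csv(paths["annotations"], index=False)
    write_table(screen, paths["screen"])
    labels.rename_axis("row_id").reset_index().to_csv(paths["labels"], index=False)
    truth = {
        "planted_map": scenario.planted_map,
        "group_effect_map": {
            g: {"features": s, "delta": d}
            for g, (s, d) in scenario.group_effect_map.items()
        },
        "planted_pairs": sorted(planted_pairs(scenario)),
        "activity_subset": scenario.activity_subset,
        "activity_effect": scenario.activity_effect,
        "seed": scenario.seed,
    }
    paths["ground_truth"].write_text(json.dumps(truth, indent=2, sort_keys=True) + "\n")
    return paths
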