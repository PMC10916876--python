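"""Transforming profiles into the annotated term space via a group-level χ².

For a profile whose features have been column-standardized against a
reference population, the score of a term with feature subset S is the
classical set-level aggregation statistic

    T = sum_{j in S} z_j²,   p = P(χ²_{|S|} >= T),

i.e. the squared standardized deviations summed over the subset, referred to
an upper-tail χ² with one degree of freedom per feature.  Under the null of
no deviation from the reference the z_j are approximately standard normal
and T is χ²-distributed; a strong coherent deviation on the subset — in
either direction, the statistic is sign-free — drives p toward 0.

The statistic is pluggable: ``transform`` accepts any callable with the
signature of :func:`score_term` so alternative set-level aggregations
(e.g. Fisher-combined per-feature tests) can be swapped in.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Callable

import numpy as np
import pandas as pd
from scipy.stats import chi2

from .profiles_io import MorphProfileTable, standardize_features
from .term_builder import BioMorphTerm, TermRegistry

__all__ = ["TermScore", "BioMorphMatrix", "score_term", "transform"]

logger = logging.getLogger("biomorph.scoring")

P_CLAMP = 1e-300  # floor for the optional -log10 output mode


@dataclass
class TermScore:
    statistic: float
    dof: int
    p_value: float


def score_term(
    z_profile: pd.Series | dict[str, float], term: BioMorphTerm
) -> TermScore:
    """Score one standardized profile against one term.

    ``z_profile`` maps feature names to standardized values; every level-5
    feature of the term must be present.
    """
    if isinstance(z_profile, dict):
        z_profile = pd.Series(z_profile)
    feats = sorted(term.level5_features)
    missing = [f for f in feats if f not in z_profile.index]
    if missing:
        raise KeyError(f"profile lacks term features: {missing}")
    z = z_profile[feats].to_numpy(dtype=float)
    stat = float(np.sum(z**2))
    dof = len(feats)
    p = float(chi2.sf(stat, dof))
    return TermScore(statistic=stat, dof=dof, p_value=p)


@dataclass
class BioMorphMatrix:
    """Profiles × terms: raw upper-tail p-values and their standardized form.

    ``values`` holds the column-standardized scores actually used for
    modelling; ``raw_p`` the untransformed p-values; ``retained_terms`` the
    term ids that survived the finiteness / non-degeneracy filter.
    """

    raw_p: pd.DataFrame
    values: pd.DataFrame
    retained_terms: list[str]

    @property
    def row_ids(self) -> list[str]:
        return self.values.index.tolist()

    @property
    def term_ids(self) -> list[str]:
        return self.raw_p.columns.tolist()

    def as_profile_table(self) -> MorphProfileTable:
        return MorphProfileTable(self.values.copy())


def transform(
    profiles: MorphProfileTable,
    registry: TermRegistry,
    scaling_reference: MorphProfileTable | tuple[pd.Series, pd.Series] | None = None,
    log10_mode: bool = False,
    statistic: Callable[[pd.Series, BioMorphTerm], TermScore] = score_term,
) -> BioMorphMatrix:
    """Map a profile table into the term space.

    Profiles are column-standardized against ``scaling_reference`` (default:
    the table itself, i.e. per-dataset scaling), every (profile, term) pair
    is scored, and the per-term p-value columns are standardized to zero mean
    and unit variance.  Terms referencing features absent from the table are
    dropped with a warning; columns that are non-finite anywhere or have zero
    variance (e.g. a term whose features are constant across the dataset) are
    dropped from ``retained_terms``.  With ``log10_mode`` the standardized
    quantity is −log10(p) with p floored at 1e-300.
    """
    if len(registry) == 0:
        raise ValueError("empty registry: nothing to score")
    available = set(profiles.feature_names)
    usable = [t for t in registry.terms if t.level5_features <= available]
    skipped = len(registry) - len(usable)
    if skipped:
        warnings.warn(
            f"{skipped} term(s) dropped: features absent from the profile table",
            UserWarning,
            stacklevel=2,
        )
    if not usable:
        raise ValueError("no registry term is scorable on this table")

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)  # zero-variance features
        z_table = standardize_features(profiles, scaling_reference)

    cols = {}
    if statistic is score_term:  # vectorized fast path, same arithmetic
        Z = z_table.data
        for term in usable:
            feats = sorted(term.level5_features)
            stat = (Z[feats].to_numpy(dtype=float) ** 2).sum(axis=1)
            cols[term.term_id] = chi2.sf(stat, len(feats))
    else:
        for term in usable:
            cols[term.term_id] = np.array(
                [statistic(z_table.data.loc[r], term).p_value for r in z_table.row_ids]
            )
    raw_p = pd.DataFrame(cols, index=z_table.data.index)
    raw_p.index.name = "row_id"

    quantity = raw_p.copy()
    if log10_mode:
        quantity = -np.log10(quantity.clip(lower=P_CLAMP))

    finite = np.isfinite(quantity.to_numpy()).all(axis=0)
    std = quantity.std(axis=0, ddof=0).to_numpy()
    keep = finite & (std > 0)
    retained = [c for c, k in zip(quantity.columns, keep) if k]
    if not retained:
        raise ValueError("zero terms retained after finiteness/variance filter")
    dropped = [c for c, k in zip(quantity.columns, keep) if not k]
    if dropped:
        logger.info("dropped %d degenerate term column(s): %s", len(dropped), dropped)

    kept = quantity[retained]
    standardized = (kept - kept.mean(axis=0)) / kept.std(axis=0, ddof=0)
    return BioMorphMatrix(raw_p=raw_p, values=standardized, retained_terms=retained)
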