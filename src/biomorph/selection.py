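"""All-relevant feature selection by competition against shadow features.

The selector answers "which features carry *any* information about the
response", not "which minimal subset predicts best".  Each iteration appends
one row-permuted shadow copy of every undecided feature, fits a random
forest, and scores a real feature a *hit* when its impurity importance beats
the best shadow importance — the shadows calibrate what an uninformative
feature of the same marginal distribution can achieve by chance.  Accumulated
hits are tested against the 0.5 null with a two-sided binomial test,
Bonferroni-corrected over the undecided features: significantly more hits
than expected confirms a feature, significantly fewer rejects it.  Decided
features leave the real-feature design, but the shadow pool always covers
every original feature so the competition bar keeps a stable reference
distribution.  Features still undecided at the iteration cap are *tentative*
and are treated as not selected downstream.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Literal

import numpy as np
import pandas as pd
from scipy.stats import binom
from sklearn.ensemble import RandomForestClassifier, RandomForestRegressor

from .profiles_io import MorphProfileTable

__all__ = ["SelectionConfig", "SelectionResult", "all_relevant_select"]

logger = logging.getLogger("biomorph.selection")


@dataclass
class SelectionConfig:
    """Knobs for the shadow-feature selector.

    alpha is the level of the binomial decision test (Bonferroni-corrected
    over undecided features each iteration).  ``estimator_trees="auto"``
    resolves to ``10 * ceil(sqrt(n_active_features))`` clipped to [64, 512],
    a declared reproducible rule.
    """

    max_iter: int = 100
    alpha: float = 0.05
    estimator_max_depth: int = 5
    estimator_trees: int | Literal["auto"] = "auto"
    task: Literal["regression", "classification"] = "regression"
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")

    def n_trees(self, n_features: int) -> int:
        if self.estimator_trees == "auto":
            return int(np.clip(10 * math.ceil(math.sqrt(n_features)), 64, 512))
        return int(self.estimator_trees)


@dataclass
class SelectionResult:
    """Partition of the feature set plus the per-iteration hit record."""

    confirmed: set[str]
    rejected: set[str]
    tentative: set[str]
    hit_history: dict[str, list[int]] = field(repr=False)

    @property
    def n_iterations(self) -> int:
        return max((len(v) for v in self.hit_history.values()), default=0)


def _estimator(config: SelectionConfig, n_features: int, seed: int):
    kwargs = dict(
        n_estimators=config.n_trees(n_features),
        max_depth=config.estimator_max_depth,
        max_features="sqrt",  # shadow competition convention
        random_state=seed,
        n_jobs=1,
    )
    if config.task == "classification":
        return RandomForestClassifier(**kwargs)
    return RandomForestRegressor(**kwargs)


def all_relevant_select(
    X: MorphProfileTable | pd.DataFrame,
    y: np.ndarray | pd.Series,
    config: SelectionConfig,
) -> SelectionResult:
    """Partition features into confirmed / rejected / tentative w.r.t. y.

    Deterministic under a fixed config seed: shadow permutations use one
    child RNG stream per iteration derived from the seed, and every forest's
    random state is seeded from the same stream.
    """
    data = X.data if isinstance(X, MorphProfileTable) else X
    y = np.asarray(y)
    if data.shape[0] != y.shape[0]:
        raise ValueError("X rows and y length differ")
    if data.shape[0] < 10:
        raise ValueError("need at least 10 rows for selection")
    if np.unique(y[~pd.isna(y)]).size < 2:
        raise ValueError("y is constant; nothing to select against")

    names = list(data.columns)
    values = np.ascontiguousarray(data.to_numpy(dtype=np.float32))
    p = len(names)
    hits = np.zeros(p, dtype=int)
    trials = np.zeros(p, dtype=int)
    status = np.zeros(p, dtype=int)  # 0 undecided, 1 confirmed, -1 rejected
    history: dict[str, list[int]] = {n: [] for n in names}

    for it in range(1, config.max_iter + 1):
        undecided = np.flatnonzero(status == 0)
        if undecided.size == 0:
            break
        rng = np.random.default_rng([abs(config.seed) % (2**31), it])
        # shadow copies of EVERY original feature (not only the undecided
        # ones): the competition bar — the maximum shadow importance — then
        # has a stable reference distribution across iterations
        shadows = rng.permuted(values, axis=0)
        Xa = values[:, undecided]
        est = _estimator(config, p, int(rng.integers(2**31)))
        est.fit(np.hstack([Xa, shadows]), y)
        imp = est.feature_importances_
        hit_now = imp[: undecided.size] > imp[undecided.size:].max()
        hits[undecided] += hit_now
        trials[undecided] += 1
        for k, j in enumerate(undecided):
            history[names[j]].append(int(hit_now[k]))

        # two-sided binomial on accumulated hits at 0.5, Bonferroni over the
        # currently undecided features; skip while no decision is reachable
        level = config.alpha / undecided.size
        if 2.0 * 0.5**it >= level:
            continue
        k_arr = hits[undecided]
        n_arr = trials[undecided]
        pval = np.minimum(
            1.0,
            2.0
            * np.minimum(
                binom.cdf(k_arr, n_arr, 0.5), binom.sf(k_arr - 1, n_arr, 0.5)
            ),
        )
        decided = pval < level
        status[undecided[decided & (k_arr > n_arr / 2)]] = 1
        status[undecided[decided & (k_arr < n_arr / 2)]] = -1

        # stop early when every remaining feature is undecidable within the
        # iteration budget even under an all-hit / all-miss future (such
        # features end tentative regardless); the Bonferroni level is frozen
        # at its current value for this horizon check
        still = np.flatnonzero(status == 0)
        if still.size and it < config.max_iter:
            k_s, n_s = hits[still], trials[still]
            horizon = config.max_iter
            best_confirm = np.minimum(
                1.0, 2.0 * binom.sf(k_s + (horizon - n_s) - 1, horizon, 0.5)
            )
            best_reject = np.minimum(1.0, 2.0 * binom.cdf(k_s, horizon, 0.5))
            if (np.minimum(best_confirm, best_reject) >= level).all():
                logger.debug("iter %d: remaining %d undecidable, stopping",
                             it, still.size)
                break
        logger.debug(
            "iter %d: %d confirmed, %d rejected, %d undecided",
            it, int((status == 1).sum()), int((status == -1).sum()),
            int((status == 0).sum()),
        )

    confirmed = {names[j] for j in range(len(names)) if status[j] == 1}
    rejected = {names[j] for j in range(len(names)) if status[j] == -1}
    tentative = set(names) - confirmed - rejected
    logger.info(
        "selection done: %d confirmed, %d rejected, %d tentative",
        len(confirmed), len(rejected), len(tentative),
    )
    return SelectionResult(confirmed, rejected, tentative, history)
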