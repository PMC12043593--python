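"""Shapley-value engine: exact enumeration, permutation sampling, bootstrap.

Regions are players in a coalitional game.  A coalition S is the set of
INTACT elements and the characteristic function v(S) is the system's
performance when exactly the elements of S are intact and all others are
perturbed; v(∅) is the all-lesioned performance.  With this orientation a
positive Shapley value means "damaging the element decreases performance".

Three computations are provided:

* :func:`exact_shapley` — full enumeration of all 2^n coalitions, the
  oracle for small games (n ≤ 20);
* :func:`estimated_shapley` — the unbiased Monte-Carlo estimator that
  averages marginal contributions over R uniformly sampled orderings of
  the elements;
* :func:`bootstrap_msa` — the estimator wrapped in patient-level bootstrap
  resampling, retraining the surrogate predictor on each resample, giving
  per-region means, standard errors, percentile confidence intervals and
  significance flags.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from typing import Callable, Optional

import numpy as np
import pandas as pd

from .data_model import LesionDataset
from .surrogate import PredictorSpec, SurrogateModel, train
from .utils import spawn_seeds

__all__ = [
    "Game",
    "ShapleyResult",
    "exact_shapley",
    "estimated_shapley",
    "bootstrap_msa",
    "normalize_contributions",
]

logger = logging.getLogger(__name__)

#: Enumeration bound for the exact computation.
EXACT_MAX_ELEMENTS = 20


class Game:
    """A coalitional game: element count plus characteristic function.

    ``v_batch`` maps a (k, n) binary matrix of configurations (1 = intact)
    to a length-k vector of performance values.  Evaluations are cached by
    configuration within the lifetime of the instance, since permutation
    sampling revisits configurations (notably the empty and full
    coalitions).
    """

    def __init__(self, n_elements: int, v_batch: Callable[[np.ndarray], np.ndarray]):
        if n_elements < 1:
            raise ValueError("game needs at least one element")
        self.n_elements = int(n_elements)
        self._v_batch = v_batch
        self._cache: dict[bytes, float] = {}

    # -- constructors ----------------------------------------------------
    @classmethod
    def from_model(cls, model: SurrogateModel) -> "Game":
        """Game whose v is a trained surrogate predictor."""
        return cls(len(model.region_set), model.evaluate_configurations)

    @classmethod
    def from_callable(cls, n_elements: int, v: Callable[[np.ndarray], float]) -> "Game":
        """Game from a scalar function of one binary configuration."""

        def batch(configs: np.ndarray) -> np.ndarray:
            return np.array([v(c) for c in configs], dtype=float)

        return cls(n_elements, batch)

    @classmethod
    def from_table(cls, table: dict[str, float]) -> "Game":
        """Tabulated game: maps bitstrings (char i = element i, '1' = intact).

        Accepts a dict or a path-like/JSON string via :func:`json.loads`
        upstream.  All 2^n configurations must be present.
        """
        keys = list(table)
        n = len(keys[0])
        if len(table) != 2**n or any(len(k) != n for k in keys):
            raise ValueError("table must enumerate all 2^n bitstrings of equal length")
        lut = np.empty(2**n)
        for k, val in table.items():
            lut[int(k, 2)] = float(val)
        weights = 1 << np.arange(n - 1, -1, -1)  # bitstring char 0 is MSB

        def batch(configs: np.ndarray) -> np.ndarray:
            idx = configs.astype(np.int64) @ weights
            return lut[idx]

        return cls(n, batch)

    # -- evaluation ------------------------------------------------------
    def evaluate(self, configs: np.ndarray) -> np.ndarray:
        """Evaluate configurations with de-duplication and caching."""
        configs = np.ascontiguousarray(np.asarray(configs, dtype=np.uint8))
        if configs.ndim != 2 or configs.shape[1] != self.n_elements:
            raise ValueError(
                f"configs must be (k, {self.n_elements}), got {configs.shape}"
            )
        packed = np.packbits(configs, axis=1)
        keys = [row.tobytes() for row in packed]
        out = np.empty(len(configs))
        missing: dict[bytes, int] = {}
        for i, key in enumerate(keys):
            if key in self._cache:
                out[i] = self._cache[key]
            elif key not in missing:
                missing[key] = i
        if missing:
            rows = np.fromiter(missing.values(), dtype=np.int64)
            vals = np.asarray(self._v_batch(configs[rows]), dtype=float)
            for key, val in zip(missing, vals):
                self._cache[key] = float(val)
        for i, key in enumerate(keys):
            out[i] = self._cache[key]
        return out


@dataclass
class ShapleyResult:
    """Bootstrap-aggregated per-region contribution estimates."""

    region_ids: list[str]
    contributions: np.ndarray  # mean over bootstrap replicates
    se: np.ndarray  # standard deviation across replicates
    ci_low: np.ndarray
    ci_high: np.ndarray
    significant: np.ndarray  # CI excludes 0 (default rule)
    n_permutations: int
    n_bootstrap: int
    seed: int
    alpha: float = 0.05
    significance_rule: str = "ci"
    replicates: Optional[np.ndarray] = field(default=None, repr=False)

    def __post_init__(self) -> None:
        k = len(self.region_ids)
        for name in ("contributions", "se", "ci_low", "ci_high", "significant"):
            arr = np.asarray(getattr(self, name))
            if arr.shape != (k,):
                raise ValueError(f"{name} must have length {k}")
            setattr(self, name, arr)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "region_id": self.region_ids,
                "contribution": self.contributions,
                "se": self.se,
                "ci_low": self.ci_low,
                "ci_high": self.ci_high,
                "significant": self.significant.astype(bool),
            }
        )

    def to_json_dict(self) -> dict:
        return {
            "region_ids": self.region_ids,
            "contributions": self.contributions.tolist(),
            "se": self.se.tolist(),
            "ci_low": self.ci_low.tolist(),
            "ci_high": self.ci_high.tolist(),
            "significant": self.significant.astype(bool).tolist(),
            "n_permutations": self.n_permutations,
            "n_bootstrap": self.n_bootstrap,
            "seed": self.seed,
            "alpha": self.alpha,
            "significance_rule": self.significance_rule,
        }


# ---------------------------------------------------------------------------
# Exact computation
# ---------------------------------------------------------------------------

def exact_shapley(game: Game) -> np.ndarray:
    """Shapley values by full coalition enumeration (oracle, n ≤ 20).

    γ_i = Σ_{S ∌ i} |S|! (n−|S|−1)! / n! · [v(S ∪ {i}) − v(S)].  Satisfies
    efficiency exactly: Σ γ_i = v(full) − v(∅).
    """
    n = game.n_elements
    if n > EXACT_MAX_ELEMENTS:
        raise ValueError(
            f"exact enumeration limited to {EXACT_MAX_ELEMENTS} elements "
            f"(2^{n} coalitions requested); use estimated_shapley instead"
        )
    n_sets = 1 << n
    masks = np.arange(n_sets, dtype=np.int64)
    configs = ((masks[:, None] >> np.arange(n)) & 1).astype(np.uint8)
    v = game.evaluate(configs)

    sizes = configs.sum(axis=1).astype(np.int64)
    fact = np.array([math.factorial(k) for k in range(n + 1)], dtype=float)
    # weight for a coalition S (i ∉ S) of size s: s! (n-s-1)! / n!
    w = fact[np.arange(n)] * fact[n - np.arange(n) - 1] / fact[n]

    gamma = np.empty(n)
    for i in range(n):
        without = (masks & (1 << i)) == 0
        s_masks = masks[without]
        marg = v[s_masks | (1 << i)] - v[s_masks]
        gamma[i] = float(np.sum(w[sizes[s_masks]] * marg))
    return gamma


# ---------------------------------------------------------------------------
# Permutation-sampling estimator
# ---------------------------------------------------------------------------

def estimated_shapley(game: Game, R: int, seed: int = 0) -> np.ndarray:
    """Monte-Carlo Shapley estimate from R random element orderings.

    For each uniformly drawn permutation π, every element i receives the
    marginal v(predecessors ∪ {i}) − v(predecessors), where predecessors
    are the elements before i in π (growing the intact coalition from ∅
    to the full set).  The per-element mean over the R permutations is an
    unbiased estimate of the exact Shapley value; each permutation's
    marginals telescope to v(full) − v(∅), so the estimate preserves
    efficiency exactly for deterministic v.
    """
    if R < 1:
        raise ValueError("R must be >= 1")
    n = game.n_elements
    rng = np.random.default_rng(seed)
    perms = np.array([rng.permutation(n) for _ in range(R)])

    # nested prefix coalitions ∅ ⊂ {π1} ⊂ {π1,π2} ⊂ … per permutation
    grow = np.zeros((R, n, n), dtype=np.uint8)
    rows = np.repeat(np.arange(R), n)
    steps = np.tile(np.arange(n), R)
    grow[rows, steps, perms.ravel()] = 1
    prefixes = np.cumsum(grow, axis=1, dtype=np.uint8)
    configs = np.concatenate([np.zeros((R, 1, n), dtype=np.uint8), prefixes], axis=1)

    v = game.evaluate(configs.reshape(-1, n)).reshape(R, n + 1)
    marginals = v[:, 1:] - v[:, :-1]  # column j = marginal of element perms[:, j]

    acc = np.zeros(n)
    np.add.at(acc, perms.ravel(), marginals.ravel())
    return acc / R


# ---------------------------------------------------------------------------
# Bootstrapped estimated MSA
# ---------------------------------------------------------------------------

def bootstrap_msa(
    dataset: LesionDataset,
    spec: PredictorSpec,
    B: int,
    R: int,
    seed: int = 0,
    alpha: float = 0.05,
    output_mode: str = "class",
    embedding: str = "ablation",
    significance_rule: str = "ci",
    max_redraws: int = 100,
) -> ShapleyResult:
    """Estimated MSA under patient-level bootstrap resampling.

    For each of B resamples of patients (with replacement, at the original
    cohort size) the surrogate is retrained and the permutation-sampling
    estimator run with R orderings.  The reported contribution is the mean
    across replicates, its uncertainty the standard deviation across
    replicates, with a percentile confidence interval at level 1 − alpha.
    A region is significant when its interval excludes 0 ("ci" rule) or
    when |mean|/sd exceeds the normal quantile ("z" rule).  Resamples that
    collapse to a single outcome class are redrawn (logged) so that all B
    replicates are effective.
    """
    if B < 1 or R < 1:
        raise ValueError("B and R must be >= 1")
    n = dataset.n_patients
    n_regions = dataset.n_regions
    resample_seed, *sub_seeds = spawn_seeds(seed, 2 * B + 1)
    rng = np.random.default_rng(resample_seed)

    replicates = np.empty((B, n_regions))
    redraws = 0
    for b in range(B):
        for _ in range(max_redraws):
            idx = rng.integers(0, n, size=n)
            if len(np.unique(dataset.performance[idx])) == 2:
                break
            redraws += 1
            logger.info("bootstrap resample %d single-class; redrawn", b)
        else:
            raise RuntimeError(
                "could not draw a two-class bootstrap resample; "
                "cohort is too imbalanced"
            )
        boot = LesionDataset(
            patient_ids=[dataset.patient_ids[i] for i in idx],
            loads=dataset.loads[idx],
            raw_motor_score=dataset.raw_motor_score[idx],
            performance=dataset.performance[idx],
            region_set=dataset.region_set,
        )
        model = train(
            boot,
            spec,
            output_mode=output_mode,
            embedding=embedding,
            random_state=sub_seeds[2 * b],
        )
        game = Game.from_model(model)
        replicates[b] = estimated_shapley(game, R, seed=sub_seeds[2 * b + 1])

    if redraws:
        logger.info("total single-class resamples redrawn: %d", redraws)

    mean = replicates.mean(axis=0)
    sd = replicates.std(axis=0, ddof=1) if B > 1 else np.zeros(n_regions)
    lo = np.percentile(replicates, 100 * alpha / 2, axis=0)
    hi = np.percentile(replicates, 100 * (1 - alpha / 2), axis=0)
    if significance_rule == "ci":
        significant = ~((lo <= 0) & (0 <= hi))
    elif significance_rule == "z":
        from scipy.stats import norm

        zcrit = norm.ppf(1 - alpha / 2)
        with np.errstate(divide="ignore", invalid="ignore"):
            z = np.abs(mean) / sd
        significant = np.where(sd > 0, z > zcrit, mean != 0)
    else:
        raise ValueError(f"unknown significance rule {significance_rule!r}")

    return ShapleyResult(
        region_ids=dataset.region_set.ids,
        contributions=mean,
        se=sd,
        ci_low=lo,
        ci_high=hi,
        significant=significant,
        n_permutations=R,
        n_bootstrap=B,
        seed=seed,
        alpha=alpha,
        significance_rule=significance_rule,
        replicates=replicates,
    )


def normalize_contributions(contributions: np.ndarray) -> np.ndarray:
    """Scale contributions by the total absolute contribution.

    Signs are preserved; the normalised absolute values sum to 1.  An
    all-zero vector has no defined normalisation.
    """
    c = np.asarray(contributions, dtype=float)
    total = np.abs(c).sum()
    if total == 0:
        raise ValueError("cannot normalise an all-zero contribution vector")
    return c / total
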