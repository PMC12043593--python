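"""Iterative estimated MSA: estimate, discard, merge, re-test.

The full procedure loops three steps until the rest-of-brain (RoB)
control tells it to stop:

1. (re-)optimise the surrogate predictor's hyperparameters on the
   current dataset;
2. run the bootstrapped permutation-sampling Shapley estimation;
3. discard the non-RoB region with the smallest absolute contribution,
   together with every region whose absolute contribution falls below a
   negligible fraction of the total, and fold the discarded columns into
   the RoB (voxel-conserving merge).

The loop seeks the smallest region set whose RoB contribution is NOT
significant: a significant RoB means regions carrying real function have
been thrown away, so the step that caused it is rolled back and the last
healthy set returned.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .data_model import LesionDataset, merge_into_rob
from .shapley import ShapleyResult, bootstrap_msa
from .surrogate import PredictorSpec, optimize_hyperparameters
from .utils import spawn_seeds

__all__ = ["RunConfig", "IterationRecord", "IterationTrace", "run_iterative_msa", "summarize_trace"]

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Tunable parameters of one iterative MSA run.

    Defaults follow the method's reference configuration: 1,000 sampled
    permutations per estimation and 1,000 bootstrap resamples, 95%
    percentile intervals, and a negligible-contribution threshold of 1% of
    the total absolute contribution (set to 0 for strict one-at-a-time
    elimination).  ``weak_share`` bounds which regions count as weak
    contributors and hence as discard candidates: a region holding at
    least that fraction of the total absolute contribution is never
    discarded, and the loop stops once no weak contributor remains.
    """

    R: int = 1000
    B: int = 1000
    alpha: float = 0.05
    negligible_fraction: float = 0.01
    weak_share: float = 0.10
    max_iterations: int = 100
    seed: int = 0
    grid: Optional[dict] = None  # None -> surrogate.DEFAULT_GRID
    output_mode: str = "class"
    embedding: str = "ablation"
    significance_rule: str = "ci"
    reoptimize_each_iteration: bool = True

    def __post_init__(self) -> None:
        if self.R < 1 or self.B < 1:
            raise ValueError("R and B must be >= 1")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        if not 0 <= self.negligible_fraction < 1:
            raise ValueError("negligible_fraction must lie in [0, 1)")
        if not 0 < self.weak_share <= 1:
            raise ValueError("weak_share must lie in (0, 1]")


@dataclass
class IterationRecord:
    """One contribution estimation performed by the elimination loop.

    ``reverted`` marks a probe whose preceding discard made the RoB
    significant and was therefore rolled back; the committed path of the
    run is the sequence of non-reverted records, whose region sets shrink
    strictly.
    """

    region_ids: list[str]
    result: ShapleyResult
    discarded_ids: list[str]
    rob_significant: bool
    predictor: PredictorSpec
    reverted: bool = False


@dataclass
class IterationTrace:
    """Complete record of an iterative MSA run."""

    iterations: list[IterationRecord]
    final_region_ids: list[str]
    final_result: ShapleyResult
    stopping_reason: str  # rob_significant_next | min_set_reached | max_iter
    config: RunConfig
    degenerate: bool = False  # no significant contributors at termination

    _rob_id: str = field(default="", repr=False)

    @property
    def final_significant_ids(self) -> list[str]:
        """Significant non-RoB regions of the final region set."""
        res = self.final_result
        return [
            rid
            for rid, sig in zip(res.region_ids, res.significant)
            if sig and rid != self._rob_id
        ]


def _select_discards(
    result: ShapleyResult,
    dataset: LesionDataset,
    negligible_fraction: float,
    weak_share: float,
    batch_cap: Optional[int] = None,
) -> list[str]:
    """Weak contributors to fold into the RoB this iteration.

    Discard candidates are the non-RoB regions whose absolute
    contribution falls below ``weak_share`` of the total absolute
    contribution; a region carrying more than that share is never
    discarded.  Of the candidates, the smallest is always discarded,
    together with every candidate below the ``negligible_fraction``
    threshold.  Ties on |contribution| break toward the smaller voxel
    count, making the choice deterministic.  ``batch_cap`` limits the
    batch (backoff after a rolled-back discard).  An empty list means no
    weak contributor remains and the loop should stop.
    """
    rs = dataset.region_set
    rob_id = rs.rob_id
    abs_c = np.abs(result.contributions)
    total = abs_c.sum()
    vox = rs.voxel_counts

    candidates = [
        (abs_c[i], int(vox[i]), rid)
        for i, rid in enumerate(result.region_ids)
        if rid != rob_id
    ]
    candidates.sort(key=lambda t: (t[0], t[1], t[2]))
    if total > 0:
        weak = [c for c in candidates if c[0] < weak_share * total]
    else:
        weak = list(candidates)  # all-zero attribution: everything is weak
    if not weak:
        return []
    discards = {weak[0][2]}  # mandatory single smallest
    if negligible_fraction > 0 and total > 0:
        thresh = negligible_fraction * total
        discards.update(rid for a, _, rid in weak if a < thresh)
    # keep at least one non-RoB region on the board
    n_non_rob = len(candidates)
    if len(discards) >= n_non_rob:
        discards = {rid for _, _, rid in candidates[: n_non_rob - 1]}
    ordered = [rid for _, _, rid in candidates if rid in discards]
    if batch_cap is not None:
        ordered = ordered[:batch_cap]
    return ordered


def run_iterative_msa(dataset: LesionDataset, config: RunConfig) -> IterationTrace:
    """Run the elimination loop until the RoB stopping rule fires.

    The final region set is the LAST set whose RoB contribution was
    non-significant.  A discard that makes the RoB significant is rolled
    back; if it was a batch discard, the loop retries from the previous
    state with the batch halved (backoff) before concluding that no
    further region can be removed.  If the RoB is already significant
    before any discard, the initial set is returned unchanged and the
    trace is flagged degenerate.
    """
    rs = dataset.region_set
    if len(rs) - 1 < 2:
        raise ValueError("need at least 2 non-RoB regions to iterate")

    iter_seeds = spawn_seeds(config.seed, 2 * config.max_iterations)
    current = dataset
    spec: Optional[PredictorSpec] = None
    records: list[IterationRecord] = []
    # previous committed state: (dataset, result, its IterationRecord)
    prev: Optional[tuple[LesionDataset, ShapleyResult, IterationRecord]] = None
    batch_cap: Optional[int] = None
    stopping = "max_iter"
    final_ds, final_res = current, None

    for t in range(config.max_iterations):
        opt_seed, msa_seed = iter_seeds[2 * t], iter_seeds[2 * t + 1]
        if spec is None or config.reoptimize_each_iteration:
            spec = optimize_hyperparameters(current, grid=config.grid, seed=opt_seed)
        result = bootstrap_msa(
            current,
            spec,
            B=config.B,
            R=config.R,
            seed=msa_seed,
            alpha=config.alpha,
            output_mode=config.output_mode,
            embedding=config.embedding,
            significance_rule=config.significance_rule,
        )
        rob_idx = current.region_set.rob_index
        rob_sig = bool(result.significant[rob_idx])
        record = IterationRecord(
            region_ids=current.region_set.ids,
            result=result,
            discarded_ids=[],
            rob_significant=rob_sig,
            predictor=spec,
        )
        records.append(record)
        logger.info(
            "iteration %d: %d regions, RoB %s",
            t,
            len(current.region_set),
            "SIGNIFICANT" if rob_sig else "non-significant",
        )

        if rob_sig:
            record.reverted = True
            if prev is None:
                warnings.warn(
                    "RoB significant before any discard; returning the "
                    "initial region set (degenerate run)"
                )
                stopping = "rob_significant_next"
                final_ds, final_res = current, result
                break
            prev_ds, prev_res, prev_rec = prev
            k = len(prev_rec.discarded_ids)
            if k > 1:
                # the batch threw away too much at once: halve and retry
                batch_cap = max(1, k // 2)
                discards = _select_discards(
                    prev_res,
                    prev_ds,
                    config.negligible_fraction,
                    config.weak_share,
                    batch_cap,
                )
                prev_rec.discarded_ids = discards
                logger.info("rolled back batch of %d; retrying with %d", k, len(discards))
                current = merge_into_rob(prev_ds, discards)
                continue
            # single discard already trips the RoB: stop at the last
            # healthy set
            prev_rec.discarded_ids = []
            stopping = "rob_significant_next"
            final_ds, final_res = prev_ds, prev_res
            break

        final_ds, final_res = current, result

        n_non_rob = len(current.region_set) - 1
        discards = (
            _select_discards(
                result,
                current,
                config.negligible_fraction,
                config.weak_share,
                batch_cap,
            )
            if n_non_rob > 1
            else []
        )
        if not discards:  # no weak contributor left (or a single region)
            stopping = "min_set_reached"
            break
        record.discarded_ids = discards
        prev = (current, result, record)
        current = merge_into_rob(current, discards)
    else:
        warnings.warn("iterative MSA did not converge within max_iterations")

    if final_res is None:  # pragma: no cover - loop always runs once
        raise RuntimeError("no iteration executed")

    rob_id = dataset.region_set.rob_id
    significant_non_rob = [
        rid
        for rid, sig in zip(final_res.region_ids, final_res.significant)
        if sig and rid != rob_id
    ]
    trace = IterationTrace(
        iterations=records,
        final_region_ids=final_ds.region_set.ids,
        final_result=final_res,
        stopping_reason=stopping,
        config=config,
        degenerate=len(significant_non_rob) == 0,
        _rob_id=rob_id,
    )
    return trace


def summarize_trace(trace: IterationTrace) -> str:
    """Human-readable report of an iterative MSA run.

    Lists each iteration (region count, RoB status, discards) and the
    final contributions sorted in descending order with standard errors
    and significance markers.
    """
    lines = []
    lines.append("Iterative estimated MSA run")
    lines.append(f"stopping reason: {trace.stopping_reason}")
    lines.append("")
    lines.append("iteration  regions  RoB           discarded")
    for t, rec in enumerate(trace.iterations):
        rob = "significant" if rec.rob_significant else "non-signif."
        disc = ", ".join(rec.discarded_ids) if rec.discarded_ids else "-"
        lines.append(f"{t:>9d}  {len(rec.region_ids):>7d}  {rob:<12}  {disc}")
    lines.append("")
    lines.append("final contributions (descending):")
    lines.append(f"{'region':<24} {'contribution':>13} {'se':>9}  signif.")
    res = trace.final_result
    order = np.argsort(-res.contributions)
    for i in order:
        star = "*" if res.significant[i] else ""
        lines.append(
            f"{res.region_ids[i]:<24} {res.contributions[i]:>13.4f} "
            f"{res.se[i]:>9.4f}  {star}"
        )
    rob_id = trace._rob_id
    significant = [
        rid
        for rid, sig in zip(res.region_ids, res.significant)
        if sig and rid != rob_id
    ]
    if not significant:
        lines.append("")
        lines.append("NO SIGNIFICANT CONTRIBUTORS: the run found no region "
                     "whose contribution differs from zero.")
    return "\n".join(lines)
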