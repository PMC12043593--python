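# lesionmsa

Multivariate lesion-symptom inference by iterative estimated
**multi-perturbation Shapley value analysis (MSA)**.

## The problem

After a stroke, which brain regions *caused* the observed deficit?
Mass-univariate lesion-symptom mapping associates each voxel or region
with the deficit separately, which confounds causality with vascular
anatomy: regions fed by the same artery are lesioned together, so an
innocent neighbour of a critical tract inherits its statistical signal.

MSA treats the question as a cooperative game.  The N regions of
interest (ROIs) — plus one catch-all "rest of the brain" (RoB) element —
are players; a coalition S ⊆ N is the set of *intact* regions; the
characteristic function v(S) is the behavioural performance when exactly
S is intact.  A region's causal contribution is its Shapley value

γᵢ = Σ_{S ∌ i} |S|!(N−|S|−1)!/N! · [v(S ∪ {i}) − v(S)],

the average marginal contribution of region i over all orderings of the
players.  Positive γᵢ means damage to the region decreases performance.

Clinical data cannot supply v for arbitrary coalitions, so a
random-forest **surrogate** is trained on the patients' graded lesion
loads (percent of each region's voxels lesioned) against the binarised
outcome (limb motor score: 10 = intact ability → 1, anything lower → 0),
and queried at the binary configurations the estimator needs.  The
Shapley value is estimated by **permutation sampling** (R random player
orderings) and its uncertainty by a **patient-level bootstrap** (B
resamples, retraining the surrogate each time) giving means, standard
errors, percentile confidence intervals and significance flags.

The full pipeline iterates: estimate contributions → discard weak
contributors into the RoB (a voxel-conserving pooled merge) → re-estimate
— until no weak contributor remains, or until removing one would make
the RoB contribution significant, the sign that real function was thrown
away.  A non-significant RoB at termination validates the retained set.

## Worked example

```python
from lesionmsa import (RunConfig, SyntheticSpec, generate,
                       recovery_metrics, run_iterative_msa, summarize_trace)

dataset, truth = generate(SyntheticSpec(n_patients=150, n_regions=12,
                                        n_blocks=4,
                                        causal_weights={0: 1.0, 4: 0.7},
                                        seed=3))
config = RunConfig(R=200, B=40, seed=5, output_mode="proba",
                   negligible_fraction=0.05)
trace = run_iterative_msa(dataset, config)
print(summarize_trace(trace))
print(recovery_metrics(trace, truth))
```

Output (from `python examples/04_iterative_msa.py`, which fixes the
forest configuration for speed):

```
Iterative estimated MSA run
stopping reason: rob_significant_next

iteration  regions  RoB           discarded
        0       13  non-signif.   R06, R07, R08, R11, R05, R09
        1        7  non-signif.   R02
        2        6  non-signif.   R10
        3        5  non-signif.   R03
        4        4  non-signif.   -
        5        3  significant   -

final contributions (descending):
region                    contribution        se  signif.
R00                             0.4111    0.0733  *
R04                             0.2478    0.1032  *
RoB                             0.0839    0.0606
R01                             0.0462    0.0688

planted truth: ['R00', 'R04']
recall=1.00 precision=1.00
```

The loop pruned ten null regions, stopped when a further discard made
the RoB significant, and flagged exactly the two planted causal regions
(weights 1.0 and 0.7, recovered in the same order).  The `se` column is
the bootstrap standard deviation; `*` marks regions whose 95% percentile
interval excludes 0.

More narrative scripts live in `examples/` (cohort simulation, surrogate
evaluation with chance level, exact-vs-estimated Shapley values, lesion
correlation matrices).  A thin CLI exposes the same steps:

```bash
lesion-msa simulate --out cohort/
lesion-msa run --loads cohort/loads.csv --scores cohort/scores.csv \
               --regions cohort/regions.json --out results/
```

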