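# torc

**Target-oriented reference construction for supervised cell-type
identification in scRNA-seq.**

Supervised cell typing trains a classifier on a labeled *reference* and
applies it to an unlabeled *target*. Its accuracy hinges on how well the
reference resembles the target — in cell-type composition (class priors)
and in expression distribution (domain shift). A reference with the wrong
composition systematically over-calls its abundant types at every
confusable boundary; a reference from another study drags its batch
effects into the decision rule.

`torc` constructs a better reference *for a given target* with a two-round
strategy:

1. train on the original reference and predict the target, giving a
   probability matrix `P` (cells × types);
2. estimate the target composition `P̂ᵀ` from `P` and score each cell's
   prediction entropy `H_i = −Σ_k p_ik ln p_ik`;
3. optionally add low-entropy (high-confidence) target cells, with their
   predicted labels, to an expanded reference pool;
4. resample the pool to match `P̂ᵀ` (exact largest-remainder counts) and
   retrain on this constructed reference to produce the final labels.

The package ships the full pipeline (MTX-triplet / dense CSV readers,
normalization, ANOVA F-test gene selection, an MLP classifier behind a
pluggable two-method backend contract), a benchmark harness comparing
reference-construction strategies, and a negative-binomial simulator with
known ground truth — composition shifts, confusable type pairs and
gene-wise batch effects are all controllable, so the whole method is
testable without external data. See `docs/methods.md` for the model
details and design choices.

## Worked example

```python
from torc.scenarios import reversal_benchmark

# four types, one mildly confusable pair whose odds are 4:1 in the
# reference but 1:4 in the target — everything else matched, 2,000 cells
# per side; compares the four reference strategies over 20 paired seeds
summary = reversal_benchmark(n_seeds=20, master_seed=0)
print(summary.to_string(index=False))
```

prints (exact numbers; the pipeline is seed-deterministic):

```
 strategy  mean_accuracy  sd_accuracy  n_seeds  sd_is_degenerate
 original       0.805475     0.018475       20             False
   oracle       0.843550     0.011988       20             False
estimated       0.835750     0.010253       20             False
    equal       0.826425     0.012850       20             False
```

Read: training on the original, composition-mismatched reference scores
0.805. Resampling the same cells to the *true* target composition (`oracle`)
lifts accuracy to 0.844; using the composition *estimated* in round 1 —
which is what the method can actually do — recovers most of that gain
(0.836); equal weighting helps less (0.826). The gains come almost entirely
from no longer over-calling the reference-abundant member of the confusable
pair.

For a plain end-to-end run on your own data:

```python
result = torc.run_torc(ref, target.matrix,
                       torc.ClassifierSpec(), torc.TorcConfig(seed=0))
result.final_labels            # one label per target cell
result.estimated_composition   # P̂ᵀ
result.pool_added_cell_ids     # entropy-gated pseudo-labeled cells
```

or from the shell, with YAML configs (see `torc run --help`):

```sh
torc simulate sim.yaml    # write MTX triplets + labels
torc run run.yaml         # labels.csv + diagnostics.json + log
torc benchmark run.yaml   # tidy + summary strategy CSVs
```

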