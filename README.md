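# flowbo

Batch Bayesian optimization for screening flow-chemistry reaction
conditions with mixed continuous and categorical variables.

Optimizing a flow synthesis means tuning five continuous knobs —
reagent equivalents, catalyst loading (mol% TfOH), temperature,
substrate concentration and syringe flow rate — together with a
categorical hardware choice, the micromixer (Comet X, β-type or
T-shaped). Experiments are slow and expensive, and several can run in
parallel, so the practical question is: given the experiments run so
far, which *batch* of q conditions should go on the pumps next?

`flowbo` answers that with the standard BO loop:

* the design space is embedded numerically — continuous variables
  min-max scaled to [0, 1], each k-way categorical variable one-hot
  encoded (choice *i* ↦ *e*ᵢ ∈ {0,1}ᵏ);
* a Gaussian-process surrogate with a Matérn-5/2 ARD kernel is fitted
  to the observed yields by maximizing the log marginal likelihood;
* candidates are scored by a confidence-bound acquisition
  α(x) = μ(x) + β·σ(x) (or expected improvement), maximized over the
  *relaxed* encoded box and mapped back to a feasible condition by
  nearest-vertex rounding of the one-hot blocks plus snapping to the
  laboratory resolution grid;
* batches of q are built by kriging-believer hallucination: after each
  selection the GP is conditioned on its own posterior-mean prediction
  there, and the acquisition is re-optimized.

The package also ships the two recorded 15-experiment screening
campaigns (biaryl cross-couplings of an iminoquinone monoacetal and a
quinone monoacetal with arenols) as replayable fixtures, flow
arithmetic (residence time t = V/(2f) for the dual-syringe feed), and a
seeded synthetic yield benchmark for comparing optimizers against
random search.

## Worked example

Replay the first recorded campaign and ask for the next batch:

```bash
$ flowbo replay --records src/flowbo/data/table1.csv
entries 1-6: max yield 75% (entry 6), running best 75%
entries 7-9: max yield 81% (entry 7), running best 81%
entries 10-12: max yield 79% (entry 12), running best 81%
entries 13-15: max yield 96% (entry 15), running best 96%
overall best: 96% at entry 15 (Comet X)
```

The six seed experiments top out at 75% NMR yield; three rounds of
three parallel suggestions later the campaign reaches 96% (Comet X
mixer, 0.08 mL/min per stream, 15 min residence).

```bash
$ flowbo residence --mixer comet_x --flow 0.08
15 min

$ flowbo suggest --records src/flowbo/data/table1.csv --acq parallel_lcb \
        --batch 3 --seed 7
entry,mixer,equiv,tfoh_mol_pct,temp_c,conc_m,flow_ml_min,yield_pct,acq_value,round
16,comet_x,1.0,2.4,15.0,0.01,0.2,,120.4247,1
17,t_shaped,1.8,0.25,80.0,0.15,0.174,,109.5302,1
18,t_shaped,1.9,0.2,75.0,0.018,0.046,,108.4274,1
```

Each suggested row is a feasible lab-grid condition with an empty
`yield_pct` awaiting the experiment. `acq_value` is the optimistic
confidence bound μ + 2σ in yield percent — it may exceed 100 in
unexplored regions, where it measures plausible upside rather than a
prediction. Runs are reproducible from (records file, config, seed);
fitted hyperparameters and proposals are logged for audit.

In Python the same loop is three calls:

```python
import flowbo

space = flowbo.widened_space()
recs = flowbo.load_fixture("table1")[:6]
state = flowbo.CampaignState(
    space=space,
    conditions=[r.condition for r in recs],
    yields=[r.yield_pct for r in recs],
    config=flowbo.AcquisitionConfig(kind="parallel_lcb", batch_size=3, seed=1),
)
proposal = flowbo.propose_batch(state)          # three conditions to run
state = flowbo.advance_round(state, proposal, [81.0, 77.0, 40.0])
```

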