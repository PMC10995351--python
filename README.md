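# pathshap

Model-free decoding of stimulus categories from fMRI independent-component
(IC) time courses with a deliberately frugal classifier — a 125-10-4 shallow
neural network — followed by two complementary explainability analyses:
**path-weight pruning** and **Shapley-value attribution**.

The package is aimed at neuroimaging / explainable-AI researchers who want a
tested, reusable implementation of this analysis chain. Because raw fMRI
acquisitions of this kind are rarely redistributable, the package ships a
first-class synthetic-data module that emulates the paradigm (four stimulus
categories — preferred brands **BP**, indifferent brands **BI**, objects
**O**, people **P** — 40 events each per subject, 4.0 s stimulus + 3.5 s
fixation, TR = 2.5 s, 485 volumes, 125 IC time courses, 15 train / 7 test
subjects) with a *known* set of informative ICs, so every downstream stage
can be validated by parameter recovery rather than by running without error.

## The analysis chain

1. **Screening** — stimuli rated on five-point pleasure (−2..+2) and arousal
   (1..5) scales are labeled *preferred* (pleasure ∈ {+1,+2} and arousal ≥ 3),
   *indifferent* (pleasure 0 and arousal ≤ 3) or *discarded*; 40 per retained
   class are drawn at random.
2. **Feature extraction** — one volume per event, the third acquired after
   onset (6.5 s post onset under the default alignment, near the hemodynamic
   peak); its 125 IC values form one instance. Splits are by subject and
   standardization uses training-set statistics, so no test information leaks.
3. **Shallow network** — tanh hidden units, sigmoid outputs, per-pattern
   gradient descent with momentum on the LMS error
   E = ½ Σₖ (tₖ − yₖ)²; hyperparameters by grid search with random restarts.
4. **Path-weight pruning** — the path-weight of input *i* → hidden *j* →
   output *k* is w_IiHj · w_HjOk (1,250 per output). Each output's sorted
   path-weight curve gets two *elbow points* (maximum perpendicular distance
   to the endpoint chord, computed separately on the negative and positive
   branches); only paths outside the elbows survive. The pruned network is
   retrained with its sparsity frozen.
5. **Shapley explanation** — interventional Shapley values φ with a
   training-set background: exact subset enumeration for the 10 hidden
   nodes, antithetic permutation sampling for the 125 inputs. Additivity
   (Σ_f φ_f + E[f] = f(x)) holds to machine precision in exact mode.
6. **Evaluation** — 4×4 confusion matrices with per-category precision
   (column-wise), per-category accuracy (row-wise) and global accuracy.

## Worked example

```python
from pathshap.config import RunConfig
from pathshap.pipeline import run_pipeline

cfg = RunConfig.model_validate({
    "seed": 1,
    "explain": {"background_n": 40, "n_permutations": 64, "n_instances": 48},
})
res = run_pipeline(cfg, out_dir="runs/demo")
print(res.accuracies)
print(res.prune_report["connections_before"], "->",
      res.prune_report["connections_after"])
print(res.recovery)
```

prints (about 15 s on one CPU):

```
{'best': 0.8830357142857143, 'pruned': 0.89375, 'retrained': 0.8946428571428572}
1290 -> 195
  category     ic  rank  mean_abs_phi
0       BP    IC4     2      0.166858
1       BP   IC18     1      0.227313
2       BI   IC10     1      0.252705
3       BI   IC43     2      0.149424
4        O   IC55     1      0.236670
5        O   IC72     2      0.185062
6        P   IC89     1      0.291921
7        P  IC104     2      0.178878
```

Reading this: on the default 22-subject synthetic cohort the dense network
classifies 88.3% of the 1,120 held-out events correctly (chance is 25%);
elbow pruning cuts the 1,290 connections to 195 while retraining keeps the
accuracy at 89.5%; and for every category, the two ICs that truly carry its
signal rank first and second among all 125 by mean |φ| — the attribution
recovers the planted ground truth. The run directory holds the instance
matrices, search tables, path-weight/elbow tables, attribution CSVs and a
manifest with seeds and artifact hashes.

The same chain is scriptable stage by stage:

```bash
pathshap simulate --n-train 15 --n-test 7 --seed 1 -o runs/sim
pathshap screen --ratings runs/sim/ratings.csv -o runs/sim
pathshap extract -i runs/sim -o runs/sim
pathshap train -i runs/sim -o runs/sim --lr-grid 0.01 --momentum-grid 0.9
pathshap prune -i runs/sim -o runs/sim
pathshap retrain -i runs/sim -o runs/sim
pathshap explain -i runs/sim -o runs/sim --level hidden
pathshap report -i runs/sim -o runs/sim
```

`pathshap run -c config.yaml -o runs/full` drives everything from one YAML
file (see `examples/config.yaml`); `paper_scale: true` swaps in the
original cluster-scale search spaces (learning rates 1e−07..0.9 log-spaced,
momenta 0.05..1.00, 500 epochs, 50,000 restarts).

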