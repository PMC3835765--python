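# sensemaker

An instance-based-learning model of geospatial *sensemaking*: estimating
which of several event-generating categories produced a probe event on a
map, revising that belief as intelligence feature layers arrive, and
allocating resources on it. The package is for computational cognitive
scientists who want a mechanistic account of where anchoring,
confirmation, base-rate-neglect and probability-matching biases come
from — not from bias parameters, but from the interaction of a memory
architecture, task statistics, and strategy.

It contains four parts:

* **Task simulator** — six tasks on a 100 x 100 grid: Gaussian event
  clouds per category (Tasks 1–2), events on random road networks
  (Task 3), and rule-governed intelligence layers
  (SOCINT/IMINT/MOVINT/SIGINT, Tasks 4–6) with generative odds matching
  the rules' likelihood ratios (2:1 region, 4:1 building/traffic, 7 and
  1/3 for chatter/silence on an inspected category).
* **Cognitive agent** — a declarative-memory kernel (activation
  `A_i = B_i + S_i + P_i + eps_i`, Boltzmann retrieval
  `P_i = e^{A_i/s} / Σ e^{A_j/s}`, blended retrieval
  `V = argmin Σ P_i (1 − Sim_ij)²`) plus the strategies built on it:
  centroid-of-centroids location estimates, instance-based probability
  adjustment over seeded (prior, factor, posterior) triplets,
  two-step blended resource allocation with winner-take-all and
  probability-matching counterfactuals, greedy road-path planning with
  power-law distance percepts `D = (1.02·(cow/crow) + crow)^{0.82}`, and
  utility-blended evidence-layer selection with a reinforcement-learned
  preference order.
* **Normative Bayesian solver** — exact posteriors from the generative
  model and exact rule updates, the gold standard per response point.
* **Metrics** — negentropy `N = 100·(E_max − E)/E_max`, KL divergence
  `K` (bits) and similarity `S = 100·2^{−K}`, relative success rate
  `RSR = 100·(S_PM − S_PR)/(100 − S_PR)`, relative match rate
  `RMR = 100·F(t, s_mod)/F(t, s_max)`, allocation score S2, and
  bias labels (agent flatter than Bayes → anchoring; peakier →
  confirmation).

## Worked example

Five simulated subjects on the two-category event task:

```python
from sensemaker import ExperimentConfig, run_experiment
from sensemaker.metrics import summarize

frame = run_experiment(seed=1, config=ExperimentConfig(tasks=(1,), n_subjects=5))
print(summarize(frame))
```

prints (numbers from this exact call):

```
{'task1': {'mean_S1': 88.10, 'mean_S2': 98.0,
           'mean_N_model': 43.36, 'mean_N_bayes': 86.16,
           'bias_counts': {'anchoring': 46, 'confirmation': 4}}}
```

Reading it: the agent's responses sit at similarity 88% to the Bayesian
reference (S1), its forced choices were almost always correct here
(S2 = 98), but its mean negentropy (43) is far below the normative one
(86) — on 46 of 50 subject-trials the agent was flatter than Bayes, the
anchoring signature. The same machinery exposes the full protocol
(`tasks=(1,...,6)`, 45 subjects, memory persisting across tasks) and the
averaged probability-adjustment curves
(`sweep_adjustment(runs=1000)`), which show the linear-similarity
low-end overestimate and mid/high-range underestimate, and the ratio
similarity's reduction of the low-end overestimate.

The same runs are available from a shell:

```bash
sensemaker simulate --task 1 --trials 10 --seed 1 --out out/
sensemaker run-all --subjects 45 --seed 1 --out out/
sensemaker sweep-adjustment --runs 1000 --out out/curves.csv
sensemaker metrics --in out/
```

## Documentation

`docs/methods.md` describes the model, its parameters and defaults, the
numerical choices, and what the synthetic stimuli do and do not show.
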