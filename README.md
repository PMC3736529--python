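# stripefit

Cellular-resolution logistic modeling of how transcription-factor
concentration fields drive striped enhancer output in the *Drosophila*
blastoderm.

At the blastoderm stage ~6000 nuclei form a single layer at the embryo
surface, each carrying a measurable concentration of the maternal and gap
transcription factors (Bcd, Hb, Kr, Gt, Kni, …). Pair-rule enhancers such
as those of *even skipped* read these concentrations and switch ON in
sharp stripes. `stripefit` models that switch as a per-nucleus logistic
regression — a regulatory input function — and provides everything around
it: an expression-atlas data model, stripe segmentation on the nuclear
neighbor graph, exhaustive regulator discovery, in-silico genetic
perturbations, accuracy/consistency evaluation, a synthetic embryo
generator for validation, and a CLI.

## The model

For nucleus *i* with regulator concentrations x<sub>ki</sub>:

```
eta_i = beta_0 + sum_k beta_k x_ki  (+ beta_qq x_qi^2 for dual regulators)
p_i   = 1 / (1 + exp(-eta_i))
```

A regulator with a positive linear and negative quadratic coefficient is a
*dual* regulator: an activator below the crossover concentration
x\* = −β<sub>q</sub>/(2β<sub>qq</sub>) and a repressor above it.

## Worked example

Generate a synthetic embryo with a known truth model, segment the stripe,
fit, evaluate, and knock out a repressor:

```python
import stripefit as sf
from stripefit import synthetic as syn, labeling as lab, model, evaluation, perturbation

spec = syn.default_spec(n_nuclei=6078, seed=0)   # stripe-2-like embryo
atlas = syn.generate_atlas(spec)
labels = lab.label_target(atlas, "eve")
print(labels.stripe_sizes)
# {1: 710}

ts = lab.build_training_set(atlas, labels, {1}, list(spec.truth_model.spec.regulators))
print(len(ts.y), ts.n_on, ts.n_off)
# 6078 710 5368

fm = model.fit(ts, spec.truth_model.spec)
print(f"ll {fm.log_likelihood:.3f} converged {fm.converged} separation {fm.separation_flag}")
# ll -0.000 converged True separation True
```

The noise-free stripe has sharp borders, so the fit reaches perfect
(quasi-separated) classification — flagged, not an error. Evaluate with the
neighbor-ring metric (% of nuclei with p > 0.5 in the stripe, among its
adjacent OFF nuclei, and two graph steps out):

```python
field = model.predict(fm, atlas)
print(evaluation.accuracy_report(field, labels, {1}).as_dict())
# {'pct_in_stripe': 100.0, 'pct_ring1': 0.0, 'pct_ring2': 0.0,
#  'n_stripe': 710, 'n_ring1': 196, 'n_ring2': 187}

null = perturbation.predict_under(fm, atlas, perturbation.scenario("gt_null"))
s = atlas.ap_fraction
print(f"anterior border: wt {s[field.p > .5].min():.3f}  gt_null {s[null.p > .5].min():.3f}")
# anterior border: wt 0.275  gt_null 0.000
```

Removing the anterior repressor Gt extends the expression domain toward
the head, as a knockout experiment would. The truth model's dual Bcd term
has its designed crossover:

```python
print(model.dual_crossover(spec.truth_model, "Bcd"))
# 0.25
```

The same pipeline runs from the shell:

```
stripefit simulate --n-nuclei 6078 --seed 0 --out runs/sim
stripefit fit --atlas runs/sim/atlas.vpc --regulators Hb,Bcd,Gt,Kr \
              --quadratic Bcd --target-stripes 1 --out runs/fit
stripefit evaluate --atlas runs/sim/atlas.vpc \
                   --prediction runs/fit/prediction.csv --out runs/eval
```

Each output directory gets a `manifest.json` (config hash, seed, version);
identical config + seed reruns are byte-identical.

## Discovery

`discovery.score_all` fits every k-subset of the candidate regulators
(all C(38,4) = 73,815 combinations at full scale) on identical training
rows, ranks them by log-likelihood, and summarizes the sweep as a
pairwise-best score matrix. `discovery` is also a CLI subcommand.

## Real atlas data

`atlas.read_atlas` reads per-nucleus CSV atlases (`gene__cohort` channel
columns, semicolon-delimited neighbor lists); a YAML `ColumnMap` adapts
other column namings. Protein channels are preferred over mRNA for the
gap-gene products Bcd, Hb, Kr and Gt. Tests that reproduce published counts
on the external wild-type atlas release look for it at
`data/D_mel_wt__atlas_r2.vpc` and skip when it is absent.

## Reproducing results

```
python -m pytest -q tests/                       # full suite, incl. acceptance criteria
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

The acceptance script reports the headline quantities (enumeration count,
optimizer-vs-grid-oracle gap, per-coefficient Wald coverage, neighbor-ring
accuracy, discovery rank of the true regulator set, crossover recovery,
knockout border shift) as JSON. See `docs/methods.md` for all modeling and
numerical choices.
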