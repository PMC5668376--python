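# palmstate

Stochastic and cooperative models of multi-site S-palmitoylation, with
native mass-spectrometry quantification of palmitoylation states.

## The problem

S-palmitoylation attaches a C16:0 acyl chain to a cysteine thiol through a
thioester bond, adding ~238.4 Da per site. Membrane proteins such as
claudin-3 (four native sites) and CD20 (two sites) carry several sites at
once, so a purified protein is really a mixture of isoforms with 0, 1, …,
n_max palmitates. Native MS of the intact, micelle-released protein resolves
this mixture as a ladder of peaks spaced by the palmitoyl delta mass,
replicated across the electrospray charge-state envelope; integrated peak
areas give the *state distribution* — the fraction of molecules in each
palmitoylation state n.

`palmstate` provides, end to end:

* **masscalc** — average/monoisotopic protein masses from sequence (FASTA)
  and the palmitoyl delta mass, so ladder positions are predictable;
* **model** — the state-distribution models (below);
* **fitting** — scikit-learn style least-squares estimation of per-site
  probabilities and cooperativity from construct panels, including the
  staged single-site → independent → cooperative analysis;
* **spectra** — peak picking, charge-series deconvolution, and palmitoyl
  ladder assignment turning spectra into state distributions;
* **synthetic** — generators for construct-panel observations (multinomial
  counting noise) and Gaussian charge-envelope spectra, including the
  ready-made claudin-3 and CD20 study scenarios;
* **cli** — a `palmstate` command with `simulate-panel`,
  `simulate-spectrum`, `quantify`, `fit`, `predict` and `protocol`
  subcommands.

## The model

Let site *i* of a construct be palmitoylated independently with probability
*p<sub>i</sub>*, and write *p̄<sub>i</sub>* = 1 − *p<sub>i</sub>*. The
probability of observing *n* palmitates is the Poisson-binomial mass
function over the available sites,

P(n) = Σ over all n-subsets S of sites  ∏<sub>i∈S</sub> p<sub>i</sub> ∏<sub>j∉S</sub> p̄<sub>j</sub>,

computed here by convolving the generating-function factors
(p̄<sub>i</sub> + p<sub>i</sub>x).

Cooperativity enters through the conditional gain
P(n+1|n) ≡ P(n+1)/P(n). Scaling it as
P<sup>coop</sup>(n+1|n) = c<sup>n</sup>·P(n+1|n) is equivalent to
reweighting the states,

P<sup>coop</sup>(n) = N · c<sup>n(n−1)/2</sup> · P(n),

with N the normalization constant over n = 0..n_max. c = 1 recovers the
independent model; c > 1 means every prior palmitoylation makes the next
one more likely. Per-site probabilities and c are estimated by least-squares
minimization of calculated minus observed fractions over an entire construct
panel (wild type, multi-site and single-site mutants, Cys-free variant),
replicates entering as separate residual rows.

## Worked example

```python
from palmstate import (cld3_scenario, cooperative_distribution,
                       distribution_summary, generate_panel, staged_protocol)

scenario = cld3_scenario()          # 4 native sites + ~10% artifact site, c = 1.24
wt = next(s for s in scenario.constructs if s.construct_id == "WT")

dist = cooperative_distribution(scenario.params, wt)
print([round(f, 4) for f in dist.fractions])
mean, mode = distribution_summary(dist)
print(f"mean = {mean:.2f}, mode = {mode}")

obs = generate_panel(scenario, counts=1000, replicates=3, seed=1)
report = staged_protocol(obs, scenario.constructs, random_state=0)
for s in report.stages:
    print(f"stage {s['stage']} ({s['label']}): R^2 = {s['r_squared']:.4f}")
print("fitted c =", round(report.final.params.c, 3))
```

prints

```
[0.0018, 0.0231, 0.1204, 0.3298, 0.4293, 0.0955]
mean = 3.45, mode = 4
stage 1 (single-site priors): R^2 = 0.9991
stage 2 (independent prediction): R^2 = 0.8156
stage 3 (cooperative prediction): R^2 = 0.9951
stage 4 (global cooperative fit): R^2 = 0.9982
fitted c = 1.252
```

Reading: under the cooperative claudin-3 model the most prevalent isoform
carries four palmitates (43% of molecules) and the average palmitoylation
state is 3.45. On a simulated triplicate panel with 1000 molecules counted
per replicate, predicting the multi-site constructs from single-site
probabilities alone (stage 2) explains far less of the data than the
cooperative model (stages 3–4), and the global fit recovers the generating
cooperativity 1.24 to within sampling noise.

The same pipeline runs from the shell:

```bash
palmstate simulate-panel --scenario cld3 --seed 1 --out obs.tsv
palmstate protocol --observations obs.tsv --constructs constructs.tsv --out report.json
palmstate simulate-spectrum --scenario cld3 --construct WT --out spectrum.tsv
palmstate quantify --spectrum spectrum.tsv --base-mass 23000 --charges 10,13 --out states.tsv
```

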