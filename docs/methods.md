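# Methods

## State-distribution models

A construct exposes a subset of the site panel; each available site *i* is
palmitoylated with probability *p<sub>i</sub>* ∈ [0, 1], independently of
the others. The palmitoylation-state distribution is then the
Poisson-binomial mass function of the available sites, computed by
sequential convolution of the generating-function factors
(1 − p<sub>i</sub> + p<sub>i</sub>x) — O(k²) in the number of sites and
exact for degenerate probabilities (p = 0 or 1; an all-zero construct is a
point mass at state 0). An explicit 2^k subset-enumeration oracle exists in
the test suite only and the convolution is checked against it to 1e-10 for
panels up to ten sites.

Cooperativity is defined on the conditional gain P(n+1|n) = P(n+1)/P(n):
the cooperative model multiplies it by c<sup>n</sup>, equivalently

  P_coop(n) = N · c^(n(n−1)/2) · P(n),

renormalized over n = 0..n_max. The exponent is implemented as n(n−1)/2; a
unit test pins it to the literal triangular-sum form (Σ_{i=0}^{n} i) − n to
guard against notation drift. c = 1 reduces to the independent model
bitwise (to 1e-12), and c is required positive. The mode of a distribution
is the smallest state among maxima; ties toward fewer palmitates (real
panels do not produce ties, so the tie-break only matters for synthetic
edge cases).

The claudin-3 scenario uses site probabilities (0.69, 0.69, 0.86, 0.64)
for Cys 103/106/182/184, a fifth low-occupancy site at 0.10 representing
the cloning-artifact site that travels with every His-tagged construct,
and cooperativity 1.24; the CD20 scenario uses (0.74, 0.82) for
Cys 111/220 with cooperativity 1.51. Under these parameters the wild-type
claudin-3 distribution peaks at four palmitates — the cooperative
reweighting is what moves the mode from 3 (independent) to 4.

## Fitting

Parameters are estimated by trust-region least squares
(`scipy.optimize.least_squares`) on the residuals observed − calculated
fraction, pooled over constructs, replicates and states. Defaults: box
constraints p ∈ [0, 1], c ∈ (0, 10]; start p = 0.5, c = 1 plus 8 random
restarts (p ~ U(0.05, 0.95), c ~ U(0.5, 2), seeded); relative objective
tolerance 1e-12 and at most 10,000 evaluations. Probabilities outside
[0, 1] are physically meaningless, hence the box; an `unrestrained` flag
frees the probabilities for a fully unconstrained minimization (c stays
positive, which the weight c^n(n−1)/2 requires), and well-behaved panels
never leave the box anyway. Non-convergence is flagged on the result, not
raised. Replicates enter as separate residual rows except in the
single-site prior stage, where replicate fractions are averaged first.

Fitting c requires at least one construct with two or more available
sites; a panel of single-site constructs carries no information about
cooperativity and raises an explicit identifiability error.

Goodness of fit defaults to the pooled coefficient of determination
1 − SS_res/SS_tot over every fraction; a squared-Pearson variant is
exposed behind a flag since summary "correlations" of predicted versus
observed distributions are reported either way in the literature. Zero
total variance makes R² undefined and is raised as such.

### Staged protocol

The staged analysis mirrors how a construct panel is interrogated:

1. **Single-site priors.** Constructs carrying (at most) one engineered
   site are fitted jointly with the independent model, replicates
   averaged. Sites present in *every* construct of the panel are treated
   as background — this is how the claudin-3 cloning-artifact site is
   recognized, so the "single-site" mutants (one native site + artifact
   site) and the Cys-free variant (artifact site only) are selected
   automatically. The subset can be overridden explicitly.
2. **Independent prediction.** The priors predict the multi-site
   constructs with c = 1; pooled R² is reported.
3. **Cooperative prediction.** Same priors with a cooperativity that is
   either borrowed (e.g. transferring a value fitted on another protein
   to a two-site protein, where a single wild-type experiment cannot pin
   c on its own) or fitted as the lone free parameter; the report records
   which.
4. **Global cooperative fit.** All probabilities and c refitted against
   all observations.

On noiseless model-generated panels stage 4 reaches R² = 1 and returns the
generating parameters to 1e-4; under multinomial noise the nested-model
ordering (cooperative objective ≤ independent objective) holds by
construction and is property-tested.

## Spectra

Simulated spectra place, for each charge z and state n, a Gaussian at
(M + n·Δ + z·1.00728)/z with area proportional to the state fraction and
width σ/z, plus seeded additive baseline noise. Defaults: base mass
23,000 Da (small-membrane-protein scale — arbitrary and irrelevant to the
model fits), Δ = 238.415 Da (average mass of C16H30O, the thioester-linked
palmitoyl), charges 10–13, σ = 3 Da, noise 0.5% of the tallest peak.

Quantification is deterministic: local maxima above relative intensity and
prominence thresholds (2% of the base peak by default) are picked; areas
are trapezoidal integrals between effective flanking minima, found by a
walk that tolerates small noise upticks (the signal must fall below half
the apex and rise back by 5% of the drop before the bound is set) — no
peak-shape model is assumed. Charge deconvolution assigns each peak the
charge whose implied neutral mass M = z·(m/z) − z·1.00728 is corroborated
by the most other peaks within tolerance (2 Da default), ties to the lower
charge; corroborated peaks merge into species (area-weighted mean mass,
areas summed) and unsupported peaks are reported as unassigned rather than
dropped. Ladder assignment maps each neutral mass to rung
n = round((M − base)/Δ) within ±1.5 Da (instrument-resolution scale for a
~23 kDa species) and converts per-rung areas to fractions; rungs sharing
two peaks are summed.

The full round trip (simulate → pick → deconvolute → assign) recovers the
generating distribution within ±0.02 per state under the default
peak-spacing and noise settings; states whose peaks fall below the picking
threshold (fractions ≲ 0.005) are reported as 0, which stays inside that
tolerance. A mean state ≥ 0.2 (inclusive) classifies an engineered
cysteine as a palmitoylation site.

## Synthetic panels

Counting noise is multinomial on state counts, 1000 molecules per
replicate and biological triplicates by default — a scatter comparable to
replicate spread seen in intact-protein quantification; no systematic
(e.g. ionization-bias) error is modelled. Random streams are derived per
(construct, replicate) from the scenario seed, so any subset of a panel is
reproducible in isolation. Because the generator samples the same
cooperative model the estimators fit, parameter-recovery tests demonstrate
estimator correctness and panel identifiability, not robustness to model
misspecification on real spectra.

A simulation study (100 seeded panels, claudin-3 design, counts = 1000,
triplicates, single-start fits) requires the global cooperative fit to
land within ±0.05 of every site probability and ±0.15 of c in at least
90% of runs.

## Mass arithmetic

Atomic weights are IUPAC 2013 standard values baked in to six decimals;
average masses are the default everywhere because native MS of intact
proteins resolves average, not monoisotopic, masses. Cysteines are free
thiols; modifications enter only as explicit deltas. The proton mass used
in charge arithmetic is 1.00728 Da and no adducts other than protons are
modelled. The monoisotopic residue table is cross-checked against
pyteomics in the test suite.

## Limitations

* No kinetic or ordered (sequential) palmitoylation models; the
  cooperative reweighting is time-independent.
* No confidence intervals or posterior sampling; model comparison is by
  R²/objective only.
* Spectrum simulation omits detergent-micelle adducts, in-source
  fragmentation, isotopic fine structure and vendor-specific peak shapes;
  equivalence with vendor deconvolution tools is claimed only at the level
  of recovered state fractions on synthetic data.
* Real replicate structures can be unbalanced across constructs; the
  generator uses a fixed replicate count per construct.
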