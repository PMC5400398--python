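# Methods

## The problem

Two nightjar hemoglobin (HbA) genotypes differ at four amino acid sites —
Gα4S, Vα13I, Aα34V, Iβ112V — and in their oxygen affinity under allosteric
effectors: the ancestral genotype `GVAI` has P50(KCl+IHP) ≈ 30 torr, the
derived quadruple mutant `SIVV` ≈ 36 torr.  Treating each site as
bi-allelic (ancestral/derived) spans a 2⁴ = 16-genotype hypercube, and the
evolutionary transition can in principle follow any of 4! = 24 *forward
pathways*: orderings in which each substitution fixes once, sequentially,
without reversion.  The analysis asks which of those pathways are
selectively accessible, given the measured phenotype of every intermediate
genotype.

## The neutral corridor

For a chosen trait (by default P50 in the simultaneous presence of KCl and
IHP, the condition closest to the avian red cell), the *neutral corridor*
is the interval between the outer 95% confidence limits of the two
endpoint genotypes: floor = min of the endpoints' lower limits, ceiling =
max of their upper limits.  An intermediate genotype is

* **strictly below/above** when its own 95% CI entirely excludes the
  corridor bound,
* **marginally below/above** when its mean lies outside the corridor but
  its CI still straddles the bound,
* **within** otherwise.

A pathway is **inaccessible** when at least one intermediate is strictly
outside, **marginal** when none is strict but at least one is marginal,
and **accessible** otherwise.  Endpoints are never judged — the question
is about intermediate steps.  The marginal rule is a design choice (the
notion of a "marginally significant" excursion is not uniquely defined);
the default CI-overlap rule is configurable, with an alternative
`epsilon` rule that also calls marginal any CI clearing the bound by less
than ε·(corridor width), ε = 0.05 by default.

Per-step monotonicity of a pathway is not used to veto accessibility; only
corridor excursions of intermediates are.

## Hill-curve phenotyping

Each genotype × treatment phenotype comes from saturation curves fitted
with the Hill model Y = PO₂ⁿ / (P50ⁿ + PO₂ⁿ).  Two routes are
implemented, matching standard oxygen-equilibrium practice:

* **Nonlinear least squares** on points with observed saturation in a
  0.30–0.70 window (points outside the window are dropped, not clamped;
  ≥3 must remain).  Initialization: P50₀ = PO₂ interpolated at Y = 0.5,
  n₀ = 2.  SEs come from the regression covariance; CI95 = estimate ±
  t(m−2)·SE.
* **Linearized Hill plot**: OLS of logit(Y) on ln(PO₂) in a 0.25–0.75
  window (≥4 points; Y = 0 or 1 excluded).  n50 is the slope; P50 the
  zero crossing.  The P50 CI is built on the log scale via the delta
  method, which keeps it positive.

On exact Hill data the two routes agree to machine precision; on noiseless
data the residual variance is zero and the CI degenerates to a point
(hence the record invariant is `lo ≤ hi`, not strict).  Natural logs are
used internally; base-10 only for display.

Replicates are aggregated as mean ± SE (SE = sd/√k) with a Student-t 95%
CI on k−1 degrees of freedom; a normal-quantile CI is available via
`ci_method="normal"`.  A single fit passes through with its own SE/CI;
both the single-curve and the replicate path are supported because
published affinity tables mix the two.  Allosteric-effector sensitivity
is defined as the fold ratio P50(effector)/P50(stripped), with SE by the
delta method on the log scale — fold-change semantics match how effector
responses are usually described.

## Mutation effects and sign epistasis

Substitution effects are computed on ln P50 (fold-change scale): for site
*i* and each of the 2ⁿ⁻¹ backgrounds lacking the derived allele at *i*,
Δ = ln P50(background + i) − ln P50(background), with SE by the delta
method.  A sign is called when |Δ|/SE > z* (default 1.96; no
multiple-testing correction is applied, and none is claimed).  A site
shows **sign epistasis** when its effect is significantly positive on some
background and significantly negative on another; the report lists both
background sets, so the witnessing pairs can be read off directly.  On
the default landscape the Iβ112V site is flagged with, e.g., a strong
negative effect on the SVAI background and a strong positive (rescuing)
effect on SIAI.

## Parsimony polarity

Which allele is ancestral at a site is inferred by Fitch small parsimony
over a user-supplied newick species tree and per-taxon residue table.
Multifurcating nodes are folded pairwise left-to-right, which is exact on
binary trees (the case tested against an exhaustive assignment oracle);
ties at the root are reported as ambiguous, with the lexicographically
first state returned deterministically.  The package does not arbitrate
between discordant gene trees — the caller chooses the topology per site.

## Quaternary-structure index

Gel-filtration calibrations regress log₁₀(MW) on elution volume over ≥2
markers (monomeric myoglobin ≈17 kDa, tetrameric human Hb ≈64.5 kDa; a
two-marker line interpolates exactly).  Base-10 logs are the SEC
convention.  A positive fitted slope — apparent MW increasing with
elution volume, the reverse of normal column behavior — is accepted but
warned about, since printed calibration coefficients are treated as data,
not re-derived.  The tetramer–dimer index places a sample's apparent MW
linearly between the tetramer and dimer reference masses, clamped to
[0, 1]; no dissociation constant is modeled.

## Synthetic data: what it does and does not show

The generator produces every input the pipeline consumes, bit-reproducibly
under a fixed seed:

* **Saturation curves**: exact Hill points plus Gaussian noise on Y
  (default σ = 0.01 per equilibration step), truncated to [0, 1].  Noise
  is on saturation only, not on PO₂.
* **The 16-genotype landscape**: endpoint records are anchored to the
  measured native isoforms (GVAI: stripped 2.48 ± 0.03, KCl 3.73 ± 0.04,
  IHP 43.55 ± 1.06, KCl+IHP 30.21 ± 0.82 torr; SIVV: 2.77, 4.24,
  50.38 ± 1.64, 36.12 ± 1.30).  Interior genotypes ramp linearly in
  Hamming distance between the endpoints with small seeded jitter
  (clipped at ±2 SD so the planted pattern is deterministic).  Three
  genotypes (SIAI, SVAV, SIVI) are planted at P50(KCl+IHP) = 12 torr with
  low cooperativity — far below the corridor floor — and GIAV is planted
  one ancestral SE below the floor, so it classifies as marginal under
  the default rule.  Default replicate count is 3 per genotype ×
  treatment.
* **Elution fixtures**: two markers on a log-linear column line and
  samples at tetramer, intermediate, and near-dimer positions, generated
  by inverting the marker line at known true MWs (noiseless by default,
  so the round trip is exact).

**Limitation — synthetic intermediate phenotypes.**  The measured P50
values for the 14 intermediate recombinant hemoglobins, and the measured
1.6-fold GVAI→SIVV affinity change, live in supplementary material that
is not redistributed here.  The interior landscape values are therefore
*synthetic stand-ins*, chosen only to realize the qualitative
accessibility structure (which genotypes fall below the corridor, and
hence the 12/4/8 pathway partition); per-genotype interior numbers carry
no empirical authority.  Passing tests demonstrate that the machinery
reproduces the combinatorial and classification structure, not the
laboratory values of individual intermediate genotypes.  The fixture
plants phenotypes, not mechanisms: it does not simulate the biophysics
linking tetramer–dimer dissociation to IHP insensitivity.

## Numerical and design choices

* Treatment tokens are normalized case-insensitively to
  `{stripped, KCl, IHP, KCl_IHP}`.
* The combinatorial guard refuses panels beyond 12 sites (n! pathway
  enumeration); the limit is configurable per call.
* Genotype labels are per-site residue letters concatenated in panel
  order; decoding rejects any letter matching neither allele rather than
  guessing.
* Corridor classification operates on arbitrary real trait values, making
  it equivariant under trait negation (below ↔ above); record validation
  separately enforces positive P50 on physical records.
* All randomness flows from a single top-level seed
  (`numpy.random.default_rng`); reports record the seed and a hash of the
  configuration.
* Simulation sizes used in the test suite (200 Monte-Carlo curve fits for
  bias, 1000 triplicates for CI coverage, 1000 curves for SE calibration,
  1000 additive landscapes for the false-positive check) were chosen to
  keep sampling error well below the asserted tolerances while running in
  seconds.

## Known limitations

* No population-genetic weighting of pathways (fixation probabilities),
  no simultaneous double fixations, no reversions — accessibility is
  judged purely under sequential fixation without reversion.
* No MWC/Adair multi-state fitting, Bohr-effect titration, or
  absorbance-to-saturation conversion; inputs are (PO₂, Y) points or
  summary tables.
* Gel-filtration inputs are peak elution volumes; chromatogram signal
  processing and concentration-dependent dissociation equilibria are out
  of scope.
* Fitch polarity is exact on binary trees only; heavily multifurcating
  trees may be scored conservatively high.
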