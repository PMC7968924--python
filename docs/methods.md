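# Methods

This note documents the models implemented in `genedrive`, the defaults
and their rationale, the design choices that were genuinely open, and the
limitations of what the synthetic-data tests can show.

## Drive genetics and inheritance cubes

Genotypes are unordered diploid allele pairs at up to three unlinked,
freely assorting autosomal loci (target/cassette, a standalone ClvR
cassette, and a split Cas9 locus). Parental origin is not tracked except
through the maternal-carryover step, which acts on the zygote genotype
distribution. Germline conversion applies to each W allele independently:
in an individual carrying both Cas9 and gRNAs, a W allele is cleaved with
probability `c` (sex-specific), converted by HDR to the drive allele H
with probability `ch` given cleavage — only in homing architectures and
only when an H homolog is present as repair template — and otherwise
end-joined to an in-frame functional allele R (fraction `cr`) or a
loss-of-function allele B. H, R, and B transmit unchanged; R is modeled
cost-free and cleavage-immune. Maternal carryover converts every zygotic
W allele to R (`dr`) or B (`1-dr`) in a fraction `d` of zygotes of
Cas9+gRNA mothers; it is applied to all zygotes of such mothers,
including drive-inheriting ones, because conversion of the inherited W
homolog matters even where rescue masks the phenotype.

Viability encodes the rescue logic. HomeR and TARE carry the rescue in
cis, so only B/B target genotypes are unviable; ClvR rescues in trans, so
a genotype dies only with zero functional target copies *and* no cassette
anywhere; the HGD is assumed to sit in a non-essential gene, so every
genotype is viable. Fitness costs are dominant, female-specific fecundity
multipliers: drive carriers for HomeR/TARE (default 5%), Cas9 carriers
for ClvR (5%), and for the HGD both drive carriers and B/B females (20%),
since without a rescue the target-gene disruption itself is costly. The
cost placement for HGD B/B females was an open choice; it follows the
attribution of the HGD's decline to disruption-derived costs.

Parameter bundles (`presets`): ideal drives use 99% cleavage; homing
drives 90% HDR with 0.5% in-frame end joining; toxin–antidote drives 0.1%
in-frame; TARE's maternal carryover is 95% against 99% elsewhere
(reflecting its weaker deposition), and deposition for homing drives
defaults to the germline cleavage rate since no separate value is
characterized. The experimentally derived HomeR bundle (`homer_exp`)
zeroes male HDR and raises in-frame end joining to 1%; the fitted bundle
(`fitted_homer`) is c_F=0.992, c_M=0.996, ch_F=0.995, ch_M=0.096,
cr=0.029, s_F=0.003 with no deposition term. In the efficacy sweep, the
deposition fraction follows the varied cleavage rate (capped at the
bundle's value) because both arise from the same Cas9/gRNA activity; a
drive with zero cleavage would otherwise still spread by deposition
alone.

Every cube row sums to 1 before viability filtering, and zeroing cleavage
and deposition reproduces the independently constructed Mendelian cube
exactly; both are enforced by `validate_cube` and by property tests over
random parameter draws.

## Cage simulator

Discrete generations at a fixed census (default 400 adults, 200 per
sex). Each generation: females mate once (multinomial over adult-male
genotype frequencies), egg numbers are Poisson with mean 50 per female
scaled by the genotype's fecundity multiplier, offspring genotypes are
multinomial draws from the cube row, unviable zygotes are removed, sexes
are assigned by a fair binomial, and census/2 adults per sex are drawn by
multivariate hypergeometric sampling (all survivors carry over on an
undershoot). The egg mean of 50 only needs to be large enough that the
census resampling, not egg supply, limits the next generation; its exact
value is immaterial and it is exposed in the configuration. Generation
labels follow the cage protocol: seeded adults are P, the first scored
offspring cohort is G0. Replicates are seeded as `seed + replicate`.

The infinite-population limit of this pipeline is the deterministic
recursion used by the inference module (fecundity-weighted mothers,
unweighted fathers, cube contraction, viability renormalization). With a
400-adult census, the stochastic replicate mean sits slightly below the
deterministic recursion in mid-trajectory (a drift-curvature effect of
order 0.004 in carrier frequency, measured over 1,500 replicates); at 500
replicates the two agree within Monte-Carlo error, which is what the test
asserts.

## Field simulator

Daily time steps with fixed stage durations (egg 2 d, larva 5 d, pupa
1 d), geometric adult mortality with mean lifespan 11 d, and a fair
binomial sex split at eclosion. Egg laying is Poisson per female genotype
(default 20 eggs/female/day, a realistic dipteran rate whose exact value
only shifts the larval equilibrium), with sires drawn from the current
adult-male genotype frequencies — females are not tracked by mate, which
makes released males effective immediately. Unviable zygotes die before
the egg stage. Density dependence acts on daily larval survival in
Beverton–Holt form `s(L) = 1/(1 + αL)`; α is calibrated in closed form so
that the wildtype equilibrium equals the configured adult census (the
functional form was an open choice; Beverton–Holt gives a stable,
analytically calibratable equilibrium). Simulations start at the
deterministic wildtype equilibrium, and an unperturbed run stays within
±10% of it — the calibration check in the test suite.

Releases are male-only, sized as a fraction (default 20%) of the current
total adult census, weekly by default for up to 13 weeks; split designs
release drive+Cas9 double homozygotes first and Cas9-only homozygotes
afterwards. Release males mate at parity with wild males. The window of
protection counts days with female drive-carrier frequency above 95%
between the first release and the horizon (4 years by default); the
threshold metric measures drive carriers, not Cas9 carriers.

## Inference

The fitted model is the one-locus homing model with parameters
(c_F, c_M, ch_F, ch_M, cr, s_F), uniform priors on [0,1]^6, B/B
recessive-lethal, and no deposition term.

A central finding of the implementation is that the per-generation
marker-positive fraction alone does **not** identify these parameters:
distant parameter vectors (for example c_F≈0.81, c_M≈0.76, ch_F≈0.89,
ch_M≈0.91, cr≈0.22, s_F≈0.28 against a generating set of 0.992, 0.996,
0.995, 0.096, 0.029, 0.003) produce carrier trajectories agreeing to
within 0.004 at every generation, and with the fecundity cost free the
female and male transmission roles are exchangeable in the trajectory.
A fit to marker counts alone therefore lands wherever prior volume
accumulates along these ridges. The likelihood consequently combines the
three assay channels such a cage study actually produces:

1. **Cage marker counts** — binomial at the model-expected carrier
   fraction. By default each generation is predicted one step ahead from
   the previously *observed* marker fraction (within-class genotype
   composition from the model); fitting the open-loop trajectory instead
   provably absorbs accumulated cage drift into biased parameters (male
   cleavage collapses toward 0.25 across seeds). Open-loop fitting
   remains available (`conditional=False`).
2. **Pair-cross F1 counts** — binomial at the sex-specific transmission
   rate 0.5(1 + c·ch); these anchor the products c_F·ch_F and c_M·ch_M.
3. **Genotype surveys** — multinomial over the model's within-class
   genotype composition: marker-negative flies genotyped at early
   generations (separating surviving W from R and B, which pins the
   cleavage rates individually) and sequenced marker-positive flies at
   the final generation (pinning the R/B balance, hence `cr`).

The sampler is random-walk Metropolis on logit-transformed parameters
with the proposal covariance adapted to the chain's recent history during
burn-in (scaled 2.38²/d, frozen afterwards) and a Nelder–Mead
posterior-mode start; fixed isotropic proposals mix too slowly along the
posterior's curved ridges. Defaults: 50,000 iterations, 10,000 burn-in.
Acceptance is reported, a zero-acceptance burn-in aborts with a
diagnostic, and zero iterations returns the initial point.

Under this design, synthetic-data refits at the fitted parameter bundle
recover female cleavage within a few tenths of a percent, the male HDR
probability with a spread of roughly ±1.5 percentage points around its
generating value, and the in-frame fraction within about one point. The
fecundity cost s_F is recovered with an upward bias of a few percent
under one-step-ahead fitting (drift variance leaks into the cost term);
its posterior still covers small generating values.

## Synthetic data

The generator emulates the cage study: parental seeding of 50
drive-homozygous males + 50 wildtype males + 100 wildtype virgin females,
propagation at a 400-adult census, and 250–350 scored flies per
generation (uniform draw, or a fixed count). Scored flies are a
multinomial genotype draw at the adult genotype frequencies, so marker
counts and survey genotype counts are mutually consistent. Assay scales
were fixed once from the study's reported precision: 10 cross vials × 200
F1 per parent sex (replicate-cross standard deviations of a few percent
imply vials of 100–200 flies), all marker-negative scored flies genotyped
at generations 2–3, and 60 marker-positive flies sequenced per cage at
the final generation. The no-drive control dataset zeroes all cleavage
and pairs the cages with Mendelian control crosses.

What the synthetic tests do not show: real cages have overlapping egg
batches, male-competitiveness differences (drive males siring ~41% was
observed but is not modeled, matching the female-only cost structure of
the fitted model), genotyping error, and resistant-allele sequence
diversity; none of these are emulated, so passing recovery tests
demonstrate estimator correctness under the model's own sampling
assumptions, not robustness to those violations.

## Numerical choices and limitations

* Cube rows are validated to 1e-12; probabilities are exact products of
  branch probabilities, not renormalized.
* The likelihood is -inf only when an expected fraction of exactly 0
  or 1 is contradicted by data; interior parameters always give finite
  values (log-pmf via gammaln, no clipping of model probabilities).
* Extinction terminates a cage trajectory with a flag rather than an
  exception; efficacy metrics use the terminal state of short replicates.
* Sex-linked insertions, linked loci with partial recombination,
  multiplexed gRNAs, spatial structure, and seasonality are out of scope.
* Problem sizes in the test suite (replicate counts, grid sizes, field
  horizons) are chosen as the smallest designs whose Monte-Carlo error is
  comfortably below the asserted tolerances.
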