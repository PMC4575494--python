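# Methods

## The model

`strmixlr` computes semi-continuous likelihood ratios for forensic STR
profiles.  The evidence at each locus is summarized as the *set* of detected
alleles E (peak heights are not modelled, except as the covariate of the
drop-out estimator).  For a hypothesis H describing the contributors, the
per-locus likelihood is

    P(E | H) = Σ_{genotypes of the unknowns} P(genotype set) · P(E | all contributor alleles)

and the likelihood ratio is LR = P(E | H1) / P(E | H2), multiplied across
loci under linkage equilibrium.

### Drop-out and drop-in

Given the full multiset of contributor alleles, P(E | alleles) factorizes
per allele:

* an allele carried in c copies drops out entirely with probability
  α^(c−1)·P(D_O)^c, and is detected with one minus that.  α < 1 encodes the
  empirical observation that a homozygote's complete drop-out is rarer than
  the square of single-allele drop-out; α = 1 recovers per-copy independence.
* an allele of an **assumed** (undisputed) contributor that is detected in E
  contributes factor 1 — its detection is certain and it may *mask* identical
  alleles of disputed contributors.  Assumed-donor alleles **not** detected
  in E carry no penalty and are excluded from masking (an undetected peak
  cannot mask anything); validation emits a warning.
* evidence alleles carried by no contributor must have dropped in.  The
  drop-in model allows at most one per locus: no unexplained allele gives a
  factor 1 − P(D_I); exactly one unexplained allele d gives P(D_I)·p_d with
  p_d the floored population frequency (not θ-adjusted — drop-in models
  contamination, not a sampled population allele); two or more unexplained
  alleles make the hypothesis impossible at that locus (probability 0).

P(D_O) is shared across loci and contributors; per-locus or per-contributor
drop-out, stutter, peak-height likelihoods and replicate analysis are out of
scope.

### Population model

Unknown genotypes are priced with the Balding–Nichols coancestry adjustment
applied *allelically*: the probability of sampling one more copy of allele a,
after m alleles with m_a copies of a have been seen, is

    P(a | counts) = (m_a·θ + (1−θ)·p_a) / (1 + (m−1)·θ)

A genotype is two sequential draws (×2 if heterozygous); the draw order does
not matter.  The conditioning counts contain the suspect's genotype (on
**both** sides of the LR — this is what makes θ > 0 pull the denominator
toward the suspect and lower the LR), all assumed donors' genotypes, and the
alleles of unknowns drawn earlier within the same term of the sum.  Evidence
alleles as such are *not* added to the counts; uncertainty in rare-allele
frequencies is handled instead by the 5/(2n) floor: any allele appearing in
the suspect profile or the evidence whose frequency is below 5/(2n) — n the
number of individuals in the frequency database — is raised to 5/(2n), and
absent alleles are inserted at that value.  No renormalization follows, so
per-locus frequency sums may slightly exceed 1; normalization-dependent
identities therefore hold for un-floored tables.

### Relatives

A denominator hypothesis may replace one unknown by a *relative* of the
suspect, summarized by (k0, k1, k2) — the probabilities of sharing 0, 1 or 2
alleles identical by descent (siblings ¼/½/¼, parent–child 0/1/0, identical
twin 0/0/1, unrelated 1/0/0).  The relative's genotype probability is
k2·1{g = g_s} + k1·P₁(g) + k0·P(g | counts), where P₁ picks the shared allele
of a heterozygous suspect uniformly (Mendelian symmetry) and draws the
non-shared allele from the conditional population model.  The IBD-shared copy
is inherited, not sampled, so it does not enter the conditioning counts for
the non-shared draw; the relative's *realized* genotype does join the counts
for any further unknowns, like every other drawn contributor.

## The sum over unknowns: dynamic program and oracle

Naive enumeration over genotype sets grows as (A(A+1)/2)^U.  The engine
instead sums over allele-*count* vectors: sequential Balding–Nichols draws
are exchangeable, so every ordered sequence of 2U alleles with counts c has
the same probability — a numerator that factorizes per allele and a
denominator common to all sequences — and reading a sequence as U
consecutive pairs puts ordered sequences in bijection with ordered genotype
tuples (heterozygote factor 2 included).  The dynamic program convolves over
the allele universe with state (draws used, unexplained evidence alleles so
far, capped at 2), folding in each allele's drop-out/detection factor and,
for an evidence allele left with zero copies, its drop-in frequency weight.
A relative contributor (at most one) is enumerated explicitly around the DP.

Correctness is owed entirely to `brute_force_sum`, a genuinely separate code
path that nests loops over ordered genotype tuples with sequential
conditioning.  The suite checks DP = brute force to relative 1e-9 on 200+
randomized cases (2–8 alleles, 0–3 unknowns, θ/P(D_O)/P(D_I) grids, with and
without masking and relatives); observed agreement is at machine precision
(~1e-15).

## Degenerate cases and numerics

* Empty evidence locus (complete drop-out): every contributor allele takes
  its drop-out factor and the drop-in factor is 1 − P(D_I).
* Denominator 0 with numerator 0 (e.g. P(D_I)=0 with an inexplicable
  allele): the locus LR is reported as 1 with a warning rather than
  aborting, so the offending locus is visible in the output.  Denominator 0
  with positive numerator reports +inf with a warning.
* A suspect allele absent from the frequency table is inserted at the floor,
  never treated as probability 0.
* All probabilities are plain double precision; per-locus values are far
  from underflow at the supported scale (≤ 4 unknowns).
* The drop-out estimator clips predictions to [1e-6, 1 − 1e-6] so degenerate
  0/1 drop-out probabilities never enter the engine.

## Parameters

| parameter | meaning | default | basis |
|---|---|---|---|
| P(D_O) | per-allele drop-out probability | user-supplied | sample-specific; estimate via the logistic model or sweep a range |
| P(D_I) | probability of exactly one drop-in at a locus | 0.01 | conventional nuisance value; larger values should alert a lab to contamination problems |
| θ (F_ST) | coancestry coefficient | 0.01 | the value in routine US forensic use |
| α | homozygote drop-out correction | 0.5 | standard semi-continuous practice; user-configurable |
| (k0,k1,k2) | IBD sharing probabilities of the hypothesized relative | none | from the relationship, e.g. siblings ¼/½/¼ |

The drop-out estimator applies a *user-supplied* logistic regression of
P(D_O) on average detected peak height (transform `identity` or `log10`,
stated explicitly because published calibrations differ); laboratories are
expected to fit coefficients to their own validation data.  Any coefficients
shipped in tests are synthetic.

## Synthetic data

The simulator generates frequency tables (Dirichlet-like draws, per-locus
sums exactly 1, n = 1000 individuals by default), θ = 0 reference profiles,
and evidence produced by independent per-copy drop-out plus at most one
frequency-weighted drop-in allele per locus.  Study conditions used by the
validation suite: 10 markers × 8 alleles, two-person mixtures at
P(D_O) = 0.3, P(D_I) = 0.01, 100 known non-contributors — small enough to run
in seconds, large enough that a true contributor separates cleanly from
non-contributors.

What the simulator does and does not show: it emulates the presence/absence
structure of low-template profiles, not peak heights, stutter, degradation
or inter-locus drop-out correlation.  Passing generative-agreement tests
show the engine's drop-out factorization is exactly the simulator's
mechanism at α = 1; they say nothing about how well α = 0.5 fits real
homozygote drop-out, which is an empirical calibration question.

Two deliberate asymmetries between simulator and engine are documented
rather than hidden:

* α: the simulator drops each copy independently (α = 1).  The α < 1
  correction is a likelihood-side adjustment with no stated generative
  mechanism, so α ≠ 1 behavior is verified only through closed-form factor
  identities.
* drop-in coincidence: the simulator's contaminant is drawn from the full
  frequency table and may coincide with a contributor allele, in which case
  it is invisible.  The semi-continuous factorization ignores this, so its
  outcome probabilities sum to 1 − P(D_I)·Σ_carried p_a < 1 and *no*
  generative process can match it on every outcome when P(D_I) > 0.
  Agreement is therefore asserted over all outcomes with drop-in off, and on
  novel-allele outcomes (where the correspondence is exact) with drop-in on.
  The discrepancy on no-novel-allele outcomes is bounded by P(D_I)·Σ_carried
  p_a — below 1% at default P(D_I) — and is one reason P(D_I) is a nuisance
  parameter, not a modelled rate.

## Known limitations

* Semi-continuous only: peak heights inform the analyst's preparation of the
  input and the drop-out estimate, never the likelihood itself.
* One drop-in per locus; profiles needing two simultaneous contaminations
  under some hypothesis get probability 0 there (reported with warnings).
* Autosomal, unlinked, diallelic-genotype markers only; no mutation, no
  suspect inbreeding, no tri-allelic patterns, no Y/X-STRs.
* Up to 4 unknown contributors (3 alongside a named suspect); runtime grows
  with the count-vector lattice, not the genotype-set space, so 4 unknowns
  on large ladders remain fast.
* Whether the original adjunct calculator's covariate is raw or log peak
  height is not fixed here; the transform is explicit configuration.
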