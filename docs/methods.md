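# Methods

## The linkage mixture

The model treats each virion's displayed tail-fiber composition as drawn
from an all-or-nothing mixture. A particle packages a mutant genome with
probability *f* (0.5 in the equimolar design). With probability λ its 18
monomers (6 fibers × 3) all match the packaged genotype — pure
self-assembly; with probability 1 − λ each monomer is drawn independently
from the shared pool and is mutant with probability *f*. The monomer-pool
fraction is taken equal to the genome fraction (expression proportional to
template abundance); no kinetic or structural detail is modelled. The
all-or-nothing form was chosen because the experimentally accessible
quantity is the *pure-class* fraction: under this parameterization the
measured pure fraction *is* the linkage estimate λ̂ (full linkage would
make every particle pure, i.e. pure fraction 1). A per-monomer mixing
alternative would fit the same data but has no extra identifiable
parameter from these readouts.

Display classes are defined on monomer counts (WT = 0 mutant monomers,
MUT = all 18, MIX otherwise) — the most permissive reading consistent
with the null infectivity hypothesis. Infectivity on the restrictive
(ReLPS) host is a separate axis, parameterized as (m, j): at least j
fibers each carrying at least m mutant monomers. H0 = (1, 1). The (m, j)
family generalizes the alternatives considered for the dilution-series
comparison; plaque formation additionally requires a mutant genome
(wild-type genomes cannot propagate on the restrictive host after
injection).

Closed forms are elementary binomials. Two independent implementations
guard them: a dynamic program over fibers (joint distribution of total
mutant monomers and qualifying fibers, used by the experiment simulator)
and a brute-force enumeration over all (K+1)^J per-fiber configurations
(refused above 24 monomers). Tests require agreement to 1e−12.

## Titer statistics

Spot assays drop 3.5 µL of each ten-fold dilution; plaques are countable
only in the open window 1 < n < 20. Each countable spot is a Poisson
estimate (sd √n); spots are pooled by inverse-variance weighting with the
variances evaluated at the common pooled titer, which is algebraically
the pooled-count estimate Σnᵢ / Σ(1/scaleᵢ). Weighting by observed counts
instead biases low (small counts get the largest weights); the pooled
form is unbiased and reproduces the single-spot arithmetic exactly. An
all-zero series returns a one-sided "below detection" bound at one plaque
equivalent of the least-diluted spot, which propagates through ratios as
a flagged bound (supporting statements like EOP < 10⁻⁵); an entirely
saturated series is an error.

All uncertainty propagation is first-order with independence assumed —
no covariance tracking. The one place correlation matters is handled
explicitly: in a solved class table, mut/MUT and wt/MUT are deterministic
rescalings of wt/WT and mut/WT, so the pure and opposing sums are
propagated as scalings (summing the table entries under independence
would understate their sds by √2 at an equimolar mix, which measurably
degrades the coverage of λ̂ intervals).

## Deconvolution conventions

The three measured fractions are
F1 = T(restrictive, co) / T(permissive, co);
F2 = T(post-challenge, co) / T(post-challenge, control) × control
wild-type content (0.5) — the challenge-survival factor cancels against
the control; and F3 = T(restrictive, amplified) / T(permissive,
amplified). Two conventions map F3 onto the population mut/WT fraction:

* **paper** (default): mut/WT = F3. This reproduces the published
  0.03% figure and the associated table.
* **strict**: mut/WT = F2 × F3, reading F3 as a fraction of the
  amplified survivor pool. This is the convention exactly consistent
  with the simulator's amplification step (the identity is exact at any
  λ, including λ → 0 where the survivor pool is nearly empty); at
  λ ≳ 0.01 the two differ by less than 10⁻⁵ absolute.

F1 is not used in the solve; it is reported as a consistency residual
|mut/MUT + mut/MIX − F1|. An EOP correction of F1 (dividing by the
mutant reference EOP 0.18) is available but off by default: the
uncorrected ratio reproduces the published 50% while the corrected value
exceeds the genotype fraction and is flagged inconsistent.

The co-expression titer pair is mapped 4×10⁸ → restrictive,
8×10⁸ → permissive. The measurement object accepts either mapping; this
one is consistent with the separately reported ~8×10⁸ permissive titer
of the co-synthesis and yields F1 = 50%.

Published metric values are arithmetic on the *rounded* class table
(pure 6% + 6%, opposing 0.03% + 0.03% → asymmetry ×200, pure fraction
12%). The unrounded titer arithmetic gives 167 and 11.1% with the same
qualitative conclusion; both routes are asserted in the tests, and the
acceptance script reports the rounded-fraction route (199.0) to match
the published statement of the quantity.

Noisy measurements can push a derived MIX fraction slightly negative at
high λ. `solve_gp_table` rejects a negative derived fraction only beyond
three propagated sds; within noise the value is kept (and flagged in the
table metadata) so that averaging replicate estimates stays unbiased.

## Experiment simulator

`simulate_experiment` draws a multinomial population over the exact joint
(genotype, display class, meets-hypothesis) probabilities, applies the
ReLPS challenge as a binomial thinning (display meeting the hypothesis
survives with probability 0 under the stringent overnight condition;
wild-type display survives with probability 0.1, matching the observed
ten-fold titer drop of a pure wild-type control), resets progeny display
to genotype on amplification with a configurable gain (any gain ≫ 1
leaves F3 invariant, which a test verifies rather than assumes), and
reads every titer through a simulated spot assay — three replicate
ten-fold dilution series with Poisson counts, as titers are typically
derived in practice. Restrictive-host plating efficiency defaults to 1.0
rather than the mutant reference EOP of 0.18, mirroring the fact that
the published 50% is the uncorrected co-expression ratio; it is
configurable on `InfectivityMatrix`. Defaults: N = 10⁷ particles,
stock 8×10⁸ PFU/mL, amplified stock 6×10¹⁰ PFU/mL.

Occasionally a simulated dilution series lands no count inside the open
(1, 20) window (the counts straddle it); the simulator then re-spots
with fresh randomness, as an experimentalist would re-titer an
uncountable plate, bounded at ten attempts.

What the simulator does *not* emulate: burst-size stochasticity,
pipetting error (an optional lognormal factor was considered and
omitted — the published replicates are consistent with counting noise),
plate-to-plate efficiency variation, and any mechanistic TXTL kinetics.
Parameter-recovery results (mean λ̂ within 10% of truth at
λ ∈ {0.05, 0.12, 0.5, 0.9} over 200 replicate experiments; ≥ 90%
coverage of ±2 sd intervals) therefore demonstrate estimator
correctness under Poisson counting noise, not robustness to systematic
assay error. A small (~3–6%) upward bias in λ̂ at high λ comes from the
counting-window truncation and ratio nonlinearity of the titer readout
and sits well inside the quoted uncertainties. The F3 readout at small λ
is dominated by the shot noise of the handful of opposing-class
survivors entering amplification, which the titer-propagated sd cannot
see; its absolute effect on λ̂ is < 10⁻⁴.

## Mutation spectra

Reads are position-anchored; mapping is out of scope (real data should
be pre-aligned, e.g. with BWA-MEM at base quality ≥ 30 — recorded as a
documented upstream filter, not implemented here). Frequencies are naive
per-read mismatch counts over depth; the per-fragment mean equals the
sum of per-position frequencies identically on full-length reads.
Positional uniformity is a chi-square over 20 near-equal bins with
expected counts proportional to bin width, refused below the standard
5-per-bin floor. Coordinates are 0-based half-open internally; the
printed display index 1..516 is internal + 1, the first codon encodes
residue 382, and the fragment maps to gene positions [1146, 1662).

The library generator plants Poisson(mean) substitution counts at
uniform distinct positions with the alternative base uniform over the
three non-reference bases (the error-prone kit's true bias is not
published; a user 4×4 bias matrix is accepted). Library means 1 / 2.5 /
5 per fragment correspond to the low/medium/high mutagenesis settings;
2×10⁵ reads per fragment pool matches the sequencing depth used for the
published spectra. The amplicon fixture is a synthetic stand-in: random
stop-free codons with landmark residues fixed (S541, G480, A500, N501,
G521, D540) so substitution-calling tests have planted truth; it is not
the real tail-fiber sequence.

## Fragment design and assembly simulation

Printed junction coordinates are treated as midpoints; natural overlaps
extend ±overlap/2 per side so adjacent fragments share exactly the
declared overlap (50 bp default). Orthogonal mode cuts exactly at
breakpoints and appends the junction's 20-bp tag to both mating ends;
the tag is therefore part of the expected assembled product (the
orthogonal tag set is user-supplied). The 12 kbp fragment ceiling is
enforced; `max_len` auto-splits evenly. Primer annealing regions are the
3' 20–30 nt chosen by the Wallace rule 2(A+T) + 4(G+C) ≥ 60 °C;
nearest-neighbor thermodynamics are out of scope.

Chew-back is deterministic: each 3' end is resected by a fixed length
(recommended overlap + 10), exposing 5' overhangs; ends join when the
exposed single strands are exact reverse complements over ≥ 15 bases.
Matching is orientation-aware and order-invariant; products follow
maximal unambiguous chains and the assembly is complete only when one
chain uses every fragment. A single supplied fragment is trivially
complete. Junction crosstalk is scored as the longest exact
complementary substring between non-partner ends (flag threshold 10;
random 20-mers stay ≤ 9). Limitations: linear topology only (no
circular-product search, so plasmid-style two-fragment circles are not
detected), no partial-homology thermodynamics, no stochastic resection
length (a fixed length is a faithful summary of the brief-digestion
protocol, which reports none).

## Problem sizes in the test suite

Distributional checks use 10⁶-particle populations, 200-seed recovery
ensembles at N = 10⁷ via the exact-probability multinomial path,
mutation libraries of 2×10⁴–2×10⁵ fragments, and 100 randomized 5–40 kbp
design round trips; these sizes give comfortable statistical resolution
for every asserted tolerance while keeping the default suite fast.
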