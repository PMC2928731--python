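# Methods

`haploscope` analyses small viral amplicon surveys of the kind produced
by Sanger-sequencing a single PCR fragment from many infected host
lines: a few dozen aligned haplotypes of ~500 bp, some samples carrying
two haplotypes at once, and missing bases concentrated at low-quality
read ends. This note records the models, the numerical choices, and
what the bundled simulator does and does not emulate.

## Substitution model

The likelihood engine implements the general time-reversible (GTR)
family with optional gamma-distributed among-site rate variation (+Γ)
and a proportion of invariant sites (+I). The generator is
Q_ij = s_ij π_j (i ≠ j), with six exchangeabilities s (AC, AG, AT, CG,
CT, GT; GT fixed to 1 when fitted), stationary frequencies π, and the
standard normalisation −Σ_i π_i Q_ii = 1, so branch lengths are expected
substitutions per variable site. JC and HKY are the obvious
restrictions (equal everything; one transition/transversion ratio κ).
Frequencies are set to their empirical (+1 pseudocount) values for
HKY/GTR and counted among the free parameters (JC 0, HKY 4, GTR 8; +Γ
and +I add one each), mirroring common model-selection practice.

Transition probabilities P(t) = exp(Qt) come from the eigendecomposition
of the π-symmetrised generator D^{1/2} Q D^{-1/2} (D = diag π), which is
real-symmetric for any reversible model, hence numerically stable;
rows are renormalised after clipping rounding negatives.

### Discrete gamma

+Γ uses K equal-probability categories (default K = 8), each carrying
the conditional mean of the mean-one Gamma(α, 1/α) within its quantile
bin. The bin means have the closed form
K·[P(α+1, α·b_{k+1}) − P(α+1, α·b_k)] in terms of the regularised lower
incomplete gamma P and the quantile boundaries b_k, so no quadrature is
needed; a unit test cross-checks them against adaptive numerical
integration. Above α = 10⁵ the discretisation is numerically a point
mass and the rates are set to exactly 1; this makes the +Γ family
contain its rate-homogeneous limit exactly, which matters for
likelihood-ratio tests (below). At α ≈ 0.1 the profile is sharply
L-shaped: with K = 8 the lowest category is below 10⁻³ and the highest
above 4, i.e. most sites effectively frozen and a few hypermutable.

### Likelihood and missing data

Site likelihoods are computed by Felsenstein pruning over compressed
site patterns, vectorised across patterns and rate categories. `N` and
`-` contribute a partial likelihood of 1 for all four states. Under +I
a column counts as possibly invariant for state s iff every non-missing
base equals s; the site likelihood is
p_inv·L_inv + (1 − p_inv)·(1/K)Σ_k L(r_k). No log-scaling of partials
is applied: at the tree sizes this package targets (tens of taxa,
branch lengths well under 10) double precision has orders of magnitude
of headroom; very large trees would need rescaling and are out of
scope. The value is invariant to root placement, leaf order, and
degree-2 node insertion (tested to 1e-8).

### Optimisation

Parameters are fitted by deterministic coordinate ascent: a sweep of
bounded Brent line searches over every branch length (1e-9 to 10), then
ln α, then p_inv, then the exchangeabilities, repeated until the
log-likelihood gains less than 1e-4 (at most 20 rounds). Branch sweeps
use an inside/outside factorisation of the likelihood (the standard
"down" and "up" partials) so each branch evaluation costs one edge, not
one tree. A fit can be warm-started from a nested model's result; the
added parameters then start at values that reproduce the nested fit
exactly (α at its degenerate range, p_inv = 0), which guarantees the
richer model never scores below the nested one — the property the LRT
contract needs. Line searches never move to a worse point than their
starting value, so the ascent is monotone.

## Tree search

A Jukes–Cantor distance matrix (d = −¾ ln(1 − 4p/3), pairwise deletion
of ambiguous sites; p ≥ 0.75 flagged as saturated and capped at 5
substitutions/site) seeds a neighbor-joining tree with deterministic
tie-breaking (lexicographically smallest cluster-label pair) and
negative branch lengths clamped to zero. NNI hill-climbing then scans
internal edges in a fixed order, evaluates both rearrangements per edge
with a shortened re-optimisation (4 coordinate rounds, warm-started),
accepts the first improvement above 1e-4 log-units, restarts the scan,
and finishes with a full re-optimisation. On 6-taxon simulations with
internal branches ≥ 0.1 and 2000 sites the generating topology is
recovered in ≥ 9/10 seeds.

Model choice is by AIC (2k − 2lnL, k counting model parameters plus
branch lengths) over {JC, HKY, GTR} × {plain, +I, +Γ, +Γ+I} on the
fixed NJ topology — a deliberately reduced nested family rather than an
88-model scan; it suffices to distinguish rate-heterogeneous from
homogeneous data, which is the scientific question here.

### Likelihood ratio test

For nested fits the statistic 2ΔlnL is referred to χ²(df) with df the
difference in free-parameter counts, e.g. df = 1 for adding +Γ, with
critical value χ²_{0.001,1} = 10.83 at the 0.1% level. Because the
null (no rate variation) sits on the boundary of the +Γ parameter
space, the χ²(1) reference is conservative; the package reproduces this
standard procedure deliberately, and the simulation suite confirms the
empirical type-I error at the 5% level stays below nominal (0 of 200
homogeneous replicates reject).

## Phasing doubly-infected samples

A sample carrying two haplotypes at unequal abundance shows two
overlapping peaks at every differing site, with heights proportional to
abundance on both strands. The caller declares a site heterozygous iff
on *both* strands the second-highest intensity is at least
`minor_ratio_min` (default 0.25) of the highest and the two top bases
agree between strands; a third peak clearing the threshold on both
strands means more than two haplotypes and raises an unphaseable error
rather than guessing. Phasing assigns the strand-averaged taller base
of every heterozygous site to the high-abundance haplotype and the
shorter to the low-abundance one; all other positions take the
strand-summed consensus.

Two numerical consequences are worth stating. First, a mixture at
ratio r has minor/major height (1−r)/r, so with the default threshold
only r ≤ 1/1.25 = 0.8 is callable at all, and noise-robust *exact*
recovery needs a few standard deviations of margin — comfortably true
at (r = 0.6, σ = 0.05) and (r = 0.7, σ = 0.02), which is the regime the
recovery tests exercise at 100% over 100 replicates. Second, strand
disagreement about which peak is taller is only treated as a phasing
conflict when it is decisive (the disagreeing strand's reversal exceeds
1.5-fold); smaller flips are ordinary peak-height noise and are
resolved by the strand average.

QC keeps a sequence iff its fraction of Ns is strictly below the
threshold (default 18%): a 500 bp record with 90 Ns is rejected, one
with 89 passes.

## Per-site evolution and rates

Minimum mutational steps per site are computed by Fitch parsimony with
bitmask state sets (`N`/`-` = full set), folding multifurcations
pairwise, which preserves the score of the underlying unrooted binary
topology; the implementation matches exhaustive enumeration over all
internal labelings on every random ≤ 6-leaf instance tested. A
variable site is flagged as amino-acid-changing if substituting any
observed base pair into the column-consensus codon changes the residue
(standard code, via Biopython); flagged sites needing ≥ 2 steps are
recurrent replacements. The reading frame defaults to 0 relative to
the analysis window and is configurable, since a trimmed amplicon's
codon offset is a property of the data, not the method.

Synonymous/non-synonymous classification of a pairwise difference
substitutes each variant into the shared codon context; codons with two
or more internal differences or with ambiguous context are reported as
ambiguous, never silently assigned. The mutation-rate upper bound is
the deliberately simple estimator s_syn / (L · T) — variable synonymous
sites per site-year against a reference isolate of known age; with
L = 500 and T = 11 years, s_syn of 3 and 10 bound the rate at 5.5×10⁻⁴
to 1.8×10⁻³. Distinct haplotypes are counted by exact identity
(default) or by missing-tolerant single linkage, which can chain groups
through heavily masked records — both counts are reported. Host/origin
clustering on the genealogy is tested by permuting leaf labels against
the Fitch step count of the label character (one-offset p-value, so
p ≥ 1/(n_perm+1) and the test is valid by construction).

## Recombination: PHI

For every pair of parsimony-informative sites within `window` (default
100) alignment positions, the refined incompatibility score is the
cyclomatic number (edges − vertices + components) of the partition
intersection graph built from observed joint states — exactly the extra
mutational steps both sites need on one tree, and the four-gamete test
in the binary case (property-tested against that oracle). Φ is the
mean score over in-window pairs; the null permutes the order of the
informative columns, destroying spatial signal while preserving the
columns, with p = (1 + #{Φ_perm ≤ Φ_obs})/(n_perm + 1). Sequences
ambiguous at either site of a pair are excluded pairwise. Fewer than
two informative sites, or no in-window pair, yields an explicit
"untestable" flag rather than a p-value. Calibration: ≤ 5% rejection
on clonal simulations; ≥ 8/10 detection of a half-and-half mosaic of
two discordant 20-taxon genealogies.

## The simulator, and what passing tests mean

The generator emulates the survey's statistical structure: random
coalescent-style joining topologies with i.i.d. exponential branch
lengths (default mean 0.02 substitutions/site — shallow, lab-epidemic
scale divergence); sequences evolved under GTR+Γ+I with default
α = 0.101, p_inv = 0.3, K = 8, mildly skewed frequencies
(0.30/0.20/0.22/0.28) and transition-biased exchangeabilities (AG = CT
= 4); ~500 bp records; two-haplotype mixtures at default abundance
0.7:0.3 with truncated-Gaussian channel noise (σ = 0.02) on both
strands independently; and Ns injected as runs at the fragment ends
(default 10% of sites). Sites draw their gamma category by index with
probability 1/K, matching the discrete approximation used in
inference, so parameter-recovery tests are internally consistent.

It does **not** emulate: indels (the analysed window is treated as
gap-free), dye- or context-specific chromatogram artifacts, base-caller
quality scores, PCR/RT errors, codon-structured selection, or more than
two haplotypes per sample. Passing tests therefore demonstrate
correctness of the algorithms and their calibration under the stated
generative model — not robustness to every artifact of real Sanger
traces.

## Problem sizes and determinism

Simulation-based checks use sizes chosen to make Monte-Carlo
conclusions stable while keeping the whole suite fast: 200 replicates
for type-I error rates, 10 seeds for power/recovery claims, 5000 sites
for shape-parameter recovery, ≤ 6 taxa wherever an exhaustive oracle
must enumerate internal states. All randomness flows from explicit
integer seeds (NumPy `default_rng`); the pipeline derives per-stage
seeds from the master seed by hashing, records them in the report's
provenance, and produces byte-identical reports for identical
config + seed.

## Known limitations

- α and p_inv are jointly weakly identifiable on short alignments; the
  pipeline reports both but only α is validated by recovery tests.
- No partial-likelihood rescaling: very large trees would underflow.
- Missing-tolerant haplotype grouping uses single linkage and can merge
  chains; the strict count is the headline number.
- The NNI search is a local hill-climber from an NJ start; it is not
  guaranteed to find the global ML topology on hard instances.
- The χ²(1) reference for boundary LRTs is conservative by design.
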