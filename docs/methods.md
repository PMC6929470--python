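# Methods

`omegak` tests orthologous protein-coding gene groups (orthogroups) for
shifts in selective regime on designated foreground lineages of a
species tree: relaxed selection (selective constraint weakened),
intensified selection (constraint strengthened), and episodic
diversifying selection (a fraction of sites with dN/dS > 1 on a
foreground branch).  This note records the models, their assumptions,
the numerical machinery, and the design choices made where more than
one reasonable construction exists.

## Codon substitution model

The engine is the MG94×HKY codon model over the 61 sense codons of the
standard genetic code.  The instantaneous rate of the single-nucleotide
change i→j is

    q_ij = κ^[transition] · ω^[nonsynonymous] · π_j

with κ the transition/transversion ratio, ω = dN/dS, and π_j the
equilibrium frequency of the *target codon* (the Goldman–Yang frequency
treatment inside MG94's single-step structure; F3x4 positional products
estimated from the alignment with one pseudocount per cell, F1x4
selectable).  Multi-nucleotide changes have rate zero.  The chain is
time-reversible by construction, so the likelihood does not depend on
root placement.

Site-to-site variation in selective pressure is a three-bin ω mixture
(ω₁ ≤ ω₂ ≤ 1 ≤ ω₃ with free proportions).  Branches are partitioned
into *reference* and *test* (foreground) sets; on test branches every
bin's ω is raised to the selection-intensity exponent k ∈ [0, 50]:
k = 1 leaves the process unchanged, k < 1 pulls all ω towards 1
(relaxation), k > 1 pushes them away (intensification).

All bins share one normalisation: rates are divided by the expected
substitution rate of the *reference* mixture, so branch lengths are
expected substitutions per codon site under the reference process, and
k changes the relative rate of test branches exactly as the model
intends.

## Likelihood

Felsenstein pruning over pattern-compressed sites, one pass per ω bin,
combined on the log scale with the bin proportions.  Gaps and IUPAC
ambiguity codes are missing data: a leaf's partial vector is the
indicator of compatible sense codons (all ones for a gap).  Numerics:

- transition matrices come from the symmetrised eigendecomposition of
  Q (D^{1/2} Q D^{-1/2} with D = diag π); eigenvalues are clamped at 0
  because a rate matrix has none positive and ω₃^k can reach 50^50,
  where roundoff would otherwise produce overflowing exponentials;
- an LRU cache stores unnormalised spectra keyed by (κ, ω, π) — the
  mixture normalisation only rescales eigenvalues, so the cache is hit
  heavily by finite-difference gradients;
- partials are rescaled per pattern only every few internal nodes
  (floor 1e-260); study-sized trees stay far from underflow;
- the pruning pass was verified against explicit summation over all
  ancestral codon-state combinations (relative error < 1e-12 on
  3–4-taxon instances).

## The selection-intensity (relax) test

Null: shared κ, a global branch-length scaler, the three-bin mixture,
k = 1.  Alternative: k free in [0, 50].  The test statistic
2(lnL_alt − lnL_null), reported as max(0, ·), is referred to χ²(2):
one degree of freedom for k plus one conservative allowance for the
corner families described below, whose extra effective freedom makes
the naive χ²(1) reference measurably liberal at study-sized alignments
(measured null rejection 0.083 at α = 0.05 over 350 neutral replicates
under χ²(1), binomial p ≈ 0.003 against the nominal 0.05; ≈ 0.05 under
χ²(2)).  Orthogroup families are corrected by Benjamini–Hochberg
(Bonferroni reported alongside).

Fitting is staged for desk-scale runtime: a single-ω fit estimates κ
and the scaler (κ is then held; its MLE is insensitive to the mixture
refinement), then bounded L-BFGS-B optimises the mixture (and k) on a
transformed parameter vector (log scaler, ω₂ ∈ (0,1], ω₁/ω₂ ∈ (0,1],
log ω₃ ∈ [0, log 50], stick-breaking proportions, log(k + 0.01)).
Convergence tolerance is ~1e-6 lnL; iteration/line-search budgets are
capped because the k–ω surface contains slow ridges (below).  A profile
scan of k at the null solution seeds up to three starts (the fixed-seed
multi-start), keeping only basins within 3 lnL of the best.

**Identifiability of k.**  The exponent enters only through k·ln ω, so
the parameterisation degenerates along two corner families: ω→0 with
k→0 (reference-invariant, test-anything), and ω→1 with k→50.  These
corners can genuinely carry the maximum likelihood — the same behaviour
real selection-intensity screens show as mass at k ≈ 0 and at the k
cap — and they add effective degrees of freedom that a χ²(1) reference
does not know about.  Three measures keep the test honest and the
estimator usable: (i) both hypotheses receive the same optimisation
effort (the null is re-polished from the winning alternative's mixture,
and both get a retry from a canonical interior mixture when they land
on a degenerate boundary) and the LRT reference carries the extra
conservative degree of freedom noted above; (ii) the simulator's
default conserved bin
sits at ω₁ = 0.15 rather than near 0, because a recovery benchmark on
an unidentifiable corner of the parameter space tests nothing; (iii)
the default study tree carries enough reference-branch length (total
~1.4 expected substitutions/site, single branches capped at 0.2) to
anchor ω₁ away from 0.  Under these conditions the measured null
rejection rate at α = 0.05 is ≈ 0.02–0.09 across replicate blocks, and
median k recovery at true k ∈ {0.2, 1, 5} falls in the documented
acceptance bands.

## The branch-site (diversifying selection) test

A deliberately simplified adaptive branch-site random-effects scheme:
the whole tree evolves under a single background ω (from the staged
fit), and each test branch in turn receives its own ω mixture with
1–3 bins.  The bin count is chosen by AICc, increasing the count only
while AICc improves ("adaptive").  The chosen model is tested against
the same model with all of that branch's ω capped at 1; the LRT is
referred to χ² with df = the branch's bin count (conservative: the true
null for bound constraints is a χ² mixture with point mass at 0, so
tail probabilities are overstated).  When the unconstrained fit already
satisfies max ω ≤ 1 the LRT is 0 and p = 1 without a second fit.
Branch p-values are Holm-corrected within the orthogroup; the
orthogroup-level p is the smallest corrected branch p; q-values are BH
across orthogroups.

Because only the focal branch's transition matrix varies, each branch
fit evaluates the likelihood as a bilinear form between cached inside
(post-order) and outside (pre-order) partials — roughly 5× cheaper than
a full pruning pass per evaluation.

## Synthetic data

The simulator emulates the comparative design the package targets: ten
taxa shaped like a salmonid phylogeny with a pike-like outgroup, two
two-taxon foreground clades (whitefish- and charr-like genus pairs)
labelled in "clade" mode (terminals plus stem).  Branch lengths are
synthetic (0.005–0.2 per branch, 1.42 total) and configurable.  Default
mixture: ω = (0.15, 0.8, 2.0) with proportions (0.45, 0.45, 0.10),
κ = 2.5, F3x4 frequencies from plausible coding-sequence positional
nucleotide frequencies.  Orthogroup classes plant the truth the
pipeline must recover: relaxed (k = 0.2), neutral (k = 1), intensified
(k = 5), and episodic (k = 1 plus one test branch with ω = 5 at 20% of
sites).  GO annotations attach a planted term to one class at odds
ratio 10 over a baseline attachment probability of 0.12, plus Poisson
background terms.  One RNG stream per orthogroup derives from (master
seed, orthogroup index), so any subset reproduces byte-identically.

Mock transcripts for the filtering stage embed coding sequences between
ORF-free UTR flanks (no ATG on either strand, junctions re-drawn until
the planted CDS is the longest ORF), optionally reverse-complemented,
and plant one group per violation class: unmapped members, collapsed
orthologues (fewer focal copies than the reference genome predicts),
copy excess (> 4), too small (< 7 sequences), too large (> 80), too few
taxa (< 7), byte-identical duplicates, and ORFs below 200 nt.

What the simulator does **not** emulate — and hence what passing tests
do not establish about real data: indel evolution and alignment error
(alignments are simulated gapless; gaps only enter through the trimming
fixtures), assembly artefacts beyond the planted violation classes,
synonymous rate variation, non-equilibrium base composition, gene-tree/
species-tree discordance, and the semantic structure of real GO
annotation (terms are exchangeable labels).

## Orthogroup filtering

Stages, in order: longest-ORF extraction (≥ 200 nt, both strands,
lowest-start/forward-strand tie-break; mitochondrial-style gene ids
excluded); retention of members mapping to reference protein-coding
genes; the collapsed-orthologue rule (every focal species needs at
least as many copies as the reference gene set predicts, and at most
4 — evaluated per species); merging of groups with identical reference
gene-set signatures and removal of exact duplicate orthologue sets
(deterministic signature order); size/taxon bounds (7–80 sequences,
≥ 7 taxa); and overlap-based trimming.  Every decision lands in an
audit table (group, stage, kept/dropped, reason).

Trimming semantics (resoverlap/seqoverlap): a position of sequence s is
good iff the fraction of other sequences matching s's gap/non-gap state
at that column reaches `resoverlap`; s is kept iff its good fraction
reaches `seqoverlap`; all-gap columns are then removed.  Note that at
resoverlap = 1.0 a column is good only when *unanimous*, which makes
the good set identical for every sequence — the step then acts as an
alignment-level quality filter (an alignment is kept or emptied as a
whole), which matches its published use for "optimising the number of
retained alignments".  A residue-presence variant is available via
`mode="residue_presence"`.

Trees come from neighbour joining on codon-level p-distances with
pairwise deletion (a closed form for 3 taxa; negative branch lengths
clamped to 0).  Balanced minimum evolution was deliberately replaced by
NJ: on clean simulated data the topologies agree, and NJ needs no
external binary.

## Downstream statistics

- **k distribution vs neutrality**: two-sided one-sample Wilcoxon
  signed-rank test against 1 (zero differences dropped, tied ranks
  averaged; exact 2^n null for n ≤ 25 without ties, else normal
  approximation with continuity and tie correction).  The V statistic
  reported is the positive-rank sum.
- **Relaxed vs intensified counts**: exact binomial sign test of the
  k < 1 count against 0.5 (k = 1 dropped); a Fisher variant on the two
  count vectors is selectable.  The published comparison never states
  its 2×2 construction, so the sign test is the default.
- **Per-GO k tests**: each term with ≥ 5 annotated orthogroups gets a
  two-sided Wilcoxon test of its members' k values against 1
  (member-level testing; the per-term mean and median are reported
  alongside for display).
- **Enrichment**: one-tailed hypergeometric (Fisher) tests per term,
  BH-FDR at 0.10, with uncorrected p < 0.05 reported as "trends".  The
  universe is every orthogroup with at least one GO annotation.
- **Overlaps**: expected overlap |A||B|/N plus a one-tailed Fisher p.
- **GSEA**: k is mapped to (k−1)/(k+1) ∈ [−1, 1] (bounded, strictly
  increasing, sign = sign(k−1); a rank-based variant is provided), and
  a weighted Kolmogorov–Smirnov running sum (weight 1) is computed over
  the descending score ranking.  The null permutes gene labels
  (single-score-per-gene designs cannot permute samples).  NES = ES
  divided by the mean |null ES| of matching sign; the permutation p is
  sign-conditional — exceedances among matching-sign nulls over the
  matching-sign count — which keeps null p-values uniform; q is BH
  across sets; the top 10 positive and negative sets are the headline
  output.

## Calibration sizes

The test suite's Monte-Carlo checks use these problem sizes, chosen as
the smallest that keep the binomial noise of each band acceptable:
likelihood oracle on 3–4 taxa × ≤ 10 codons; k recovery with 16
replicates per non-neutral true k ∈ {0.2, 5} at 500 codons; null
calibration at 500 codons with 80 replicates for the relax test
(two-sided band) and the first 50 of them for the branch-site test (a
one-sided bound), the first 20 doubling as the k = 1 recovery arm; the
end-to-end study with 45 orthogroups (15/15/15) at 300 codons; 20
annotation replicates
for planted-GO recovery around the fitted study; 100 random inputs for
the Wilcoxon enumeration; 1000 permutations for the planted-GSEA check.
`scripts/acceptance.py` runs a 55-orthogroup study (15/15/15 relaxed/
neutral/intensified + 10 episodic) at 400 codons with both tests —
class sizes large enough that the enrichment and GSEA demonstrations
are adequately powered.

## Known limitations

- The χ²(2) reference for the relax LRT is a pragmatic finite-sample
  correction, not an exact null: it over-corrects on well-behaved
  replicate blocks (rates towards 0.02) and barely corrects the worst
  blocks.  A parametric bootstrap would calibrate it exactly at ~100×
  the cost.
- k̂ retains an atom near 0 for strongly relaxed genes (the ω→0 corner
  family); directional conclusions (k̂ < 1 vs > 1) are robust, point
  values of very small k̂ are not.
- The branch-site test fixes the background at one ω; full per-branch
  random effects would be more powerful but are an order of magnitude
  slower.
- Branch lengths are rescaled by a single global factor per fit rather
  than re-optimised per branch (full re-optimisation was judged not
  worth the runtime at these data sizes).
- The wider ω-category count and frequency model match common defaults
  of comparable tools, not a fit to any particular empirical dataset.
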