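# Methods

This note documents the models, algorithms, parameter choices, and known
limitations of `bitterevo`.

## Substitution models and likelihood

All likelihood machinery is generic over the state alphabet (20 amino acids
or the 61 sense codons of the standard genetic code).  A model is a
symmetric exchangeability matrix `S` and equilibrium frequencies `π`; the
generator is `Q = S diag(π)` with the diagonal set so rows sum to zero,
rescaled so `-Σ π_i Q_ii = 1` (one expected substitution per site per unit
branch length).  Transition matrices `P(t) = exp(Qt)` come from the
eigendecomposition of the symmetrized generator
`diag(√π) Q diag(1/√π)`; tiny negative entries from floating-point round-off
are clipped and rows renormalized, keeping row sums at 1 to ~1e-15.

Bundled models: the Poisson model (equal rates/frequencies; its closed forms
anchor several tests, e.g. `P_same(t) = 1/20 + (19/20)e^{-(20/19)t}`) and
the JTT empirical matrix in PAML `.dat` format, the default for protein
analyses because it is the standard general-purpose matrix for globular and
membrane proteins of this size.  Among-site rate variation uses the
equal-probability discrete gamma approximation with category means computed
from the regularized incomplete gamma function; one category reduces exactly
to the rate-homogeneous model.

Site likelihoods use Felsenstein pruning over pattern-compressed columns
with per-node partial-vector rescaling and log accumulators, so 100-taxon,
300-residue alignments are safe from underflow.  Gaps and unrecognized
symbols are missing data (partial vector of ones); likelihood is invariant
to root placement for these reversible models (tested).

Codon models are Muse–Gaut (MG94): single-nucleotide codon exchanges at a
κ-adjusted (transition/transversion, default κ=2) nucleotide rate, times ω
for nonsynonymous changes, with F1x4 codon frequencies.  The process is
reversible with respect to those frequencies, so the same pruning/ASR code
applies.

## Trees

Newick I/O (dendropy-backed parsing) preserves leaf names, internal labels,
and branch lengths to 12 significant digits.  Topology inference is
deliberately minimal — neighbor joining (scikit-bio) on model-corrected
pairwise distances, negative branch estimates clamped to zero — because the
pipeline's contribution is downstream of topology; users with a better tree
supply it as Newick.  Distances use the Poisson closed form
`d = -(19/20) ln(1 - (20/19) p̂)` or, for empirical models, bounded 1-D ML;
saturated pairs (p̂ ≥ 19/20) return a configurable `d_max` (default 10).
Branch lengths are then fitted by coordinate ascent (bounded Brent per
branch) until a full sweep improves the log-likelihood by less than `tol`
(default 1e-4); the log-likelihood is non-decreasing across sweeps.  The
two branches meeting at the root are identifiable only through their sum,
which the tests respect.

Rooting is by user-designated outgroup: the root is placed at the midpoint
of the branch separating the outgroup from the ingroup.  Internal nodes are
labeled `N#` by deterministic postorder numbering; labels from any external
tool run will differ, so comparisons to published node names should match
clades by leaf content.

## Ancestral reconstruction

Marginal reconstruction computes, per internal node and column, the
posterior over states by up/down message passing: `posterior ∝ π ⊙ U_v ⊙
D_v` with `U_v` the upward partials and `D_v` the downward message seeded
with `π` at the root.  Under discrete-gamma rates, per-category posteriors
are mixed with each category's per-site responsibility.  Joint
reconstruction is max-product dynamic programming with backtracking; with
gamma rates it maximizes over (assignment, category) pairs per site.  Both
are verified exactly against exhaustive enumeration on 4-taxon trees.

Indels are not modeled in the likelihood.  Instead an internal node-site is
flagged as a gap when more than half of its descendant leaves are gapped
there (a simple, testable majority rule standing in for full
maximum-likelihood indel reconstruction, which is out of scope); flagged
sites are excluded from residue calls.

Tied predictions: when the top two posterior residues at a node-site differ
by less than `tie_delta` (default 0.05, chosen to mirror the reporting of
dual ancestral predictions of "similar confidence" in the source residue
matrix), both are reported as `X/Y`, primary first.

Calibration on data simulated under the same (JTT) model: MAP calls with
posterior > 0.99 are ≥ 99% correct, and mean posterior tracks empirical
accuracy within ±0.05 per posterior decile (≥ 5000 node-site pairs).  This
shows the posterior is a trustworthy confidence measure *when the model is
right*; real receptor alignments involve alignment error, indels, and
model misspecification that these simulations do not emulate.

## Relative divergence times

The dating scheme is a tip-averaged, geometric-mean-free variant of the
RelTime family, keeping that family's defining constraint — the two
lineages descending from a node span equal elapsed time — while remaining
small enough to verify by hand.  With `L(v)` the tip-count-weighted mean
path length from `v` to its descendant tips, lineage rates propagate from
the ingroup root (`r = 1`) as `r(c) = r(v)·(b_c + L(c))/L(v)`, and node
times telescope exactly to `T(v) = L(v)/r(v)`, normalized so the ingroup
root is 1 and tips are 0.  Consequences (all tested): ultrametric ingroups
give all rates 1 and times proportional to height; rates and times are
invariant to global branch-length scaling; elapsed times along any
root-to-tip path sum to 1.  Zero-length terminal branches take rate 1 by
convention (the ratio is 0/0); internal zero-length branches (resolved
polytomies) inherit the parent's rate.  Rates are reported mean-normalized
across ingroup branches.  The outgroup locates the root and is excluded
from estimation; a non-monophyletic outgroup triggers a warning with the
root placed on the outgroup MRCA edge.

Because lineage rates are tip-averaged, the one branch directly above a
split between a fast and a slow clade carries a mixture rate; on two-class
simulations all pure-class branches separate completely (the 3× class is
recovered at ~3× the rate of the 1× class) and the class-recovery rank
correlation is ~1.0.  Note that the rank correlation of a *binary* truth
against any continuous estimate is mathematically capped at √3/2 ≈ 0.866,
which is why recovery is scored on the binarized (midpoint-thresholded)
rates.

The two quantities printed on published trees of this kind — "relative
time elapsed" per branch and "relative divergence rate" — are both emitted
(`elapsed` and `relative_rate` columns) since usage in the literature is
ambiguous between them.

## Site-specific selection

A counting (SLAC-style) estimator stands in for server-based Bayesian
site-model fits, because the downstream analysis consumes only the sign of
ω and the positive/purifying site classes, which counting recovers and
which can be validated against simulation; reproducing a specific server's
per-site Bayesian intervals is a non-goal.  Expected synonymous and
nonsynonymous site fractions per codon follow Nei–Gojobori (1986): each of
the nine one-step changes contributes 1/3 site, changes to stop codons
counted on neither side (so `S + N = 3 − stops/3`).  Observed substitutions
are summed over branches between codon states at the branch endpoints;
multi-nucleotide changes are averaged over all minimal stop-free mutational
paths.  Endpoint states come either from the caller (e.g. recorded
simulation truth) or from joint ancestral reconstruction under the neutral
(ω=1) MG94 model — neutral to avoid assuming the quantity being estimated.
Per site, `ω = (Nd/N)/(Sd/S)`; neutrality is tested by a two-sided binomial
test of `round(Nd)` out of `round(Nd+Sd)` against `p = N/(N+S)`, with
positive (ω>1) or purifying (ω<1) calls at α = 0.05 by default.  No
multiple-testing correction is applied by default (per-site reporting, as
in the server-based workflow this replaces); Benjamini–Hochberg is
available as a flag.  Sites with no inferred changes are neutral with
undefined ω; stop-containing alignment codons flag the site undefined.

Calibration (32 taxa, 0.2 substitutions/codon-site branches): under ω=1
the positive call rate stays within the α=0.05 binomial envelope at 500
sites (measured with fully reconstructed ancestors, i.e. the end-to-end
method); for ω ∈ {0.2, 1, 5} the mean ω̂ rank-orders the three regimes and
ω=5 sites are detected with power ≈ 0.65 when the ancestral states are
known.  With re-reconstructed ancestors that power drops to ≈ 0.17, since
neutral joint reconstruction smooths repeated nonsynonymous changes — an
inherent conservatism of counting methods worth remembering when
interpreting per-site positive calls on real data.

## Key-position catalog and binder calls

The catalog (data, not code: `data/key_position_catalog.json`) lists 12
T2R10-mode and 15 T2R46-mode key positions (20 distinct, 7 in both modes),
each with the functional key residue, a criticality tag, and ordered
substitution-effect rules.  Explicit-residue rules encode assay outcomes
(e.g. at 7.39 in the T2R46 mode: D→reduced, Q→reduced, K→abolished);
property-class rules encode the qualitative biochemical statements behind
them (loss of the 7.39 negative charge to a hydrophobic residue abolishes
the salt bridge; no long side chains at 7.42; hydrophobicity at 7.43 is
fundamental).  First matching rule wins; no match means the effect is
unknown.  Criticality: 7.39/7.42/7.43 for the T2R46 mode and 3.37/7.39 for
the T2R10 mode, mirroring which single mutations abolish activation.

Property classes are fixed and documented: charge {D,E | K,R,H | rest};
hydropathy by Kyte–Doolittle with threshold 0 (hydrophobic: A,C,F,I,L,M,V);
side-chain volume small < 120 Å³ ≤ medium ≤ 170 Å³ < large.  "Chemically
similar" (e.g. V/I, M/I, T/S) means same charge class, same hydropathy
class, and volume within one class step — such substitutions have
unpredictable effects and push a verdict toward `uncertain`.

Per mode, the verdict is: any abolished effect, or ≥ 2 non-conservative
changes at critical positions → `non_binder`; otherwise any unknown effect
→ `uncertain`; otherwise any tolerated/reduced mismatch →
`reduced_binder`; all key residues exact → `binder`.  The `uncertain`
trigger applies to unknown effects at *any* key position, not only critical
ones: a substitution with no mutagenesis data at a supporting position
(e.g. K174^5.39 in the T2R10 mode) genuinely leaves the verdict open, and
this is how the published per-ancestor calls behave.  The overall verdict
is the better of the two mode verdicts, so a sequence binding through
either mode is called accordingly — which is exactly how convergent
acquisition through two modes is detected.

Tied ancestral predictions are handled conservatively but not punitively:
a tie that *includes* the key residue contributes a `reduced` effect (the
functional residue is plausibly present, full function cannot be asserted),
while a tie without it contributes the worst effect among its
alternatives.  An unambiguous abolishing substitution (e.g. an extant
A268^7.42R) still abolishes.  This distinction matters for deep T2R46-clade
ancestors, where position 7.42 is reconstructed with high sampling
variability; the bundled residue matrix records those entries as ties.

## Synthetic data

The generators define the conditions under which the pipeline's claims are
tested.  Protein evolution samples exact transition-matrix rows along each
branch (optionally scaled by per-branch lineage-rate multipliers); codon
evolution is a Gillespie jump process so true synonymous/nonsynonymous
event counts are recorded per site; binder histories evolve key positions
by a Markov jump process among rule-listed residues, with forced
substitutions available for constructing convergence scenarios.  Defaults
used in tests and acceptance runs: 16 taxa × 1000 sites (balanced
ultrametric tree, 0.06 branches) for reconstruction calibration; 16-taxon
ingroup × 2000 sites with a 3× rate clade for dating; 32 taxa × 500
neutral / 180 mixed-ω sites at 0.2 branches for selection.  These sizes
were chosen as the smallest at which the statistical claims are stable and
each stage's empirical behavior is clearly resolved.  All generators are
byte-deterministic for a fixed integer seed.

What the simulations do *not* emulate: indels and alignment error,
GPCR-specific structural constraints, compositional heterogeneity across
lineages, and recombination.  Passing tests therefore validate the
algorithms under their own model assumptions; they do not certify accuracy
on real receptor data where those assumptions fail to varying degrees.

## Other numerical choices and limitations

- Identity filtering aligns ungapped sequences globally under a fixed
  scheme (BLOSUM62, gap open 10, extend 0.5) with identity = matches /
  aligned columns; the length cutoff is strict (a 265-residue sequence is
  removed at `min_length=265`).  The filter is idempotent and always keeps
  the query; outgroup taxa are exempt (they are present for rooting, not as
  homolog candidates).
- BW annotation positions index the *ungapped* reference (1-based), so the
  mapping is immune to gap-only column edits elsewhere in the MSA; file
  outputs are 1-based, internal column indices 0-based.
- Degenerate inputs: empty FASTA, duplicate ids, negative branch lengths,
  asymmetric distance matrices, stop/ambiguous codons, missing outgroup
  taxa and unresolvable BW labels all raise informative errors naming the
  offender.
- The pipeline aborts on the first failing stage, reporting the stage name
  and renaming completed outputs with a `.partial` suffix; a JSON run log
  records versions, the seed, input hashes, and a configuration hash, and
  fixed (config, seed) pairs give byte-identical tables.
- Bootstrap support, ML topology search, absolute-time calibration,
  confidence intervals on relative times, Bayesian site models, and
  structural docking are out of scope.
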