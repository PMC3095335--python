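# Methods

`seldiv` implements the comparative-evolution toolkit used to dissect how a
duplicated gene family (the motivating case is the NIP III / NIP2 aquaporin
subgroup of plants, split into monocot and dicot clades) diversified in
function: codon-alignment construction, 4DTv paralog dating, distance-based
phylogenetics, codon-model tests of positive selection, Type-I/Type-II
functional-divergence estimation, and specificity-determining-position (SDP)
scanning. This note records the models, the defaults and why they were
chosen, the numerical choices, and what the synthetic data do and do not
establish.

## Codon alignments

Protein alignments are consumed, never computed: each aligned row is
back-translated by threading its CDS through the row, expanding residue gaps
to `---`. Terminal stop codons on CDS inputs are stripped silently (the usual
CDS-dump convention); internal stops or codons that do not translate to the
aligned residue are hard errors. Column filtering applies only a removal
clause: codon columns observed in fewer than `min_present` sequences
(default 3) are dropped, so columns gapped in all but one or two sequences
disappear and every other column survives. Columns of intermediate
gappiness are deliberately kept — the filter's job is to remove
alignment overhangs, not to second-guess the aligner. All reported
coordinates are 0-based codon columns of the filtered alignment; a
`column_map` back to the original columns is attached because residue
numbering against any single reference sequence is ambiguous in a gapped
alignment.

## 4DTv

The 4DTv distance of a codon-aligned pair is the fraction of conserved
fourfold-degenerate sites whose third positions differ by a transversion.
Eligibility is a codon-box property: both codons must lie in one of the eight
fourfold boxes (GCN, CGN, GGN, CTN, CCN, TCN, ACN, GTN) and encode the same
residue, which excludes the twofold members of serine, leucine, and arginine;
gaps or ambiguity codes exclude a site. No multiple-hit correction is
applied: the raw proportion runs from 0 for fresh duplicates to an asymptote
of 0.5 when third positions are fully randomized, which is the scale used to
place paralog pairs against known whole-genome duplications. A pair with no
eligible site returns NaN, never 0.

## Distance trees and clock dating

p-distances support protein, nucleotide, and transversion-only nucleotide
modes with pairwise or complete gap deletion; a pair with no comparable
positions is flagged undefined rather than silently zero. Neighbor joining is
the Saitou–Nei Q-criterion agglomeration, exact on additive matrices;
Q-ties break on the lexicographically smallest active index pair and negative
branch-length estimates are clamped to zero (and logged), mirroring common
tree-software behavior. Bootstrap resamples columns — codon columns for codon
alignments, preserving codon structure — with one RNG stream per seed, and
canonical bipartition bookkeeping makes supports independent of sequence
input order. Divergence dating is a deliberately minimal strict clock: a
single calibration (distance `d_cal` spanning a split of age `t_cal`) fixes
the rate, and any pairwise distance converts linearly to an age. It is a
back-of-envelope dating device, not a relaxed-clock inference.

## Codon substitution models

The substitution process is the Goldman–Yang codon model on the 61 sense
codons: single-nucleotide exchanges at rate `pi_j * kappa^[ts] *
omega^[nonsyn]`, scaled to one expected substitution per codon per unit
branch length. Codon frequencies default to F3x4 (position-specific
nucleotide frequencies, floored at 1e-8 and renormalized); equal frequencies
are available for controlled experiments. Site models:

* **M0** one omega;
* **M3** K discrete classes (default K = 3, configurable — published
  summaries sometimes print fewer classes than were fitted, so K is not
  hard-wired);
* **M7** Beta(p, q) on (0, 1), discretized into 10 equal-probability classes
  at bin medians (inverse CDF at (2k+1)/20) — deterministic quadrature;
* **M8** p0 of M7 plus a free class at omega_s >= 1.

Likelihoods use Felsenstein pruning with per-node rescaling, vectorized over
mixture classes and compressed site patterns; gap and ambiguous codons are
missing data. Trees with a basal bifurcation are analyzed unrooted (the two
root edges are confounded under a reversible stationary process — derooting
removes a spurious degree of freedom that otherwise lets the optimizer park
arbitrary omega on a near-empty root edge).

Optimization is a deterministic warm-start cascade rather than random
multistart: M0 is fitted jointly over branch lengths, kappa, and omega; its
branch lengths seed the richer models, which alternate bounded L-BFGS-B
blocks over (kappa + distribution parameters) and branch lengths until the
round improvement falls below 0.02 log-units; M8 starts from the fitted M7
and additionally keeps the M7 solution mapped to its p0 -> 1 boundary as a
candidate, which structurally guarantees a non-negative M7-vs-M8 LRT
statistic. Staged warm starts proved more reliable and cheaper than random
restarts for these heavily nested models; seeded random restarts remain
available via `FitSettings.n_starts` for unusual data.

LRTs use chi-square with df equal to the parameter-count difference (4 for
M0 vs M3 with K = 3, 2 for M7 vs M8, n_branches − 1 for one-ratio vs
free-ratio). No boundary-mixture correction is applied for M7 vs M8,
matching standard practice; the test is therefore conservative, which the
null-calibration test quantifies. Site identification is naive empirical
Bayes: posterior class memberships from the fitted mixture, with the
posterior mass on omega > 1 classes reported per site; sites at or above
0.95 are starred, sites below the 0.7 reporting floor are suppressed. A full
Bayes-empirical-Bayes integration over parameter uncertainty is out of
scope. Branch models share the machinery with one omega per branch
(free-ratio); branches whose fitted length falls below 1e-5 substitutions
per codon are flagged unidentifiable and excluded from omega > 1 flagging.

## Functional divergence

**Type-I** (rate decoupling between two clusters). Per-site substitution
counts within each cluster subtree come from Fitch parsimony (gaps are
missing data; polytomies use the k-minus-max-agreement step). The counts
feed a two-state mixture: with probability theta_I a site draws independent
Gamma(alpha, alpha) rates in the two clusters, otherwise one shared rate;
gamma-Poisson marginals make the independent term a product of negative
binomials and the shared term a bivariate negative binomial. theta_I, the
shared shape alpha (bounded to [0.05, 100]), and the cluster mean counts D1,
D2 are estimated by ML (theta on a logit scale, boundary hits flagged); the
SE comes from the observed Fisher information in the original
parameterization; the LRT compares against theta_I = 0; Q_k is the posterior
that site k is rate-decoupled, and sites with Q_k above 0.9 (configurable)
are the critical amino acid sites.

**Type-II** (radical property shifts at otherwise conserved sites) is a
closed-form estimator built from cluster-ancestral residues (Fitch root
states; ties broken by cluster consensus, then alphabetically). Applicable
sites are monomorphic within both clusters; among those whose ancestors
differ, pi_R is the fraction whose residues fall in different property
groups (default partition: charge — {K,R,H}, {D,E}, rest; polarity and
hydrophobicity partitions are shipped as alternatives). The background
radical probability p_r0 pools within-cluster substitution events at
non-applicable sites, each event being a cluster-consensus residue versus
one other observed residue — the event enumeration is a design choice, made
because parsimony counts alone do not identify which residue pairs were
exchanged — with a model-free fallback of 0.5 when no events exist. Then
theta_II = (pi_R − p_r0)/(1 − p_r0), which is negative whenever radical
differences are rarer than background, the SE is the binomial delta method
with p_r0 treated as known, and Q_k for radical-difference sites is
theta/(theta + (1 − theta) p_r0). This is an intentionally transparent
reformulation that reports the same quantities (theta_II, SE, Q_k bands) as
the classical software, not a numerical clone of it.

## SDP scan

Each alignment column is scored by the mutual information (bits) between
residue identity and group label, with additive smoothing of the
within-group residue distributions toward the alignment-wide frequencies
(default pseudocount 1.0; 0 gives the plug-in MI, bounded by log2 of the
group count). Columns with more than 10% gaps are not scored. Significance
comes from label permutations: one permutation per replicate applied to all
columns, Z = (MI − shuffle mean)/shuffle sd, with Z = 0 where sd = 0;
shuffles are canonicalized over id-sorted sequences so scores do not depend
on record order. The recognition cutoff ranks columns by Z and, for each
candidate count L, computes B(L) = log10 P(Binomial(N, eps_L) >= L) with
eps_L the standard-normal upper tail at the L-th ranked score (an empirical
pooled-shuffle tail is available); the minimizing L is the cutoff, numerical
ties going to the smallest L. Columns with Z <= 0 are never reported as
SDPs, so an alignment of identical sequences yields an empty set. The
binomial-tail operationalization is this package's own definition of the
published "Bernoulli estimator" idea, whose exact internals are not public.

## Synthetic data

Every estimator ships with the simulator of its own generating model: codon
alignments evolved site-by-site under an omega mixture down a tree (with
optional per-branch omega overrides), gamma-Poisson change counts with a
rate-decoupled fraction, grouped protein alignments with planted SDP columns
(per-group residues with a 5% error rate over an i.i.d. background), and
fourfold-degenerate paralog pairs whose third positions diverge under a
Kimura two-parameter process or are drawn uniformly (saturation). All
simulators are pure functions of (parameters, seed) and emit standard
FASTA/Newick/TSV through the package's own I/O, so tests exercise the public
interfaces end to end.

Problem sizes in the test suite are chosen to make each statistical property
measurable at desk scale: 4-taxon trees for exact likelihood oracles, 6–8
taxa and 150–300 codons for parameter recovery and null calibration (50
replicates for the M7-vs-M8 rejection rate), 16 taxa and 500 codons for
posterior site detection — posterior identification of selected sites needs
deep trees, and shallow ones are reported honestly as powerless — 500 sites
for theta_I recovery, and 16 sequences over 200 columns with 5 planted SDPs
for the scan.

What passing these tests shows: the estimators recover the parameters of
their own generating models, the LRTs are calibrated or conservative under
their nulls, and the boundary identities hold exactly. What they do not
show: robustness to model misspecification in real alignments —
among-site rate autocorrelation, indel placement error, biased codon usage
beyond F3x4, non-stationary composition, or tree-estimation error are all
absent from the simulators, and the simulated sequences have no aquaporin
domain structure (no transmembrane helices or NPA motifs); sequence content
is statistical only.

## Numerical choices and degenerate inputs

Reversible generators are exponentiated via symmetric eigendecomposition
(Pi^1/2-similarity), with tiny negative propagator entries clipped at zero.
Partial likelihoods are rescaled per node; class mixing happens in log space.
Branch lengths are bounded to [1e-7, 25] expected substitutions per codon,
kappa to [0.05, 60], omega to [1e-6, 60], beta shapes to [5e-3, 99].
Identical sequences drive all branch lengths to the lower bound and the
likelihood to the stationary log-probability of the observed codons; such
branches are flagged unidentifiable in branch-model output. A 4DTv pair
without eligible sites, a Type-II analysis without differing applicable
sites, and a p-distance pair without comparable positions all return
explicit undefined markers. Known limitations: free-ratio fits on many taxa
are high-dimensional and slow; NEB posteriors understate uncertainty in the
omega distribution relative to full BEB; Fitch counts underestimate
per-site changes on long branches, biasing D1/D2 (but not their contrast)
downward.
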