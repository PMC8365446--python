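# Methods

`nrdmotif` implements the computational chain from a class II
ribonucleotide reductase (NrdJ) protein sequence to its predicted
substrate phosphate specificity, plus the evolutionary and kinetic
analyses built on that prediction. This note records the models, the
parameters that matter, the numerical choices, and what the synthetic
data do and do not establish.

## The specificity model

RNRs reduce either ribonucleoside diphosphates (NDP) or triphosphates
(NTP). In NrdJ enzymes the discriminating element is the *apical loop*
of the phosphate-binding site: a 4–5-residue motif (P-N-S-P in
diphosphate reducers, P-A-G-R and variants in triphosphate reducers).
The package treats the motif as a sufficient predictor of specificity
and everything downstream — census statistics, tree mapping, genome
co-occurrence — consumes the motif label only. The distal loop of the
binding site is conserved across both specificities; it is carried as
an annotation on the reference and plays no role in classification.

## Loop anchoring and extraction

A query is anchored to an annotated reference by global (Needleman–
Wunsch) alignment under BLOSUM62 with affine gaps, gap open 11 and gap
extend 1 (a gap of length L costs 11 + (L−1)); the ambiguity residue X
scores 0 against everything. These are conventional protein defaults;
nothing in the analysis is sensitive to them at the divergence levels
involved. Alignment is delegated to `Bio.Align.PairwiseAligner`; among
co-optimal tracebacks the engine's first alignment is used, which is
deterministic for fixed inputs.

The motif is read from the **loop window**: every query residue in
alignment columns strictly between the reference residues flanking the
apical span. When the alignment is gapless across the span this is
exactly the span columns. The open-interval definition matters for
length-5 motifs on a length-4 reference span: the affine-gap optimum is
free to place the insertion column at either edge of the span (for
P-Q-G-S-P against P-A-G-R it lands after the final R), and the window
captures the inserted residue regardless of which side the aligner
chose. Insertions beyond the immediately flanking reference residues
are never captured.

Coordinates are 1-based inclusive throughout, matching mutagenesis
numbering (e.g. "G68"). Calls are flagged FULL, PARTIAL (some span
column aligned to a gap) or UNMAPPED. A query is UNMAPPED when its
alignment score falls below 0.25 × the reference self-score; real NrdJ
homologs sit far above this floor and random sequences far below, so
the exact value is uncritical — it exists so that screening mixed
sequence sets has a defined behaviour. Alternatively, motifs can be
read directly from designated columns of an existing multiple sequence
alignment; the column indices are an input, since they depend on the
alignment at hand.

## The motif lexicon

Classification is regex matching against a small, versioned lexicon
shipped as `data/lexicon.yaml` (editable, because motif variants accrue
as more enzymes are characterised):

| pattern | label |
|---|---|
| `[PF]NSP` | NDP |
| `P[ASG]GR` | NTP |
| `PSMR` | NTP |
| `P[QA]GSP` | NTP |

First match wins; the patterns are mutually exclusive anyway (different
lengths and anchors), so order only matters defensively. Matching is
case-insensitive and anchored to the whole motif. Anything else —
including engineered loops such as P-A-G-S that were never observed
active — is UNKNOWN. Census statistics count PARTIAL/UNMAPPED calls as
UNKNOWN because their extraction is not trusted.

## Sequence logos

Observed-frequency logos: per column, residue probabilities over the 20
amino acids (gaps excluded from the denominator, X spread uniformly,
optional uniform pseudocount, default 0), information content
IC = log₂20 − H(p) bits, letter heights hₐ = pₐ · IC · occupancy.
Gaps reduce occupancy rather than acting as a 21st symbol. This is the
classic Shannon construction; no profile-HMM/posterior letter weighting
is applied, so heights for sparse, gappy alignments will differ from
HMM-weighted logo services. A small-sample correction
(19/(2 ln2 · n) bits) is available but off by default, as motif-class
subsets are typically large.

## Parsimony mapping

Specificity states are mapped onto a phylogeny with Fitch small
parsimony. Tips labelled UNKNOWN are missing data, not a third state:
they are pruned before counting. Polytomies use the multifurcating
extension (keep the states attaining the maximum membership count m
among k children, add k − m changes), which reduces to the classic
union/intersection rule on bifurcations and agrees with exhaustive
internal-labeling enumeration on every ≤6-tip topology (tested). The
count is invariant to the arbitrary rooting.

Monophyly is defined unrooted, via bipartitions: a state's tips are
monophyletic iff some edge separates exactly those tips from the rest
of the informative tips. The smallest bipartition side containing all
of the state's tips is reported as witness. For a binary character with
both states present, monophyly of either state is equivalent to a Fitch
count of 1 — the property-tested link between "single origin" and the
change count. Branch support values are not consulted.

## Genome co-occurrence

Per genome, UNKNOWN copies are dropped first; genomes with ≥2 remaining
classified copies are "multi" and categorised MIXED (both NDP and NTP
present), NTP_ONLY or NDP_ONLY. A genome with one classified and one
unclassifiable copy is SINGLE, not multi — unclassifiable copies are
evidence of nothing. Identical duplicate sequences count as separate
copies (the unit is the gene occurrence). The headline percentage of
MIXED among multi genomes is rounded to the nearest integer for
reports; full precision is retained in the JSON output.

## Kinetics

Rates are turnover numbers (min⁻¹, product per enzyme per minute);
`activity_from_product` converts product formed over a fixed incubation
to turnover. Two rate laws:

* Michaelis–Menten: v = k_cat·S/(K_M + S)
* substrate-surplus inhibition (uncompetitive form):
  v = k_cat·S/(K_M + S·(1 + S/K_i)), maximal at S = √(K_M·K_i) and
  reducing to plain MM as K_i → ∞.

The uncompetitive form is the standard textbook substrate-inhibition
equation; it is the package's choice of parameterisation for "MM with
substrate surplus inhibition".

Fitting is unweighted Levenberg–Marquardt least squares
(`scipy.optimize.least_squares`, method `"lm"`, xtol/ftol/gtol 1e-8,
≤500 evaluations), initialised scale-free at k_cat⁰ = max v, K_M⁰ = S
nearest half-maximal v, K_i⁰ = max S. Standard errors come from the
Jacobian at the optimum (σ² = RSS/(n−p) times the inverse of JᵀJ).
Non-convergence, non-positive estimates, or a singular Jacobian set
`converged=False` on the reported fit rather than raising — fitting
plain MM to strongly inhibited wide-range data is *supposed* to surface
an unhealthy fit. MM requires ≥4 distinct substrate concentrations,
MM_SI ≥5.

The *apparent* fit truncates the data at a chosen S_max and fits plain
MM; under substrate inhibition the apparent K_M underestimates the true
K_M (tested by simulation), so it is reported with an `apparent` flag
and should be read as a lower bound.

## Synthetic data: what it emulates

The generators define the conditions all tests and the acceptance
script run under.

**Families.** A fixed 150-residue NrdJ-like backbone with the apical
loop at 66–69 (P-A-G-R in the reference state) and a distal-loop
annotation at 50–53. Planted motif counts use largest-remainder
allocation, so zero-noise censuses are exact. Background substitutions
(default rate 0.1 per site — the divergence of real NrdJ selections is
not documented, and this value makes anchoring non-trivial without
being adversarial) and optional single-residue indels are applied
everywhere except the loop spans ±2 residues, keeping the planted truth
well-defined. The backbone has none of NrdJ's real domain architecture
(B12-binding or allosteric sites); what the round-trip tests show is
that anchoring and extraction are correct under point/indel noise, not
that the pipeline handles arbitrary real-world divergence.

**Genomes.** Copy numbers and multi-copy specificity categories are
drawn from configurable distributions; `assignment="deterministic"`
converts both to exact largest-remainder counts (shuffled across
genomes), so printed count tables are reproduced exactly and seed
changes alter sequence content but not category counts. MIXED genomes
carry at least one P-N-S-P and one P-A-G-R copy.

**Trees.** Random binary topologies with exponential branch lengths.
SINGLE_ORIGIN joins a derived-state clade and an ancestral-state clade
at the root, so exactly one change exists by construction; K_ORIGINS
interleaves k derived clades with ancestral tips along a caterpillar
backbone (requiring ≥ k+1 ancestral tips), making the parsimony minimum
exactly k — verified against the enumeration oracle; RANDOM assigns
states independently.

**Assays.** The forward model evaluates MM or MM_SI on a substrate grid
(default 0.05–3 mM, 10 points, 3 replicates, matching the wild-type
assay design) and applies multiplicative Gaussian noise v·(1+ε),
ε ~ N(0, cv²), truncated at v ≥ 0, default cv = 0.05. The error model
of the original instrument is not documented; multiplicative noise is
the conventional choice for HPLC-quantified rates spanning an order of
magnitude.

## Problem sizes

The test suite and acceptance script use a 1655-member family, 1108
two-copy genomes, 64-tip trees, and 100 replicate assay simulations —
the sizes of the analyses they reproduce; the exhaustive oracles cover
all ≤6-tip topologies and all ≤5-residue alignment pairs over a reduced
alphabet, which is where enumeration is tractable.

## Known limitations

* The pairwise anchor assumes global homology to the reference; domain
  fusions or fragments would need local anchoring, which is not
  implemented.
* The lexicon is NrdJ-calibrated. Class I (NrdA) enzymes show the NDP
  motif with more variability and class III (NrdD) is out of scope;
  applying the classifier outside NrdJ will over-produce UNKNOWN.
* Monophyly ignores branch support; a "likely monophyletic" judgement
  with support values is beyond the bipartition test.
* Logo matrices are observed-frequency only; they are not comparable to
  HMM-posterior logo services on gappy alignments.
* The kinetic fitter is single-substrate; no global multi-substrate or
  binding models.
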