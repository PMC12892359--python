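# Methods

This note documents the models, conventions and numerical choices
behind `dtlflux`, and what the synthetic-data generator does and does
not emulate.

## The DTL gene-content process

Gene families evolve independently along a rooted, binary,
branch-length-bearing species tree. Time runs from the root (t = 0)
toward the tips; between node times the set of live lineages is
constant, and events follow competing exponential clocks:

* **duplication** and **loss** at per-copy rates `d`, `l` (per unit
  branch length), applied to the copies on each branch;
* **origination** at per-branch rate `o`, active only while the family
  has zero copies anywhere (origination is family birth; repeat
  origination after total extinction is possible but rare);
* **transfer** indexed by the *recipient* branch: branch `b` receives
  at rate `t_b · (copies elsewhere) / (n_live − 1)`, with the donor
  drawn copy-weighted from the other live lineages. A transfer
  therefore always names an extant, contemporaneous donor.

Recipient-side indexing is deliberate: the phenomenon being emulated
is gene *influx into* a clade (an HGT-fed proteome expansion), so a
clade-specific transfer multiplier must raise that clade's rate of
receiving genes. When the transfer rate is uniform over branches the
parameterisation is equivalent in total flux to the more common
per-copy donor clock with a uniformly chosen recipient.

At a speciation both daughter branches inherit the parental copy
number. Copy number is tracked internally; the exported matrix keeps
counts and exposes a binarised view, because all downstream profiling
is presence/absence.

Root presence is sampled (probability `root_presence_prob`) and is
*state*, not an event; the event log plus the root states replay to
the exact tip matrix, which the tests verify.

The per-family simulation is an epoch-wise Gillespie algorithm; it is
exact, and cheap at the scales used here (10 000 families on a quartet
in ~1 s). Zero-length internal edges (only possible via resolved
polytomies in imported trees) are not supported by the simulator.

## Ancestral reconstruction

Gene-tree-aware reconciliation is **not** reimplemented; tables of
per-branch event frequencies from such tools can be ingested directly
(`ingest_event_table`), with raw sums always retained and a
half-to-even rounded column for convenience. The package's own
inference is profile-based, which keeps every stage testable at desk
scale, with two consequences that are flagged in all outputs:
duplications are invisible (D ≡ 0 from profiles), and the
origination/transfer split of gains is a stated convention, not a
mechanistic inference.

**Wagner parsimony.** Sankoff dynamic programming over states {0, 1}
with gain penalty 2 and loss penalty 1 by default — asymmetric because
in gene-content data content-increasing events are rarer than losses.
Ties prefer absence, resolved root-ward (root first, children
conditioned on the parent's choice), making the labelling
deterministic. The root state is free: no penalty is charged for
presence at the root (there is no root edge). The exhaustive
enumeration oracle in the tests confirms optimality on random
instances.

**Two-state Markov model.** Gain rate μ (0→1), loss rate λ (1→0), root
prior π; transition probabilities are the closed-form two-state CTMC
solution, the likelihood is computed by pruning (vectorised over
families), and marginal posteriors by the standard up-down pass. The
fit maximises the product likelihood over families with L-BFGS-B on
(log μ, log λ, logit π) from a fixed 3×3×2 grid of starts (rates 0.02,
0.2, 1.0; priors 0.2, 0.8), bounds 1e−6…50 on rates — deterministic,
with ties resolved to the earlier grid point. All-present or
all-absent matrices are degenerate: π is pinned to the boundary, rates
left at the lower search bound, and a warning emitted.

**Event extraction.** For binarised states, a 0→1 edge is a gain and a
1→0 edge a loss. Per family, the preorder-first gain is labelled O;
every later gain is labelled T with the donor recorded as the earliest
lineage already carrying the family (the first-gain branch, or the
root for ancestrally present families). A present root produces no
event. Posterior states are binarised at a threshold (presence
requires probability strictly above it, so a tie goes to absent,
matching the parsimony tie rule); 0.5 is the recommended threshold.

## Event flux

Category shares are percentages of the D+T+L+O total, reported raw and
rounded half-to-even to two decimals; a zero total yields undefined
(not zero) shares. The per-node log-ratio is
`log10((D+T+O + c)/(L + c))` with the pseudocount `c` (default 1)
applied to both sides and *only* when one side is zero, so typical
nodes are unperturbed. "Gains" is configurable; D+T+O is the default
because all three increase content. Hotspot ranking is a pure sort:
T descending, node id ascending (plain string comparison, so "n10"
sorts before "n2" — documented, deterministic). The transfer-partner
matrix counts donor-clade × recipient-clade pairs; its cell sum equals
the number of donor-resolved transfers.

## Pathway completeness and occurrence classes

A pathway is an ordered list of steps, each a set of alternative gene
families. Gene mode scores the fraction of listed genes present
(matching "percentage of present genes"); step mode scores the
fraction of steps with at least one alternative present, which is the
right reading when isofunctional enzymes (pfkA/pfkC) should not be
double-counted. With posterior presence probabilities both modes
report expectations; a step is present with probability
1 − ∏(1 − p_alt). Both modes are bounded in [0, 1] and monotone under
content addition.

Occurrence ratio r of a gene in a clade classifies as absent (r = 0),
minority (0 < r < 0.5) or majority (r ≥ 0.5); the boundary is
inclusive. Overlapping clades are rejected by default because
occurrence is a per-lineage statistic.

The shipped pFLAG definition file (`dtlflux/data/pflag_pathways.tsv`)
seeds the six categories with marker genes of EMP glycolysis, the TCA
cycle, purine/pyrimidine, amino-acid, cofactor and archaeal
membrane-lipid biosynthesis. It is a contract, not a claim: replace it
with a study-specific table for real annotations. Reverse gyrase
(`rgy`), a hyperthermophily marker rather than a biosynthetic-pathway
member, is intentionally not filed under any category.

## Thermal adaptation and streamlining metrics

IVYWREL is the fraction of I, V, Y, W, R, E, L among canonical
residues; CvP-bias is 100·(f_D+f_E+f_K+f_R) − 100·(f_N+f_Q+f_S+f_T)
(histidine excluded from the charged set by convention; both sets are
configurable). Ambiguous letters (B, J, Z, X, U, O, `*`) are excluded
from denominators and tallied separately. Both metrics depend only on
the residue multiset, hence are invariant to re-splitting or
reordering sequences.

OGT is predicted linearly from IVYWREL. The default coefficients
(−335, 937 °C per unit fraction) follow the published IVYWREL
predictor from the thermophily literature and are configuration only;
the supported path is `calibrate_ogt`, an OLS fit on a labelled set.

Coding density is |union of CDS intervals| / genome length — union,
not sum, so heavily overlapping gene sets (observed up to ~40%
overlapping genes in streamlined genomes) cannot push density past
100%. A gene is overlapping when it shares ≥1 bp with another gene on
either strand. Geneless records have density and overlap fraction 0
by definition. `linear_fit` is OLS with adjusted
R² = 1 − (1−R²)(n−1)/(n−2) and a two-sided t-test on the slope; a
constant response is defined to have slope 0 and R² = 0.

## The synthetic-data generator

The generator replaces metagenome-derived inputs with data that carry
the statistical structure the analysis assumes:

* **Species trees** from a birth–death process (general sampling
  approach, so terminal branches are strictly positive), default 16
  tips, birth 1.0, death 0.2. Two disjoint clades are labelled: an
  HGT-influx clade (transfer ×8 by default) and a loss-dominated clade
  (loss ×5), emulating a transfer-fed expanding lineage and a
  streamlining lineage. Clades are chosen deterministically, targeting
  ~25% of tips each, so a background always remains.
* **Gene content** under the DTL process (defaults: o = 0.02,
  d = 0.02, t = 0.12, l = 0.35 per unit branch length, root presence
  0.35), 500 families by default. A separate exact sampler for the
  two-state gain/loss Markov chain exists for parameter-recovery
  checks of the Markov fit — it matches that model by construction.
* **Pathway groupings**: the leading families are grouped into one
  synthetic pathway per pFLAG category (8 genes each by default, ~20%
  of steps with two alternatives).
* **Proteomes**: residues drawn i.i.d. from a typical prokaryotic
  composition whose IVYWREL mass is shifted linearly with the genome's
  true OGT (slope 0.002 per °C by default — comparable to published
  IVYWREL–OGT slopes), clipped to (0, 1). OGTs are uniform on
  45–80 °C with +15 °C for the loss-dominated clade, emulating the
  hyperthermophile–streamlining association.
* **Annotations**: gene intervals laid left-to-right with a controlled
  fraction of overlapping pairs (1–60 bp shared), target coding
  density 0.92, overlap fraction 0.12 background / 0.39 in the
  streamlined clade, gene lengths gamma-distributed around 800 bp —
  magnitudes typical of compact archaeal genomes.

What the generator does **not** emulate: sequence-level evolution (no
substitution models or gene trees), annotation error and incomplete
genome assembly, copy-number variation biases of real metagenome bins,
rate heterogeneity across families, and correlated family co-gain or
co-loss beyond the shared tree. Passing tests therefore demonstrate
algorithmic correctness and statistical identifiability under the
stated model, not robustness to the noise sources of real
metagenome-assembled genomes.

## Problem sizes and tolerances

The test and acceptance workloads are sized for interactive runs:
Sankoff-vs-enumeration on 200 random trees of ≤8 tips; pruning vs
brute-force summation on ≤6-tip trees at 1e−10 relative error;
loss-only survival at 10 000 families against exp(−λ·depth) within 3
binomial standard errors; (μ, λ) recovery within ±30% on a 64-tip /
2 000-family simulation; IVYWREL-slope recovery within ±20% from 64
proteomes of 200 000 residues; and the top-hotspot sign check over 50
replicate clade-shift simulations of 600 families each (600 keeps the
per-node counts large enough that the ranking reflects rates rather
than sampling noise). End-to-end pipeline runs default to 16 tips and
400–500 families.

## Known limitations

* Profile-based inference cannot see duplications and cannot
  mechanistically separate origination from transfer; treat the O/T
  split as a labelling convention (it is marked as such in outputs).
* The Markov model assumes one global (μ, λ, π) for all families; with
  strong rate heterogeneity the fit is a compromise value.
* The simulator's transfer model has no donor–recipient distance
  preference; real HGT is biased toward cohabiting lineages.
* OGT prediction from composition is a one-predictor linear model;
  calibration data should match the clade of interest.
* External event tables are matched to the tree by internal-node
  labels; relabel nodes to the package's preorder scheme before
  ingestion (node ids are deterministic, "n" + preorder index).
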