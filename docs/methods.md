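# Methods

## Scope and model

`formulanet` treats a multi-herb formula as a set of compounds, each
attributed to one or more herbs, acting on protein targets through a
bipartite compound–target (C-T) graph. The pipeline's claims are
set-theoretic: which compounds survive a pharmacokinetic screen, which
compound–target pairs survive a dual-model score filter, which targets
are shared between herb groups or formula variants, and — the decision
the package exists for — whether a component set can be removed from a
formula while preserving disease-relevant target coverage. No binding
affinities, doses or kinetics are modelled; "acts on" is Boolean.

## Herb–disease mining

Literature co-occurrence is scored with the hypergeometric upper tail:
with a corpus of `n_total` papers, `n_disease` disease-linked,
`n_herb` herb-linked and `n_joint` joint papers, the score is
P(X ≥ k) for X hypergeometric. Evaluation goes through
`scipy.stats.hypergeom.sf`, which works in log space, so corpus-scale
counts (10⁷ papers) neither overflow nor lose the tail. `k = 0` gives
P = 1 (the empty lower-tail sum), and out-of-support pmf terms are zero
by the standard convention. Significance is strict: P < α with
α = 0.01 by default, uncorrected — the screen is a shortlisting device,
not an inference, and a fixed cutoff keeps it interpretable. Corpus
retrieval itself is out of scope; counts are caller-supplied inputs.

## ADME screen

The candidate rule is OB ≥ 30 (percent) and DL ≥ 0.18 (unitless), both
boundaries **inclusive**: several tabulated candidates sit exactly at
DL = 0.18 and are counted as passes, which fixes the convention. DL can
be recomputed from a descriptor vector as the continuous Tanimoto
similarity to a reference mean vector; when a tabulated DL and a
recomputed one both exist, the tabulated value wins (the descriptor set
behind tabulated scores is generally unknown, so recomputation cannot
be assumed comparable). The Tanimoto denominator Σa² + Σb² − Σab is
zero only for two all-zero vectors, which is rejected as undefined
input rather than mapped to 0 or 1.

Rescue is an explicit whitelist, never inferred: which sub-threshold
compounds deserve retention is a literature judgement, not a
computation. The shipped whitelist for the packaged candidate table is
exactly its 10 sub-threshold rows, marked in the fixture's `rescued`
column. The screen reports strict passes, rescues and rejects as a
disjoint cover of the library, and per-herb counts dedupe by compound
id while counting a multi-herb compound under every herb it belongs to
(one table row, one herb set — so shared compounds are never double
loaded into a single herb's count but feed every relevant sub-network).

Oral bioavailability is consumed as an input column, not predicted; the
regression models behind published OB values are not reproducible from
their coefficients.

## Target consensus

All four comparisons of the keep rule are **strict** (`>`), following
the rule's wording: both scores above the positive-list level 0.5, RF
above 0.7, SVM above 0.8. The rule is row-local and therefore
order-stable and permutation-equivariant; duplicate (compound, target)
pairs are rejected. The two levels are composed conjunctively — the
positive-list level is exposed separately in `ConsensusConfig` even
though with default settings the 0.7/0.8 pair is binding, so users can
study either rule alone. The RF/SVM models themselves are upstream;
scores are inputs.

## Networks and overlap statistics

Networks are stored as explicit node/edge sets (a dataclass, with
`networkx` used only for GraphML serialization), because every
statistic the analysis needs — degrees, per-group target sets, the
shared/specific partition — is set algebra, and an explicit
representation keeps the invariants (degree-sum conservation, disjoint
cover) assertable. "Shared" across more than two groups means hit by
**all** groups (intersection); a target hit by some-but-not-all groups
and by more than one falls into the `other` bucket, so the partition
always covers the target side exactly. Node identity is by id; names
and groups are attributes.

Printed-figure arithmetic (overlap percentages, mean targets per
compound) rounds **half-up** via `decimal`, not banker's rounding:
67/132 = 50.7575… must print 50.76. `overlap_percentage` with 0
decimals reproduces integer-precision figures such as 97 from
(135, 139).

## Formula comparison and the removal verdict

The comparison partitions the union of two networks' target sets into
shared, A-specific and B-specific; `shared_fraction` uses the **union**
as denominator (matching the convention under which 135 shared of 139
union targets reads as 97 %). The removability rule is the package's
formalization of an argument usually made informally:

* coverage: shared_fraction ≥ threshold (default **0.90**, chosen below
  the 0.97 observed in the motivating case so that case passes with
  margin; configurable), and
* disease link: no B-specific (removed-only) target is
  disease-associated.

Unknown disease annotation among removed-only targets yields an
**indeterminate** verdict, not a pass — removal is a safety-relevant
claim and silence must not count as evidence. Edge multiplicity (how
many compounds hit a shared target) is deliberately ignored; only set
membership enters the verdict.

## Synthetic data

The generators exist because no edge lists, score matrices or corpus
counts are published for the study system; they are first-class,
tested code, not test scaffolding. Design choices:

* **Library**: OB and DL are drawn from two-component normal mixtures
  straddling the 30 / 0.18 thresholds (defaults: OB 0.9·N(45, 8²) +
  0.1·N(15, 6²); DL 0.9·N(0.45, 0.15²) + 0.1·N(0.08, 0.04²)), clipped
  to their domains; since clipping never moves a draw across the
  threshold, the design strict-pass rate is the exact mixture-CDF
  product, which the tests check at 3 standard errors on 10 000 draws.
  Zero component spread is rejected as degenerate. Herb attribution is
  sampled from the seven default herb groups with weights proportional
  to the real per-herb candidate counts (11, 8, 11, 12, 9, 7, 15), with
  a 10 % chance of a second herb.
* **Scores**: planted true interactions draw both scores strictly above
  their cutoffs within a band of width `score_noise` (default 0.2);
  decoys fail at least one cutoff (rf-only 30 %, both 40 %, svm-only
  30 %). Draws map the half-open uniform [0, 1) to (0, 1] so a true
  score can never land exactly on a strict threshold: the consensus
  filter recovers the truth set *exactly*, which the suite asserts.
* **Formula pairs**: of `n_targets` union targets,
  `round(f·n_targets)` are shared, `n_b_specific` belong only to the
  removed components, the remainder only to the kept formula; edges are
  laid round-robin over a small compound set so every target has ≥ 1
  edge. Noise-free recovery of the planted fraction is exact by
  construction and tested over f ∈ {0.5, 0.75, 0.9, 0.97}; with
  `pair_noise` > 0 each shared target is independently demoted with
  that probability. Defaults mirror the study shape: 139 targets,
  f = 135/139, 4 removed-only targets, none disease-linked.

All draws come from a single seeded `numpy` generator consumed in a
fixed order, so output is deterministic across platforms. What the
synthetic data does **not** emulate: chemistry (descriptors are
abstract vectors), correlated score errors between RF and SVM, degree
heterogeneity of real C-T networks, or literature-count overdispersion.
Passing tests therefore demonstrate correctness of the set logic and
thresholds under controlled truth, not predictive validity on real
score matrices.

## Problem sizes

The test suite and acceptance script run the fixture analyses at their
natural size (66 and 37 compounds; 139 comparison targets), the
consensus oracle checks at 9 174–10 000 rows, and the hypergeometric
sweep exhaustively over every (N, K, n, k) with N ≤ 60 against exact
integer-arithmetic pmf summation at 10⁻¹² tolerance. These sizes were
chosen to cover the full combinatorial space of the small statistics
while keeping a complete run in seconds.

## Known limitations

* The removability rule is a formalization the package defines; other
  operationalizations (edge-weighted coverage, per-axis coverage) are
  plausible and out of scope.
* The per-herb counts of the packaged tables embed editorial rescue
  decisions; changing the whitelist changes the retained counts.
* Pathway membership is a static annotation table; no enrichment
  statistics are computed because target-to-pathway assignment here is
  curation, not sampling.
* Reported OB/DL values are accepted as given; the screen's validity
  inherits whatever bias those upstream predictors carry.
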