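# Methods

This note documents the statistical models, the synthetic data the tests
run on, the numerical conventions, and the design choices made where the
problem was genuinely open.

## Study design and data model

The pipeline assumes a two-group, two-tissue design: every individual is
case or control and contributes one sample per tissue (subcutaneous and
visceral adipose, SAT/VAT). The default synthetic cohort is 12 case / 13
control individuals, mirroring the scale of surgical metabolic cohorts.
Inputs are a probe-by-sample beta-value matrix per tissue (array
methylation, values in [0,1]), a gene-by-sample log2 expression matrix per
tissue, a probe annotation (chromosome, 1-based position, gene, promoter
region class, CpG-island relation), a tissue-specific regulatory network
(undirected gene-level edge list), a labeled TF binding-site interval
catalogue (BED), and validation gene sets (GMT). Tissues are never pooled;
every differential analysis is within-tissue.

Coordinates: probe positions are 1-based (array-manifest convention),
intervals are 0-based half-open (BED convention). A single rule owns the
mapping — a probe at position p overlaps interval (s, e) iff s ≤ p−1 < e —
so the off-by-one surface is one tested function.

## Moderated t-statistics

Both differential layers share one empirical-Bayes engine. For each
feature, the pooled two-sample variance s² (d = n₁+n₂−2 df) is shrunk
toward a prior: s̃² = (d₀s₀² + d·s²)/(d₀+d), and t = effect / (s̃·√(1/n₁+1/n₂))
is referred to t(d₀+d). The prior is fit by method of moments under the
scaled-F model s² ~ s₀²·F(d, d₀): with c = (Var s²/Mean² s²)·d/2,
d₀ = (d−2+4c)/(c−1) when c > 1 (always in (4, ∞)), and d₀ = ∞ with
s₀² = mean(s²) when c ≤ 1 (variances consistent with a common value; the
statistic then uses the prior variance alone and a normal reference).
Degenerate inputs (fewer than two features, zero mean variance) fall back
to d₀ = 0, the ordinary pooled t. Features with zero spread and zero
effect get statistic 0 and p 1.

Methylation is tested on M-values, M = log2(β/(1−β)) with β clipped to
[ε, 1−ε], ε = 10⁻⁶ — the variance-stabilized scale — while effect sizes
are reported as Δβ (difference of group mean betas), which is what a
reader can interpret. Significance everywhere is Benjamini–Hochberg FDR,
with q < 0.1 as the default threshold.

Gene-level promoter methylation uses the min-p representative probe over
TSS200/TSS1500/5'UTR probes (ties: larger |Δβ|, then lexicographic probe
id). This preserves the strongest promoter signal for the module search; a
mean-statistic summarizer is available via `method="mean"`. The choice is
ours — averaging dilutes single-CpG promoter signals at array resolution.

## DMR calling

Probes are clustered per chromosome into maximal runs with inter-probe gap
≤ max_gap (default 1000 bp). Clusters with ≥ min_probes (3) probes and
|mean Δβ| ≥ min_abs_delta (0.05) are candidates. Each candidate is scored
with a Stouffer combination Z = Σzᵢ/√n of the signed normal-quantile
transforms of the probe p-values. Significance comes from B group-label
permutations within the tissue (default B = 1000; samples are sorted by id
first so the result is invariant to input order). Crucially, the candidate
filter is re-applied inside every permutation and the null records the
per-permutation maximum |Z| over the permutation's own candidates; the
empirical p is add-one, p = (1+#{null ≥ obs})/(B+1), so it is never 0 and
never below 1/(B+1). Mirroring the selection step in the null is what
keeps the p-values valid — observed candidates are chosen for large |Δβ|,
and comparing them to unselected permutation scores is anti-conservative
(we measured roughly half of null candidates being called without it).
The max-over-candidates null makes the p-values jointly (maxT-style)
valid, at the cost of conservatism for weak regions. Candidates at BH
q < 0.1 are reported with hyper/hypo direction; cross-tissue DMRs are
matched by ≥1 bp overlap and grouped by connected components, each
component counted once.

## TF binding-site methylation

For each TF with ≥ min_probes (10) probes overlapping its sites, the
distribution of probe-level t-statistics inside the sites is compared to
the TF's own complement (all probes not overlapping any site of that TF)
with a two-sample KS test; Mann–Whitney is available by configuration. A
distributional test was chosen because binding-site methylation changes
need not be unidirectional; the median shift is reported for the
concordance classification (significant in both tissues with agreeing
shift sign → similar, disagreeing → divergent; one tissue → tissue-specific).

## Functional epigenetic modules

|t| values of each layer are rank-transformed to (rank−0.5)/m (midranks
for ties) over the genes present in the network; a gene missing a layer
gets weight 0 for it and is flagged rather than excluded, which keeps
connector genes available as control biomarkers. Node weight is the
unweighted mean of the two layers; every edge carries the mean of its
endpoint node weights (an invariant asserted after construction and under
every permutation).

Module search is deterministic seeded greedy hill-climbing: seeds are the
top-n (default 10) genes by node weight; from a seed, the neighbor
maximizing the new mean-edge-weight score is added (ties: higher node
weight, then lexicographic id), with growth forced up to min_size (4),
stopped when no addition increases the score, and capped at max_size (50).

Significance is Monte-Carlo: the per-gene (methylation, expression) weight
pairs are permuted jointly across all non-seed nodes — preserving each
gene's pairing, so correlated layers do not inflate significance — and the
greedy search is rerun from the same seed; p = (1+#{null ≥ obs})/(B+1),
default B = 999. The seed keeps its own weights in the null: seeds are
selected for high weight, so their weight is a selection artifact rather
than module evidence, and conditioning on it makes the null scores
exchangeable with the observed score when the other weights carry no
signal (without this, noise networks produced "significant" modules far
above the nominal rate). BH is applied across seeds and modules with
q < 0.1 survive; survivors whose memberships overlap at Jaccard > 0.5 are
merged by union of members (score recomputed on the union, the
best-scoring constituent's seed and significance kept). Union-merging is
deliberate: the greedy ascent from any single seed recovers the densest
core of a module, and the union of the per-seed cores reconstructs the
full membership.

## Biomarkers and validation

Candidates are the union of module members and DMR-annotated genes.
Disease biomarkers have q < 0.1 in either layer (evidence: expression,
methylation or both); non-differential candidates adjacent to a disease
biomarker in the regulatory network are control biomarkers; candidates
with neither property are dropped with a logged reason. Validation is
pure set overlap against GMT collections in seven categories; a biomarker
hits a category if it appears in any of its sets (once per category), and
percentages (validated-in-any, TF fraction) are reported to one decimal,
per tissue and pooled.

## Synthetic data: what it emulates, and what it does not

The generator plants, per study: one 8-gene module (promoter Δβ = +0.15,
expression log2 fold change = −1 — the hypermethylated/downregulated
motif), five-probe DMRs (|Δβ| = 0.2; one shared hypomethylated region plus
one hyper region per tissue, each occupying a whole probe cluster so
called boundaries are well-defined), binding-site shifts for 2 of 20 TFs
(Δβ = +0.15 at 60 dedicated probes), and 30 ordinary DEGs (|lfc| = 1).
Baseline methylation is bimodal (low at islands, high in open sea) with
noise on the logit scale, sd 0.35 — within-group beta SD ≈ 0.02–0.09,
typical of methylation arrays — which also keeps betas strictly inside
(0,1). Expression is log-normal with within-group sd 0.5 on the log2
scale. The regulatory network is preferential-attachment (scale-free) with
the planted module additionally wired as a clique, reflecting that modules
are densely interconnected gene sets. Validation gene sets contain a
configured fraction (75%) of planted genes. All randomness flows from one
seed; every planted entity is recorded in a ground-truth JSON sufficient
to score recall/precision/F1 of each stage.

Not emulated: array probe-type chemistry biases, RNA-seq count
overdispersion at read level, batch structure, cell-type composition, LD
between genetic signals, and realistic correlation between neighboring
probes beyond shared planted effects. Passing tests therefore demonstrate
that the statistics are calibrated and the planted-effect recovery works
at the stated effect sizes and sample sizes — not that any particular real
cohort would yield the same counts.

## Problem sizes and numerical conventions

Calibration tests use B = 200 resamples, null fixtures of a few hundred
probes or a 150-node network, and 20–50 replicates; recovery tests use 20
seeded studies at the default design (300 genes, one tissue per study,
since the two tissue arms are identical code paths). The acceptance script
uses 10 recovery seeds plus one full two-tissue run. Production defaults
are B = 1000 (DMR) and B = 999 (modules).

Determinism: all RNGs are numpy `default_rng` seeded from the run seed
(per-stage streams derived via seed sequences); samples and probes are
sorted canonically before permutation so results are order-invariant;
tables are written with fixed float formatting, making reruns
byte-identical. Add-one empirical p-values bound every permutation p away
from 0. z-transforms are clipped at |z| = 40 to avoid infinities from
underflowing p-values.

## Known limitations

- The DMR null is maxT-shared across candidates: strong regions are easy
  to call, weak true regions near the Δβ threshold are conservative.
- Greedy module search finds dense cores; long "stringy" modules with
  weak internal edges can be fragmented across seeds (partially mitigated
  by union-merging).
- Gene-level methylation uses promoter probes only by default; gene-body
  methylation signal is ignored unless region classes are reconfigured.
- The moment-based variance prior assumes a unimodal variance
  distribution; strongly bimodal variances would mis-shrink.
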