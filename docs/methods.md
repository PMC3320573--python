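# Methods

This note documents the models and procedures implemented in `adrsub`,
their assumptions, the parameters that matter, the synthetic-data design
behind the test suite, and the numerical and design choices made where the
problem left the design open.

## Scope and data model

The toolkit operates on a *local snapshot* of pharmacology knowledge: seven
TSV association tables (compounds, metabolites, protein catalogue,
drug–target, event–protein, expression, pathway membership), an interaction
edge list, an event-code → concept-identifier mapping, optional
DailyMed/DrugBank-style extraction tables and a JSON-lines citation corpus.
There are no live queries; retrieval, concept recognition (the corpus
arrives pre-annotated) and in-silico target profiling (its predictions
arrive as SIMILARITY-tagged rows) are upstream concerns. Loading is strict
about structure — a missing column or unparseable number is fatal — but
collects rather than raises row-level violations (malformed ATC codes,
unknown evidence types, dangling references), mirroring how heterogeneous
database exports are handled in practice.

A drug's **target profile** pools its own target rows with those of its
metabolites; a protein is flagged `via_metabolite` when *no* parent-drug
row supports it. Pooling before testing reflects the view that a
metabolite's activity is part of the drug's mechanism; the per-protein flag
keeps the attribution auditable, and batch summaries report the fraction of
connected pairs explained only by metabolites. An **event profile** is the
union of event–protein rows over the event's concept identifiers; duplicate
rows collapse at the protein level while every evidence record is retained
(evidence rows, not proteins, are the unit of reporting, and the result
graph draws one edge per record).

Affinities (pKi, pIC50; −log10 molar) are stored per row; the arithmetic
mean per (protein, kind) is a derived display value only. Affinities never
enter any score — the overlap statistic is deliberately binary membership.
SMILES strings are opaque lookup keys; no chemistry toolkit is involved.

## Overlap significance

For profile sizes m (drug) and n (event) with k shared proteins in a
universe of N, the p-value is the one-sided Fisher exact (hypergeometric)
tail P(X ≥ k), X ~ Hypergeom(N, n, m), evaluated in log space with no
normal approximation (`scipy.stats.hypergeom.sf`). The 2×2 construction is
the standard enrichment convention: rows = drug-profile membership,
columns = event-profile membership, over the universe N. Degenerate cases
are exact: k = 0 gives p = 1, and a forced overlap (m = N or n = N) gives
p = 1.

**The universe N** defaults to the union of proteins appearing in the
drug–target and event–protein tables — the set a pair could possibly draw
from under this knowledge base. When no association rows exist at all, the
protein catalogue is the universe. A fixed override
(`universe_size_override`) substitutes, e.g., a proteome-scale constant;
the bundled worked example uses 1500 because its table slice carries only
the proteins the example touches, while the appropriate universe is the
full annotated catalogue such a snapshot would have.

Batches are corrected by Benjamini–Hochberg step-up FDR (own
implementation: sort, scale by m/rank, running minima from the largest
rank, clip at 1; q ≥ p holds element-wise). The default significance
threshold is α = 0.01, configurable. BH within a batch assumes the usual
PRDS-type positive dependence; pairs sharing a drug or event are not
independent, which BH tolerates.

## Pathway bridging

Pathway annotations are canonical and context-free, so the profiles are
first passed through a **co-expression filter**: a protein is retained iff
some protein of the *opposite* profile is expressed in at least one common
(tissue, cell type) combination — both levels must agree; shared tissue
with disjoint cell types does not count. A protein present in both
profiles co-expresses with itself wherever it is expressed. Witness
triples (tissue, cell type, partner) are recorded for audit. Proteins with
no expression rows are dropped by default (treated as not expressed); the
`missing_expression="retain"` policy keeps them without witnesses, for
knowledge bases with patchy expression coverage. The filter runs before
bridging, and it is monotone: adding expression rows never shrinks the
retained sets.

A **connecting pathway** contains ≥ 1 retained drug protein and ≥ 1
retained event protein (one protein may serve both roles). Memberships are
taken as given — no hierarchy rollup or reaction-level topology; real
pathway collections sit at a high level of their hierarchies and results
must be read accordingly.

Because no closed-form null for the connecting-pathway count is available
(profile sizes, pathway sizes and the two-sided filter interact), batch
significance uses a **permutation test**: R replicates draw uniform random
protein sets of the two profile sizes from the universe, rerun the filter
and bridging identically, and p = (1 + #{count ≥ observed}) / (R + 1).
R = 1000 by default, seeded; p can never be smaller than 1/(R+1).

## Network proximity

The interaction network is undirected and unweighted (simple graph;
self-loops rejected, duplicate edges collapsed), so shortest paths are
breadth-first hop counts; the interface would accept weights, in which
case Dijkstra applies unchanged. The observed statistic is the arithmetic
mean of finite cross-pair distances between the two profiles;
identical-protein pairs are excluded, unreachable pairs are excluded but
counted, and proteins absent from the network are dropped with a count —
all three choices are reported so they can be audited. The null draws R
disjoint uniform random node-set pairs of the same (network-covered) sizes,
without degree matching ("randomly chosen" is implemented literally; a
degree-matched variant would be stricter and is deliberately not the
default).

Two p-values are reported. The **one-sample, one-sided t-test** of the
null-replicate means against the observed value asks whether the random
ensemble's *mean* exceeds the observed mean. Because the ensemble mean's
standard error shrinks as 1/√R while the observed value is a single draw,
this t-test is anti-conservative as a pair-level test: under the null it
rejects roughly half the time. It is retained for comparability with
common practice. The **empirical permutation p**,
(1 + #{null mean ≤ observed}) / (R + 1), treats the observed value as one
more draw and is exactly calibrated (super-uniform under the null); it is
the value the test suite holds to type-I-error bounds, and the value we
recommend acting on. With a zero-variance null (e.g. complete graphs) the
t statistic is undefined and the empirical p is used, flagged.

## Literature and database filters

*MeSH route.* A citation matches iff (some event descriptor carries the
subheading "chemically induced") AND (some drug descriptor — the drug
itself or any member of its pharmacological-action expansion — carries
"adverse effects"). The conjunction is required; the disjunctive reading
would trade precision for recall and is not implemented. Matching is
case-insensitive descriptor lookup; reports group matched citations by
publication type and count per year.

*Sentence route.* Every corpus sentence falls in exactly one cell of the
2×2 table (drug mention × event mention); matching is case-insensitive
whole-token containment, with multi-word terms required to appear as a
contiguous token run. Independence is tested by the closed-form 1-df
chi-square N(n11·n00 − n10·n01)² / (r1·r0·c1·c0) without Yates correction,
two-sided p — the correction choice is documented here because conventions
differ; with any zero margin the statistic is undefined and a not-testable
status is returned. Reports always carry the raw counts; the p ≤ 0.05
convention for "reported in literature" is a default, not a hard rule.

*Database routes.* DailyMed-style records index both the adverse-reaction
and boxed-warning fields; DrugBank-style cards are flat. A source whose
table is absent is reported "NA", distinct from zero matches.

## Synthetic data

The generator (`adrsub.synth`) emits complete knowledge bases and corpora
whose ground truth is known exactly, in two regimes:

* **null mode** — every drug and event profile is an independent uniform
  draw from the universe. This is the regime in which the overlap test's
  p-values must be conservative: with 2000 such pairs the fraction with
  p ≤ 0.05 stays below 0.05 plus Monte-Carlo error (discreteness of the
  exact test makes it conservative). Pairs built from 200 drugs × 10
  events share profiles across pairs; each pair's p-value is still
  marginally valid, which is all the calibration bound needs.
* **planted mode** — pair i (drug i, event i) shares exactly
  `planted_overlap` reserved proteins. Reserves are disjoint across pairs,
  and the non-reserved parts of planted drug and event profiles come from
  disjoint drug-side/event-side pools, so planted linking sets are exact
  by construction and no accidental overlap can occur (exact planted truth
  beats rejection sampling). A configurable fraction of planted pairs is
  wired only through metabolite rows (parent rows omitted for the shared
  proteins). Planted pathway bridges give each planted pair dedicated
  pathways holding one drug-side and one event-side protein with a shared
  (tissue, cell type) expression witness; `planted_hub` network mode wires
  both profiles of each planted pair to a dedicated hub protein, putting
  every cross pair within 2 hops.

Defaults (20 drugs, 10 events, 200 proteins, profile sizes 4–8, overlap 3,
30 pathways of 6, 5 tissues × 4 cell types, 2 expression sites per protein,
ER interaction network with edge probability 0.05, 10000-sentence-scale
corpora with signal co-occurrence rate 0.1) are sized so that planted
structure is unambiguous while null structure stays null; generation is
byte-deterministic given the seed. What the generator does **not** emulate:
realistic degree distributions of interaction networks, the marginal
distributions of real association databases, pathway hierarchy, or
correlated annotation biases (well-studied proteins appearing everywhere).
Passing tests therefore demonstrate correctness of the algorithms and
calibration under idealized sampling — not performance on real snapshots,
where annotation bias can inflate overlaps for well-studied drugs.

Recovery is checked in a balanced batch (planted pairs plus an equal
number of null pairs) — the natural reading of "recovering a planted
batch"; BH across a batch that is almost entirely null would measure the
null fraction as much as the method.

## Problem sizes used in the checks

The automated checks run at desk scale by choice: exhaustive oracle
agreement for all hypergeometric configurations with N ≤ 30; 1000 random
vectors for BH; 2000 null pairs for calibration; 50 planted pairs
(universe ≤ 200) for recovery; 100 hub-wired and 100 random 100-node
graphs (R = 150) for proximity power and size. These sizes give
Monte-Carlo margins well inside the asserted bounds while keeping the full
suite around ten seconds.

## Known limitations

* Overlap evidence is symmetric and binary; affinity strengths and
  association directions are reported but never weighted into the score.
* The universe choice materially affects p-values; results across
  knowledge bases with different coverage are not comparable unless a
  common override is fixed.
* The co-expression filter treats missing expression coverage as absence
  by default, which is conservative for bridging but can drop genuinely
  expressed proteins in sparsely covered tissue atlases.
* The t-test proximity p-value is reported for continuity with common
  practice but is not calibrated; use the empirical p.
* XGMML/GraphML outputs carry evidence multiplicity; consumers that
  collapse parallel edges lose information by design.
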