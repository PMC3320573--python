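# adrsub — filtering and mechanistic substantiation of drug safety signals

Pharmacovigilance surveillance flags *drug safety signals*: (drug, clinical
event) pairs that may be causally related. Before such a signal is acted on,
two questions arise. Has the association already been reported in the
literature or in drug reference databases (**signal filtering**)? And is
there a plausible molecular mechanism connecting the drug to the event
(**signal substantiation**)? `adrsub` is a local, fully testable toolkit
answering both questions from plain tab-separated knowledge tables
(drug–target associations with pKi/pIC50 affinities, metabolites,
event–protein associations, tissue/cell-type expression, pathway
membership, a protein interaction network, an annotated citation corpus and
pre-extracted drug-label tables). It is aimed at pharmacovigilance and
computational drug-safety researchers who want the analysis reproducible at
the desk rather than behind web services.

## The statistics at the core

**Protein overlap.** Let the drug's target profile (its own targets pooled
with its metabolites' targets) contain *m* proteins and the event's protein
profile contain *n* proteins, out of a universe of *N* annotated proteins.
With *k* proteins shared, the evidence for a mechanistic link is scored by
the one-sided Fisher exact test — the hypergeometric tail

P(X ≥ k), X ~ Hypergeom(N, n, m),

computed exactly in log space. Batches of pairs are corrected by
Benjamini–Hochberg step-up FDR (q-values). Shared proteins reachable only
through a metabolite are flagged, so altered-metabolism mechanisms remain
attributable.

**Pathway bridging.** Canonical pathways are context-free, so profiles are
first filtered to proteins co-expressed with a partner from the opposite
profile in at least one shared (tissue, cell type) — agreement at the tissue
level alone does not count. Pathways containing at least one retained drug
protein and one retained event protein are *connecting pathways*; their
count is assessed by a permutation test over random protein sets of the
same sizes.

**Network proximity.** The mean shortest-path length (hops) between the two
profiles on a protein interaction network is compared with the means for
randomly drawn set pairs of the same sizes: a one-sample, one-sided t-test
of the random ensemble against the observed value is reported together with
the empirical permutation p-value (1 + #{null ≤ observed})/(R + 1). The
empirical p is the calibrated quantity; see `docs/methods.md`.

**Literature filters.** A MeSH route (citation matches iff an event
descriptor carries the subheading *chemically induced* **and** the drug
descriptor — or a pharmacological-action sibling — carries *adverse
effects*) and a sentence route (2×2 sentence co-occurrence counts with a
1-df chi-square, no continuity correction), plus lookups in DailyMed-style
label extractions (adverse-reaction and boxed-warning fields) and
DrugBank-style cards.

## Worked example

The package bundles a knowledge base for six antipsychotics and the
EU-ADR event `QTPROL` (QT-interval prolongation), transcribing published
channel affinities (pKi/pIC50 averages across source databases):

```python
import adrsub
from adrsub.examples import qt_antipsychotics_kb, QT_DRUGS

kb = qt_antipsychotics_kb()
event = kb.resolve_event("QTPROL")
batch = adrsub.substantiate_batch(
    kb, [(atc, "QTPROL") for atc in QT_DRUGS.values()], alpha=0.01
)
for res in batch.results:
    genes = ", ".join(lp.gene_symbol for lp in res.linking) or "none"
    print(f"{kb.compounds[res.drug_atc].name:12s} k={res.k} m={res.m} "
          f"p={res.p_value:.4f} q={res.q_value:.4f} linking: {genes}")
```

prints

```
sulpiride    k=0 m=1 p=1.0000 q=1.0000 linking: none
quetiapine   k=1 m=3 p=0.0080 q=0.0096 linking: KCNH2
olanzapine   k=1 m=3 p=0.0080 q=0.0096 linking: KCNH2
ziprasidone  k=1 m=3 p=0.0080 q=0.0096 linking: KCNH2
pimozide     k=3 m=5 p=0.0000 q=0.0000 linking: KCNH1, KCNH2, CACNA1C
haloperidol  k=3 m=6 p=0.0000 q=0.0000 linking: KCNH1, KCNH2, CACNA1C
```

Reading: sulpiride (low-risk) shares no protein with the event; the
mid-risk drugs link only through the HERG potassium channel (KCNH2); the
high-risk drugs pimozide and haloperidol additionally link through the
hEAG1 (KCNH1) and Cav1.2 (CACNA1C) channels, and their overlaps of 3 are
far beyond chance (q ≪ 0.01). Pathway bridging for haloperidol retains the
cardiac co-expressed proteins and finds five connecting pathways
(Integration of energy metabolism; Axon guidance; Synaptic transmission;
Signaling by GPCRs; Diabetes pathways). The full run also emits the
evidence multigraph — one edge per evidence record, so parallel edges show
independent evidences — as Cytoscape XGMML.

The same pipeline is scriptable from the shell:

```sh
adr synth --out demo --seed 5            # synthetic KB + corpus with planted truth
cd demo
adr run --config config.yaml --drug A01AA01 --event EV001 --seed 3
adr filter --config config.yaml --drug A01AA01 --event EV001 \
    --drug-term drugname1 --event-term eventterm1
```

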