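# protnet

Causal protein-network components and prognostic activity signatures from
label-free proteomics.

Tumour proteomes quantify ~1,000 proteins across ~100 samples. `protnet`
asks two questions of such a matrix: *which proteins causally co-vary*, and
*do the functional modules they form predict outcome?* It is aimed at
computational biologists analysing cohort-level expression data (the shipped
defaults mirror a breast-cancer cohort with ER-true / TN-like / TNBC
subtypes and distant-metastasis follow-up), and at methodologists who want a
tested, order-independent PC-stable implementation with a d-separation
oracle harness.

## The method

1. **Preprocess** — keep proteins with ≥ 2 unique peptides detected in
   ≥ 75 % of samples of at least one sample type; log2; impute missing
   values from a down-shifted normal per sample column
   (μ<sub>obs</sub> − 1.8 σ<sub>obs</sub>, width 0.3 σ<sub>obs</sub>);
   z-score each protein.
2. **Learn structure** — PC-stable: starting from the complete graph, delete
   the edge *i–j* whenever a conditioning set *S* with
   ρ(i, j | S) ≈ 0 is found, testing with the Fisher z statistic
   √(n−|S|−3) · |arctanh r| at level α (default 0.01); orient unshielded
   colliders *i→k←j* when *k* ∉ sepset(i, j); close under Meek rules R1–R4.
   Directed edges are "guided", the rest "undetermined"; adjacency sets are
   frozen per level and all enumeration is lexicographic, so the output is
   identical under any protein or sample permutation.
3. **Components** — connected components of the mixed graph, named by node
   count ("Component 13"); components under 9 nodes are dismissed by
   default.
4. **Annotate & score** — hypergeometric term over-representation against an
   offline annotation table assigns each component a major function; the
   component's per-sample *activity* is the mean z-score of the members
   annotated to that function.
5. **Compare & validate** — Mann–Whitney tests between subtypes per
   component; prognostic value via Kaplan–Meier ranking, univariate Cox
   regression (Efron ties), and a leave-one-out risk assignment whose
   cross-validated, signed log-rank statistic is referred to a null built by
   re-running the whole procedure on B = 1,000 permutations:
   p = (1 + #{perm ≥ observed}) / (B + 1).

A synthetic-data module samples cohorts from known sparse linear-Gaussian
DAGs — with left-censored missingness, subtype mean-shifts, and
exponential survival tied to one module's activity — so every stage is
testable against ground truth, and the learner is additionally validated
against an exact d-separation oracle and an independent
DAG-to-CPDAG construction.

## Worked example

```bash
protnet simulate -p 60 -n 96 --seed 11 --outdir cohort
protnet run-all --config config.yaml     # config points at cohort/, B=1000
```

The manifest summarises the run (60 proteins → 54 quantifiable; 31 edges of
which 28 guided and 3 undetermined; 23 components, 7 kept at ≥ 3 nodes),
and `run/survival_validation.tsv` holds the validation table:

```
component_id  hazard_ratio  cox_p     km_logrank_p  permutation_p
Component 9   2.24          0.0060    0.0392        0.0350
Component 7   0.66          0.0010    0.0012        0.0020
Component 4   2.27          1.2e-06   0.0013        0.0030
Component 3b  1.68          0.0041    0.0033        0.0060
...
```

The generating truth planted an 8-protein co-regulated module whose mean
activity drives the hazard (log-HR 1.0). At n = 96 the learner recovers it
in fragments — Component 4 carries three of its members (activity
correlation 0.85 with the true module activity, HR 2.27) and Component 7 is
a negatively coupled neighbour (correlation −0.65, HR 0.66) — and exactly
those fragments, not the null components, validate at permutation
p ≤ 0.006. `run/risk_by_subtype.tsv` cross-tabulates the leave-one-out risk
labels against subtype, the shape used to report how a predictor
distributes tumour subtypes across risk groups.

Every stage is also available as its own subcommand (`preprocess`, `learn`,
`components`, `activity`, `compare`, `survival`) reading and writing TSV,
SIF and GraphML, so intermediate results plug into external tools
(e.g. Cytoscape for network drawing).

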