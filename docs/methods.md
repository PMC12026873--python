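# Methods

## Scope and model

The package implements a desk-scale network-pharmacology analysis: a set of
small molecules is screened for oral bioavailability, mapped to protein
targets by ligand-set similarity, intersected with disease genes derived
from case/control expression chips and curated lists, and the resulting
compound–target and protein–protein networks are ranked by centrality and
annotated by gene-set over-representation. Web databases (ADME predictors,
ligand databases, GEO, STRING, GO/KEGG services) are replaced by file
inputs; a synthetic generator produces statistically faithful stand-ins
with planted ground truth so that every stage has a recovery test.

## Bioavailability screen

The bioavailability score is the Abbott/Martin rule table: for compounds
predominantly anionic near pH 7, TPSA > 150 Å² → 0.11, 75 < TPSA ≤ 150 →
0.56, TPSA ≤ 75 → 0.85; otherwise rule-of-five pass (≤ 1 violation among
MW ≤ 500 g/mol, logP ≤ 5, HBD ≤ 5, HBA ≤ 10) → 0.55, fail → 0.17. The
screen keeps BS ≥ `bs_min` (default 0.10, inclusive). Note that the rule
table's smallest value is 0.11, so the default threshold never removes a
compound whose score was computed from a profile; the threshold is exposed
as configuration, and an externally supplied `bs` column bypasses the rule
table entirely.

## Similarity-ensemble target prediction

Fingerprints are fixed-length bit vectors; for real structures the default
is a radius-2, 2048-bit Morgan fingerprint (RDKit). For a query q and a
target's ligand set A of size N_A,

    raw(q, A) = Σ_{ℓ∈A} Tc(q, ℓ) · [Tc(q, ℓ) > τ],   τ = 0.45 (strict),

normalized = raw / N_A, and

    Z = (raw − μ·N_A) / (σ·N_A^λ),   λ = 0.335.

The background (μ, σ) is calibrated by sampling random (query, ligand-set)
pairs from the pooled ligand universe: μ is the least-squares slope through
the origin of mean raw score versus set size N, and σ the intercept of a
log–log fit of SD(raw) against N with λ held fixed. By default queries are
drawn from the ligand pool itself (a query never appears in its own
background set); this keeps the background non-degenerate under a high
similarity cutoff even in small, homogeneous databases. Independent random
bit-vector queries are available (`query_source="random"`), but in a
universe of tight ligand sets they essentially never exceed τ and the fit
degenerates — the error message says so. Predictions are reported for
targets with raw > 0 and Z ≥ `z_min` (default 3.0 — the cutoff is a
configuration choice, not a fitted quantity), sorted by Z, ties broken by
normalized score then target id. For single-compound queries the pair
count equals N_A; the set-vs-set generalization (N_query·N_A) exists in
the code but is unused by the pipeline.

## Differential expression

logFC is mean(case) − mean(control) in log2 units; up-regulated means
positive. Two tests are available:

* **welch** — unequal-variance two-sample t (SciPy). Probes with zero
  variance in both groups get the degenerate-limit convention p = 0 if the
  means differ, else 1, and are flagged.
* **moderated** (default) — empirical-Bayes variance shrinkage: pooled
  per-probe variance s² with d = n₁+n₂−2 df, prior (d₀, s₀²) estimated by
  moment matching on log s² via digamma/trigamma (trigamma inverted by
  Newton iteration), s²_post = (d₀s₀² + ds²)/(d₀+d), t = logFC/(s_post·√(1/n₁+1/n₂))
  referred to t with d₀+d df (normal when d₀ = ∞, i.e. when the spread of
  log variances does not exceed sampling noise; the shrunken denominator is
  then effectively non-random, so the normal reference is the correct
  limit). The implementation agrees with limma's `eBayes` to machine
  precision on shared fixtures, and with the ordinary pooled t when the
  prior weight is pinned to zero.

The DEG filter is |logFC| ≥ 0.5 and p ≤ 0.05, both boundary-inclusive, on
unadjusted p-values. Probe→gene collapsing keeps the probe with the largest
|logFC| per gene (ties: smaller p, then probe id); a mean-logFC alternative
exists. Chip-level DEG counts are reported both probe-level and gene-level.
Cross-chip union and the union with disease-gene lists are plain set unions
after upper-casing symbols.

## Networks

Key targets are the exact intersection of predicted target genes with the
disease set. The compound–target graph has one edge per retained prediction
into the key set; isolated nodes are dropped. Betweenness is Brandes on the
unweighted graph, endpoints excluded, each unordered pair counted once,
unnormalized by default (a normalized variant is always emitted alongside).
PPI edges come from STRING-style tables filtered at combined score ≥ 400
("medium confidence", configurable) and restricted to key targets; scores
are kept as edge attributes but never used in path counting. Hub targets
are defined operationally as the key targets that also belong to the
expression-derived DEG union, ranked by degree (ties: betweenness, then
id) and truncated to `hub_top_k` (default 8). Exports are SIF, GraphML and
a node-attribute TSV, all Cytoscape-loadable.

## Enrichment

One-sided hypergeometric over-representation: for overlap k, term size K,
query size n and universe N, p = P(X ≥ k). The universe defaults to the
union of the collection's genes; query genes outside it are dropped with a
warning. BH adjustment runs across all tested terms (every term with at
least one universe gene), rows are reported for k ≥ 1, significance is
p_adj ≤ 0.01 by default with a strict-< variant exposed, and the top 20
significant terms are reported separately.

## Synthetic data

* **Ligand universe** — each target draws a scaffold vector with
  0.2·L set bits (L = 512 by default); each ligand keeps every scaffold bit
  with probability q = 2s/(1+s), giving expected within-set Tanimoto s
  (default 0.7, a realistic congeneric-series similarity). Cross-target
  similarity stays near d/(2−d) ≈ 0.1, far below the 0.45 cutoff.
* **Query compounds** — actives are distinct ligand copies with a few bits
  flipped (default 10 of 512, ≈ 10% of the set bits); decoys are
  independent draws at pool density. Profiles (MW, TPSA, logP, HBD/HBA,
  charge class) are sampled from broad natural-product-like ranges.
* **Expression chips** — per-gene baselines Normal(8, 2) in log2 units
  (series-matrix scale), Normal(0, σ) noise, planted genes shifted by
  ±effect (alternating sign, so both volcano branches are exercised) in
  case samples of both chips; ~10% of genes carry a second probe. Defaults
  effect = 2.0, σ = 0.5.
* **Annotations** — random terms plus one term exactly equal to the
  planted gene set; **PPI** — Erdős–Rényi edges with uniform scores.

All generators are deterministic given their seed; identical seeds produce
byte-identical files.

The demo bundle fixes the study conditions at: 40 targets × 8 ligands,
39 compounds (30 actives + 9 decoys), chips of 20 vs 20 and 5 vs 4 samples
(a large and a small biopsy cohort) over 1200 genes with 40 planted DEGs
(half overlapping the target genes), 50 annotation terms, PPI edge
probability 0.25. These sizes run the full pipeline in a few seconds while
keeping every downstream count non-trivial.

What the generator does **not** emulate: real chemistry (fingerprints are
abstract bit vectors, not molecular substructures), probe-level microarray
artifacts (background, saturation, batch effects), correlated gene
expression, scale-free PPI topology, or annotation-term overlap structure.
Passing recovery tests therefore demonstrates that the statistical
machinery is correct under its own assumptions, not that any particular
biological conclusion transfers to real data.

## Numerical choices and edge cases

* Tanimoto of two all-zero vectors is defined as 0.
* "Greater than the threshold" is strict (Tc > 0.45); the DEG and
  enrichment cutoffs are inclusive (≥, ≤).
* Background fitting requires ≥ 100 samples and raises a descriptive error
  when every sampled raw score is zero; a single set size still yields a
  (one-point) σ fit.
* Series-matrix values with a maximum above 50 are treated as unlogged and
  log2(x+1)-transformed with a warning.
* Hypergeometric tails and BH adjustment are computed by SciPy and
  statsmodels (log-gamma based internally); tests check them against exact
  combinatorial enumeration and a hand step-up.
* All tie-breaks (prediction ranking, probe collapsing, hub ranking, SIF
  ordering) are total and deterministic, so byte-identical reruns are an
  invariant, not an accident.

## Known limitations

* The BS rule table cannot produce values below 0.11, so the default
  0.10 screen is a no-op unless scores are supplied externally.
* The moderated test assumes exchangeable per-probe variances; wildly
  heteroskedastic data will shrink too aggressively.
* The hub definition (key ∩ DEG-union, degree-ranked) is one reasonable
  operationalization; other choices (pure degree top-k, PPI-degree hubs)
  are available through `rank_hubs` but not wired into the report.
* Reproducing published headline counts from real studies requires the
  original database snapshots (ligand sets, GEO matrices, disease lists),
  which are inputs, not artifacts of this package.
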