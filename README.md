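# netpharm

A network-pharmacology pipeline linking a natural product's compounds to
disease genes. It was built around the classic workflow used to study
polyphenol-rich botanical extracts (e.g. pomegranate peel) against
gastrointestinal disease: rule-based oral-bioavailability screening,
ligand-similarity target prediction, microarray differential expression,
compound–target and protein–protein interaction networks, and
over-representation enrichment. Every stage is a plain library function (or
a small fit/predict class), the formats are the field's text formats
(TSV, GMT, SIF, GraphML, GEO series-matrix layout), and a synthetic-data
generator with planted ground truth makes the whole pipeline testable
offline.

## The method

1. **ADME screen.** Each compound gets a bioavailability score (BS) from the
   Abbott/Martin rule table over its charge state and physicochemical
   profile (one of 0.11, 0.17, 0.55, 0.56, 0.85); compounds with
   BS ≥ 0.10 proceed.
2. **Target prediction.** A query fingerprint is scored against each
   target's reference ligand set A (size N_A) by the thresholded similarity
   sum `raw = Σ_ℓ Tc(q, ℓ)·[Tc > 0.45]`, normalized by N_A, and
   standardized against a calibrated random background:

   `Z_A = (raw_A − μ·N_A) / (σ·N_A^0.335)`

   where μ is the expected per-pair contribution for random query/ligand
   pairs and σ the scale of the SD power law, both fitted by sampling
   random ligand sets from the database.
3. **Disease targets.** Per-probe two-group differential expression
   (Welch t or empirical-Bayes moderated t) on case/control chips, the
   filter |logFC| ≥ 0.5 and p ≤ 0.05 (both inclusive), probe→gene
   collapsing, cross-chip union, and union with disease-gene lists.
4. **Networks.** Key targets = predicted ∩ disease targets; a bipartite
   compound–target network plus a score-filtered PPI network, ranked by
   degree and Brandes betweenness centrality; hub targets are the key
   targets that are themselves expression-derived disease genes.
5. **Enrichment.** Hypergeometric over-representation of the key targets
   in GMT annotation collections, Benjamini–Hochberg adjusted, significant
   at p_adj ≤ 0.01, top-20 reported.

## Worked example

```sh
netpharm demo --outdir demo --seed 1     # synthetic inputs + truth tables
netpharm run  --config demo/config.yaml
```

prints

```
demo bundle written; config at demo/config.yaml
pipeline done: 39 compounds kept, 21 predicted targets, 108 DEGs, 21 key targets, 1 significant terms
```

The demo bundle is 39 compounds (30 "actives" copied from target ligands
with small bit perturbations, 9 random decoys) against a 40-target ligand
universe, two expression chips (20 vs 20 and 5 vs 4 samples) with 40
planted differentially expressed genes at ±2 log2 units, disease lists,
an annotation collection with one planted term, and random PPI edges.
All 39 compounds clear the BS ≥ 0.10 screen (the rule table's minimum is
0.11); the 30 actives are predicted back to 21 distinct targets, all of
which are disease-associated, so they become the key targets; the union of
the two chips' gene-level DEG calls (108 genes) contains every planted
gene; and the planted annotation term is the single term passing
p_adj ≤ 0.01, ranked first. Per-stage outputs land in `demo/results/`
(`predictions.tsv`, `deg_union.txt`, `key_targets.txt`, `ct_network.sif`,
`ct_nodes.tsv`, `enrichment.tsv`, `report.json`, ...), all loadable by
Cytoscape or pandas.

The same workflow runs on real inputs: a compound TSV (with SMILES or
precomputed fingerprint columns), a target–ligand table, GEO
series-matrix files with group sidecars, gene lists, a STRING edge export
and GMT collections — see the subcommands `screen`, `predict`, `deg`,
`network`, `enrich`, or drive everything from one YAML config with
`netpharm run`.

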