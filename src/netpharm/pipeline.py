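"""End-to-end pipeline: screen -> predict -> DEG -> intersect -> networks ->
enrichment, driven by a single config, plus a synthetic demo-bundle writer.

Every intermediate is written as plain text (TSV/SIF/GraphML/GMT); identical
config and seed produce an identical output bundle (timings excluded, which
is why they live in a separate file).
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import yaml

from . import __version__
from .admet import screen_compounds
from .degs import (build_disease_targets, collapse_probes,
                   differential_expression, filter_degs, read_series_matrix,
                   union_deg_sets, write_series_matrix)
from .enrich import enrich, read_gmt, top_terms
from .io import (read_compounds_tsv, read_target_db, write_compounds_tsv,
                 write_gene_list, write_predictions_tsv, write_target_db)
from .networks import (build_ct_network, intersect_targets, rank_hubs,
                       read_ppi_edges, write_graphml, write_node_attributes,
                       write_sif)
from .similarity import calibrate_background, fingerprint_from_smiles, \
    predict_targets
from . import synthetic

log = logging.getLogger(__name__)

__all__ = ["RunConfig", "RunReport", "StageError", "run_pipeline", "make_demo"]


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage and cause."""


@dataclass
class RunConfig:
    """All file inputs and thresholds of one pipeline run."""

    compounds: str = ""
    target_db: str = ""
    chips: list[str] = field(default_factory=list)
    groups: list[str] = field(default_factory=list)
    probe_map: str = ""
    disease_lists: list[str] = field(default_factory=list)
    ppi: str = ""
    gmt: str = ""
    outdir: str = "out"
    seed: int = 0

    bs_min: float = 0.10
    tc_threshold: float = 0.45
    z_min: float = 3.0
    lfc_min: float = 0.5
    p_max: float = 0.05
    ppi_score_min: float = 400.0
    p_adj_max: float = 0.01
    de_method: str = "moderated"
    collapse: str = "max_abs_lfc"
    background_samples: int = 2000
    top_k: int = 20
    hub_top_k: int = 8

    def validate(self) -> None:
        if not 0 <= self.bs_min <= 1:
            raise ValueError("bs_min must lie in [0, 1]")
        if not 0 < self.tc_threshold < 1:
            raise ValueError("tc_threshold must lie in (0, 1)")
        if self.lfc_min < 0 or not 0 < self.p_max <= 1:
            raise ValueError("lfc_min/p_max out of range")
        if not 0 < self.p_adj_max <= 1:
            raise ValueError("p_adj_max out of range")
        if len(self.chips) != len(self.groups):
            raise ValueError("need one group sidecar per chip")
        if self.seed is None:
            raise ValueError("seed is mandatory")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        path = Path(path)
        data = yaml.safe_load(path.read_text()) or {}
        cfg = cls(**data)
        base = path.parent
        def resolve(p):
            return str((base / p).resolve()) if p and not Path(p).is_absolute() else p
        cfg.compounds = resolve(cfg.compounds)
        cfg.target_db = resolve(cfg.target_db)
        cfg.chips = [resolve(p) for p in cfg.chips]
        cfg.groups = [resolve(p) for p in cfg.groups]
        cfg.probe_map = resolve(cfg.probe_map)
        cfg.disease_lists = [resolve(p) for p in cfg.disease_lists]
        cfg.ppi = resolve(cfg.ppi)
        cfg.gmt = resolve(cfg.gmt)
        cfg.outdir = resolve(cfg.outdir)
        return cfg

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self),
                                             sort_keys=True))


@dataclass
class RunReport:
    """Per-stage counts of one pipeline run; every count equals a recount of
    the corresponding output file."""

    version: str = __version__
    seed: int = 0
    n_compounds_in: int = 0
    n_compounds_kept: int = 0
    n_compounds_removed: int = 0
    n_predictions: int = 0
    n_predicted_targets: int = 0
    degs_probe_level: list[int] = field(default_factory=list)
    degs_gene_level: list[int] = field(default_factory=list)
    deg_union_size: int = 0
    disease_set_size: int = 0
    n_key_targets: int = 0
    ct_nodes: int = 0
    ct_edges: int = 0
    hub_targets: list[str] = field(default_factory=list)
    ppi_nodes: int = 0
    ppi_edges: int = 0
    n_terms_tested: int = 0
    n_significant_terms: int = 0
    top_term_ids: list[str] = field(default_factory=list)
    config: dict = field(default_factory=dict)

    def to_json(self, path) -> None:
        Path(path).write_text(
            json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)
            + "\n")


def _stage(name: str, fn, *args, **kwargs):
    try:
        return fn(*args, **kwargs)
    except Exception as exc:
        raise StageError(f"stage '{name}' failed: {exc}") from exc


def run_pipeline(config: RunConfig) -> RunReport:
    """Execute the full workflow and write the output bundle to
    ``config.outdir``.  Deterministic for fixed config and seed."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report = RunReport(seed=config.seed,
                       config={k: v for k, v in
                               dataclasses.asdict(config).items()})
    timings: dict[str, float] = {}

    def timed(name, fn, *args, **kwargs):
        t0 = time.perf_counter()
        out = _stage(name, fn, *args, **kwargs)
        timings[name] = round(time.perf_counter() - t0, 3)
        return out

    # -- screen ------------------------------------------------------------
    def do_screen():
        compounds = read_compounds_tsv(config.compounds)
        kept, removed = screen_compounds(compounds, bs_min=config.bs_min)
        write_compounds_tsv(kept, outdir / "screened_compounds.tsv")
        return compounds, kept, removed

    compounds, kept, removed = timed("screen", do_screen)
    report.n_compounds_in = len(compounds)
    report.n_compounds_kept = len(kept)
    report.n_compounds_removed = len(removed)

    # -- predict -----------------------------------------------------------
    def do_predict():
        db = read_target_db(config.target_db)
        model = calibrate_background(
            db, n_samples=config.background_samples,
            tc_threshold=config.tc_threshold, seed=config.seed)
        preds = []
        for c in kept:
            if c.fingerprint is None and c.smiles:
                c.fingerprint = fingerprint_from_smiles(c.smiles)
            if c.fingerprint is None:
                raise ValueError(f"compound {c.id}: no fingerprint or SMILES")
            preds.extend(predict_targets(c, db, model, z_min=config.z_min))
        write_predictions_tsv(preds, outdir / "predictions.tsv")
        (outdir / "background_model.json").write_text(json.dumps(
            {"mu": model.mu, "sigma": model.sigma, "lam": model.lam,
             "tc_threshold": model.tc_threshold, "fit_n": model.fit_n},
            indent=2, sort_keys=True) + "\n")
        return preds

    predictions = timed("predict", do_predict)
    predicted_genes = {p.gene_symbol for p in predictions}
    report.n_predictions = len(predictions)
    report.n_predicted_targets = len(predicted_genes)

    # -- differential expression -------------------------------------------
    def do_deg():
        import pandas as pd
        probe_map = {}
        if config.probe_map:
            df = pd.read_csv(config.probe_map, sep="\t", dtype=str)
            probe_map = dict(zip(df["probe_id"], df["gene_symbol"]))
        per_chip_sets, probe_counts, gene_counts = [], [], []
        for i, (chip, grp) in enumerate(zip(config.chips, config.groups)):
            m = read_series_matrix(chip, groups_path=grp)
            records = differential_expression(m, method=config.de_method)
            passed_probes = filter_degs(records, config.lfc_min, config.p_max)
            gene_records = collapse_probes(records, probe_map,
                                           how=config.collapse)
            passed_genes = filter_degs(gene_records, config.lfc_min,
                                       config.p_max)
            probe_counts.append(len(passed_probes))
            gene_counts.append(len(passed_genes))
            per_chip_sets.append({r.gene_symbol for r in passed_genes})
            pd.DataFrame([dataclasses.asdict(r) for r in gene_records]
                         ).to_csv(outdir / f"degs_chip{i + 1}.tsv",
                                  sep="\t", index=False)
        deg_union = union_deg_sets(per_chip_sets)
        disease = build_disease_targets(deg_union, config.disease_lists)
        write_gene_list(deg_union, outdir / "deg_union.txt")
        write_gene_list(disease, outdir / "disease_targets.txt")
        return per_chip_sets, probe_counts, gene_counts, deg_union, disease

    (per_chip_sets, probe_counts, gene_counts, deg_union,
     disease) = timed("deg", do_deg)
    report.degs_probe_level = probe_counts
    report.degs_gene_level = gene_counts
    report.deg_union_size = len(deg_union)
    report.disease_set_size = len(disease)

    # -- networks ----------------------------------------------------------
    def do_network():
        key = intersect_targets(predicted_genes, disease)
        write_gene_list(key, outdir / "key_targets.txt")
        ct = build_ct_network(predictions, key)
        write_sif(ct, outdir / "ct_network.sif")
        write_graphml(ct, outdir / "ct_network.graphml")
        write_node_attributes(ct, outdir / "ct_nodes.tsv")
        _, hubs = rank_hubs(ct, deg_set=deg_union, top_k=config.hub_top_k)
        write_gene_list(hubs, outdir / "hub_targets.txt")
        ppi = None
        if config.ppi:
            ppi = read_ppi_edges(config.ppi, score_min=config.ppi_score_min,
                                 allowed_nodes=key)
            write_graphml(ppi, outdir / "ppi_network.graphml")
            write_sif(ppi, outdir / "ppi_network.sif")
            write_node_attributes(ppi, outdir / "ppi_nodes.tsv")
        return key, ct, hubs, ppi

    key_targets, ct, hubs, ppi = timed("network", do_network)
    report.n_key_targets = len(key_targets)
    report.ct_nodes = ct.n_nodes
    report.ct_edges = ct.n_edges
    report.hub_targets = hubs
    if ppi is not None:
        report.ppi_nodes = ppi.n_nodes
        report.ppi_edges = ppi.n_edges

    # -- enrichment ---------------------------------------------------------
    def do_enrich():
        import pandas as pd
        if not config.gmt:
            return [], []
        collection = read_gmt(config.gmt)
        rows = enrich(key_targets, collection, p_adj_max=config.p_adj_max)
        pd.DataFrame([dataclasses.asdict(r) for r in rows]
                     ).to_csv(outdir / "enrichment.tsv", sep="\t", index=False)
        top = top_terms(rows, k=config.top_k)
        pd.DataFrame([dataclasses.asdict(r) for r in top]
                     ).to_csv(outdir / "top_terms.tsv", sep="\t", index=False)
        return rows, top

    rows, top = timed("enrich", do_enrich)
    report.n_terms_tested = len(rows)
    report.n_significant_terms = sum(r.significant for r in rows)
    report.top_term_ids = [r.term_id for r in top]

    report.to_json(outdir / "report.json")
    (outdir / "timings.json").write_text(
        json.dumps(timings, indent=2, sort_keys=True) + "\n")
    return report


# --------------------------------------------------------------------------
# demo bundle

#: Demo study conditions: two chips sized like a large and a small biopsy
#: cohort, a 40-target ligand universe, 39 query compounds (30 actives,
#: 9 decoys), strong planted expression shifts.
DEMO = dict(
    n_genes=1200, n_planted=40, effect=2.0, sigma=0.5,
    chip_sizes=[(20, 20), (5, 4)],
    n_targets=40, ligands_per_target=8, fp_length=512,
    within_set_similarity=0.7,
    n_actives=30, n_decoys=9, perturb_bits=10,
    n_terms=50, term_size_range=(10, 60),
    ppi_edge_prob=0.25, ppi_score_range=(150, 999),
)


def make_demo(outdir, seed: int = 0) -> Path:
    """Write a complete synthetic input bundle plus truth tables.

    Returns the path of the generated ``config.yaml``; the bundle feeds
    :func:`run_pipeline` unchanged and runs in seconds.
    """
    import pandas as pd
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    d = DEMO

    genes = [f"GENE{i + 1:04d}" for i in range(d["n_genes"])]
    target_genes = genes[:d["n_targets"]]
    # planted DEGs: half overlap the target genes, half do not
    planted = target_genes[:20] + genes[100:120]

    universe, _ = synthetic.generate_ligand_universe(
        d["n_targets"], d["ligands_per_target"], d["fp_length"],
        d["within_set_similarity"], seed=seed, gene_symbols=target_genes)
    compounds, truth_c = synthetic.generate_query_compounds(
        universe, d["n_actives"], d["n_decoys"], d["perturb_bits"],
        seed=seed + 1)
    chips, truth_e = synthetic.generate_expression_chips(
        d["n_genes"], 0, 0, len(planted), effect=d["effect"],
        sigma=d["sigma"], seed=seed + 2, planted_genes=planted,
        chip_sizes=d["chip_sizes"])

    rng = np.random.default_rng(seed + 3)
    # disease lists cover the remaining target genes plus random background
    extra = [g for g in rng.choice(genes[200:], size=180, replace=False)]
    list1 = target_genes[20:] + extra[:120]
    list2 = extra[100:]

    terms, truth_t = synthetic.generate_annotations(
        genes, d["n_terms"], d["term_size_range"],
        planted_term_genes=set(target_genes[:10]), seed=seed + 4)
    ppi = synthetic.generate_ppi_edges(
        target_genes, d["ppi_edge_prob"], d["ppi_score_range"], seed=seed + 5)

    # write the bundle
    write_compounds_tsv(compounds, outdir / "compounds.tsv")
    write_target_db(universe, outdir / "target_db.tsv")
    for i, m in enumerate(chips):
        write_series_matrix(m, outdir / f"chip{i + 1}.tsv",
                            groups_path=outdir / f"groups{i + 1}.tsv")
    pd.DataFrame(sorted(truth_e.probe_gene_map.items()),
                 columns=["probe_id", "gene_symbol"]
                 ).to_csv(outdir / "probe_map.tsv", sep="\t", index=False)
    write_gene_list(list1, outdir / "disease_db1.txt")
    write_gene_list(list2, outdir / "disease_db2.txt")
    from .enrich import write_gmt
    write_gmt(terms, outdir / "annotations.gmt")
    ppi.to_csv(outdir / "ppi_edges.tsv", sep="\t", index=False)

    truth = {
        "planted_deg_genes": sorted(truth_e.planted_deg_genes),
        "planted_signs": truth_e.planted_signs,
        "planted_effect": truth_e.planted_effect,
        "active_pairs": sorted(list(truth_c.active_pairs)),
        "enriched_terms": sorted(truth_t.enriched_terms),
        "target_genes": {t.target_id: t.gene_symbol for t in universe},
        "seed": seed,
    }
    (outdir / "truth.json").write_text(json.dumps(truth, indent=2,
                                                  sort_keys=True) + "\n")

    cfg = RunConfig(
        compounds="compounds.tsv", target_db="target_db.tsv",
        chips=[f"chip{i + 1}.tsv" for i in range(len(chips))],
        groups=[f"groups{i + 1}.tsv" for i in range(len(chips))],
        probe_map="probe_map.tsv",
        disease_lists=["disease_db1.txt", "disease_db2.txt"],
        ppi="ppi_edges.tsv", gmt="annotations.gmt",
        outdir="results", seed=seed)
    cfg.to_yaml(outdir / "config.yaml")
    return outdir / "config.yaml"
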