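"""Synthetic pipeline inputs with known ground truth.

Every downstream stage (screening, target prediction, differential
expression, network construction, enrichment) gets inputs whose planted
signal is recorded in a :class:`SyntheticTruth`, so recovery can be tested
without any database download.  Only the statistical structure the pipeline
assumes is emulated — mutually similar ligands within a target set, log2
expression with planted fold-change shifts, annotation sets with one planted
term, Erdős–Rényi PPI edges — not real chemistry or biology.

Fingerprints here are plain fixed-length bit vectors: each target has a
hidden "scaffold" bit vector and its ligands keep each scaffold bit
independently with probability q = 2s/(1+s), giving expected within-set
pairwise Tanimoto q/(2-q) = s, the requested similarity.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .admet import Compound, PhyschemProfile
from .similarity import TargetSet
from .degs import ExpressionMatrix
from .enrich import GeneSet

__all__ = [
    "SyntheticTruth",
    "generate_ligand_universe",
    "generate_query_compounds",
    "generate_expression_chips",
    "generate_annotations",
    "generate_ppi_edges",
]


@dataclass
class SyntheticTruth:
    """Ground truth planted by the generators."""

    planted_deg_genes: set[str] = field(default_factory=set)
    planted_effect: float = 0.0
    active_pairs: set[tuple[str, str]] = field(default_factory=set)
    enriched_terms: set[str] = field(default_factory=set)
    seed: int = 0
    probe_gene_map: dict[str, str] = field(default_factory=dict)
    planted_signs: dict[str, int] = field(default_factory=dict)


def generate_ligand_universe(
    n_targets: int,
    ligands_per_target: int = 8,
    fp_length: int = 512,
    within_set_similarity: float = 0.7,
    seed: int = 0,
    density: float = 0.2,
    gene_symbols: Optional[Sequence[str]] = None,
) -> tuple[list[TargetSet], SyntheticTruth]:
    """Target sets whose ligands are mutually similar bit vectors.

    Each target draws a scaffold vector with ``density * fp_length`` set
    bits; each ligand keeps every scaffold bit independently with
    probability ``q = 2s/(1+s)`` where ``s`` is the requested within-set
    similarity, so E[Tanimoto] between two ligands of one set is ``s``.
    Ligands of different targets are independent draws.
    """
    if n_targets < 0 or fp_length <= 0:
        raise ValueError("counts must be positive")
    if not 0 < within_set_similarity < 1:
        raise ValueError("within_set_similarity must lie in (0, 1)")
    truth = SyntheticTruth(seed=seed)
    if n_targets == 0:
        return [], truth
    if ligands_per_target < 2:
        raise ValueError("ligands_per_target must be at least 2")

    rng = np.random.default_rng(seed)
    q = 2.0 * within_set_similarity / (1.0 + within_set_similarity)
    k = max(int(round(density * fp_length)), 4)
    targets = []
    for i in range(n_targets):
        scaffold_idx = rng.choice(fp_length, size=k, replace=False)
        keep = rng.random((ligands_per_target, k)) < q
        ligands = np.zeros((ligands_per_target, fp_length), dtype=np.uint8)
        for j in range(ligands_per_target):
            ligands[j, scaffold_idx[keep[j]]] = 1
        sym = (gene_symbols[i] if gene_symbols is not None
               else f"TGT{i + 1:03d}")
        targets.append(TargetSet(target_id=f"T{i + 1:03d}",
                                 gene_symbol=sym, ligands=ligands))
    return targets, truth


def _synthetic_profile(rng: np.random.Generator) -> PhyschemProfile:
    return PhyschemProfile(
        mw=float(rng.uniform(150, 700)),
        tpsa=float(rng.uniform(20, 220)),
        logp=float(rng.uniform(-1, 6)),
        hbd=int(rng.integers(0, 9)),
        hba=int(rng.integers(1, 13)),
        anionic=bool(rng.random() < 0.3),
    )


def generate_query_compounds(
    universe: Sequence[TargetSet],
    n_actives: int,
    n_decoys: int,
    perturb_bits: int = 10,
    seed: int = 0,
) -> tuple[list[Compound], SyntheticTruth]:
    """Query compounds: actives copied (with bit flips) from target ligands.

    Actives are exact copies of distinct, randomly chosen ligands with
    ``perturb_bits`` random bit positions flipped; the source target is
    recorded in ``truth.active_pairs``.  Decoys are independent bit vectors
    at the pooled ligand density.  Every compound carries a synthetic
    physicochemical profile for the screening stage.
    """
    if n_actives < 0 or n_decoys < 0:
        raise ValueError("counts must be nonnegative")
    if not universe:
        raise ValueError("universe must be nonempty")
    fp_length = universe[0].fp_length
    if perturb_bits >= fp_length:
        raise ValueError("perturb_bits must be smaller than the "
                         "fingerprint length")
    pool = np.vstack([t.ligands for t in universe])
    owner = np.concatenate([[t.target_id] * t.n_ligands for t in universe])
    if n_actives > pool.shape[0]:
        raise ValueError("n_actives exceeds the universe's ligand count")

    rng = np.random.default_rng(seed)
    truth = SyntheticTruth(seed=seed)
    compounds: list[Compound] = []
    src = rng.choice(pool.shape[0], size=n_actives, replace=False)
    for i, s in enumerate(src):
        fp = pool[s].copy()
        if perturb_bits > 0:
            flip = rng.choice(fp_length, size=perturb_bits, replace=False)
            fp[flip] ^= 1
        cid = f"C{i + 1:03d}"
        compounds.append(Compound(id=cid, name=f"active-{i + 1}",
                                  cls="Polyphenols",
                                  profile=_synthetic_profile(rng),
                                  fingerprint=fp))
        truth.active_pairs.add((cid, str(owner[s])))
    density = float(pool.mean())
    for i in range(n_decoys):
        fp = (rng.random(fp_length) < density).astype(np.uint8)
        compounds.append(Compound(id=f"C{n_actives + i + 1:03d}",
                                  name=f"decoy-{i + 1}", cls="Alkaloids",
                                  profile=_synthetic_profile(rng),
                                  fingerprint=fp))
    return compounds, truth


def generate_expression_chips(
    n_genes: int,
    n_case: int,
    n_control: int,
    n_planted: int,
    effect: float = 2.0,
    sigma: float = 0.5,
    seed: int = 0,
    duplicate_probe_frac: float = 0.1,
    planted_genes: Optional[Sequence[str]] = None,
    chip_sizes: Optional[Sequence[tuple[int, int]]] = None,
) -> tuple[list[ExpressionMatrix], SyntheticTruth]:
    """Two case/control chips with a shared planted DEG set.

    Values are gene baselines (Normal(8, 2) in log2 units, per chip) plus
    Normal(0, sigma) noise.  Planted genes receive +effect or -effect
    (alternating) in case samples only, identically on both chips; noise is
    independent between chips.  A fraction of genes gets a second probe so
    probe-to-gene collapsing is exercised; the probe map is recorded on the
    truth object.  ``chip_sizes`` overrides (n_case, n_control) per chip.
    """
    if n_planted > n_genes:
        raise ValueError("n_planted cannot exceed n_genes")
    if effect < 0:
        raise ValueError("effect must be nonnegative")
    sizes = list(chip_sizes) if chip_sizes is not None \
        else [(n_case, n_control), (n_case, n_control)]
    for nc, nk in sizes:
        if nc < 2 or nk < 2:
            raise ValueError("each group needs at least 2 samples "
                             "(variance undefined otherwise)")

    rng = np.random.default_rng(seed)
    genes = [f"GENE{i + 1:04d}" for i in range(n_genes)]
    if planted_genes is None:
        planted = list(rng.choice(genes, size=n_planted, replace=False))
    else:
        planted = [g.upper() for g in planted_genes]
        if not set(planted) <= set(genes):
            raise ValueError("planted_genes must be drawn from the "
                             "generated gene universe")
    signs = {g: (1 if i % 2 == 0 else -1) for i, g in enumerate(planted)}

    n_dup = int(round(duplicate_probe_frac * n_genes))
    dup_genes = list(rng.choice(genes, size=n_dup, replace=False))
    probe_gene: list[tuple[str, str]] = []
    pnum = 0
    for g in genes:
        pnum += 1
        probe_gene.append((f"P{pnum:06d}_at", g))
    for g in dup_genes:
        pnum += 1
        probe_gene.append((f"P{pnum:06d}_at", g))

    truth = SyntheticTruth(planted_deg_genes=set(planted),
                           planted_effect=effect, seed=seed,
                           probe_gene_map=dict(probe_gene),
                           planted_signs=signs)

    chips = []
    for ci, (nc, nk) in enumerate(sizes):
        baseline = {g: rng.normal(8.0, 2.0) for g in genes}
        samples = ([f"CH{ci + 1}_CASE{j + 1:02d}" for j in range(nc)]
                   + [f"CH{ci + 1}_CTRL{j + 1:02d}" for j in range(nk)])
        groups = {s: ("case" if "CASE" in s else "control") for s in samples}
        values = np.empty((len(probe_gene), nc + nk))
        for r, (pid, g) in enumerate(probe_gene):
            row = baseline[g] + rng.normal(0.0, sigma, size=nc + nk)
            if g in signs:
                row[:nc] += signs[g] * effect
            values[r] = row
        chips.append(ExpressionMatrix(
            probe_ids=[p for p, _ in probe_gene], sample_ids=samples,
            values=values, groups=groups, platform=f"SYN{ci + 1}"))
    return chips, truth


def generate_annotations(
    genes: Sequence[str],
    n_terms: int,
    term_size_range: tuple[int, int] = (10, 60),
    planted_term_genes: Optional[set[str]] = None,
    seed: int = 0,
) -> tuple[list[GeneSet], SyntheticTruth]:
    """Random annotation terms plus one term equal to the planted gene set."""
    genes = [g.upper() for g in genes]
    lo, hi = term_size_range
    if hi > len(genes):
        raise ValueError("term sizes cannot exceed the gene universe")
    if n_terms < 0:
        raise ValueError("n_terms must be nonnegative")
    truth = SyntheticTruth(seed=seed)
    planted = {g.upper() for g in planted_term_genes} if planted_term_genes \
        else set()
    if planted and not planted <= set(genes):
        raise ValueError("planted term genes must lie inside the universe")

    rng = np.random.default_rng(seed)
    out: list[GeneSet] = []
    start = 0
    if planted and n_terms >= 1:
        out.append(GeneSet(term_id="TERM0001", term_name="planted",
                           genes=frozenset(planted)))
        truth.enriched_terms.add("TERM0001")
        start = 1
    for i in range(start, n_terms):
        size = int(rng.integers(lo, hi + 1))
        members = rng.choice(genes, size=size, replace=False)
        out.append(GeneSet(term_id=f"TERM{i + 1:04d}",
                           term_name=f"random-{i + 1}",
                           genes=frozenset(members)))
    return out, truth


def generate_ppi_edges(
    nodes: Sequence[str],
    edge_prob: float,
    score_range: tuple[float, float] = (400, 999),
    seed: int = 0,
) -> pd.DataFrame:
    """Erdős–Rényi edges with uniform combined scores, STRING column layout."""
    if not 0 <= edge_prob <= 1:
        raise ValueError("edge_prob must lie in [0, 1]")
    lo, hi = score_range
    rng = np.random.default_rng(seed)
    nodes = [str(n).upper() for n in nodes]
    rows = []
    for i in range(len(nodes)):
        for j in range(i + 1, len(nodes)):
            if rng.random() < edge_prob:
                rows.append((nodes[i], nodes[j],
                             int(round(rng.uniform(lo, hi)))))
    return pd.DataFrame(rows, columns=["node1", "node2", "combined_score"])
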