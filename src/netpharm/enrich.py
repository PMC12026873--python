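"""Over-representation (hypergeometric) gene-set enrichment with BH control.

For a query gene set of size n drawn from a universe of N genes, a term with
K members in the universe, and an overlap of k genes, the enrichment p-value
is the hypergeometric upper tail P(X >= k).  p-values are adjusted across
all tested terms by Benjamini-Hochberg step-up and thresholded at
``p_adj <= 0.01`` by default.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "GeneSet",
    "EnrichmentRow",
    "read_gmt",
    "write_gmt",
    "hypergeom_tail",
    "bh_adjust",
    "enrich",
    "top_terms",
]


@dataclass
class GeneSet:
    """An annotation term (GO term, pathway, ...) and its member genes."""

    term_id: str
    term_name: str
    genes: frozenset[str]
    namespace: str = "pathway"

    def __post_init__(self) -> None:
        self.genes = frozenset(g.upper() for g in self.genes)
        if not self.genes:
            raise ValueError(f"term {self.term_id}: empty gene set")


@dataclass
class EnrichmentRow:
    term_id: str
    term_name: str
    k: int      # overlap with the query
    K: int      # term size within the universe
    n: int      # query size within the universe
    N: int      # universe size
    p: float
    p_adj: float
    significant: bool


def read_gmt(path) -> list[GeneSet]:
    """One term per line: id <TAB> description <TAB> gene ... (GMT layout)."""
    out = []
    for lineno, ln in enumerate(Path(path).read_text().splitlines(), start=1):
        if not ln.strip():
            continue
        cells = ln.rstrip("\n").split("\t")
        if len(cells) < 3:
            raise ValueError(f"{path}:{lineno}: GMT line needs id, "
                             "description and at least one gene")
        out.append(GeneSet(term_id=cells[0], term_name=cells[1],
                           genes=frozenset(c for c in cells[2:] if c)))
    return out


def write_gmt(collection: Iterable[GeneSet], path) -> None:
    with Path(path).open("w") as fh:
        for gs in collection:
            fh.write("\t".join([gs.term_id, gs.term_name]
                               + sorted(gs.genes)) + "\n")


def hypergeom_tail(k: int, K: int, n: int, N: int) -> float:
    """Upper tail P(X >= k) for X ~ Hypergeometric(N, K, n)."""
    if not (0 <= k <= min(K, n) <= N) or K > N or n > N:
        raise ValueError(f"inconsistent counts k={k}, K={K}, n={n}, N={N}")
    if k == 0:
        return 1.0
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def bh_adjust(pvals: Sequence[float]) -> list[float]:
    """Benjamini-Hochberg step-up adjusted p-values, original order kept."""
    p = np.asarray(list(pvals), dtype=float)
    if p.size == 0:
        return []
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1].tolist()


def enrich(
    query: set[str],
    collection: Sequence[GeneSet],
    universe: Optional[set[str]] = None,
    p_adj_max: float = 0.01,
    strict: bool = False,
) -> list[EnrichmentRow]:
    """Over-representation of ``query`` in each term of ``collection``.

    The universe defaults to the union of all genes in the collection; query
    genes outside it are dropped with a warning.  BH adjustment runs across
    every tested term (any term with at least one universe gene); rows are
    returned for terms with overlap k >= 1, sorted by (p_adj, p, term_id).
    ``strict`` switches the significance comparator from ``p_adj <= cutoff``
    to ``p_adj < cutoff``.
    """
    if universe is None:
        universe = set()
        for gs in collection:
            universe |= gs.genes
    universe = {g.upper() for g in universe}
    if not universe:
        raise ValueError("empty universe")

    query = {g.upper() for g in query}
    dropped = query - universe
    if dropped:
        warnings.warn(f"{len(dropped)} query genes outside the universe "
                      "dropped", stacklevel=2)
    query &= universe
    n, N = len(query), len(universe)

    tested: list[tuple[GeneSet, int, int, float]] = []
    for gs in collection:
        genes = gs.genes & universe
        K = len(genes)
        if K == 0:
            continue
        k = len(genes & query)
        tested.append((gs, k, K, hypergeom_tail(k, K, n, N)))
    if not tested:
        return []

    p_adj = bh_adjust([t[3] for t in tested])
    rows = []
    for (gs, k, K, p), pa in zip(tested, p_adj):
        if k < 1:
            continue
        sig = pa < p_adj_max if strict else pa <= p_adj_max
        rows.append(EnrichmentRow(term_id=gs.term_id, term_name=gs.term_name,
                                  k=k, K=K, n=n, N=N, p=p, p_adj=pa,
                                  significant=sig))
    rows.sort(key=lambda r: (r.p_adj, r.p, r.term_id))
    return rows


def top_terms(rows: Sequence[EnrichmentRow], k: int = 20) -> list[EnrichmentRow]:
    """First ``k`` significant rows of an already-sorted result."""
    return [r for r in rows if r.significant][:k]
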