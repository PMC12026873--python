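"""Ligand-similarity ensemble target prediction.

A query compound is scored against a protein target by summing the Tanimoto
coefficients between the query fingerprint and every reference ligand of the
target that exceeds a similarity threshold (default 0.45).  The raw score is
standardized against a random background model in which the expected score
grows linearly with the ligand-set size ``N`` and its standard deviation
follows a power law ``sigma * N**lam`` (``lam`` fixed at 0.335):

    Z = (raw - mu * N) / (sigma * N**lam)

High Z means the query is more similar to the target's known ligands than a
random compound drawn from the ligand universe would be.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "TargetSet",
    "BackgroundModel",
    "PredictionScore",
    "tanimoto",
    "tanimoto_to_set",
    "raw_score",
    "raw_score_set",
    "calibrate_background",
    "z_score",
    "predict_targets",
    "fingerprint_from_smiles",
    "SimilarityEnsemble",
]


def _as_fingerprint(fp) -> np.ndarray:
    fp = np.asarray(fp, dtype=np.uint8)
    if fp.ndim != 1:
        raise ValueError("fingerprint must be a 1-D bit vector")
    return fp


@dataclass
class TargetSet:
    """A protein target with its reference ligand fingerprints.

    ``ligands`` is an ``(N_A, length)`` uint8 array of 0/1 bits; ``N_A`` is
    the number of reference ligands.
    """

    target_id: str
    gene_symbol: str
    ligands: np.ndarray

    def __post_init__(self) -> None:
        self.ligands = np.atleast_2d(np.asarray(self.ligands, dtype=np.uint8))
        if self.ligands.shape[0] < 1:
            raise ValueError(f"target {self.target_id}: needs at least one ligand")

    @property
    def n_ligands(self) -> int:
        return int(self.ligands.shape[0])

    @property
    def fp_length(self) -> int:
        return int(self.ligands.shape[1])


@dataclass
class BackgroundModel:
    """Random-background calibration of the raw similarity score.

    mu     : expected raw score per ligand pair.
    sigma  : scale coefficient of the SD power law ``SD(raw) = sigma * N**lam``.
    lam    : power-law exponent (0.335 by convention).
    tc_threshold : Tanimoto cutoff used when the model was fitted.
    fit_n  : number of background samples used in the fit.
    """

    mu: float
    sigma: float
    lam: float = 0.335
    tc_threshold: float = 0.45
    fit_n: int = 0

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        if not 0 < self.tc_threshold < 1:
            raise ValueError("tc_threshold must lie in (0, 1)")
        if not 0 < self.lam < 1:
            raise ValueError("lam must lie in (0, 1)")


@dataclass(order=False)
class PredictionScore:
    """Score of one (compound, target) pair."""

    compound_id: str
    target_id: str
    gene_symbol: str
    raw: float
    n_pairs: int
    normalized: float
    z: float


def tanimoto(a, b) -> float:
    """Tanimoto coefficient |a AND b| / |a OR b| of two bit vectors.

    Defined as 0.0 when both vectors are all-zero.
    """
    a = _as_fingerprint(a)
    b = _as_fingerprint(b)
    if a.shape != b.shape:
        raise ValueError(f"fingerprint length mismatch: {a.size} vs {b.size}")
    union = int(np.count_nonzero(a | b))
    if union == 0:
        return 0.0
    return int(np.count_nonzero(a & b)) / union


def tanimoto_to_set(query, ligands: np.ndarray) -> np.ndarray:
    """Vectorized Tanimoto of one query against the rows of a ligand matrix."""
    query = _as_fingerprint(query)
    ligands = np.atleast_2d(np.asarray(ligands, dtype=np.uint8))
    if ligands.shape[1] != query.size:
        raise ValueError(
            f"fingerprint length mismatch: {query.size} vs {ligands.shape[1]}"
        )
    inter = ligands @ query.astype(np.int64)
    union = ligands.sum(axis=1, dtype=np.int64) + int(query.sum(dtype=np.int64)) - inter
    with np.errstate(invalid="ignore"):
        tc = np.where(union > 0, inter / np.maximum(union, 1), 0.0)
    return tc


def raw_score(query, target: TargetSet, tc_threshold: float = 0.45) -> tuple[float, int]:
    """Sum of Tanimoto coefficients strictly above ``tc_threshold``.

    Returns ``(raw, n_pairs)`` where ``n_pairs`` is the target's ligand count.
    """
    if target.n_ligands < 1:
        raise ValueError("target has no ligands")
    tc = tanimoto_to_set(query, target.ligands)
    raw = float(tc[tc > tc_threshold].sum())
    return raw, target.n_ligands


def raw_score_set(queries: np.ndarray, target: TargetSet,
                  tc_threshold: float = 0.45) -> tuple[float, int]:
    """Set-vs-set raw score: thresholded Tanimoto sum over all
    query-ligand pairs; ``n_pairs = N_query * N_A``.

    Generalizes :func:`raw_score`, which is the single-query case.  Unused
    by the pipeline (compounds are scored one at a time) but exposed for
    ensemble-vs-ensemble comparisons.
    """
    queries = np.atleast_2d(np.asarray(queries, dtype=np.uint8))
    if target.n_ligands < 1:
        raise ValueError("target has no ligands")
    raw = 0.0
    for q in queries:
        tc = tanimoto_to_set(q, target.ligands)
        raw += float(tc[tc > tc_threshold].sum())
    return raw, queries.shape[0] * target.n_ligands


def _random_queries(rng: np.random.Generator, n: int, pool: np.ndarray,
                    source: str) -> np.ndarray:
    if source == "pool":
        idx = rng.integers(0, pool.shape[0], size=n)
        return pool[idx]
    if source == "random":
        density = float(pool.mean())
        return (rng.random((n, pool.shape[1])) < density).astype(np.uint8)
    raise ValueError(f"unknown query source {source!r}")


def calibrate_background(
    universe: Sequence[TargetSet],
    set_sizes: Sequence[int] | None = None,
    n_samples: int = 2000,
    tc_threshold: float = 0.45,
    seed: int = 0,
    lam: float = 0.335,
    query_source: str = "pool",
) -> BackgroundModel:
    """Fit the (mu, sigma) background model on random query/ligand-set pairs.

    For each size ``N`` in ``set_sizes`` the sampler draws a random query
    fingerprint and ``N`` random ligands from the pooled universe, records the
    raw score, and then fits

      * ``mu``    -- least-squares slope through the origin of mean raw vs N;
      * ``sigma`` -- log-log least squares of ``SD(raw) = sigma * N**lam``
        with ``lam`` held fixed, over sizes with nonzero SD.

    ``query_source='pool'`` draws queries from the ligand pool itself (the
    query's own sampled set excludes it), which keeps the background
    non-degenerate even under a high Tanimoto cutoff; ``'random'`` draws
    independent bit vectors at the pool's bit density.
    """
    if not universe:
        raise ValueError("universe must be nonempty")
    if n_samples < 100:
        raise ValueError("n_samples must be at least 100")
    if set_sizes is None:
        set_sizes = sorted({t.n_ligands for t in universe})
    set_sizes = [int(s) for s in set_sizes]
    if any(s < 1 for s in set_sizes):
        raise ValueError("set sizes must be positive")

    rng = np.random.default_rng(seed)
    pool = np.vstack([t.ligands for t in universe])
    n_per = max(n_samples // len(set_sizes), 50)

    mean_by_size: list[tuple[int, float, float]] = []
    total = 0
    any_nonzero = False
    n_pool = pool.shape[0]
    for size in set_sizes:
        if query_source == "pool":
            q_idx = rng.integers(0, n_pool, size=n_per)
            queries = pool[q_idx]
        else:
            q_idx = np.full(n_per, -1)
            queries = _random_queries(rng, n_per, pool, query_source)
        raws = np.empty(n_per)
        for i in range(n_per):
            # a pool query never appears in its own background set
            avail = n_pool - (1 if q_idx[i] >= 0 else 0)
            idx = rng.choice(avail, size=size, replace=avail < size)
            if q_idx[i] >= 0:
                idx = idx + (idx >= q_idx[i])
            tc = tanimoto_to_set(queries[i], pool[idx])
            raws[i] = tc[tc > tc_threshold].sum()
        total += n_per
        if np.any(raws > 0):
            any_nonzero = True
        sd = float(raws.std(ddof=1)) if n_per > 1 else 0.0
        mean_by_size.append((size, float(raws.mean()), sd))

    if not any_nonzero:
        raise ValueError(
            "background degenerate; lower tc_threshold or enlarge samples"
        )

    sizes = np.array([s for s, _, _ in mean_by_size], dtype=float)
    means = np.array([m for _, m, _ in mean_by_size])
    sds = np.array([s for _, _, s in mean_by_size])

    mu = float((sizes * means).sum() / (sizes**2).sum())

    pos = sds > 0
    if not np.any(pos):
        raise ValueError(
            "background degenerate; lower tc_threshold or enlarge samples"
        )
    # log SD = log sigma + lam * log N, lam fixed -> average the intercept
    log_sigma = float(np.mean(np.log(sds[pos]) - lam * np.log(sizes[pos])))
    sigma = float(np.exp(log_sigma))

    return BackgroundModel(mu=mu, sigma=sigma, lam=lam,
                           tc_threshold=tc_threshold, fit_n=total)


def z_score(raw: float, n_pairs: int, model: BackgroundModel) -> float:
    """Standardized similarity-ensemble score for one (query, target) pair."""
    if n_pairs < 1:
        raise ValueError("n_pairs must be at least 1")
    return float((raw - model.mu * n_pairs) / (model.sigma * n_pairs**model.lam))


def predict_targets(
    compound,
    db: Sequence[TargetSet],
    model: BackgroundModel,
    z_min: float = 3.0,
) -> list[PredictionScore]:
    """Score one compound against every target set.

    Returns one :class:`PredictionScore` per target with raw score > 0 and
    Z >= ``z_min``, sorted by Z descending (ties: normalized score descending,
    then target id).  ``compound`` must expose ``id`` and ``fingerprint``.
    """
    fp = getattr(compound, "fingerprint", None)
    if fp is None:
        raise ValueError(f"compound {getattr(compound, 'id', compound)!r} "
                         "has no fingerprint")
    out: list[PredictionScore] = []
    for target in db:
        raw, n = raw_score(fp, target, model.tc_threshold)
        if raw <= 0:
            continue
        z = z_score(raw, n, model)
        if z < z_min:
            continue
        out.append(PredictionScore(
            compound_id=compound.id,
            target_id=target.target_id,
            gene_symbol=target.gene_symbol,
            raw=raw,
            n_pairs=n,
            normalized=raw / n,
            z=z,
        ))
    out.sort(key=lambda s: (-s.z, -s.normalized, s.target_id))
    return out


def fingerprint_from_smiles(smiles: str, n_bits: int = 2048,
                            radius: int = 2) -> np.ndarray:
    """Morgan (circular, radius-2 by default) fingerprint of a SMILES string.

    Requires RDKit.  Canonically equivalent SMILES map to identical bit
    vectors because the fingerprint is computed on the parsed molecule.
    """
    from rdkit import Chem
    from rdkit.Chem import rdFingerprintGenerator

    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"unparseable SMILES: {smiles!r}")
    gen = rdFingerprintGenerator.GetMorganGenerator(radius=radius, fpSize=n_bits)
    bv = gen.GetFingerprint(mol)
    arr = np.zeros(n_bits, dtype=np.uint8)
    for bit in bv.GetOnBits():
        arr[bit] = 1
    return arr


class SimilarityEnsemble:
    """Fit-then-predict wrapper around background calibration and scoring.

    Parameters
    ----------
    tc_threshold : Tanimoto cutoff for a ligand pair to contribute to the
        raw score (strictly greater than).
    z_min : minimum Z for a prediction to be reported.
    n_samples : background samples for calibration.
    random_state : seed for the background sampler.
    """

    def __init__(self, tc_threshold: float = 0.45, z_min: float = 3.0,
                 lam: float = 0.335, n_samples: int = 2000,
                 set_sizes: Sequence[int] | None = None,
                 query_source: str = "pool", random_state: int = 0):
        self.tc_threshold = tc_threshold
        self.z_min = z_min
        self.lam = lam
        self.n_samples = n_samples
        self.set_sizes = set_sizes
        self.query_source = query_source
        self.random_state = random_state

    def fit(self, universe: Sequence[TargetSet]) -> "SimilarityEnsemble":
        self.universe_ = list(universe)
        self.background_ = calibrate_background(
            self.universe_, set_sizes=self.set_sizes, n_samples=self.n_samples,
            tc_threshold=self.tc_threshold, seed=self.random_state,
            lam=self.lam, query_source=self.query_source)
        return self

    def predict(self, compounds: Iterable) -> dict[str, list[PredictionScore]]:
        if not hasattr(self, "background_"):
            raise RuntimeError("SimilarityEnsemble is not fitted; call fit first")
        return {c.id: predict_targets(c, self.universe_, self.background_,
                                      self.z_min)
                for c in compounds}
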