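"""Two-group differential expression for microarray-style matrices.

Per-probe log2 fold change (case minus control) with either a Welch
two-sample t-test or an empirical-Bayes moderated t-test; boundary-inclusive
filtering on |logFC| and p; probe-to-gene collapsing; cross-chip union; and
union with disease gene lists.

The moderated test shrinks per-probe sample variances toward a common prior
estimated by moment matching on the log sample variances: with per-probe
residual df ``d`` and prior df/variance ``(d0, s0^2)``,

    s_post^2 = (d0 * s0^2 + d * s^2) / (d0 + d)
    t = logFC / (s_post * sqrt(1/n1 + 1/n2)),   df = d0 + d.

(d0, s0^2) come from matching the mean and variance of log(s^2) to the
scaled-F sampling theory via digamma/trigamma functions.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import special, stats

log = logging.getLogger(__name__)

__all__ = [
    "ExpressionMatrix",
    "DEGRecord",
    "ParseError",
    "read_series_matrix",
    "write_series_matrix",
    "differential_expression",
    "filter_degs",
    "collapse_probes",
    "union_deg_sets",
    "read_gene_list",
    "build_disease_targets",
]

TABLE_BEGIN = "!series_matrix_table_begin"
TABLE_END = "!series_matrix_table_end"


class ParseError(ValueError):
    pass


@dataclass
class ExpressionMatrix:
    """Probes-by-samples log2 expression with case/control labels."""

    probe_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray
    groups: dict[str, str]
    platform: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.probe_ids), len(self.sample_ids)):
            raise ValueError("values shape does not match probe/sample ids")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("expression values must be finite")
        missing = [s for s in self.sample_ids if s not in self.groups]
        if missing:
            raise ValueError(f"samples missing group labels: {missing}")
        bad = {g for g in self.groups.values()} - {"case", "control"}
        if bad:
            raise ValueError(f"unknown group labels: {sorted(bad)}")

    def group_columns(self, group: str) -> np.ndarray:
        return np.array([i for i, s in enumerate(self.sample_ids)
                         if self.groups[s] == group], dtype=int)


@dataclass
class DEGRecord:
    """Per-probe (or per-gene after collapsing) differential-expression call."""

    probe_id: str
    gene_symbol: str
    logfc: float
    p: float
    passed: bool = False
    direction: str = "up"
    degenerate: bool = False


def _read_groups_sidecar(path) -> dict[str, str]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    cols = [c.lower() for c in df.columns]
    if "sample_id" in cols and "group" in cols:
        df.columns = cols
    else:  # headerless two-column file
        df = pd.read_csv(path, sep="\t", dtype=str, header=None,
                         names=["sample_id", "group"])
    return dict(zip(df["sample_id"], df["group"].str.lower()))


def read_series_matrix(path, groups_path=None, platform: str = "") -> ExpressionMatrix:
    """Parse a GEO series-matrix-style file.

    The expression table sits between ``!series_matrix_table_begin`` and
    ``!series_matrix_table_end`` marker lines; the header row carries sample
    ids after an ``ID_REF`` cell.  Group labels come from a two-column
    sidecar TSV (sample_id, group) or from ``!Sample_characteristics`` lines
    of the form ``group: case``.  Values are assumed log2 already; when the
    table maximum exceeds 50 the matrix is log2(x+1)-transformed with a
    warning.
    """
    path = Path(path)
    lines = path.read_text().splitlines()
    try:
        begin = next(i for i, ln in enumerate(lines)
                     if ln.strip() == TABLE_BEGIN)
        end = next(i for i, ln in enumerate(lines) if ln.strip() == TABLE_END)
    except StopIteration:
        raise ParseError(f"{path}: missing {TABLE_BEGIN}/{TABLE_END} markers")

    groups: dict[str, str] = {}
    char_samples: list[str] = []
    for ln in lines[:begin]:
        if ln.startswith("!Sample_geo_accession"):
            char_samples = [t.strip().strip('"') for t in ln.split("\t")[1:]]
        if ln.startswith("!Sample_characteristics") and "group:" in ln:
            labels = [t.strip().strip('"').split("group:")[-1].strip().lower()
                      for t in ln.split("\t")[1:]]
            if char_samples and len(labels) == len(char_samples):
                groups = dict(zip(char_samples, labels))

    header = lines[begin + 1].rstrip("\n").split("\t")
    sample_ids = [h.strip().strip('"') for h in header[1:]]
    probe_ids: list[str] = []
    rows: list[list[float]] = []
    for lineno in range(begin + 2, end):
        cells = lines[lineno].rstrip("\n").split("\t")
        if len(cells) != len(header):
            raise ParseError(
                f"{path}:{lineno + 1}: expected {len(header)} columns, "
                f"got {len(cells)}")
        probe_ids.append(cells[0].strip().strip('"'))
        try:
            rows.append([float(c) for c in cells[1:]])
        except ValueError as exc:
            raise ParseError(f"{path}:{lineno + 1}: non-numeric value ({exc})")

    values = np.array(rows, dtype=float)
    if values.size and values.max() > 50:
        warnings.warn(
            f"{path}: values look unlogged (max {values.max():.1f}); "
            "applying log2(x+1)", stacklevel=2)
        values = np.log2(values + 1.0)

    if groups_path is not None:
        groups = _read_groups_sidecar(groups_path)
    if not groups:
        raise ParseError(f"{path}: no group labels (sidecar or "
                         "characteristics lines required)")
    missing = [s for s in sample_ids if s not in groups]
    if missing:
        raise ParseError(f"{path}: samples absent from group labels: {missing}")

    return ExpressionMatrix(probe_ids=probe_ids, sample_ids=sample_ids,
                            values=values,
                            groups={s: groups[s] for s in sample_ids},
                            platform=platform)


def write_series_matrix(m: ExpressionMatrix, path, groups_path=None) -> None:
    """Write a series-matrix-style file (and optionally the group sidecar)."""
    path = Path(path)
    with path.open("w") as fh:
        if m.platform:
            fh.write(f"!Series_platform_id\t\"{m.platform}\"\n")
        fh.write("!Sample_geo_accession\t"
                 + "\t".join(f'"{s}"' for s in m.sample_ids) + "\n")
        fh.write("!Sample_characteristics_ch1\t"
                 + "\t".join(f'"group: {m.groups[s]}"' for s in m.sample_ids)
                 + "\n")
        fh.write(TABLE_BEGIN + "\n")
        fh.write("\t".join(['"ID_REF"'] + [f'"{s}"' for s in m.sample_ids]) + "\n")
        for pid, row in zip(m.probe_ids, m.values):
            fh.write(pid + "\t" + "\t".join(f"{v:.6g}" for v in row) + "\n")
        fh.write(TABLE_END + "\n")
    if groups_path is not None:
        pd.DataFrame({"sample_id": m.sample_ids,
                      "group": [m.groups[s] for s in m.sample_ids]}
                     ).to_csv(groups_path, sep="\t", index=False)


def _trigamma_inverse(x: np.ndarray | float) -> np.ndarray:
    """Solve trigamma(y) = x by Newton iteration (vectorized)."""
    x = np.atleast_1d(np.asarray(x, dtype=float))
    y = 0.5 + 1.0 / x  # good starting value for x not too large
    for _ in range(50):
        tri = special.polygamma(1, y)
        dif = tri * (1.0 - tri / x) / special.polygamma(2, y)
        y = y + dif
        if np.max(np.abs(dif) / y) < 1e-10:
            break
    return y


def _fit_prior(s2: np.ndarray, df: int) -> tuple[float, float]:
    """Moment-match (d0, s0^2) on log sample variances.

    Under the scaled-F sampling model, e = log(s^2) - digamma(d/2) + log(d/2)
    has mean log(s0^2) + digamma(d0/2) - log(d0/2) and variance
    trigamma(d/2) + trigamma(d0/2).  Probes with zero variance are excluded
    from the fit.  Returns d0 = inf when the observed spread of log
    variances is no larger than sampling noise alone.
    """
    pos = s2 > 0
    if pos.sum() < 2:
        return np.inf, float(s2[pos].mean()) if pos.any() else 0.0
    e = np.log(s2[pos]) - special.digamma(df / 2.0) + np.log(df / 2.0)
    emean = float(e.mean())
    evar = float(e.var(ddof=1))
    excess = evar - float(special.polygamma(1, df / 2.0))
    if excess <= 0:
        return np.inf, float(np.exp(emean))
    d0 = float(2.0 * _trigamma_inverse(excess)[0])
    s02 = float(np.exp(emean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    return d0, s02


def differential_expression(
    m: ExpressionMatrix,
    method: str = "moderated",
    d0_override: Optional[float] = None,
) -> list[DEGRecord]:
    """Per-probe two-group test; logFC is mean(case) - mean(control), log2.

    ``method='welch'`` runs an unequal-variance two-sample t-test.
    ``method='moderated'`` runs the empirical-Bayes shrunken-variance t.
    ``d0_override`` pins the prior df (0 recovers the ordinary pooled t;
    intended for testing).
    """
    case = m.group_columns("case")
    ctrl = m.group_columns("control")
    n1, n2 = len(case), len(ctrl)
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs at least 2 samples")

    x1 = m.values[:, case]
    x2 = m.values[:, ctrl]
    logfc = x1.mean(axis=1) - x2.mean(axis=1)
    v1 = x1.var(axis=1, ddof=1)
    v2 = x2.var(axis=1, ddof=1)
    degenerate = np.zeros(len(m.probe_ids), dtype=bool)

    if method == "welch":
        with np.errstate(divide="ignore", invalid="ignore"):
            res = stats.ttest_ind(x1, x2, axis=1, equal_var=False)
            p = np.asarray(res.pvalue, dtype=float)
        zero = (v1 == 0) & (v2 == 0)
        if np.any(zero):
            degenerate[zero] = True
            p[zero] = np.where(logfc[zero] != 0, 0.0, 1.0)
    elif method == "moderated":
        df = n1 + n2 - 2
        s2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / df
        if d0_override is not None:
            d0 = float(d0_override)
            s02 = 0.0 if d0 == 0 else _fit_prior(s2, df)[1]
        else:
            d0, s02 = _fit_prior(s2, df)
        if np.isinf(d0):
            s2_post = np.full_like(s2, s02)
        else:
            s2_post = (d0 * s02 + df * s2) / (d0 + df)
        se = np.sqrt(s2_post * (1.0 / n1 + 1.0 / n2))
        with np.errstate(divide="ignore", invalid="ignore"):
            t = logfc / se
        if np.isinf(d0):
            p = 2.0 * stats.norm.sf(np.abs(t))
        else:
            p = 2.0 * stats.t.sf(np.abs(t), d0 + df)
        zero = se == 0
        if np.any(zero):
            degenerate[zero] = True
            p[zero] = np.where(logfc[zero] != 0, 0.0, 1.0)
    else:
        raise ValueError(f"unknown method {method!r}")

    return [
        DEGRecord(probe_id=pid, gene_symbol="", logfc=float(lfc), p=float(pv),
                  direction="up" if lfc >= 0 else "down", degenerate=bool(dg))
        for pid, lfc, pv, dg in zip(m.probe_ids, logfc, p, degenerate)
    ]


def filter_degs(records: Iterable[DEGRecord], lfc_min: float = 0.5,
                p_max: float = 0.05) -> list[DEGRecord]:
    """Keep records with |logFC| >= lfc_min and p <= p_max (both inclusive).

    ``passed`` is set on every input record; the returned list holds the
    passing ones in input order.  Idempotent.
    """
    out = []
    for r in records:
        r.passed = abs(r.logfc) >= lfc_min and r.p <= p_max
        if r.passed:
            out.append(r)
    return out


def collapse_probes(
    records: Sequence[DEGRecord],
    probe_gene_map: Mapping[str, str],
    how: str = "max_abs_lfc",
) -> list[DEGRecord]:
    """Collapse probe-level records to one record per gene symbol.

    ``how='max_abs_lfc'`` keeps, per gene, the probe with the largest
    |logFC| (ties: smaller p, then probe id).  ``how='mean'`` averages the
    logFC across the gene's probes and keeps the smallest p.  Probes absent
    from the map are dropped and counted in the log.
    """
    by_gene: dict[str, list[DEGRecord]] = {}
    unmapped = 0
    for r in records:
        gene = probe_gene_map.get(r.probe_id)
        if gene is None:
            unmapped += 1
            continue
        by_gene.setdefault(gene.upper(), []).append(r)
    if unmapped:
        log.info("collapse_probes: dropped %d unmapped probes", unmapped)

    out: list[DEGRecord] = []
    for gene in sorted(by_gene):
        grp = by_gene[gene]
        if how == "max_abs_lfc":
            best = min(grp, key=lambda r: (-abs(r.logfc), r.p, r.probe_id))
            rec = DEGRecord(probe_id=best.probe_id, gene_symbol=gene,
                            logfc=best.logfc, p=best.p, passed=best.passed,
                            direction=best.direction, degenerate=best.degenerate)
        elif how == "mean":
            lfc = float(np.mean([r.logfc for r in grp]))
            rec = DEGRecord(probe_id=";".join(sorted(r.probe_id for r in grp)),
                            gene_symbol=gene, logfc=lfc,
                            p=float(min(r.p for r in grp)),
                            direction="up" if lfc >= 0 else "down")
        else:
            raise ValueError(f"unknown collapse rule {how!r}")
        out.append(rec)
    return out


def union_deg_sets(per_chip_gene_sets: Sequence[set[str]]) -> set[str]:
    """Duplicate-removing union of per-chip DEG gene sets."""
    out: set[str] = set()
    for s in per_chip_gene_sets:
        out |= {g.upper() for g in s}
    log.info("union_deg_sets: %d genes after duplicate removal", len(out))
    return out


def read_gene_list(path) -> set[str]:
    """One gene symbol per line, case-normalized to upper."""
    out = set()
    for ln in Path(path).read_text().splitlines():
        sym = ln.strip()
        if sym and not sym.startswith("#"):
            out.add(sym.upper())
    return out


def build_disease_targets(deg_union: set[str],
                          database_lists: Sequence = ()) -> set[str]:
    """Union of the DEG genes with disease-gene list files (symbols uppered)."""
    out = {g.upper() for g in deg_union}
    for path in database_lists:
        out |= read_gene_list(path)
    return out
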