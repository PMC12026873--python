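"""Tabular readers/writers for compounds, target databases and predictions.

Fingerprints travel as hex strings (packed bits, most-significant bit
first) so every artifact stays plain text.
"""

from __future__ import annotations

from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .admet import Compound, PhyschemProfile
from .similarity import PredictionScore, TargetSet, fingerprint_from_smiles

__all__ = [
    "fp_to_hex",
    "fp_from_hex",
    "write_compounds_tsv",
    "read_compounds_tsv",
    "write_target_db",
    "read_target_db",
    "write_predictions_tsv",
    "read_predictions_tsv",
    "write_smiles_file",
    "write_gene_list",
]

_PROFILE_COLS = ("mw", "tpsa", "logp", "hbd", "hba", "anionic")


def fp_to_hex(fp: np.ndarray) -> str:
    fp = np.asarray(fp, dtype=np.uint8)
    return np.packbits(fp).tobytes().hex()


def fp_from_hex(s: str, length: int) -> np.ndarray:
    raw = np.frombuffer(bytes.fromhex(s), dtype=np.uint8)
    return np.unpackbits(raw)[:length].astype(np.uint8)


def write_compounds_tsv(compounds: Sequence[Compound], path) -> None:
    rows = []
    for c in compounds:
        row = {"id": c.id, "name": c.name, "cas": c.cas, "class": c.cls or "",
               "smiles": c.smiles or "", "bs": "" if c.bs is None else c.bs}
        if c.profile is not None:
            for col in _PROFILE_COLS:
                v = getattr(c.profile, col)
                row[col] = int(v) if col == "anionic" else v
        row["fingerprint"] = "" if c.fingerprint is None else fp_to_hex(c.fingerprint)
        row["fp_length"] = "" if c.fingerprint is None else len(c.fingerprint)
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_compounds_tsv(path) -> list[Compound]:
    df = pd.read_csv(path, sep="\t", dtype={"id": str, "name": str,
                                            "cas": str, "smiles": str})
    out = []
    for _, r in df.iterrows():
        profile = None
        if all(c in df.columns and pd.notna(r[c]) for c in _PROFILE_COLS):
            profile = PhyschemProfile(
                mw=float(r["mw"]), tpsa=float(r["tpsa"]), logp=float(r["logp"]),
                hbd=int(r["hbd"]), hba=int(r["hba"]),
                anionic=bool(int(r["anionic"])))
        fp = None
        if "fingerprint" in df.columns and pd.notna(r["fingerprint"]) \
                and str(r["fingerprint"]):
            fp = fp_from_hex(str(r["fingerprint"]), int(r["fp_length"]))
        smiles = r.get("smiles")
        smiles = None if pd.isna(smiles) or not str(smiles) else str(smiles)
        cls = r.get("class")
        cls = None if pd.isna(cls) or not str(cls) else str(cls)
        bs = r.get("bs")
        bs = None if pd.isna(bs) or bs == "" else float(bs)
        out.append(Compound(
            id=str(r["id"]),
            name="" if pd.isna(r.get("name")) else str(r.get("name", "")),
            cas="" if pd.isna(r.get("cas")) else str(r.get("cas", "")),
            cls=cls, smiles=smiles, profile=profile, bs=bs, fingerprint=fp))
    return out


def write_target_db(targets: Sequence[TargetSet], path) -> None:
    rows = []
    for t in targets:
        for j in range(t.n_ligands):
            rows.append({"target_id": t.target_id,
                         "gene_symbol": t.gene_symbol,
                         "ligand_id": f"{t.target_id}_L{j + 1:03d}",
                         "fingerprint": fp_to_hex(t.ligands[j]),
                         "fp_length": t.fp_length})
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_target_db(path, n_bits: int = 2048, radius: int = 2) -> list[TargetSet]:
    """Target ligand table, either pre-fingerprinted (``fingerprint`` hex
    column) or structural (``ligand_smiles`` column, fingerprinted on read).
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    if "fingerprint" in df.columns:
        def to_fp(r):
            return fp_from_hex(r["fingerprint"], int(r["fp_length"]))
    elif "ligand_smiles" in df.columns:
        def to_fp(r):
            return fingerprint_from_smiles(r["ligand_smiles"],
                                           n_bits=n_bits, radius=radius)
    else:
        raise ValueError(f"{path}: need a 'fingerprint' or 'ligand_smiles' "
                         "column")
    out = []
    for (tid, sym), grp in df.groupby(["target_id", "gene_symbol"], sort=True):
        ligands = np.vstack([to_fp(r) for _, r in grp.iterrows()])
        out.append(TargetSet(target_id=str(tid), gene_symbol=str(sym),
                             ligands=ligands))
    return out


def write_predictions_tsv(predictions: Sequence[PredictionScore], path) -> None:
    pd.DataFrame([{
        "compound_id": p.compound_id, "target_id": p.target_id,
        "gene_symbol": p.gene_symbol, "raw": p.raw, "n_pairs": p.n_pairs,
        "normalized": p.normalized, "z": p.z,
    } for p in predictions]).to_csv(path, sep="\t", index=False)


def read_predictions_tsv(path) -> list[PredictionScore]:
    df = pd.read_csv(path, sep="\t")
    return [PredictionScore(compound_id=str(r.compound_id),
                            target_id=str(r.target_id),
                            gene_symbol=str(r.gene_symbol), raw=float(r.raw),
                            n_pairs=int(r.n_pairs),
                            normalized=float(r.normalized), z=float(r.z))
            for r in df.itertuples()]


def write_smiles_file(compounds: Sequence[Compound], path) -> None:
    """``smiles<TAB>id`` per line; compounds without SMILES are skipped."""
    with Path(path).open("w") as fh:
        for c in compounds:
            if c.smiles:
                fh.write(f"{c.smiles}\t{c.id}\n")


def write_gene_list(genes, path) -> None:
    Path(path).write_text("\n".join(sorted({g.upper() for g in genes})) + "\n")
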