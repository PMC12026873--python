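"""Rule-based oral bioavailability scoring and compound screening.

The bioavailability score (BS) estimates the probability that a compound
reaches >10% oral bioavailability in rat.  It is a rule table over the
compound's predominant charge state near pH 7 and simple physicochemical
descriptors; the table emits one of five constants:

  anionic, TPSA > 150 A^2        -> 0.11
  anionic, 75 < TPSA <= 150 A^2  -> 0.56
  anionic, TPSA <= 75 A^2        -> 0.85
  neutral/cationic, Ro5 pass     -> 0.55
  neutral/cationic, Ro5 fail     -> 0.17

"Ro5 pass" means at most one violation among MW <= 500 g/mol, logP <= 5,
H-bond donors <= 5, H-bond acceptors <= 10.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "PhyschemProfile",
    "Compound",
    "ro5_violations",
    "bioavailability_score",
    "screen_compounds",
]

COMPOUND_CLASSES = ("Polyphenols", "Alkaloids", "Triterpenoids", "Furfurals")


@dataclass
class PhyschemProfile:
    """Physicochemical descriptors feeding the bioavailability rule table.

    mw: molecular weight, g/mol.  tpsa: topological polar surface area, A^2.
    logp: octanol/water partition coefficient.  hbd/hba: hydrogen-bond
    donor/acceptor counts.  anionic: predominant species near pH 7 carries a
    negative charge.
    """

    mw: float
    tpsa: float
    logp: float
    hbd: int
    hba: int
    anionic: bool
    ro5_violations: Optional[int] = None

    def __post_init__(self) -> None:
        for name in ("mw", "tpsa", "logp", "hbd", "hba", "anionic"):
            if getattr(self, name) is None:
                raise ValueError(f"profile field {name!r} is missing")
        if self.tpsa < 0:
            raise ValueError("tpsa must be nonnegative")
        if self.hbd < 0 or self.hba < 0:
            raise ValueError("H-bond counts must be nonnegative")
        if self.ro5_violations is None:
            self.ro5_violations = ro5_violations(self.mw, self.logp,
                                                 self.hbd, self.hba)


@dataclass
class Compound:
    """A small molecule entering the pipeline."""

    id: str
    name: str = ""
    cas: str = ""
    cls: Optional[str] = None
    smiles: Optional[str] = None
    profile: Optional[PhyschemProfile] = None
    bs: Optional[float] = None
    fingerprint: Optional[np.ndarray] = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if self.bs is not None and not 0.0 <= self.bs <= 1.0:
            raise ValueError(f"compound {self.id}: bs must lie in [0, 1]")
        if self.cls is not None and self.cls not in COMPOUND_CLASSES:
            raise ValueError(
                f"compound {self.id}: unknown class {self.cls!r}; "
                f"expected one of {COMPOUND_CLASSES}")


def ro5_violations(mw: float, logp: float, hbd: int, hba: int) -> int:
    """Number of Lipinski rule-of-five violations."""
    return int(mw > 500) + int(logp > 5) + int(hbd > 5) + int(hba > 10)


def bioavailability_score(profile: PhyschemProfile) -> float:
    """Rule-table bioavailability score; pure function of the profile."""
    if profile.anionic:
        if profile.tpsa > 150:
            return 0.11
        if profile.tpsa > 75:
            return 0.56
        return 0.85
    return 0.55 if profile.ro5_violations <= 1 else 0.17


def screen_compounds(
    compounds: Sequence[Compound],
    bs_min: float = 0.10,
    compute_missing: bool = True,
) -> tuple[list[Compound], list[Compound]]:
    """Partition compounds into (kept, removed) by ``bs >= bs_min``.

    A compound without a ``bs`` gets one computed from its profile when
    ``compute_missing`` is set; with neither, the compound is named in the
    error.  Input order is preserved in both outputs.
    """
    kept: list[Compound] = []
    removed: list[Compound] = []
    for c in compounds:
        if c.bs is None:
            if compute_missing and c.profile is not None:
                c.bs = bioavailability_score(c.profile)
            else:
                raise ValueError(
                    f"compound {c.id!r} has no bioavailability score and no "
                    "profile to compute one from")
        (kept if c.bs >= bs_min else removed).append(c)
    return kept, removed
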