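"""Direct nose-to-brain transport indices.

After intranasal dosing, drug reaches the brain both directly (olfactory /
trigeminal pathways) and indirectly via the systemic circulation.  Two
indices quantify the direct component from brain and plasma AUC(0->tlast):

* %DTE (direct transport efficiency): the nasal brain:plasma AUC ratio
  relative to the same ratio after intravenous dosing, x100.  100% means
  the nasal route gives no brain-targeting advantage.
* %DTP (direct transport percentage): the fraction of nasal brain exposure
  not attributable to redistribution from plasma across the blood-brain
  barrier.  The systemic contribution is Bx = R_iv * plasma AUC, where
  R_iv = (brain AUC / plasma AUC) after i.v. dosing.

The two are algebraically linked: %DTP = 100 - 10000/%DTE, so %DTP < 100
always, and %DTP >= 0 exactly when %DTE >= 100.

Only the i.v. brain:plasma ratio R_iv is identifiable from the formulas,
so the reference enters as a ratio; when the i.v. AUCs themselves are not
available, the ratio can be back-calculated from any formulation whose
%DTE is already known (:func:`calibrate_iv_ratio`).

Units follow bioanalytical convention: brain AUC per gram tissue, plasma
AUC per mL; the indices use their quotient directly, with no tissue-density
correction.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

__all__ = ["FormulationPK", "IVReference", "TargetingIndices",
           "dte", "dtp", "calibrate_iv_ratio", "targeting_report"]


@dataclass(frozen=True)
class FormulationPK:
    """Brain and plasma AUC(0->tlast) of one intranasal formulation."""

    name: str
    brain_auc: float   # min*ug/g
    plasma_auc: float  # min*ug/mL

    def __post_init__(self) -> None:
        if not (self.brain_auc > 0 and self.plasma_auc > 0):
            raise ValueError(f"{self.name!r}: AUCs must be positive")


@dataclass(frozen=True)
class IVReference:
    """The intravenous brain:plasma AUC ratio R_iv = B_iv / P_iv."""

    ratio: float

    def __post_init__(self) -> None:
        if not self.ratio > 0:
            raise ValueError("i.v. brain:plasma ratio must be positive")

    @classmethod
    def from_aucs(cls, brain_auc: float, plasma_auc: float) -> "IVReference":
        if not (brain_auc > 0 and plasma_auc > 0):
            raise ValueError("i.v. AUCs must be positive")
        return cls(ratio=brain_auc / plasma_auc)


@dataclass(frozen=True)
class TargetingIndices:
    """%DTE, %DTP and the systemic brain contribution Bx."""

    dte_percent: float
    dtp_percent: float
    bx: float  # min*ug/g

    def __post_init__(self) -> None:
        if not self.dtp_percent < 100.0:
            raise ValueError("%DTP must be < 100")


def dte(f: FormulationPK, iv: IVReference) -> float:
    """Direct transport efficiency, percent."""
    return (f.brain_auc / f.plasma_auc) / iv.ratio * 100.0


def dtp(f: FormulationPK, iv: IVReference) -> TargetingIndices:
    """Direct transport percentage (with %DTE and Bx alongside)."""
    bx = iv.ratio * f.plasma_auc
    return TargetingIndices(
        dte_percent=dte(f, iv),
        dtp_percent=(f.brain_auc - bx) / f.brain_auc * 100.0,
        bx=bx)


def calibrate_iv_ratio(f: FormulationPK, known_dte_percent: float) -> IVReference:
    """Back-calculate R_iv from a formulation with known %DTE.

    Inverts the %DTE formula: R_iv = (brain/plasma) / (%DTE/100).  Useful
    when the i.v. study is published only through the derived indices.
    """
    if not known_dte_percent > 0:
        raise ValueError("%DTE must be positive")
    return IVReference(ratio=(f.brain_auc / f.plasma_auc)
                       / (known_dte_percent / 100.0))


def targeting_report(formulations, iv: IVReference) -> pd.DataFrame:
    """%DTE/%DTP table for several formulations under one i.v. reference."""
    rows = []
    for f in formulations:
        idx = dtp(f, iv)
        rows.append({"formulation": f.name, "brain_auc": f.brain_auc,
                     "plasma_auc": f.plasma_auc, "bx": idx.bx,
                     "dte_percent": idx.dte_percent,
                     "dtp_percent": idx.dtp_percent})
    return pd.DataFrame(rows).set_index("formulation")
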