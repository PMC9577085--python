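"""Bundled example data from a published rufinamide nanocrystal study.

These are the printed summary tables of a nanocrystal
formulation-optimization and nasal pharmacokinetics study in rats: the
20-run inscribed central composite design with measured particle sizes,
the brain/plasma AUC summaries of four intranasal formulations, and a
freeze-dried-product stability series.  They serve as worked-example
inputs and as regression anchors for the fitting, optimization and
targeting code.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .doe import DesignTable, make_inscribed_ccd
from .quality import StabilitySeries

__all__ = ["ccd_factors", "ccd_design", "ccd_particle_size",
           "formulation_auc", "REFERENCE_DTE", "stability_series"]

#: Factor names, natural bounds and units of the nanocrystal CCD.
CCD_FACTORS = (
    ("hpmc_conc", 0.1, 2.0, "% w/v"),          # stabilizer concentration
    ("ultrasonication_time", 5.0, 15.0, "min"),
    ("process_temperature", 5.0, 15.0, "degC"),
)

# 20-run inscribed rotatable CCD (alpha = 2**(3/4)) with the measured mean
# particle size (nm) per run, keyed by standard order.  Natural levels are
# as printed by the design software (rounded to ~3 significant figures).
_CCD_ROWS = [
    # std, HPMC % w/v, sonication min, temperature degC, particle size nm
    (1, 0.48, 7.0, 7.0, 299.0),
    (2, 1.61, 7.0, 7.0, 601.2),
    (3, 0.48, 12.9, 7.0, 256.8),
    (4, 1.61, 12.9, 7.0, 583.3),
    (5, 0.48, 7.0, 12.9, 314.0),
    (6, 1.61, 7.02, 12.9, 595.8),
    (7, 0.48, 12.9, 12.9, 261.5),
    (8, 1.61, 12.9, 12.9, 550.7),
    (9, 0.10, 10.0, 10.0, 234.1),
    (10, 2.0, 10.0, 10.0, 910.0),
    (11, 1.05, 5.0, 10.0, 480.9),
    (12, 1.05, 15.0, 10.0, 383.3),
    (13, 1.05, 10.0, 5.0, 475.8),
    (14, 1.05, 10.0, 15.0, 449.3),
    (15, 1.05, 10.0, 10.0, 474.2),
    (16, 1.05, 10.0, 10.0, 444.8),
    (17, 1.05, 10.0, 10.0, 518.8),
    (18, 1.05, 10.0, 10.0, 500.3),
    (19, 1.05, 10.0, 10.0, 510.9),
    (20, 1.05, 10.0, 10.0, 468.5),
]


def ccd_factors():
    """(name, low, high, units) tuples of the three optimization factors."""
    return list(CCD_FACTORS)


def ccd_design() -> DesignTable:
    """The 20-run inscribed rotatable CCD (2^3 factorial + 6 axial + 6 center)."""
    return make_inscribed_ccd(CCD_FACTORS, n_center=6, alpha="rotatable")


def ccd_particle_size(natural: bool = True) -> pd.DataFrame:
    """The design runs with their measured particle sizes, by standard order.

    With ``natural=True`` the factor columns are the printed natural levels;
    re-code them through :func:`nanopk.doe.to_coded` (snapping absorbs the
    print rounding) before fitting.
    """
    names = [f[0] for f in CCD_FACTORS]
    frame = pd.DataFrame(_CCD_ROWS,
                         columns=["std_order", *names, "particle_size"])
    if not natural:
        design = ccd_design()
        coded = {f"{f.name}": design.coded[:, j]
                 for j, f in enumerate(design.factors)}
        frame = pd.DataFrame({"std_order": design.std_order, **coded})
        frame["particle_size"] = [r[4] for r in sorted(_CCD_ROWS)]
    return frame


# Brain (min*ug/g) and plasma (min*ug/mL) AUC(0->tlast) of the four
# intranasal formulations at 1 mg/kg in rats, with the published %DTE/%DTP.
# nc = nanocrystal; rxg = thermoresponsive xyloglucan in situ gel.
_FORMULATIONS = [
    # name, brain AUC, plasma AUC, %DTE printed, %DTP printed
    ("Rufi-NC-Susp", 340.7, 258.2, 373.16, 73.3),
    ("Rufi-NC-RXG", 471.3, 192.3, 693.1, 85.5),
    ("Rufi-Susp", 104.28, 200.75, 146.8, 31.9),
    ("Rufi-RXG", 201.8, 53.34, 1069.9, 90.6),
]

#: Formulation whose published %DTE anchors the i.v. ratio calibration.
REFERENCE_DTE = ("Rufi-NC-Susp", 373.16)


def formulation_auc() -> pd.DataFrame:
    """Published AUC summaries and targeting indices of the four formulations."""
    return pd.DataFrame(
        _FORMULATIONS,
        columns=["name", "brain_auc", "plasma_auc",
                 "dte_printed", "dtp_printed"]).set_index("name")


def stability_series() -> dict[str, StabilitySeries]:
    """60-day stability of the freeze-dried nanocrystals at 25 degC/60% RH."""
    return {
        "particle_size": StabilitySeries(
            parameter="particle_size_nm", baseline=244.0,
            days=(15, 30, 45, 60), values=(243.0, 244.0, 254.0, 255.0)),
        "percent_yield": StabilitySeries(
            parameter="percent_yield", baseline=87.3,
            days=(15, 30, 45, 60), values=(86.3, 85.6, 83.6, 83.0)),
    }
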