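"""Formulation quality arithmetic: % yield, dosing precision, stability.

Small, exact computations used around the main pipeline: process yield of
a nanocrystal batch, relative standard deviation of repeated device doses,
and %-bias assessment of stability series against their baseline.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["percent_yield", "percent_rsd", "StabilitySeries",
           "stability_assess"]


def percent_yield(w_total: float, w_pellet: float,
                  as_printed: bool = False) -> float:
    """Process yield of a batch, percent.

    ``w_total`` is the drug mass charged into the batch and ``w_pellet``
    the drug mass recovered in the centrifuged pellet (the product), so
    yield = pellet/total x 100.  ``as_printed=True`` instead returns the
    complementary loss fraction (total - pellet)/total x 100, the form some
    reports print even when quoting recovery-scale values.
    """
    if not w_total > 0:
        raise ValueError("w_total must be positive")
    if not 0 <= w_pellet <= w_total:
        raise ValueError("w_pellet must lie in [0, w_total]")
    if as_printed:
        return (w_total - w_pellet) / w_total * 100.0
    return w_pellet / w_total * 100.0


def percent_rsd(values) -> float:
    """Relative standard deviation (sample SD / mean), percent."""
    v = np.asarray(list(values), dtype=float)
    if v.size < 2:
        raise ValueError("need at least 2 values")
    mean = v.mean()
    if mean == 0:
        raise ZeroDivisionError("%RSD undefined for zero mean")
    return float(v.std(ddof=1) / mean * 100.0)


@dataclass(frozen=True)
class StabilitySeries:
    """One stability parameter followed over storage time (days)."""

    parameter: str
    baseline: float
    days: tuple
    values: tuple

    def __post_init__(self) -> None:
        if not self.baseline > 0:
            raise ValueError("baseline must be positive")
        days = np.asarray(self.days, dtype=float)
        if len(self.days) != len(self.values):
            raise ValueError("days and values must have equal length")
        if np.any(days < 0) or np.any(np.diff(days) <= 0):
            raise ValueError("days must be non-negative and increasing")


def stability_assess(series: StabilitySeries,
                     bias_threshold_percent: float = 5.0) -> pd.DataFrame:
    """Per-timepoint %bias against baseline with a pass/fail verdict.

    bias_t = (value_t - baseline)/baseline x 100; the series passes when
    |bias_t| < threshold at every sampling point.  The overall verdict is
    stored in ``result.attrs["pass"]``.
    """
    vals = np.asarray(series.values, dtype=float)
    bias = (vals - series.baseline) / series.baseline * 100.0
    ok = np.abs(bias) < bias_threshold_percent
    out = pd.DataFrame({"day": list(series.days), "value": vals,
                        "bias_percent": bias, "within_threshold": ok})
    out.attrs["parameter"] = series.parameter
    out.attrs["pass"] = bool(ok.all())
    return out
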