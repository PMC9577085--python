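"""Non-compartmental pharmacokinetic analysis.

Summarizes concentration-time profiles without assuming a compartmental
model: Cmax, Tmax, AUC and AUMC to the last quantifiable point by the
linear trapezoid rule, and MRT = AUMC/AUC.  No extrapolation to infinity
and no terminal-slope estimation is performed: all exposure metrics are
"to tlast", which is what sparse destructive designs support.

Destructive (one sample per animal) designs, typical of brain sampling,
are handled by pooling: the per-time mean over animals forms a single
profile whose NCA summaries are point estimates without a standard
deviation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["ConcProfile", "NCAResult", "nca", "pool_destructive",
           "summarize_arm"]


@dataclass
class ConcProfile:
    """A concentration-time series for one subject (or a pooled mean).

    Times in minutes, strictly increasing; concentrations in ug/mL (plasma)
    or ug/g (brain).  ``blq`` flags points below the limit of quantification.
    Pooled profiles built by :func:`pool_destructive` carry per-time ``n``
    and SD in ``pooled_n`` / ``pooled_sd``.
    """

    subject_id: str
    matrix: str
    times: np.ndarray
    concentrations: np.ndarray
    dose: float = np.nan
    blq: np.ndarray = None  # type: ignore[assignment]
    pooled_n: np.ndarray | None = None
    pooled_sd: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.concentrations = np.asarray(self.concentrations, dtype=float)
        if self.blq is None:
            self.blq = np.zeros(self.times.shape, dtype=bool)
        self.blq = np.asarray(self.blq, dtype=bool)
        if self.times.ndim != 1 or self.times.shape != self.concentrations.shape \
                or self.blq.shape != self.times.shape:
            raise ValueError("times, concentrations and blq must be equal-length 1-d")
        if self.times.size and self.times[0] < 0:
            raise ValueError("first sampling time must be >= 0")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(self.concentrations[~self.blq] < 0):
            raise ValueError("quantifiable concentrations must be non-negative")


@dataclass
class NCAResult:
    cmax: float
    tmax: float
    tlast: float
    auc_last: float
    aumc_last: float
    mrt: float
    n_points: int = 0

    def as_series(self) -> pd.Series:
        return pd.Series({"cmax": self.cmax, "tmax": self.tmax,
                          "tlast": self.tlast, "auc_last": self.auc_last,
                          "aumc_last": self.aumc_last, "mrt": self.mrt})


def _effective_curve(profile: ConcProfile) -> tuple[np.ndarray, np.ndarray]:
    """Apply BLQ rules: leading/embedded BLQ -> 0, trailing BLQ dropped."""
    quant = ~profile.blq
    if not quant.any():
        raise ValueError(f"profile {profile.subject_id!r}: all points are BLQ")
    last = np.max(np.nonzero(quant)[0])
    t = profile.times[: last + 1]
    c = profile.concentrations[: last + 1].copy()
    c[profile.blq[: last + 1]] = 0.0
    # implicit pre-dose zero if the profile starts after t=0
    if t[0] > 0:
        t = np.concatenate([[0.0], t])
        c = np.concatenate([[0.0], c])
    return t, c


def nca(profile: ConcProfile) -> NCAResult:
    """Non-compartmental summary of one profile.

    Cmax is the maximum concentration and Tmax the earliest time attaining
    it; AUC/AUMC use the linear trapezoid on C(t) and t*C(t) from the first
    time to the last quantifiable time; MRT = AUMC_last / AUC_last.
    """
    t, c = _effective_curve(profile)
    if t.size < 2:
        raise ValueError(f"profile {profile.subject_id!r}: need >= 2 points")
    imax = int(np.argmax(c))  # argmax returns the earliest maximum
    auc = float(np.trapezoid(c, t))
    aumc = float(np.trapezoid(t * c, t))
    if auc <= 0:
        raise ZeroDivisionError(
            f"profile {profile.subject_id!r}: AUC is 0, MRT undefined")
    return NCAResult(cmax=float(c[imax]), tmax=float(t[imax]),
                     tlast=float(t[-1]), auc_last=auc, aumc_last=aumc,
                     mrt=aumc / auc, n_points=int(t.size))


def pool_destructive(samples, matrix: str = "brain",
                     subject_id: str = "pooled") -> ConcProfile:
    """Pool destructive sampling into a mean concentration-time profile.

    ``samples`` is a sequence of ``(time, concentrations)`` pairs, one pair
    per sampling time, where ``concentrations`` holds the value from each
    animal sacrificed at that time.  Returns the per-time mean as a single
    profile, with per-time n and sample SD recorded as side metadata.
    """
    times = [float(t) for t, _ in samples]
    if len(set(times)) != len(times):
        raise ValueError("duplicate time groups in destructive samples")
    order = np.argsort(times)
    t_arr, means, ns, sds = [], [], [], []
    for idx in order:
        t, conc = samples[idx]
        conc = np.asarray(conc, dtype=float)
        if conc.size == 0:
            raise ValueError(f"time {t}: no concentrations")
        t_arr.append(float(t))
        means.append(float(conc.mean()))
        ns.append(conc.size)
        sds.append(float(conc.std(ddof=1)) if conc.size > 1 else np.nan)
    return ConcProfile(subject_id=subject_id, matrix=matrix,
                       times=np.array(t_arr), concentrations=np.array(means),
                       pooled_n=np.array(ns), pooled_sd=np.array(sds))


def summarize_arm(profiles) -> pd.DataFrame:
    """Per-subject NCA then mean +/- SD per parameter for one study arm.

    Tmax is reported as a ``lo-hi`` range when subjects differ (the
    conventional presentation for a discrete sampling grid).
    """
    profiles = list(profiles)
    if not profiles:
        raise ValueError("no profiles")
    matrices = {p.matrix for p in profiles}
    if len(matrices) > 1:
        raise ValueError(f"mixed matrices in one arm: {sorted(matrices)}")
    results = pd.DataFrame([nca(p).as_series() for p in profiles],
                           index=[p.subject_id for p in profiles])
    rows = {}
    for param in ["cmax", "tmax", "auc_last", "mrt"]:
        vals = results[param]
        if param == "tmax":
            lo, hi = vals.min(), vals.max()
            rows[param] = {"mean": vals.mean(), "sd": vals.std(ddof=1),
                           "display": (f"{lo:g}" if lo == hi
                                       else f"{lo:g}-{hi:g}")}
        else:
            rows[param] = {"mean": vals.mean(), "sd": vals.std(ddof=1),
                           "display": f"{vals.mean():.4g} ± "
                                      f"{vals.std(ddof=1):.4g}"}
    out = pd.DataFrame(rows).T
    out.index.name = "parameter"
    out.attrs["n"] = len(profiles)
    out.attrs["per_subject"] = results
    return out
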