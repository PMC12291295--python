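"""Non-compartmental analysis of MPA plasma concentration-time profiles.

Oral MPA profiles over a 12-h dosing interval show a primary absorption peak
within the first hours and, in many patients, a secondary peak 6-10 h after
dosing caused by enterohepatic recirculation (biliary MPAG, bacterial
reactivation, re-absorption).  The degree of enterohepatic recirculation is
quantified as the partial-AUC ratio

    EHR% = 100 * AUC(n, 12) / AUC(0, 12)

where ``n`` is the last sampling time before the onset of recirculation.
All AUCs use the linear trapezoidal rule on the *recorded* (not nominal)
sampling times.  The onset itself is detected as the last local minimum in a
configurable window that is followed by a concentration rise of at least a
relative threshold; profiles without a qualifying rebound score EHR% = 0 with
an explicit diagnostic so cohort summaries remain computable.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from . import constants as C

__all__ = [
    "PKProfile",
    "NCAResult",
    "auc_trapezoid",
    "detect_ehr_onset",
    "degree_ehr",
    "summarize_cohort",
]

DEFAULT_ONSET_WINDOW_H = (3.0, 11.0)
DEFAULT_RISE_THRESHOLD = 0.10


@dataclass
class PKProfile:
    """One patient's MPA plasma concentrations over a dosing interval."""

    patient_id: str
    visit: str
    times_h: np.ndarray
    conc_mg_l: np.ndarray
    dose_mg: float | None = None
    truth: dict | None = None

    def __post_init__(self) -> None:
        self.times_h = np.asarray(self.times_h, dtype=float)
        self.conc_mg_l = np.asarray(self.conc_mg_l, dtype=float)
        if self.times_h.ndim != 1 or self.times_h.size < 2:
            raise ValueError("need at least 2 time points")
        if self.times_h.size != self.conc_mg_l.size:
            raise ValueError("times and concentrations must have equal length")
        if self.times_h[0] < 0 or np.any(np.diff(self.times_h) <= 0):
            raise ValueError("times must be non-negative and strictly increasing")
        if np.any(self.conc_mg_l < 0) or not np.all(np.isfinite(self.conc_mg_l)):
            raise ValueError("concentrations must be finite and non-negative")


@dataclass(frozen=True)
class NCAResult:
    patient_id: str
    visit: str
    auc_0_12: float
    onset_n: float | None
    auc_n_12: float
    ehr_percent: float
    c12: float
    cmax: float
    tmax: float
    onset_diagnostic: str


def _index_of_time(profile: PKProfile, t: float) -> int:
    idx = np.flatnonzero(np.isclose(profile.times_h, t, rtol=0.0, atol=1e-9))
    if idx.size == 0:
        raise ValueError(f"time {t} h is not an observed sampling time")
    return int(idx[0])


def auc_trapezoid(
    profile: PKProfile, t_start: float | None = None, t_end: float | None = None
) -> float:
    """Linear trapezoidal AUC (mg·h/L) between two observed time points.

    Defaults to the full observed range.  No extrapolation: both endpoints
    must be members of the recorded grid.
    """
    t_start = profile.times_h[0] if t_start is None else t_start
    t_end = profile.times_h[-1] if t_end is None else t_end
    i, j = _index_of_time(profile, t_start), _index_of_time(profile, t_end)
    if i >= j:
        raise ValueError("t_start must precede t_end")
    return float(np.trapezoid(profile.conc_mg_l[i : j + 1], profile.times_h[i : j + 1]))


def detect_ehr_onset(
    profile: PKProfile,
    window: tuple[float, float] = DEFAULT_ONSET_WINDOW_H,
    rise_threshold: float = DEFAULT_RISE_THRESHOLD,
) -> tuple[float | None, str]:
    """Detect the recirculation onset time ``n``.

    A candidate is an interior local minimum whose time lies inside
    ``window`` and that is followed, at any later sample, by a concentration
    exceeding it by at least ``rise_threshold`` (relative).  The latest
    candidate is returned ("last sampling time before onset"); ``None`` with a
    diagnostic when no rebound qualifies.
    """
    t, c = profile.times_h, profile.conc_mg_l
    if window[0] >= t[-1] or window[1] <= t[0]:
        raise ValueError("onset window lies outside the observed time range")
    onset = None
    for i in range(1, t.size - 1):
        if not (window[0] <= t[i] <= window[1]):
            continue
        if not (c[i] <= c[i - 1] and c[i] <= c[i + 1]):
            continue
        later = c[i + 1 :]
        rebound = np.any((later >= c[i] * (1.0 + rise_threshold)) & (later > c[i]))
        if rebound:
            onset = float(t[i])
    if onset is None:
        return None, "no recirculation detected"
    return onset, "onset detected"


def degree_ehr(
    profile: PKProfile,
    window: tuple[float, float] = DEFAULT_ONSET_WINDOW_H,
    rise_threshold: float = DEFAULT_RISE_THRESHOLD,
    onset_n: float | None = None,
) -> NCAResult:
    """Full NCA of one profile: AUC(0-12), onset, partial AUC, EHR%, trough.

    ``onset_n`` overrides automatic detection (it must be an observed time).
    """
    t, c = profile.times_h, profile.conc_mg_l
    if np.all(c == 0):
        raise ValueError("all-zero profile")
    auc_total = auc_trapezoid(profile)
    if auc_total <= 0:
        raise ValueError("zero total AUC")
    if onset_n is None:
        onset_n, diagnostic = detect_ehr_onset(profile, window, rise_threshold)
    else:
        _index_of_time(profile, onset_n)
        diagnostic = "onset forced"
    if onset_n is None:
        auc_n_12, ehr = 0.0, 0.0
    else:
        auc_n_12 = auc_trapezoid(profile, onset_n, t[-1])
        ehr = 100.0 * auc_n_12 / auc_total
    imax = int(np.argmax(c))
    return NCAResult(
        patient_id=profile.patient_id,
        visit=profile.visit,
        auc_0_12=auc_total,
        onset_n=onset_n,
        auc_n_12=auc_n_12,
        ehr_percent=ehr,
        c12=float(c[-1]),
        cmax=float(c[imax]),
        tmax=float(t[imax]),
        onset_diagnostic=diagnostic,
    )


def summarize_cohort(
    profiles: Sequence[PKProfile],
    nominal_times: Sequence[float] = C.PK_NOMINAL_TIMES_H,
    window: tuple[float, float] = DEFAULT_ONSET_WINDOW_H,
    rise_threshold: float = DEFAULT_RISE_THRESHOLD,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-time mean ± SEM table (nominal-time bins) and per-profile NCA table."""
    if len(profiles) < 2:
        raise ValueError("need at least 2 profiles")
    nominal = np.asarray(nominal_times, dtype=float)
    binned: dict[float, list[float]] = {t: [] for t in nominal}
    for p in profiles:
        for t, c in zip(p.times_h, p.conc_mg_l):
            nearest = float(nominal[np.argmin(np.abs(nominal - t))])
            binned[nearest].append(float(c))
    rows = []
    for t in nominal:
        vals = np.array(binned[t])
        if vals.size == 0:
            continue
        sem = float(np.std(vals, ddof=1) / np.sqrt(vals.size)) if vals.size > 1 else 0.0
        rows.append(
            {"time_h": t, "mean_mg_l": float(vals.mean()), "sem_mg_l": sem, "n": vals.size}
        )
    summary = pd.DataFrame(rows)
    nca = pd.DataFrame(
        [vars(degree_ehr(p, window, rise_threshold)) for p in profiles]
    )
    return summary, nca
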