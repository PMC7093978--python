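"""Depletion ratios, VRRT normalization, and exponential-decay rate fitting.

For each cleavage time point the depletion ratio of PAM p is its
(pseudocount-adjusted) read frequency in the cleaved sample divided by its
frequency in the uncleaved negative control. Ratios are then divided by
the median ratio of the 12 uncleavable VRRT PAMs, which pins the null set
at 1 and removes sample-to-sample scale drift. The normalized time series
y(t) of each PAM is fit by bounded nonlinear least squares to the decay
model

    y(t) = A * exp(-k * t),   k >= 0 (per minute), 0 < A <= 2,

and the rate constants are reported normalized to the maximum fitted k.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .pam import PAM_LENGTH, enumerate_pams, vrrt_pams

__all__ = [
    "DepletionSeries",
    "RateEstimate",
    "RateTable",
    "depletion_ratio",
    "vrrt_normalize",
    "fit_exponential_decay",
    "build_rate_table",
    "estimate_rates",
]


@dataclass(frozen=True)
class DepletionSeries:
    """Normalized depletion ratios y at strictly increasing times t (min)."""

    pam: str
    t: tuple[float, ...]
    y: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.t) != len(self.y):
            raise ValueError("t and y must have equal length")
        if any(b <= a for a, b in zip(self.t, self.t[1:])):
            raise ValueError("time points must be strictly increasing")
        if any(v < 0 for v in self.y):
            raise ValueError("depletion ratios must be nonnegative")


@dataclass(frozen=True)
class RateEstimate:
    """Fitted exponential-decay parameters for one PAM."""

    pam: str
    amplitude: float  # A
    k: float  # per minute
    rss: float
    converged: bool


def depletion_ratio(
    sample: "PamCountTable",
    control: "PamCountTable",
    pseudocount: float = 0.5,
) -> dict[str, float]:
    """Per-PAM depletion ratio: sample frequency / control frequency.

    Both frequencies use pseudocount-adjusted counts, so the ratio is
    finite for every PAM even when a strongly cleaved PAM has zero reads
    at a late time point.
    """
    pams = enumerate_pams(PAM_LENGTH)
    if set(sample.counts) != set(pams) or set(control.counts) != set(pams):
        raise ValueError("count tables must cover all 256 PAMs")
    if control.total_reads_used <= 0:
        raise ValueError("control table is empty")
    tot_s = sample.total_reads_used + pseudocount * len(pams)
    tot_c = control.total_reads_used + pseudocount * len(pams)
    return {
        p: ((sample.counts[p] + pseudocount) / tot_s)
        / ((control.counts[p] + pseudocount) / tot_c)
        for p in pams
    }


def vrrt_normalize(ratios: Mapping[str, float]) -> dict[str, float]:
    """Divide every ratio by the median ratio of the 12 VRRT PAMs.

    The VRRT set is not cleaved by Cas12a, so its median is the per-sample
    null level; after normalization the VRRT median is exactly 1.
    """
    null_set = vrrt_pams()
    missing = [p for p in null_set if p not in ratios]
    if missing:
        raise ValueError(f"ratios missing VRRT PAMs: {missing}")
    med = float(np.median([ratios[p] for p in null_set]))
    if med <= 0:
        raise ValueError(f"degenerate VRRT median {med}")
    return {p: v / med for p, v in ratios.items()}


def fit_exponential_decay(
    series: DepletionSeries,
    xtol: float = 1e-8,
    max_nfev: int = 1000,
) -> RateEstimate:
    """Bounded nonlinear least-squares fit of y(t) = A*exp(-k*t).

    Bounds: k in [0, inf), A in (0, 2]. Initialization: A0 = y(0) (1 if
    y(0) <= 0), k0 from a log-linear regression on the positive points.
    Requires >= 3 points including t = 0. A failed optimization is reported
    with ``converged=False`` rather than raised, so one pathological PAM
    cannot abort a 256-PAM run.
    """
    t = np.asarray(series.t, dtype=float)
    y = np.asarray(series.y, dtype=float)
    if t.size < 3:
        raise ValueError("need at least 3 time points to fit")
    if t[0] != 0:
        raise ValueError("time grid must include t=0")

    a0 = float(np.clip(y[0] if y[0] > 0 else 1.0, 1e-6, 2.0))
    pos = y > 0
    if pos.sum() >= 2:
        slope = np.polyfit(t[pos], np.log(y[pos]), 1)[0]
        k0 = max(-float(slope), 0.0)
    else:
        k0 = 1.0

    def residuals(params: np.ndarray) -> np.ndarray:
        a, k = params
        return a * np.exp(-k * t) - y

    try:
        res = least_squares(
            residuals,
            x0=[a0, k0],
            bounds=([1e-9, 0.0], [2.0, np.inf]),
            xtol=xtol,
            ftol=xtol,
            gtol=xtol,
            max_nfev=max_nfev,
        )
        converged = bool(res.success)
        a_hat, k_hat = (float(res.x[0]), float(res.x[1]))
        rss = float(np.sum(res.fun**2))
    except Exception:
        converged, a_hat, k_hat, rss = False, float("nan"), float("nan"), float("nan")
    return RateEstimate(
        pam=series.pam, amplitude=a_hat, k=k_hat, rss=rss, converged=converged
    )


@dataclass
class RateTable:
    """All per-PAM rate estimates plus max-normalized rates."""

    estimates: dict[str, RateEstimate]
    normalized_rate: dict[str, float]

    @property
    def k_max_pam(self) -> str:
        """The PAM attaining the maximum fitted k (lexicographic tie-break)."""
        conv = [e for e in self.estimates.values() if e.converged]
        return max(conv, key=lambda e: (e.k, [-ord(c) for c in e.pam])).pam

    def to_frame(self) -> pd.DataFrame:
        pams = sorted(self.estimates)
        rows = []
        for p in pams:
            e = self.estimates[p]
            rows.append(
                {
                    "pam": p,
                    "A": e.amplitude,
                    "k": e.k,
                    "rss": e.rss,
                    "converged": e.converged,
                    "normalized_rate": self.normalized_rate.get(p, float("nan")),
                }
            )
        return pd.DataFrame(rows).set_index("pam")

    def to_matrix(self) -> pd.DataFrame:
        """16x16 normalized-rate matrix: rows = first two PAM bases, columns
        = last two — the layout used for PAM-activity heatmaps."""
        duos = ["".join(d) for d in product("ACGT", repeat=2)]
        mat = pd.DataFrame(index=pd.Index(duos, name="first2"), columns=duos, dtype=float)
        for p, v in self.normalized_rate.items():
            mat.loc[p[:2], p[2:]] = v
        mat.columns.name = "last2"
        return mat


def build_rate_table(estimates: Mapping[str, RateEstimate]) -> RateTable:
    """Normalize fitted k by the maximum over converged estimates.

    Non-converged PAMs are excluded from normalization (their
    normalized_rate is NaN). If every converged k is 0 the normalized rates
    are all 0 (degenerate flat run).
    """
    conv = {p: e for p, e in estimates.items() if e.converged}
    if not conv:
        raise ValueError("no converged rate estimates")
    k_max = max(e.k for e in conv.values())
    if k_max > 0:
        norm = {p: e.k / k_max for p, e in conv.items()}
    else:
        norm = {p: 0.0 for p in conv}
    return RateTable(estimates=dict(estimates), normalized_rate=norm)


def estimate_rates(
    samples: Mapping[float, "PamCountTable"],
    control: "PamCountTable",
    pseudocount: float = 0.5,
) -> RateTable:
    """End-to-end kinetics: count tables -> normalized ratios -> rate table.

    The VRRT median normalization is applied independently at each time
    point, which pins y(0) near 1 by construction.
    """
    times = sorted(samples)
    per_time: dict[float, dict[str, float]] = {}
    for t in times:
        ratios = depletion_ratio(samples[t], control, pseudocount=pseudocount)
        per_time[t] = vrrt_normalize(ratios)
    estimates = {}
    for pam in enumerate_pams(PAM_LENGTH):
        series = DepletionSeries(
            pam=pam,
            t=tuple(times),
            y=tuple(per_time[t][pam] for t in times),
        )
        estimates[pam] = fit_exponential_decay(series)
    return build_rate_table(estimates)
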