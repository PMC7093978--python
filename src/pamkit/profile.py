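"""PAM logos (position probability + information content) and class-wise
stringency statistics.

The logo for a nuclease is built from per-PAM weights — by default the
fitted cleavage rate constants, which integrate the whole depletion time
course. Position information content is 2 - H(column) bits against a
uniform background, the quantity drawn as letter height in a web logo.
Stringency is summarized as the ratio of mean activity at each C-containing
PAM class to the mean at the canonical TTTV class.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .kinetics import RateTable
from .pam import PAM_ALPHABET, PAM_LENGTH, classify_pam

__all__ = ["PamProfile", "build_pam_profile", "stringency_ratios", "rank_pams"]


@dataclass
class PamProfile:
    """Position probability matrix and per-position information content."""

    ppm: pd.DataFrame  # positions (1..4) x bases (A,C,G,T)
    information: np.ndarray  # bits per position, in [0, 2]

    @property
    def consensus(self) -> str:
        """Argmax base at each position (lexicographic tie-break)."""
        return "".join(self.ppm.idxmax(axis=1))


def build_pam_profile(weights: Mapping[str, float]) -> PamProfile:
    """Weighted position probability matrix over the 4 PAM positions.

    ``ppm[pos][base]`` is the total weight of PAMs carrying ``base`` at
    ``pos``, normalized by the total weight; information content per
    position is 2 - Shannon entropy in bits. Scale-invariant in the
    weights. Raises if no weight is positive.
    """
    items = [(p, w) for p, w in weights.items() if w > 0]
    if any(w < 0 for w in weights.values()):
        raise ValueError("weights must be nonnegative")
    if not items:
        raise ValueError("at least one weight must be positive")
    n_pos = len(items[0][0])
    mat = np.zeros((n_pos, len(PAM_ALPHABET)))
    base_idx = {b: i for i, b in enumerate(PAM_ALPHABET)}
    for pam, w in items:
        if len(pam) != n_pos:
            raise ValueError("all PAMs must have equal length")
        for pos, base in enumerate(pam):
            mat[pos, base_idx[base]] += w
    ppm = mat / mat.sum(axis=1, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(ppm > 0, ppm * np.log2(ppm), 0.0)
    information = 2.0 + plogp.sum(axis=1)
    frame = pd.DataFrame(
        ppm,
        index=pd.Index(range(1, n_pos + 1), name="position"),
        columns=list(PAM_ALPHABET),
    )
    return PamProfile(ppm=frame, information=information)


def stringency_ratios(
    activity: Mapping[str, float],
    classes: Mapping[str, str] | None = None,
    reference: str = "TTTV",
) -> pd.DataFrame:
    """Mean activity per PAM class relative to the reference class.

    ``activity`` maps a site or PAM to an activity value — either in vitro
    rate constants or in vivo percent-modified values. If ``classes`` is
    None the keys must be 4-mer PAMs and are classified directly. Returns a
    frame with columns (n, mean_activity, ratio_to_reference); the reference
    class has ratio 1 by construction. Lower C-class ratios mean stricter
    PAM recognition.
    """
    if classes is None:
        classes = {key: classify_pam(key) for key in activity}
    groups: dict[str, list[float]] = {}
    for key, value in activity.items():
        groups.setdefault(classes[key], []).append(float(value))
    if reference not in groups:
        raise ValueError(f"no entries in reference class {reference!r}")
    ref_mean = float(np.mean(groups[reference]))
    if ref_mean <= 0:
        raise ValueError(f"reference class mean must be positive, got {ref_mean}")
    rows = [
        {
            "pam_class": cls,
            "n": len(vals),
            "mean_activity": float(np.mean(vals)),
            "ratio_to_reference": float(np.mean(vals)) / ref_mean,
        }
        for cls, vals in sorted(groups.items())
    ]
    return pd.DataFrame(rows).set_index("pam_class")


def rank_pams(
    rates: RateTable | Mapping[str, float], top_n: int | None = None
) -> list[str]:
    """PAMs in descending rate order, ties broken lexicographically."""
    if isinstance(rates, RateTable):
        k = {p: e.k for p, e in rates.estimates.items() if e.converged}
    else:
        k = dict(rates)
    ordered = sorted(k, key=lambda p: (-k[p], p))
    return ordered if top_n is None else ordered[: max(top_n, 0)]
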