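"""Alignment quality filters.

Three filters decide whether a triplet alignment enters the evolutionary
analysis:

1. sliding-window divergence — reject alignments with any 50-column window
   holding more than 12 human-chimp or 17 human-macaque substitution
   differences (misalignment signature);
2. gap fraction — reject alignments with more than 10% gap-containing
   columns;
3. intronic neutrality — reject intron alignments whose human-specific
   substitution ratio falls outside a genome-wide interval (mean ± n·s.d.),
   which guards the neutral reference against locally selected or
   misaligned introns.

A "difference" always means a substitution column: both compared residues in
{A,C,G,T} and unequal.  Indel and N columns never count.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .alignment import TripletAlignment

__all__ = [
    "QCThresholds",
    "NeutralityParams",
    "WindowVerdict",
    "sliding_window_filter",
    "gap_site_fraction",
    "human_specific_ratio",
    "neutrality_filter",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class QCThresholds:
    window: int = 50
    max_hc_diffs: int = 12
    max_hm_diffs: int = 17
    max_gap_fraction: float = 0.10

    def __post_init__(self) -> None:
        if self.window <= 0:
            raise ValueError("window must be positive")
        if min(self.max_hc_diffs, self.max_hm_diffs) < 0 or self.max_gap_fraction < 0:
            raise ValueError("thresholds must be >= 0")


@dataclass(frozen=True)
class NeutralityParams:
    """Accepted human-specific substitution ratio interval: mean ± n_sd·sd."""

    mean: float = 0.0053
    sd: float = 0.0022
    n_sd: float = 2.0

    def __post_init__(self) -> None:
        if self.sd <= 0 or self.n_sd <= 0:
            raise ValueError("sd and n_sd must be positive")

    @property
    def lower(self) -> float:
        return self.mean - self.n_sd * self.sd

    @property
    def upper(self) -> float:
        return self.mean + self.n_sd * self.sd


@dataclass(frozen=True)
class WindowVerdict:
    passed: bool
    failing_window: int | None = None  # start column of the first breaching window
    failing_pair: str | None = None  # "human-chimp" or "human-macaque"
    max_hc: int = 0
    max_hm: int = 0


def _pair_diff_indicator(codes: np.ndarray, i: int, j: int) -> np.ndarray:
    a, b = codes[i], codes[j]
    return ((a < 4) & (b < 4) & (a != b)).astype(np.int64)


def sliding_window_filter(
    aln: TripletAlignment, thr: QCThresholds | None = None
) -> WindowVerdict:
    """Scan every window of ``thr.window`` columns (step 1) for excess divergence.

    Fails iff some window holds strictly more than ``max_hc_diffs``
    human-chimp or ``max_hm_diffs`` human-macaque substitution differences.
    Alignments shorter than the window pass trivially (with a logged warning).
    """
    thr = thr or QCThresholds()
    codes = aln.codes()
    L = codes.shape[1]
    if L < thr.window:
        logger.warning(
            "alignment length %d shorter than window %d: sliding-window filter "
            "passes trivially",
            L,
            thr.window,
        )
        return WindowVerdict(passed=True)
    hc = _pair_diff_indicator(codes, 0, 1)
    hm = _pair_diff_indicator(codes, 0, 2)
    kern = np.ones(thr.window, dtype=np.int64)
    hc_win = np.convolve(hc, kern, mode="valid")
    hm_win = np.convolve(hm, kern, mode="valid")
    bad = (hc_win > thr.max_hc_diffs) | (hm_win > thr.max_hm_diffs)
    if bad.any():
        w = int(np.flatnonzero(bad)[0])
        pair = "human-chimp" if hc_win[w] > thr.max_hc_diffs else "human-macaque"
        return WindowVerdict(
            passed=False,
            failing_window=w,
            failing_pair=pair,
            max_hc=int(hc_win.max()),
            max_hm=int(hm_win.max()),
        )
    return WindowVerdict(passed=True, max_hc=int(hc_win.max()), max_hm=int(hm_win.max()))


def gap_site_fraction(aln: TripletAlignment) -> float:
    """Fraction of alignment columns containing at least one gap character."""
    codes = aln.codes()
    if codes.shape[1] == 0:
        raise ValueError("empty alignment")
    return float((codes == 5).any(axis=0).mean())


def human_specific_ratio(aln: TripletAlignment) -> float:
    """Human-branch substitutions per ungapped site, by strict parsimony.

    Numerator: columns with all three residues in {A,C,G,T} where human
    differs from both chimp and macaque while chimp equals macaque.
    Denominator: all columns with three unambiguous residues.
    """
    codes = aln.codes()
    clean = (codes < 4).all(axis=0)
    denom = int(clean.sum())
    if denom == 0:
        raise ValueError("no gap-free unambiguous columns: ratio undefined")
    h, c, m = codes[0, clean], codes[1, clean], codes[2, clean]
    num = int(((h != c) & (h != m) & (c == m)).sum())
    return num / denom


def neutrality_filter(ratio: float, params: NeutralityParams | None = None) -> bool:
    """True iff the ratio lies inside the accepted interval (endpoints inclusive)."""
    if ratio < 0:
        raise ValueError("ratio must be >= 0")
    params = params or NeutralityParams()
    return params.lower <= ratio <= params.upper
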