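"""Protocol metrics: Score, enrichment value, cost reduction and robustness.

For a candidate protocol (enzyme family or pair plus a size-selection
window) with ``NF`` selected fragments and recovery indicators
``gamma_i`` over ``n`` weighted sites:

    Score      = sum_i w_i * gamma_i
    max_Score  = sum_i w_i
    EV         = -log10( (Score / NF) * (n / max_Score) )
    CRF        = (g / r) / NF

``EV`` (enrichment value) is minimised: it rewards a high per-fragment
yield of target sites.  ``CRF`` (cost reduction factor) compares the
fragment count against whole-genome bisulfite sequencing, whose fragment
count is roughly genome size ``g`` over read length ``r``.

Robustness quantifies how fragile the optimum is to gel-excision error
``delta``: EV is re-evaluated on the 3x3 stencil of windows whose lower
limit and breadth are displaced by +/- delta, and

    theta = sum_stencil |EV_xy - EV_ab| / EV_ab,    R = exp(-theta)

so R in (0, 1], with 1 meaning a locally flat EV landscape.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np

__all__ = [
    "UNDEFINED_EV",
    "ProtocolMetrics",
    "RunConfig",
    "compute_score",
    "enrichment_value",
    "cost_reduction_factor",
    "robustness",
]

#: Sentinel for an undefined enrichment value (NF = 0 or Score = 0).
#: Compares worse than any defined EV.
UNDEFINED_EV = math.inf


@dataclass(frozen=True)
class ProtocolMetrics:
    """The measured quantities of one evaluated protocol."""

    nf: int
    score: float
    max_score: float
    n_sites: int
    ev: float
    crf: float | None = None
    robustness: float | None = None

    def __post_init__(self) -> None:
        if self.nf < 0:
            raise ValueError("NF cannot be negative")
        if not (0.0 <= self.score <= self.max_score + 1e-9):
            raise ValueError(
                f"Score {self.score} outside [0, max_Score={self.max_score}]"
            )
        if self.robustness is not None and not (0.0 < self.robustness <= 1.0):
            raise ValueError(f"robustness {self.robustness} outside (0, 1]")


@dataclass
class RunConfig:
    """User-tunable parameters of a protocol search.

    Parameters
    ----------
    read_length : int
        Single-end read length r in bp (typical range 30-300); determines
        which positions of a selected fragment are observable.
    adapters_size : int
        Total adapter length s in bp added during library preparation;
        shifts the *experimental* size-selection window reported to the
        user relative to the theoretical fragment-length window.
    score_threshold : float
        Fraction c in [0, 1] of max_Score a window must recover.
    genome_size : int | None
        g in bp, used for the CRF; defaults to the digested genome's
        total length.
    nf_constant : float
        k in [0, 1]; the NF ceiling is k * g / 1000, equivalently a
        minimum acceptable CRF of 1000 / (k * r).
    experimental_error : int
        delta in bp (default 20, plausible range 5-500): assumed size-
        selection error; also the grid resolution for candidate windows.
    max_breadth : int
        Widest window breadth considered (default 980 bp).
    output_size : int
        Number of top protocols reported (default 30).
    emit_site_ids : bool
        Attach the recovered site IDs to each reported protocol.
    min_lower, max_lower : int
        Grid limits for the window's lower bound (defaults 20 and
        1000 bp; fragments much shorter than 20 bp are not mappable).
    fixed_range : tuple[int, int] | None
        If set, ``(lower, upper)`` bounds of a single window to evaluate
        instead of the grid (validation-style runs with a predetermined
        size selection).
    """

    read_length: int
    adapters_size: int = 0
    score_threshold: float = 0.25
    genome_size: int | None = None
    nf_constant: float = 0.2
    experimental_error: int = 20
    max_breadth: int = 980
    output_size: int = 30
    emit_site_ids: bool = False
    min_lower: int = 20
    max_lower: int = 1000
    fixed_range: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        if self.read_length < 1:
            raise ValueError("read_length must be >= 1")
        if not (0.0 <= self.score_threshold <= 1.0):
            raise ValueError("score_threshold must lie in [0, 1]")
        if not (0.0 <= self.nf_constant <= 1.0):
            raise ValueError("nf_constant must lie in [0, 1]")
        if self.experimental_error < 1:
            raise ValueError("experimental_error must be >= 1")
        if self.adapters_size < 0:
            raise ValueError("adapters_size cannot be negative")
        if self.fixed_range is not None:
            lo, hi = self.fixed_range
            if not (1 <= lo < hi):
                raise ValueError(f"fixed range {self.fixed_range} is not a valid window")

    def nf_max(self, genome_size: int) -> float:
        """The NF ceiling k * g / 1000 for a genome of ``genome_size`` bp."""
        g = self.genome_size if self.genome_size is not None else genome_size
        return self.nf_constant * g / 1000.0


def compute_score(
    gamma: Sequence[int] | np.ndarray, weights: Sequence[float] | np.ndarray
) -> tuple[float, float]:
    """Weighted recovery score and its maximum.

    Returns ``(Score, max_Score)`` with Score = sum w_i * gamma_i and
    max_Score = sum w_i.
    """
    gamma = np.asarray(gamma, dtype=float)
    weights = np.asarray(weights, dtype=float)
    if gamma.shape != weights.shape:
        raise ValueError("gamma and weights must have equal length")
    if np.any(weights < 0):
        raise ValueError("site weights must be non-negative")
    return float(np.dot(weights, gamma)), float(weights.sum())


def enrichment_value(score: float, nf: int, n: int, max_score: float) -> float:
    """EV = -log10((Score/NF) * (n/max_Score)); lower is better.

    Returns the :data:`UNDEFINED_EV` sentinel (+inf) when NF = 0 or
    Score = 0, so infeasible windows compare as worse than any feasible
    one without raising.
    """
    if nf <= 0 or score <= 0:
        return UNDEFINED_EV
    if n <= 0 or max_score <= 0:
        raise ValueError("n and max_score must be positive")
    return -math.log10((score / nf) * (n / max_score))


def cost_reduction_factor(nf: int, g: int, r: int) -> float:
    """CRF = (g/r) / NF — fold cost reduction versus whole-genome sequencing."""
    if g <= 0 or r <= 0:
        raise ValueError("genome size and read length must be positive")
    if nf <= 0:
        return math.inf
    return (g / r) / nf


def robustness(
    ev_at: Callable[[int, int], float], a: int, b: int, delta: int
) -> float | None:
    """R = exp(-theta) over the 3x3 stencil around the window (a, b).

    ``ev_at(x, y)`` must return the EV of the window with lower limit x
    and breadth y (the sentinel +inf for infeasible windows).  Stencil
    lower limits below 1 bp are clamped to 1; a stencil point whose EV is
    undefined, or whose breadth is non-positive, contributes the full
    relative deviation 1 to theta — fragile optima adjacent to empty
    windows are thus penalised rather than crashing.

    Returns None when the centre EV itself is undefined or <= 0 (theta
    would not be meaningful).
    """
    ev_centre = ev_at(a, b)
    if not math.isfinite(ev_centre) or ev_centre <= 0:
        return None
    theta = 0.0
    for x in (a - delta, a, a + delta):
        for y in (b - delta, b, b + delta):
            if (x, y) == (a, b):
                continue
            if y <= 0:
                ev = UNDEFINED_EV
            else:
                ev = ev_at(max(x, 1), y)
            if math.isfinite(ev):
                theta += abs(ev - ev_centre) / ev_centre
            else:
                theta += 1.0
    return math.exp(-theta)
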