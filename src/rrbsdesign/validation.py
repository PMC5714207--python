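"""Comparing predicted site recovery against experimental sequencing data.

Given the universe of candidate sites (e.g. all CpGs in CpG islands),
the subset a protocol predicts to be sequenced, and the sites actually
observed in an RRBS experiment (each with a read depth), the standard
confusion matrix is computed after filtering the observed set by a
minimum depth — low-depth observations are commonly noise:

    TP  predicted and observed      FP  predicted, not observed
    FN  observed, not predicted     TN  neither

    sensitivity = TP / (TP + FN) * 100
    specificity = TN / (FP + TN) * 100

Site identity is by ID string (conventionally ``chrom:coordinate``),
which avoids coordinate-convention mismatches at the comparison
boundary.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

__all__ = [
    "ObservedSite",
    "ConfusionCounts",
    "read_observed_sites",
    "confusion",
    "sensitivity",
    "specificity",
    "metric_curve",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ObservedSite:
    """A site seen in experimental data, with its read depth."""

    site_id: str
    depth: int

    def __post_init__(self) -> None:
        if self.depth < 1:
            raise ValueError(f"site {self.site_id!r}: depth must be >= 1")


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


def read_observed_sites(path: str | Path) -> list[ObservedSite]:
    """Read a tab-separated ``site_id, depth`` file ('#' comments allowed)."""
    observed: list[ObservedSite] = []
    with open(Path(path)) as fh:
        for line_no, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 2:
                raise ValueError(
                    f"{path} line {line_no}: expected 'site_id<TAB>depth'"
                )
            try:
                depth = int(fields[1])
            except ValueError:
                raise ValueError(
                    f"{path} line {line_no}: non-integer depth {fields[1]!r}"
                ) from None
            observed.append(ObservedSite(fields[0].strip(), depth))
    return observed


def confusion(
    universe: Iterable[str],
    predicted: Iterable[str],
    observed: Sequence[ObservedSite],
    min_depth: int = 1,
) -> ConfusionCounts:
    """Confusion counts of predicted vs observed sites over a site universe.

    Observed sites are first filtered to depth >= ``min_depth``.
    Predicted sites must be a subset of the universe; observed IDs
    outside the universe are logged and dropped.
    """
    universe_set = set(universe)
    if not universe_set:
        raise ValueError("site universe is empty")
    predicted_set = set(predicted)
    stray = predicted_set - universe_set
    if stray:
        raise ValueError(
            f"{len(stray)} predicted sites are not in the universe "
            f"(e.g. {sorted(stray)[:3]})"
        )
    observed_set = set()
    dropped = 0
    for site in observed:
        if site.site_id not in universe_set:
            dropped += 1
            continue
        if site.depth >= min_depth:
            observed_set.add(site.site_id)
    if dropped:
        logger.warning("dropped %d observed sites outside the universe", dropped)

    tp = len(predicted_set & observed_set)
    fp = len(predicted_set - observed_set)
    fn = len(observed_set - predicted_set)
    tn = len(universe_set) - len(predicted_set | observed_set)
    return ConfusionCounts(tp=tp, tn=tn, fp=fp, fn=fn)


def sensitivity(counts: ConfusionCounts) -> float | None:
    """TP / (TP + FN) * 100, or None when no site was observed."""
    denom = counts.tp + counts.fn
    if denom == 0:
        return None
    return counts.tp / denom * 100.0


def specificity(counts: ConfusionCounts) -> float | None:
    """TN / (FP + TN) * 100, or None when everything was observed."""
    denom = counts.fp + counts.tn
    if denom == 0:
        return None
    return counts.tn / denom * 100.0


def metric_curve(
    universe: Iterable[str],
    predicted: Iterable[str],
    observed: Sequence[ObservedSite],
    depth_thresholds: Sequence[int],
) -> pd.DataFrame:
    """Sensitivity/specificity as a function of the depth-of-coverage cutoff.

    Returns one row per threshold with columns ``min_depth, tp, tn, fp,
    fn, sensitivity, specificity`` (the metrics are NaN where undefined).
    Thresholds must be sorted ascending.
    """
    thresholds = list(depth_thresholds)
    if thresholds != sorted(thresholds):
        raise ValueError("depth thresholds must be sorted ascending")
    universe_set = set(universe)
    predicted_set = set(predicted)
    rows = []
    for t in thresholds:
        c = confusion(universe_set, predicted_set, observed, min_depth=t)
        rows.append(
            {
                "min_depth": t,
                "tp": c.tp,
                "tn": c.tn,
                "fp": c.fp,
                "fn": c.fn,
                "sensitivity": sensitivity(c),
                "specificity": specificity(c),
            }
        )
    return pd.DataFrame(rows)
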