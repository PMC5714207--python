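"""Exhaustive protocol search over enzymes, pairs and size-selection windows.

For every isoschizomer family and every unordered pair of families, the
genome is digested (pairs take the union of cut sites), fragments are
built once, and all candidate size-selection windows on a grid with
resolution equal to the assumed experimental error are evaluated.
Windows failing either threshold — recovered Score below the configured
fraction of max_Score, or fragment count NF above k*g/1000 — are
discarded; among the survivors the window minimising the enrichment
value EV wins.  Combinations are then ranked by EV and the top-t written
to a tab-separated report.

The per-window evaluation is O(log F) after one sort: NF is a range
count over sorted fragment lengths, and Score a prefix-sum difference
over the (fragment length, weight) pairs of the sites that are close
enough to a fragment end to be read at all.  Whether a site is within
``read_length`` of an end does not depend on the window, so it is
precomputed once per combination.
"""

from __future__ import annotations

import itertools
import math
from bisect import bisect_right
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .catalog import IsoschizomerFamily
from .digestion import CutSiteIndex, digest_genome, merge_cut_indices, read_precomputed
from .fragmentation import (
    Fragment,
    SiteOfInterest,
    SizeRange,
    build_fragments,
    recovered_sites,
    select_by_size,
)
from .genome import GenomeSequence
from .scoring import (
    ProtocolMetrics,
    RunConfig,
    cost_reduction_factor,
    enrichment_value,
    robustness,
)

__all__ = [
    "ProtocolResult",
    "candidate_ranges",
    "evaluate_combination",
    "run_search",
    "write_report",
    "precomputed_filename",
]

#: Absolute tolerance below which two EVs are considered tied in ranking.
EV_TIE_TOL = 1e-12


@dataclass
class ProtocolResult:
    """One reported protocol: enzyme family (or pair), window and metrics."""

    enzymes: tuple[str, ...]
    size_range: SizeRange
    metrics: ProtocolMetrics
    experimental_range: tuple[int, int]
    recovered_site_ids: list[str] | None = None

    @property
    def label(self) -> str:
        return "+".join(self.enzymes)


def candidate_ranges(
    delta: int, max_breadth: int, min_lower: int, max_lower: int
) -> list[SizeRange]:
    """The delta-resolution grid of candidate windows.

    Lower limits run from ``min_lower`` to ``max_lower`` in steps of
    ``delta``; breadths from ``delta`` to ``max_breadth`` in steps of
    ``delta``.  Sampling finer than the experimental size-selection error
    would distinguish windows a gel cannot.
    """
    if delta < 1:
        raise ValueError("grid resolution delta must be >= 1")
    lowers = list(range(min_lower, max_lower + 1, delta))
    breadths = list(range(delta, max_breadth + 1, delta))
    if not lowers or not breadths:
        raise ValueError(
            f"empty size-range grid (lowers {min_lower}..{max_lower}, "
            f"breadths up to {max_breadth}, step {delta})"
        )
    return [SizeRange(a, b) for a in lowers for b in breadths]


class _Landscape:
    """Sorted-length machinery for O(log F) NF/Score queries per window."""

    def __init__(
        self,
        fragments: Sequence[Fragment],
        sites: Sequence[SiteOfInterest],
        read_length: int,
    ) -> None:
        self.frag_lengths = np.sort(
            np.fromiter((f.length for f in fragments), dtype=np.int64,
                        count=len(fragments))
        )
        # For each site: the length of its containing fragment, kept only
        # if the site is within read_length of a fragment end (otherwise
        # no window can ever recover it).
        by_chrom: dict[str, tuple[list[int], list[int]]] = {}
        for frag in sorted(fragments, key=lambda f: (f.chrom, f.start)):
            starts, ends = by_chrom.setdefault(frag.chrom, ([], []))
            starts.append(frag.start)
            ends.append(frag.end)
        flens: list[int] = []
        weights: list[float] = []
        for site in sites:
            if site.chrom not in by_chrom:
                continue
            starts, ends = by_chrom[site.chrom]
            j = bisect_right(starts, site.coord) - 1
            if j < 0:
                continue
            s, e = starts[j], ends[j]
            if not (s <= site.coord < e):
                continue
            if (site.coord - s < read_length) or (e - site.coord <= read_length):
                flens.append(e - s)
                weights.append(site.weight)
        order = np.argsort(np.asarray(flens, dtype=np.int64), kind="stable")
        self.site_flens = np.asarray(flens, dtype=np.int64)[order]
        w = np.asarray(weights, dtype=float)[order]
        self.cum_weights = np.concatenate([[0.0], np.cumsum(w)])

    def nf(self, lower: int, upper: int) -> int:
        lo = np.searchsorted(self.frag_lengths, lower, side="left")
        hi = np.searchsorted(self.frag_lengths, upper, side="right")
        return int(hi - lo)

    def score(self, lower: int, upper: int) -> float:
        lo = np.searchsorted(self.site_flens, lower, side="left")
        hi = np.searchsorted(self.site_flens, upper, side="right")
        return float(self.cum_weights[hi] - self.cum_weights[lo])


def _combination_index(
    families: Sequence[IsoschizomerFamily],
    genome: GenomeSequence,
    indices: Mapping[str, CutSiteIndex] | None,
) -> CutSiteIndex:
    ordered = sorted(families, key=lambda f: f.family_id)
    parts = []
    for fam in ordered:
        if indices is not None and fam.family_id in indices:
            parts.append(indices[fam.family_id])
        else:
            parts.append(digest_genome(genome, fam))
    index = parts[0]
    for other in parts[1:]:
        index = merge_cut_indices(index, other)
    return index


def evaluate_combination(
    families: Sequence[IsoschizomerFamily],
    sites: Sequence[SiteOfInterest],
    genome: GenomeSequence,
    config: RunConfig,
    indices: Mapping[str, CutSiteIndex] | None = None,
) -> ProtocolResult | None:
    """Best window for one enzyme family or unordered pair, or None.

    Evaluates every candidate window (or the single fixed window), drops
    those with Score < c * max_Score or NF > k * g / 1000, and returns
    the surviving window with the lowest EV (ties broken by smaller
    lower limit, then smaller breadth).  Robustness and CRF are computed
    for the winning window only.
    """
    if not 1 <= len(families) <= 2:
        raise ValueError("a combination is one family or an unordered pair")
    if not sites:
        raise ValueError("no sites of interest given")

    index = _combination_index(families, genome, indices)
    fragments = build_fragments(index, genome)
    land = _Landscape(fragments, sites, config.read_length)

    n = len(sites)
    max_score = float(sum(s.weight for s in sites))
    g = config.genome_size if config.genome_size is not None else genome.total_length
    nf_max = config.nf_max(genome.total_length)
    min_score = config.score_threshold * max_score

    if config.fixed_range is not None:
        lo, hi = config.fixed_range
        ranges = [SizeRange(lo, hi - lo)]
    else:
        ranges = candidate_ranges(
            config.experimental_error,
            config.max_breadth,
            config.min_lower,
            config.max_lower,
        )

    best: tuple[float, int, int] | None = None  # (ev, a, b)
    best_nf = 0
    best_score = 0.0
    for rng in ranges:
        nf = land.nf(rng.lower, rng.upper)
        if nf > nf_max:
            continue
        score = land.score(rng.lower, rng.upper)
        if score < min_score - EV_TIE_TOL:
            continue
        ev = enrichment_value(score, nf, n, max_score)
        if not math.isfinite(ev):
            continue
        key = (ev, rng.lower, rng.breadth)
        if best is None or ev < best[0] - EV_TIE_TOL or (
            abs(ev - best[0]) <= EV_TIE_TOL and key < best
        ):
            best = key
            best_nf = nf
            best_score = score
    if best is None:
        return None

    ev, a, b = best

    def ev_at(x: int, y: int) -> float:
        return enrichment_value(land.score(x, x + y), land.nf(x, x + y), n, max_score)

    rob = robustness(ev_at, a, b, config.experimental_error)
    crf = cost_reduction_factor(best_nf, g, config.read_length)
    metrics = ProtocolMetrics(
        nf=best_nf,
        score=best_score,
        max_score=max_score,
        n_sites=n,
        ev=ev,
        crf=crf,
        robustness=rob,
    )
    winner = SizeRange(a, b)
    site_ids: list[str] | None = None
    if config.emit_site_ids:
        selected, _ = select_by_size(fragments, winner)
        _, site_ids = recovered_sites(selected, sites, config.read_length)
    s = config.adapters_size
    return ProtocolResult(
        enzymes=tuple(sorted(f.family_id for f in families)),
        size_range=winner,
        metrics=metrics,
        experimental_range=(a + s, a + b + s),
        recovered_site_ids=site_ids,
    )


def _rank_key(result: ProtocolResult) -> tuple:
    rob = result.metrics.robustness
    return (
        result.metrics.ev,
        -(rob if rob is not None else 0.0),
        result.metrics.nf,
        result.enzymes,
    )


def run_search(
    catalog: Sequence[IsoschizomerFamily],
    sites: Sequence[SiteOfInterest],
    genome: GenomeSequence,
    config: RunConfig,
    precomputed_dir: str | Path | None = None,
) -> list[ProtocolResult]:
    """Evaluate all single families and unordered pairs; return the top t.

    With F families, F + F*(F-1)/2 combinations are evaluated.  Each
    family is digested once (or loaded from ``precomputed_dir``) and the
    per-family indices are reused across pairs.  Results are sorted by EV
    ascending with deterministic tie-breaking (robustness descending,
    then NF ascending, then family names) and truncated to
    ``config.output_size``.
    """
    if not catalog:
        raise ValueError("enzyme catalog is empty")
    if not sites:
        raise ValueError("no sites of interest given")

    indices: dict[str, CutSiteIndex] = {}
    for fam in catalog:
        loaded = None
        if precomputed_dir is not None:
            candidate = Path(precomputed_dir) / precomputed_filename(
                genome.genome_id, fam.family_id
            )
            if candidate.exists():
                loaded = read_precomputed(candidate, expect_genome_id=genome.genome_id)
        indices[fam.family_id] = loaded or digest_genome(genome, fam)

    combos: list[tuple[IsoschizomerFamily, ...]] = [(f,) for f in catalog]
    combos.extend(itertools.combinations(catalog, 2))

    results = []
    for combo in combos:
        res = evaluate_combination(combo, sites, genome, config, indices=indices)
        if res is not None:
            results.append(res)
    results.sort(key=_rank_key)
    return results[: config.output_size]


def precomputed_filename(genome_id: str, family_id: str) -> str:
    """Canonical file name for a pre-computed digest of one family."""
    return f"{genome_id}__{family_id}.cuts.txt.gz"


_REPORT_COLUMNS = [
    "rank",
    "enzymes",
    "theoretical_range",
    "experimental_range",
    "NF",
    "Score",
    "max_Score",
    "EV",
    "CRF",
    "robustness",
]


def write_report(
    results: Sequence[ProtocolResult], path: str | Path, config: RunConfig
) -> None:
    """Write the ranked protocol table as tab-separated text.

    ``#`` header lines record every run parameter for reproducibility.
    CRF is printed to one decimal place; EV and robustness to six.  When
    site IDs were requested an extra column holds them comma-joined.
    """
    path = Path(path)
    columns = list(_REPORT_COLUMNS)
    if config.emit_site_ids:
        columns.append("recovered_site_ids")
    with open(path, "w") as fh:
        fh.write("# protocol search report\n")
        for key in (
            "read_length", "adapters_size", "score_threshold", "genome_size",
            "nf_constant", "experimental_error", "max_breadth", "output_size",
            "min_lower", "max_lower", "fixed_range",
        ):
            fh.write(f"# {key}={getattr(config, key)}\n")
        fh.write("\t".join(columns) + "\n")
        for rank, res in enumerate(results, start=1):
            m = res.metrics
            row = [
                str(rank),
                res.label,
                str(res.size_range),
                f"{res.experimental_range[0]}-{res.experimental_range[1]}",
                str(m.nf),
                f"{m.score:g}",
                f"{m.max_score:g}",
                f"{m.ev:.6f}",
                "NA" if m.crf is None or math.isinf(m.crf) else f"{m.crf:.1f}",
                "NA" if m.robustness is None else f"{m.robustness:.6f}",
            ]
            if config.emit_site_ids:
                row.append(",".join(res.recovered_site_ids or []))
            fh.write("\t".join(row) + "\n")
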