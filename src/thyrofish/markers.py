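"""Differential region ranking and greedy minimal-marker selection.

Samples are compared on the union-breakpoint grid: the intervals between
consecutive breakpoints pooled over every sample's segment boundaries.
Each (sample, region) cell carries the covering segment's mean and its
aberration state (loss / normal / gain); a probe belongs to a region iff
its midpoint does.

Regions are ranked by a two-sided Wilcoxon rank-sum test between classes.
By default the test runs on the ordinal aberration states (-1/0/+1), whose
heavy ties are handled by the tie-corrected normal approximation with
continuity correction: recurrent aberrations are discrete carrier/
non-carrier contrasts, and testing the raw segment means instead dilutes a
minority of strong carriers into the noise ranks of the majority (a 5-of-33
carrier subgroup is then invisible at any amplitude).  Testing the
continuous segment means remains available (``on="values"``); with small
groups and no ties it uses the exact enumeration null.

Selection follows the iterative greedy procedure: keep regions significant
below the p threshold in which every cFA is normal, then repeatedly take
the region covering the most not-yet-covered cFTC samples (ties broken by
smaller p, then genome order) until no region adds coverage.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy.stats import mannwhitneyu

from .core import AberrationCall, ProbeSet, Segment
from .genome import GenomicRegion, chrom_sort_key

logger = logging.getLogger(__name__)

_STATE_CODE = {"loss": -1, "normal": 0, "gain": 1}


@dataclass
class RegionMatrix:
    """Per-sample segment means and call states on the union-breakpoint grid."""

    regions: list[GenomicRegion]          # genome-ordered, non-overlapping
    sample_ids: list[str]
    values: np.ndarray                    # (n_samples, n_regions) float
    states: np.ndarray                    # (n_samples, n_regions) int8 in {-1,0,1}
    region_probes: list[tuple[int, int]]  # probe index span of each region

    def state_name(self, sample: int, region: int) -> str:
        return {-1: "loss", 0: "normal", 1: "gain"}[int(self.states[sample, region])]


@dataclass
class RankedRegion:
    """A region with its class-differential test result and cFTC coverage."""

    region: GenomicRegion
    region_index: int
    p_value: float
    direction: str                 # "gain" or "loss" (cFTC-enriched direction)
    coverage: frozenset[str]       # cFTC samples aberrant in that direction
    all_cfa_normal: bool

    def __post_init__(self) -> None:
        if not (0 <= self.p_value <= 1):
            raise ValueError("p-value out of [0, 1]")


def build_region_matrix(
    segments_by_sample: Mapping[str, Sequence[Segment]],
    calls_by_sample: Mapping[str, Sequence[AberrationCall]],
    probes: ProbeSet,
) -> RegionMatrix:
    """Region grid from the union of all samples' segment boundaries."""
    sample_ids = list(segments_by_sample)
    breakpoints: dict[str, set[int]] = {}
    for segments in segments_by_sample.values():
        for seg in segments:
            bp = breakpoints.setdefault(seg.chromosome, set())
            bp.add(seg.istart)
            bp.add(seg.iend)
    regions: list[GenomicRegion] = []
    spans: list[tuple[int, int]] = []
    for chrom in sorted(breakpoints, key=chrom_sort_key):
        cuts = sorted(breakpoints[chrom])
        for lo, hi in zip(cuts[:-1], cuts[1:]):
            regions.append(
                GenomicRegion(
                    chrom, int(probes.starts[lo]), int(probes.ends[hi - 1])
                )
            )
            spans.append((lo, hi))

    values = np.zeros((len(sample_ids), len(regions)))
    states = np.zeros((len(sample_ids), len(regions)), dtype=np.int8)
    for r, sid in enumerate(sample_ids):
        seg_state = {
            (c.segment.istart, c.segment.iend): _STATE_CODE[c.state]
            for c in calls_by_sample.get(sid, [])
        }
        for seg in segments_by_sample[sid]:
            code = seg_state.get((seg.istart, seg.iend), 0)
            for j, (lo, hi) in enumerate(spans):
                if lo >= seg.istart and hi <= seg.iend:
                    values[r, j] = seg.mean
                    states[r, j] = code
    return RegionMatrix(regions, sample_ids, values, states, spans)


def _wilcoxon_p(x: np.ndarray, y: np.ndarray) -> float:
    """Two-sided rank-sum p: exact enumeration for small tie-free groups,
    tie-corrected normal approximation with continuity correction otherwise."""
    if np.all(x == x[0]) and np.all(y == y[0]) and x[0] == y[0]:
        return 1.0
    pooled = np.concatenate([x, y])
    has_ties = len(np.unique(pooled)) < len(pooled)
    if not has_ties and min(len(x), len(y)) <= 10:
        method = "exact"
    else:
        method = "asymptotic"
    res = mannwhitneyu(x, y, alternative="two-sided", method=method,
                       use_continuity=True)
    return float(min(res.pvalue, 1.0))


def rank_regions(
    matrix: RegionMatrix,
    labels: Mapping[str, str],
    on: str = "states",
) -> list[RankedRegion]:
    """Rank regions by increasing raw Wilcoxon p-value (cFA vs cFTC).

    ``on="states"`` (default) tests the ordinal -1/0/+1 aberration states;
    ``on="values"`` tests the continuous segment means.
    """
    if on not in ("states", "values"):
        raise ValueError("on must be 'states' or 'values'")
    cfa_idx = [i for i, s in enumerate(matrix.sample_ids) if labels[s] == "cFA"]
    cftc_idx = [i for i, s in enumerate(matrix.sample_ids) if labels[s] == "cFTC"]
    if not cfa_idx or not cftc_idx:
        raise ValueError("both classes must be non-empty")
    data = matrix.states if on == "states" else matrix.values
    ranked: list[RankedRegion] = []
    for j, region in enumerate(matrix.regions):
        x = np.asarray(data[cfa_idx, j], dtype=np.float64)
        y = np.asarray(data[cftc_idx, j], dtype=np.float64)
        p = _wilcoxon_p(x, y)
        # direction: the aberrant state with the larger cFTC-minus-cFA excess
        st = matrix.states
        gain_excess = (st[cftc_idx, j] == 1).mean() - (st[cfa_idx, j] == 1).mean()
        loss_excess = (st[cftc_idx, j] == -1).mean() - (st[cfa_idx, j] == -1).mean()
        direction = "gain" if gain_excess >= loss_excess else "loss"
        code = 1 if direction == "gain" else -1
        coverage = frozenset(
            matrix.sample_ids[i] for i in cftc_idx if st[i, j] == code
        )
        all_cfa_normal = bool(np.all(st[cfa_idx, j] == 0))
        ranked.append(
            RankedRegion(region, j, p, direction, coverage, all_cfa_normal)
        )
    ranked.sort(key=lambda r: (r.p_value, chrom_sort_key(r.region.chromosome),
                               r.region.start))
    return ranked


def select_minimal_markers(
    ranked: Sequence[RankedRegion],
    p_threshold: float = 0.05,
) -> list[RankedRegion]:
    """Greedy minimal discriminating set over the significant cFA-clean regions.

    Candidates must have p < ``p_threshold`` and be normal in every cFA.
    Repeatedly selects the candidate covering the most not-yet-covered cFTC
    samples; ties break toward smaller raw p, then genome order.  Stops
    when no candidate adds coverage.  The selected set never contains a
    region aberrant in any cFA (asserted).
    """
    candidates = [
        r for r in ranked if r.p_value < p_threshold and r.all_cfa_normal
    ]
    if not candidates:
        logger.warning("no significant cFA-clean candidate regions")
        return []
    selected: list[RankedRegion] = []
    covered: set[str] = set()
    remaining = list(candidates)
    while remaining:
        best = max(
            remaining,
            key=lambda r: (
                len(r.coverage - covered),
                -r.p_value,
                -chrom_sort_key(r.region.chromosome),
                -r.region.start,
            ),
        )
        gain = len(best.coverage - covered)
        if gain == 0:
            break
        selected.append(best)
        covered |= best.coverage
        remaining.remove(best)
    assert all(r.all_cfa_normal for r in selected)
    return selected


def minimal_common_region(
    intervals: Sequence[GenomicRegion],
) -> GenomicRegion:
    """Intersection of the aberrant intervals of all carrying samples."""
    if not intervals:
        raise ValueError("at least one carrying sample is required")
    chrom = intervals[0].chromosome
    if any(iv.chromosome != chrom for iv in intervals):
        raise ValueError("carrier intervals lie on different chromosomes")
    start = max(iv.start for iv in intervals)
    end = min(iv.end for iv in intervals)
    if start >= end:
        offenders = [f"{iv.chromosome}:{iv.start}-{iv.end}" for iv in intervals]
        raise ValueError(
            "carrier intervals have empty intersection: " + ", ".join(offenders)
        )
    return GenomicRegion(chrom, start, end)


def marker_carrier_interval(
    calls: Sequence[AberrationCall], seed_region: GenomicRegion, state: str
) -> GenomicRegion | None:
    """One sample's aberrant interval of the given state overlapping the seed."""
    for call in calls:
        if call.state != state:
            continue
        seg = call.segment
        region = GenomicRegion(seg.chromosome, seg.start, seg.end)
        if region.overlaps(seed_region):
            return region
    return None
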