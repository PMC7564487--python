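"""Core domain types: probe grids, log2-ratio profiles, segments and calls."""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterator

import numpy as np

from .genome import CHROM_ORDER, GenomicRegion, chrom_sort_key, normalize_chrom

CLASS_LABELS = ("cFA", "cFTC", "unknown")
SEXES = ("female", "male")


@dataclass(frozen=True)
class ProbeSet:
    """Ordered genomic probe grid with GC content.

    Probes are sorted by (chromosome order, start); every profile in an
    analysis is aligned to one ProbeSet by index.
    """

    ids: np.ndarray          # str
    chromosomes: np.ndarray  # bare names, str
    starts: np.ndarray       # int64, 0-based
    ends: np.ndarray         # int64, half-open
    gc: np.ndarray           # float64 in [0, 1]

    def __post_init__(self) -> None:
        n = len(self.ids)
        for name in ("chromosomes", "starts", "ends", "gc"):
            if len(getattr(self, name)) != n:
                raise ValueError("probe arrays must have equal length")
        if n == 0:
            raise ValueError("empty probe set")
        if len(set(self.ids.tolist())) != n:
            raise ValueError("duplicate probe ids")
        if np.any(self.starts >= self.ends):
            raise ValueError("probe start must be < end")
        if np.any((self.gc < 0) | (self.gc > 1)):
            raise ValueError("GC fraction must lie in [0, 1]")
        ranks = np.array([chrom_sort_key(c) for c in self.chromosomes])
        order = np.lexsort((self.starts, ranks))
        if not np.array_equal(order, np.arange(n)):
            raise ValueError("probes must be sorted by (chromosome, start)")
        for chrom, count in zip(*np.unique(self.chromosomes, return_counts=True)):
            if count < 3:
                raise ValueError(
                    f"chromosome {chrom} has {count} probes; at least 3 required"
                )

    def __len__(self) -> int:
        return len(self.ids)

    @property
    def midpoints(self) -> np.ndarray:
        return (self.starts + self.ends) // 2

    @property
    def chrom_list(self) -> list[str]:
        seen: list[str] = []
        for c in self.chromosomes:
            if not seen or seen[-1] != c:
                seen.append(str(c))
        return seen

    def chrom_slice(self, chrom: str) -> slice:
        """Contiguous index slice of a chromosome's probes."""
        chrom = normalize_chrom(chrom)
        idx = np.flatnonzero(self.chromosomes == chrom)
        if idx.size == 0:
            raise KeyError(f"chromosome {chrom} not in probe set")
        return slice(int(idx[0]), int(idx[-1]) + 1)

    def region_mask(self, region: GenomicRegion) -> np.ndarray:
        """Probes whose midpoint falls inside the region (midpoint rule)."""
        mid = self.midpoints
        return (
            (self.chromosomes == normalize_chrom(region.chromosome))
            & (mid >= region.start)
            & (mid < region.end)
        )


def build_probe_set(
    ids: list[str],
    chromosomes: list[str],
    starts: list[int],
    ends: list[int],
    gc: list[float],
) -> ProbeSet:
    """Construct a ProbeSet from columns, sorting by genome order."""
    chroms = np.array([normalize_chrom(c) for c in chromosomes], dtype=object)
    starts_a = np.asarray(starts, dtype=np.int64)
    ranks = np.array([chrom_sort_key(c) for c in chroms])
    order = np.lexsort((starts_a, ranks))
    return ProbeSet(
        ids=np.asarray(ids, dtype=object)[order],
        chromosomes=chroms[order],
        starts=starts_a[order],
        ends=np.asarray(ends, dtype=np.int64)[order],
        gc=np.asarray(gc, dtype=np.float64)[order],
    )


@dataclass
class AcghProfile:
    """Per-probe log2(Cy5/Cy3) ratios for one sample, aligned to a ProbeSet."""

    sample_id: str
    values: np.ndarray                 # float64, len == len(probe set)
    label: str = "unknown"             # cFA | cFTC | unknown
    sex: str = "female"
    purity: float = 1.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if not np.all(np.isfinite(self.values)):
            raise ValueError(f"profile {self.sample_id}: non-finite log2 ratios")
        if self.label not in CLASS_LABELS:
            raise ValueError(f"unknown class label {self.label!r}")
        if self.sex not in SEXES:
            raise ValueError(f"unknown sex {self.sex!r}")
        if not (0 < self.purity <= 1):
            raise ValueError("purity must lie in (0, 1]")

    def with_values(self, values: np.ndarray) -> "AcghProfile":
        return replace(self, values=np.asarray(values, dtype=np.float64))


@dataclass(frozen=True)
class Segment:
    """Piecewise-constant summary of a run of consecutive probes."""

    chromosome: str
    start: int            # bp, 0-based (start of first probe)
    end: int              # bp, half-open (end of last probe)
    mean: float           # mean log2 ratio over member probes
    n_probes: int
    istart: int           # probe index range [istart, iend) in the ProbeSet
    iend: int

    def __post_init__(self) -> None:
        if self.n_probes < 1 or self.iend - self.istart != self.n_probes:
            raise ValueError("segment probe bookkeeping inconsistent")


@dataclass(frozen=True)
class AberrationCall:
    """A segment called as gained or lost against a per-profile threshold."""

    segment: Segment
    state: str            # "gain" | "loss"
    threshold: float

    def __post_init__(self) -> None:
        if self.state not in ("gain", "loss"):
            raise ValueError(f"invalid aberration state {self.state!r}")
        if self.state == "gain" and not self.segment.mean >= self.threshold:
            raise ValueError("gain call below threshold")
        if self.state == "loss" and not self.segment.mean <= -self.threshold:
            raise ValueError("loss call above threshold")


def check_partition(segments: list[Segment], n_probes: int) -> None:
    """Assert segments tile the probe index range [0, n_probes) exactly."""
    pos = 0
    for seg in segments:
        if seg.istart != pos:
            raise AssertionError(
                f"segment gap/overlap at probe {pos} (segment starts at {seg.istart})"
            )
        pos = seg.iend
    if pos != n_probes:
        raise AssertionError(f"segments end at probe {pos}, expected {n_probes}")


@dataclass
class Phenotype:
    """Sample-level annotations travelling beside the numeric probe matrix."""

    sample_id: str
    label: str
    sex: str
    purity: float


def sort_chromosomes(chroms: Iterator[str]) -> list[str]:
    return sorted(set(chroms), key=chrom_sort_key)


__all__ = [
    "AberrationCall",
    "AcghProfile",
    "CHROM_ORDER",
    "CLASS_LABELS",
    "Phenotype",
    "ProbeSet",
    "Segment",
    "build_probe_set",
    "check_partition",
    "sort_chromosomes",
]
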