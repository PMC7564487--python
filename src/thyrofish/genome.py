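"""Genome coordinate model: chromosomes, cytobands, band-range resolution.

Coordinates are 0-based half-open internally.  Chromosome names are
normalized to bare names ("1".."22", "X", "Y"); "chr"-prefixed names are
accepted on input and written on output.

The bundled fixture ``data/cytoBand_hg19like_synthetic.tsv`` is a synthetic,
hg19-approximate banding table (hg19 chromosome lengths, self-consistent
band boundaries) so that no download is ever required; a real UCSC
cytoBand.txt in the same 5-column dialect is accepted wherever a cytoband
path is taken.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from typing import Iterable

CHROM_ORDER: tuple[str, ...] = tuple(str(i) for i in range(1, 23)) + ("X", "Y")
_CHROM_RANK = {c: i for i, c in enumerate(CHROM_ORDER)}


class CytobandFormatError(ValueError):
    """Raised when a cytoband file violates the UCSC dialect or tiling rules."""


def normalize_chrom(name: str) -> str:
    """Map 'chr1'/'1' -> '1'; raise on unknown chromosomes."""
    bare = name[3:] if name.lower().startswith("chr") else name
    bare = bare.upper() if bare.upper() in ("X", "Y") else bare
    if bare not in _CHROM_RANK:
        raise ValueError(f"unknown chromosome name: {name!r}")
    return bare


def chrom_sort_key(name: str) -> int:
    return _CHROM_RANK[normalize_chrom(name)]


@dataclass(frozen=True)
class Band:
    name: str          # e.g. "p36.33"
    start: int         # 0-based
    end: int           # half-open
    arm: str           # "p" or "q"


@dataclass(frozen=True)
class GenomicRegion:
    """A half-open genomic interval, optionally carrying a band-range name."""

    chromosome: str
    start: int
    end: int
    name: str | None = None

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid region bounds: {self.start}..{self.end}")

    def overlaps(self, other: "GenomicRegion") -> bool:
        return (
            self.chromosome == other.chromosome
            and self.start < other.end
            and other.start < self.end
        )

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class GenomeMap:
    """Ordered chromosomes with lengths and banding.

    Invariants (enforced by :func:`read_cytobands`): bands of one chromosome
    are sorted, non-overlapping and tile [0, length); band names are unique
    per chromosome; all p bands precede all q bands.
    """

    chromosomes: list[str]
    lengths: dict[str, int]
    bands: dict[str, list[Band]] = field(default_factory=dict)

    def length(self, chrom: str) -> int:
        return self.lengths[normalize_chrom(chrom)]

    def band(self, chrom: str, band_name: str) -> Band:
        chrom = normalize_chrom(chrom)
        for b in self.bands.get(chrom, []):
            if b.name == band_name:
                return b
        raise KeyError(f"band {band_name!r} not found on chromosome {chrom}")

    def subset(self, chromosomes: Iterable[str]) -> "GenomeMap":
        keep = [normalize_chrom(c) for c in chromosomes]
        return GenomeMap(
            chromosomes=[c for c in self.chromosomes if c in keep],
            lengths={c: self.lengths[c] for c in keep},
            bands={c: self.bands.get(c, []) for c in keep},
        )


def read_cytobands(path) -> GenomeMap:
    """Parse a UCSC-dialect cytoband file (chrom, start, end, band, stain).

    Input coordinates are 0-based half-open.  Chromosome length is taken as
    the maximum band end.  Overlapping, unsorted or non-tiling bands raise
    :class:`CytobandFormatError` naming the offending line.
    """
    per_chrom: dict[str, list[tuple[int, Band]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 5:
                raise CytobandFormatError(
                    f"line {lineno}: expected 5 tab-separated columns, got {len(cols)}"
                )
            chrom_raw, start_s, end_s, band_name, _stain = cols
            try:
                chrom = normalize_chrom(chrom_raw)
            except ValueError:
                continue  # skip alt contigs / chrM
            try:
                start, end = int(start_s), int(end_s)
            except ValueError as exc:
                raise CytobandFormatError(f"line {lineno}: non-integer coordinate") from exc
            if start >= end:
                raise CytobandFormatError(f"line {lineno}: empty or inverted band")
            if not band_name or band_name[0] not in "pq":
                raise CytobandFormatError(f"line {lineno}: band name must start with p/q")
            per_chrom.setdefault(chrom, []).append(
                (lineno, Band(band_name, start, end, band_name[0]))
            )

    if not per_chrom:
        raise CytobandFormatError("no cytoband records found")

    chromosomes = sorted(per_chrom, key=chrom_sort_key)
    lengths: dict[str, int] = {}
    bands: dict[str, list[Band]] = {}
    for chrom in chromosomes:
        recs = per_chrom[chrom]
        prev_end = 0
        seen_q = False
        names: set[str] = set()
        for lineno, b in recs:
            if b.start != prev_end:
                kind = "overlapping" if b.start < prev_end else "non-contiguous"
                raise CytobandFormatError(
                    f"line {lineno}: {kind} band {b.name} on chr{chrom} "
                    f"(starts at {b.start}, previous band ends at {prev_end})"
                )
            if b.name in names:
                raise CytobandFormatError(
                    f"line {lineno}: duplicate band name {b.name} on chr{chrom}"
                )
            if b.arm == "q":
                seen_q = True
            elif seen_q:
                raise CytobandFormatError(
                    f"line {lineno}: p band {b.name} after q bands on chr{chrom}"
                )
            names.add(b.name)
            prev_end = b.end
        lengths[chrom] = prev_end
        bands[chrom] = [b for _, b in recs]
    return GenomeMap(chromosomes=chromosomes, lengths=lengths, bands=bands)


def load_default_genome() -> GenomeMap:
    """Load the bundled synthetic hg19-like cytoband fixture."""
    ref = importlib.resources.files("thyrofish.data").joinpath(
        "cytoBand_hg19like_synthetic.tsv"
    )
    with importlib.resources.as_file(ref) as path:
        return read_cytobands(path)


def _parse_band_token(token: str, default_chrom: str | None) -> tuple[str, str]:
    """Split '1p36.33' -> ('1', 'p36.33'); bare 'p35.1' inherits the chromosome."""
    token = token.strip()
    for i, ch in enumerate(token):
        if ch in "pq":
            chrom_part, band_part = token[:i], token[i:]
            break
    else:
        raise ValueError(f"cannot parse band token {token!r}: no arm letter")
    if not band_part[1:]:
        # whole-arm token like "1p" is not a band name
        raise ValueError(f"cannot parse band token {token!r}: missing band number")
    if chrom_part:
        return normalize_chrom(chrom_part), band_part
    if default_chrom is None:
        raise ValueError(f"band token {token!r} carries no chromosome")
    return default_chrom, band_part


def resolve_band_range(gmap: GenomeMap, name: str) -> GenomicRegion:
    """Resolve 'CHRbandA-CHRbandB' (or a single 'CHRband') to a region.

    The region spans min(start A, start B) .. max(end A, end B); the two
    endpoint bands must lie on the same chromosome.  Symmetric in its
    endpoints: f(A-B) == f(B-A).
    """
    parts = name.split("-")
    if len(parts) not in (1, 2):
        raise ValueError(f"cannot parse band range {name!r}")
    chrom_a, band_a = _parse_band_token(parts[0], None)
    a = gmap.band(chrom_a, band_a)
    if len(parts) == 1:
        return GenomicRegion(chrom_a, a.start, a.end, name=f"{chrom_a}{band_a}")
    chrom_b, band_b = _parse_band_token(parts[1], default_chrom=chrom_a)
    if chrom_b != chrom_a:
        raise ValueError(
            f"band range {name!r} spans chromosomes {chrom_a} and {chrom_b}"
        )
    b = gmap.band(chrom_b, band_b)
    lo, hi = sorted((a, b), key=lambda x: x.start)
    return GenomicRegion(
        chrom_a,
        min(a.start, b.start),
        max(a.end, b.end),
        name=f"{chrom_a}{lo.name}-{chrom_a}{hi.name}",
    )


def whole_chromosome_region(gmap: GenomeMap, chrom: str) -> GenomicRegion:
    chrom = normalize_chrom(chrom)
    return GenomicRegion(chrom, 0, gmap.lengths[chrom], name=f"chr{chrom}")
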