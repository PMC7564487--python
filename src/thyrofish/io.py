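"""Readers and writers for the pipeline's external formats.

Dialects
--------
probe table   tab-delimited; header ``ProbeID Chrom Start End GC <sample>...``;
              log2 ratios printed at 6 decimals; 0-based half-open coordinates.
phenotype     CSV with columns sample_id, label, sex, purity.
SEG           tab-delimited ``Sample Chromosome Start End Num_Probes
              Segment_Mean``; 1-based inclusive coordinates on disk.
BED           ``chrom start end name`` (0-based half-open), chr-prefixed.
FISH counts   CSV with columns case_id, sex, panel, target_count,
              control_count; one row per nucleus.
"""

from __future__ import annotations

import logging
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .core import AcghProfile, Phenotype, ProbeSet, Segment, build_probe_set
from .genome import GenomicRegion, chrom_sort_key, normalize_chrom

logger = logging.getLogger(__name__)

PROBE_TABLE_FIXED_COLS = ["ProbeID", "Chrom", "Start", "End", "GC"]


class ProbeTableError(ValueError):
    """Raised when a probe table violates the dialect."""


def read_probe_table(path) -> tuple[ProbeSet, list[AcghProfile]]:
    """Read a probe table; returns the sorted grid plus one profile per sample.

    Non-numeric ratios raise :class:`ProbeTableError` naming the cell.
    Unsorted input is sorted with a logged warning.  Round-trips with
    :func:`write_probe_table` bit-exactly on values printed at 6 decimals.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in PROBE_TABLE_FIXED_COLS if c not in df.columns]
    if missing:
        raise ProbeTableError(f"probe table missing columns: {missing}")
    sample_cols = [c for c in df.columns if c not in PROBE_TABLE_FIXED_COLS]
    values: dict[str, np.ndarray] = {}
    for col in sample_cols:
        try:
            values[col] = df[col].astype(np.float64).to_numpy()
        except (TypeError, ValueError):
            bad = df.index[pd.to_numeric(df[col], errors="coerce").isna()][0]
            raise ProbeTableError(
                f"non-numeric log2 ratio at row {bad + 2}, column {col!r}: "
                f"{df[col].iloc[bad]!r}"
            ) from None
        if np.any(~np.isfinite(values[col])):
            bad = int(np.flatnonzero(~np.isfinite(values[col]))[0])
            raise ProbeTableError(
                f"non-numeric log2 ratio at row {bad + 2}, column {col!r}: "
                f"{df[col].iloc[bad]!r}"
            )
    chroms = [normalize_chrom(c) for c in df["Chrom"]]
    starts = df["Start"].astype(np.int64).to_numpy()
    ranks = np.array([chrom_sort_key(c) for c in chroms])
    order = np.lexsort((starts, ranks))
    if not np.array_equal(order, np.arange(len(df))):
        logger.warning("probe table %s is not genome-sorted; sorting", path)
    probes = build_probe_set(
        ids=df["ProbeID"].tolist(),
        chromosomes=chroms,
        starts=starts.tolist(),
        ends=df["End"].astype(np.int64).tolist(),
        gc=df["GC"].astype(np.float64).tolist(),
    )
    profiles = [
        AcghProfile(sample_id=col, values=vals[order]) for col, vals in values.items()
    ]
    return probes, profiles


def write_probe_table(probes: ProbeSet, profiles: Sequence[AcghProfile], path) -> None:
    data: dict[str, object] = {
        "ProbeID": probes.ids,
        "Chrom": [f"chr{c}" for c in probes.chromosomes],
        "Start": probes.starts,
        "End": probes.ends,
        "GC": [f"{g:.4f}" for g in probes.gc],
    }
    for prof in profiles:
        if len(prof.values) != len(probes):
            raise ValueError(f"profile {prof.sample_id} not aligned to probe set")
        data[prof.sample_id] = [f"{v:.6f}" for v in prof.values]
    pd.DataFrame(data).to_csv(path, sep="\t", index=False)


def read_phenotypes(path) -> list[Phenotype]:
    df = pd.read_csv(path, dtype={"sample_id": str})
    return [
        Phenotype(
            sample_id=row.sample_id,
            label=row.label,
            sex=row.sex,
            purity=float(row.purity),
        )
        for row in df.itertuples()
    ]


def write_phenotypes(phenotypes: Sequence[Phenotype], path) -> None:
    pd.DataFrame(
        {
            "sample_id": [p.sample_id for p in phenotypes],
            "label": [p.label for p in phenotypes],
            "sex": [p.sex for p in phenotypes],
            "purity": [f"{p.purity:.3f}" for p in phenotypes],
        }
    ).to_csv(path, index=False)


SEG_HEADER = ["Sample", "Chromosome", "Start", "End", "Num_Probes", "Segment_Mean"]


def write_seg(segments_by_sample: Mapping[str, Sequence[Segment]], path) -> None:
    """Write standard SEG (1-based inclusive on disk; internal is 0-based)."""
    rows = []
    for sample, segments in segments_by_sample.items():
        for seg in segments:
            rows.append(
                (
                    sample,
                    f"chr{seg.chromosome}",
                    seg.start + 1,
                    seg.end,
                    seg.n_probes,
                    f"{seg.mean:.6f}",
                )
            )
    pd.DataFrame(rows, columns=SEG_HEADER).to_csv(path, sep="\t", index=False)


def read_seg(path) -> dict[str, list[Segment]]:
    """Read SEG written by :func:`write_seg` (probe index ranges are rebuilt
    per sample in file order)."""
    df = pd.read_csv(path, sep="\t", dtype={"Sample": str})
    out: dict[str, list[Segment]] = {}
    counters: dict[str, int] = {}
    for row in df.itertuples():
        pos = counters.get(row.Sample, 0)
        n = int(row.Num_Probes)
        out.setdefault(row.Sample, []).append(
            Segment(
                chromosome=normalize_chrom(row.Chromosome),
                start=int(row.Start) - 1,
                end=int(row.End),
                mean=float(row.Segment_Mean),
                n_probes=n,
                istart=pos,
                iend=pos + n,
            )
        )
        counters[row.Sample] = pos + n
    return out


def write_bed(regions: Sequence[tuple[GenomicRegion, str]], path) -> None:
    """Write (region, name) pairs as 4-column BED (0-based half-open)."""
    with open(path, "w") as fh:
        for region, name in regions:
            fh.write(
                f"chr{normalize_chrom(region.chromosome)}\t{region.start}\t"
                f"{region.end}\t{name}\n"
            )


def read_fish_counts(path) -> pd.DataFrame:
    """Read a FISH nucleus-count CSV; validates columns and count bounds."""
    df = pd.read_csv(path, dtype={"case_id": str})
    required = ["case_id", "sex", "panel", "target_count", "control_count"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"FISH counts file missing columns: {missing}")
    for col in ("target_count", "control_count"):
        df[col] = df[col].astype(int)
        if (df[col] < 0).any():
            raise ValueError(f"negative signal count in column {col}")
    return df


def write_fish_counts(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)
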