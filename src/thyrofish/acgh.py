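"""Profile normalization, noise-adaptive aberration calling and summaries.

Normalization removes the local GC% trend by locally-weighted regression of
the log2 ratio on probe GC fraction, then centers the profile at median
zero (the dye offset).  The per-profile noise threshold is one-fourth of
the median absolute difference between consecutive probes on the genome
(never crossing a chromosome boundary), floored at a small configurable
constant so that noiseless synthetic profiles do not call everything.
"""

from __future__ import annotations

import logging
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy as sch
import scipy.spatial.distance as ssd
from statsmodels.nonparametric.smoothers_lowess import lowess

from .core import AberrationCall, AcghProfile, ProbeSet, Segment, check_partition
from .segmentation import CallConfig, NoiseEstimate

logger = logging.getLogger(__name__)


def normalize(profile: AcghProfile, probes: ProbeSet, frac: float = 0.3) -> AcghProfile:
    """GC-trend removal (lowess on GC fraction) followed by median centering.

    Output median is zero within 1e-9.  With (near-)constant GC the GC step
    is skipped with a logged warning and the profile is only centered.
    """
    if len(profile.values) != len(probes):
        raise ValueError("profile is not aligned to the probe set")
    y = profile.values.astype(np.float64)
    gc = probes.gc
    gc_span = float(gc.max() - gc.min())
    if gc_span < 1e-6:
        logger.warning(
            "profile %s: constant GC content; skipping GC correction",
            profile.sample_id,
        )
        fitted = np.zeros_like(y)
    else:
        fitted = lowess(
            y,
            gc,
            frac=frac,
            it=1,
            delta=0.01 * gc_span,
            return_sorted=False,
        )
    out = y - fitted
    out -= np.median(out)
    return profile.with_values(out)


def profile_noise(profile: AcghProfile, probes: ProbeSet) -> NoiseEstimate:
    """tau = median(|x[i+1] - x[i]|) / 4 over within-chromosome probe pairs."""
    if len(profile.values) < 2:
        raise ValueError("noise estimation needs at least 2 probes")
    diffs: list[np.ndarray] = []
    for chrom in probes.chrom_list:
        sl = probes.chrom_slice(chrom)
        x = profile.values[sl]
        if len(x) >= 2:
            diffs.append(np.abs(np.diff(x)))
    if not diffs:
        raise ValueError("no within-chromosome consecutive probe pairs")
    tau = float(np.median(np.concatenate(diffs))) / 4.0
    return NoiseEstimate(tau=tau)


def call_aberrations(
    segments: Sequence[Segment],
    noise: NoiseEstimate,
    config: CallConfig | None = None,
) -> list[AberrationCall]:
    """Call gains/losses: |segment mean| >= max(tau, floor) and >= min probes."""
    config = config or CallConfig()
    thr = noise.threshold(config.threshold_floor)
    calls: list[AberrationCall] = []
    for seg in segments:
        if seg.n_probes < config.min_probes:
            continue
        if seg.mean >= thr:
            calls.append(AberrationCall(segment=seg, state="gain", threshold=thr))
        elif seg.mean <= -thr:
            calls.append(AberrationCall(segment=seg, state="loss", threshold=thr))
    return calls


def call_profile(
    profile: AcghProfile,
    probes: ProbeSet,
    config: CallConfig | None = None,
    seed: int = 0,
) -> tuple[list[Segment], list[AberrationCall], NoiseEstimate]:
    """Convenience wrapper: normalize -> segment -> noise -> call."""
    from .segmentation import segment_profile

    config = config or CallConfig()
    norm = normalize(profile, probes)
    segments = segment_profile(norm, probes, config, seed=seed)
    check_partition(segments, len(probes))
    noise = profile_noise(norm, probes)
    calls = call_aberrations(segments, noise, config)
    return segments, calls, noise


def call_coverage(
    calls: Sequence[AberrationCall], n_probes: int
) -> tuple[np.ndarray, np.ndarray]:
    """Boolean per-probe gain/loss coverage vectors for one sample."""
    gain = np.zeros(n_probes, dtype=bool)
    loss = np.zeros(n_probes, dtype=bool)
    for call in calls:
        sl = slice(call.segment.istart, call.segment.iend)
        (gain if call.state == "gain" else loss)[sl] = True
    return gain, loss


def frequency_table(
    calls_by_sample: Mapping[str, Sequence[AberrationCall]],
    labels: Mapping[str, str],
    probes: ProbeSet,
) -> pd.DataFrame:
    """Per-probe fraction of samples called gain/loss, per class.

    Columns: chromosome, start, end, then ``<class>_gain``/``<class>_loss``
    fractions.  Gain + loss fraction never exceeds 1 for any probe/class.
    """
    n = len(probes)
    classes = sorted(set(labels.values()))
    sums = {c: {"gain": np.zeros(n), "loss": np.zeros(n)} for c in classes}
    counts = {c: 0 for c in classes}
    for sample, calls in calls_by_sample.items():
        cls = labels[sample]
        gain, loss = call_coverage(calls, n)
        sums[cls]["gain"] += gain
        sums[cls]["loss"] += loss
        counts[cls] += 1
    out = pd.DataFrame(
        {
            "chromosome": probes.chromosomes,
            "start": probes.starts,
            "end": probes.ends,
        }
    )
    for cls in classes:
        if counts[cls] == 0:
            logger.warning("class %s has no samples; frequency row is zero", cls)
            out[f"{cls}_gain"] = 0.0
            out[f"{cls}_loss"] = 0.0
        else:
            out[f"{cls}_gain"] = sums[cls]["gain"] / counts[cls]
            out[f"{cls}_loss"] = sums[cls]["loss"] / counts[cls]
    return out


def cluster_samples(
    matrix: np.ndarray,
    sample_ids: Sequence[str],
    distance: str = "pearson",
    k: int | None = None,
) -> tuple[np.ndarray, dict[str, int] | None]:
    """Ward hierarchical clustering of samples on per-probe segment means.

    ``distance``: ``pearson`` (1 - Pearson correlation between sample
    vectors; zero-variance vectors get the maximal distance 2.0 with a
    warning) or ``euclidean``.  Returns the scipy linkage matrix and, when
    ``k`` is given, a sample -> cluster-label map (labels 1..k).
    """
    X = np.asarray(matrix, dtype=np.float64)
    if X.ndim != 2 or X.shape[0] != len(sample_ids):
        raise ValueError("matrix rows must correspond to sample_ids")
    if distance == "euclidean":
        d = ssd.pdist(X, metric="euclidean")
    elif distance == "pearson":
        sd = X.std(axis=1)
        degenerate = sd == 0
        if degenerate.any():
            logger.warning(
                "%d zero-variance sample vector(s); distances set to 2.0",
                int(degenerate.sum()),
            )
        d = ssd.pdist(X, metric="correlation")
        # scipy yields nan for zero-variance rows; apply the documented maximum
        n = X.shape[0]
        idx = 0
        for a in range(n - 1):
            for b in range(a + 1, n):
                if degenerate[a] or degenerate[b]:
                    d[idx] = 2.0
                idx += 1
        if np.any(~np.isfinite(d)):
            raise ValueError("non-finite distances after pearson correction")
    else:
        raise ValueError(f"unknown distance {distance!r}")
    linkage = sch.linkage(d, method="ward")
    if k is None:
        return linkage, None
    flat = sch.fcluster(linkage, t=k, criterion="maxclust")
    return linkage, {sid: int(c) for sid, c in zip(sample_ids, flat)}


def segment_mean_matrix(
    segments_by_sample: Mapping[str, Sequence[Segment]], n_probes: int
) -> tuple[np.ndarray, list[str]]:
    """Stack per-probe segment means (rows = samples, genome-ordered ids)."""
    sample_ids = list(segments_by_sample)
    X = np.zeros((len(sample_ids), n_probes))
    for r, sid in enumerate(sample_ids):
        for seg in segments_by_sample[sid]:
            X[r, seg.istart : seg.iend] = seg.mean
    return X, sample_ids
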