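"""Circular binary segmentation of log2-ratio profiles.

Per chromosome the probe values are arranged on a circle; over all arc pairs
the two-sample mean-shift statistic

    T(i, j) = |mean(x[i:j]) - mean(rest)| * sqrt(k (n - k) / n),   k = j - i,

is maximized (the overall variance is permutation-invariant, so it is left
out of T).  The best arc is accepted as a split when its permutation p-value
is below ``alpha``; accepted splits recurse into the up-to-three resulting
sub-segments.  Ties in the argmax break toward smaller arc width, then
smaller start index.

Permutation testing is sequential (in the spirit of the early-stopping
boundaries used by standard CBS implementations), with three documented
rules evaluated after every permutation m (e = exceedance count so far):

  * hard reject  : e >= ceil(alpha * (1 + nperm))  — the full-run p-value
                   (1 + e) / (1 + nperm) could no longer fall below alpha;
  * early reject : e >= 5 and (1 + e) / (1 + m) >= alpha;
  * checkpoints  : at m in {500, 1000, 2000, 5000} (when m < nperm),
                   accept when (1 + e) / (1 + m) < alpha / 5 and reject
                   when (1 + e) / (1 + m) >= alpha / 2 — clearly
                   significant splits have permutation p far below alpha,
                   so a running estimate still at alpha/2 after hundreds
                   of draws is not going to clear it;
  * at m == nperm: accept iff (1 + e) / (1 + nperm) < alpha.

A permuted maximum counts as an exceedance when it reaches the observed
maximum within a relative tolerance of 1e-9: permutations that re-create
the observed arc partition tie the maximum exactly in real arithmetic, and
the tolerance keeps those ties counted regardless of floating-point
summation order.

The permutation stream for a (sub)segment is ``numpy.random.default_rng([
seed, chrom_rank, segment_offset, segment_length])`` drawing index
permutations one per test, so every segment decision is reproducible
independently of recursion order.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from numba import njit

from .core import AcghProfile, ProbeSet, Segment
from .genome import chrom_sort_key

logger = logging.getLogger(__name__)

EARLY_REJECT_MIN_EXCEEDANCES = 5
EARLY_ACCEPT_CHECKPOINTS = (500, 1000, 2000, 5000)
EARLY_ACCEPT_FACTOR = 5.0


@dataclass
class CallConfig:
    """Tunables for segmentation and aberration calling."""

    min_probes: int = 3            # minimum probes for a gain/loss call
    threshold_floor: float = 0.05  # log2 floor under the per-profile noise threshold
    alpha: float = 0.01            # split significance level
    n_permutations: int = 10_000
    min_width: int = 2             # minimum segment width in probes

    def __post_init__(self) -> None:
        if self.min_probes < 1:
            raise ValueError("min_probes must be >= 1")
        if not (0 < self.alpha < 1):
            raise ValueError("alpha must lie in (0, 1)")
        if self.n_permutations < 100:
            raise ValueError("n_permutations must be >= 100")
        if self.min_width < 1:
            raise ValueError("min_width must be >= 1")


@dataclass
class NoiseEstimate:
    """Per-profile internal noise tau (log2 units)."""

    tau: float

    def __post_init__(self) -> None:
        if self.tau < 0:
            raise ValueError("noise estimate must be >= 0")

    def threshold(self, floor: float) -> float:
        return max(self.tau, floor)


@njit(cache=True)
def _best_arc(x, min_width):
    """Max arc statistic and its (i, j); ties -> smaller width, then smaller i."""
    n = x.shape[0]
    s = np.empty(n + 1)
    s[0] = 0.0
    for t in range(n):
        s[t + 1] = s[t] + x[t]
    total = s[n]
    best = -1.0
    bi = -1
    bj = -1
    for k in range(min_width, n - min_width + 1):
        w = math.sqrt(k * (n - k) / n)
        for i in range(0, n - k + 1):
            d = (s[i + k] - s[i]) / k - (total - s[i + k] + s[i]) / (n - k)
            t_stat = abs(d) * w
            if t_stat > best:
                best = t_stat
                bi = i
                bj = i + k
    return best, bi, bj


@njit(cache=True)
def _max_arc_stat(x, min_width, stop_at):
    """Max arc statistic, short-circuiting once ``stop_at`` is reached."""
    n = x.shape[0]
    s = np.empty(n + 1)
    s[0] = 0.0
    for t in range(n):
        s[t + 1] = s[t] + x[t]
    total = s[n]
    best = -1.0
    for k in range(min_width, n - min_width + 1):
        w = math.sqrt(k * (n - k) / n)
        for i in range(0, n - k + 1):
            d = (s[i + k] - s[i]) / k - (total - s[i + k] + s[i]) / (n - k)
            t_stat = abs(d) * w
            if t_stat > best:
                best = t_stat
                if best >= stop_at:
                    return best
    return best


@njit(cache=True)
def _scan_permutations(x, perms, obs, min_width, m0, e0, alpha, nperm, checkpoints):
    """Process a chunk of permutations with the sequential decision rules.

    Returns (m, e, decision): decision 0 = continue, 1 = accept split,
    -1 = reject split.
    """
    m = m0
    e = e0
    hard_reject = math.ceil(alpha * (1.0 + nperm))
    thresh = obs - 1e-9 * max(1.0, abs(obs))  # tie tolerance
    for p in range(perms.shape[0]):
        xp = x[perms[p]]
        stat = _max_arc_stat(xp, min_width, thresh)
        m += 1
        if stat >= thresh:
            e += 1
        if e >= hard_reject:
            return m, e, -1
        if e >= EARLY_REJECT_MIN_EXCEEDANCES and (1.0 + e) >= alpha * (1.0 + m):
            return m, e, -1
        for c in range(checkpoints.shape[0]):
            if m == checkpoints[c] and m < nperm:
                if (1.0 + e) * EARLY_ACCEPT_FACTOR < alpha * (1.0 + m):
                    return m, e, 1
                if 2.0 * (1.0 + e) >= alpha * (1.0 + m):
                    return m, e, -1
        if m == nperm:
            if (1.0 + e) < alpha * (1.0 + nperm):
                return m, e, 1
            return m, e, -1
    return m, e, 0


def _split_test(
    x: np.ndarray, config: CallConfig, rng: np.random.Generator
) -> tuple[bool, int, int, float]:
    """Decide whether the best circular split of ``x`` is significant.

    Returns (significant, i, j, p_estimate).
    """
    n = len(x)
    obs, i, j, = _best_arc(x, config.min_width)
    if obs <= 0 or i < 0:
        return False, -1, -1, 1.0
    checkpoints = np.asarray(EARLY_ACCEPT_CHECKPOINTS, dtype=np.int64)
    m, e = 0, 0
    chunk = 64
    while True:
        size = min(chunk, config.n_permutations - m)
        perms = np.empty((size, n), dtype=np.int64)
        for t in range(size):
            perms[t] = rng.permutation(n)
        m, e, decision = _scan_permutations(
            x, perms, obs, config.min_width, m, e,
            config.alpha, config.n_permutations, checkpoints,
        )
        p_est = (1.0 + e) / (1.0 + m)
        if decision != 0:
            return decision == 1, i, j, p_est
        chunk = min(2 * chunk, 1024)


def _segment_rng(seed: int, chrom: str, offset: int, length: int) -> np.random.Generator:
    return np.random.default_rng([seed, chrom_sort_key(chrom), offset, length])


def _recurse(
    x: np.ndarray, offset: int, chrom: str, config: CallConfig, seed: int
) -> list[tuple[int, int]]:
    """Return probe-index spans (relative to the chromosome) of final segments."""
    n = len(x)
    if n < 2 * config.min_width:
        return [(offset, offset + n)]
    rng = _segment_rng(seed, chrom, offset, n)
    significant, i, j, _p = _split_test(x, config, rng)
    if not significant:
        return [(offset, offset + n)]
    spans: list[tuple[int, int]] = []
    for lo, hi in ((0, i), (i, j), (j, n)):
        if hi > lo:
            spans.extend(_recurse(x[lo:hi], offset + lo, chrom, config, seed))
    return spans


def segment_profile(
    profile: AcghProfile,
    probes: ProbeSet,
    config: CallConfig | None = None,
    seed: int = 0,
) -> list[Segment]:
    """Segment a profile chromosome by chromosome with circular binary splits.

    Deterministic for a fixed seed; segments partition the probe grid and
    each segment mean is the arithmetic mean of its member probes.
    """
    config = config or CallConfig()
    if len(profile.values) != len(probes):
        raise ValueError("profile is not aligned to the probe set")
    segments: list[Segment] = []
    for chrom in probes.chrom_list:
        sl = probes.chrom_slice(chrom)
        x = profile.values[sl]
        if len(x) < 2 * config.min_width:
            logger.warning(
                "chromosome %s has %d probes (< %d); emitting a single segment",
                chrom, len(x), 2 * config.min_width,
            )
            spans = [(0, len(x))]
        else:
            spans = _recurse(x, 0, chrom, config, seed)
        for lo, hi in spans:
            istart, iend = sl.start + lo, sl.start + hi
            segments.append(
                Segment(
                    chromosome=chrom,
                    start=int(probes.starts[istart]),
                    end=int(probes.ends[iend - 1]),
                    mean=float(np.mean(profile.values[istart:iend])),
                    n_probes=hi - lo,
                    istart=istart,
                    iend=iend,
                )
            )
    return segments
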