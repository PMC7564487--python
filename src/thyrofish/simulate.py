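"""Synthetic cohorts: aCGH profiles, FISH nucleus counts and DNA indices.

The generator reproduces the statistical structure the analysis assumes for
two-class cohorts of classic follicular adenoma (cFA) and carcinoma (cFTC):

* the three cFTC marker alterations — loss of 1p36.33-1p35.1, loss of
  22q13.2-22q13.31 and gain of whole chromosome X — implanted at the
  per-set frequencies of the study design (training 5/8/8 among 33 cFTC
  with one double- and one triple-positive case, i.e. 21 alterations in 18
  patients; validation 3/12/4 among 34 with the 1p losses always joined by
  22q loss; feasibility 2/2/2 among 14 with no co-occurrence);
* background whole-chromosome gains (5, 7, 9, 12, 14, 16, 17, 20) and
  losses (3, 4, 8, 11, 21) shared by both classes, carried by a
  "complex-genome" subgroup (13 of 33 cFTC, 4 of 33 cFA in the training
  configuration); every background chromosome recurs in at least one cFA,
  so by construction only the three markers are exclusive to cFTC.
  Complex genomes draw a balanced mix of background gains and losses so
  that the median of the profile stays at the two-copy baseline — the
  assumption that median centering encodes (a strongly gain-dominated
  genome would shift the centered baseline of every other chromosome);
* purity-attenuated log2 amplitudes, probe-level Gaussian noise, a smooth
  GC trend and a constant dye offset;
* FISH nucleus counts with hybridization failure and normal-cell
  contamination, and DNA indices per ploidy class.

Copy-number states are mixed with the tumor purity on the linear scale:
``log2((purity * cn + (1 - purity) * baseline) / baseline)``.  The
reference is sex-matched, so the male X baseline is one copy (a male
whole-X gain is one extra copy on a one-copy baseline).  Female chrY
probes have no signal in either channel and are emitted at log2 ratio 0
plus noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import AcghProfile, Phenotype, ProbeSet, build_probe_set
from .fish import FishCase, NucleusCount
from .genome import GenomeMap, GenomicRegion, normalize_chrom, resolve_band_range

MARKER_1P = "1p36.33-1p35.1"
MARKER_22Q = "22q13.2-22q13.31"
MARKERS = ("1p", "22q", "X")

BACKGROUND_GAINS = ("5", "7", "9", "12", "14", "16", "17", "20")
BACKGROUND_LOSSES = ("3", "4", "8", "11", "21")


@dataclass(frozen=True)
class CnvEvent:
    """One somatic copy-number event: a region at an integer tumor copy number."""

    region: GenomicRegion
    tumor_cn: int

    def __post_init__(self) -> None:
        if self.tumor_cn < 0:
            raise ValueError("tumor copy number must be >= 0")


@dataclass
class SimConfig:
    """Study conditions for aCGH profile simulation."""

    probe_spacing: int = 100_000
    noise_sd: float = 0.12        # per-probe log2 noise (free parameter)
    purity: float = 0.8           # minimum tumor cell content of the design
    gc_bias: float = 0.5          # log2 per GC-fraction unit, removed by normalization
    dye_offset: float = 0.1       # constant log2 offset, removed by centering
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise sd must be >= 0")
        if not (0 < self.purity <= 1):
            raise ValueError("purity must lie in (0, 1]")
        if self.probe_spacing < 1:
            raise ValueError("probe spacing must be >= 1")


@dataclass
class FishSimConfig:
    """Study conditions for FISH nucleus-count simulation."""

    n_nuclei: int = 200
    aberrant_fraction: float = 0.6   # tumor-cell clone carrying the alteration
    failure_rate: float = 0.05       # per-signal hybridization dropout
    contamination: float = 0.1       # admixed normal cells
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_nuclei < 1:
            raise ValueError("n_nuclei must be >= 1")
        for name in ("aberrant_fraction", "failure_rate", "contamination"):
            v = getattr(self, name)
            if not (0 <= v <= 1):
                raise ValueError(f"{name} must lie in [0, 1]")


def make_probe_set(
    gmap: GenomeMap,
    spacing: int = 100_000,
    chromosomes: list[str] | None = None,
    seed: int = 0,
) -> ProbeSet:
    """Regular probe grid (one 60-mer per ``spacing`` bp) with smooth GC."""
    chroms = chromosomes or gmap.chromosomes
    rng = np.random.default_rng([seed, 7])
    ids, cs, starts, ends, gcs = [], [], [], [], []
    for rank, chrom in enumerate(normalize_chrom(c) for c in chroms):
        length = gmap.lengths[chrom]
        pos = np.arange(0, length - 60, spacing, dtype=np.int64)
        mid = pos + 30
        gc = (
            0.42
            + 0.08 * np.sin(2 * np.pi * mid / 30e6 + rank)
            + rng.normal(0.0, 0.02, size=len(pos))
        )
        ids.extend(f"P{chrom}_{i:06d}" for i in range(len(pos)))
        cs.extend([chrom] * len(pos))
        starts.extend(pos.tolist())
        ends.extend((pos + 60).tolist())
        gcs.extend(np.clip(gc, 0.28, 0.72).tolist())
    return build_probe_set(ids, cs, starts, ends, gcs)


def baseline_cn(chrom: str, sex: str) -> int:
    """Germline copy number against a sex-matched reference."""
    chrom = normalize_chrom(chrom)
    if chrom == "X":
        return 2 if sex == "female" else 1
    if chrom == "Y":
        return 0 if sex == "female" else 1
    return 2


def expected_log2(tumor_cn: int, baseline: int, purity: float) -> float:
    """Purity-mixture log2 ratio of a tumor copy state over its baseline."""
    if baseline < 1:
        raise ValueError("baseline copy number must be >= 1")
    if not (0 < purity <= 1):
        raise ValueError("purity must lie in (0, 1]")
    return float(np.log2((purity * tumor_cn + (1 - purity) * baseline) / baseline))


def simulate_profile(
    probes: ProbeSet,
    events: list[CnvEvent],
    config: SimConfig,
    sex: str,
    seed: int,
    sample_id: str = "S",
    label: str = "unknown",
) -> AcghProfile:
    """Noisy log2-ratio profile with the given events implanted.

    Per-probe value = purity-mixture log2 of the covering event (baseline
    elsewhere) + gc_bias * (gc - mean gc) + dye_offset + N(0, noise_sd).
    Events must not overlap within a chromosome.  Deterministic per seed.
    """
    by_chrom: dict[str, list[CnvEvent]] = {}
    for ev in events:
        chrom = normalize_chrom(ev.region.chromosome)
        for other in by_chrom.get(chrom, []):
            if ev.region.overlaps(other.region):
                raise ValueError(
                    f"overlapping events on chromosome {chrom}: "
                    f"{ev.region} vs {other.region}"
                )
        by_chrom.setdefault(chrom, []).append(ev)

    rng = np.random.default_rng([config.seed, seed])
    values = np.zeros(len(probes), dtype=np.float64)
    mid = probes.midpoints
    for chrom, chrom_events in by_chrom.items():
        try:
            sl = probes.chrom_slice(chrom)
        except KeyError:
            continue  # event lies outside the simulated grid
        base = baseline_cn(chrom, sex)
        if base == 0:
            continue  # female chrY: no signal either channel; stays at 0
        for ev in chrom_events:
            mask = (mid[sl] >= ev.region.start) & (mid[sl] < ev.region.end)
            values[sl][mask] = expected_log2(ev.tumor_cn, base, config.purity)
    values += config.gc_bias * (probes.gc - probes.gc.mean())
    values += config.dye_offset
    if config.noise_sd > 0:
        values += rng.normal(0.0, config.noise_sd, size=len(probes))
    return AcghProfile(
        sample_id=sample_id, values=values, label=label, sex=sex,
        purity=config.purity,
    )


def marker_event(
    gmap: GenomeMap, marker: str, sex: str
) -> CnvEvent:
    """The CnvEvent for one of the three marker alterations."""
    if marker == "1p":
        return CnvEvent(resolve_band_range(gmap, MARKER_1P), tumor_cn=1)
    if marker == "22q":
        return CnvEvent(resolve_band_range(gmap, MARKER_22Q), tumor_cn=1)
    if marker == "X":
        region = GenomicRegion("X", 0, gmap.lengths["X"], name="chrX")
        return CnvEvent(region, tumor_cn=baseline_cn("X", sex) + 1)
    raise ValueError(f"unknown marker {marker!r}")


def _background_event(gmap: GenomeMap, chrom: str) -> CnvEvent:
    region = GenomicRegion(chrom, 0, gmap.lengths[chrom], name=f"chr{chrom}")
    cn = 3 if chrom in BACKGROUND_GAINS else 1
    return CnvEvent(region, tumor_cn=cn)


#: fixed background menus of the four complex-genome cFA cases; jointly they
#: cover every background chromosome, keeping the markers cFTC-exclusive.
_CFA_COMPLEX_MENUS = (
    ("3", "4", "5", "7"),
    ("8", "9", "11", "12"),
    ("14", "16", "17"),
    ("20", "21"),
)


@dataclass
class CohortDesign:
    """Fixed per-set design: class sizes and marker carrier assignment."""

    prefix: str
    n_cfa: int
    n_cftc: int
    # carrier index (0-based within cFTC) -> tuple of markers
    carriers: dict[int, tuple[str, ...]]
    n_complex_cftc: int = 0
    n_complex_cfa: int = 0
    # male fractions follow the study's sex distribution
    cfa_females: int = 0
    cftc_females: int = 0


TRAINING_DESIGN = CohortDesign(
    prefix="TR",
    n_cfa=33,
    n_cftc=33,
    carriers={
        0: ("1p", "22q", "X"),           # the triple-positive case
        1: ("1p", "22q"),                # the double-positive case
        2: ("1p",), 3: ("1p",), 4: ("1p",),
        5: ("22q",), 6: ("22q",), 7: ("22q",),
        8: ("22q",), 9: ("22q",), 10: ("22q",),
        11: ("X",), 12: ("X",), 13: ("X",), 14: ("X",),
        15: ("X",), 16: ("X",), 17: ("X",),
    },
    n_complex_cftc=13,
    n_complex_cfa=4,
    cfa_females=21,
    cftc_females=16,
)

VALIDATION_DESIGN = CohortDesign(
    prefix="VA",
    n_cfa=26,
    n_cftc=34,
    carriers={
        # 1p loss systematically associated with 22q loss in this set
        0: ("1p", "22q"), 1: ("1p", "22q"), 2: ("1p", "22q"),
        3: ("22q",), 4: ("22q",), 5: ("22q",), 6: ("22q",), 7: ("22q",),
        8: ("22q",), 9: ("22q",), 10: ("22q",), 11: ("22q",),
        # X gain always the only abnormality in this set
        12: ("X",), 13: ("X",), 14: ("X",), 15: ("X",),
    },
    cfa_females=20,
    cftc_females=20,
)

FEASIBILITY_DESIGN = CohortDesign(
    prefix="FE",
    n_cfa=13,
    n_cftc=14,
    carriers={
        0: ("1p",), 1: ("1p",),
        2: ("22q",), 3: ("22q",),
        4: ("X",), 5: ("X",),
    },
    cfa_females=8,
    cftc_females=8,
)


def _sexes(n: int, n_female: int, start_female: bool = True) -> list[str]:
    """Deterministic alternating sex assignment with the given female count."""
    out: list[str] = []
    f = m = 0
    want = "female" if start_female else "male"
    for _ in range(n):
        if want == "female" and f < n_female:
            out.append("female"); f += 1
        elif want == "male" and m < n - n_female:
            out.append("male"); m += 1
        elif f < n_female:
            out.append("female"); f += 1
        else:
            out.append("male"); m += 1
        want = "male" if want == "female" else "female"
    return out


def simulate_cohort(
    probes: ProbeSet,
    gmap: GenomeMap,
    config: SimConfig,
    design: CohortDesign,
) -> tuple[list[AcghProfile], dict[str, list[CnvEvent]], list[Phenotype]]:
    """Simulate one two-class aCGH cohort under a fixed design.

    Returns (profiles, ground-truth events per sample, phenotypes).  Events
    on chromosomes absent from the probe grid are dropped from the ground
    truth as well, so truth always refers to what is observable.
    """
    covered = max(design.carriers, default=-1)
    if covered >= design.n_cftc:
        raise ValueError("carrier assignment exceeds the number of cFTC cases")
    rng = np.random.default_rng([config.seed, 11])
    grid_chroms = set(probes.chrom_list)

    profiles: list[AcghProfile] = []
    truth: dict[str, list[CnvEvent]] = {}
    phenotypes: list[Phenotype] = []

    cfa_sex = _sexes(design.n_cfa, design.cfa_females, start_female=True)
    cftc_sex = _sexes(design.n_cftc, design.cftc_females, start_female=False)

    # complex-genome cFTC cases: all X carriers plus the next cases in order
    x_carriers = [i for i, ms in design.carriers.items() if "X" in ms]
    complex_cftc = list(x_carriers)
    nxt = max(design.carriers, default=-1) + 1
    while len(complex_cftc) < design.n_complex_cftc and nxt < design.n_cftc:
        complex_cftc.append(nxt)
        nxt += 1
    background_menu = [*BACKGROUND_LOSSES, *BACKGROUND_GAINS]

    for k, (label, n, sexes) in enumerate(
        (("cFA", design.n_cfa, cfa_sex), ("cFTC", design.n_cftc, cftc_sex))
    ):
        for i in range(n):
            sid = f"{design.prefix}-{'FA' if label == 'cFA' else 'TC'}{i + 1:02d}"
            sex = sexes[i]
            events: list[CnvEvent] = []
            if label == "cFTC":
                for marker in design.carriers.get(i, ()):
                    events.append(marker_event(gmap, marker, sex))
                if i in complex_cftc:
                    n_bg = int(rng.integers(3, 7))
                    n_gain = n_bg - n_bg // 2
                    gains = rng.choice(
                        BACKGROUND_GAINS, size=n_gain, replace=False
                    )
                    losses = rng.choice(
                        BACKGROUND_LOSSES, size=n_bg - n_gain, replace=False
                    )
                    events.extend(
                        _background_event(gmap, c) for c in (*gains, *losses)
                    )
            else:
                cfa_complex_rank = i  # first cases carry the fixed menus
                if cfa_complex_rank < min(design.n_complex_cfa, len(_CFA_COMPLEX_MENUS)):
                    events.extend(
                        _background_event(gmap, c)
                        for c in _CFA_COMPLEX_MENUS[cfa_complex_rank]
                    )
            events = [
                ev for ev in events
                if normalize_chrom(ev.region.chromosome) in grid_chroms
            ]
            profile = simulate_profile(
                probes, events, config, sex,
                seed=k * 1000 + i, sample_id=sid, label=label,
            )
            profiles.append(profile)
            truth[sid] = events
            phenotypes.append(Phenotype(sid, label, sex, config.purity))
    return profiles, truth, phenotypes


def simulate_training_cohort(
    probes: ProbeSet, gmap: GenomeMap, config: SimConfig
) -> tuple[list[AcghProfile], dict[str, list[CnvEvent]], list[Phenotype]]:
    """The study-faithful 33 cFA + 33 cFTC training cohort (21 marker
    alterations in 18 distinct cFTC carriers)."""
    return simulate_cohort(probes, gmap, config, TRAINING_DESIGN)


# --- FISH simulation --------------------------------------------------------

_PANEL_BASE = {
    # panel -> state -> (target, control) expected signal counts
    "P1": {"normal": (2, 2), "1p-loss": (1, 2)},
    "P22": {"normal": (2, 2), "22q-loss": (1, 2)},
}


def _pxy_base(state: str, sex: str) -> tuple[int, int]:
    if sex == "female":
        return (3, 0) if state == "X-gain" else (2, 0)
    return (2, 1) if state == "X-gain" else (1, 1)


def simulate_fish_case(
    true_states: dict[str, str],
    config: FishSimConfig,
    sex: str,
    seed: int = 0,
    case_id: str = "C",
) -> FishCase:
    """Simulate per-nucleus counts for the three panels of one case.

    ``true_states`` maps panel to its state: P1/P22 in {normal, 1p-loss /
    22q-loss}, PXY in {normal, X-gain}.  A nucleus shows the aberrant
    pattern with probability aberrant_fraction * (1 - contamination);
    every expected signal is then dropped independently with the
    hybridization failure rate.
    """
    rng = np.random.default_rng([config.seed, seed])
    nuclei: dict[str, list[NucleusCount]] = {}
    p_aberrant = config.aberrant_fraction * (1 - config.contamination)
    for panel in ("P1", "P22", "PXY"):
        state = true_states.get(panel, "normal")
        counts: list[NucleusCount] = []
        for _ in range(config.n_nuclei):
            aberrant = state != "normal" and rng.random() < p_aberrant
            if panel == "PXY":
                base_t, base_c = _pxy_base(state if aberrant else "normal", sex)
            else:
                base = _PANEL_BASE[panel]
                base_t, base_c = base[state] if aberrant else base["normal"]
            t = int(rng.binomial(base_t, 1 - config.failure_rate)) if base_t else 0
            c = int(rng.binomial(base_c, 1 - config.failure_rate)) if base_c else 0
            counts.append(NucleusCount(panel=panel, target=t, control=c))
        nuclei[panel] = counts
    return FishCase(case_id=case_id, sex=sex, nuclei=nuclei)


@dataclass
class FishSetDesign:
    """One FISH set: class sizes and per-case true marker states."""

    name: str
    prefix: str
    n_cfa: int
    n_cftc: int
    cftc_carriers: dict[int, tuple[str, ...]]
    # cFA index -> (markers, aberrant fraction): subclonal false positives
    cfa_carriers: dict[int, tuple[tuple[str, ...], float]] = field(default_factory=dict)
    cfa_females: int = 0
    cftc_females: int = 0


#: the training set's FISH arm: 44 touch preparations (20 cFA / 24 cFTC);
#: one cFA carries a subclonal 22q loss seen by FISH only.
TRAINING_FISH_DESIGN = FishSetDesign(
    name="training",
    prefix="TF",
    n_cfa=20,
    n_cftc=24,
    cftc_carriers=TRAINING_DESIGN.carriers,
    cfa_carriers={0: (("22q",), 0.35)},
    cfa_females=13,
    cftc_females=12,
)

VALIDATION_FISH_DESIGN = FishSetDesign(
    name="validation",
    prefix="VF",
    n_cfa=26,
    n_cftc=34,
    cftc_carriers=VALIDATION_DESIGN.carriers,
    cfa_females=20,
    cftc_females=20,
)

FEASIBILITY_FISH_DESIGN = FishSetDesign(
    name="feasibility",
    prefix="FF",
    n_cfa=13,
    n_cftc=14,
    cftc_carriers=FEASIBILITY_DESIGN.carriers,
    cfa_females=8,
    cftc_females=8,
)

_MARKER_TO_STATE = {"1p": ("P1", "1p-loss"), "22q": ("P22", "22q-loss"),
                    "X": ("PXY", "X-gain")}


def simulate_fish_set(
    design: FishSetDesign, config: FishSimConfig, seed_offset: int = 0
) -> tuple[list[FishCase], pd.DataFrame]:
    """Simulate all cases of one FISH set.

    Returns the cases plus a truth table (case_id, set, label, sex,
    true_markers).
    """
    cases: list[FishCase] = []
    rows: list[dict] = []
    cfa_sex = _sexes(design.n_cfa, design.cfa_females, start_female=True)
    cftc_sex = _sexes(design.n_cftc, design.cftc_females, start_female=False)
    for k, (label, n, sexes, carriers) in enumerate(
        (
            ("cFA", design.n_cfa, cfa_sex,
             {i: m for i, (m, _f) in design.cfa_carriers.items()}),
            ("cFTC", design.n_cftc, cftc_sex, design.cftc_carriers),
        )
    ):
        for i in range(n):
            cid = f"{design.prefix}-{'FA' if label == 'cFA' else 'TC'}{i + 1:02d}"
            markers = carriers.get(i, ())
            states = dict(_MARKER_TO_STATE[m] for m in markers)
            cfg = config
            if label == "cFA" and i in design.cfa_carriers:
                frac = design.cfa_carriers[i][1]
                cfg = FishSimConfig(
                    n_nuclei=config.n_nuclei,
                    aberrant_fraction=frac,
                    failure_rate=config.failure_rate,
                    contamination=config.contamination,
                    seed=config.seed,
                )
            case = simulate_fish_case(
                states, cfg, sexes[i],
                seed=seed_offset + k * 1000 + i, case_id=cid,
            )
            cases.append(case)
            rows.append(
                {
                    "case_id": cid,
                    "set": design.name,
                    "label": label,
                    "sex": sexes[i],
                    "true_markers": "+".join(markers) if markers else "none",
                }
            )
    return cases, pd.DataFrame(rows)


def fish_cases_to_counts(cases: list[FishCase]) -> pd.DataFrame:
    """Flatten cases to the nucleus-count CSV dialect."""
    rows = []
    for case in cases:
        for panel, nuclei in case.nuclei.items():
            for n in nuclei:
                rows.append(
                    {
                        "case_id": case.case_id,
                        "sex": case.sex,
                        "panel": panel,
                        "target_count": n.target,
                        "control_count": n.control,
                    }
                )
    return pd.DataFrame(rows)


def fish_cases_from_counts(df: pd.DataFrame) -> list[FishCase]:
    """Group a nucleus-count table back into FishCase objects."""
    cases: list[FishCase] = []
    for (cid, sex), sub in df.groupby(["case_id", "sex"], sort=False):
        nuclei: dict[str, list[NucleusCount]] = {}
        for row in sub.itertuples():
            nuclei.setdefault(row.panel, []).append(
                NucleusCount(
                    panel=row.panel,
                    target=int(row.target_count),
                    control=int(row.control_count),
                )
            )
        cases.append(FishCase(case_id=str(cid), sex=str(sex), nuclei=nuclei))
    return cases


# --- DNA indices ------------------------------------------------------------

_DI_INTERVALS = {
    "diploid": [(0.90, 1.10)],
    "aneuploid": [(0.62, 0.88), (1.12, 1.78)],
    "haploid": [(0.50, 0.595)],
    "tetraploid": [(1.80, 2.20)],
}


def simulate_di(ploidy_class: str, seed: int = 0) -> list[float]:
    """Draw DNA indices whose :func:`~thyrofish.fish.classify_ploidy` class
    round-trips to ``ploidy_class``."""
    rng = np.random.default_rng([seed, 13])
    if ploidy_class == "multiploid":
        lo = rng.uniform(*_DI_INTERVALS["aneuploid"][0])
        hi = rng.uniform(*_DI_INTERVALS["aneuploid"][1])
        return [float(lo), float(hi)]
    if ploidy_class not in _DI_INTERVALS:
        raise ValueError(f"unknown ploidy class {ploidy_class!r}")
    intervals = _DI_INTERVALS[ploidy_class]
    interval = intervals[int(rng.integers(len(intervals)))]
    return [float(rng.uniform(*interval))]
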