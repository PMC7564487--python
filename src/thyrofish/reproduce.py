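"""End-to-end study reproduction on the study-faithful synthetic cohorts.

Chains every stage: simulate the training cohort, normalize / segment /
call each aCGH profile, discover the minimal discriminating markers on the
training set, simulate and score the three FISH sets (training touch
preparations, validation, feasibility), pool the per-set calls into one
confusion table, and report the accuracy statistics with exact binomial
CIs plus predictive values re-adjusted to a 10% disease prevalence.

One global seed fans out to per-stage seeds by fixed offsets (probe grid,
cohort simulation, segmentation permutations, FISH counts), so stages can
be re-run independently yet reproducibly; two runs with the same
configuration produce byte-identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

from .acgh import call_profile
from .core import AberrationCall, Phenotype, ProbeSet, Segment
from .diagnostics import (
    AccuracyReport,
    ConfusionTable,
    accuracy_stats,
    adjust_prevalence,
    pool_confusion,
    positivity_rates,
)
from .genome import GenomeMap, GenomicRegion, load_default_genome
from .io import write_bed, write_fish_counts, write_phenotypes, write_seg
from .markers import (
    RankedRegion,
    build_region_matrix,
    marker_carrier_interval,
    minimal_common_region,
    rank_regions,
    select_minimal_markers,
)
from .fish import score_case
from .segmentation import CallConfig
from .simulate import (
    FEASIBILITY_FISH_DESIGN,
    TRAINING_FISH_DESIGN,
    VALIDATION_FISH_DESIGN,
    FishSimConfig,
    SimConfig,
    fish_cases_to_counts,
    make_probe_set,
    simulate_fish_set,
    simulate_training_cohort,
)

logger = logging.getLogger(__name__)

# default grid: whole genome, as on the emulated whole-genome array
DEFAULT_CHROMOSOMES = tuple(str(i) for i in range(1, 23)) + ("X", "Y")


@dataclass
class RunConfig:
    """Configuration of the end-to-end reproduction run."""

    seed: int = 0
    probe_spacing: int = 100_000
    chromosomes: tuple[str, ...] = DEFAULT_CHROMOSOMES
    noise_sd: float = 0.12
    purity: float = 0.8
    p_threshold: float = 0.05
    min_nuclei: int = 100
    positivity_fraction: float = 0.20
    adjusted_prevalence: float = 0.10
    skip_fish: bool = False
    call: CallConfig = field(default_factory=CallConfig)

    def config_hash(self) -> str:
        payload = repr(
            (
                self.seed, self.probe_spacing, self.chromosomes, self.noise_sd,
                self.purity, self.p_threshold, self.min_nuclei,
                self.positivity_fraction, self.adjusted_prevalence,
                self.skip_fish, self.call,
            )
        ).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


@dataclass
class MarkerResult:
    ranked: RankedRegion
    minimal_common: GenomicRegion
    n_carriers: int


@dataclass
class ReproduceResult:
    config: RunConfig
    probes: ProbeSet
    phenotypes: list[Phenotype]
    segments: dict[str, list[Segment]]
    calls: dict[str, list[AberrationCall]]
    markers: list[MarkerResult]
    acgh_positive: set[str]
    per_set_calls: dict[str, list[tuple[str, str, str]]]
    confusion: ConfusionTable | None
    report: AccuracyReport | None
    adjusted: tuple[float, float] | None
    positivity: dict[str, tuple[int, int, float]]


def _discover_markers(
    result_segments, result_calls, probes, labels, p_threshold
) -> tuple[list[MarkerResult], set[str]]:
    matrix = build_region_matrix(result_segments, result_calls, probes)
    ranked = rank_regions(matrix, labels, on="states")
    selected = select_minimal_markers(ranked, p_threshold=p_threshold)
    markers: list[MarkerResult] = []
    covered: set[str] = set()
    for sel in selected:
        state = sel.direction
        intervals = []
        for sid in sorted(sel.coverage):
            iv = marker_carrier_interval(result_calls[sid], sel.region, state)
            if iv is not None:
                intervals.append(iv)
        mcr = minimal_common_region(intervals) if intervals else sel.region
        markers.append(MarkerResult(sel, mcr, len(sel.coverage)))
        covered |= set(sel.coverage)
    return markers, covered


def run_reproduce(config: RunConfig, outdir: str | Path | None = None) -> ReproduceResult:
    """Run the full pipeline; optionally persist all outputs under ``outdir``."""
    gmap: GenomeMap = load_default_genome()
    out = Path(outdir) if outdir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)
    stage_log: list[str] = []

    def log(stage: str, msg: str) -> None:
        line = f"[{stage}] {msg}"
        stage_log.append(line)
        logger.info("%s", line)

    # --- stage 1: probe grid and training cohort ---------------------------
    probes = make_probe_set(
        gmap, spacing=config.probe_spacing,
        chromosomes=list(config.chromosomes), seed=config.seed + 3,
    )
    log("grid", f"{len(probes)} probes on {len(config.chromosomes)} chromosomes")
    sim = SimConfig(
        probe_spacing=config.probe_spacing, noise_sd=config.noise_sd,
        purity=config.purity, seed=config.seed,
    )
    profiles, truth, phenotypes = simulate_training_cohort(probes, gmap, sim)
    log("simulate", f"{len(profiles)} training profiles "
        f"({sum(bool(v) for v in truth.values())} with events)")

    # --- stage 2: per-profile aCGH calling ----------------------------------
    segments: dict[str, list[Segment]] = {}
    calls: dict[str, list[AberrationCall]] = {}
    for prof in profiles:
        segs, cls, _noise = call_profile(
            prof, probes, config.call, seed=config.seed + 2
        )
        segments[prof.sample_id] = segs
        calls[prof.sample_id] = cls
    n_calls = sum(len(c) for c in calls.values())
    log("acgh", f"{n_calls} aberration calls across {len(profiles)} profiles")

    # --- stage 3: marker discovery on the training set ----------------------
    labels = {p.sample_id: p.label for p in phenotypes}
    markers, covered = _discover_markers(
        segments, calls, probes, labels, config.p_threshold
    )
    log("markers", f"{len(markers)} markers selected covering "
        f"{len(covered)} cFTC samples")

    # training-set aCGH positivity: carriers of at least one selected marker
    training_records = [
        (p.sample_id, p.label,
         "positive" if p.sample_id in covered else "negative")
        for p in phenotypes
    ]

    per_set_calls: dict[str, list[tuple[str, str, str]]] = {}
    confusion = report = adjusted = None
    fish_counts_frames = []
    fish_results_rows = []
    if not config.skip_fish:
        # --- stage 4: FISH scoring of the three sets ------------------------
        fish_cfg = FishSimConfig(seed=config.seed + 1)
        for offset, design in (
            (0, TRAINING_FISH_DESIGN),
            (100_000, VALIDATION_FISH_DESIGN),
            (200_000, FEASIBILITY_FISH_DESIGN),
        ):
            cases, truth_df = simulate_fish_set(design, fish_cfg, seed_offset=offset)
            fish_counts_frames.append((design.name, fish_cases_to_counts(cases)))
            records = []
            truth_by_id = truth_df.set_index("case_id")
            for case in cases:
                res = score_case(
                    case, min_nuclei=config.min_nuclei,
                    positivity_fraction=config.positivity_fraction,
                )
                label = str(truth_by_id.loc[case.case_id, "label"])
                records.append((case.case_id, label, res.call))
                for panel, pr in res.panels.items():
                    fish_results_rows.append(
                        {
                            "set": design.name, "case_id": case.case_id,
                            "label": label, "panel": panel, "call": pr.call,
                            "aberrant_fraction": pr.aberrant_fraction,
                            "n_informative": pr.n_informative,
                            "case_call": res.call,
                        }
                    )
            per_set_calls[design.name] = records
            n_pos = sum(r[2] == "positive" for r in records)
            log("fish", f"{design.name}: {len(records)} cases, {n_pos} positive")

        # --- stage 5: pooled diagnostics ------------------------------------
        confusion = pool_confusion(per_set_calls)
        report = accuracy_stats(confusion)
        adjusted = adjust_prevalence(
            report.sensitivity.fraction, report.specificity.fraction,
            config.adjusted_prevalence,
        )
        log("diagnostics",
            f"pooled table TP={confusion.tp} FP={confusion.fp} "
            f"TN={confusion.tn} FN={confusion.fn}")

    # positivity rates: training at the aCGH level, the rest at the FISH level
    positivity_input = {"training": training_records}
    for name in ("validation", "feasibility"):
        if name in per_set_calls:
            positivity_input[name] = per_set_calls[name]
    positivity = positivity_rates(positivity_input)

    result = ReproduceResult(
        config=config, probes=probes, phenotypes=phenotypes,
        segments=segments, calls=calls, markers=markers,
        acgh_positive=covered, per_set_calls=per_set_calls,
        confusion=confusion, report=report, adjusted=adjusted,
        positivity=positivity,
    )

    if out is not None:
        _write_outputs(result, out, fish_counts_frames, fish_results_rows,
                       stage_log)
    return result


def _write_outputs(result, out: Path, fish_counts_frames, fish_results_rows,
                   stage_log) -> None:
    import pandas as pd

    cfg = result.config
    write_seg(result.segments, out / "training_calls.seg")
    write_phenotypes(result.phenotypes, out / "training_phenotypes.csv")
    bed_rows = []
    for k, m in enumerate(result.markers, start=1):
        r = m.minimal_common
        bed_rows.append(
            (r, f"marker{k}|{m.ranked.direction}|p={m.ranked.p_value:.3g}"
                f"|carriers={m.n_carriers}")
        )
    write_bed(bed_rows, out / "markers.bed")
    call_rows = []
    for sid, sample_calls in result.calls.items():
        for c in sample_calls:
            seg = c.segment
            call_rows.append(
                (GenomicRegion(seg.chromosome, seg.start, seg.end),
                 f"{sid}|{c.state}")
            )
    write_bed(call_rows, out / "training_call_regions.bed")
    for name, frame in fish_counts_frames:
        write_fish_counts(frame, out / f"fish_counts_{name}.csv")
    if fish_results_rows:
        pd.DataFrame(fish_results_rows).to_csv(
            out / "fish_results.csv", index=False
        )
    payload: dict = {
        "seed": cfg.seed,
        "config_hash": cfg.config_hash(),
        "n_probes": len(result.probes),
        "markers": [
            {
                "chromosome": m.minimal_common.chromosome,
                "start": m.minimal_common.start,
                "end": m.minimal_common.end,
                "direction": m.ranked.direction,
                "p_value": m.ranked.p_value,
                "n_carriers": m.n_carriers,
            }
            for m in result.markers
        ],
        "positivity": {
            name: {"positives": pos, "tested": n, "fraction": frac}
            for name, (pos, n, frac) in result.positivity.items()
        },
    }
    if result.confusion is not None:
        t = result.confusion
        payload["confusion"] = {"TP": t.tp, "FP": t.fp, "TN": t.tn, "FN": t.fn}
        payload["accuracy"] = result.report.as_dict()
        ppv_adj, npv_adj = result.adjusted
        payload["adjusted_predictive_values"] = {
            "prevalence": cfg.adjusted_prevalence,
            "ppv": ppv_adj,
            "npv": npv_adj,
        }
    with open(out / "accuracy.json", "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")
    with open(out / "run_log.txt", "w") as fh:
        fh.write(f"seed={cfg.seed} config_hash={cfg.config_hash()}\n")
        for line in stage_log:
            fh.write(line + "\n")
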