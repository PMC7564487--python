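"""Triple DNA FISH scoring: nucleus patterns, case calls, DNA-index ploidy.

The assay scores three probe panels per case:

* ``P1``  : 1p36.31 target / 1q25.3 control  (marker: 1p loss)
* ``P22`` : 22q13.3 target / 22q11.2 control (marker: 22q loss)
* ``PXY`` : CEP X target / CEP Y control     (marker: X gain)

For the locus panels a ratio rule is used so that polyploid nuclei are read
correctly (3 target : 6 control is still a loss).  Nuclei whose control
hybridization failed (fewer than two control signals for P1/P22, or no
signals at all) are uninformative and excluded from both numerator and
denominator of the aberrant fraction.  For CEP X/Y the male pattern of two
X with one Y is read as a gain ("trisomic"); the male X=1 without Y and the
locus-panel 1:1 patterns are whole-chromosome/monosomy-like and are kept in
a separate tally rather than counted for the focal markers.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

logger = logging.getLogger(__name__)

PANELS = ("P1", "P22", "PXY")
MAX_SIGNALS = 10  # higher counts are rejected as scoring artifacts

#: pattern each panel's marker corresponds to
MARKER_PATTERN = {"P1": "loss", "P22": "loss", "PXY": "gain"}
MARKER_NAME = {"P1": "1p36-loss", "P22": "22q13-loss", "PXY": "X-gain"}


@dataclass(frozen=True)
class NucleusCount:
    """Signal counts for one nucleus on one panel (PXY: target=X, control=Y)."""

    panel: str
    target: int
    control: int

    def __post_init__(self) -> None:
        if self.panel not in PANELS:
            raise ValueError(f"unknown panel {self.panel!r}")
        if not (0 <= self.target <= MAX_SIGNALS and 0 <= self.control <= MAX_SIGNALS):
            raise ValueError(
                f"signal counts must lie in 0..{MAX_SIGNALS}: "
                f"({self.target}, {self.control})"
            )


@dataclass
class FishCase:
    """Per-nucleus counts for the three panels of one case."""

    case_id: str
    sex: str
    nuclei: dict[str, list[NucleusCount]] = field(default_factory=dict)
    dna_indices: list[float] | None = None

    def __post_init__(self) -> None:
        if self.sex not in ("female", "male"):
            raise ValueError(f"unknown sex {self.sex!r}")


@dataclass
class PanelResult:
    call: str                  # positive | negative | insufficient
    aberrant_fraction: float | None
    n_informative: int
    n_scored: int
    monosomy_like: int         # separate tally of whole-chromosome-like patterns


@dataclass
class FishCaseResult:
    case_id: str
    panels: dict[str, PanelResult]
    positive: bool | None      # None when every panel is insufficient
    positivity_fraction: float

    @property
    def call(self) -> str:
        if self.positive is None:
            return "insufficient"
        return "positive" if self.positive else "negative"


def classify_nucleus(n: NucleusCount, sex: str) -> str:
    """Classify one nucleus as normal / loss / gain / uninformative.

    Locus panels (P1, P22): nuclei need at least two control signals to be
    informative; then target < control is a loss (ratio rule), target >
    control a gain, and a balanced pattern is normal.  CEP X/Y: female gain
    is X >= 3, male gain is X >= 2 regardless of Y ("trisomic" at X=2,Y=1);
    fewer X copies than the sex baseline is a loss pattern; a nucleus with
    no signals at all is uninformative, as is the monosomy-like male
    X=1/Y=0 pattern (tallied separately by :func:`score_case`).
    """
    if sex not in ("female", "male"):
        raise ValueError(f"unknown sex {sex!r}")
    t, c = n.target, n.control
    if n.panel in ("P1", "P22"):
        if t == 0 and c == 0:
            return "uninformative"
        if c < 2:
            return "uninformative"
        if t < c:
            return "loss"
        if t > c:
            return "gain"
        return "normal"  # balanced: 2:2 diploid, 4:4 tetraploid, ...
    # PXY: target = X signals, control = Y signals
    if t == 0 and c == 0:
        return "uninformative"
    if sex == "female":
        if t >= 3:
            return "gain"
        if t == 2:
            return "normal"
        return "loss"  # X=0/1 in a female: monosomy-like
    # male
    if t >= 2:
        return "gain"  # includes the trisomic X=2, Y=1 pattern
    if t == 1 and c == 1:
        return "normal"
    if t == 0:
        return "loss"
    return "uninformative"  # X=1, Y!=1: monosomy-like / control failure


def _is_monosomy_like(n: NucleusCount, sex: str) -> bool:
    if n.panel in ("P1", "P22"):
        return n.target == 1 and n.control == 1
    return sex == "male" and n.target == 1 and n.control == 0


def score_case(
    case: FishCase,
    min_nuclei: int = 100,
    positivity_fraction: float = 0.20,
) -> FishCaseResult:
    """Case-level marker calls from per-nucleus patterns.

    A panel is *insufficient* when fewer than ``min_nuclei`` informative
    nuclei were scored; otherwise its marker is *positive* when the
    aberrant-pattern fraction (P1/P22: loss; PXY: gain) reaches
    ``positivity_fraction`` of informative nuclei.  The case is positive
    iff at least one marker is positive.
    """
    if not (0 <= positivity_fraction <= 1):
        raise ValueError("positivity_fraction must lie in [0, 1]")
    panels: dict[str, PanelResult] = {}
    any_positive = False
    any_scored = False
    for panel in PANELS:
        nuclei = case.nuclei.get(panel, [])
        if not nuclei:
            logger.warning("case %s: panel %s has no nuclei", case.case_id, panel)
            panels[panel] = PanelResult("insufficient", None, 0, 0, 0)
            continue
        patterns = [classify_nucleus(n, case.sex) for n in nuclei]
        informative = [p for p in patterns if p != "uninformative"]
        monosomy = sum(_is_monosomy_like(n, case.sex) for n in nuclei)
        if len(informative) < min_nuclei:
            panels[panel] = PanelResult(
                "insufficient", None, len(informative), len(nuclei), monosomy
            )
            continue
        aberrant = sum(p == MARKER_PATTERN[panel] for p in informative)
        frac = aberrant / len(informative)
        call = "positive" if frac >= positivity_fraction else "negative"
        panels[panel] = PanelResult(call, frac, len(informative), len(nuclei), monosomy)
        any_scored = True
        any_positive = any_positive or call == "positive"
    positive = any_positive if any_scored else None
    return FishCaseResult(
        case_id=case.case_id,
        panels=panels,
        positive=positive,
        positivity_fraction=positivity_fraction,
    )


# --- DNA-index ploidy -------------------------------------------------------

PLOIDY_CLASSES = (
    "diploid",
    "aneuploid",
    "haploid",
    "tetraploid",
    "multiploid",
    "unclassifiable",
)

#: DI intervals; boundaries are assigned to the more benign class, so the
#: diploid interval is closed and its neighbours are open at the shared ends.
DI_DIPLOID = (0.9, 1.1)
DI_HAPLOID = (0.5, 0.6)       # [0.5, 0.6)
DI_ANEUPLOID_LOW = (0.6, 0.9)  # [0.6, 0.9)
DI_ANEUPLOID_HIGH = (1.1, 1.8)  # (1.1, 1.8)
DI_TETRAPLOID = (1.8, 2.2)    # [1.8, 2.2]
DI_DISTINCT_DELTA = 0.05       # DIs closer than this are one stemline


def _classify_single_di(di: float) -> str:
    if DI_DIPLOID[0] <= di <= DI_DIPLOID[1]:
        return "diploid"
    if DI_HAPLOID[0] <= di < DI_HAPLOID[1]:
        return "haploid"
    if DI_ANEUPLOID_LOW[0] <= di < DI_ANEUPLOID_LOW[1]:
        return "aneuploid"
    if DI_ANEUPLOID_HIGH[0] < di < DI_ANEUPLOID_HIGH[1]:
        return "aneuploid"
    if DI_TETRAPLOID[0] <= di <= DI_TETRAPLOID[1]:
        return "tetraploid"
    return "unclassifiable"


def classify_ploidy(dna_indices: list[float]) -> str:
    """Ploidy class from flow-cytometric DNA indices (diploid DI = 1.0).

    Two or more distinct DIs (differing by more than ``DI_DISTINCT_DELTA``,
    the flow-cytometric CV scale) mean multiploidy; otherwise the single
    stemline DI is classified by interval.
    """
    if not dna_indices:
        raise ValueError("at least one DNA index is required")
    if any(di <= 0 for di in dna_indices):
        raise ValueError("DNA indices must be positive")
    stemlines: list[list[float]] = []
    for di in sorted(dna_indices):
        if stemlines and di - stemlines[-1][0] <= DI_DISTINCT_DELTA:
            stemlines[-1].append(di)
        else:
            stemlines.append([di])
    if len(stemlines) >= 2:
        return "multiploid"
    return _classify_single_di(float(sum(stemlines[0]) / len(stemlines[0])))
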