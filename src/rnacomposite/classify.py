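"""Per-nucleotide strandedness calls from nuclease-ratio and DMS channels,
and cutoff evaluation/calibration against reference structures.

A nucleotide is called single-stranded when the S1:V1 ratio exceeds the
ratio cutoff (default 1) and unprotected when the DMS stop count exceeds the
count cutoff (default 20); values exactly at a cutoff are undetermined.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .core import ReferenceStructure
from .probing import ProbingTrack

__all__ = [
    "Cutoffs",
    "NtCall",
    "classify_pars",
    "classify_dms",
    "classify_track",
    "ChannelReport",
    "AccuracyReport",
    "evaluate_against_references",
    "calibrate",
]


@dataclass(frozen=True)
class Cutoffs:
    pars_ratio: float = 1.0
    dms_count: float = 20.0
    #: pseudocount substituted for v1 when v1 == 0 and s1 > 0
    pseudocount: float = 0.5

    def __post_init__(self) -> None:
        if self.pars_ratio <= 0 or self.dms_count <= 0 or self.pseudocount <= 0:
            raise ValueError("cutoffs must be positive")


DEFAULT_CUTOFFS = Cutoffs()


@dataclass(frozen=True)
class NtCall:
    position: int
    pars_call: str  # single / double / undetermined / no_data
    dms_call: str  # unprotected / protected / undetermined / no_data


def classify_pars(s1: float | None, v1: float | None, cutoffs: Cutoffs = DEFAULT_CUTOFFS) -> str:
    """Classify from the S1:V1 ratio: > cutoff single, < cutoff double."""
    if s1 is None or v1 is None:
        return "no_data"
    if s1 < 0 or v1 < 0:
        raise ValueError(f"negative counts s1={s1} v1={v1}")
    if s1 == 0 and v1 == 0:
        return "no_data"
    denom = v1 if v1 > 0 else cutoffs.pseudocount
    ratio = s1 / denom
    if ratio > cutoffs.pars_ratio:
        return "single"
    if ratio < cutoffs.pars_ratio:
        return "double"
    return "undetermined"


def classify_dms(base: str, dms: float | None, cutoffs: Cutoffs = DEFAULT_CUTOFFS) -> str:
    """Classify A/C reactivity: count > cutoff unprotected, < cutoff protected."""
    if base not in "ACGUN":
        raise ValueError(f"bad base {base!r}")
    if base in "GUN":
        return "no_data"
    if dms is None:
        return "no_data"
    if dms > cutoffs.dms_count:
        return "unprotected"
    if dms < cutoffs.dms_count:
        return "protected"
    return "undetermined"


def classify_track(rows: list[ProbingTrack], cutoffs: Cutoffs = DEFAULT_CUTOFFS) -> dict[int, NtCall]:
    return {
        r.position: NtCall(
            position=r.position,
            pars_call=classify_pars(r.s1, r.v1, cutoffs),
            dms_call=classify_dms(r.base, r.dms, cutoffs),
        )
        for r in rows
    }


@dataclass
class ChannelReport:
    """Confusion counts for one channel against reference truth."""

    correct: int = 0
    incorrect: int = 0
    confusion: dict[tuple[str, str], int] = field(default_factory=dict)

    @property
    def covered(self) -> int:
        return self.correct + self.incorrect

    @property
    def accuracy(self) -> float:
        return self.correct / self.covered if self.covered else 0.0


@dataclass
class AccuracyReport:
    cutoffs: Cutoffs
    pars: ChannelReport
    dms: ChannelReport

    @property
    def mean_accuracy(self) -> float:
        return 0.5 * (self.pars.accuracy + self.dms.accuracy)

    def to_row(self) -> dict:
        return {
            "pars_ratio": self.cutoffs.pars_ratio,
            "dms_count": self.cutoffs.dms_count,
            "pars_correct": self.pars.correct,
            "pars_covered": self.pars.covered,
            "pars_accuracy": self.pars.accuracy,
            "dms_correct": self.dms.correct,
            "dms_covered": self.dms.covered,
            "dms_accuracy": self.dms.accuracy,
            "mean_accuracy": self.mean_accuracy,
        }


_PARS_MATCH = {"single": "unpaired", "double": "paired"}
_DMS_MATCH = {"unprotected": "unpaired", "protected": "paired"}


def evaluate_against_references(
    track: list[ProbingTrack],
    references: list[ReferenceStructure],
    cutoffs: Cutoffs = DEFAULT_CUTOFFS,
) -> AccuracyReport:
    """Score calls against reference structures.

    Denominators are covered reference positions (A/C with a DMS value for
    the DMS channel); undetermined calls count as incorrect.
    """
    if not references:
        raise ValueError("no reference structures given")
    by_pos = {r.position: r for r in track}
    pars = ChannelReport()
    dms = ChannelReport()
    for ref in references:
        for pos in ref.region.positions():
            row = by_pos.get(pos)
            if row is None:
                continue
            truth = ref.truth_at(pos)
            pars_call = classify_pars(row.s1, row.v1, cutoffs)
            if pars_call != "no_data":
                key = (pars_call, truth)
                pars.confusion[key] = pars.confusion.get(key, 0) + 1
                if _PARS_MATCH.get(pars_call) == truth:
                    pars.correct += 1
                else:
                    pars.incorrect += 1
            dms_call = classify_dms(row.base, row.dms, cutoffs)
            if dms_call != "no_data":
                key = (dms_call, truth)
                dms.confusion[key] = dms.confusion.get(key, 0) + 1
                if _DMS_MATCH.get(dms_call) == truth:
                    dms.correct += 1
                else:
                    dms.incorrect += 1
    return AccuracyReport(cutoffs=cutoffs, pars=pars, dms=dms)


def calibrate(
    track: list[ProbingTrack],
    references: list[ReferenceStructure],
    grid: list[Cutoffs],
) -> tuple[Cutoffs, list[AccuracyReport]]:
    """Grid search maximizing the unweighted mean of the two channel accuracies.

    Ties break toward the default cutoffs (1.0, 20.0), then toward the
    smallest values. Returns the winner and the full report table.
    """
    if not grid:
        raise ValueError("empty cutoff grid")
    reports = [evaluate_against_references(track, references, c) for c in grid]
    if all(r.pars.covered == 0 and r.dms.covered == 0 for r in reports):
        raise ValueError("references have no track coverage")

    def rank(rep: AccuracyReport):
        c = rep.cutoffs
        is_default = c.pars_ratio == DEFAULT_CUTOFFS.pars_ratio and (
            c.dms_count == DEFAULT_CUTOFFS.dms_count
        )
        return (-rep.mean_accuracy, 0 if is_default else 1, c.pars_ratio, c.dms_count)

    best = min(reports, key=rank)
    return best.cutoffs, reports
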