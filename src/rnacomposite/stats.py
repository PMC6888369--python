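"""Agreement and coverage statistics for the composite model."""

from __future__ import annotations

import json
from dataclasses import dataclass

from .classify import NtCall
from .composite import CompositeState, DuplexCluster
from .core import Interval
from .probing import ProbingTrack

__all__ = [
    "Fraction",
    "AgreementReport",
    "agreement_pars_dms",
    "agreement_with_composite",
    "coverage",
    "build_report",
]


@dataclass(frozen=True)
class Fraction:
    numerator: int
    denominator: int

    @property
    def value(self) -> float:
        return self.numerator / self.denominator if self.denominator else 0.0


@dataclass
class AgreementReport:
    pars_dms_agree: Fraction
    pars_vs_composite: Fraction
    dms_vs_composite: Fraction
    paris_vs_composite: Fraction
    coverage: Fraction

    def to_json(self) -> str:
        payload = {}
        for name in (
            "pars_dms_agree",
            "pars_vs_composite",
            "dms_vs_composite",
            "paris_vs_composite",
            "coverage",
        ):
            f: Fraction = getattr(self, name)
            payload[name] = {
                "numerator": f.numerator,
                "denominator": f.denominator,
                "value": f.value,
            }
        return json.dumps(payload, indent=2)


def agreement_pars_dms(
    track: list[ProbingTrack],
    calls: dict[int, NtCall],
    subranges: list[Interval] | None = None,
) -> Fraction:
    """Concordance of the two probing channels over DMS-covered A/C positions.

    Denominator: every covered A/C (with a DMS value) inside the configured
    subranges. Numerator: positions where both channels are determined and
    concordant (single & unprotected, or double & protected).
    """
    denom = num = 0
    for row in track:
        if row.base not in "AC" or row.dms is None:
            continue
        if subranges is not None and not any(row.position in iv for iv in subranges):
            continue
        denom += 1
        call = calls.get(row.position)
        if call is None:
            continue
        if (call.pars_call, call.dms_call) in (
            ("single", "unprotected"),
            ("double", "protected"),
        ):
            num += 1
    if denom == 0:
        raise ValueError("no covered A/C positions in the requested subranges")
    return Fraction(num, denom)


_CHANNEL_STATE = {
    "pars": {"single": "unpaired", "double": "paired"},
    "dms": {"unprotected": "unpaired", "protected": "paired"},
}


def agreement_with_composite(
    channel: str,
    calls: dict[int, NtCall],
    composite: CompositeState,
    accepted_clusters: list[DuplexCluster] | None = None,
    paris_pairs: list[tuple[int, int]] | None = None,
) -> Fraction:
    """Fraction of channel-determined positions matching the composite state.

    For ``paris``, the positions are the duplex-registry members of accepted
    clusters and a match means the composite says paired.
    """
    if channel == "paris":
        positions: set[int] = set()
        if paris_pairs:
            positions = {p for ij in paris_pairs for p in ij}
        num = sum(1 for p in positions if composite.state.get(p) == "paired")
        return Fraction(num, len(positions))
    try:
        mapping = _CHANNEL_STATE[channel]
    except KeyError:
        raise ValueError(f"unknown channel {channel!r}") from None
    denom = num = 0
    for pos, call in calls.items():
        raw = call.pars_call if channel == "pars" else call.dms_call
        want = mapping.get(raw)
        if want is None:  # undetermined / no_data excluded from both sides
            continue
        denom += 1
        if composite.state.get(pos) == want:
            num += 1
    return Fraction(num, denom)


def coverage(
    track: list[ProbingTrack],
    accepted_clusters: list[DuplexCluster],
    mfe_regions: list[Interval],
    transcript_len: int,
) -> Fraction:
    """|union of track positions, accepted duplex spans, MFE regions| / length."""
    covered: set[int] = {r.position for r in track}
    for c in accepted_clusters:
        covered.update(c.left.positions())
        covered.update(c.right.positions())
    for iv in mfe_regions:
        covered.update(iv.positions())
    return Fraction(len(covered), transcript_len)


def build_report(
    track: list[ProbingTrack],
    calls: dict[int, NtCall],
    composite: CompositeState,
    accepted_clusters: list[DuplexCluster],
    paris_pairs: list[tuple[int, int]],
    mfe_regions: list[Interval],
    transcript_len: int,
    subranges: list[Interval] | None = None,
) -> AgreementReport:
    return AgreementReport(
        pars_dms_agree=agreement_pars_dms(track, calls, subranges),
        pars_vs_composite=agreement_with_composite("pars", calls, composite),
        dms_vs_composite=agreement_with_composite("dms", calls, composite),
        paris_vs_composite=agreement_with_composite(
            "paris", calls, composite, paris_pairs=paris_pairs
        ),
        coverage=coverage(track, accepted_clusters, mfe_regions, transcript_len),
    )
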