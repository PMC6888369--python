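"""Composite model inference.

Accepts crosslink-ligation duplex groups under read-count criteria, assigns
duplex base-pair registries by constrained co-folding, reconciles the
per-nucleotide evidence channels under explicit precedence, harvests
helices, and calls pseudoknot layers.

Per-nucleotide precedence:

1. an accepted duplex covers the position -> paired (provenance ``paris``);
2. the two probing channels agree -> that state (``pars+dms``);
3. they disagree, or only one is determined -> the MFE scaffold decides
   (``mfe_resolved``);
4. no evidence at all -> unpaired inside probed regions
   (``default_unstructured``), ``no_data`` outside.

Nucleotides resolved paired but left without an assignable partner are
demoted to unpaired (``default_unstructured``).
"""

from __future__ import annotations

import logging
import warnings
from collections import Counter
from dataclasses import dataclass, field

from .classify import Cutoffs, DEFAULT_CUTOFFS, NtCall, classify_track
from .core import (
    Interval,
    StructureModel,
    TranscriptSeq,
    helices_from_pairs,
    name_elements,
    pairs_cross,
)
from .fold import fold, fold_uncovered_region
from .probing import DuplexGroup, ProbingTrack

__all__ = [
    "ParisCriteria",
    "CompositeState",
    "DuplexCluster",
    "AssemblyResult",
    "accept_duplex",
    "cluster_duplexes",
    "duplex_to_pairs",
    "resolve_nucleotide",
    "call_pseudoknots",
    "assemble",
    "loop_distance",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class ParisCriteria:
    """Read-count acceptance rules for duplex groups (strict inequalities)."""

    multi_dataset_reads: int = 3
    multi_dataset_min: int = 2
    single_dataset_reads: int = 5

    def __post_init__(self) -> None:
        if min(self.multi_dataset_reads, self.multi_dataset_min, self.single_dataset_reads) < 1:
            raise ValueError("criteria must all be >= 1")


@dataclass
class CompositeState:
    """Per-nucleotide composite assignment with provenance."""

    state: dict[int, str] = field(default_factory=dict)  # paired/unpaired/no_data
    provenance: dict[int, str | None] = field(default_factory=dict)

    def counts(self) -> dict[str, int]:
        return dict(Counter(f"{s}:{self.provenance.get(p)}" for p, s in self.state.items()))


@dataclass
class DuplexCluster:
    """Duplex groups merged across datasets onto one span pair."""

    left: Interval
    right: Interval
    reads_by_dataset: dict[str, int]
    members: list[DuplexGroup]


@dataclass
class AssemblyResult:
    """Everything assemble() inferred, for serialization and statistics."""

    model: StructureModel
    composite: CompositeState
    accepted_clusters: list[DuplexCluster]
    paris_pairs: list[tuple[int, int]]
    mfe_regions: list[Interval]

    def __iter__(self):  # allow model, composite, accepted = assemble(...)
        return iter((self.model, self.composite, self.accepted_clusters))


def accept_duplex(groups, criteria: ParisCriteria = ParisCriteria()) -> bool:
    """True iff reads > multi threshold in >= min datasets, or > single threshold in any."""
    if not groups:
        return False
    if isinstance(groups, DuplexCluster):
        reads = list(groups.reads_by_dataset.values())
    else:
        by_dataset: dict[str, int] = {}
        for g in groups:
            by_dataset[g.dataset_id] = by_dataset.get(g.dataset_id, 0) + g.reads
        reads = list(by_dataset.values())
    n_multi = sum(1 for r in reads if r > criteria.multi_dataset_reads)
    if n_multi >= criteria.multi_dataset_min:
        return True
    return any(r > criteria.single_dataset_reads for r in reads)


def cluster_duplexes(duplexes: list[DuplexGroup], slack: int = 5) -> list[DuplexCluster]:
    """Merge duplex records whose left spans and right spans each lie within
    ``slack`` nt of one another (transitively); per-dataset reads are summed."""
    n = len(duplexes)
    parent = list(range(n))

    def find(a):
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    for a in range(n):
        for b in range(a + 1, n):
            da, db = duplexes[a], duplexes[b]
            if da.left.gap_to(db.left) <= slack and da.right.gap_to(db.right) <= slack:
                parent[find(a)] = find(b)

    groups: dict[int, list[DuplexGroup]] = {}
    for k in range(n):
        groups.setdefault(find(k), []).append(duplexes[k])

    clusters = []
    for members in groups.values():
        left = _merge_span([m.left for m in members])
        right = _merge_span([m.right for m in members])
        reads: dict[str, int] = {}
        for m in members:
            reads[m.dataset_id] = reads.get(m.dataset_id, 0) + m.reads
        clusters.append(DuplexCluster(left=left, right=right, reads_by_dataset=reads, members=members))
    clusters.sort(key=lambda c: (c.left.start, c.right.start))
    return clusters


def _merge_span(spans: list[Interval]) -> Interval:
    """Intersection extended halfway to the union (midpoint rule)."""
    u_start = min(s.start for s in spans)
    u_end = max(s.end for s in spans)
    i_start = max(s.start for s in spans)
    i_end = min(s.end for s in spans)
    if i_start > i_end:  # no common core: fall back to the union
        return Interval(u_start, u_end)
    return Interval((u_start + i_start) // 2, (u_end + i_end + 1) // 2)


_LINKER = "NNN"  # unpairable spacer for span co-folding


def duplex_to_pairs(seq: TranscriptSeq, left: Interval, right: Interval) -> list[tuple[int, int]]:
    """Assign base pairs to a duplex by MFE co-folding of its two spans.

    The spans are concatenated around an unpairable 3-nt linker and folded
    with pairing restricted to one-partner-per-span; returns transcript-
    coordinate pairs (possibly empty, with a warning, when the spans have no
    canonical complementarity).
    """
    ls, rs = seq.subseq(left), seq.subseq(right)
    chimera = ls + _LINKER + rs
    n_left = len(ls)
    r_off = n_left + len(_LINKER)

    def cross_only(i: int, j: int) -> bool:
        return i <= n_left and j > r_off

    res = fold(chimera, pair_filter=cross_only)
    pairs = []
    for i, j in res.pairs:
        gi = left.start + i - 1
        gj = right.start + (j - r_off) - 1
        pairs.append((gi, gj))
    if not pairs:
        warnings.warn(
            f"duplex spans {left}/{right} have no canonical complementarity", stacklevel=2
        )
    return sorted(pairs)


def resolve_nucleotide(
    nt_call: NtCall | None,
    paris_paired: bool,
    mfe_paired: bool,
    *,
    in_probed_region: bool = True,
) -> tuple[str, str | None]:
    """Apply the evidence-precedence rules; returns (state, provenance)."""
    if paris_paired:
        return "paired", "paris"
    pars = nt_call.pars_call if nt_call else "no_data"
    dms = nt_call.dms_call if nt_call else "no_data"
    pars_det = pars in ("single", "double")
    dms_det = dms in ("unprotected", "protected")
    if pars_det and dms_det:
        if pars == "single" and dms == "unprotected":
            return "unpaired", "pars+dms"
        if pars == "double" and dms == "protected":
            return "paired", "pars+dms"
        # discrepancy -> MFE tiebreak
        return ("paired" if mfe_paired else "unpaired"), "mfe_resolved"
    if pars_det or dms_det:
        return ("paired" if mfe_paired else "unpaired"), "mfe_resolved"
    if in_probed_region:
        return "unpaired", "default_unstructured"
    return "no_data", None


def loop_distance(left: Interval, right: Interval) -> int:
    """Intervening nucleotides between the two strands of a duplex."""
    if left.end >= right.start:
        raise ValueError(f"spans {left} and {right} overlap or are misordered")
    return right.start - left.end - 1


def call_pseudoknots(model: StructureModel) -> StructureModel:
    """Assign pseudoknot layers to crossing helices.

    Among a crossing pair, the helix whose removal leaves more pairs nested
    is demoted (i.e., the larger helix stays at layer 0); ties keep the more
    5' helix at layer 0. Demoted helices take the lowest layer on which they
    cross nothing.
    """
    helices = sorted(model.helices, key=lambda h: h.pairs[0][0])
    layer0 = list(range(len(helices)))
    demoted: list[int] = []
    changed = True
    while changed:
        changed = False
        for ai in range(len(layer0)):
            for bi in range(ai + 1, len(layer0)):
                a, b = layer0[ai], layer0[bi]
                if pairs_cross(helices[a].pairs[0], helices[b].pairs[0]):
                    # keep the helix with more pairs; tie -> keep the 5'-most (a)
                    loser = b if len(helices[b].pairs) <= len(helices[a].pairs) else a
                    layer0.remove(loser)
                    demoted.append(loser)
                    changed = True
                    break
            if changed:
                break
    for k in layer0:
        helices[k].pk_layer = 0
    for k in sorted(demoted, key=lambda k: helices[k].pairs[0][0]):
        t = 1
        while any(
            helices[m].pk_layer == t and pairs_cross(helices[k].pairs[0], helices[m].pairs[0])
            for m in range(len(helices))
            if m != k and (m in layer0 or helices[m].pk_layer > 0)
        ):
            t += 1
        helices[k].pk_layer = t
    model.helices = helices
    return model


def assemble(
    track: list[ProbingTrack],
    duplexes: list[DuplexGroup],
    seq: TranscriptSeq,
    *,
    criteria: ParisCriteria = ParisCriteria(),
    cutoffs: Cutoffs = DEFAULT_CUTOFFS,
    uncovered_regions: list[Interval] = (),
    cluster_slack: int = 5,
    window: int = 100,
    overlap: int = 20,
    scaffold_max_span: int = 3000,
) -> AssemblyResult:
    """Run the full inference pipeline; deterministic for fixed inputs.

    Returns an :class:`AssemblyResult` with the named structure model, the
    per-nucleotide composite state, the accepted duplex clusters, and the
    duplex-registry pairs.
    """
    for iv in uncovered_regions:
        if iv.start < seq.start or iv.end > seq.end:
            raise ValueError(f"uncovered region {iv} outside transcript")
    calls = classify_track(track, cutoffs)

    # --- duplex acceptance and registry
    clusters = cluster_duplexes(duplexes, slack=cluster_slack)
    accepted = [c for c in clusters if accept_duplex(c, criteria)]
    log.info("duplex clusters: %d total, %d accepted", len(clusters), len(accepted))
    paris_pairs: list[tuple[int, int]] = []
    paris_taken: set[int] = set()
    for c in accepted:
        for i, j in duplex_to_pairs(seq, c.left, c.right):
            if i not in paris_taken and j not in paris_taken:
                paris_pairs.append((i, j))
                paris_taken.update((i, j))

    # --- MFE scaffold over the probed region, constrained by channel evidence
    probed_positions = {r.position for r in track}
    mfe_pairs: list[tuple[int, int]] = []
    if probed_positions:
        lo, hi = min(probed_positions), max(probed_positions)
        allowed = {
            p
            for p in range(lo, hi + 1)
            if p not in paris_taken and not _evidence_single(calls.get(p))
        }
        region = Interval(lo, hi)
        if len(region) <= scaffold_max_span:
            # one global fold avoids truncated-helix artifacts at window edges
            res = fold(
                seq.subseq(region),
                allowed_positions={p - lo + 1 for p in allowed},
            )
            mfe_pairs.extend((i + lo - 1, j + lo - 1) for i, j in res.pairs)
        else:
            mfe_pairs.extend(
                _scan_fold_constrained(seq, region, allowed, window, overlap)
            )

    # --- MFE-only fallback for unprobed regions
    mfe_only_pairs: list[tuple[int, int]] = []
    mfe_only_positions: set[int] = set()
    for iv in uncovered_regions:
        frag = fold_uncovered_region(seq, iv, window=window, overlap=overlap)
        mfe_only_pairs.extend(frag.pairs)
        mfe_only_positions.update(iv.positions())

    mfe_paired_pos = {p for ij in mfe_pairs for p in ij} | {
        p for ij in mfe_only_pairs for p in ij
    }

    # --- per-nucleotide resolution
    comp = CompositeState()
    for p in range(seq.start, seq.end + 1):
        in_probed = p in probed_positions or p in mfe_only_positions
        if p in mfe_only_positions and p not in probed_positions:
            state = "paired" if p in mfe_paired_pos else "unpaired"
            comp.state[p], comp.provenance[p] = state, "mfe_only_region"
            continue
        state, prov = resolve_nucleotide(
            calls.get(p),
            paris_paired=p in paris_taken,
            mfe_paired=p in mfe_paired_pos,
            in_probed_region=in_probed,
        )
        comp.state[p], comp.provenance[p] = state, prov

    # --- harvest: a pair survives iff both endpoints resolved paired
    final_pairs = list(paris_pairs)
    taken = set(paris_taken)
    for i, j in sorted(mfe_pairs) + sorted(mfe_only_pairs):
        if i in taken or j in taken:
            continue
        if comp.state.get(i) == "paired" and comp.state.get(j) == "paired":
            final_pairs.append((i, j))
            taken.update((i, j))
    # demote paired positions that found no partner
    for p, s in comp.state.items():
        if s == "paired" and p not in taken:
            comp.state[p] = "unpaired"
            comp.provenance[p] = "default_unstructured"

    helices = helices_from_pairs(final_pairs)
    model = StructureModel(
        seq=seq,
        helices=helices,
        per_nt_state=dict(comp.state),
    )
    model = call_pseudoknots(model)
    model = name_elements(model)
    log.info("composite provenance counts: %s", comp.counts())
    return AssemblyResult(
        model=model,
        composite=comp,
        accepted_clusters=accepted,
        paris_pairs=paris_pairs,
        mfe_regions=list(uncovered_regions),
    )


def _evidence_single(call: NtCall | None) -> bool:
    """Net single-stranded channel evidence forbids the position from the scaffold."""
    if call is None:
        return False
    single = call.pars_call == "single" or call.dms_call == "unprotected"
    double = call.pars_call == "double" or call.dms_call == "protected"
    return single and not double


def _scan_fold_constrained(
    seq: TranscriptSeq,
    region: Interval,
    allowed: set[int],
    window: int,
    overlap: int,
) -> list[tuple[int, int]]:
    """Windowed constrained fold (same scan/merge discipline as the MFE fallback)."""
    step = window - overlap
    windows = []
    start = region.start
    while True:
        end = min(start + window - 1, region.end)
        windows.append(Interval(start, end))
        if end >= region.end:
            break
        start += step
    per_window: list[set[tuple[int, int]]] = []
    for w in windows:
        local_allowed = {p - w.start + 1 for p in allowed if p in w}
        res = fold(seq.subseq(w), allowed_positions=local_allowed)
        per_window.append({(i + w.start - 1, j + w.start - 1) for i, j in res.pairs})
    candidates = set().union(*per_window) if per_window else set()
    kept = []
    for i, j in sorted(candidates):
        containing = [k for k, w in enumerate(windows) if i in w and j in w]
        if all((i, j) in per_window[k] for k in containing):
            kept.append((min(containing), (i, j)))
    taken: set[int] = set()
    final = []
    for _, (i, j) in sorted(kept):
        if i in taken or j in taken:
            continue
        if any((a < i < b < j) or (i < a < j < b) for a, b in final):
            continue
        final.append((i, j))
        taken.update((i, j))
    return final
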