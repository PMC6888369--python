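"""Functional-annotation overlay: structural context of binding sites,
modification matrices, differential duplex ("structural switch") calls, and
mutation/SNP refolding impact.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources

import pandas as pd

from .composite import DuplexCluster
from .core import Interval, StructureModel, TranscriptSeq
from .fold import fold

__all__ = [
    "Annotation",
    "ModificationMatrix",
    "load_m6a_matrix",
    "matrix_summary",
    "structural_context",
    "differential_duplexes",
    "parse_edit",
    "apply_edit",
    "mutation_impact",
    "site_accessibility_delta",
]

ANNOTATION_KINDS = {
    "protein_site",
    "mirna_site",
    "rna_rna_site",
    "modification",
    "mutation",
    "snp",
}

_SUB_RE = re.compile(r"^([ACGU])(\d+)([ACGU])$")
_DEL_RE = re.compile(r"^(?:Δ|del)([ACGU]+)(\d+)-(\d+)$")


@dataclass(frozen=True)
class Annotation:
    kind: str
    region: Interval
    label: str
    payload: str = ""

    def __post_init__(self) -> None:
        if self.kind not in ANNOTATION_KINDS:
            raise ValueError(f"unknown annotation kind {self.kind!r}")


@dataclass
class ModificationMatrix:
    """Presence/absence of modification marks across cell lines."""

    positions: list[int]
    columns: list[str]
    cells: dict[tuple[int, str], bool]

    def __post_init__(self) -> None:
        if len(set(self.positions)) != len(self.positions):
            raise ValueError("duplicate modification positions")

    def present(self, position: int, column: str) -> bool:
        return self.cells[(position, column)]


def load_m6a_matrix(path=None) -> ModificationMatrix:
    """Load a modification matrix TSV; defaults to the packaged m6A table."""
    if path is None:
        path = resources.files("rnacomposite.data") / "m6a_matrix.tsv"
    df = pd.read_csv(path, sep="\t", dtype=str)
    positions = [int(p) for p in df.iloc[:, 0]]
    columns = list(df.columns[1:])
    cells = {}
    for row, pos in zip(df.itertuples(index=False), positions):
        for col, raw in zip(columns, row[1:]):
            if raw not in "+-":
                raise ValueError(f"matrix cell for {pos}/{col} must be '+' or '-'")
            cells[(pos, col)] = raw == "+"
    return ModificationMatrix(positions=positions, columns=columns, cells=cells)


def matrix_summary(m: ModificationMatrix) -> dict:
    """Per-column / per-row presence counts and presence sets."""
    col_counts = {
        c: sum(1 for p in m.positions if m.cells[(p, c)]) for c in m.columns
    }
    row_counts = {
        p: sum(1 for c in m.columns if m.cells[(p, c)]) for p in m.positions
    }
    row_present = {
        p: [c for c in m.columns if m.cells[(p, c)]] for p in m.positions
    }
    return {
        "n_positions": len(m.positions),
        "column_counts": col_counts,
        "row_counts": row_counts,
        "row_present": row_present,
    }


def differential_rows(
    m: ModificationMatrix, cols_a: list[str], cols_b: list[str]
) -> list[int]:
    """Rows present in every column of A and absent in every column of B."""
    return [
        p
        for p in m.positions
        if all(m.cells[(p, c)] for c in cols_a) and not any(m.cells[(p, c)] for c in cols_b)
    ]


@dataclass
class ContextReport:
    annotation: Annotation
    paired_fraction: float
    elements: list[str]
    classification: str  # structured / unstructured / mixed


def structural_context(model: StructureModel, annotation: Annotation) -> ContextReport:
    """Pairing context of an annotated site within the model."""
    seq = model.seq
    if annotation.region.start < seq.start or annotation.region.end > seq.end:
        raise ValueError(f"annotation {annotation.label} outside transcript")
    positions = list(annotation.region.positions())
    paired = sum(1 for p in positions if model.is_paired(p))
    frac = paired / len(positions)
    elements = []
    for h in model.helices:
        span = h.span
        if annotation.region.overlaps(span):
            elements.append(h.name)
    if frac > 0.5:
        cls = "structured"
    elif frac == 0.0:
        cls = "unstructured"
    else:
        cls = "mixed"
    return ContextReport(
        annotation=annotation, paired_fraction=frac, elements=elements, classification=cls
    )


@dataclass
class SwitchCandidate:
    cluster: DuplexCluster
    modification_overlap: list[int] = field(default_factory=list)

    @property
    def is_switch(self) -> bool:
        return bool(self.modification_overlap)


def differential_duplexes(
    accepted_a: list[DuplexCluster],
    accepted_b: list[DuplexCluster],
    modifications: list[Annotation] = (),
    slack: int = 5,
) -> list[SwitchCandidate]:
    """Duplexes accepted in condition A but absent from condition B.

    Matching uses the same span slack as duplex clustering; each lost duplex
    is flagged as a structural-switch candidate when a modification position
    falls within either of its spans.
    """
    out = []
    for ca in accepted_a:
        matched = any(
            ca.left.gap_to(cb.left) <= slack and ca.right.gap_to(cb.right) <= slack
            for cb in accepted_b
        )
        if matched:
            continue
        overlap = [
            p
            for ann in modifications
            if ann.kind == "modification"
            for p in ann.region.positions()
            if p in ca.left or p in ca.right
        ]
        out.append(SwitchCandidate(cluster=ca, modification_overlap=sorted(set(overlap))))
    return out


def parse_edit(edit: str):
    """Parse a mutation edit string.

    Substitutions are written ``U4056C``; deletions ``ΔAA4040-4041`` (the
    ASCII spelling ``delAA4040-4041`` is also accepted).
    """
    m = _SUB_RE.match(edit)
    if m:
        ref, pos, alt = m.group(1), int(m.group(2)), m.group(3)
        return ("sub", pos, pos, ref, alt)
    m = _DEL_RE.match(edit)
    if m:
        bases, start, end = m.group(1), int(m.group(2)), int(m.group(3))
        if end - start + 1 != len(bases):
            raise ValueError(f"deletion {edit!r}: span does not match deleted bases")
        return ("del", start, end, bases, "")
    raise ValueError(f"cannot parse edit {edit!r}")


def apply_edit(seq: TranscriptSeq, edit: str) -> TranscriptSeq:
    """Apply a substitution or deletion; validates the reference bases."""
    kind, start, end, ref, alt = parse_edit(edit)
    observed = seq.subseq(Interval(start, end))
    if observed != ref:
        raise ValueError(
            f"edit {edit!r}: reference base(s) at {start}-{end} are {observed}, not {ref}"
        )
    off = seq.numbering_offset
    res = seq.residues
    if kind == "sub":
        new = res[: start - off] + alt + res[start - off + 1 :]
    else:
        new = res[: start - off] + res[end - off + 1 :]
    return TranscriptSeq(id=f"{seq.id}|{edit}", residues=new, numbering_offset=off)


@dataclass
class MutationImpact:
    edit: str
    window: Interval
    dg_wt: float
    dg_mut: float
    ddg: float  # > 0 means destabilizing
    wt_structure: str
    mut_structure: str
    pairing_diff: list[int]  # window-local positions whose pairing changed


def mutation_impact(
    seq: TranscriptSeq,
    model: StructureModel,
    mutation: Annotation,
    window_pad: int = 20,
) -> MutationImpact:
    """Refold the enclosing element's window with and without the edit.

    ``ddg = dg_mut - dg_wt``; positive values are destabilizing. The window
    is the enclosing helix span padded by ``window_pad`` (or the mutation
    region padded, when no helix encloses it).
    """
    edit = mutation.payload or mutation.label
    kind, start, end, _, _ = parse_edit(edit)
    if start < seq.start or end > seq.end:
        raise ValueError(f"edit {edit!r} outside transcript")
    host = None
    for h in model.helices:
        span = h.span
        if start in span and end in span:
            if host is None or len(span) < len(host.span):
                host = h
    base_iv = host.span if host is not None else Interval(start, end)
    window = Interval(
        max(seq.start, base_iv.start - window_pad),
        min(seq.end, base_iv.end + window_pad),
    )
    mut_seq = apply_edit(seq, edit)
    wt_window = seq.subseq(window)
    mut_window = mut_seq.subseq(
        Interval(window.start, window.end - (end - start + 1 if kind == "del" else 0))
    )
    wt_res = fold(wt_window)
    mut_res = fold(mut_window)
    ddg = round(mut_res.energy - wt_res.energy, 1)
    wt_paired = wt_res.paired_positions()
    mut_paired = mut_res.paired_positions()
    if kind == "sub":
        diff = sorted(wt_paired ^ mut_paired)
    else:  # deletions shift coordinates; report union of changed wt positions
        diff = sorted(wt_paired ^ mut_paired)
    return MutationImpact(
        edit=edit,
        window=window,
        dg_wt=wt_res.energy,
        dg_mut=mut_res.energy,
        ddg=ddg,
        wt_structure=wt_res.dotbracket,
        mut_structure=mut_res.dotbracket,
        pairing_diff=diff,
    )


@dataclass
class AccessibilityDelta:
    site: Interval
    unpaired_fraction_wt: float
    unpaired_fraction_mut: float

    @property
    def delta(self) -> float:
        """Positive = site is more accessible in the mutant."""
        return self.unpaired_fraction_mut - self.unpaired_fraction_wt


def site_accessibility_delta(
    model_wt: StructureModel, model_mut: StructureModel, site: Interval
) -> AccessibilityDelta:
    def unpaired_frac(model: StructureModel) -> float:
        positions = list(site.positions())
        return sum(1 for p in positions if not model.is_paired(p)) / len(positions)

    return AccessibilityDelta(
        site=site,
        unpaired_fraction_wt=unpaired_frac(model_wt),
        unpaired_fraction_mut=unpaired_frac(model_mut),
    )
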