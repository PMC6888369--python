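"""Core domain types: sequences, intervals, helices, structure models.

Coordinates are 1-based inclusive throughout the package; the only place
0-based half-open coordinates appear is inside BED writers.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace

__all__ = [
    "RNA_ALPHABET",
    "CANONICAL_PAIRS",
    "Interval",
    "TranscriptSeq",
    "Helix",
    "StructureModel",
    "ReferenceStructure",
    "DotBracketError",
    "pairs_cross",
    "helices_cross",
    "helices_from_pairs",
    "parse_dotbracket",
    "write_dotbracket",
    "name_elements",
    "write_ct",
    "write_bed6",
    "read_fasta",
    "write_fasta",
]

RNA_ALPHABET = frozenset("ACGUN")

#: Watson-Crick plus wobble pairs, as unordered base combinations.
CANONICAL_PAIRS = frozenset(
    {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G"), ("G", "U"), ("U", "G")}
)

COMPLEMENT = {"A": "U", "U": "A", "G": "C", "C": "G", "N": "N"}

# Bracket tiers for pseudoknot layers, in order of assignment.
_OPENERS = "([{<" + "".join(chr(c) for c in range(ord("A"), ord("Z") + 1))
_CLOSERS = ")]}>" + "".join(chr(c) for c in range(ord("a"), ord("z") + 1))


class DotBracketError(ValueError):
    """Malformed dot-bracket text."""


@dataclass(frozen=True, order=True)
class Interval:
    """A 1-based inclusive span on the transcript."""

    start: int
    end: int

    def __post_init__(self) -> None:
        if not (1 <= self.start <= self.end):
            raise ValueError(f"invalid interval [{self.start}, {self.end}]")

    def __len__(self) -> int:
        return self.end - self.start + 1

    def __contains__(self, pos: int) -> bool:
        return self.start <= pos <= self.end

    def overlaps(self, other: "Interval") -> bool:
        return self.start <= other.end and other.start <= self.end

    def gap_to(self, other: "Interval") -> int:
        """Nucleotides strictly between two disjoint intervals (0 if they touch/overlap)."""
        if self.overlaps(other):
            return 0
        if self.end < other.start:
            return other.start - self.end - 1
        return self.start - other.end - 1

    def positions(self) -> range:
        return range(self.start, self.end + 1)


@dataclass(frozen=True)
class TranscriptSeq:
    """A transcript sequence with an explicit coordinate offset.

    ``numbering_offset`` is the coordinate of the first residue (default 1);
    all downstream coordinates follow the transcript's own numbering.
    """

    id: str
    residues: str
    numbering_offset: int = 1

    def __post_init__(self) -> None:
        if len(self.residues) < 1:
            raise ValueError("empty sequence")
        res = self.residues.upper().replace("T", "U")
        bad = set(res) - RNA_ALPHABET
        if bad:
            raise ValueError(f"non-RNA residues in {self.id!r}: {sorted(bad)}")
        object.__setattr__(self, "residues", res)

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def start(self) -> int:
        return self.numbering_offset

    @property
    def end(self) -> int:
        return self.numbering_offset + len(self.residues) - 1

    def base(self, pos: int) -> str:
        if not (self.start <= pos <= self.end):
            raise IndexError(f"position {pos} outside transcript [{self.start}, {self.end}]")
        return self.residues[pos - self.numbering_offset]

    def subseq(self, iv: Interval) -> str:
        if iv.start < self.start or iv.end > self.end:
            raise IndexError(f"interval {iv} outside transcript [{self.start}, {self.end}]")
        off = self.numbering_offset
        return self.residues[iv.start - off : iv.end - off + 1]


@dataclass
class Helix:
    """A run of mutually non-crossing, stacked base pairs.

    Stems interrupted by internal loops or bulges are represented as several
    Helix records; named elements that span such interruptions are groups of
    records sharing a name prefix.
    """

    pairs: list[tuple[int, int]]
    name: str = ""
    pk_layer: int = 0
    non_canonical: bool = False

    def __post_init__(self) -> None:
        if not self.pairs:
            raise ValueError("helix with no pairs")
        for i, j in self.pairs:
            if i >= j:
                raise ValueError(f"pair ({i},{j}) not 5'<3'")
        self.pairs = sorted(self.pairs)
        for (i1, j1), (i2, j2) in zip(self.pairs, self.pairs[1:]):
            if not (i1 < i2 and j2 < j1):
                raise ValueError("pairs within a helix must be nested")

    @property
    def five_prime(self) -> Interval:
        return Interval(self.pairs[0][0], self.pairs[-1][0])

    @property
    def three_prime(self) -> Interval:
        return Interval(self.pairs[-1][1], self.pairs[0][1])

    @property
    def span(self) -> Interval:
        return Interval(self.pairs[0][0], self.pairs[0][1])

    def __len__(self) -> int:
        return len(self.pairs)


def pairs_cross(p: tuple[int, int], q: tuple[int, int]) -> bool:
    (i, j), (k, l) = p, q
    return (i < k < j < l) or (k < i < l < j)


def helices_cross(a: Helix, b: Helix) -> bool:
    # all pairs within a helix are nested, so outermost pairs decide
    return pairs_cross(a.pairs[0], b.pairs[0])


def helices_from_pairs(pairs):
    """Group a pair set into Helix records of contiguously stacked pairs.

    Two pairs (i,j) and (i+1,j-1) stack; any interruption starts a new record.
    """
    out: list[Helix] = []
    run: list[tuple[int, int]] = []
    for i, j in sorted(set(pairs)):
        if run and (i == run[-1][0] + 1 and j == run[-1][1] - 1):
            run.append((i, j))
        else:
            if run:
                out.append(Helix(run))
            run = [(i, j)]
    if run:
        out.append(Helix(run))
    return out


@dataclass
class StructureModel:
    """A full structural assignment over a transcript."""

    seq: TranscriptSeq
    helices: list[Helix] = field(default_factory=list)
    #: per-position state, "paired" / "unpaired" / "no_data"
    per_nt_state: dict[int, str] = field(default_factory=dict)
    #: junction records (name like "3WJ1", member helix names)
    junctions: list[tuple[str, list[str]]] = field(default_factory=list)

    def __post_init__(self) -> None:
        partner: dict[int, int] = {}
        for h in self.helices:
            for i, j in h.pairs:
                if i in partner or j in partner:
                    raise ValueError(f"position in more than one pair: ({i},{j})")
                partner[i] = j
                partner[j] = i
        self._partner = partner
        if not self.per_nt_state:
            self.per_nt_state = {
                p: ("paired" if p in partner else "unpaired")
                for p in range(self.seq.start, self.seq.end + 1)
            }

    @property
    def pairs(self) -> list[tuple[int, int]]:
        return sorted(p for h in self.helices for p in h.pairs)

    def partner_of(self, pos: int) -> int | None:
        return self._partner.get(pos)

    def is_paired(self, pos: int) -> bool:
        return pos in self._partner

    def helix_of(self, pos: int) -> Helix | None:
        for h in self.helices:
            if any(pos in (i, j) for i, j in h.pairs):
                return h
        return None


@dataclass(frozen=True)
class ReferenceStructure:
    """A validated local structure used for cutoff calibration."""

    name: str
    region: Interval
    truth: tuple[str, ...]  # "paired" / "unpaired" per position

    def __post_init__(self) -> None:
        if len(self.region) != len(self.truth):
            raise ValueError(
                f"{self.name}: region length {len(self.region)} != truth length {len(self.truth)}"
            )
        bad = set(self.truth) - {"paired", "unpaired"}
        if bad:
            raise ValueError(f"{self.name}: invalid truth states {bad}")

    def truth_at(self, pos: int) -> str:
        return self.truth[pos - self.region.start]


# ---------------------------------------------------------------------------
# dot-bracket


def parse_dotbracket(text: str, seq: TranscriptSeq) -> StructureModel:
    """Parse layered dot-bracket notation into a StructureModel.

    Tiers are "()", "[]", "{}", "<>", then "Aa".."Zz". Raises
    :class:`DotBracketError` naming the first offending column on unbalanced
    brackets, or on a length mismatch with the sequence.
    """
    if len(text) != len(seq):
        raise DotBracketError(
            f"structure length {len(text)} != sequence length {len(seq)}"
        )
    off = seq.numbering_offset
    stacks: dict[int, list[int]] = {}
    tier_pairs: dict[int, list[tuple[int, int]]] = {}
    for col, ch in enumerate(text):
        if ch in ".-_,:~":
            continue
        if ch in _OPENERS:
            tier = _OPENERS.index(ch)
            stacks.setdefault(tier, []).append(off + col)
        elif ch in _CLOSERS:
            tier = _CLOSERS.index(ch)
            stack = stacks.get(tier)
            if not stack:
                raise DotBracketError(f"unbalanced {ch!r} at column {col + 1}")
            i = stack.pop()
            tier_pairs.setdefault(tier, []).append((i, off + col))
        else:
            raise DotBracketError(f"unrecognized character {ch!r} at column {col + 1}")
    for tier, stack in stacks.items():
        if stack:
            col = stack[-1] - off + 1
            raise DotBracketError(
                f"unbalanced {_OPENERS[tier]!r} opened at column {col}"
            )
    helices: list[Helix] = []
    for tier in sorted(tier_pairs):
        for h in helices_from_pairs(tier_pairs[tier]):
            h.pk_layer = tier
            helices.append(h)
    model = StructureModel(seq=seq, helices=helices)
    return name_elements(model)


def _assign_tiers(helices: list[Helix]) -> dict[int, int]:
    """Greedy lowest-available-tier assignment; returns helix index -> tier."""
    order = sorted(range(len(helices)), key=lambda k: helices[k].pairs[0][0])
    tiers: dict[int, int] = {}
    for k in order:
        t = 0
        while any(
            tiers.get(m) == t and helices_cross(helices[k], helices[m])
            for m in order
            if m in tiers
        ):
            t += 1
        tiers[k] = t
    return tiers


def write_dotbracket(model: StructureModel) -> str:
    """Serialize a model to layered dot-bracket (inverse of parse_dotbracket)."""
    n = len(model.seq)
    off = model.seq.numbering_offset
    chars = ["."] * n
    tiers = _assign_tiers(model.helices)
    if tiers and max(tiers.values()) >= len(_OPENERS):
        raise ValueError("too many crossing classes for the bracket alphabet")
    for k, h in enumerate(model.helices):
        t = tiers[k]
        for i, j in h.pairs:
            chars[i - off] = _OPENERS[t]
            chars[j - off] = _CLOSERS[t]
    return "".join(chars)


def _layers_valid(helices: list[Helix]) -> bool:
    for a in range(len(helices)):
        for b in range(a + 1, len(helices)):
            if helices[a].pk_layer == helices[b].pk_layer and helices_cross(
                helices[a], helices[b]
            ):
                return False
    return all(h.pk_layer >= 0 for h in helices)


def name_elements(model: StructureModel) -> StructureModel:
    """Name helices H1..Hn / PK1..PKm in 5'-to-3' order and label junctions.

    Helices with ``pk_layer`` 0 take H-names; crossing (layer > 0) helices
    take PK-names, both ordered by their 5'-most position. Multiway junctions
    among nested helices are labelled by degree, e.g. "3WJ". Pre-assigned
    layers are kept when geometrically consistent (same-layer helices never
    cross); otherwise layers are recomputed greedily.
    """
    helices = sorted(model.helices, key=lambda h: h.pairs[0][0])
    if not _layers_valid(helices):
        tiers = _assign_tiers(helices)
        for k, h in enumerate(helices):
            h.pk_layer = tiers[k]
    h_count = pk_count = 0
    for h in helices:
        if h.pk_layer == 0:
            h_count += 1
            h.name = f"H{h_count}"
        else:
            pk_count += 1
            h.name = f"PK{pk_count}"
    model.helices = helices
    model.junctions = _find_junctions(helices)
    return model


def _find_junctions(helices: list[Helix]) -> list[tuple[str, list[str]]]:
    nested = [h for h in helices if h.pk_layer == 0]
    junctions: list[tuple[str, list[str]]] = []
    counter: dict[int, int] = {}
    for h in nested:
        lo, hi = h.pairs[-1]  # innermost pair bounds the loop
        children = [
            c
            for c in nested
            if c is not h and lo < c.pairs[0][0] and c.pairs[0][1] < hi
        ]
        # immediate children only: not nested inside another child
        direct = [
            c
            for c in children
            if not any(
                d is not c and d.pairs[0][0] < c.pairs[0][0] and c.pairs[0][1] < d.pairs[0][1]
                for d in children
            )
        ]
        if len(direct) >= 2:
            deg = len(direct) + 1
            counter[deg] = counter.get(deg, 0) + 1
            junctions.append((f"{deg}WJ{counter[deg]}", [h.name] + [c.name for c in direct]))
    return junctions


# ---------------------------------------------------------------------------
# exports


def write_ct(model: StructureModel, title: str | None = None) -> str:
    """Connect-table export (1-based, standard 6-column CT)."""
    n = len(model.seq)
    off = model.seq.numbering_offset
    lines = [f"{n}\t{title or model.seq.id}"]
    for k in range(n):
        pos = off + k
        partner = model.partner_of(pos) or 0
        partner_idx = partner - off + 1 if partner else 0
        lines.append(
            f"{k + 1}\t{model.seq.residues[k]}\t{k}\t{k + 2 if k + 1 < n else 0}"
            f"\t{partner_idx}\t{pos}"
        )
    return "\n".join(lines) + "\n"


def write_bed6(model: StructureModel, chrom: str | None = None) -> str:
    """BED6 export of helix strands (0-based half-open on write)."""
    chrom = chrom or model.seq.id
    lines = []
    for h in model.helices:
        for strand_iv, suffix, strand in (
            (h.five_prime, "_5p", "+"),
            (h.three_prime, "_3p", "-"),
        ):
            lines.append(
                f"{chrom}\t{strand_iv.start - 1}\t{strand_iv.end}\t"
                f"{h.name}{suffix}\t{h.pk_layer}\t{strand}"
            )
    return "\n".join(lines) + ("\n" if lines else "")


# ---------------------------------------------------------------------------
# FASTA (thin wrappers over Biopython so coordinates/typing stay in-house)


def read_fasta(path) -> TranscriptSeq:
    from Bio import SeqIO

    rec = next(SeqIO.parse(str(path), "fasta"))
    return TranscriptSeq(id=rec.id, residues=str(rec.seq))


def write_fasta(seq: TranscriptSeq, path) -> None:
    with open(path, "w") as fh:
        fh.write(f">{seq.id}\n")
        for k in range(0, len(seq.residues), 60):
            fh.write(seq.residues[k : k + 60] + "\n")
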