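"""Helix conservation calls and covariation counting over homolog alignments.

Alignments are Stockholm files carrying a ``#=GC SS_cons`` consensus line;
the first row (or a named reference row) maps model coordinates to columns.
Presence thresholds are absolute homolog counts; identity and intactness
thresholds are fractions. A helix is "present" in a homolog when enough of
its base pairs remain canonical after gap removal and the local window
refolds to those pairs by MFE.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from Bio import AlignIO

from .core import CANONICAL_PAIRS, Helix
from .fold import fold

__all__ = [
    "HomologAlignment",
    "ConservationThresholds",
    "read_stockholm",
    "write_stockholm",
    "helix_presence",
    "helix_conserved",
    "presence_fraction",
    "count_covarying_pairs",
    "PairCovariation",
]


@dataclass(frozen=True)
class ConservationThresholds:
    """Defaults follow the all-homologs rule (43 of 53)."""

    min_presence: int = 43
    group_size: int = 53
    min_identity: float = 0.75
    min_intact: float = 0.90

    def __post_init__(self) -> None:
        if not (0 < self.min_identity <= 1 and 0 < self.min_intact <= 1):
            raise ValueError("fractions must be in (0, 1]")
        if self.min_presence > self.group_size:
            raise ValueError("min_presence exceeds group size")


@dataclass
class HomologAlignment:
    """Gapped homolog rows with the model mapped onto alignment columns."""

    ids: list[str]
    rows: list[str]  # gapped, uppercase, same length
    ss_cons: str = ""
    reference_id: str | None = None

    def __post_init__(self) -> None:
        if not self.rows:
            raise ValueError("empty alignment")
        width = len(self.rows[0])
        if any(len(r) != width for r in self.rows):
            raise ValueError("unequal row lengths")
        if self.ss_cons and len(self.ss_cons) != width:
            raise ValueError("SS_cons length mismatch")
        self.rows = [r.upper().replace("T", "U").replace(".", "-") for r in self.rows]
        if self.reference_id is None:
            self.reference_id = self.ids[0]
        self._ref_row = self.rows[self.ids.index(self.reference_id)]
        # model position (ungapped reference coordinate, 1-based) -> column (0-based)
        self._col_of: dict[int, int] = {}
        pos = 0
        for col, ch in enumerate(self._ref_row):
            if ch != "-":
                pos += 1
                self._col_of[pos] = col

    @property
    def width(self) -> int:
        return len(self.rows[0])

    @property
    def n_rows(self) -> int:
        return len(self.rows)

    def column_of(self, model_pos: int) -> int:
        try:
            return self._col_of[model_pos]
        except KeyError:
            raise ValueError(f"model position {model_pos} has no alignment column") from None

    def homolog_ids(self) -> list[str]:
        return [i for i in self.ids if i != self.reference_id]

    def row(self, rid: str) -> str:
        return self.rows[self.ids.index(rid)]


def read_stockholm(path, reference_id: str | None = None) -> HomologAlignment:
    aln = AlignIO.read(str(path), "stockholm")
    ss = aln.column_annotations.get("secondary_structure", "")
    return HomologAlignment(
        ids=[rec.id for rec in aln],
        rows=[str(rec.seq) for rec in aln],
        ss_cons=ss,
        reference_id=reference_id,
    )


def write_stockholm(alignment: HomologAlignment, path) -> None:
    name_w = max(len(i) for i in alignment.ids) + 2
    with open(path, "w") as fh:
        fh.write("# STOCKHOLM 1.0\n")
        for rid, row in zip(alignment.ids, alignment.rows):
            fh.write(f"{rid:<{name_w}}{row}\n")
        if alignment.ss_cons:
            fh.write(f"{'#=GC SS_cons':<{name_w}}{alignment.ss_cons}\n")
        fh.write("//\n")


def _is_canonical(a: str, b: str) -> bool:
    return (a, b) in CANONICAL_PAIRS


def helix_presence(
    helix: Helix,
    alignment: HomologAlignment,
    homolog_id: str,
    min_intact: float = 0.90,
    *,
    check_fold: bool = True,
) -> bool:
    """Is the helix present (intact and refoldable) in one homolog row?

    A pair survives when both of its columns are ungapped in the homolog and
    the bases form a canonical (WC or G-U) pair; presence additionally
    requires that an MFE fold of the homolog's local window recovers at
    least ``min_intact`` of those surviving pairs.
    """
    row = alignment.row(homolog_id)
    cols = [(alignment.column_of(i), alignment.column_of(j)) for i, j in helix.pairs]
    surviving = []
    for ci, cj in cols:
        a, b = row[ci], row[cj]
        if a != "-" and b != "-" and _is_canonical(a, b):
            surviving.append((ci, cj))
    if len(surviving) < min_intact * len(helix.pairs):
        return False
    if not check_fold:
        return True
    five_cols = sorted({ci for ci, _ in surviving})
    three_cols = sorted({cj for _, cj in surviving})
    gap_cols = three_cols[0] - five_cols[-1] - 1
    if gap_cols <= 60:
        # contiguous local window
        window_cols = [c for c in range(five_cols[0], three_cols[-1] + 1) if row[c] != "-"]
        window_seq = "".join(row[c] for c in window_cols)
        local_index = {c: k + 1 for k, c in enumerate(window_cols)}
        res = fold(window_seq)
    else:
        # long-range helix: co-fold the two strands across an unpairable linker
        window_cols = five_cols + three_cols
        left_seq = "".join(row[c] for c in five_cols)
        right_seq = "".join(row[c] for c in three_cols)
        n_left = len(left_seq)
        local_index = {c: k + 1 for k, c in enumerate(five_cols)}
        local_index.update({c: n_left + 3 + k + 1 for k, c in enumerate(three_cols)})
        res = fold(
            left_seq + "NNN" + right_seq,
            pair_filter=lambda i, j: i <= n_left and j > n_left + 3,
        )
    folded = set(res.pairs)
    recovered = sum(1 for ci, cj in surviving if (local_index[ci], local_index[cj]) in folded)
    return recovered >= min_intact * len(surviving)


def helix_conserved(
    helix: Helix,
    alignment: HomologAlignment,
    thresholds: ConservationThresholds = ConservationThresholds(),
    *,
    check_fold: bool = True,
) -> tuple[bool, dict]:
    """Conservation call: presence count and pooled column identity.

    Identity is pooled over the helix's paired columns across homolog rows
    (terminal-loop columns are never part of a helix record and so are
    excluded by construction); gap cells count as mismatches.
    """
    homologs = alignment.homolog_ids()
    present = sum(
        1
        for rid in homologs
        if helix_presence(helix, alignment, rid, thresholds.min_intact, check_fold=check_fold)
    )
    ref = alignment.rows[alignment.ids.index(alignment.reference_id)]
    cols = sorted({c for i, j in helix.pairs for c in (alignment.column_of(i), alignment.column_of(j))})
    match = total = 0
    for rid in homologs:
        row = alignment.row(rid)
        for c in cols:
            total += 1
            if row[c] == ref[c] and row[c] != "-":
                match += 1
    identity = match / total if total else 0.0
    conserved = present >= thresholds.min_presence and identity >= thresholds.min_identity
    return conserved, {
        "present": present,
        "n_homologs": len(homologs),
        "identity": identity,
        "n_pairs": len(helix.pairs),
    }


def presence_fraction(count: int, group_size: int) -> int:
    """Integer percentage round(100 * count / group_size)."""
    if group_size <= 0:
        raise ValueError("group_size must be positive")
    if not (0 <= count <= group_size):
        raise ValueError(f"count {count} outside [0, {group_size}]")
    return round(100 * count / group_size)


@dataclass
class PairCovariation:
    pair: tuple[int, int]
    realizations: set[tuple[str, str]] = field(default_factory=set)

    @property
    def covarying(self) -> bool:
        return len(self.realizations) >= 2

    @property
    def comutation_only(self) -> bool:
        """All realization differences change one side only (wobble shifts)."""
        if not self.covarying:
            return False
        reals = sorted(self.realizations)
        return all(
            sum(x != y for x, y in zip(a, b)) == 1
            for ai, a in enumerate(reals)
            for b in reals[ai + 1 :]
        )


def count_covarying_pairs(alignment: HomologAlignment, pairs) -> tuple[int, list[PairCovariation]]:
    """Count model base pairs realized by >= 2 distinct canonical pair types.

    Only rows where both columns are ungapped and canonical contribute; the
    reference row's realization counts too. Per-pair detail flags pure
    co-mutations (single-sided changes preserving pairing via wobble).
    """
    details: list[PairCovariation] = []
    for i, j in sorted(pairs):
        ci, cj = alignment.column_of(i), alignment.column_of(j)
        cov = PairCovariation(pair=(i, j))
        for row in alignment.rows:
            a, b = row[ci], row[cj]
            if a != "-" and b != "-" and _is_canonical(a, b):
                cov.realizations.add((a, b))
        details.append(cov)
    total = sum(1 for d in details if d.covarying)
    return total, details
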