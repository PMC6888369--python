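"""Minimum-free-energy folding contract.

Two backends:

* ``vienna`` — external Turner-parameter folder (ViennaRNA python bindings),
  used when importable and no pairing constraints are requested.
* ``builtin`` — exact dynamic program maximizing a base-pair score with a
  stacking bonus and a minimum hairpin loop of 3 nt (documented as an
  approximate energy model). Pair weights: G-C 3, A-U 2, G-U 1; each
  stacked pair adds 1. Reported energy is the negated score in kcal/mol.

The builtin backend supports arbitrary pair constraints (position masks and
pair filters), which the composite builder relies on; it is the default.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import Interval, StructureModel, TranscriptSeq, helices_from_pairs

__all__ = [
    "FoldResult",
    "PAIR_WEIGHTS",
    "STACK_BONUS",
    "MIN_HAIRPIN",
    "fold",
    "score_structure",
    "fold_uncovered_region",
]

PAIR_WEIGHTS = {
    ("G", "C"): 3.0,
    ("C", "G"): 3.0,
    ("A", "U"): 2.0,
    ("U", "A"): 2.0,
    ("G", "U"): 1.0,
    ("U", "G"): 1.0,
}
STACK_BONUS = 1.0
MIN_HAIRPIN = 3

_NEG = -1e18


@dataclass(frozen=True)
class FoldResult:
    """Non-crossing MFE structure over a folded window (1-based in-window)."""

    pairs: tuple[tuple[int, int], ...]
    energy: float
    backend: str
    length: int

    @property
    def dotbracket(self) -> str:
        chars = ["."] * self.length
        for i, j in self.pairs:
            chars[i - 1] = "("
            chars[j - 1] = ")"
        return "".join(chars)

    def paired_positions(self) -> set[int]:
        return {p for ij in self.pairs for p in ij}


def _check_seq(seq: str) -> str:
    seq = seq.upper().replace("T", "U")
    bad = set(seq) - set("ACGUN")
    if bad:
        raise ValueError(f"non-RNA characters: {sorted(bad)}")
    return seq


def score_structure(seq: str, pairs) -> float:
    """Score a structure under the builtin model (shared with tests' oracle users)."""
    seq = _check_seq(seq)
    total = 0.0
    pairset = set(pairs)
    for i, j in pairset:
        w = PAIR_WEIGHTS.get((seq[i - 1], seq[j - 1]))
        if w is None:
            raise ValueError(f"non-canonical pair ({i},{j})")
        total += w
        if (i + 1, j - 1) in pairset:
            total += STACK_BONUS
    return total


def fold(
    seq_window: str,
    *,
    backend: str = "builtin",
    allowed_positions: set[int] | None = None,
    pair_filter=None,
) -> FoldResult:
    """Fold one window; returns a non-crossing structure and its energy.

    ``allowed_positions``/``pair_filter`` restrict which (1-based, in-window)
    positions/pairs may form; constraints force the builtin backend.
    """
    seq = _check_seq(seq_window)
    n = len(seq)
    if not (1 <= n <= 10_000):
        raise ValueError(f"window length {n} outside [1, 10000]")
    constrained = allowed_positions is not None or pair_filter is not None
    if backend == "vienna" and not constrained:
        try:
            import RNA  # type: ignore

            db, mfe = RNA.fold(seq)
            pairs = _pairs_from_db(db)
            return FoldResult(pairs=tuple(sorted(pairs)), energy=round(mfe, 1), backend="vienna", length=n)
        except ImportError:
            pass  # fall back to builtin
    return _fold_builtin(seq, allowed_positions, pair_filter)


def _pairs_from_db(db: str) -> list[tuple[int, int]]:
    stack: list[int] = []
    pairs = []
    for k, ch in enumerate(db, start=1):
        if ch == "(":
            stack.append(k)
        elif ch == ")":
            pairs.append((stack.pop(), k))
    return pairs


def _fold_builtin(seq, allowed_positions, pair_filter) -> FoldResult:
    n = len(seq)
    W = np.zeros((n + 1, n + 1))  # pair weights, 0 where pairing is disallowed
    for i in range(1, n + 1):
        if allowed_positions is not None and i not in allowed_positions:
            continue
        for j in range(i + MIN_HAIRPIN + 1, n + 1):
            if allowed_positions is not None and j not in allowed_positions:
                continue
            w = PAIR_WEIGHTS.get((seq[i - 1], seq[j - 1]))
            if w is None:
                continue
            if pair_filter is not None and not pair_filter(i, j):
                continue
            W[i, j] = w

    M = np.zeros((n + 2, n + 2))  # best score on [i, j]
    P = np.full((n + 2, n + 2), _NEG)  # best score on [i, j] with (i, j) paired
    for span in range(MIN_HAIRPIN + 1, n):
        for i in range(1, n - span + 1):
            j = i + span
            if W[i, j] > 0:
                inner = M[i + 1, j - 1]
                if P[i + 1, j - 1] + STACK_BONUS > inner:
                    inner = P[i + 1, j - 1] + STACK_BONUS
                P[i, j] = W[i, j] + inner
            best = M[i, j - 1]
            ks = np.arange(i, j - MIN_HAIRPIN)
            if ks.size:
                cand = M[i, ks - 1] + P[ks, j]
                kbest = cand.max()
                if kbest > best:
                    best = kbest
            M[i, j] = best

    pairs: list[tuple[int, int]] = []
    _traceback(1, n, M, P, W, pairs)
    score = score_structure(seq, pairs)
    energy = -round(score, 1) if pairs else 0.0
    return FoldResult(pairs=tuple(sorted(pairs)), energy=energy, backend="builtin", length=n)


def _traceback(i, j, M, P, W, out, paired=False):
    # iterative on an explicit stack; frames are (i, j, via_pair)
    stack = [(i, j, paired)]
    while stack:
        i, j, via_pair = stack.pop()
        if j - i < MIN_HAIRPIN + 1:
            continue
        if via_pair:
            out.append((i, j))
            if P[i + 1, j - 1] + STACK_BONUS >= M[i + 1, j - 1] and P[i + 1, j - 1] > _NEG / 2:
                stack.append((i + 1, j - 1, True))
            else:
                stack.append((i + 1, j - 1, False))
            continue
        target = M[i, j]
        if target <= 0:
            continue
        if M[i, j - 1] == target:
            stack.append((i, j - 1, False))
            continue
        for k in range(i, j - MIN_HAIRPIN):
            if M[i, k - 1] + P[k, j] == target:
                if k > i:
                    stack.append((i, k - 1, False))
                stack.append((k, j, True))
                break


def fold_uncovered_region(
    seq: TranscriptSeq,
    region: Interval,
    *,
    window: int = 100,
    overlap: int = 20,
    backend: str = "builtin",
) -> StructureModel:
    """Scan-fold a region 5'->3' in fixed windows and merge predictions.

    Windows start at ``region.start`` and step ``window - overlap``; the last
    window is truncated at ``region.end``. A pair is kept iff it appears in
    every window that fully contains both partners; residual conflicts are
    resolved in favor of the more 5' window.
    """
    if window <= overlap:
        raise ValueError(f"window ({window}) must exceed overlap ({overlap})")
    if region.start < seq.start or region.end > seq.end:
        raise ValueError(f"region {region} outside transcript [{seq.start}, {seq.end}]")
    step = window - overlap
    windows: list[Interval] = []
    start = region.start
    while True:
        end = min(start + window - 1, region.end)
        windows.append(Interval(start, end))
        if end >= region.end:
            break
        start += step

    per_window_pairs: list[set[tuple[int, int]]] = []
    for w in windows:
        res = fold(seq.subseq(w), backend=backend)
        per_window_pairs.append({(i + w.start - 1, j + w.start - 1) for i, j in res.pairs})

    candidates = set().union(*per_window_pairs) if per_window_pairs else set()
    kept = []
    for i, j in sorted(candidates):
        containing = [k for k, w in enumerate(windows) if i in w and j in w]
        if all((i, j) in per_window_pairs[k] for k in containing):
            first = min(containing)
            kept.append((first, (i, j)))

    # conflict resolution: accept pairs window by window, 5' first; a pair
    # must neither reuse a position nor cross an already-accepted pair
    taken: set[int] = set()
    final: list[tuple[int, int]] = []
    for _, (i, j) in sorted(kept):
        if i in taken or j in taken:
            continue
        if any((a < i < b < j) or (i < a < j < b) for a, b in final):
            continue
        final.append((i, j))
        taken.update((i, j))

    helices = helices_from_pairs(final)
    state = {p: "unpaired" for p in region.positions()}
    for i, j in final:
        state[i] = state[j] = "paired"
    return StructureModel(seq=seq, helices=helices, per_nt_state=state)
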