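"""Ground-truth simulator.

Generates transcripts with planted nested helices, long-range duplexes
(bridging >= 100 intervening nt), and H-type pseudoknots; per-nucleotide
probing counts drawn from Poisson models whose means straddle the default
classification cutoffs; duplex tables across replicate datasets; homolog
alignments with compensatory substitutions inside helices; and annotation
fixtures. Deterministic under a fixed seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .annotate import Annotation
from .conservation import HomologAlignment, write_stockholm
from .core import (
    COMPLEMENT,
    Helix,
    Interval,
    StructureModel,
    TranscriptSeq,
    name_elements,
    write_dotbracket,
    write_fasta,
)
from .probing import DuplexGroup, ProbingTrack, write_duplexes, write_track

__all__ = ["SimConfig", "SimBundle", "generate", "truth_compare"]

_CANONICAL = [("G", "C"), ("C", "G"), ("A", "U"), ("U", "A")]


@dataclass(frozen=True)
class SimConfig:
    transcript_len: int = 1000
    n_helices: int = 15
    n_long_range: int = 2
    n_pk: int = 1
    helix_len: tuple[int, int] = (4, 10)
    loop_len: tuple[int, int] = (4, 8)
    seed: int = 0
    # Poisson count means; chosen so the default cutoffs (ratio 1, count 20)
    # separate the classes by ~5-fold
    s1_unpaired: float = 10.0
    s1_paired: float = 2.0
    v1_unpaired: float = 2.0
    v1_paired: float = 10.0
    dms_unpaired: float = 60.0
    dms_paired: float = 5.0
    paris_read_mean: float = 8.0
    n_false_duplexes: int = 2
    false_read_mean: float = 1.0
    n_datasets: int = 3
    coverage_fraction: float = 0.95
    duplex_jitter: int = 0
    # homolog alignment
    n_homologs: int = 53
    substitution_rate: float = 0.10
    p_cov: float = 1.0
    background_sub_rate: float = 0.10
    nonconserved_helix_rate: float = 0.3
    noise: bool = True

    def __post_init__(self) -> None:
        if self.transcript_len < 200:
            raise ValueError("transcript too short to plant structure")
        if self.helix_len[0] < 2 or self.helix_len[1] < self.helix_len[0]:
            raise ValueError("bad helix_len range")

    @classmethod
    def noise_free(cls, **overrides) -> "SimConfig":
        """A configuration whose counts separate classes with no overlap."""
        defaults = dict(
            s1_unpaired=50.0,
            s1_paired=0.0,
            v1_unpaired=0.0,
            v1_paired=50.0,
            dms_unpaired=100.0,
            dms_paired=0.0,
            coverage_fraction=1.0,
            n_false_duplexes=0,
            duplex_jitter=0,
            noise=False,
        )
        defaults.update(overrides)
        return cls(**defaults)


@dataclass
class SimBundle:
    config: SimConfig
    seq: TranscriptSeq
    truth_model: StructureModel
    track: list[ProbingTrack]
    duplexes: list[DuplexGroup]
    alignment: HomologAlignment
    annotations: list[Annotation]
    truth: dict = field(default_factory=dict)

    def write(self, outdir) -> dict[str, Path]:
        """Write every artifact as plain text; byte-identical per config."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "fasta": outdir / "transcript.fa",
            "dotbracket": outdir / "truth.db",
            "track": outdir / "track.tsv",
            "duplexes": outdir / "duplexes.tsv",
            "stockholm": outdir / "homologs.sto",
            "annotations": outdir / "annotations.tsv",
            "truth": outdir / "truth.json",
        }
        write_fasta(self.seq, paths["fasta"])
        with open(paths["dotbracket"], "w") as fh:
            fh.write(f">{self.seq.id}\n{self.seq.residues}\n")
            fh.write(write_dotbracket(self.truth_model) + "\n")
        write_track(self.track, paths["track"])
        write_duplexes(self.duplexes, paths["duplexes"])
        write_stockholm(self.alignment, paths["stockholm"])
        with open(paths["annotations"], "w") as fh:
            fh.write("kind\tstart\tend\tlabel\tpayload\n")
            for a in self.annotations:
                fh.write(f"{a.kind}\t{a.region.start}\t{a.region.end}\t{a.label}\t{a.payload}\n")
        with open(paths["truth"], "w") as fh:
            json.dump(self.truth, fh, indent=2, sort_keys=True)
            fh.write("\n")
        return paths


class _FreeSpace:
    """Bookkeeping of unassigned transcript segments."""

    def __init__(self, length: int):
        self.segments: list[tuple[int, int]] = [(1, length)]

    def take(self, rng, span: int, *, min_start: int = 1) -> Interval | None:
        candidates = [
            (k, s, e)
            for k, (s, e) in enumerate(self.segments)
            if e - max(s, min_start) + 1 >= span
        ]
        if not candidates:
            return None
        k, s, e = candidates[rng.integers(0, len(candidates))]
        lo = max(s, min_start)
        start = int(rng.integers(lo, e - span + 2))
        self.reserve(Interval(start, start + span - 1))
        return Interval(start, start + span - 1)

    def reserve(self, iv: Interval) -> None:
        out = []
        for s, e in self.segments:
            if iv.end < s or iv.start > e:
                out.append((s, e))
                continue
            if s < iv.start:
                out.append((s, iv.start - 1))
            if iv.end < e:
                out.append((iv.end + 1, e))
        self.segments = sorted(out)


def _stem_pairs(left: Interval, right: Interval) -> list[tuple[int, int]]:
    """Antiparallel registry between two equal-length spans."""
    n = len(left)
    assert len(right) == n
    return [(left.start + k, right.end - k) for k in range(n)]


def generate(config: SimConfig) -> SimBundle:
    """Sample a full synthetic bundle; raises on infeasible packing."""
    rng = np.random.default_rng(config.seed)
    L = config.transcript_len
    free = _FreeSpace(L)
    hmin, hmax = config.helix_len
    lmin, lmax = config.loop_len

    truth_pairs: list[tuple[int, int]] = []
    helices: list[Helix] = []
    paris_elements: list[tuple[Interval, Interval]] = []  # duplex-supported
    outer_pairs: list[tuple[int, int]] = []  # for crossing checks

    def crosses_existing(i: int, j: int, allow=None) -> bool:
        for a, b in outer_pairs:
            if (a, b) == allow:
                continue
            if (i < a < j < b) or (a < i < b < j):
                return True
        return False

    # --- long-range duplexes (PARIS-supported, >= 100 intervening nt)
    for _ in range(config.n_long_range):
        placed = False
        for _attempt in range(200):
            stem = int(rng.integers(max(hmin, 6), hmax + 1))
            left = free.take(rng, stem)
            if left is None:
                break
            right = free.take(rng, stem, min_start=left.end + 101)
            if right is None:
                free_undo = Interval(left.start, left.end)
                # give the span back and retry
                free.segments.append((free_undo.start, free_undo.end))
                free.segments.sort()
                continue
            if crosses_existing(left.start, right.end):
                # spans already consumed; accept the waste and retry elsewhere
                continue
            pairs = _stem_pairs(left, right)
            truth_pairs.extend(pairs)
            helices.append(Helix(pairs))
            outer_pairs.append((left.start, right.end))
            paris_elements.append((left, right))
            placed = True
            break
        if not placed:
            raise ValueError("infeasible packing: cannot place long-range duplexes")

    # --- pseudoknot hosts and crossing stems
    for _ in range(config.n_pk):
        placed = False
        for _attempt in range(200):
            pk_stem = int(rng.integers(max(3, hmin - 1), hmin + 1))
            host_stem = int(rng.integers(max(pk_stem, hmin), hmax + 1))
            host_loop = pk_stem + 6
            span = 2 * host_stem + host_loop
            host = free.take(rng, span)
            if host is None:
                break
            h_pairs = [(host.start + k, host.end - k) for k in range(host_stem)]
            loop_lo = host.start + host_stem
            pk_left = Interval(loop_lo + 2, loop_lo + 2 + pk_stem - 1)
            pk_right = free.take(rng, pk_stem, min_start=host.end + 5)
            if pk_right is None:
                continue
            if crosses_existing(pk_left.start, pk_right.end):
                continue
            pk_pairs = _stem_pairs(pk_left, pk_right)
            truth_pairs.extend(h_pairs)
            truth_pairs.extend(pk_pairs)
            helices.append(Helix(h_pairs))
            helices.append(Helix(pk_pairs))
            outer_pairs.append((host.start, host.end))
            outer_pairs.append((pk_left.start, pk_right.end))
            paris_elements.append((pk_left, pk_right))
            placed = True
            break
        if not placed:
            raise ValueError("infeasible packing: cannot place pseudoknots")

    # --- plain nested hairpins
    n_plain = config.n_helices - config.n_pk
    for _ in range(n_plain):
        stem = int(rng.integers(hmin, hmax + 1))
        loop = int(rng.integers(lmin, lmax + 1))
        span = 2 * stem + loop
        iv = free.take(rng, span)
        if iv is None:
            raise ValueError("infeasible packing: too many helices for transcript length")
        pairs = [(iv.start + k, iv.end - k) for k in range(stem)]
        truth_pairs.extend(pairs)
        helices.append(Helix(pairs))
        outer_pairs.append((iv.start, iv.end))

    # --- sequence: random, then complementarity written into every pair
    bases = np.array(list("ACGU"))
    residues = list(rng.choice(bases, size=L))
    for i, j in truth_pairs:
        residues[j - 1] = COMPLEMENT[residues[i - 1]]
    seq = TranscriptSeq(id=f"synthetic_{config.seed}", residues="".join(residues))

    paired_set = {p for ij in truth_pairs for p in ij}
    truth_model = name_elements(StructureModel(seq=seq, helices=helices))

    # --- probing track
    track: list[ProbingTrack] = []
    pars_ok = pars_tot = dms_ok = dms_tot = 0
    for pos in range(1, L + 1):
        if config.noise and rng.random() > config.coverage_fraction:
            continue
        paired = pos in paired_set
        if config.noise:
            s1 = float(rng.poisson(config.s1_paired if paired else config.s1_unpaired))
            v1 = float(rng.poisson(config.v1_paired if paired else config.v1_unpaired))
        else:
            s1 = config.s1_paired if paired else config.s1_unpaired
            v1 = config.v1_paired if paired else config.v1_unpaired
        base = seq.base(pos)
        if base in "AC":
            if config.noise:
                dms = float(rng.poisson(config.dms_paired if paired else config.dms_unpaired))
            else:
                dms = config.dms_paired if paired else config.dms_unpaired
        else:
            dms = None
        track.append(ProbingTrack(position=pos, base=base, s1=s1, v1=v1, dms=dms))
        # direct threshold bookkeeping at the default cutoffs
        if s1 > 0 or v1 > 0:
            ratio = s1 / (v1 if v1 > 0 else 0.5)
            call = "single" if ratio > 1 else ("double" if ratio < 1 else "und")
            pars_tot += 1
            pars_ok += int(call == ("double" if paired else "single"))
        if dms is not None:
            dcall = "unprotected" if dms > 20 else ("protected" if dms < 20 else "und")
            dms_tot += 1
            dms_ok += int(dcall == ("protected" if paired else "unprotected"))

    # --- duplex tables across datasets
    duplexes: list[DuplexGroup] = []
    for left, right in paris_elements:
        for d in range(config.n_datasets):
            if config.noise:
                reads = int(rng.poisson(config.paris_read_mean))
            else:
                reads = int(config.paris_read_mean)
            if reads < 1:
                continue
            jl = jr = 0
            if config.duplex_jitter:
                jl = int(rng.integers(-config.duplex_jitter, config.duplex_jitter + 1))
                jr = int(rng.integers(-config.duplex_jitter, config.duplex_jitter + 1))
            duplexes.append(
                DuplexGroup(
                    dataset_id=f"DS{d + 1}",
                    left=Interval(max(1, left.start + jl), left.end + jl),
                    right=Interval(right.start + jr, min(L, right.end + jr)),
                    reads=reads,
                )
            )
    for _ in range(config.n_false_duplexes):
        a = int(rng.integers(1, L - 200))
        b = a + int(rng.integers(8, 15))
        c = b + int(rng.integers(30, 120))
        d_end = c + int(rng.integers(8, 15))
        if d_end >= L:
            continue
        reads = max(1, int(rng.poisson(config.false_read_mean)))
        ds = f"DS{int(rng.integers(1, config.n_datasets + 1))}"
        duplexes.append(
            DuplexGroup(dataset_id=ds, left=Interval(a, b), right=Interval(c, d_end), reads=reads)
        )

    # --- homolog alignment with planted conservation pattern
    alignment, conserved_names = _make_alignment(rng, config, seq, truth_model)

    # --- annotations
    annotations = _make_annotations(truth_model, paris_elements)

    truth = {
        "pairs": sorted(truth_pairs),
        "paired_positions": sorted(paired_set),
        "n_helices_nested": sum(1 for h in truth_model.helices if h.pk_layer == 0),
        "n_pk": sum(1 for h in truth_model.helices if h.pk_layer > 0),
        "paris_spans": [
            [left.start, left.end, right.start, right.end] for left, right in paris_elements
        ],
        "pars_concordance": pars_ok / pars_tot if pars_tot else 0.0,
        "dms_concordance": dms_ok / dms_tot if dms_tot else 0.0,
        "conserved_helices": sorted(conserved_names),
        "helix_names": [h.name for h in truth_model.helices],
    }
    return SimBundle(
        config=config,
        seq=seq,
        truth_model=truth_model,
        track=track,
        duplexes=duplexes,
        alignment=alignment,
        annotations=annotations,
        truth=truth,
    )


def _make_alignment(rng, config: SimConfig, seq: TranscriptSeq, truth_model: StructureModel):
    L = len(seq)
    conserved: dict[str, bool] = {}
    for h in truth_model.helices:
        conserved[h.name] = bool(rng.random() >= config.nonconserved_helix_rate)
    # rows in which each non-conserved helix is deleted (half of them)
    deletion_rows: dict[str, set[int]] = {}
    for h in truth_model.helices:
        if not conserved[h.name]:
            rows = rng.permutation(config.n_homologs)[: (config.n_homologs + 1) // 2]
            deletion_rows[h.name] = set(int(r) for r in rows)

    paired_cols = {p for ij in truth_model.pairs for p in ij}
    ids = [seq.id]
    rows = [seq.residues]
    for r in range(config.n_homologs):
        row = list(seq.residues)
        for h in truth_model.helices:
            if not conserved[h.name]:
                if r in deletion_rows[h.name]:
                    for i, j in h.pairs:
                        row[i - 1] = "-"
                        row[j - 1] = "-"
                continue
            for i, j in h.pairs:
                if rng.random() < config.substitution_rate:
                    if rng.random() < config.p_cov:
                        cur = (row[i - 1], row[j - 1])
                        options = [p for p in _CANONICAL if p != cur]
                        a, b = options[rng.integers(0, len(options))]
                        row[i - 1], row[j - 1] = a, b
                    else:
                        # break one side
                        cur = row[i - 1]
                        row[i - 1] = {"A": "C", "C": "A", "G": "A", "U": "C"}[cur]
        for pos in range(1, L + 1):
            if pos not in paired_cols and rng.random() < config.background_sub_rate:
                others = [b for b in "ACGU" if b != row[pos - 1] and row[pos - 1] != "-"]
                if others:
                    row[pos - 1] = others[rng.integers(0, len(others))]
        ids.append(f"hom{r + 1:02d}")
        rows.append("".join(row))
    ss_cons = write_dotbracket(truth_model)
    alignment = HomologAlignment(ids=ids, rows=rows, ss_cons=ss_cons, reference_id=seq.id)
    return alignment, [n for n, c in conserved.items() if c]


def _make_annotations(truth_model: StructureModel, paris_elements) -> list[Annotation]:
    annotations: list[Annotation] = []
    # a binding site in the terminal loop of the first plain hairpin
    for h in truth_model.helices:
        if h.pk_layer != 0:
            continue
        lo, hi = h.pairs[-1]
        if hi - lo - 1 >= 4 and not any(
            lo < o.pairs[0][0] < hi for o in truth_model.helices if o is not h
        ):
            annotations.append(
                Annotation(
                    kind="mirna_site",
                    region=Interval(lo + 1, hi - 1),
                    label=f"loop_site_{h.name}",
                )
            )
            break
    # a site inside a helix stem
    for h in truth_model.helices:
        if h.pk_layer == 0 and len(h.pairs) >= 4:
            annotations.append(
                Annotation(
                    kind="protein_site",
                    region=h.five_prime,
                    label=f"stem_site_{h.name}",
                )
            )
            break
    # a modification on the left span of the first duplex-supported element
    if paris_elements:
        left, _right = paris_elements[0]
        annotations.append(
            Annotation(
                kind="modification",
                region=Interval(left.start, left.start),
                label="m6A_site",
                payload="m6A",
            )
        )
    return annotations


def truth_compare(model: StructureModel, truth: dict) -> dict:
    """Recovery metrics of a model against generator bookkeeping.

    Base-level sensitivity/PPV/accuracy on paired states plus helix-level
    recall (a helix counts as recovered when >= 90% of its pairs appear).
    """
    truth_pairs = {tuple(p) for p in truth["pairs"]}
    truth_paired = set(truth["paired_positions"])
    model_pairs = set(model.pairs)
    model_paired = {p for ij in model_pairs for p in ij}
    tp = len(model_paired & truth_paired)
    sens = tp / len(truth_paired) if truth_paired else 1.0
    ppv = tp / len(model_paired) if model_paired else 0.0
    all_pos = range(model.seq.start, model.seq.end + 1)
    acc = sum(
        1 for p in all_pos if (p in model_paired) == (p in truth_paired)
    ) / len(model.seq)
    # helix-level recall over truth helices (reconstructed from pair runs)
    helix_groups: list[list[tuple[int, int]]] = []
    run: list[tuple[int, int]] = []
    for i, j in sorted(truth_pairs):
        if run and i == run[-1][0] + 1 and j == run[-1][1] - 1:
            run.append((i, j))
        else:
            if run:
                helix_groups.append(run)
            run = [(i, j)]
    if run:
        helix_groups.append(run)
    recovered = sum(
        1
        for grp in helix_groups
        if sum(1 for p in grp if p in model_pairs) >= 0.9 * len(grp)
    )
    return {
        "sensitivity": sens,
        "ppv": ppv,
        "accuracy": acc,
        "pair_f1": (
            2 * len(model_pairs & truth_pairs) / (len(model_pairs) + len(truth_pairs))
            if model_pairs or truth_pairs
            else 1.0
        ),
        "helix_recall": recovered / len(helix_groups) if helix_groups else 1.0,
        "n_truth_helices": len(helix_groups),
        "n_model_helices": len(model.helices),
    }
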