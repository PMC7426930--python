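"""Per-species multiple alignment, frame-aware gap resolution, end trimming.

The internal aligner is deterministic center-star: the longest sequence is
the center, every other sequence is aligned to it semi-globally, and rows are
merged on center coordinates.  Downstream, gap runs that would break the
reading frame of a protein-coding locus (length not divisible by 3) are
filled from the column consensus where the column is uniform and replaced by
'N' where it is not; in-frame (codon-length) indels are left alone, as are
terminal gaps.  Ambiguity runs at row ends become terminal gaps.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Optional, Sequence

from ._scoring import AlignScoring, PairwiseEngine
from .refmap import MappedSeq

ACGT = frozenset("ACGT")
GAP = "-"


@dataclass
class SpeciesAlignment:
    """Gap-resolved multiple alignment of conspecific sequences.

    ``frame_offset`` is the column index (0-2) of the first codon position
    relative to the reference reading frame, taken from the center row's
    placement on the reference.
    """

    species: str
    rows: list[tuple[str, str]]
    frame_offset: int = 0

    @property
    def length(self) -> int:
        return len(self.rows[0][1]) if self.rows else 0

    @property
    def labels(self) -> list[str]:
        return [label for label, _ in self.rows]

    def __post_init__(self):
        lengths = {len(seq) for _, seq in self.rows}
        if len(lengths) > 1:
            raise ValueError("alignment rows have unequal lengths")


def _pairwise_pieces(
    engine: PairwiseEngine, center: str, query: str
) -> tuple[dict[int, str], dict[int, str]]:
    """Align ``query`` to ``center``; return (chars at center positions,
    insertions keyed by the center position they follow; -1 = before start).

    Query characters trimmed into free end gaps by the optimizer are kept as
    terminal insertions so no residue is lost in the merged alignment.
    """
    at: dict[int, str] = {}
    ins: dict[int, str] = {}
    offset = engine.best_diagonal(center, query)
    dp_score = engine.score(center, query)
    if offset is not None:
        hit = engine.gapless_overlap(center, query, offset)
        if hit is not None and hit.score == dp_score:
            # full-overlap gapless optimum: place by diagonal directly
            for c in range(hit.ref_start, hit.ref_end):
                at[c] = query[c + offset]
            if hit.query_start > 0:
                ins[-1] = query[: hit.query_start]
            if hit.query_end < len(query):
                ins[len(center) - 1] = query[hit.query_end :]
            return at, ins
    aln = engine.align(center, query)
    t_blocks, q_blocks = aln.aligned
    if len(t_blocks) == 0:
        ins[-1] = query
        return at, ins
    prev_t = int(t_blocks[0][0])
    prev_q = int(q_blocks[0][0])
    if prev_q > 0:
        ins[-1] = query[:prev_q]
    for (t0, t1), (q0, q1) in zip(
        (tuple(map(int, b)) for b in t_blocks),
        (tuple(map(int, b)) for b in q_blocks),
    ):
        if q0 > prev_q:
            # insertion in query between center positions prev_t-1 and t0
            ins[prev_t - 1] = ins.get(prev_t - 1, "") + query[prev_q:q0]
        for c, q in zip(range(t0, t1), range(q0, q1)):
            at[c] = query[q]
        prev_t, prev_q = t1, q1
    if prev_q < len(query):
        ins[prev_t - 1] = ins.get(prev_t - 1, "") + query[prev_q:]
    return at, ins


def align_sequences(
    pairs: Sequence[tuple[str, str]],
    scoring: Optional[AlignScoring] = None,
    engine: Optional[PairwiseEngine] = None,
) -> list[tuple[str, str]]:
    """Deterministic center-star MSA of labeled sequences.

    Center = longest sequence (ties: first in input order); all others are
    aligned to it semi-globally and merged on center coordinates.  Row order
    is input order.
    """
    if not pairs:
        return []
    if len(pairs) == 1:
        return [pairs[0]]
    engine = engine or PairwiseEngine(scoring)
    if engine.mode != "semiglobal":
        raise ValueError("align_sequences requires a semiglobal engine")
    center_idx = max(range(len(pairs)), key=lambda i: (len(pairs[i][1]), -i))
    center = pairs[center_idx][1]
    pieces: list[tuple[dict[int, str], dict[int, str]]] = []
    max_ins: dict[int, int] = {}
    for i, (_, seq) in enumerate(pairs):
        if i == center_idx:
            pieces.append(({c: ch for c, ch in enumerate(center)}, {}))
            continue
        at, ins = _pairwise_pieces(engine, center, seq)
        pieces.append((at, ins))
        for slot, chars in ins.items():
            max_ins[slot] = max(max_ins.get(slot, 0), len(chars))
    rows: list[tuple[str, str]] = []
    for (label, _), (at, ins) in zip(pairs, pieces):
        chunks: list[str] = []
        lead = ins.get(-1, "")
        chunks.append(lead.rjust(max_ins.get(-1, 0), GAP))
        for c in range(len(center)):
            chunks.append(at.get(c, GAP))
            w = max_ins.get(c, 0)
            if w:
                chunks.append(ins.get(c, "").ljust(w, GAP))
        rows.append((label, "".join(chunks)))
    return rows


def align_species(
    mapped: Sequence[MappedSeq],
    scoring: Optional[AlignScoring] = None,
    engine: Optional[PairwiseEngine] = None,
) -> SpeciesAlignment:
    """Center-star alignment of all conspecific mapped sequences."""
    if not mapped:
        raise ValueError("align_species requires at least one sequence")
    species = {m.species_key for m in mapped}
    if len(species) > 1:
        raise ValueError(f"mixed species in align_species: {sorted(species)}")
    # reverse-mapped records already carry forward-strand oriented_seq
    if any(m.orientation not in ("forward", "reverse") for m in mapped):
        raise ValueError("align_species requires successfully oriented sequences")
    pairs = [(m.label, m.oriented_seq) for m in mapped]
    rows = align_sequences(pairs, scoring=scoring, engine=engine)
    center = max(range(len(mapped)), key=lambda i: (len(mapped[i].oriented_seq), -i))
    frame_offset = (-mapped[center].ref_start) % 3
    return SpeciesAlignment(
        species=species.pop(), rows=rows, frame_offset=frame_offset
    )


def _internal_gap_runs(seq: str) -> list[tuple[int, int]]:
    """Maximal internal gap runs as [start, end); terminal runs excluded."""
    first = next((i for i, ch in enumerate(seq) if ch != GAP), None)
    if first is None:
        return []
    last = len(seq) - next(i for i, ch in enumerate(reversed(seq)) if ch != GAP)
    runs = []
    i = first
    while i < last:
        if seq[i] == GAP:
            j = i
            while j < last and seq[j] == GAP:
                j += 1
            runs.append((i, j))
            i = j
        else:
            i += 1
    return runs


def resolve_gaps(aln: SpeciesAlignment, strict_three: bool = False) -> SpeciesAlignment:
    """Fill or N-out frame-breaking internal gap runs.

    For every maximal internal gap run whose length is not divisible by 3
    (with ``strict_three`` instead: not exactly 3), each gapped position is
    replaced by the column consensus base when all other rows' non-gap
    characters at that column agree, and by 'N' when they disagree or the
    column is otherwise empty.  In-frame runs and terminal gaps are left
    untouched.  Idempotent; never alters a non-gap character.
    """
    if not aln.rows:
        return aln
    original = [seq for _, seq in aln.rows]
    ncols = aln.length
    new_rows: list[tuple[str, str]] = []
    for r, (label, seq) in enumerate(aln.rows):
        cells = list(seq)
        for start, end in _internal_gap_runs(seq):
            run_len = end - start
            frame_breaking = (run_len != 3) if strict_three else (run_len % 3 != 0)
            if not frame_breaking:
                continue
            for col in range(start, end):
                others = {
                    original[other][col]
                    for other in range(len(original))
                    if other != r and original[other][col] != GAP
                }
                cells[col] = others.pop() if len(others) == 1 else "N"
        new_rows.append((label, "".join(cells)))
    assert all(len(s) == ncols for _, s in new_rows)
    return replace(aln, rows=new_rows)


def trim_ambiguous_ends(aln: SpeciesAlignment) -> SpeciesAlignment:
    """Convert leading/trailing ambiguity runs (non-ACGT) to terminal gaps.

    Gaps already present at the ends are skipped over, internal ambiguities
    are untouched, and the column count is unchanged.
    """
    new_rows: list[tuple[str, str]] = []
    for label, seq in aln.rows:
        cells = list(seq)
        i = 0
        while i < len(cells) and cells[i] not in ACGT:
            if cells[i] != GAP:
                cells[i] = GAP
            i += 1
        j = len(cells) - 1
        while j >= i and cells[j] not in ACGT:
            if cells[j] != GAP:
                cells[j] = GAP
            j -= 1
        new_rows.append((label, "".join(cells)))
    return replace(aln, rows=new_rows)


def write_alignment_fasta(aln: SpeciesAlignment, path: str | Path) -> None:
    with open(path, "w") as fh:
        for label, seq in aln.rows:
            fh.write(f">{label}\n")
            for i in range(0, len(seq), 60):
                fh.write(seq[i : i + 60] + "\n")


def read_alignment_fasta(path: str | Path, species: str = "") -> SpeciesAlignment:
    from Bio import SeqIO

    rows = [(e.id, str(e.seq).upper()) for e in SeqIO.parse(str(path), "fasta")]
    return SpeciesAlignment(species=species, rows=rows)
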