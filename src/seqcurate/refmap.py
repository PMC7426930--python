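"""Reference-guided orientation detection and locus extraction.

Each record is aligned semi-globally against the reference locus in both
orientations; the higher-scoring strand wins, backward submissions are
reverse-complemented, and the aligned span on the reference is extracted.
Inputs much longer than the locus (e.g. whole mitogenomes) are pre-screened
with a k-mer seed step to locate the candidate window before dynamic
programming; the windowed result equals full DP on that window.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional, Sequence

from Bio import SeqIO

from ._scoring import (
    AlignScoring,
    GaplessHit,
    PairwiseEngine,
    reverse_complement,
    sanitize,
)
from .records import Record

FORWARD = "forward"
REVERSE = "reverse"
UNDETERMINED = "undetermined"


@dataclass(frozen=True)
class ReferenceLocus:
    """The target locus used to orient and trim every record."""

    accession: str
    seq: str

    def __post_init__(self):
        object.__setattr__(self, "seq", sanitize(self.seq))
        if not self.seq:
            raise ValueError("reference locus is empty")

    def __len__(self) -> int:
        return len(self.seq)

    @classmethod
    def from_fasta(cls, path: str | Path) -> "ReferenceLocus":
        entries = list(SeqIO.parse(str(path), "fasta"))
        if len(entries) != 1:
            raise ValueError(f"reference FASTA must hold exactly one record: {path}")
        return cls(accession=entries[0].id, seq=str(entries[0].seq))


@dataclass
class MappedSeq:
    """A record oriented and placed on the reference.

    ``ref_row`` holds, for every reference position in ``[ref_start,
    ref_end)``, the forward-strand query character aligned there ('-' for a
    deletion in the query; query insertions relative to the reference are
    dropped from the row but retained in ``oriented_seq``).
    """

    record: Record
    orientation: str
    ref_start: int = 0
    ref_end: int = 0
    oriented_seq: str = ""
    ref_row: str = ""
    score_fwd: float = 0.0
    score_rev: float = 0.0
    identity: float = 0.0
    source: str = "locus"
    failure: Optional[str] = None

    @property
    def label(self) -> str:
        return self.record.label

    @property
    def species_key(self) -> str:
        return self.record.name.species_key

    def projected(self, ref_length: int) -> str:
        """Length-L reference-coordinate projection, gap-padded outside the span."""
        return (
            "-" * self.ref_start
            + self.ref_row
            + "-" * (ref_length - self.ref_end)
        )


class RefMapper:
    """Orients records against a reference locus and extracts the mapped span.

    Parameters
    ----------
    reference:
        The target locus.
    scoring:
        Semi-global alignment scores (defaults: match +1, mismatch -1, gap of
        length k costs 4 + k, free end gaps, ambiguity codes neutral).
    min_length:
        Records (or aligned spans) shorter than this are not mappable.
    min_identity:
        Identity floor over the aligned reference span; below it the mapping
        is rejected ("mapping_failure").
    long_factor:
        Inputs longer than ``long_factor * len(reference)`` are treated as
        genome-scale and pre-screened with the k-mer seed step.
    """

    def __init__(
        self,
        reference: ReferenceLocus,
        scoring: Optional[AlignScoring] = None,
        min_length: int = 100,
        min_identity: float = 0.5,
        kmer: int = 12,
        long_factor: float = 2.0,
        window_pad: int = 200,
    ):
        self.reference = reference
        # local mode: unalignable flanks (vector padding, genome context
        # beyond the locus) are shaved from both sequences
        self.engine = PairwiseEngine(scoring, kmer=kmer, mode="local")
        self.min_length = min_length
        self.min_identity = min_identity
        self.long_factor = long_factor
        self.window_pad = window_pad

    # ------------------------------------------------------------------

    def _candidate_window(self, seq: str) -> tuple[str, int]:
        """Window of a genome-scale sequence likely to contain the locus."""
        L = len(self.reference)
        offset = self.engine.best_diagonal(self.reference.seq, seq)
        if offset is None:
            return seq, 0
        start = max(0, offset - self.window_pad)
        end = min(len(seq), offset + L + self.window_pad)
        return seq[start:end], start

    def _strand_view(self, seq: str) -> tuple[str, int, float]:
        """(window, window offset, semi-global score) for one strand."""
        if len(seq) > self.long_factor * len(self.reference):
            window, off = self._candidate_window(seq)
        else:
            window, off = seq, 0
        return window, off, self.engine.score(self.reference.seq, window)

    def _place(self, window: str, dp_score: float) -> tuple[int, int, str, str, float]:
        """Coordinates, oriented fragment, reference row and identity.

        Uses the exact gapless shortcut when its score matches the DP
        optimum; falls back to the full alignment path otherwise.
        """
        ref = self.reference.seq
        offset = self.engine.best_diagonal(ref, window)
        if offset is not None:
            hit = self.engine.gapless_hit(ref, window, offset)
            if hit is not None and hit.score == dp_score:
                frag = window[hit.query_start : hit.query_end]
                matches = sum(
                    1
                    for a, b in zip(ref[hit.ref_start : hit.ref_end], frag)
                    if a == b and a in "ACGT"
                )
                span = hit.ref_end - hit.ref_start
                identity = matches / span if span else 0.0
                return hit.ref_start, hit.ref_end, frag, frag, identity
        aln = self.engine.align(ref, window)
        t_blocks, q_blocks = aln.aligned
        if len(t_blocks) == 0:
            return 0, 0, "", "", 0.0
        ref_start = int(t_blocks[0][0])
        ref_end = int(t_blocks[-1][1])
        q_start = int(q_blocks[0][0])
        q_end = int(q_blocks[-1][1])
        row = []
        matches = 0
        prev_t = ref_start
        for (t0, t1), (q0, q1) in zip(t_blocks, q_blocks):
            row.append("-" * (t0 - prev_t))
            seg_r = ref[t0:t1]
            seg_q = window[q0:q1]
            row.append(seg_q)
            matches += sum(1 for a, b in zip(seg_r, seg_q) if a == b and a in "ACGT")
            prev_t = t1
        ref_row = "".join(row)
        span = ref_end - ref_start
        identity = matches / span if span else 0.0
        return ref_start, ref_end, window[q_start:q_end], ref_row, identity

    # ------------------------------------------------------------------

    def orient(self, record: Record) -> MappedSeq:
        """Decide strand and place the record on the reference.

        Ties between strand scores, identities below the floor, and aligned
        spans shorter than ``min_length`` yield orientation "undetermined"
        with the failure reason set.
        """
        seq = sanitize(record.seq)
        if len(seq) < self.min_length:
            return MappedSeq(
                record=record, orientation=UNDETERMINED, failure="too_short"
            )
        fwd_window, fwd_off, score_fwd = self._strand_view(seq)
        rev_seq = reverse_complement(seq)
        rev_window, rev_off, score_rev = self._strand_view(rev_seq)
        if score_fwd == score_rev:
            return MappedSeq(
                record=record,
                orientation=UNDETERMINED,
                score_fwd=score_fwd,
                score_rev=score_rev,
                failure="mapping_failure",
            )
        orientation = FORWARD if score_fwd > score_rev else REVERSE
        window = fwd_window if orientation == FORWARD else rev_window
        ref_start, ref_end, frag, ref_row, identity = self._place(
            window, max(score_fwd, score_rev)
        )
        mapped = MappedSeq(
            record=record,
            orientation=orientation,
            ref_start=ref_start,
            ref_end=ref_end,
            oriented_seq=frag,
            ref_row=ref_row,
            score_fwd=score_fwd,
            score_rev=score_rev,
            identity=identity,
            source="mitogenome"
            if len(seq) > self.long_factor * len(self.reference)
            else "locus",
        )
        if ref_end - ref_start < self.min_length or identity < self.min_identity:
            mapped.orientation = UNDETERMINED
            mapped.failure = "mapping_failure"
        return mapped

    def extract_locus(self, record: Record) -> MappedSeq:
        """Orient the record and trim it to the aligned span on the reference."""
        return self.orient(record)

    def map_records(
        self, records: Sequence[Record]
    ) -> tuple[list[MappedSeq], list[tuple[str, str]]]:
        """Map every record; returns (mapped, failures as (accession, reason))."""
        mapped: list[MappedSeq] = []
        failures: list[tuple[str, str]] = []
        for rec in records:
            m = self.orient(rec)
            if m.failure is None:
                mapped.append(m)
            else:
                failures.append((rec.accession, m.failure))
        return mapped, failures


def write_mapping_table(mapped: Iterable[MappedSeq], path: str | Path) -> None:
    """TSV of (accession, orientation, ref_start, ref_end, identity, ref_row)."""
    with open(path, "w") as fh:
        fh.write("accession\tspecies\torientation\tref_start\tref_end\tidentity\tref_row\n")
        for m in mapped:
            fh.write(
                f"{m.record.accession}\t{m.species_key}\t{m.orientation}\t"
                f"{m.ref_start}\t{m.ref_end}\t{m.identity:.4f}\t{m.ref_row}\n"
            )


def write_oriented_fasta(mapped: Iterable[MappedSeq], path: str | Path) -> None:
    with open(path, "w") as fh:
        for m in mapped:
            label = (
                m.record.label
                if m.record.name.is_binomial
                else f"{m.record.name.genus}_{m.record.accession}"
            )
            fh.write(f">{label}\n")
            for i in range(0, len(m.oriented_seq), 60):
                fh.write(m.oriented_seq[i : i + 60] + "\n")
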