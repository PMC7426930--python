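"""Pairwise alignment engine shared by reference mapping and MSA.

Semi-global (free end-gap) affine alignment over the IUPAC nucleotide
alphabet.  The heavy lifting is done by :class:`Bio.Align.PairwiseAligner`;
a gapless fast path (k-mer diagonal vote followed by a maximum-sum subarray
scan along the best diagonal) is used whenever its score provably equals the
full dynamic-programming optimum, which is the common case for records
without indels.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices

IUPAC_ALPHABET = "ACGTRYSWKMBDHVN"
_ACGT = frozenset(b"ACGT")

_COMPLEMENT = str.maketrans(
    "ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN"
)

_SANITIZE = {ord(c): c for c in IUPAC_ALPHABET}
_SANITIZE.update({ord(c.lower()): c for c in IUPAC_ALPHABET})
_SANITIZE[ord("U")] = "T"
_SANITIZE[ord("u")] = "T"


def sanitize(seq: str) -> str:
    """Uppercase, map U->T, strip gaps/whitespace, anything unknown -> N."""
    out = []
    for ch in seq:
        if ch in "-. \t\r\n":
            continue
        out.append(_SANITIZE.get(ord(ch), "N"))
    return "".join(out)


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class AlignScoring:
    """Scoring for semi-global mapping and alignment.

    A gap of length ``k`` costs ``gap_open + k * gap_extend``; terminal gaps
    are free.  IUPAC ambiguity codes are scored 0 against any character so
    that legitimate ambiguity calls are never penalized.
    """

    match: float = 1.0
    mismatch: float = -1.0
    gap_open: float = 4.0
    gap_extend: float = 1.0

    def substitution_matrix(self) -> substitution_matrices.Array:
        mat = substitution_matrices.Array(alphabet=IUPAC_ALPHABET, dims=2)
        for a in IUPAC_ALPHABET:
            for b in IUPAC_ALPHABET:
                if a in "ACGT" and b in "ACGT":
                    mat[a, b] = self.match if a == b else self.mismatch
                else:
                    mat[a, b] = 0.0
        return mat

    def build_aligner(self, mode: str = "semiglobal") -> Align.PairwiseAligner:
        """``semiglobal``: global with free end gaps (MSA use).  ``local``:
        Smith-Waterman (mapping use, where unalignable flanks such as vector
        padding must be shaved off both sequences)."""
        aligner = Align.PairwiseAligner()
        aligner.substitution_matrix = self.substitution_matrix()
        aligner.open_gap_score = -(self.gap_open + self.gap_extend)
        aligner.extend_gap_score = -self.gap_extend
        if mode == "local":
            aligner.mode = "local"
        elif mode == "semiglobal":
            aligner.mode = "global"
            # free end gaps on both sequences
            aligner.end_insertion_score = 0.0
            aligner.end_deletion_score = 0.0
        else:
            raise ValueError(f"unknown alignment mode: {mode!r}")
        return aligner


@dataclass
class GaplessHit:
    """Optimal gapless semi-global alignment along one diagonal."""

    score: float
    ref_start: int
    ref_end: int
    query_start: int
    query_end: int


class PairwiseEngine:
    """Reusable aligner bound to one scoring scheme."""

    def __init__(
        self,
        scoring: Optional[AlignScoring] = None,
        kmer: int = 12,
        mode: str = "semiglobal",
    ):
        self.scoring = scoring or AlignScoring()
        self.kmer = kmer
        self.mode = mode
        self._aligner = self.scoring.build_aligner(mode)
        self._index_key: Optional[str] = None
        self._index: dict[str, list[int]] = {}

    def score(self, ref: str, query: str) -> float:
        return float(self._aligner.score(ref, query))

    def align(self, ref: str, query: str) -> Align.Alignment:
        return self._aligner.align(ref, query)[0]

    # -- gapless fast path ---------------------------------------------------

    def best_diagonal(self, ref: str, query: str) -> Optional[int]:
        """Most-supported diagonal offset o (query index - ref index).

        Exact k-mer matches vote for their diagonal; returns None when no
        k-mer is shared (the DP fallback then decides).
        """
        k = self.kmer
        if len(ref) < k or len(query) < k:
            return None
        if ref is not self._index_key and ref != self._index_key:
            index: dict[str, list[int]] = {}
            for r in range(len(ref) - k + 1):
                index.setdefault(ref[r : r + k], []).append(r)
            self._index_key, self._index = ref, index
        index = self._index
        votes: dict[int, int] = {}
        for q in range(len(query) - k + 1):
            for r in index.get(query[q : q + k], ()):
                o = q - r
                votes[o] = votes.get(o, 0) + 1
        if not votes:
            return None
        # max votes, ties to the smallest offset for determinism
        return min(votes, key=lambda o: (-votes[o], o))

    def _diagonal_sites(self, ref: str, query: str, offset: int):
        r_lo = max(0, -offset)
        r_hi = min(len(ref), len(query) - offset)
        if r_hi - r_lo <= 0:
            return None, None, None
        ra = np.frombuffer(ref[r_lo:r_hi].encode(), dtype=np.uint8)
        qa = np.frombuffer(
            query[r_lo + offset : r_hi + offset].encode(), dtype=np.uint8
        )
        plain_r = np.isin(ra, np.frombuffer(b"ACGT", dtype=np.uint8))
        plain_q = np.isin(qa, np.frombuffer(b"ACGT", dtype=np.uint8))
        both = plain_r & plain_q
        site = np.zeros(ra.shape, dtype=np.float64)
        site[both] = np.where(
            ra[both] == qa[both], self.scoring.match, self.scoring.mismatch
        )
        return r_lo, r_hi, site

    def gapless_overlap(self, ref: str, query: str, offset: int) -> Optional[GaplessHit]:
        """Full-overlap gapless alignment on diagonal ``offset``.

        This is the best gapless alignment under semi-global (free end gap)
        semantics, where trimming can only remove a prefix/suffix of one
        sequence: on a fixed diagonal the aligned run necessarily covers the
        whole overlap window.
        """
        r_lo, r_hi, site = self._diagonal_sites(ref, query, offset)
        if site is None:
            return None
        return GaplessHit(
            score=float(site.sum()),
            ref_start=r_lo,
            ref_end=r_hi,
            query_start=r_lo + offset,
            query_end=r_hi + offset,
        )

    def gapless_hit(self, ref: str, query: str, offset: int) -> Optional[GaplessHit]:
        """Best gapless local alignment on diagonal ``offset``.

        The aligned span is the maximum-sum contiguous run of per-site scores
        along the diagonal (ties: leftmost start, then longest run, so
        zero-scoring ambiguity flanks are kept).
        """
        r_lo, r_hi, site = self._diagonal_sites(ref, query, offset)
        if site is None:
            return None
        best_sum = -np.inf
        best: tuple[int, int] | None = None
        run_sum = 0.0
        run_start = 0
        for i, s in enumerate(site):
            if run_sum < 0:
                run_sum = 0.0
                run_start = i
            run_sum += s
            if run_sum > best_sum or (
                best_sum == run_sum
                and best is not None
                and (run_start, -(i + 1)) < (best[0], -best[1])
            ):
                best_sum = run_sum
                best = (run_start, i + 1)
        if best is None:
            return None
        b0, b1 = best
        return GaplessHit(
            score=float(best_sum),
            ref_start=r_lo + b0,
            ref_end=r_lo + b1,
            query_start=r_lo + b0 + offset,
            query_end=r_lo + b1 + offset,
        )
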