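"""Uncorrected pairwise divergence (p-distance) with pairwise deletion.

A site is comparable for a pair when both characters are plain A/C/G/T;
gaps, N and IUPAC ambiguity codes are excluded pairwise.  The distance is
the mismatch proportion over comparable sites and is reported missing when
fewer than ``min_overlap`` sites are comparable.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

_ACGT = np.frombuffer(b"ACGT", dtype=np.uint8)

DEFAULT_MIN_OVERLAP = 100


def _as_bytes(seq: str) -> np.ndarray:
    return np.frombuffer(seq.upper().encode(), dtype=np.uint8)


def p_distance(
    a: str, b: str, min_overlap: int = DEFAULT_MIN_OVERLAP
) -> tuple[float, int]:
    """Uncorrected distance between two equal-length gapped sequences.

    Returns ``(d, n)`` where ``n`` is the comparable-site count and ``d`` the
    mismatch proportion; ``d`` is NaN when ``n < min_overlap``.
    """
    if len(a) != len(b):
        raise ValueError("p_distance requires sequences from the same alignment")
    xa, xb = _as_bytes(a), _as_bytes(b)
    valid = np.isin(xa, _ACGT) & np.isin(xb, _ACGT)
    n = int(valid.sum())
    if n < min_overlap or n == 0:
        return float("nan"), n
    mism = int((xa[valid] != xb[valid]).sum())
    return mism / n, n


@dataclass
class DistanceMatrix:
    """Symmetric uncorrected-divergence matrix with comparable-site counts.

    Missing (insufficient-overlap) distances are NaN in ``d``.
    """

    labels: list[str]
    species: list[str]
    d: np.ndarray
    n_sites: np.ndarray
    min_overlap: int = DEFAULT_MIN_OVERLAP

    def __post_init__(self):
        n = len(self.labels)
        assert self.d.shape == (n, n) and self.n_sites.shape == (n, n)

    def __len__(self) -> int:
        return len(self.labels)

    @classmethod
    def from_rows(
        cls,
        rows: Sequence[tuple[str, str]],
        species: Sequence[str],
        min_overlap: int = DEFAULT_MIN_OVERLAP,
    ) -> "DistanceMatrix":
        """All-pairs matrix over equal-length gapped rows (vectorized)."""
        labels = [label for label, _ in rows]
        n = len(rows)
        if n == 0:
            return cls(labels=[], species=[], d=np.zeros((0, 0)),
                       n_sites=np.zeros((0, 0), dtype=int), min_overlap=min_overlap)
        mat = np.vstack([_as_bytes(seq) for _, seq in rows])
        valid = np.isin(mat, _ACGT)
        n_sites = valid.astype(np.int64) @ valid.T.astype(np.int64)
        matches = np.zeros((n, n), dtype=np.int64)
        for base in _ACGT:
            hit = ((mat == base) & valid).astype(np.int64)
            matches += hit @ hit.T
        with np.errstate(invalid="ignore", divide="ignore"):
            d = (n_sites - matches) / n_sites
        d[n_sites < min_overlap] = np.nan
        np.fill_diagonal(d, 0.0)
        return cls(
            labels=labels,
            species=list(species),
            d=d,
            n_sites=n_sites,
            min_overlap=min_overlap,
        )

    def is_defined(self, i: int, j: int) -> bool:
        return not np.isnan(self.d[i, j])

    def submatrix(self, idx: Sequence[int]) -> "DistanceMatrix":
        idx = list(idx)
        return DistanceMatrix(
            labels=[self.labels[i] for i in idx],
            species=[self.species[i] for i in idx],
            d=self.d[np.ix_(idx, idx)],
            n_sites=self.n_sites[np.ix_(idx, idx)],
            min_overlap=self.min_overlap,
        )

    def set_pair(self, i: int, j: int, d: float, n: int) -> None:
        self.d[i, j] = self.d[j, i] = d
        self.n_sites[i, j] = self.n_sites[j, i] = n

    def to_long_dataframe(self) -> pd.DataFrame:
        recs = []
        for i in range(len(self.labels)):
            for j in range(i + 1, len(self.labels)):
                recs.append(
                    {
                        "label_i": self.labels[i],
                        "label_j": self.labels[j],
                        "species_i": self.species[i],
                        "species_j": self.species[j],
                        "d": self.d[i, j],
                        "n_sites": int(self.n_sites[i, j]),
                    }
                )
        return pd.DataFrame(
            recs,
            columns=["label_i", "label_j", "species_i", "species_j", "d", "n_sites"],
        )

    def to_square_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.d, index=self.labels, columns=self.labels)


def genus_matrix(
    alignments: Sequence,
    projections: Mapping[str, str],
    min_overlap: int = DEFAULT_MIN_OVERLAP,
) -> DistanceMatrix:
    """Distance matrix over every sequence of one genus.

    Cross-species pairs are computed on reference-coordinate projections
    (equal-length rows supplied in ``projections``, keyed by label);
    within-species pairs are recomputed on the species' own gap-resolved
    alignment, which anchors conspecific indels better than the projection.
    """
    labels: list[str] = []
    species: list[str] = []
    for aln in alignments:
        for label in aln.labels:
            labels.append(label)
            species.append(aln.species)
    rows = [(label, projections[label]) for label in labels]
    matrix = DistanceMatrix.from_rows(rows, species, min_overlap=min_overlap)
    index = {label: i for i, label in enumerate(labels)}
    for aln in alignments:
        local = DistanceMatrix.from_rows(
            aln.rows, [aln.species] * len(aln.rows), min_overlap=min_overlap
        )
        for a in range(len(aln.rows)):
            for b in range(a + 1, len(aln.rows)):
                i, j = index[aln.labels[a]], index[aln.labels[b]]
                matrix.set_pair(i, j, local.d[a, b], int(local.n_sites[a, b]))
    return matrix
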