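"""Per-position coverage profiling, best-region search, summary statistics.

Coverage counts, for every reference position, the sequences (and distinct
species) contributing a non-missing base there; the best-region scan finds
the fixed-width window usable end-to-end by the most species, preferring
species coverage over sequence depth (lexicographic on the window minimum,
leftmost on ties).  Summary statistics report sequences/species and
species/genus (and species/family when a genus->family map is supplied) with
medians and linearly interpolated quartiles.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .records import Record
from .refmap import MappedSeq

_ACGT = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass
class CoverageProfile:
    """Per-position sequence and species coverage over the reference."""

    counts_seq: np.ndarray
    counts_sp: np.ndarray

    def __post_init__(self):
        assert self.counts_seq.shape == self.counts_sp.shape

    @property
    def length(self) -> int:
        return len(self.counts_seq)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "position": np.arange(self.length),
                "counts_seq": self.counts_seq,
                "counts_sp": self.counts_sp,
            }
        )


def _cover_mask(m: MappedSeq, ref_length: int) -> np.ndarray:
    row = np.frombuffer(m.projected(ref_length).encode(), dtype=np.uint8)
    return np.isin(row, _ACGT)


def coverage_profile(mapped: Sequence[MappedSeq], ref_length: int) -> CoverageProfile:
    """Tally per-position coverage of the reference.

    A position counts for a record iff it lies in the mapped span and the
    aligned character there is a plain base (A/C/G/T).
    """
    counts_seq = np.zeros(ref_length, dtype=np.int64)
    by_species: dict[str, np.ndarray] = {}
    for m in mapped:
        mask = _cover_mask(m, ref_length)
        counts_seq += mask
        key = m.species_key
        if key in by_species:
            by_species[key] |= mask
        else:
            by_species[key] = mask.copy()
    counts_sp = np.zeros(ref_length, dtype=np.int64)
    for mask in by_species.values():
        counts_sp += mask
    return CoverageProfile(counts_seq=counts_seq, counts_sp=counts_sp)


@dataclass(frozen=True)
class BestRegion:
    start: int
    end: int
    n_species: int
    n_seqs: int


def best_region(profile: CoverageProfile, window: int) -> BestRegion:
    """Exhaustive scan for the best fixed-width reference window.

    Maximizes the minimum species coverage over the window, tie-broken by
    the minimum sequence coverage, then by the smallest start.
    """
    L = profile.length
    if not (0 < window <= L):
        raise ValueError(f"window must be in (0, {L}]: {window}")
    best: Optional[tuple[int, int, int]] = None
    for s in range(L - window + 1):
        key = (
            int(profile.counts_sp[s : s + window].min()),
            int(profile.counts_seq[s : s + window].min()),
        )
        if best is None or key > (best[0], best[1]):
            best = (key[0], key[1], s)
    assert best is not None
    n_sp, n_seq, s = best
    return BestRegion(start=s, end=s + window, n_species=n_sp, n_seqs=n_seq)


@dataclass
class SummaryStats:
    """Database composition summaries with median and quartiles."""

    seqs_per_species: pd.Series
    species_per_genus: pd.Series
    species_per_family: Optional[pd.Series] = None
    quantiles: dict = field(default_factory=dict)

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for grouping, series in (
            ("seqs_per_species", self.seqs_per_species),
            ("species_per_genus", self.species_per_genus),
            ("species_per_family", self.species_per_family),
        ):
            if series is None:
                continue
            for key, value in series.items():
                rows.append({"grouping": grouping, "group": key, "count": int(value)})
        return pd.DataFrame(rows, columns=["grouping", "group", "count"])


def _quants(series: pd.Series) -> dict:
    if len(series) == 0:
        return {}
    values = series.to_numpy(dtype=float)
    q25, median, q75 = np.percentile(values, [25, 50, 75])  # linear interpolation
    return {"median": float(median), "q25": float(q25), "q75": float(q75)}


def summarize(
    records: Sequence[Record], family_map: Optional[Mapping[str, str]] = None
) -> SummaryStats:
    """Per-species sequence counts and per-genus/per-family species counts."""
    if not records:
        return SummaryStats(
            seqs_per_species=pd.Series(dtype=int),
            species_per_genus=pd.Series(dtype=int),
        )
    frame = pd.DataFrame(
        {
            "species": [r.name.species_key for r in records],
            "genus": [r.name.genus for r in records],
        }
    )
    seqs_per_species = frame.groupby("species").size().sort_index()
    species_per_genus = (
        frame.drop_duplicates("species").groupby("genus").size().sort_index()
    )
    species_per_family = None
    quantiles = {
        "seqs_per_species": _quants(seqs_per_species),
        "species_per_genus": _quants(species_per_genus),
    }
    if family_map:
        fam = frame.drop_duplicates("species").copy()
        fam["family"] = [family_map.get(g, "unknown") for g in fam["genus"]]
        species_per_family = fam.groupby("family").size().sort_index()
        quantiles["species_per_family"] = _quants(species_per_family)
    return SummaryStats(
        seqs_per_species=seqs_per_species,
        species_per_genus=species_per_genus,
        species_per_family=species_per_family,
        quantiles=quantiles,
    )
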