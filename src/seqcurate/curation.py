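"""Threshold-based conflict detection and the curation report.

Two complementary rules share one divergence threshold ``t`` (default 3%, a
conservative barcoding-gap value for mitochondrial protein-coding markers in
amphibians; re-estimate for other loci):

* intraspecific: conspecific sequences are accepted at divergence <= t and
  flagged above it.  Flagging is by single-linkage clustering at t — if the
  conspecific set splits into multiple clusters, every member outside the
  largest cluster is flagged (ties broken toward the cluster holding the
  lexicographically smallest label).
* intrageneric: heterospecific pairs are accepted at divergence > t and
  flagged at or below it (suspiciously similar across species), both members
  of the pair being reported with their closest offending partner.

Final verdicts (misidentification vs contamination vs hybridization vs
submission error) require literature review; the report carries empty
annotation columns for that human step and never auto-assigns a verdict.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import pandas as pd

from .divergence import DistanceMatrix

CATEGORY_INTRA = "intraspecific_divergent"
CATEGORY_INTER = "intrageneric_similar"
CATEGORY_MAPPING = "mapping_failure"
CATEGORY_NON_BINOMIAL = "non_binomial"
CATEGORY_DUPLICATE = "duplicate"

REPORT_COLUMNS = [
    "accession",
    "species",
    "category",
    "partner",
    "d_percent",
    "n_sites",
    "threshold_percent",
    "verdict",
    "rationale",
    "reference",
]


@dataclass(frozen=True)
class Thresholds:
    """Divergence threshold as a proportion (0 < t < 1)."""

    t: float = 0.03

    def __post_init__(self):
        if not (0.0 < self.t < 1.0):
            raise ValueError(f"threshold must be a proportion in (0, 1): {self.t}")


@dataclass(frozen=True)
class ConflictFlag:
    accession: str
    species: str
    category: str
    partner: str = ""
    d: Optional[float] = None
    n_sites: Optional[int] = None
    threshold: Optional[float] = None


def _accession_of(label: str) -> str:
    """Accession from a ``Genus_epithet_ACCESSION`` label."""
    return label.rsplit("_", 1)[-1]


def _single_linkage(matrix: DistanceMatrix, t: float, idx: Sequence[int]) -> list[set[int]]:
    parent = {i: i for i in idx}

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for a in range(len(idx)):
        for b in range(a + 1, len(idx)):
            i, j = idx[a], idx[b]
            if matrix.is_defined(i, j) and matrix.d[i, j] <= t:
                ri, rj = find(i), find(j)
                if ri != rj:
                    parent[rj] = ri
    clusters: dict[int, set[int]] = {}
    for i in idx:
        clusters.setdefault(find(i), set()).add(i)
    return list(clusters.values())


def _nearest(matrix: DistanceMatrix, i: int, pool: Iterable[int]) -> Optional[int]:
    best: Optional[int] = None
    for j in pool:
        if j == i or not matrix.is_defined(i, j):
            continue
        if best is None or (matrix.d[i, j], matrix.labels[j]) < (
            matrix.d[i, best],
            matrix.labels[best],
        ):
            best = j
    return best


def flag_intraspecific(
    matrix: DistanceMatrix, t: float = 0.03
) -> tuple[list[ConflictFlag], list[tuple[str, str]]]:
    """Flag conspecific sequences more than ``t`` divergent from their kin.

    ``matrix`` must cover exactly one species.  Returns (flags, notes);
    notes carry per-sequence reasons where no assessment was possible
    ("unassessable_single", "insufficient_overlap").
    """
    if len({s for s in matrix.species}) > 1:
        raise ValueError("flag_intraspecific expects a single-species matrix")
    notes: list[tuple[str, str]] = []
    n = len(matrix)
    if n <= 1:
        for label in matrix.labels:
            notes.append((_accession_of(label), "unassessable_single"))
        return [], notes
    assessable = [
        i
        for i in range(n)
        if any(matrix.is_defined(i, j) for j in range(n) if j != i)
    ]
    for i in range(n):
        if i not in assessable:
            notes.append((_accession_of(matrix.labels[i]), "insufficient_overlap"))
    if len(assessable) <= 1:
        for i in assessable:
            notes.append((_accession_of(matrix.labels[i]), "unassessable_single"))
        return [], notes
    clusters = _single_linkage(matrix, t, assessable)
    if len(clusters) == 1:
        return [], notes
    max_size = max(len(c) for c in clusters)
    keep = min(
        (c for c in clusters if len(c) == max_size),
        key=lambda c: min(matrix.labels[i] for i in c),
    )
    flags: list[ConflictFlag] = []
    for cluster in clusters:
        if cluster is keep:
            continue
        for i in sorted(cluster, key=lambda i: matrix.labels[i]):
            j = _nearest(matrix, i, assessable)
            flags.append(
                ConflictFlag(
                    accession=_accession_of(matrix.labels[i]),
                    species=matrix.species[i],
                    category=CATEGORY_INTRA,
                    partner=matrix.labels[j] if j is not None else "",
                    d=float(matrix.d[i, j]) if j is not None else None,
                    n_sites=int(matrix.n_sites[i, j]) if j is not None else None,
                    threshold=t,
                )
            )
    return flags, notes


def flag_intrageneric(
    matrix: DistanceMatrix, t: float = 0.03
) -> list[ConflictFlag]:
    """Flag heterospecific pairs at divergence <= t within a genus.

    Both members of every offending pair are flagged, deduplicated per
    sequence keeping the closest partner as evidence.
    """
    n = len(matrix)
    best: dict[int, int] = {}
    for i in range(n):
        for j in range(i + 1, n):
            if matrix.species[i] == matrix.species[j]:
                continue
            if not matrix.is_defined(i, j) or matrix.d[i, j] > t:
                continue
            for a, b in ((i, j), (j, i)):
                cur = best.get(a)
                if cur is None or (matrix.d[a, b], matrix.labels[b]) < (
                    matrix.d[a, cur],
                    matrix.labels[cur],
                ):
                    best[a] = b
    flags = []
    for i in sorted(best, key=lambda i: matrix.labels[i]):
        j = best[i]
        flags.append(
            ConflictFlag(
                accession=_accession_of(matrix.labels[i]),
                species=matrix.species[i],
                category=CATEGORY_INTER,
                partner=matrix.labels[j],
                d=float(matrix.d[i, j]),
                n_sites=int(matrix.n_sites[i, j]),
                threshold=t,
            )
        )
    return flags


@dataclass
class CurationReport:
    table: pd.DataFrame
    category_counts: pd.DataFrame
    flagged_accessions: set[str]
    policy: str = "exclude"

    def curated_subset(self, accessions: Sequence[str]) -> list[str]:
        """Accessions surviving curation under the configured policy."""
        if self.policy == "annotate":
            return list(accessions)
        return [a for a in accessions if a not in self.flagged_accessions]


def build_conflict_report(
    flags: Sequence[ConflictFlag],
    mapping_failures: Sequence[tuple[str, str]] = (),
    non_binomials: Sequence[tuple[str, str]] = (),
    duplicates: Sequence[tuple[str, str]] = (),
    threshold: float = 0.03,
    policy: str = "exclude",
) -> CurationReport:
    """Assemble the conflict report table.

    One row per flag; divergence evidence is rendered as a percentage to two
    decimals (all threshold comparisons upstream happen on exact values).
    The verdict / rationale / reference columns are left empty for human
    annotation.  ``mapping_failures``, ``non_binomials`` and ``duplicates``
    are (accession, detail) pairs from the earlier pipeline stages.
    """
    if policy not in ("exclude", "annotate"):
        raise ValueError(f"unknown policy: {policy!r}")
    rows = []
    for f in flags:
        rows.append(
            {
                "accession": f.accession,
                "species": f.species,
                "category": f.category,
                "partner": f.partner,
                "d_percent": "" if f.d is None else f"{100 * f.d:.2f}",
                "n_sites": "" if f.n_sites is None else f.n_sites,
                "threshold_percent": f"{100 * (f.threshold if f.threshold is not None else threshold):.2f}",
            }
        )
    for acc, reason in mapping_failures:
        rows.append(
            {"accession": acc, "species": "", "category": CATEGORY_MAPPING,
             "partner": reason, "d_percent": "", "n_sites": "",
             "threshold_percent": ""}
        )
    for acc, raw in non_binomials:
        rows.append(
            {"accession": acc, "species": raw, "category": CATEGORY_NON_BINOMIAL,
             "partner": "", "d_percent": "", "n_sites": "",
             "threshold_percent": ""}
        )
    for acc, partner in duplicates:
        rows.append(
            {"accession": acc, "species": "", "category": CATEGORY_DUPLICATE,
             "partner": partner, "d_percent": "", "n_sites": "",
             "threshold_percent": ""}
        )
    table = pd.DataFrame(rows, columns=REPORT_COLUMNS[:7])
    for col in ("verdict", "rationale", "reference"):
        table[col] = ""
    counts = (
        table.groupby("category").size().rename("count").reset_index()
        if len(table)
        else pd.DataFrame(columns=["category", "count"])
    )
    flagged = {f.accession for f in flags}
    return CurationReport(
        table=table,
        category_counts=counts,
        flagged_accessions=flagged,
        policy=policy,
    )
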