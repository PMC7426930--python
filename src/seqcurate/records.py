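"""Record parsing, normalization, deduplication and taxonomy reconciliation.

Repository records arrive as FASTA (optionally with a sidecar metadata TSV of
``accession / organism / definition`` columns).  Organism strings are parsed
into structured taxon names; open-nomenclature qualifiers (cf., aff., sp.,
ssp.) mark a record as taxonomically uncertain and route it to the
uncertain-taxonomy report rather than the curated set.
"""

from __future__ import annotations

import csv
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Optional, Sequence

from Bio import SeqIO

QUALIFIERS = ("cf", "aff", "sp", "ssp")

_GENUS_RE = re.compile(r"[A-Z][A-Za-z-]+$")
_EPITHET_RE = re.compile(r"[a-z][a-z-]*$")


@dataclass(frozen=True)
class TaxonName:
    """Genus + epithet + open-nomenclature qualifier.

    ``qualifier == "none"`` if and only if the name is a complete binomial.
    """

    genus: str = ""
    epithet: str = ""
    qualifier: str = "none"
    raw: str = ""

    @property
    def is_binomial(self) -> bool:
        return bool(self.genus) and bool(self.epithet) and self.qualifier == "none"

    @property
    def canonical(self) -> str:
        """``Genus_epithet`` label; only defined for complete binomials."""
        if not self.is_binomial:
            raise ValueError(f"not a complete binomial: {self.raw!r}")
        return f"{self.genus}_{self.epithet}"

    @property
    def species_key(self) -> str:
        """Grouping key: the binomial when complete, else the raw string."""
        if self.is_binomial:
            return f"{self.genus} {self.epithet}"
        return " ".join(self.raw.split()) or self.genus


@dataclass
class Record:
    """One repository record (accession, parsed name, nucleotides)."""

    accession: str
    name: TaxonName
    seq: str
    definition: str = ""
    source: str = "locus"
    notes: list[str] = field(default_factory=list)

    @property
    def is_refseq(self) -> bool:
        return self.accession.startswith("NC_")

    @property
    def label(self) -> str:
        """``Genus_epithet_ACCESSION`` rendering for binomial records."""
        return f"{self.name.canonical}_{self.accession}"


@dataclass(frozen=True)
class ParseError:
    accession: str
    reason: str


def parse_organism_with_notes(text: str) -> tuple[TaxonName, list[str]]:
    """Parse an organism string into a :class:`TaxonName` plus parse notes.

    Recognizes ``Genus epithet``, open-nomenclature qualifiers (``cf.``,
    ``aff.``, ``sp.``, ``ssp.``, with or without the period, case-insensitive),
    and trinomials (the subspecies epithet is dropped — species rank only).
    Trailing tokens that fit none of these (authorities, definition text) are
    stripped and noted.
    """
    raw = " ".join(text.replace("_", " ").split())
    tokens = raw.split()
    if not tokens or not _GENUS_RE.fullmatch(tokens[0]):
        return TaxonName(raw=raw), ["no genus recognized"]
    genus = tokens[0]
    epithet = ""
    qualifier = "none"
    notes: list[str] = []
    i = 1
    while i < len(tokens):
        tok = tokens[i]
        bare = tok.rstrip(".").lower()
        if bare in QUALIFIERS and tok.lower() in (bare, bare + "."):
            if qualifier == "none":
                qualifier = bare
            i += 1
            continue
        if _EPITHET_RE.fullmatch(tok):
            if not epithet:
                epithet = tok
                i += 1
                continue
            # candidate subspecies epithet: accept only as the final token,
            # otherwise it is definition text leaking into the organism field
            if i == len(tokens) - 1 and qualifier == "none":
                notes.append(f"trinomial truncated: dropped {tok!r}")
                i += 1
                continue
            break
        if tok.isdigit() and qualifier != "none":
            # informal numbering, e.g. "Rana sp. 2"
            i += 1
            continue
        break
    if i < len(tokens):
        notes.append(f"stripped trailing tokens: {' '.join(tokens[i:])!r}")
    name = TaxonName(genus=genus, epithet=epithet, qualifier=qualifier, raw=raw)
    return name, notes


def parse_organism(text: str) -> TaxonName:
    """Parse an organism string into a :class:`TaxonName` (notes discarded)."""
    return parse_organism_with_notes(text)[0]


def _strip_version(accession: str) -> str:
    return accession.split(".", 1)[0]


def _load_metadata(path: Path) -> dict[str, dict[str, str]]:
    table: dict[str, dict[str, str]] = {}
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            table[_strip_version(row["accession"])] = row
    return table


def parse_records(
    fasta: str | Path, metadata: Optional[str | Path] = None
) -> tuple[list[Record], list[ParseError]]:
    """Parse a FASTA file (plus optional metadata TSV) into records.

    Headers follow the ``>ACCESSION Organism ...`` convention; when a
    metadata table is given its ``organism`` column takes precedence.
    Unparseable entries become :class:`ParseError` rows, never exceptions.
    """
    meta = _load_metadata(Path(metadata)) if metadata else {}
    records: list[Record] = []
    errors: list[ParseError] = []
    for entry in SeqIO.parse(str(fasta), "fasta"):
        accession = _strip_version(entry.id)
        desc = entry.description.split(None, 1)
        organism = desc[1] if len(desc) > 1 else ""
        definition = organism
        if accession in meta:
            organism = meta[accession].get("organism", organism)
            definition = meta[accession].get("definition", definition)
        if not organism:
            errors.append(ParseError(accession, "no organism string"))
            continue
        name, notes = parse_organism_with_notes(organism)
        if not name.genus:
            errors.append(ParseError(accession, f"unparseable organism: {organism!r}"))
            continue
        records.append(
            Record(
                accession=accession,
                name=name,
                seq=str(entry.seq).upper(),
                definition=definition,
                notes=notes,
            )
        )
    return records, errors


def _dedup_key(record: Record) -> tuple[str, str]:
    return record.name.species_key, record.seq.upper().strip("N").strip("n")


def deduplicate(
    records: Sequence[Record],
) -> tuple[list[Record], list[tuple[str, str]]]:
    """Drop RefSeq (``NC_``) records whose sequence duplicates a conspecific.

    A RefSeq record is removed only when another record of the same species
    carries an identical sequence (case-insensitive, terminal-N padding
    ignored); if a species is represented solely by identical RefSeq copies,
    the lexicographically first accession is retained.  Non-RefSeq records
    are never removed.  Idempotent.
    """
    groups: dict[tuple[str, str], list[Record]] = {}
    for rec in records:
        groups.setdefault(_dedup_key(rec), []).append(rec)
    dropped_accessions: dict[str, str] = {}
    for members in groups.values():
        refseq = [r for r in members if r.is_refseq]
        plain = [r for r in members if not r.is_refseq]
        if not refseq:
            continue
        if plain:
            partner = plain[0]
            for r in refseq:
                dropped_accessions[r.accession] = partner.accession
        elif len(refseq) > 1:
            keep = min(refseq, key=lambda r: r.accession)
            for r in refseq:
                if r is not keep:
                    dropped_accessions[r.accession] = keep.accession
    kept = [r for r in records if r.accession not in dropped_accessions]
    dropped = [
        (r.accession, f"duplicate_of:{dropped_accessions[r.accession]}")
        for r in records
        if r.accession in dropped_accessions
    ]
    return kept, dropped


class TaxonomyTable:
    """Synonym map (raw name -> accepted binomial) plus optional genus->family."""

    def __init__(
        self,
        synonyms: dict[str, str],
        families: Optional[dict[str, str]] = None,
    ):
        self.synonyms: dict[str, TaxonName] = {}
        self.families = dict(families or {})
        for raw, accepted in synonyms.items():
            name = parse_organism(accepted)
            if not name.is_binomial:
                raise ValueError(
                    f"taxonomy table value is not a complete binomial: {accepted!r}"
                )
            self.synonyms[" ".join(raw.split())] = name
        # accepted names map to themselves, making application idempotent
        for name in list(self.synonyms.values()):
            self.synonyms.setdefault(name.species_key, name)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "TaxonomyTable":
        synonyms: dict[str, str] = {}
        families: dict[str, str] = {}
        with open(path, newline="") as fh:
            for row in csv.DictReader(fh, delimiter="\t"):
                synonyms[row["raw_name"]] = row["accepted_name"]
                fam = (row.get("family") or "").strip()
                if fam:
                    genus = parse_organism(row["accepted_name"]).genus
                    families[genus] = fam
        return cls(synonyms, families)

    def lookup(self, name: TaxonName) -> Optional[TaxonName]:
        hit = self.synonyms.get(" ".join(name.raw.split()))
        if hit is None and name.is_binomial:
            hit = self.synonyms.get(name.species_key)
        return hit


def apply_taxonomy(
    records: Sequence[Record], table: TaxonomyTable
) -> tuple[list[Record], list[tuple[str, str, str]]]:
    """Rewrite names found in the synonym map to their accepted binomial.

    Returns the updated records and a changelog with one
    ``(accession, old, new)`` entry per record whose name actually changed.
    Idempotent: accepted names map to themselves.
    """
    out: list[Record] = []
    changelog: list[tuple[str, str, str]] = []
    for rec in records:
        hit = table.lookup(rec.name)
        if hit is not None and (
            hit.genus != rec.name.genus
            or hit.epithet != rec.name.epithet
            or rec.name.qualifier != "none"
        ):
            old = rec.name.species_key
            new_name = TaxonName(
                genus=hit.genus, epithet=hit.epithet, qualifier="none", raw=hit.raw
            )
            out.append(replace(rec, name=new_name))
            changelog.append((rec.accession, old, new_name.species_key))
        else:
            out.append(rec)
    return out, changelog


def unmatched_names(
    records: Iterable[Record], table: TaxonomyTable
) -> list[str]:
    """Distinct raw names absent from the synonym map (for the changelog report)."""
    seen: set[str] = set()
    for rec in records:
        if table.lookup(rec.name) is None:
            seen.add(rec.name.species_key)
    return sorted(seen)


def partition_binomial(
    records: Sequence[Record],
) -> tuple[list[Record], list[Record]]:
    """Split records into complete binomials and uncertain-taxonomy records."""
    binomial = [r for r in records if r.name.is_binomial]
    uncertain = [r for r in records if not r.name.is_binomial]
    return binomial, uncertain


def write_curated_fasta(records: Iterable[Record], path: str | Path) -> None:
    """Write records with ``>Genus_epithet_ACCESSION`` headers (60-col wrap)."""
    with open(path, "w") as fh:
        for rec in records:
            label = rec.label if rec.name.is_binomial else f"{rec.name.genus}_{rec.accession}"
            fh.write(f">{label}\n")
            for i in range(0, len(rec.seq), 60):
                fh.write(rec.seq[i : i + 60] + "\n")
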