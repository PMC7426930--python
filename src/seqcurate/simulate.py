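"""Deterministic synthetic repository-record generator with planted errors.

The generator states a simple world: each species descends from the
reference by independent per-site substitution at ``inter_div``, each
conspecific sequence from its species ancestor at ``intra_div`` (uniform
alternative base, no indels unless planted), so expected pairwise
divergences are analytic.  Error classes mirror what real repositories
contain: cross-taxon label swaps, backward-read submissions, RefSeq twins,
open-nomenclature names, terminal ambiguity runs, locus-in-mitogenome
records, and frame-breaking single-base deletions.  Every emitted record is
accounted for in a truth table so each pipeline stage can be scored against
the planted ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from ._scoring import reverse_complement
from .records import Record, TaxonName, parse_organism
from .refmap import ReferenceLocus

ERROR_CLASSES = (
    "misidentified",
    "revcomp",
    "refseq_duplicate",
    "non_binomial",
    "terminal_ambiguity",
    "mitogenome_embedded",
    "frameshift_gap",
)

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass
class SyntheticConfig:
    """World parameters for one synthetic record set.

    Defaults match the benchmark: 10 genera x 3 species x 8 sequences on a
    1,140 nt locus, 1% conspecific and 8% heterospecific substitution
    (comfortably either side of the 3% flagging threshold).
    """

    seed: int = 0
    n_genera: int = 10
    species_per_genus: int = 3
    seqs_per_species: int = 8
    intra_div: float = 0.01
    inter_div: float = 0.08
    locus_length: int = 1140
    mitogenome_length: int = 16000
    planted: dict[str, int] = field(default_factory=dict)
    misid_cross_genus: bool = True

    def __post_init__(self):
        unknown = set(self.planted) - set(ERROR_CLASSES)
        if unknown:
            raise ValueError(f"unknown error classes: {sorted(unknown)}")
        self.planted = {cls: int(self.planted.get(cls, 0)) for cls in ERROR_CLASSES}

    @property
    def n_ordinary(self) -> int:
        return self.n_genera * self.species_per_genus * self.seqs_per_species


@dataclass
class SyntheticDataset:
    """Generated records plus ground truth."""

    records: list[Record]
    truth: pd.DataFrame
    reference: ReferenceLocus
    config: SyntheticConfig

    def fasta_text(self) -> str:
        chunks = []
        for rec in self.records:
            chunks.append(f">{rec.accession} {rec.name.raw}\n")
            for i in range(0, len(rec.seq), 60):
                chunks.append(rec.seq[i : i + 60] + "\n")
        return "".join(chunks)

    def metadata_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "accession": [r.accession for r in self.records],
                "organism": [r.name.raw for r in self.records],
                "definition": [r.definition for r in self.records],
            }
        )

    def write(self, outdir: str | Path) -> dict[str, Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "fasta": outdir / "records.fasta",
            "metadata": outdir / "metadata.tsv",
            "truth": outdir / "truth.tsv",
            "reference": outdir / "reference.fasta",
        }
        paths["fasta"].write_text(self.fasta_text())
        self.metadata_frame().to_csv(paths["metadata"], sep="\t", index=False)
        self.truth.to_csv(paths["truth"], sep="\t", index=False)
        ref = self.reference
        paths["reference"].write_text(
            f">{ref.accession}\n"
            + "\n".join(ref.seq[i : i + 60] for i in range(0, len(ref.seq), 60))
            + "\n"
        )
        return paths

    def planted_accessions(self, error_class: str) -> set[str]:
        hit = self.truth[self.truth["error_class"] == error_class]
        return set(hit["accession"])


def _letters(i: int) -> str:
    return chr(97 + i // 26) + chr(97 + i % 26)


def _mutate(rng: np.random.Generator, seq: np.ndarray, rate: float) -> np.ndarray:
    """Independent per-site substitution with a uniform alternative base."""
    out = seq.copy()
    hits = np.flatnonzero(rng.random(len(seq)) < rate)
    if len(hits):
        # shift by 1..3 within ACGT guarantees a different base
        idx = np.searchsorted(_BASES, out[hits])
        out[hits] = _BASES[(idx + rng.integers(1, 4, size=len(hits))) % 4]
    return out


def _random_seq(rng: np.random.Generator, length: int) -> np.ndarray:
    return _BASES[rng.integers(0, 4, size=length)]


def generate(
    config: SyntheticConfig, reference: Optional[ReferenceLocus] = None
) -> SyntheticDataset:
    """Emit a record set per ``config``; byte-identical for identical seeds."""
    rng = np.random.default_rng(config.seed)
    L = config.locus_length
    if reference is None:
        reference = ReferenceLocus(
            accession="SYNREF01", seq=_random_seq(rng, L).tobytes().decode()
        )
    else:
        L = len(reference)
    ref_arr = np.frombuffer(reference.seq.encode(), dtype=np.uint8)

    species_names: list[tuple[str, str]] = []  # (genus, epithet)
    for g in range(config.n_genera):
        genus = "Gen" + _letters(g)
        genus = genus[0].upper() + genus[1:]
        for s in range(config.species_per_genus):
            species_names.append((genus, "spec" + _letters(s)))

    ancestors = {
        name: _mutate(rng, ref_arr, config.inter_div) for name in species_names
    }

    n_total = config.n_ordinary
    for cls, count in config.planted.items():
        if cls != "refseq_duplicate" and count < 0:
            raise ValueError("planted counts must be non-negative")
    n_planted_in_place = sum(
        c for cls, c in config.planted.items() if cls != "refseq_duplicate"
    )
    if n_planted_in_place > n_total:
        raise ValueError("planted counts exceed available records")

    rows: list[dict] = []
    records: list[Record] = []
    acc_counter = 0
    for genus, epithet in species_names:
        for _ in range(config.seqs_per_species):
            acc_counter += 1
            accession = f"SYN{acc_counter:06d}"
            seq = _mutate(rng, ancestors[(genus, epithet)], config.intra_div)
            records.append(
                Record(
                    accession=accession,
                    name=TaxonName(
                        genus=genus, epithet=epithet, raw=f"{genus} {epithet}"
                    ),
                    seq=seq.tobytes().decode(),
                    definition=f"{genus} {epithet} synthetic locus record",
                )
            )
            rows.append(
                {
                    "accession": accession,
                    "true_species": f"{genus} {epithet}",
                    "assigned_species": f"{genus} {epithet}",
                    "error_class": "",
                    "orientation": "forward",
                    "embed_offset": -1,
                    "pad_left": 0,
                    "pad_right": 0,
                }
            )

    # one planted error per record, drawn without replacement in class order
    pool = list(range(len(records)))
    chosen: dict[str, list[int]] = {}
    for cls in ERROR_CLASSES:
        count = config.planted[cls]
        if cls == "refseq_duplicate" or count == 0:
            chosen[cls] = []  # twins are appended later, not drawn from the pool
            continue
        pick = rng.choice(len(pool), size=count, replace=False)
        chosen[cls] = [pool[i] for i in sorted(pick)]
        for i in sorted(pick, reverse=True):
            pool.pop(i)

    for i in chosen["misidentified"]:
        rec = records[i]
        true_genus = rec.name.genus
        if config.misid_cross_genus:
            targets = [
                (g, e) for (g, e) in species_names if g != true_genus
            ]
        else:
            targets = [
                (g, e)
                for (g, e) in species_names
                if g == true_genus and (g, e) != (rec.name.genus, rec.name.epithet)
            ]
        if not targets:
            raise ValueError("no relabel target available for misidentified planting")
        g, e = targets[int(rng.integers(0, len(targets)))]
        records[i] = Record(
            accession=rec.accession,
            name=TaxonName(genus=g, epithet=e, raw=f"{g} {e}"),
            seq=rec.seq,
            definition=rec.definition,
        )
        rows[i]["assigned_species"] = f"{g} {e}"
        rows[i]["error_class"] = "misidentified"

    for i in chosen["revcomp"]:
        records[i].seq = reverse_complement(records[i].seq)
        rows[i]["orientation"] = "reverse"
        rows[i]["error_class"] = "revcomp"

    for i in chosen["non_binomial"]:
        rec = records[i]
        variants = (
            f"{rec.name.genus} cf. {rec.name.epithet}",
            f"{rec.name.genus} sp. {int(rng.integers(1, 9))}",
            f"{rec.name.genus} aff. {rec.name.epithet}",
            f"{rec.name.genus} {rec.name.epithet} ssp.",
        )
        raw = variants[int(rng.integers(0, len(variants)))]
        records[i] = Record(
            accession=rec.accession,
            name=parse_organism(raw),
            seq=rec.seq,
            definition=rec.definition,
        )
        rows[i]["assigned_species"] = raw
        rows[i]["error_class"] = "non_binomial"

    for i in chosen["terminal_ambiguity"]:
        left = int(rng.integers(5, 31))
        right = int(rng.integers(5, 31))
        records[i].seq = "N" * left + records[i].seq + "N" * right
        rows[i]["pad_left"] = left
        rows[i]["pad_right"] = right
        rows[i]["error_class"] = "terminal_ambiguity"

    for i in chosen["mitogenome_embedded"]:
        background = _random_seq(rng, config.mitogenome_length).tobytes().decode()
        offset = int(rng.integers(0, config.mitogenome_length - 1))
        records[i].seq = background[:offset] + records[i].seq + background[offset:]
        rows[i]["embed_offset"] = offset
        rows[i]["error_class"] = "mitogenome_embedded"

    for i in chosen["frameshift_gap"]:
        seq = records[i].seq
        pos = int(rng.integers(10, len(seq) - 10))
        records[i].seq = seq[:pos] + seq[pos + 1 :]
        rows[i]["error_class"] = "frameshift_gap"

    # RefSeq twins are appended as extra records duplicating a partner
    n_twins = config.planted["refseq_duplicate"]
    if n_twins:
        partners = rng.choice(len(records), size=n_twins, replace=False)
        for k, i in enumerate(sorted(int(p) for p in partners), start=1):
            rec = records[i]
            accession = f"NC_{k:06d}"
            records.append(
                Record(
                    accession=accession,
                    name=rec.name,
                    seq=rec.seq,
                    definition=rec.definition,
                )
            )
            rows.append(
                {
                    "accession": accession,
                    "true_species": rows[i]["true_species"],
                    "assigned_species": rows[i]["assigned_species"],
                    "error_class": "refseq_duplicate",
                    "orientation": rows[i]["orientation"],
                    "embed_offset": rows[i]["embed_offset"],
                    "pad_left": rows[i]["pad_left"],
                    "pad_right": rows[i]["pad_right"],
                }
            )

    truth = pd.DataFrame(
        rows,
        columns=[
            "accession",
            "true_species",
            "assigned_species",
            "error_class",
            "orientation",
            "embed_offset",
            "pad_left",
            "pad_right",
        ],
    )
    return SyntheticDataset(
        records=records, truth=truth, reference=reference, config=config
    )


def benchmark_config(seed: int, misidentified: int = 15, **overrides) -> SyntheticConfig:
    """The planted-misidentification benchmark world."""
    planted = overrides.pop("planted", {})
    planted.setdefault("misidentified", misidentified)
    return SyntheticConfig(seed=seed, planted=planted, **overrides)
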