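from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from seqcurate import (
    Record,
    TaxonName,
    TaxonomyTable,
    apply_taxonomy,
    deduplicate,
    parse_organism,
    parse_records,
    partition_binomial,
)
from seqcurate.records import parse_organism_with_notes, unmatched_names


def make_record(accession: str, organism: str, seq: str = "ACGT" * 50) -> Record:
    return Record(accession=accession, name=parse_organism(organism), seq=seq)


class TestParseOrganism:
    @pytest.mark.parametrize(
        "text, genus, epithet, qualifier",
        [
            ("Bufo bufo", "Bufo", "bufo", "none"),
            ("Hyla cf. arborea", "Hyla", "arborea", "cf"),
            ("Hyla cf arborea", "Hyla", "arborea", "cf"),
            ("Rana sp. 2", "Rana", "", "sp"),
            ("Rana sp.", "Rana", "", "sp"),
            ("Triturus aff. cristatus", "Triturus", "cristatus", "aff"),
            ("Salamandra salamandra ssp.", "Salamandra", "salamandra", "ssp"),
            ("Bufo SP. 1", "Bufo", "", "sp"),
        ],
    )
    def test_qualifier_detection(self, text, genus, epithet, qualifier):
        name = parse_organism(text)
        assert (name.genus, name.epithet, name.qualifier) == (genus, epithet, qualifier)
        assert name.is_binomial == (qualifier == "none" and bool(epithet))

    def test_trinomial_truncated_to_binomial(self):
        name, notes = parse_organism_with_notes("Salamandra salamandra terrestris")
        assert name.is_binomial and name.epithet == "salamandra"
        assert any("trinomial" in n for n in notes)

    def test_trailing_definition_text_stripped(self):
        name, notes = parse_organism_with_notes(
            "Bufo bufo cytochrome b gene, partial cds"
        )
        assert (name.genus, name.epithet) == ("Bufo", "bufo")
        assert any("stripped" in n for n in notes)

    def test_unparseable_returns_empty_genus(self):
        assert parse_organism("123 nothing").genus == ""

    @settings(derandomize=True, max_examples=50)
    @given(
        genus=st.from_regex(r"[A-Z][a-z]{2,8}", fullmatch=True),
        epithet=st.from_regex(r"[a-z]{2,10}", fullmatch=True),
        accession=st.from_regex(r"[A-Z]{2}[0-9]{6}", fullmatch=True),
    )
    def test_label_round_trip(self, genus, epithet, accession):
        """Rendering Genus_epithet_ACCESSION and re-parsing recovers the parts."""
        rec = Record(
            accession=accession,
            name=TaxonName(genus=genus, epithet=epithet, raw=f"{genus} {epithet}"),
            seq="ACGT",
        )
        stem, acc = rec.label.rsplit("_", 1)
        assert acc == accession
        reparsed = parse_organism(stem.replace("_", " "))
        assert (reparsed.genus, reparsed.epithet) == (genus, epithet)
        assert reparsed.is_binomial


class TestParseRecords:
    def test_fasta_with_headers(self, tmp_path):
        fasta = tmp_path / "in.fasta"
        fasta.write_text(
            ">AB123456 Bufo bufo\nACGTACGT\nACGT\n"
            ">XY000001 Hyla cf. arborea\nACGTACGT\n"
            ">XY000002 Rana sp. 2\nACGT\n"
        )
        records, errors = parse_records(fasta)
        assert not errors
        assert [r.accession for r in records] == ["AB123456", "XY000001", "XY000002"]
        assert records[0].seq == "ACGTACGTACGT"
        assert records[0].name.is_binomial
        assert records[1].name.qualifier == "cf"
        assert records[2].name.qualifier == "sp" and records[2].name.epithet == ""

    def test_metadata_overrides_header(self, tmp_path):
        fasta = tmp_path / "in.fasta"
        fasta.write_text(">AB000001\nACGT\n>AB000002 ignored\nACGT\n")
        meta = tmp_path / "meta.tsv"
        meta.write_text(
            "accession\torganism\tdefinition\n"
            "AB000001\tBufo bufo\tcytb\n"
            "AB000002\tRana temporaria\tcytb\n"
        )
        records, errors = parse_records(fasta, meta)
        assert not errors
        assert records[0].name.species_key == "Bufo bufo"
        assert records[1].name.species_key == "Rana temporaria"

    def test_bad_header_becomes_error_entry_not_crash(self, tmp_path):
        fasta = tmp_path / "in.fasta"
        fasta.write_text(">ONLYACC\nACGT\n>AB000001 Bufo bufo\nACGT\n")
        records, errors = parse_records(fasta)
        assert len(records) == 1 and len(errors) == 1
        assert errors[0].accession == "ONLYACC"

    def test_empty_file_empty_list(self, tmp_path):
        fasta = tmp_path / "in.fasta"
        fasta.write_text("")
        records, errors = parse_records(fasta)
        assert records == [] and errors == []


class TestDeduplicate:
    def test_refseq_twin_dropped(self):
        a = make_record("AB123456", "Bufo bufo", "ACGTTGCA" * 20)
        nc = make_record("NC_000001", "Bufo bufo", "ACGTTGCA" * 20)
        kept, dropped = deduplicate([nc, a])
        assert [r.accession for r in kept] == ["AB123456"]
        assert dropped == [("NC_000001", "duplicate_of:AB123456")]

    def test_lone_refseq_kept(self):
        nc = make_record("NC_000002", "Bufo bufo")
        kept, dropped = deduplicate([nc])
        assert kept == [nc] and dropped == []

    def test_case_and_terminal_n_ignored(self):
        a = make_record("AB000001", "Bufo bufo", "acgttgca" * 20)
        nc = make_record("NC_000003", "Bufo bufo", "NN" + "ACGTTGCA" * 20 + "N")
        kept, _ = deduplicate([a, nc])
        assert [r.accession for r in kept] == ["AB000001"]

    def test_same_sequence_other_species_not_dropped(self):
        a = make_record("AB000001", "Bufo bufo", "ACGTTGCA" * 20)
        nc = make_record("NC_000004", "Rana temporaria", "ACGTTGCA" * 20)
        kept, dropped = deduplicate([a, nc])
        assert len(kept) == 2 and not dropped

    def test_planted_twins_and_idempotence(self, rng):
        from tests.conftest import random_dna

        records = []
        for i in range(7):
            records.append(
                make_record(f"AB{i:06d}", f"Bufo spec{chr(97 + i)}", random_dna(rng, 200))
            )
        twins = [0, 3, 5]
        for k, i in enumerate(twins):
            records.append(
                Record(
                    accession=f"NC_{k:06d}",
                    name=records[i].name,
                    seq=records[i].seq,
                )
            )
        kept, dropped = deduplicate(records)
        assert len(kept) == 7 and len(dropped) == 3
        # brute-force oracle: every drop names a same-species identical partner
        by_acc = {r.accession: r for r in records}
        for acc, reason in dropped:
            partner = by_acc[reason.split(":", 1)[1]]
            assert by_acc[acc].seq == partner.seq
            assert by_acc[acc].name.species_key == partner.name.species_key
        kept2, dropped2 = deduplicate(kept)
        assert kept2 == kept and dropped2 == []

    def test_never_removes_non_refseq_and_preserves_species(self, rng):
        from tests.conftest import random_dna

        seq = random_dna(rng, 150)
        records = [
            make_record("NC_900001", "Alpha beta", seq),
            make_record("NC_900002", "Alpha beta", seq),
            make_record("AB000009", "Gamma delta", seq),
        ]
        kept, dropped = deduplicate(records)
        assert {r.accession for r in kept} == {"NC_900001", "AB000009"}
        assert {r.name.species_key for r in kept} == {
            r.name.species_key for r in records
        }


class TestApplyTaxonomy:
    def test_synonym_renamed_once(self):
        table = TaxonomyTable({"Bufo calamita": "Epidalea calamita"})
        rec = make_record("AB000001", "Bufo calamita")
        out, changelog = apply_taxonomy([rec], table)
        assert out[0].name.species_key == "Epidalea calamita"
        assert changelog == [("AB000001", "Bufo calamita", "Epidalea calamita")]
        again, changelog2 = apply_taxonomy(out, table)
        assert changelog2 == [] and again[0].name == out[0].name

    def test_accepted_name_untouched(self):
        table = TaxonomyTable({"Bufo calamita": "Epidalea calamita"})
        rec = make_record("AB000002", "Epidalea calamita")
        out, changelog = apply_taxonomy([rec], table)
        assert out[0].name == rec.name and changelog == []

    def test_planted_synonym_count(self, rng):
        table = TaxonomyTable({f"Oldgen spec{chr(97+i)}": "Newgen species" for i in range(20)})
        records = [
            make_record(f"AB{i:06d}", f"Oldgen spec{chr(97 + i % 20)}")
            for i in range(20)
        ] + [make_record(f"CD{i:06d}", "Other taxon" if False else "Othera taxon") for i in range(80)]
        out, changelog = apply_taxonomy(records, table)
        assert len(changelog) == 20
        assert unmatched_names(out, table) == ["Othera taxon"]

    def test_non_binomial_accepted_name_rejected(self):
        with pytest.raises(ValueError):
            TaxonomyTable({"Bufo calamita": "Epidalea sp."})

    def test_from_tsv_with_family(self, tmp_path):
        tsv = tmp_path / "tax.tsv"
        tsv.write_text(
            "raw_name\taccepted_name\tfamily\n"
            "Bufo calamita\tEpidalea calamita\tBufonidae\n"
        )
        table = TaxonomyTable.from_tsv(tsv)
        assert table.families == {"Epidalea": "Bufonidae"}
        assert table.lookup(parse_organism("Bufo calamita")).species_key == "Epidalea calamita"


class TestPartitionBinomial:
    def test_examples(self):
        recs = [
            make_record("A1", "Bufo bufo"),
            make_record("A2", "Hyla cf. arborea"),
            make_record("A3", "Rana sp."),
        ]
        binomial, uncertain = partition_binomial(recs)
        assert [r.accession for r in binomial] == ["A1"]
        assert [r.accession for r in uncertain] == ["A2", "A3"]
        assert len(binomial) + len(uncertain) == len(recs)

    def test_all_binomial(self):
        recs = [make_record("A1", "Bufo bufo"), make_record("A2", "Rana temporaria")]
        _, uncertain = partition_binomial(recs)
        assert uncertain == []

    def test_planted_qualifier_fraction(self, rng):
        n, q = 200, 0.2
        planted = rng.random(n) < q
        recs = []
        for i, is_unc in enumerate(planted):
            org = "Bufo cf. bufo" if is_unc else "Bufo bufo"
            recs.append(make_record(f"A{i:05d}", org))
        binomial, uncertain = partition_binomial(recs)
        assert len(uncertain) == int(planted.sum())
        assert len(binomial) == n - int(planted.sum())
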