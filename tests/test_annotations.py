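"""Ingest and training: parsing, evidence filtering, term mapping,
count matrices and localization-ratio tables."""

import itertools
import random

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pfantom import (
    AnnotationRecord,
    CompartmentVocabulary,
    DomainAssignment,
    PfamCountMatrix,
    PfamLocalizationTable,
    build_count_matrix,
    compute_ratio_table,
    filter_by_evidence,
    load_domain_assignments,
    map_terms_to_compartments,
    parse_annotation_file,
)
from pfantom._ids import normalize_gene_id, species_of
from pfantom.annotations import MalformedLineWarning

GAF_HEADER = "!gaf-version: 2.2\n"


def gaf_line(protein, go, evidence, qualifier="located_in"):
    cols = ["TAIR", protein, protein, qualifier, go, "REF:1", evidence,
            "", "C", "", "", "protein", "taxon:3702", "20100101", "TAIR", "", ""]
    return "\t".join(cols) + "\n"


class TestParsing:
    def test_tsv_skips_comments(self, tmp_path):
        p = tmp_path / "a.tsv"
        p.write_text("# header\nAT1G01010\tGO:0005634\tIDA\nAT1G01020\tGO:0005886\tISS\n")
        records = parse_annotation_file(p, format="tsv")
        assert len(records) == 2
        assert records[0] == AnnotationRecord("AT1G01010", "GO:0005634", "IDA")

    def test_empty_file(self, tmp_path):
        p = tmp_path / "empty.tsv"
        p.write_text("")
        assert parse_annotation_file(p, format="tsv") == []

    def test_gaf_malformed_lines_counted(self, tmp_path):
        lines = [gaf_line(f"AT1G0{i:04d}", "GO:0005634", "IDA") for i in range(10)]
        lines[4] = "AT1G00004\tbroken\n"  # too few columns
        p = tmp_path / "a.gaf"
        p.write_text(GAF_HEADER + "".join(lines))
        with pytest.warns(MalformedLineWarning, match="1 malformed"):
            records = parse_annotation_file(p, format="gaf")
        assert len(records) == 9

    def test_gaf_not_qualifier_dropped(self, tmp_path):
        p = tmp_path / "a.gaf"
        p.write_text(
            GAF_HEADER
            + gaf_line("AT1G01010", "GO:0005634", "IDA")
            + gaf_line("AT1G01020", "GO:0005634", "IDA", qualifier="NOT|located_in")
        )
        records = parse_annotation_file(p, format="gaf")
        assert [r.protein_id for r in records] == ["AT1G01010"]

    def test_unknown_format_rejected(self, tmp_path):
        p = tmp_path / "a.tsv"
        p.write_text("")
        with pytest.raises(ValueError, match="format"):
            parse_annotation_file(p, format="xml")

    def test_splice_variants_normalized(self, tmp_path):
        p = tmp_path / "a.tsv"
        p.write_text("at1g01010.1\tGO:0005634\tIDA\n")
        (rec,) = parse_annotation_file(p, format="tsv")
        assert rec.protein_id == "AT1G01010"


class TestIdNormalization:
    @pytest.mark.parametrize(
        "raw, expected",
        [
            ("at1g67510", "AT1G67510"),
            ("AT5G48560.2", "AT5G48560"),
            ("OS01G0926400", "Os01g0926400"),
            ("Os01g0926400", "Os01g0926400"),
            ("  BAIT_X ", "BAIT_X"),
        ],
    )
    def test_normalize(self, raw, expected):
        assert normalize_gene_id(raw) == expected

    def test_species(self):
        assert species_of("AT1G27440") == "arabidopsis"
        assert species_of("Os05g0123100") == "rice"
        assert species_of("G000123") == "other"


class TestEvidenceFilter:
    def test_default_keeps_ida_only(self):
        recs = [
            AnnotationRecord("P1", "GO:0005634", "IDA"),
            AnnotationRecord("P2", "GO:0005634", "ISS"),
        ]
        assert filter_by_evidence(recs) == [recs[0]]

    def test_multiple_allowed_codes(self):
        codes = ["IDA", "IMP", "ISS", "IDA", "IMP", "IDA"]
        recs = [AnnotationRecord(f"P{i}", "GO:0005634", c) for i, c in enumerate(codes)]
        assert len(filter_by_evidence(recs, {"IDA", "IMP"})) == 5

    def test_empty_input(self):
        assert filter_by_evidence([], {"IDA"}) == []

    def test_empty_allowed_set_rejected(self):
        with pytest.raises(ValueError):
            filter_by_evidence([], set())

    @given(
        codes=st.lists(st.sampled_from(["IDA", "IMP", "ISS", "IEP"]), max_size=30),
        allowed=st.sets(st.sampled_from(["IDA", "IMP", "ISS", "IEP"]), min_size=1),
    )
    def test_monotone_and_order_preserving(self, codes, allowed):
        recs = [AnnotationRecord(f"P{i}", "GO:0005634", c) for i, c in enumerate(codes)]
        out = filter_by_evidence(recs, allowed)
        assert len(out) <= len(recs)
        assert out == [r for r in recs if r.evidence_code in allowed]
        assert filter_by_evidence(recs, {"IDA", "IMP", "ISS", "IEP"}) == recs


class TestTermMapping:
    def test_golgi_term_maps(self):
        recs = [AnnotationRecord("P1", "GO:0005794", "IDA")]
        m = map_terms_to_compartments(recs)
        assert m == {"P1": {"Golgi apparatus"}}

    def test_unmapped_term_dropped_and_counted(self):
        recs = [AnnotationRecord("P1", "GO:9999999", "IDA")]
        m = map_terms_to_compartments(recs)
        assert "P1" not in m and m.n_dropped == 1

    def test_set_semantics(self):
        recs = [
            AnnotationRecord("P1", "GO:0005634", "IDA"),
            AnnotationRecord("P1", "GO:0005634", "IDA"),
            AnnotationRecord("P1", "GO:0005886", "IDA"),
        ]
        m = map_terms_to_compartments(recs)
        assert m["P1"] == {"nucleus", "plasma membrane"}

    def test_vocabulary_expansion(self):
        vocab = CompartmentVocabulary().expanded({"GO:0005802": "GO:0005794"})
        recs = [AnnotationRecord("P1", "GO:0005802", "IDA")]
        m = map_terms_to_compartments(recs, vocab)
        assert m["P1"] == {"Golgi apparatus"}

    def test_default_vocabulary_has_eleven_terms(self):
        vocab = CompartmentVocabulary()
        assert len(vocab.entries) == 11
        assert vocab.go_to_name["GO:0005634"] == "nucleus"
        assert vocab.go_to_name["GO:0048046"] == "extracellular"


class TestDomainAssignments:
    def test_valid_row(self, tmp_path):
        p = tmp_path / "pfam.tsv"
        p.write_text("AT5G48560\tPF00010\n")
        (a,) = load_domain_assignments(p)
        assert a == DomainAssignment("AT5G48560", "PF00010")

    def test_bad_accession_rejected_with_warning(self, tmp_path):
        p = tmp_path / "pfam.tsv"
        p.write_text("AT1G01010\tXX123\nAT1G01010\tPF00010\n")
        with pytest.warns(MalformedLineWarning, match="rejected 1"):
            out = load_domain_assignments(p)
        assert len(out) == 1

    def test_duplicates_kept(self, tmp_path):
        rows = ["AT1G01010\tPF00001"] * 2 + [
            "AT1G01020\tPF00002", "AT1G01030\tPF00003", "AT1G01040\tPF00004"]
        p = tmp_path / "pfam.tsv"
        p.write_text("\n".join(rows) + "\n")
        assert len(load_domain_assignments(p)) == 5

    def test_coordinates(self, tmp_path):
        p = tmp_path / "pfam.tsv"
        p.write_text("AT1G01010\tPF00001\t10\t80\n")
        (a,) = load_domain_assignments(p)
        assert (a.start, a.end) == (10, 80)

    def test_bad_coordinates_rejected(self):
        with pytest.raises(ValueError):
            DomainAssignment("P1", "PF00001", start=10, end=5)


def brute_force_counts(protein_compartments, assignments):
    """Independent oracle: nested loop over (protein, pfam, compartment)."""
    counts, totals = {}, {}
    all_pfams = sorted({a.pfam_id for a in assignments})
    for protein in protein_compartments:
        for pfam in all_pfams:
            if not any(a.protein_id == protein and a.pfam_id == pfam for a in assignments):
                continue
            for comp in protein_compartments[protein]:
                counts[(pfam, comp)] = counts.get((pfam, comp), 0) + 1
                totals[pfam] = totals.get(pfam, 0) + 1
    return counts, totals


class TestCountMatrix:
    def test_single_protein_single_domain(self):
        m = build_count_matrix(
            {"P1": {"nucleus"}}, [DomainAssignment("P1", "PF00001")]
        )
        assert m.counts == {("PF00001", "nucleus"): 1}
        assert m.pfam_totals == {"PF00001": 1}

    def test_cross_product_counting(self):
        m = build_count_matrix(
            {"P1": {"nucleus", "plasma membrane"}},
            [DomainAssignment("P1", "PF00001"), DomainAssignment("P1", "PF00002")],
        )
        assert all(v == 1 for v in m.counts.values()) and len(m.counts) == 4
        assert m.pfam_totals == {"PF00001": 2, "PF00002": 2}
        assert m.n_domain_annotations == 4

    def test_repeated_domain_copies_count_once(self):
        m = build_count_matrix(
            {"P1": {"nucleus"}},
            [DomainAssignment("P1", "PF00001", 1, 50),
             DomainAssignment("P1", "PF00001", 60, 110)],
        )
        assert m.pfam_totals == {"PF00001": 1}

    def test_matches_brute_force_oracle_on_random_corpora(self):
        rng = random.Random(20)
        comps = ["nucleus", "Golgi apparatus", "vacuole"]
        for _ in range(25):
            n = rng.randint(1, 20)
            membership = {
                f"P{i}": set(rng.sample(comps, rng.randint(1, 3))) for i in range(n)
            }
            assignments = [
                DomainAssignment(f"P{rng.randrange(n)}", f"PF0000{rng.randint(1, 5)}")
                for _ in range(rng.randint(0, 3 * n))
            ]
            m = build_count_matrix(membership, assignments)
            counts, totals = brute_force_counts(membership, assignments)
            assert m.counts == counts and m.pfam_totals == totals


class TestRatioTable:
    def test_forced_by_definition(self):
        t = compute_ratio_table(PfamCountMatrix(
            counts={("PF00001", "nucleus"): 8, ("PF00001", "plasma membrane"): 2},
            pfam_totals={"PF00001": 10},
        ))
        assert t.ratio("PF00001", "nucleus") == 0.8
        assert t.ratio("PF00001", "plasma membrane") == 0.2

    def test_pure_pfam(self):
        t = compute_ratio_table(PfamCountMatrix(
            counts={("PF00001", "Golgi apparatus"): 7}, pfam_totals={"PF00001": 7}
        ))
        assert t.ratio("PF00001", "Golgi apparatus") == 1.0
        assert t.ratio("PF00001", "nucleus") == 0.0

    def test_rows_sum_to_one(self, lrr_table):
        for pfam in lrr_table.pfams:
            assert sum(lrr_table.ratio_vector(pfam).values()) == pytest.approx(1.0, abs=1e-9)

    def test_zero_total_pfam_absent(self):
        t = compute_ratio_table(PfamCountMatrix(
            counts={("PF00001", "nucleus"): 3}, pfam_totals={"PF00001": 3}
        ))
        assert "PF00002" not in t and t.ratio_vector("PF00002") is None

    def test_inconsistent_totals_rejected(self):
        with pytest.raises(ValueError):
            PfamCountMatrix(
                counts={("PF00001", "nucleus"): 3}, pfam_totals={"PF00001": 5}
            ).validate()

    def test_tsv_round_trip_bit_exact(self, tmp_path, lrr_table):
        p1, p2 = tmp_path / "t1.tsv", tmp_path / "t2.tsv"
        lrr_table.to_tsv(p1)
        again = PfamLocalizationTable.from_tsv(p1)
        assert again.ratios == lrr_table.ratios
        again.to_tsv(p2)
        assert p1.read_bytes() == p2.read_bytes()
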