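"""Proteome module: FASTA input, digestion vs brute force, localization."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from siteabpp.proteome import (
    CHYMOTRYPSIN,
    PEPSIN_NONSPECIFIC,
    TRYPSIN,
    DigestRule,
    ProteinRecord,
    ProteomeIndex,
    classify_uniqueness,
    digest,
    locate_peptide,
    read_fasta,
)

from conftest import RESIDUES, random_protein


def brute_force_digest(seq: str, rule: DigestRule) -> set[tuple[int, int]]:
    """Independent oracle: every substring with valid termini, allowed
    missed cleavages and length — O(n^2), fine for short proteins."""
    n = len(seq)
    out = set()
    for start in range(1, n + 1):
        for end in range(start, n + 1):
            if not (rule.length_min <= end - start + 1 <= rule.length_max):
                continue
            if start > 1 and seq[start - 2] not in rule.cleave_after:
                continue
            if end < n and seq[end - 1] not in rule.cleave_after:
                continue
            internal = sum(
                1 for i in range(start, end) if seq[i - 1] in rule.cleave_after
            )
            if internal > rule.max_missed:
                continue
            out.add((start, end))
    return out


def brute_force_locate(peptide: str, records) -> list[tuple[str, int]]:
    out = []
    for rec in records:
        start = rec.sequence.find(peptide)
        while start != -1:
            out.append((rec.accession, start + 1))
            start = rec.sequence.find(peptide, start + 1)
    return sorted(out)


class TestReadFasta:
    def test_single_record(self, tmp_path):
        path = tmp_path / "one.fasta"
        path.write_text(">sp|P1|T1 test GN=G1\nMKEVPVAIKTLK\n")
        index = read_fasta(path)
        assert len(index) == 1
        rec = index["P1"]
        assert rec.gene_symbol == "G1"
        assert len(rec.sequence) == 12

    def test_synthetic_proteome_roundtrip(self, tmp_path):
        from siteabpp.synthetic_data import generate_proteome, write_fasta

        records, flags = generate_proteome(n_proteins=50, seed=3)
        path = tmp_path / "syn.fasta"
        write_fasta(records, flags, path)
        index = read_fasta(path)
        assert len(index) == 50
        assert index.total_length == sum(len(r.sequence) for r in records)
        for rec in records:
            assert index[rec.accession].sequence == rec.sequence

    def test_duplicate_accession_rejected(self, tmp_path):
        path = tmp_path / "dup.fasta"
        path.write_text(">sp|P1|A\nMKKK\n>sp|P1|B\nMRRR\n")
        with pytest.raises(ValueError, match="P1"):
            read_fasta(path)

    def test_empty_file_rejected(self, tmp_path):
        path = tmp_path / "empty.fasta"
        path.write_text("")
        with pytest.raises(ValueError):
            read_fasta(path)

    def test_plain_header_first_token(self, tmp_path):
        path = tmp_path / "plain.fasta"
        path.write_text(">myprot some description\nMKAVLY\n")
        index = read_fasta(path)
        assert "myprot" in index


class TestDigest:
    @pytest.mark.parametrize("rule", [TRYPSIN, CHYMOTRYPSIN])
    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force(self, rule, seed):
        rng = np.random.default_rng(seed)
        seq = random_protein(rng, int(rng.integers(30, 200)))
        rec = ProteinRecord("X", "", seq)
        got = {(m.start, m.end) for m in digest(rec, rule)}
        assert got == brute_force_digest(seq, rule)

    def test_example_protein_all_lengths(self):
        rule = DigestRule("trypsin", frozenset("KR"), max_missed=2,
                          length_min=1, length_max=30)
        rec = ProteinRecord("X", "", "MKRAPKLDEW")
        got = {(m.start, m.end, m.peptide) for m in digest(rec, rule)}
        expected = {
            (m_start, m_end, rec.sequence[m_start - 1 : m_end])
            for m_start, m_end in brute_force_digest(rec.sequence, rule)
        }
        assert got == expected

    def test_no_cleavage_sites_whole_protein(self):
        rec = ProteinRecord("X", "", "AAAAAAA")
        matches = digest(rec, TRYPSIN)
        assert [(m.start, m.end) for m in matches] == [(1, 7)]

    def test_postconditions_hold(self):
        rng = np.random.default_rng(42)
        rec = ProteinRecord("X", "", random_protein(rng, 150))
        for m in digest(rec, TRYPSIN):
            assert rec.sequence[m.start - 1 : m.end] == m.peptide
            assert TRYPSIN.length_min <= len(m.peptide) <= TRYPSIN.length_max
            assert m.end == len(rec.sequence) or m.peptide[-1] in "KR"
            assert m.start == 1 or rec.sequence[m.start - 2] in "KR"
            internal = sum(1 for ch in m.peptide[:-1] if ch in "KR")
            assert internal <= TRYPSIN.max_missed

    def test_agrees_with_pyteomics_cleave(self):
        """Cross-check peptide sets against an independent library digester
        (positions are ours; sequence sets must agree)."""
        pyteomics_parser = pytest.importorskip("pyteomics.parser")
        rng = np.random.default_rng(8)
        seq = random_protein(rng, 180)
        ours = {
            m.peptide
            for m in digest(ProteinRecord("X", "", seq), TRYPSIN)
        }
        theirs = {
            p
            for p in pyteomics_parser.cleave(
                seq, r"(?<=[KR])", missed_cleavages=2, min_length=5
            )
            if len(p) <= 30
        }
        assert ours == theirs

    def test_nonspecific_rule_refused(self):
        rec = ProteinRecord("X", "", "MKAVLY")
        with pytest.raises(ValueError, match="locate_peptide"):
            digest(rec, PEPSIN_NONSPECIFIC)

    def test_proline_suppression_flag(self):
        rule = DigestRule("trypsin", frozenset("KR"), max_missed=0,
                          length_min=1, length_max=30, proline_suppression=True)
        rec = ProteinRecord("X", "", "AAKPAAKAA")
        peptides = {m.peptide for m in digest(rec, rule)}
        # K before P is not cleaved; K at 7 is
        assert peptides == {"AAKPAAK", "AA"}


class TestLocate:
    def test_known_position(self):
        index = ProteomeIndex([ProteinRecord("A", "", "MKEVPVAIKTLKAGYTE")])
        (m,) = locate_peptide("EVPVAIKTLK", index)
        assert (m.accession, m.start, m.end) == ("A", 3, 12)

    def test_full_sequence_match(self):
        index = ProteomeIndex([ProteinRecord("A", "", "MKEVPVAIK")])
        (m,) = locate_peptide("MKEVPVAIK", index)
        assert (m.start, m.end) == (1, 9)

    def test_ordering_of_identical_records(self):
        index = ProteomeIndex(
            [ProteinRecord("C", "", "MKAVLYK"), ProteinRecord("B", "", "MKAVLYK")]
        )
        matches = locate_peptide("KAVLY", index)
        assert [m.accession for m in matches] == ["B", "C"]

    def test_isoleucine_leucine_distinct(self):
        index = ProteomeIndex([ProteinRecord("A", "", "MKAVLYK")])
        assert locate_peptide("KAVIY", index) == []

    def test_noncanonical_never_matches(self):
        index = ProteomeIndex([ProteinRecord("A", "", "MKAXVLYK")])
        assert locate_peptide("KAAVL", index) == []
        with pytest.raises(ValueError):
            locate_peptide("KAXVL", index)

    def test_no_cross_record_matches(self):
        index = ProteomeIndex(
            [ProteinRecord("A", "", "MKAVL"), ProteinRecord("B", "", "YKWML")]
        )
        assert locate_peptide("AVLYK", index) == []

    @settings(max_examples=50, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_matches_naive_scan(self, seed):
        rng = np.random.default_rng(seed)
        records = [
            ProteinRecord(f"P{i}", "", random_protein(rng, int(rng.integers(20, 80))))
            for i in range(5)
        ]
        index = ProteomeIndex(records)
        rec = records[int(rng.integers(5))]
        start = int(rng.integers(0, len(rec.sequence) - 6))
        peptide = rec.sequence[start : start + 6]
        if rng.random() < 0.3:  # mutate to mostly-miss queries too
            pos = int(rng.integers(6))
            peptide = peptide[:pos] + rng.choice(list(RESIDUES)) + peptide[pos + 1 :]
        got = [(m.accession, m.start) for m in locate_peptide(peptide, index)]
        assert got == brute_force_locate(peptide, records)


class TestClassifyUniqueness:
    def test_three_way(self, small_index):
        unique = classify_uniqueness(locate_peptide("NPQRSTKYLWF", small_index))
        assert unique.status == "unique" and unique.accessions == ("C1",)
        shared = classify_uniqueness(locate_peptide("EVPVAIKTLK", small_index))
        assert shared.status == "shared" and shared.accessions == ("A1", "B1")
        assert classify_uniqueness([]).status == "unmatched"
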