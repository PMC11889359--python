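"""Proteome handling: FASTA input, rule-based in-silico digestion, and
exact-substring peptide localization.

Tryptic and chymotryptic peptides are enumerated from cleavage rules;
peptides from a nonspecific protease (pepsin is modeled this way) can start
and end anywhere, so they are never pre-enumerated — they are localized by
exact substring search against the whole proteome instead.

Coordinates are 1-based inclusive residue indices throughout, matching how
modification sites are reported in the field (e.g. "lysine 646" is position
646 of the canonical sequence).
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass, field

from Bio import SeqIO

__all__ = [
    "CANONICAL_RESIDUES",
    "ProteinRecord",
    "ProteomeIndex",
    "DigestRule",
    "PeptideMatch",
    "TRYPSIN",
    "CHYMOTRYPSIN",
    "PEPSIN_NONSPECIFIC",
    "read_fasta",
    "digest",
    "locate_peptide",
    "classify_uniqueness",
    "UniquenessCall",
]

#: The 20 canonical amino acids. X/U/B/Z may occur in database sequences but
#: never match any query peptide.
CANONICAL_RESIDUES = frozenset("ACDEFGHIKLMNPQRSTVWY")
EXTENDED_RESIDUES = CANONICAL_RESIDUES | frozenset("XUBZ")


@dataclass(frozen=True)
class ProteinRecord:
    """One database protein: accession, optional gene symbol, sequence."""

    accession: str
    gene_symbol: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"empty sequence for {self.accession!r}")
        bad = set(self.sequence) - EXTENDED_RESIDUES
        if bad:
            raise ValueError(
                f"{self.accession}: non-amino-acid characters {sorted(bad)}"
            )

    @property
    def label(self) -> str:
        """Display label: gene symbol when known, else the accession."""
        return self.gene_symbol or self.accession


@dataclass(frozen=True)
class PeptideMatch:
    """A peptide located within one protein (1-based inclusive span)."""

    accession: str
    start: int
    end: int
    peptide: str


class ProteomeIndex:
    """Protein records plus an exact-substring lookup over all sequences.

    The lookup concatenates every sequence with a separator character and
    scans with ``str.find``; results are identical to a naive per-record
    scan but a single pass over one string is considerably faster for the
    repeated queries issued during site mapping.
    """

    _SEP = "#"

    def __init__(self, records: list[ProteinRecord]):
        seen: set[str] = set()
        for rec in records:
            if rec.accession in seen:
                raise ValueError(f"duplicate accession {rec.accession!r}")
            seen.add(rec.accession)
        self.records: list[ProteinRecord] = list(records)
        self._by_accession = {r.accession: r for r in self.records}
        # offsets[i] = start of record i in the concatenated text
        offsets: list[int] = []
        parts: list[str] = []
        pos = 0
        for rec in self.records:
            offsets.append(pos)
            parts.append(rec.sequence)
            pos += len(rec.sequence) + 1
        self._offsets = offsets
        self._text = self._SEP.join(parts)

    def __len__(self) -> int:
        return len(self.records)

    def __getitem__(self, accession: str) -> ProteinRecord:
        return self._by_accession[accession]

    def __contains__(self, accession: str) -> bool:
        return accession in self._by_accession

    @property
    def total_length(self) -> int:
        return sum(len(r.sequence) for r in self.records)

    def locate(self, peptide: str) -> list[PeptideMatch]:
        """All exact occurrences of ``peptide``, sorted by (accession, start)."""
        if not peptide:
            raise ValueError("empty peptide")
        bad = set(peptide) - CANONICAL_RESIDUES
        if bad:
            raise ValueError(f"peptide contains non-canonical residues {sorted(bad)}")
        matches: list[PeptideMatch] = []
        pos = self._text.find(peptide)
        while pos != -1:
            i = bisect.bisect_right(self._offsets, pos) - 1
            rec = self.records[i]
            start = pos - self._offsets[i] + 1
            matches.append(
                PeptideMatch(rec.accession, start, start + len(peptide) - 1, peptide)
            )
            pos = self._text.find(peptide, pos + 1)
        matches.sort(key=lambda m: (m.accession, m.start))
        return matches


def _parse_header(header: str) -> tuple[str, str]:
    """Accession and gene symbol from a FASTA header line (no leading '>').

    Accession is taken from a UniProt-style ``db|ACC|NAME`` first token, or
    the first whitespace-delimited token otherwise; the gene symbol from a
    ``GN=`` attribute when present.
    """
    first = header.split()[0] if header.split() else header
    fields = first.split("|")
    accession = fields[1] if len(fields) >= 3 and fields[1] else first
    gene = ""
    for tok in header.split():
        if tok.startswith("GN="):
            gene = tok[3:]
            break
    return accession, gene


def read_fasta(path) -> ProteomeIndex:
    """Read a proteome FASTA into a :class:`ProteomeIndex`.

    Raises on an empty file and on duplicate accessions (a proteome database
    with repeated primary accessions would make site keys ambiguous).
    """
    records: list[ProteinRecord] = []
    for entry in SeqIO.parse(str(path), "fasta"):
        accession, gene = _parse_header(entry.description)
        records.append(ProteinRecord(accession, gene, str(entry.seq).upper()))
    if not records:
        raise ValueError(f"no FASTA records in {path}")
    return ProteomeIndex(records)


@dataclass(frozen=True)
class DigestRule:
    """Protease cleavage rule.

    ``cleave_after`` lists residues after which the backbone is cut
    (C-terminal side). An empty set means nonspecific digestion, which is
    handled by substring localization, never by enumeration.
    ``proline_suppression`` optionally skips cleavage before proline; the
    default is plain K/R (trypsin) / F/L/Y/W (chymotrypsin) cutting with no
    suppression.
    """

    name: str
    cleave_after: frozenset[str]
    max_missed: int = 2
    length_min: int = 5
    length_max: int = 30
    proline_suppression: bool = False

    def __post_init__(self) -> None:
        if self.length_min > self.length_max:
            raise ValueError("length_min > length_max")
        if self.max_missed < 0:
            raise ValueError("max_missed < 0")

    @property
    def nonspecific(self) -> bool:
        return not self.cleave_after


TRYPSIN = DigestRule("trypsin", frozenset("KR"), max_missed=2)
CHYMOTRYPSIN = DigestRule("chymotrypsin", frozenset("FLYW"), max_missed=2)
PEPSIN_NONSPECIFIC = DigestRule("pepsin_nonspecific", frozenset())


def digest(record: ProteinRecord, rule: DigestRule) -> list[PeptideMatch]:
    """Enumerate all fully-specific peptides of ``record`` under ``rule``.

    Every returned peptide has valid termini (its C-terminal residue is a
    cleavage residue or the protein C-terminus; the preceding residue is a
    cleavage residue or the protein N-terminus), at most ``rule.max_missed``
    internal cleavage sites, and a length within the rule's bounds. Output
    is ordered by (start, end).
    """
    if rule.nonspecific:
        raise ValueError(
            "nonspecific digestion is not enumerable; use locate_peptide to "
            "localize nonspecific peptides"
        )
    seq = record.sequence
    n = len(seq)
    # cut points in inter-residue coordinates: 0 = N-terminus, n = C-terminus
    cuts = [0]
    for i in range(n - 1):
        if seq[i] in rule.cleave_after:
            if rule.proline_suppression and seq[i + 1] == "P":
                continue
            cuts.append(i + 1)
    cuts.append(n)
    out: list[PeptideMatch] = []
    for a in range(len(cuts) - 1):
        for b in range(a + 1, min(a + 2 + rule.max_missed, len(cuts))):
            start, end = cuts[a], cuts[b]
            length = end - start
            if length < rule.length_min or length > rule.length_max:
                continue
            out.append(
                PeptideMatch(record.accession, start + 1, end, seq[start:end])
            )
    out.sort(key=lambda m: (m.start, m.end))
    return out


def locate_peptide(peptide: str, index: ProteomeIndex) -> list[PeptideMatch]:
    """Exact-substring occurrences of ``peptide`` across the whole proteome.

    I and L are distinct characters; non-canonical database residues
    (X/U/B/Z) never match. No match returns an empty list, not an error.
    """
    return index.locate(peptide)


@dataclass(frozen=True)
class UniquenessCall:
    """Outcome of peptide-to-protein assignment: unique / shared / unmatched."""

    status: str  # "unique" | "shared" | "unmatched"
    accessions: tuple[str, ...] = field(default=())


def classify_uniqueness(matches: list[PeptideMatch]) -> UniquenessCall:
    """Classify localization results by how many proteins carry the peptide."""
    accs = tuple(sorted({m.accession for m in matches}))
    if not accs:
        return UniquenessCall("unmatched")
    if len(accs) == 1:
        return UniquenessCall("unique", accs)
    return UniquenessCall("shared", accs)
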