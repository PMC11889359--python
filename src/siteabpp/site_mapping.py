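"""Map probe-modified peptides to protein residues and cluster them into
binding-site groups.

A covalent probe leaves a constant-mass adduct on the labeled residue; the
search engine reports the modified peptide with the adduct position inside
the peptide. Localizing the peptide in the proteome and adding the in-peptide
offset yields the exact modified residue. Peptides from different proteases
that resolve to the same (protein, residue) are pooled into one binding-site
group; a peptide whose sequence occurs in several proteins (homologous
ATP pockets are common among kinases) forms a multi-protein site group
rather than being arbitrarily assigned to one member.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field

import pandas as pd

from .proteome import ProteomeIndex, classify_uniqueness, locate_peptide

__all__ = [
    "XO44_PHOSPHONATE_MASS",
    "ModificationSpec",
    "XO44_PHOSPHONATE",
    "ModifiedPeptideRecord",
    "SiteMember",
    "BindingSiteGroup",
    "parse_assigned_modifications",
    "map_modification_site",
    "cluster_to_sites",
    "merge_protease_runs",
]

logger = logging.getLogger(__name__)

#: Monoisotopic delta mass (Da) of the clicked probe-phosphonate adduct.
XO44_PHOSPHONATE_MASS = 754.2532

#: Mass tolerance when deciding whether a reported variable modification is
#: the probe adduct (search engines print deltas to 4 decimals).
MASS_MATCH_TOL = 0.01


@dataclass(frozen=True)
class ModificationSpec:
    """A variable modification: name, delta mass, and allowed residues."""

    name: str
    delta_mass: float
    allowed_residues: frozenset[str]

    def __post_init__(self) -> None:
        if self.delta_mass <= 0:
            raise ValueError("delta_mass must be positive")
        if not self.allowed_residues:
            raise ValueError("allowed_residues must be non-empty")

    def matches_mass(self, delta: float) -> bool:
        return abs(delta - self.delta_mass) <= MASS_MATCH_TOL


#: The probe adduct. The search may restrict it to lysine only or allow
#: tyrosine as well; both residue sets are supported, K+Y is the default.
XO44_PHOSPHONATE = ModificationSpec(
    "XO44-phosphonate", XO44_PHOSPHONATE_MASS, frozenset("KY")
)


@dataclass(eq=False)
class ModifiedPeptideRecord:
    """One quantified peptidoform from a modified-peptide table.

    ``mod_positions`` holds (1-based index within the peptide, delta mass)
    pairs; ``intensities`` maps sample id to a positive intensity — missing
    values are simply absent from the map. Identity (not value) equality is
    deliberate: two table rows with identical fields are distinct evidence.
    """

    peptide: str
    mod_positions: tuple[tuple[int, float], ...]
    assigned_accession: str = ""
    protease: str = ""
    intensities: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for pos, _ in self.mod_positions:
            if not 1 <= pos <= len(self.peptide):
                raise ValueError(
                    f"modification position {pos} outside peptide "
                    f"{self.peptide!r} (length {len(self.peptide)})"
                )

    def probe_positions(self, spec: ModificationSpec = XO44_PHOSPHONATE) -> list[int]:
        """In-peptide positions carrying the probe adduct."""
        out = []
        for pos, mass in self.mod_positions:
            if spec.matches_mass(mass):
                if self.peptide[pos - 1] not in spec.allowed_residues:
                    raise ValueError(
                        f"probe adduct on {self.peptide[pos - 1]!r} at position "
                        f"{pos} of {self.peptide!r}; allowed residues are "
                        f"{sorted(spec.allowed_residues)}"
                    )
                out.append(pos)
        return out


@dataclass(frozen=True, order=True)
class SiteMember:
    """One (protein, residue) position of a binding site."""

    accession: str
    residue: int
    letter: str


@dataclass(eq=False)
class BindingSiteGroup:
    """A binding site (or multi-protein site group for shared peptides).

    ``members`` is the sorted tuple of (accession, residue, letter)
    positions consistent with the member peptides; a unique site has exactly
    one member. ``peptides`` carries the evidence with protease provenance.
    """

    members: tuple[SiteMember, ...]
    peptides: list[ModifiedPeptideRecord] = field(default_factory=list)
    unique: bool = True
    multi_probe: bool = False

    @property
    def key(self) -> tuple[tuple[str, int], ...]:
        return tuple((m.accession, m.residue) for m in self.members)

    @property
    def proteases(self) -> tuple[str, ...]:
        return tuple(sorted({p.protease for p in self.peptides}))

    def site_id(self, index: ProteomeIndex | None = None) -> str:
        """Display label, ``GENE;K646`` style; members joined with ``|``."""
        parts = []
        for m in self.members:
            label = m.accession
            if index is not None and m.accession in index:
                label = index[m.accession].label
            parts.append(f"{label};{m.letter}{m.residue}")
        return "|".join(parts)


_MOD_TOKEN = re.compile(r"^(?:(\d+)([A-Z])|([NC]-term))\(([-\d.]+)\)$")


def parse_assigned_modifications(text: str) -> tuple[tuple[int, float], ...]:
    """Parse an assigned-modifications string like ``"7K(754.2532), 3M(15.9949)"``.

    Returns (position, delta mass) pairs. Terminal modifications (e.g.
    ``N-term(42.0106)``) are accepted and reported at position 0 / -1 by
    convention but are never probe adducts. Malformed tokens raise.
    """
    text = text.strip()
    if not text:
        return ()
    out: list[tuple[int, float]] = []
    for token in text.split(","):
        token = token.strip()
        if not token:
            continue
        m = _MOD_TOKEN.match(token)
        if m is None:
            raise ValueError(f"malformed modification token {token!r}")
        if m.group(3):  # terminal
            pos = 0 if m.group(3) == "N-term" else -1
        else:
            pos = int(m.group(1))
        out.append((pos, float(m.group(4))))
    return tuple(out)


def map_modification_site(
    rec: ModifiedPeptideRecord,
    index: ProteomeIndex,
    spec: ModificationSpec = XO44_PHOSPHONATE,
) -> list[SiteMember]:
    """Resolve a probe-modified peptide to exact proteome residues.

    For every occurrence of the peptide and every probe position within it,
    the modified residue is ``match.start + position − 1`` (both 1-based).
    The residue letter in the protein must equal the modified letter in the
    peptide — a mismatch means the index and the peptide table disagree and
    is an error, never silently accepted. An unmatched peptide returns an
    empty list; callers record it in an unmapped report.
    """
    probe_pos = rec.probe_positions(spec)
    if not probe_pos:
        raise ValueError(f"peptide {rec.peptide!r} carries no probe adduct")
    matches = locate_peptide(rec.peptide, index)
    out: list[SiteMember] = []
    for match in matches:
        for pos in probe_pos:
            residue = match.start + pos - 1
            letter = rec.peptide[pos - 1]
            db_letter = index[match.accession].sequence[residue - 1]
            if db_letter != letter:
                raise ValueError(
                    f"residue letter mismatch at {match.accession}:{residue}: "
                    f"peptide says {letter!r}, database says {db_letter!r}"
                )
            out.append(SiteMember(match.accession, residue, letter))
    return sorted(set(out))


def cluster_to_sites(
    records: list[ModifiedPeptideRecord],
    index: ProteomeIndex,
    spec: ModificationSpec = XO44_PHOSPHONATE,
) -> tuple[list[BindingSiteGroup], list[ModifiedPeptideRecord]]:
    """Cluster modified peptides into binding-site groups.

    Peptides resolving to the same (accession, residue) share one group. A
    shared peptide (several proteins carry its sequence) forms a group keyed
    by its full sorted member set, mirroring joint reporting of homologous
    sites, so groups are disjoint over peptides. A rare peptide with two
    probe adducts contributes fully to each adduct's group and both groups
    are flagged ``multi_probe``.

    Returns (groups sorted by key, unmapped records). When the search
    engine's assigned accession is absent from the localization result the
    localization wins and the conflict is logged.
    """
    by_key: dict[tuple, BindingSiteGroup] = {}
    unmapped: list[ModifiedPeptideRecord] = []
    for rec in records:
        probe_pos = rec.probe_positions(spec)
        matches = locate_peptide(rec.peptide, index)
        if not matches:
            unmapped.append(rec)
            continue
        call = classify_uniqueness(matches)
        if rec.assigned_accession and rec.assigned_accession not in call.accessions:
            logger.warning(
                "assigned accession %s for peptide %s not among localized "
                "proteins %s; using localization",
                rec.assigned_accession,
                rec.peptide,
                list(call.accessions),
            )
        multi = len(probe_pos) > 1
        for pos in probe_pos:
            members = []
            for match in matches:
                residue = match.start + pos - 1
                letter = rec.peptide[pos - 1]
                db_letter = index[match.accession].sequence[residue - 1]
                if db_letter != letter:
                    raise ValueError(
                        f"residue letter mismatch at {match.accession}:{residue}"
                    )
                members.append(SiteMember(match.accession, residue, letter))
            members = tuple(sorted(set(members)))
            key = tuple((m.accession, m.residue) for m in members)
            group = by_key.get(key)
            if group is None:
                group = BindingSiteGroup(members, unique=len(members) == 1)
                by_key[key] = group
            group.peptides.append(rec)
            group.multi_probe = group.multi_probe or multi
    groups = [by_key[k] for k in sorted(by_key)]
    return groups, unmapped


def merge_protease_runs(
    per_protease_groups: dict[str, list[BindingSiteGroup]],
    index: ProteomeIndex | None = None,
) -> pd.DataFrame:
    """Union site groups over protease runs with per-protease detection flags.

    Quantification stays separate per protease (dose-response fits are done
    per protease, never pooled); this table only records which protease(s)
    detected each site and with how many peptidoforms.

    Columns: site_id, members, unique, detected_<protease> (bool),
    n_peptides_<protease> (int), one row per distinct site key.
    """
    if not per_protease_groups:
        raise ValueError("at least one protease run is required")
    proteases = sorted(per_protease_groups)
    merged: dict[tuple, dict] = {}
    for protease in proteases:
        for group in per_protease_groups[protease]:
            row = merged.setdefault(
                group.key,
                {
                    "site_id": group.site_id(index),
                    "members": ";".join(
                        f"{m.accession}:{m.letter}{m.residue}" for m in group.members
                    ),
                    "unique": group.unique,
                    **{f"detected_{p}": False for p in proteases},
                    **{f"n_peptides_{p}": 0 for p in proteases},
                },
            )
            row[f"detected_{protease}"] = True
            row[f"n_peptides_{protease}"] = len(group.peptides)
    table = pd.DataFrame(
        [merged[k] for k in sorted(merged)],
        index=pd.Index([merged[k]["site_id"] for k in sorted(merged)], name="site"),
    )
    return table
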