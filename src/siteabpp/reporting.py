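"""Protease-complementarity summaries, kinase annotation, and export tables."""

from __future__ import annotations

import pandas as pd

__all__ = [
    "read_kinase_annotation",
    "overlap_counts",
    "annotate_kinases",
    "export_heatmap_table",
]


def read_kinase_annotation(path) -> pd.DataFrame:
    """Kinase annotation TSV: accession, gene, is_kinase (+ optional group).

    Lookups for accessions not in the table are treated as not-kinase.
    """
    ann = pd.read_csv(path, sep="\t")
    if "accession" not in ann.columns or "is_kinase" not in ann.columns:
        raise ValueError("kinase annotation needs 'accession' and 'is_kinase' columns")
    ann["is_kinase"] = ann["is_kinase"].astype(bool)
    return ann.set_index("accession")


def _site_accessions(members: str) -> list[str]:
    """Accessions from a merged-table 'members' cell ('ACC:K646;ACC2:K650')."""
    return [part.split(":")[0] for part in members.split(";") if part]


def _is_kinase_site(members: str, kinases: pd.DataFrame) -> bool:
    return any(
        acc in kinases.index and bool(kinases.loc[acc, "is_kinase"])
        for acc in _site_accessions(members)
    )


def overlap_counts(merged: pd.DataFrame, kinases: pd.DataFrame) -> pd.DataFrame:
    """Per-protease exclusive / intersection / union site counts, stratified
    into protein-kinase sites and other sites.

    ``merged`` is the combined site table with ``detected_<protease>``
    boolean columns; two proteases are summarized pairwise. The identity
    |A| + |B| − |A∩B| = |A∪B| is asserted for every stratum.
    """
    det_cols = [c for c in merged.columns if c.startswith("detected_")]
    proteases = [c.removeprefix("detected_") for c in det_cols]
    kin_mask = merged["members"].map(lambda m: _is_kinase_site(m, kinases))
    rows = []
    for stratum, mask in (("protein_kinase", kin_mask), ("other", ~kin_mask)):
        sub = merged[mask]
        row = {"stratum": stratum, "n_sites": len(sub)}
        for p in proteases:
            row[f"n_{p}"] = int(sub[f"detected_{p}"].sum())
        if len(proteases) == 2:
            a, b = proteases
            inter = int((sub[f"detected_{a}"] & sub[f"detected_{b}"]).sum())
            union = int((sub[f"detected_{a}"] | sub[f"detected_{b}"]).sum())
            row["n_both"] = inter
            row[f"n_{a}_only"] = row[f"n_{a}"] - inter
            row[f"n_{b}_only"] = row[f"n_{b}"] - inter
            row["n_union"] = union
            assert row[f"n_{a}"] + row[f"n_{b}"] - inter == union
        rows.append(row)
    return pd.DataFrame(rows).set_index("stratum")


def annotate_kinases(
    merged: pd.DataFrame, kinases: pd.DataFrame
) -> tuple[pd.DataFrame, dict]:
    """Add an ``is_kinase`` flag to the site table and tally proteins.

    A shared (multi-protein) site counts once in site tallies but expands to
    all member accessions for the distinct-protein tallies, each accession
    counted once. Returns (annotated table, summary dict with n_sites,
    n_kinase_sites, n_distinct_kinases, n_distinct_proteins).
    """
    table = merged.copy()
    table["is_kinase"] = table["members"].map(lambda m: _is_kinase_site(m, kinases))
    kinase_accs: set[str] = set()
    all_accs: set[str] = set()
    for members, is_kin in zip(table["members"], table["is_kinase"]):
        accs = _site_accessions(members)
        all_accs.update(accs)
        if is_kin:
            kinase_accs.update(
                a for a in accs
                if a in kinases.index and bool(kinases.loc[a, "is_kinase"])
            )
    summary = {
        "n_sites": len(table),
        "n_kinase_sites": int(table["is_kinase"].sum()),
        "n_distinct_kinases": len(kinase_accs),
        "n_distinct_proteins": len(all_accs),
    }
    return table, summary


def export_heatmap_table(
    condition_means: pd.DataFrame,
    annotated: pd.DataFrame,
    path=None,
) -> pd.DataFrame:
    """Site × condition mean-log2 table in heatmap layout.

    Rows: kinase sites first, then alphabetical within each block. Columns:
    per protease, DMSO first then ascending dose (the MultiIndex order of
    ``condition_means``). Cells with no surviving evidence are written
    ``ND`` (not detected) rather than left blank.
    """
    kin = annotated["is_kinase"] if "is_kinase" in annotated else None
    sites = list(condition_means.index)
    if kin is not None:
        order = sorted(sites, key=lambda s: (not bool(kin.get(s, False)), s))
    else:
        order = sorted(sites)
    out = condition_means.loc[order]
    flat = out.copy()
    flat.columns = [f"{p}_{('DMSO' if d == 0 else f'{d:g}nM')}" for p, d in out.columns]
    if path is not None:
        flat.round(4).fillna("ND").to_csv(path, sep="\t")
    return flat
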