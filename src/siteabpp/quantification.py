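"""Replicate-presence filtering and peptide-to-site intensity aggregation.

The quantitative input is one modified-peptide table per protease, with one
label-free intensity column per sample. Peptidoforms must be present (any
positive intensity) in at least two vehicle-control (DMSO) replicates of
their protease to enter the analysis; surviving peptidoform intensities are
then summed per binding site and per sample. Missing is never zero: a
site-sample with no surviving evidence stays missing and is excluded from
downstream fits rather than imputed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .site_mapping import (
    BindingSiteGroup,
    ModifiedPeptideRecord,
    parse_assigned_modifications,
)

__all__ = [
    "DMSO_TOKEN",
    "read_sample_annotation",
    "QuantTableColumns",
    "parse_quant_table",
    "filter_dmso_presence",
    "SiteQuantMatrix",
    "aggregate_to_sites",
    "summarize_condition_means",
]

DMSO_TOKEN = "DMSO"


def _condition_to_dose(condition: str) -> float:
    """Dose in nM for a condition token; the vehicle control is dose 0."""
    if str(condition).strip().upper() == DMSO_TOKEN:
        return 0.0
    dose = float(condition)
    if dose < 0:
        raise ValueError(f"negative dose {condition!r}")
    return dose


def read_sample_annotation(path) -> pd.DataFrame:
    """Read the sample annotation TSV: sample_id, condition, replicate, protease.

    Returns a DataFrame indexed by sample_id with a numeric ``dose_nM``
    column (DMSO mapped to 0). (condition, replicate, protease) must be
    unique — two samples with the same design coordinates would be
    indistinguishable downstream.
    """
    ann = pd.read_csv(path, sep="\t", dtype={"condition": str})
    required = {"sample_id", "condition", "replicate", "protease"}
    missing = required - set(ann.columns)
    if missing:
        raise ValueError(f"annotation lacks columns {sorted(missing)}")
    ann = ann.set_index("sample_id", verify_integrity=True)
    ann["dose_nM"] = [_condition_to_dose(c) for c in ann["condition"]]
    dup = ann.duplicated(subset=["condition", "replicate", "protease"])
    if dup.any():
        raise ValueError(
            f"duplicate (condition, replicate, protease): "
            f"{ann.index[dup].tolist()}"
        )
    return ann


@dataclass(frozen=True)
class QuantTableColumns:
    """Column naming of the modified-peptide table.

    Defaults follow the search-engine dialect: per-sample intensity columns
    are either named exactly by the sample id or ``"<sample_id> Intensity"``.
    """

    peptide: str = "Peptide Sequence"
    modifications: str = "Assigned Modifications"
    protein: str = "Protein ID"
    intensity_suffix: str = " Intensity"


def parse_quant_table(
    path,
    annotation: pd.DataFrame,
    protease: str,
    columns: QuantTableColumns = QuantTableColumns(),
) -> tuple[list[ModifiedPeptideRecord], list[dict]]:
    """Parse one protease's modified-peptide TSV into peptidoform records.

    Zero intensities become missing (label-free software writes 0 for not
    quantified); negative intensities are rejected. Rows with a malformed
    modification string are reported row-by-row, not silently dropped:
    returns (records, row_errors). ``path`` may also be an already-loaded
    DataFrame in the same dialect.
    """
    table = path if isinstance(path, pd.DataFrame) else pd.read_csv(path, sep="\t")
    for col in (columns.peptide, columns.modifications):
        if col not in table.columns:
            raise ValueError(f"quantification table lacks column {col!r}")
    sample_ids = set(annotation.index[annotation["protease"] == protease])
    col_to_sample: dict[str, str] = {}
    for col in table.columns:
        candidate = col.removesuffix(columns.intensity_suffix)
        if candidate in sample_ids:
            col_to_sample[col] = candidate
        elif col.endswith(columns.intensity_suffix):
            raise ValueError(f"intensity column {col!r} matches no annotated sample")
    if not col_to_sample:
        raise ValueError(f"no intensity columns for protease {protease!r}")
    records: list[ModifiedPeptideRecord] = []
    errors: list[dict] = []
    for row_no, row in enumerate(table.itertuples(index=False), start=2):
        row = dict(zip(table.columns, row))
        try:
            mods = parse_assigned_modifications(
                "" if pd.isna(row[columns.modifications]) else str(row[columns.modifications])
            )
            intensities: dict[str, float] = {}
            for col, sample in col_to_sample.items():
                value = row[col]
                if pd.isna(value):
                    continue
                value = float(value)
                if value < 0:
                    raise ValueError(f"negative intensity {value} in {col!r}")
                if value > 0:
                    intensities[sample] = value
            protein = row.get(columns.protein, "")
            records.append(
                ModifiedPeptideRecord(
                    peptide=str(row[columns.peptide]).strip(),
                    mod_positions=mods,
                    assigned_accession="" if pd.isna(protein) else str(protein),
                    protease=protease,
                    intensities=intensities,
                )
            )
        except ValueError as exc:
            errors.append({"line": row_no, "error": str(exc)})
    return records, errors


def filter_dmso_presence(
    records: list[ModifiedPeptideRecord],
    annotation: pd.DataFrame,
    min_present: int = 2,
) -> list[ModifiedPeptideRecord]:
    """Keep peptidoforms present in ≥ ``min_present`` DMSO replicates.

    Presence means a non-missing (positive) intensity in a vehicle-control
    sample of the peptidoform's own protease. The filter is applied per
    peptidoform, not per site; a site survives if any member peptidoform
    survives. Idempotent by construction.
    """
    dmso = annotation[annotation["dose_nM"] == 0]
    dmso_by_protease: dict[str, set[str]] = {
        p: set(sub.index) for p, sub in dmso.groupby("protease")
    }
    for protease in {r.protease for r in records}:
        n_ctrl = len(dmso_by_protease.get(protease, ()))
        if n_ctrl < min_present:
            raise ValueError(
                f"protease {protease!r} has {n_ctrl} DMSO samples; "
                f"at least {min_present} are required for the presence filter"
            )
    kept = []
    for rec in records:
        ctrl = dmso_by_protease[rec.protease]
        n_present = sum(1 for s in rec.intensities if s in ctrl)
        if n_present >= min_present:
            kept.append(rec)
    return kept


@dataclass
class SiteQuantMatrix:
    """Site × sample summed intensities with a derived log2 layer.

    ``intensity`` holds raw summed intensities (NaN = missing); ``log2`` is
    log2 of the positive sums. Row index: site id; columns: sample ids.
    """

    intensity: pd.DataFrame
    groups: dict[str, BindingSiteGroup]

    @property
    def log2(self) -> pd.DataFrame:
        with np.errstate(divide="ignore", invalid="ignore"):
            return np.log2(self.intensity.where(self.intensity > 0))

    def median_centered(self) -> pd.DataFrame:
        """Optional per-sample median centering of the log2 layer (off the
        default path; upstream label-free normalization is trusted as-is)."""
        log2 = self.log2
        return log2 - log2.median(axis=0, skipna=True)


def aggregate_to_sites(
    records: list[ModifiedPeptideRecord],
    groups: list[BindingSiteGroup],
    annotation: pd.DataFrame,
    index=None,
) -> SiteQuantMatrix:
    """Sum member-peptidoform intensities per site and sample.

    Only peptidoforms in ``records`` (i.e. the filtered set) contribute;
    missing peptide terms contribute nothing and an all-missing site-sample
    stays missing (NaN). Conservation holds by construction: per sample, the
    matrix total equals the total retained intensity of single-site peptides
    (a peptide in a shared group belongs to exactly that one group).
    """
    retained = set(map(id, records))
    samples = list(annotation.index)
    rows: dict[str, dict[str, float]] = {}
    site_groups: dict[str, BindingSiteGroup] = {}
    for group in groups:
        peptides = [p for p in group.peptides if id(p) in retained]
        if not peptides:
            continue
        site = group.site_id(index)
        sums: dict[str, float] = {}
        for pep in peptides:
            for sample, value in pep.intensities.items():
                sums[sample] = sums.get(sample, 0.0) + value
        rows[site] = sums
        site_groups[site] = group
    matrix = pd.DataFrame.from_dict(rows, orient="index", dtype=float)
    matrix = matrix.reindex(columns=samples).sort_index()
    matrix.index.name = "site"
    matrix.columns.name = "sample"
    _assert_conservation(records, groups, retained, matrix)
    return SiteQuantMatrix(matrix, site_groups)


def _assert_conservation(records, groups, retained, matrix) -> None:
    """Per-sample mass conservation between retained peptides and the matrix.

    Multi-probe peptides (two adducts, hence membership in two groups) are
    deliberately double-counted on the matrix side, so they are excluded
    from the identity.
    """
    grouped = set()
    multi = set()
    for g in groups:
        for p in g.peptides:
            if g.multi_probe and len(p.probe_positions()) > 1:
                multi.add(id(p))
            grouped.add(id(p))
    expected: dict[str, float] = {}
    for rec in records:
        if id(rec) in grouped and id(rec) not in multi:
            for sample, value in rec.intensities.items():
                expected[sample] = expected.get(sample, 0.0) + value
    if multi:
        return  # identity only stated for single-site peptides
    totals = matrix.sum(axis=0, skipna=True)
    for sample in matrix.columns:
        want = expected.get(sample, 0.0)
        got = float(totals.get(sample, 0.0))
        if not math.isclose(want, got, rel_tol=1e-9, abs_tol=1e-6):
            raise AssertionError(
                f"intensity conservation violated in sample {sample}: "
                f"peptides sum to {want}, matrix to {got}"
            )


def summarize_condition_means(
    matrix: SiteQuantMatrix, annotation: pd.DataFrame
) -> pd.DataFrame:
    """Mean log2 site intensity per (protease, dose), replicates averaged.

    Missing values are excluded from the mean (never treated as zero).
    Columns are a (protease, dose_nM) MultiIndex ordered protease-
    alphabetically, then DMSO (dose 0) first and doses ascending — the
    layout of a dose-response heatmap.
    """
    log2 = matrix.log2
    pieces: dict[tuple[str, float], pd.Series] = {}
    for (protease, dose), sub in annotation.groupby(["protease", "dose_nM"]):
        cols = [s for s in sub.index if s in log2.columns]
        if not cols:
            continue
        pieces[(protease, float(dose))] = log2[cols].mean(axis=1, skipna=True)
    ordered = sorted(pieces)
    out = pd.DataFrame({k: pieces[k] for k in ordered})
    out.columns = pd.MultiIndex.from_tuples(ordered, names=["protease", "dose_nM"])
    return out
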