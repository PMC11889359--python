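"""End-to-end orchestration: tables in, site matrix and fit results out.

Thin glue over the stage modules; every step is available separately for
interactive use.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .dose_response import fit_all_sites
from .proteome import ProteomeIndex
from .quantification import (
    SiteQuantMatrix,
    aggregate_to_sites,
    filter_dmso_presence,
    parse_quant_table,
    summarize_condition_means,
)
from .site_mapping import (
    ModifiedPeptideRecord,
    cluster_to_sites,
    merge_protease_runs,
)

__all__ = ["PipelineResult", "run_pipeline"]


@dataclass
class PipelineResult:
    """Everything a pipeline run produces."""

    records: list[ModifiedPeptideRecord]
    retained: list[ModifiedPeptideRecord]
    merged_sites: pd.DataFrame
    matrix: SiteQuantMatrix
    condition_means: pd.DataFrame
    fits: pd.DataFrame
    unmapped: list[ModifiedPeptideRecord] = field(default_factory=list)
    parse_errors: list[dict] = field(default_factory=list)

    @property
    def site_keys(self) -> dict[str, tuple]:
        """Result site id → (accession, residue) member key."""
        return {site: g.key for site, g in self.matrix.groups.items()}


def run_pipeline(
    index: ProteomeIndex,
    tables: dict,
    annotation: pd.DataFrame,
    min_present: int = 2,
    label_with_genes: bool = False,
    **fit_kwargs,
) -> PipelineResult:
    """Run mapping → filtering → aggregation → per-protease 4PL fitting.

    ``tables`` maps protease name to a quantification table (path or
    DataFrame). ``label_with_genes`` switches site ids from accession-based
    to gene-symbol labels.
    """
    label_index = index if label_with_genes else None
    records: list[ModifiedPeptideRecord] = []
    errors: list[dict] = []
    for protease, table in sorted(tables.items()):
        recs, errs = parse_quant_table(table, annotation, protease)
        records.extend(recs)
        errors.extend({"protease": protease, **e} for e in errs)

    per_protease = {}
    for protease in sorted(tables):
        sub = [r for r in records if r.protease == protease]
        groups_p, _ = cluster_to_sites(sub, index)
        per_protease[protease] = groups_p
    merged = merge_protease_runs(per_protease, label_index)

    groups, unmapped = cluster_to_sites(records, index)
    retained = filter_dmso_presence(records, annotation, min_present=min_present)
    matrix = aggregate_to_sites(retained, groups, annotation, label_index)
    cond_means = summarize_condition_means(matrix, annotation)
    fits = fit_all_sites(matrix, annotation, **fit_kwargs)
    return PipelineResult(
        records, retained, merged, matrix, cond_means, fits,
        unmapped=unmapped, parse_errors=errors,
    )
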