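"""Quantification: table parsing, DMSO presence filter, site aggregation."""

import io

import numpy as np
import pandas as pd
import pytest

from siteabpp.quantification import (
    aggregate_to_sites,
    filter_dmso_presence,
    parse_quant_table,
    read_sample_annotation,
    summarize_condition_means,
)
from siteabpp.site_mapping import (
    XO44_PHOSPHONATE_MASS,
    ModifiedPeptideRecord,
    cluster_to_sites,
)

PROBE = XO44_PHOSPHONATE_MASS


def make_annotation(n_rep=3, doses=(0.0, 10.0, 100.0), protease="trypsin"):
    rows = []
    for dose in doses:
        cond = "DMSO" if dose == 0 else f"{dose:g}"
        for rep in range(1, n_rep + 1):
            rows.append(
                {
                    "sample_id": f"{protease}_{cond}_r{rep}",
                    "condition": cond,
                    "replicate": rep,
                    "protease": protease,
                    "dose_nM": dose,
                }
            )
    return pd.DataFrame(rows).set_index("sample_id")


def make_record(peptide, pos, intensities, protease="trypsin"):
    return ModifiedPeptideRecord(
        peptide, ((pos, PROBE),), protease=protease, intensities=intensities
    )


class TestAnnotation:
    def test_roundtrip_and_dose(self, tmp_path):
        path = tmp_path / "samples.tsv"
        make_annotation().reset_index().drop(columns="dose_nM").to_csv(
            path, sep="\t", index=False
        )
        ann = read_sample_annotation(path)
        assert ann.loc["trypsin_DMSO_r1", "dose_nM"] == 0.0
        assert ann.loc["trypsin_100_r2", "dose_nM"] == 100.0

    def test_duplicate_design_rejected(self, tmp_path):
        ann = make_annotation().reset_index().drop(columns="dose_nM")
        ann.loc[1, "sample_id"] = "other"
        ann.loc[1, "condition"] = "DMSO"
        ann.loc[1, "replicate"] = 1
        path = tmp_path / "bad.tsv"
        ann.to_csv(path, sep="\t", index=False)
        with pytest.raises(ValueError, match="duplicate"):
            read_sample_annotation(path)


class TestParseQuantTable:
    def test_parse_identity_two_rows(self):
        ann = make_annotation(n_rep=2, doses=(0.0, 10.0))
        tsv = io.StringIO(
            "Peptide Sequence\tAssigned Modifications\tProtein ID\t"
            "trypsin_DMSO_r1\ttrypsin_DMSO_r2\ttrypsin_10_r1\ttrypsin_10_r2\n"
            f"EVPVAIKTLK\t7K({PROBE})\tP1\t100.0\t110.0\t0\t90.0\n"
            f"KAVLYEW\t1K({PROBE})\tP2\t55.5\t0\t44.4\t33.3\n"
        )
        records, errors = parse_quant_table(pd.read_csv(tsv, sep="\t"), ann, "trypsin")
        assert not errors
        r1, r2 = records
        assert r1.intensities == {
            "trypsin_DMSO_r1": 100.0, "trypsin_DMSO_r2": 110.0, "trypsin_10_r2": 90.0,
        }  # zero became missing
        assert r2.mod_positions == ((1, PROBE),)

    def test_negative_intensity_is_row_error(self):
        ann = make_annotation(n_rep=2, doses=(0.0,))
        table = pd.DataFrame(
            {
                "Peptide Sequence": ["KAVLYEW"],
                "Assigned Modifications": [f"1K({PROBE})"],
                "Protein ID": ["P1"],
                "trypsin_DMSO_r1": [-5.0],
                "trypsin_DMSO_r2": [1.0],
            }
        )
        records, errors = parse_quant_table(table, ann, "trypsin")
        assert not records and len(errors) == 1

    def test_unknown_intensity_column_rejected(self):
        ann = make_annotation(n_rep=2, doses=(0.0,))
        table = pd.DataFrame(
            {
                "Peptide Sequence": ["KAVLYEW"],
                "Assigned Modifications": [f"1K({PROBE})"],
                "mystery_sample Intensity": [5.0],
                "trypsin_DMSO_r1": [1.0],
                "trypsin_DMSO_r2": [1.0],
            }
        )
        with pytest.raises(ValueError, match="mystery"):
            parse_quant_table(table, ann, "trypsin")

    def test_generator_tables_round_trip(self, small_experiment):
        exp = small_experiment
        for protease, table in exp.tables.items():
            records, errors = parse_quant_table(table, exp.annotation, protease)
            assert not errors
            assert len(records) == len(table)
            # every positive cell came through; zeros are missing
            for rec, (_, row) in zip(records, table.iterrows()):
                for s in exp.annotation.index[
                    exp.annotation["protease"] == protease
                ]:
                    if row[s] > 0:
                        assert rec.intensities[s] == row[s]
                    else:
                        assert s not in rec.intensities


def brute_force_presence(present: set[str], dmso: list[str], k: int) -> bool:
    return sum(1 for s in dmso if s in present) >= k


class TestDmsoFilter:
    def test_rule_examples(self):
        ann = make_annotation()
        dmso = [s for s in ann.index if ann.loc[s, "dose_nM"] == 0]
        only_one = make_record("KAVLYEW", 1, {dmso[0]: 5.0})
        two = make_record("KAVLYEW", 1, {dmso[0]: 5.0, dmso[2]: 3.0})
        kept = filter_dmso_presence([only_one, two], ann)
        assert kept == [two]

    @pytest.mark.parametrize("seed", range(3))
    def test_random_patterns_match_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        ann = make_annotation()
        dmso = [s for s in ann.index if ann.loc[s, "dose_nM"] == 0]
        records = []
        for _ in range(100):
            present = {s for s in ann.index if rng.random() < 0.5}
            records.append(
                make_record("KAVLYEW", 1, {s: 1.0 for s in present})
            )
        kept = filter_dmso_presence(records, ann)
        expected = [
            r
            for r in records
            if brute_force_presence(set(r.intensities), dmso, 2)
        ]
        assert kept == expected

    def test_idempotent(self):
        rng = np.random.default_rng(1)
        ann = make_annotation()
        records = [
            make_record("KAVLYEW", 1,
                        {s: 1.0 for s in ann.index if rng.random() < 0.5})
            for _ in range(50)
        ]
        once = filter_dmso_presence(records, ann)
        assert filter_dmso_presence(once, ann) == once

    def test_too_few_dmso_samples_rejected(self):
        ann = make_annotation(n_rep=1)
        with pytest.raises(ValueError, match="DMSO"):
            filter_dmso_presence([make_record("KAVLYEW", 1, {})], ann)


class TestAggregate:
    def _setup(self):
        from siteabpp.proteome import ProteinRecord, ProteomeIndex

        index = ProteomeIndex([ProteinRecord("A", "", "MMMMEVPVAIKTLKAGYTEWWW")])
        ann = make_annotation(n_rep=2, doses=(0.0, 10.0))
        r1 = make_record("EVPVAIKTLK", 7,
                         {"trypsin_DMSO_r1": 100.0, "trypsin_DMSO_r2": 80.0,
                          "trypsin_10_r1": 50.0})
        r2 = make_record("IKTLKAGYTE", 2,
                         {"trypsin_DMSO_r1": 50.0, "trypsin_DMSO_r2": 70.0})
        groups, _ = cluster_to_sites([r1, r2], index)
        return index, ann, [r1, r2], groups

    def test_sums_and_missing(self):
        index, ann, records, groups = self._setup()
        matrix = aggregate_to_sites(records, groups, ann)
        row = matrix.intensity.loc["A;K11"]
        assert row["trypsin_DMSO_r1"] == 150.0
        assert row["trypsin_DMSO_r2"] == 150.0
        assert row["trypsin_10_r1"] == 50.0  # one peptide missing: sum of rest
        assert np.isnan(row["trypsin_10_r2"])  # all missing stays missing

    def test_log2_layer(self):
        index, ann, records, groups = self._setup()
        matrix = aggregate_to_sites(records, groups, ann)
        assert matrix.log2.loc["A;K11", "trypsin_DMSO_r1"] == pytest.approx(
            np.log2(150.0)
        )

    def test_spreadsheet_recomputation_full_table(self, small_experiment):
        """Matrix equals an independent per-sample recomputation over the
        generator's truth plan."""
        exp = small_experiment
        index = exp.manifest.index()
        records = []
        for protease, table in exp.tables.items():
            recs, _ = parse_quant_table(table, exp.annotation, protease)
            records.extend(recs)
        records = filter_dmso_presence(records, exp.annotation)
        groups, _ = cluster_to_sites(records, index)
        matrix = aggregate_to_sites(records, groups, exp.annotation)
        # independent recomputation: group by mapped site key via raw loop
        by_site: dict[str, dict[str, float]] = {}
        for rec in records:
            from siteabpp.site_mapping import map_modification_site

            members = tuple(sorted(map_modification_site(rec, index)))
            site = "|".join(f"{m.accession};{m.letter}{m.residue}" for m in members)
            acc = by_site.setdefault(site, {})
            for s, v in rec.intensities.items():
                acc[s] = acc.get(s, 0.0) + v
        assert set(by_site) == set(matrix.intensity.index)
        for site, sums in by_site.items():
            for s, v in sums.items():
                assert matrix.intensity.loc[site, s] == pytest.approx(v, rel=1e-12)

    def test_row_order_invariance(self):
        index, ann, records, groups = self._setup()
        m1 = aggregate_to_sites(records, groups, ann)
        groups_r, _ = cluster_to_sites(records[::-1], index)
        m2 = aggregate_to_sites(records[::-1], groups_r, ann)
        pd.testing.assert_frame_equal(m1.intensity, m2.intensity)


class TestConditionMeans:
    def test_mean_and_single_replicate(self):
        index, ann, records, groups = self._make()
        matrix = aggregate_to_sites(records, groups, ann)
        means = summarize_condition_means(matrix, ann)
        log2 = matrix.log2.loc["A;K11"]
        expected = np.mean([log2["trypsin_DMSO_r1"], log2["trypsin_DMSO_r2"]])
        assert means.loc["A;K11", ("trypsin", 0.0)] == pytest.approx(expected)
        # single surviving replicate at dose 10: the mean is that value
        assert means.loc["A;K11", ("trypsin", 10.0)] == pytest.approx(
            log2["trypsin_10_r1"]
        )

    def test_dose_ordering_dmso_first(self):
        index, ann, records, groups = self._make()
        matrix = aggregate_to_sites(records, groups, ann)
        means = summarize_condition_means(matrix, ann)
        doses = [d for _, d in means.columns]
        assert doses == sorted(doses)
        assert doses[0] == 0.0

    _make = TestAggregate._setup
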