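"""Omics tables: parsing, common-gene restriction, GPR mapping, thresholds."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ymcflux.errors import OmicsError
from ymcflux.gpr import UNMAPPED
from ymcflux.model import MetabolicModel, Metabolite, Reaction
from ymcflux.gpr import parse_gpr
from ymcflux.omics import (
    OmicsTable,
    average_replicates,
    log_transform,
    map_sample_to_reactions,
    percentile_threshold,
    read_omics,
    restrict_to_common_genes,
)


def _write_tsv(tmp_path, text, name="omics.tsv"):
    path = tmp_path / name
    path.write_text(text)
    return path


class TestReadOmics:
    def test_small_table(self, tmp_path):
        path = _write_tsv(tmp_path, "gene_id\ts1\ts2\ng1\t1.0\t2.0\ng2\t3.5\tNA\ng3\t0\t4\n")
        table = read_omics(path)
        assert table.genes == ["g1", "g2", "g3"]
        assert table.sample_values("s1") == {"g1": 1.0, "g2": 3.5, "g3": 0.0}
        assert table.sample_values("s2") == {"g1": 2.0, "g3": 4.0}  # NA omitted

    def test_header_only_file_is_an_empty_table(self, tmp_path):
        table = read_omics(_write_tsv(tmp_path, "gene_id\ts1\n"))
        assert table.genes == [] and table.samples == ["s1"]

    def test_duplicate_gene_rows_rejected(self, tmp_path):
        path = _write_tsv(tmp_path, "gene_id\ts1\ng1\t1\ng1\t2\n")
        with pytest.raises(OmicsError, match="g1"):
            read_omics(path)

    def test_non_numeric_cell_located(self, tmp_path):
        path = _write_tsv(tmp_path, "gene_id\ts1\ng1\t1\ng2\toops\n")
        with pytest.raises(OmicsError, match="g2"):
            read_omics(path)


class TestCommonGenes:
    def _table(self, genes):
        return OmicsTable(pd.DataFrame({"s1": range(len(genes))}, index=list(genes)))

    def test_intersection_preserving_values(self):
        a, b = self._table("abc"), self._table("bcd")
        ra, rb = restrict_to_common_genes(a, b)
        assert ra.genes == rb.genes == ["b", "c"]
        assert list(ra.data["s1"]) == [1, 2]  # original values untouched
        assert list(rb.data["s1"]) == [0, 1]

    def test_identical_gene_sets_are_a_no_op(self):
        a, b = self._table("abc"), self._table("abc")
        ra, rb = restrict_to_common_genes(a, b)
        assert ra.data.equals(a.data) and rb.data.equals(b.data)

    def test_disjoint_gene_sets_error(self):
        with pytest.raises(OmicsError, match="common"):
            restrict_to_common_genes(self._table("ab"), self._table("cd"))


class TestMapping:
    @pytest.fixture
    def mini_model(self):
        return MetabolicModel(
            id="mini",
            metabolites=[Metabolite("A")],
            reactions=[
                Reaction("R_and", {"A": 1}, 0, 1, gpr=parse_gpr("g1 and g2")),
                Reaction("R_or", {"A": 1}, 0, 1, gpr=parse_gpr("g1 or g2")),
                Reaction("R_none", {"A": -2}, 0, 1),
            ],
            objective_reaction="R_none",
        )

    def test_per_rule_semantics(self, mini_model):
        table = OmicsTable(pd.DataFrame({"s": {"g1": 1.0, "g2": 4.0}}))
        vector = map_sample_to_reactions(mini_model, table, "s")
        assert vector["R_and"] == 1.0
        assert vector["R_or"] == 4.0
        assert vector["R_none"] is UNMAPPED

    def test_unknown_sample(self, mini_model):
        table = OmicsTable(pd.DataFrame({"s": {"g1": 1.0}}))
        with pytest.raises(KeyError, match="nope"):
            map_sample_to_reactions(mini_model, table, "nope")

    def test_unmapped_iff_gpr_unmapped(self, toy_model, default_spec):
        from ymcflux.synthetic import simulate_omics

        rna, _ = simulate_omics(toy_model, default_spec)
        vector = map_sample_to_reactions(toy_model, rna, rna.samples[0])
        for rxn in toy_model.reactions:
            assert (vector[rxn.id] is UNMAPPED) == rxn.gpr.is_empty


class TestPercentile:
    @pytest.mark.parametrize(
        "values, pct, expected",
        [
            ([0, 10], 50, 5.0),
            ([5, 5, 5], 30, 5.0),
            ([1, 2, 3, 4], 25, 1.75),  # linear interpolation between closest ranks
        ],
    )
    def test_examples(self, values, pct, expected):
        assert percentile_threshold(values, pct) == pytest.approx(expected)

    def test_unmapped_excluded(self):
        assert percentile_threshold([None, 2.0, None, 4.0], 50) == pytest.approx(3.0)

    def test_all_unmapped_errors(self):
        with pytest.raises(OmicsError):
            percentile_threshold([None, None], 25)

    @given(
        values=st.lists(st.floats(0, 1e3), min_size=1, max_size=30),
        p1=st.floats(0, 100),
        p2=st.floats(0, 100),
    )
    @settings(max_examples=100, derandomize=True, deadline=None)
    def test_monotone_in_pct_and_bounded(self, values, p1, p2):
        lo, hi = min(p1, p2), max(p1, p2)
        assert percentile_threshold(values, lo) <= percentile_threshold(values, hi)
        assert min(values) <= percentile_threshold(values, lo) <= max(values)


class TestTransforms:
    def test_log2_with_pseudocount(self):
        table = OmicsTable(pd.DataFrame({"s": {"g1": 0.0, "g2": 1.0, "g3": 7.0}}))
        out = log_transform(table)
        assert list(out.data["s"]) == pytest.approx([0.0, 1.0, 3.0])

    def test_negative_values_rejected(self):
        table = OmicsTable(pd.DataFrame({"s": {"g1": -1.0}}))
        with pytest.raises(OmicsError, match="negative"):
            log_transform(table)

    def test_replicate_averaging_is_raw_scale_arithmetic_mean(self):
        table = OmicsTable(
            pd.DataFrame({"p1_r1": {"g": 2.0}, "p1_r2": {"g": 8.0}, "p2_r1": {"g": 3.0}})
        )
        out = average_replicates(table, {"p1": ["p1_r1", "p1_r2"], "p2": ["p2_r1"]})
        assert out.data.loc["g", "p1"] == pytest.approx(5.0)  # not the geometric mean
        assert out.data.loc["g", "p2"] == pytest.approx(3.0)
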