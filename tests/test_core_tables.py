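"""Data model, TSV round-trips, rarefaction and aggregation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import picodepth as pk
from picodepth import core_tables as ct


class TestOtuTableIO:
    def test_parse_well_formed(self, tmp_path):
        p = tmp_path / "t.tsv"
        p.write_text("otu_id\ts1\ts2\no1\t1\t2\no2\t0\t5\no3\t7\t0\n")
        t = pk.read_otu_table(p)
        assert t.shape == (3, 2)
        assert t.otu_ids == ["o1", "o2", "o3"]
        assert t.data.loc["o3", "s1"] == 7

    def test_duplicate_sample_header_rejected(self, tmp_path):
        p = tmp_path / "t.tsv"
        p.write_text("otu_id\ts1\ts1\no1\t1\t2\n")
        with pytest.raises(ValueError, match="s1"):
            pk.read_otu_table(p)

    def test_negative_and_fractional_cells_rejected(self, tmp_path):
        p = tmp_path / "t.tsv"
        p.write_text("otu_id\ts1\no1\t-3\n")
        with pytest.raises(ValueError, match="o1"):
            pk.read_otu_table(p)
        p.write_text("otu_id\ts1\no1\t2.5\n")
        with pytest.raises(ValueError, match="o1"):
            pk.read_otu_table(p)

    def test_round_trip_identity(self, tiny_table, tmp_path):
        p = tmp_path / "t.tsv"
        pk.write_otu_table(tiny_table, p)
        assert pk.read_otu_table(p) == tiny_table


class TestMetadata:
    @pytest.mark.parametrize(
        "oxygen,expected", [(1.5, True), (2.0, False), (6.3, False)]
    )
    def test_omz_is_strictly_below_threshold(
        self, tmp_path, make_sample_info, oxygen, expected
    ):
        meta = [make_sample_info("s1", "st1", 500.0, "mesopelagic", "rDNA",
                                 oxygen=oxygen)]
        p = tmp_path / "m.tsv"
        pk.write_metadata(meta, p)
        rec = pk.read_metadata(p)[0]
        assert rec.omz is expected

    def test_round_trip_preserves_content(self, tmp_path, make_sample_info):
        meta = [
            make_sample_info("a", "st1", 3.0, "surface", "rDNA"),
            make_sample_info("b", "st1", 500.0, "mesopelagic", "rRNA", oxygen=1.0,
                             dsl=True),
        ]
        meta[1].water_mass = {"AAIW": 0.25, "NADW": 0.75}
        meta[1].nutrients = {"NO3": 30.5}
        p = tmp_path / "m.tsv"
        pk.write_metadata(meta, p)
        back = pk.read_metadata(p)
        assert [m.sample_id for m in back] == ["a", "b"]
        assert back[1].water_mass == {"AAIW": 0.25, "NADW": 0.75}
        assert back[1].nutrients == {"NO3": 30.5}
        assert back[1].dsl and back[1].omz
        assert back[1].sublayer == "meso_upper"

    def test_missing_column_rejected(self, tmp_path):
        p = tmp_path / "m.tsv"
        p.write_text("sample_id\tstation\ns1\tst1\n")
        with pytest.raises(ValueError, match="required column"):
            pk.read_metadata(p)

    def test_layer_depth_consistency_enforced(self, make_sample_info):
        bad = make_sample_info("x", "st1", 3000.0, "surface", "rDNA")
        with pytest.raises(ValueError, match="inconsistent"):
            bad.validate()


class TestRarefy:
    def test_column_at_depth_unchanged(self):
        t = pk.OtuTable(pd.DataFrame({"s1": [4, 6]}, index=["a", "b"]))
        out = pk.rarefy(t, depth=10, seed=0)
        assert out.data["s1"].tolist() == [4, 6]

    def test_columns_sum_exactly_to_depth_and_short_samples_dropped(self):
        t = pk.OtuTable(
            pd.DataFrame({"s1": [90, 30], "s2": [5, 2], "s3": [40, 40]},
                         index=["a", "b"])
        )
        out = pk.rarefy(t, depth=20, seed=1)
        assert out.sample_ids == ["s1", "s3"]
        assert (out.column_sums() == 20).all()

    def test_default_depth_is_minimum_column_sum(self):
        t = pk.OtuTable(pd.DataFrame({"s1": [90, 30], "s2": [5, 2]}, index=["a", "b"]))
        out = pk.rarefy(t, seed=0)
        assert (out.column_sums() == 7).all()

    def test_deterministic_given_seed(self):
        t = pk.OtuTable(pd.DataFrame({"s1": [900, 100]}, index=["a", "b"]))
        a = pk.rarefy(t, depth=50, seed=42).data
        b = pk.rarefy(t, depth=50, seed=42).data
        assert a.equals(b)

    def test_hypergeometric_unbiasedness(self):
        """Mean subsampled count matches depth * (count / column sum)."""
        col = np.array([500, 300, 100, 60, 40])
        depth, n_rep = 50, 1500
        t = pk.OtuTable(pd.DataFrame({"s": col}, index=[f"o{i}" for i in range(5)]))
        sums = np.zeros(5)
        for seed in range(n_rep):
            out = pk.rarefy(t, depth=depth, seed=seed)
            sums += out.data["s"].reindex(t.otu_ids, fill_value=0).to_numpy()
        mean = sums / n_rep
        p = col / col.sum()
        expected = depth * p
        n_total = col.sum()
        var = depth * p * (1 - p) * (n_total - depth) / (n_total - 1)
        se = np.sqrt(var / n_rep)
        assert np.all(np.abs(mean - expected) < 4 * se)

    def test_invalid_depth_rejected(self, tiny_table):
        with pytest.raises(ValueError):
            pk.rarefy(tiny_table, depth=0, seed=0)
        with pytest.raises(ValueError, match="fewer"):
            pk.rarefy(tiny_table, depth=10_000, seed=0)

    @settings(max_examples=25, deadline=None)
    @given(
        counts=st.lists(
            st.lists(st.integers(0, 50), min_size=3, max_size=3),
            min_size=2, max_size=5,
        ),
        seed=st.integers(0, 2**16),
    )
    def test_property_columns_conserve_requested_depth(self, counts, seed):
        df = pd.DataFrame(
            np.array(counts).T,
            index=[f"o{i}" for i in range(3)],
            columns=[f"s{j}" for j in range(len(counts))],
        )
        sums = df.sum(axis=0)
        if (sums == 0).all():
            return
        depth = max(1, int(sums[sums > 0].min()) // 2 + 1)
        table = pk.OtuTable(df)
        out = pk.rarefy(table, depth=depth, seed=seed)
        assert (out.column_sums() == depth).all()
        # without replacement: never more reads of an OTU than it had
        common = out.data.reindex(index=table.otu_ids, columns=out.sample_ids,
                                  fill_value=0)
        assert (common.to_numpy() <= df[out.sample_ids].to_numpy()).all()


class TestRelativeAbundance:
    def test_simple_and_exact_values(self):
        t = pk.OtuTable(pd.DataFrame({"s": [2, 2]}, index=["a", "b"]))
        rel = pk.relative_abundance(t)
        assert rel.data["s"].tolist() == [0.5, 0.5]

    def test_rarefied_proportion_is_count_over_depth(self):
        counts = np.zeros(2, dtype=int)
        counts[0] = 224
        counts[1] = 22_379 - 224
        t = pk.OtuTable(pd.DataFrame({"s": counts}, index=["a", "b"]))
        rel = pk.relative_abundance(t)
        assert rel.data.loc["a", "s"] == pytest.approx(224 / 22_379, abs=1e-15)

    def test_all_zero_column_rejected(self):
        t = pk.OtuTable(pd.DataFrame({"s": [0, 0]}, index=["a", "b"]))
        with pytest.raises(ValueError, match="zero reads"):
            pk.relative_abundance(t)


class TestSplitAndAggregate:
    def test_split_partitions_without_loss(self, make_sample_info):
        df = pd.DataFrame(
            {"d1": [1, 2], "r1": [3, 4], "d2": [5, 6]},
            index=["a", "b"],
        )
        meta = [
            make_sample_info("d1", "st1", 3.0, "surface", "rDNA"),
            make_sample_info("r1", "st1", 3.0, "surface", "rRNA"),
            make_sample_info("d2", "st2", 3.0, "surface", "rDNA"),
        ]
        t = pk.OtuTable(df)
        rdna, rrna = pk.split_by_template(t, meta)
        assert rdna.sample_ids == ["d1", "d2"]
        assert rrna.sample_ids == ["r1"]
        assert rdna.total_reads() + rrna.total_reads() == t.total_reads()

    def test_single_template_gives_empty_partner(self, make_sample_info):
        t = pk.OtuTable(pd.DataFrame({"d1": [1]}, index=["a"]))
        meta = [make_sample_info("d1", "st1", 3.0, "surface", "rDNA")]
        rdna, rrna = pk.split_by_template(t, meta)
        assert rdna.shape == (1, 1) and rrna.shape == (1, 0)

    def test_sample_missing_from_metadata_rejected(self, tiny_table):
        with pytest.raises(ValueError, match="missing from metadata"):
            pk.split_by_template(tiny_table, [])

    def test_aggregate_sums_and_conserves(self):
        t = pk.OtuTable(
            pd.DataFrame({"s1": [1, 2, 7], "s2": [4, 0, 6]}, index=["a", "b", "c"])
        )
        tax = [
            pk.TaxonAssignment("a", "G1"),
            pk.TaxonAssignment("b", "G1"),
            pk.TaxonAssignment("c", "G2"),
        ]
        agg = pk.aggregate_by_group(t, tax)
        assert agg.loc["G1", "s1"] == 3
        assert (agg.sum(axis=0) == t.column_sums()).all()

    def test_unassigned_pooled(self):
        t = pk.OtuTable(pd.DataFrame({"s1": [1, 2]}, index=["a", "b"]))
        agg = pk.aggregate_by_group(t, [])
        assert list(agg.index) == [ct.UNASSIGNED_GROUP]
        assert agg.loc[ct.UNASSIGNED_GROUP, "s1"] == 3
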