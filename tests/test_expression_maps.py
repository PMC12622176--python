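import numpy as np
import pandas as pd
import pytest

from psymap import (GeneSet, gen_parcel_atlas, gene_map, load_expression,
                    network_profile, set_average_map)
from psymap.atlas import NETWORKS
from psymap.expression_maps import RegionalMap
from psymap.errors import AlignmentError, SchemaError, ZeroVarianceError


@pytest.fixture(scope="module")
def atlas():
    return gen_parcel_atlas(20, seed=3)


def _write_expr(path, atlas, values, genes, drop_parcels=()):
    df = pd.DataFrame(values, columns=genes)
    df.insert(0, "parcel_id", atlas.parcel_id)
    df = df[~df["parcel_id"].isin(drop_parcels)]
    df.to_csv(path, index=False)
    return path


class TestLoadExpression:
    def test_absent_rows_become_missing_parcels(self, tmp_path, atlas):
        rng = np.random.default_rng(0)
        p = _write_expr(tmp_path / "e.csv", atlas, rng.standard_normal((20, 3)),
                        ["A", "B", "C"], drop_parcels=[2, 5])
        E = load_expression(p, atlas)
        assert int(E.missing_mask.sum()) == 2
        assert set(atlas.parcel_id[E.missing_mask]) == {2, 5}

    def test_columns_restandardised_to_z_scores(self, tmp_path, atlas):
        rng = np.random.default_rng(1)
        vals = 100 + 17 * rng.standard_normal((20, 2))  # arbitrary scaling
        E = load_expression(_write_expr(tmp_path / "e.csv", atlas, vals, ["A", "B"]),
                            atlas)
        sub = E.values[E.nonmissing]
        assert np.allclose(sub.mean(0), 0, atol=1e-9)
        assert np.allclose(sub.std(0, ddof=1), 1, atol=1e-9)

    def test_constant_column_raises_naming_gene(self, tmp_path, atlas):
        vals = np.random.default_rng(2).standard_normal((20, 2))
        vals[:, 1] = 7.0
        p = _write_expr(tmp_path / "e.csv", atlas, vals, ["A", "FLAT"])
        with pytest.raises(ZeroVarianceError, match="FLAT"):
            load_expression(p, atlas)

    def test_unknown_parcel_id_is_alignment_error(self, tmp_path, atlas):
        df = pd.DataFrame({"parcel_id": [1, 999], "A": [1.0, 2.0], "B": [0.5, 1.5]})
        df.to_csv(tmp_path / "e.csv", index=False)
        with pytest.raises(AlignmentError, match="999"):
            load_expression(tmp_path / "e.csv", atlas)

    def test_duplicate_gene_column_is_schema_error(self, tmp_path, atlas):
        (tmp_path / "e.csv").write_text(
            "parcel_id,A,A\n" + "\n".join(f"{p},{p},{p * 2}" for p in range(1, 21)))
        with pytest.raises(SchemaError, match="duplicate"):
            load_expression(tmp_path / "e.csv", atlas)

    def test_row_order_irrelevant(self, tmp_path, atlas):
        rng = np.random.default_rng(3)
        vals = rng.standard_normal((20, 3))
        p1 = _write_expr(tmp_path / "a.csv", atlas, vals, ["A", "B", "C"])
        df = pd.read_csv(p1).sample(frac=1, random_state=0)
        df.to_csv(tmp_path / "b.csv", index=False)
        E1 = load_expression(p1, atlas)
        E2 = load_expression(tmp_path / "b.csv", atlas)
        assert np.allclose(E1.values, E2.values, equal_nan=True)

    def test_round_trip(self, tmp_path, atlas):
        rng = np.random.default_rng(4)
        E = load_expression(
            _write_expr(tmp_path / "e.csv", atlas, rng.standard_normal((20, 4)),
                        list("ABCD"), drop_parcels=[7]), atlas)
        E.to_csv(tmp_path / "rt.csv")
        E2 = load_expression(tmp_path / "rt.csv", atlas)
        assert np.allclose(E.values, E2.values, atol=1e-12, equal_nan=True)


class TestGeneMap:
    def test_is_z_scored_column(self, clustered_expression):
        E, _ = clustered_expression
        m = gene_map(E, E.genes[0])
        ok = m.finite
        assert np.isclose(m.values[ok].mean(), 0, atol=1e-9)
        assert np.isclose(m.values[ok].std(ddof=1), 1, atol=1e-9)
        assert np.array_equal(m.values[ok], E.values[~E.missing_mask][:, 0])

    def test_unknown_symbol_raises_with_near_matches(self, clustered_expression):
        E, _ = clustered_expression
        with pytest.raises(KeyError):
            gene_map(E, "NOSUCHGENE")


class TestSetAverageMap:
    def test_singleton_equals_gene_map(self, clustered_expression):
        E, _ = clustered_expression
        g = E.genes[3]
        m = set_average_map(E, GeneSet("one", [g]))
        assert np.allclose(m.values, gene_map(E, g).values, equal_nan=True)

    def test_two_genes_elementwise_mean(self, clustered_expression):
        E, _ = clustered_expression
        g1, g2 = E.genes[0], E.genes[1]
        m = set_average_map(E, GeneSet("two", [g1, g2]))
        expect = (gene_map(E, g1).values + gene_map(E, g2).values) / 2
        assert np.allclose(m.values, expect, equal_nan=True)

    def test_linear_in_disjoint_union(self, clustered_expression):
        E, _ = clustered_expression
        a, b = GeneSet("a", E.genes[:4]), GeneSet("b", E.genes[4:10])
        union = set_average_map(E, GeneSet("u", E.genes[:10]))
        expect = (4 * set_average_map(E, a).values
                  + 6 * set_average_map(E, b).values) / 10
        assert np.allclose(union.values, expect, equal_nan=True)

    def test_absent_genes_skipped_but_empty_intersection_fails(self, clustered_expression):
        E, _ = clustered_expression
        m = set_average_map(E, GeneSet("mix", [E.genes[0], "ABSENT"]))
        assert np.allclose(m.values, gene_map(E, E.genes[0]).values, equal_nan=True)
        with pytest.raises(KeyError):
            set_average_map(E, GeneSet("none", ["ABSENT"]))

    def test_planted_cluster_split_half_agreement(self, clustered_expression):
        # averaging over cluster members cancels noise: two disjoint halves
        # of a planted cluster must yield near-identical average maps
        E, labels = clustered_expression
        members = [g for g, c in zip(E.genes, labels) if c == 1]
        half = len(members) // 2
        m1 = set_average_map(E, GeneSet("h1", members[:half]))
        m2 = set_average_map(E, GeneSet("h2", members[half:]))
        ok = m1.finite
        r = np.corrcoef(m1.values[ok], m2.values[ok])[0, 1]
        assert r > 0.9


class TestNetworkProfile:
    def test_constant_map(self, atlas60):
        m = RegionalMap(atlas60, np.full(60, 3.25))
        assert all(v == pytest.approx(3.25) for v in network_profile(m).values())

    def test_indicator_map(self, atlas60):
        vals = np.where(atlas60.network == "VN", 1.0, -1.0)
        prof = network_profile(RegionalMap(atlas60, vals))
        assert prof["VN"] == pytest.approx(1.0)
        assert all(prof[n] == pytest.approx(-1.0) for n in NETWORKS if n != "VN")

    def test_count_weighted_mean_of_zscored_map_is_zero(self, clustered_expression):
        E, _ = clustered_expression
        m = gene_map(E, E.genes[5])
        prof = network_profile(m)
        ok = m.finite
        counts = {n: int((ok & (E.atlas.network == n)).sum()) for n in NETWORKS}
        weighted = sum(prof[n] * counts[n] for n in NETWORKS) / sum(counts.values())
        assert weighted == pytest.approx(0.0, abs=1e-9)
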