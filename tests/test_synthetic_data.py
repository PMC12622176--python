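import json

import numpy as np
import pytest

from psymap import (SyntheticSpec, build_study, compound_cov, connectivity,
                    filter_acute, gen_bold, gen_expression, gen_gene_table,
                    gen_parcel_atlas, global_fc, group_difference,
                    make_overlapping_sets, smooth_cov, write_study)
from psymap.atlas import NETWORKS


class TestGenParcelAtlas:
    def test_hemispheres_and_networks(self):
        atlas = gen_parcel_atlas(200, seed=1)
        assert (atlas.hemisphere == "L").sum() == 100
        assert (atlas.hemisphere == "R").sum() == 100
        assert set(atlas.network) == set(NETWORKS)
        assert np.unique(atlas.parcel_id).size == 200

    def test_small_atlas(self):
        atlas = gen_parcel_atlas(4, seed=1)
        assert atlas.n_parcels == 4
        assert (atlas.hemisphere == "L").sum() == 2

    def test_deterministic(self):
        a, b = gen_parcel_atlas(50, seed=9), gen_parcel_atlas(50, seed=9)
        assert np.array_equal(a.centroids, b.centroids)
        assert np.array_equal(a.network, b.network)

    def test_centroids_on_sphere(self):
        atlas = gen_parcel_atlas(64, seed=2)
        radii = np.linalg.norm(atlas.centroids, axis=1)
        assert np.allclose(radii, radii[0])

    def test_invalid_sizes(self):
        with pytest.raises(ValueError):
            gen_parcel_atlas(1, seed=0)
        with pytest.raises(ValueError):
            gen_parcel_atlas(5, seed=0, n_missing=4)


class TestGenExpression:
    def test_z_score_contract(self, clustered_expression):
        E, _ = clustered_expression
        sub = E.values[~E.missing_mask]
        assert np.allclose(sub.mean(axis=0), 0, atol=1e-9)
        assert np.allclose(sub.std(axis=0, ddof=1), 1, atol=1e-9)
        assert np.all(np.isnan(E.values[E.missing_mask]))

    def test_noise_free_within_cluster_correlation_is_one(self, atlas60):
        spec = SyntheticSpec(n_parcels=60, n_genes=8, n_clusters=2,
                             noise_sd=0.0, spatial_scale=0.0, seed=3)
        E, labels = gen_expression(atlas60, spec)
        ok = ~E.missing_mask
        C = np.corrcoef(E.values[ok], rowvar=False)
        same = labels[:, None] == labels[None, :]
        assert np.allclose(C[same], 1.0, atol=1e-12)

    def test_deterministic(self, atlas60):
        spec = SyntheticSpec(n_parcels=60, n_genes=10, n_clusters=2, seed=4)
        E1, l1 = gen_expression(atlas60, spec)
        E2, l2 = gen_expression(atlas60, spec)
        assert np.array_equal(l1, l2)
        assert np.allclose(E1.values, E2.values, equal_nan=True)

    def test_background_genes_unstructured(self, atlas60):
        spec = SyntheticSpec(n_parcels=60, n_genes=6, n_clusters=2,
                             n_background=20, noise_sd=0.3, seed=5)
        E, labels = gen_expression(atlas60, spec)
        assert (labels == 0).sum() == 20
        assert len(E.genes) == 26

    def test_spec_validation(self):
        with pytest.raises(ValueError):
            SyntheticSpec(n_parcels=10, n_genes=2, n_clusters=3)
        with pytest.raises(ValueError):
            SyntheticSpec(n_parcels=10, n_genes=5, n_clusters=2, noise_sd=-1)


class TestGenBold:
    def test_deterministic(self, atlas60):
        cov = smooth_cov(atlas60)
        e = np.zeros(60)
        a1, b1 = gen_bold(atlas60, cov, e, n_subjects=2, n_timepoints=50, seed=1)
        a2, b2 = gen_bold(atlas60, cov, e, n_subjects=2, n_timepoints=50, seed=1)
        assert all(np.array_equal(x, y) for x, y in zip(a1 + b1, a2 + b2))

    def test_zero_effect_gives_matched_groups(self, atlas60):
        cov = compound_cov(60, rho=0.3)
        a, b = gen_bold(atlas60, cov, np.zeros(60), n_subjects=4,
                        n_timepoints=2000, seed=2)
        ga = group_difference([global_fc(connectivity(x, atlas60)) for x in a],
                              [global_fc(connectivity(x, atlas60)) for x in b])
        assert np.abs(np.mean(ga.values)) < 0.02

    def test_identity_cov_gives_near_zero_gfc(self, atlas60):
        a, _ = gen_bold(atlas60, np.eye(60), np.zeros(60), n_subjects=1,
                        n_timepoints=2000, seed=3)
        g = global_fc(connectivity(a[0], atlas60))
        assert np.abs(g.values).max() < 0.08

    def test_non_psd_cov_rejected(self, atlas60):
        bad = -np.eye(60)
        with pytest.raises(ValueError):
            gen_bold(atlas60, bad, np.zeros(60), n_subjects=1,
                     n_timepoints=10, seed=0)


class TestGenGeneTable:
    UNIVERSE = [f"GENE{i:03d}" for i in range(200)]

    def test_planted_acute_count_recovered(self):
        records, truth = gen_gene_table(156, 56 / 156, self.UNIVERSE, seed=1)
        assert len(records) == 156
        acute = filter_acute(records)
        assert set(acute) == set(truth)
        assert len(acute) == 56

    def test_acute_fraction_zero_and_one(self):
        records, truth = gen_gene_table(20, 0.0, self.UNIVERSE, seed=2)
        assert len(filter_acute(records)) == 0 and len(truth) == 0
        records, truth = gen_gene_table(20, 1.0, self.UNIVERSE, seed=3)
        assert len(filter_acute(records)) == 20

    def test_times_in_planted_windows(self):
        records, truth = gen_gene_table(100, 0.4, self.UNIVERSE, seed=4)
        for r in records:
            if r.symbol in truth:
                continue
            assert r.time_hours is None or r.time_hours > 5.0
        acute_times = [r.time_hours for r in records if r.symbol in truth
                       and r.time_hours is not None and r.time_hours <= 5]
        assert min(acute_times) >= 0.75 and max(acute_times) <= 5.0

    def test_deterministic_and_validation(self):
        r1, _ = gen_gene_table(30, 0.5, self.UNIVERSE, seed=5)
        r2, _ = gen_gene_table(30, 0.5, self.UNIVERSE, seed=5)
        assert r1 == r2
        with pytest.raises(ValueError):
            gen_gene_table(10, 0.5, [], seed=0)


def test_make_overlapping_sets_exact_overlap():
    universe = [f"U{i}" for i in range(100)]
    a, b = make_overlapping_sets(universe, 20, 30, 7, seed=1)
    assert (len(a), len(b)) == (20, 30)
    assert len(set(a) & set(b)) == 7


@pytest.fixture(scope="module")
def study():
    return build_study(seed=2, n_parcels=80, n_missing=5, n_subjects=3,
                       n_timepoints=60, n_background=150)


class TestBuildStudy:

    def test_planted_accounting(self, study):
        acute = filter_acute(study.records)
        assert len(acute) == 56
        gcep = [g for g in acute if g in study.expression._index]
        assert len(gcep) == 51
        assert len(set(study.query_set) & set(study.har_set)) == 9

    def test_write_study_files(self, study, tmp_path):
        write_study(study, tmp_path / "study")
        base = tmp_path / "study"
        for f in ("atlas.csv", "expression.csv", "genes.csv", "har_genes.txt",
                  "query_genes.txt", "truth.json"):
            assert (base / f).exists()
        assert len(list((base / "bold_groupA").glob("*.csv"))) == 3
        truth = json.loads((base / "truth.json").read_text())
        assert len(truth["query_genes"]) == 51
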