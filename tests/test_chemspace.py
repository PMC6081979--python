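"""Satellite selection, projection fitting/reuse and map quality control."""

import numpy as np
import pytest

import chemprofile as cp

from conftest import noise_free_spec, two_cluster_libraries


@pytest.fixture(scope="module")
def lib50():
    lib = cp.generate_library(noise_free_spec(n=50, seed=71))
    return cp.curate(lib.records, "fifty")


class TestSelectSatellites:
    def test_k_equals_n_returns_whole_library(self, lib50):
        for method in ("random", "maxmin"):
            sats = cp.select_satellites(lib50, k=len(lib50), method=method)
            assert sats == lib50.records

    def test_seeded_determinism(self, lib50):
        for method in ("random", "maxmin"):
            a = cp.select_satellites(lib50, k=10, method=method, seed=5)
            b = cp.select_satellites(lib50, k=10, method=method, seed=5)
            assert a == b

    def test_maxmin_never_selects_both_duplicates(self, lib50):
        dup = cp.MoleculeRecord("dup", lib50.records[0].canonical_structure)
        records = lib50.records + [dup]
        sats = cp.select_satellites(records, k=len(records) - 1, method="maxmin", seed=2)
        structures = [s.canonical_structure for s in sats]
        assert structures.count(dup.canonical_structure) == 1

    def test_k_out_of_range(self, lib50):
        for k in (1, len(lib50) + 1):
            with pytest.raises(ValueError):
                cp.select_satellites(lib50, k=k)


class TestFitProjection:
    def test_identity_with_classical_pca(self, lib50):
        """With every molecule a satellite the map equals classical PC scores
        of the full centered similarity matrix (sklearn PCA as oracle)."""
        from sklearn.decomposition import PCA

        from chemprofile.chemspace import _similarity_to_satellites
        from chemprofile.diversity import _fingerprint_matrix

        model = cp.fit_projection(lib50, cp.select_satellites(lib50, k=len(lib50)), d=2)
        coords = np.array([p.coords for p in cp.project(model, [lib50])])
        fps = _fingerprint_matrix(lib50.records)
        sim = _similarity_to_satellites(fps, fps)
        scores = PCA(n_components=2, svd_solver="full").fit_transform(sim)
        for c in range(2):  # align axis signs to the model's convention
            if np.dot(scores[:, c], coords[:, c]) < 0:
                scores[:, c] *= -1
        np.testing.assert_allclose(coords, scores, atol=1e-8)

    def test_orthonormal_loadings_and_variance_fractions(self, lib50):
        model = cp.fit_projection(lib50, cp.select_satellites(lib50, k=20, seed=1), d=3)
        gram = model.loadings.T @ model.loadings
        np.testing.assert_allclose(gram, np.eye(3), atol=1e-10)
        evf = model.explained_variance_fractions
        assert np.all(np.diff(evf) <= 1e-12) and evf.sum() <= 1.0 + 1e-12

    def test_all_identical_molecules_zero_variance(self):
        records = [cp.MoleculeRecord(f"m{i}", "c1ccccc1O") for i in range(8)]
        with pytest.warns(UserWarning):
            model = cp.fit_projection(records, records[:3], d=2)
        lib = cp.CuratedLibrary(tag="t", records=records, log=cp.CurationLog())
        coords = np.array([p.coords for p in cp.project(model, [lib])])
        assert np.allclose(coords, coords[0])

    def test_duplicate_records_identical_coordinates(self, lib50):
        records = lib50.records + [cp.MoleculeRecord("twin", lib50.records[0].canonical_structure)]
        model = cp.fit_projection(records, cp.select_satellites(lib50, k=15, seed=3), d=2)
        lib = cp.CuratedLibrary(tag="t", records=records, log=cp.CurationLog())
        coords = np.array([p.coords for p in cp.project(model, [lib])])
        np.testing.assert_allclose(coords[-1], coords[0], atol=1e-12)


class TestProject:
    def test_projection_reproduces_fit_coordinates(self, lib50):
        sats = cp.select_satellites(lib50, k=12, seed=4)
        model = cp.fit_projection(lib50, sats, d=2)
        a = np.array([p.coords for p in cp.project(model, [lib50])])
        b = np.array([p.coords for p in cp.project(model, [lib50])])
        np.testing.assert_allclose(a, b)

    def test_molecule_identical_to_satellite_lands_on_it(self, lib50):
        sats = cp.select_satellites(lib50, k=12, seed=4)
        model = cp.fit_projection(lib50, sats, d=2)
        sat_lib = cp.CuratedLibrary(tag="sat", records=[sats[0]], log=cp.CurationLog())
        clone = cp.CuratedLibrary(
            tag="clone",
            records=[cp.MoleculeRecord("c", sats[0].canonical_structure)],
            log=cp.CurationLog())
        p_sat = cp.project(model, [sat_lib])[0]
        p_clone = cp.project(model, [clone])[0]
        np.testing.assert_allclose(p_sat.coords, p_clone.coords, atol=1e-12)

    def test_empty_library_list_rejected(self, lib50):
        model = cp.fit_projection(lib50, cp.select_satellites(lib50, k=5, seed=0), d=2)
        with pytest.raises(ValueError):
            cp.project(model, [])

    def test_disjoint_clusters_separate_in_map(self):
        ca, cb = two_cluster_libraries(seed=0)
        merged = cp.CuratedLibrary(tag="m", records=ca.records + cb.records, log=ca.log)
        sats = cp.select_satellites(merged, k=20, seed=0)
        model = cp.fit_projection(merged, sats, d=2)
        pts = cp.project(model, [ca, cb])
        X = np.array([p.coords for p in pts])
        src = np.array([p.source for p in pts])
        intra_a = np.linalg.norm(X[src == "aromatic"][:, None] - X[src == "aromatic"], axis=-1).mean()
        intra_b = np.linalg.norm(X[src == "acyclic"][:, None] - X[src == "acyclic"], axis=-1).mean()
        inter = np.linalg.norm(X[src == "aromatic"][:, None] - X[src == "acyclic"], axis=-1).mean()
        assert inter > intra_a and inter > intra_b


class TestDistancePreservation:
    def test_duplicated_library_well_defined(self, lib50):
        records = lib50.records + [cp.MoleculeRecord(r.id + "_copy", r.canonical_structure)
                                   for r in lib50.records]
        model = cp.fit_projection(records, cp.select_satellites(lib50, k=15, seed=6), d=2)
        rho = cp.distance_preservation(model, records, n_pairs=2000, seed=0)
        assert np.isfinite(rho)

    def test_full_rank_at_least_as_good_as_2d(self, lib50):
        sats = cp.select_satellites(lib50, k=len(lib50))
        rho2 = cp.distance_preservation(cp.fit_projection(lib50, sats, d=2),
                                        lib50, n_pairs=1000, seed=0)
        rho3 = cp.distance_preservation(cp.fit_projection(lib50, sats, d=3),
                                        lib50, n_pairs=1000, seed=0)
        assert rho3 >= rho2 - 1e-9

    def test_separated_clusters_preserve_distances(self):
        ca, cb = two_cluster_libraries(seed=1)
        merged = cp.CuratedLibrary(tag="m", records=ca.records + cb.records, log=ca.log)
        model = cp.fit_projection(merged, cp.select_satellites(merged, k=20, seed=1), d=2)
        assert cp.distance_preservation(model, merged, n_pairs=5000, seed=1) >= 0.8


class TestModelSerialization:
    def test_json_roundtrip(self, lib50, tmp_path):
        sats = cp.select_satellites(lib50, k=10, seed=8)
        model = cp.fit_projection(lib50, sats, d=2)
        path = tmp_path / "model.json"
        model.to_json(str(path))
        loaded = cp.ProjectionModel.from_json(str(path))
        assert loaded.satellites == model.satellites
        np.testing.assert_allclose(loaded.loadings, model.loadings)
        a = np.array([p.coords for p in cp.project(model, [lib50])])
        b = np.array([p.coords for p in cp.project(loaded, [lib50])])
        np.testing.assert_allclose(a, b)
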