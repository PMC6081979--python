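"""Fingerprint/property diversity statistics and CDP assembly."""

import numpy as np
import pandas as pd
import pytest

import chemprofile as cp
from chemprofile.diversity import (
    DiversityProfile,
    _pair_sample,
    pairwise_tanimoto_matrix,
    pooled_scaling_stats,
    property_vectors,
)

from conftest import noise_free_spec


def exhaustive_median_tanimoto(records):
    """Brute-force oracle: median over the full similarity matrix."""
    from chemprofile.diversity import _fingerprint_matrix

    sim = pairwise_tanimoto_matrix(_fingerprint_matrix(records))
    iu = np.triu_indices(len(records), k=1)
    return float(np.median(sim[iu]))


class TestTanimoto:
    def test_identical(self):
        fp = cp.maccs_fingerprint("c1ccccc1O")
        assert cp.tanimoto(fp, fp) == 1.0

    def test_disjoint_and_fraction(self):
        a = cp.BitFingerprint(np.array([1, 1, 0, 0], dtype=bool))
        b = cp.BitFingerprint(np.array([0, 0, 1, 1], dtype=bool))
        c = cp.BitFingerprint(np.array([0, 1, 1, 0], dtype=bool))
        assert cp.tanimoto(a, b) == 0.0
        assert cp.tanimoto(a, c) == pytest.approx(1 / 3)

    def test_all_zero_convention(self):
        z = cp.BitFingerprint(np.zeros(8, dtype=bool))
        assert cp.tanimoto(z, z) == 1.0

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            cp.tanimoto(cp.BitFingerprint(np.zeros(4, dtype=bool)),
                        cp.BitFingerprint(np.zeros(8, dtype=bool)))

    def test_fingerprint_length_166(self):
        assert len(cp.maccs_fingerprint("CCO")) == 166


class TestMedianPairwiseTanimoto:
    def test_copies_of_one_molecule(self):
        records = [cp.MoleculeRecord(f"m{i}", "Oc1ccccc1") for i in range(5)]
        assert cp.median_pairwise_tanimoto(records) == 1.0

    def test_small_library_exact(self):
        records = [cp.MoleculeRecord(str(i), s)
                   for i, s in enumerate(["CCO", "CCC", "CCN"])]
        assert cp.median_pairwise_tanimoto(records) == pytest.approx(
            exhaustive_median_tanimoto(records))

    def test_sampled_close_to_exhaustive(self):
        lib = cp.generate_library(noise_free_spec(n=200, seed=51))
        curated = cp.curate(lib.records, "t")
        exact = cp.median_pairwise_tanimoto(curated, max_pairs=10**9)
        sampled = cp.median_pairwise_tanimoto(curated, max_pairs=10_000, seed=1)
        assert exact == pytest.approx(exhaustive_median_tanimoto(curated.records))
        assert abs(sampled - exact) <= 0.02

    def test_requires_two_molecules(self):
        with pytest.raises(ValueError):
            cp.median_pairwise_tanimoto([cp.MoleculeRecord("a", "CCO")])

    def test_pair_sample_decoding(self):
        # sampled flat indices decode to valid unique (i < j) pairs
        i, j = _pair_sample(50, 100, seed=3)
        assert len(i) == 100 and np.all(i < j) and np.all(j < 50)
        assert len({(a, b) for a, b in zip(i, j)}) == 100


class TestPcpDiversity:
    def test_identical_vectors(self):
        vecs = property_vectors([cp.MoleculeRecord(str(i), "CCO") for i in range(4)])
        other = property_vectors([cp.MoleculeRecord("x", "c1ccccc1"),
                                  cp.MoleculeRecord("y", "CCCCCCCC")])
        stats = pooled_scaling_stats([vecs, other])
        assert cp.pcp_diversity(vecs, stats) == 0.0

    def test_affine_invariance(self):
        rng = np.random.default_rng(0)
        raw = [pd.DataFrame(rng.normal(size=(30, 6)) * 10 + 50,
                            columns=["SlogP", "TPSA", "AMW", "RB", "HBD", "HBA"])
               for _ in range(3)]
        stats = pooled_scaling_stats(raw)
        base = [cp.pcp_diversity(df, stats, seed=0) for df in raw]
        scaled = [df.assign(TPSA=3.5 * df.TPSA - 12.0) for df in raw]
        stats2 = pooled_scaling_stats(scaled)
        after = [cp.pcp_diversity(df, stats2, seed=0) for df in scaled]
        assert np.allclose(base, after, atol=1e-10)

    def test_constant_property_dropped_with_warning(self):
        df = pd.DataFrame({"SlogP": [1.0, 2.0], "TPSA": [0.0, 0.0],
                           "AMW": [10.0, 20.0], "RB": [1, 2],
                           "HBD": [0, 1], "HBA": [1, 2]})
        stats = pooled_scaling_stats(df)
        with pytest.warns(UserWarning, match="TPSA"):
            cp.pcp_diversity(df, stats)


class TestConsensusProfiles:
    def test_identical_libraries_identical_profiles(self, small_library):
        _, curated = small_library
        twin = cp.CuratedLibrary(tag=curated.tag, records=curated.records,
                                 log=curated.log)
        a, b = cp.consensus_profiles([curated, twin], seed=0)
        assert vars(a) == vars(b)

    def test_profile_bounds(self, small_library):
        lib2 = cp.generate_library(noise_free_spec(n=80, seed=61))
        _, curated = small_library
        profiles = cp.consensus_profiles([curated, cp.curate(lib2.records, "b")], seed=0)
        for p in profiles:
            assert 0.0 <= p.median_tanimoto <= 1.0
            assert 0.5 - 1e-12 <= p.scaffold_auc <= 1.0
            assert p.pcp_distance >= 0.0 and p.size > 0


class TestCdpAssign:
    def _profiles(self):
        return [
            DiversityProfile("diverse", 0.2, 0.55, 3.0, 100),
            DiversityProfile("redundant", 0.8, 0.9, 1.0, 400),
        ]

    def test_dominating_profile_lower_left(self):
        df = cp.cdp_assign(self._profiles())
        assert df.loc["diverse", "quadrant"].startswith("lower-left")
        assert df.loc["redundant", "quadrant"].startswith("upper-right")

    def test_threshold_tie_goes_to_diverse_side(self):
        profiles = self._profiles()
        df = cp.cdp_assign(profiles, x_threshold=0.2, y_threshold=0.55)
        assert df.loc["diverse", "quadrant"].startswith("lower-left")

    def test_shrinking_tanimoto_never_moves_right(self):
        profiles = self._profiles()
        before = cp.cdp_assign(profiles, x_threshold=0.5, y_threshold=0.7)
        profiles[1] = DiversityProfile("redundant", 0.4, 0.9, 1.0, 400)
        after = cp.cdp_assign(profiles, x_threshold=0.5, y_threshold=0.7)
        assert before.loc["redundant", "quadrant"].startswith("upper-right")
        assert after.loc["redundant", "quadrant"].startswith("upper-left")

    def test_auto_needs_two_profiles(self):
        with pytest.raises(ValueError):
            cp.cdp_assign(self._profiles()[:1])

    def test_plot_written(self, tmp_path):
        out = tmp_path / "cdp.svg"
        cp.cdp_assign(self._profiles(), plot_path=str(out))
        assert out.exists() and out.stat().st_size > 0
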