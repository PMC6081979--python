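import pytest

import chemprofile as cp


def noise_free_spec(n=200, seed=0, **kw):
    defaults = dict(n_molecules=n, seed=seed, salt_noise_fraction=0.0,
                    duplicate_fraction=0.0)
    defaults.update(kw)
    return cp.LibrarySpec(**defaults)


def ordering_spec(n_scaffolds, seed):
    """Conditions for scaffold-count ordering checks: uniform assignment and
    a small acyclic block (the recovery-AUC ordering is only monotone there)."""
    return cp.LibrarySpec(
        n_molecules=500, n_scaffolds=n_scaffolds, scaffold_skew=0.0,
        polyphenol_fraction=0.0, acyclic_fraction=0.02,
        salt_noise_fraction=0.0, duplicate_fraction=0.0, seed=seed,
    )


def two_cluster_libraries(seed, n=60):
    """Two structurally disjoint clusters: hydroxylated aromatics vs acyclics."""
    a = cp.generate_library(cp.LibrarySpec(
        n_molecules=n, n_scaffolds=4, seed=seed, acyclic_fraction=0.0,
        polyphenol_fraction=0.5, salt_noise_fraction=0.0,
        duplicate_fraction=0.0, ring_count_range=(1, 1)))
    b = cp.generate_library(cp.LibrarySpec(
        n_molecules=n, n_scaffolds=1, seed=seed + 1000, acyclic_fraction=1.0,
        polyphenol_fraction=0.0, salt_noise_fraction=0.0, duplicate_fraction=0.0))
    return cp.curate(a.records, "aromatic"), cp.curate(b.records, "acyclic")


@pytest.fixture(scope="session")
def small_library():
    """A 120-molecule noise-free synthetic library, curated, with its truth."""
    lib = cp.generate_library(noise_free_spec(n=120, seed=42))
    return lib, cp.curate(lib.records, "small")


@pytest.fixture(scope="session")
def noisy_library():
    """A 200-molecule library with salts and duplicates, plus its truth table."""
    lib = cp.generate_library(cp.LibrarySpec(n_molecules=200, seed=7,
                                             duplicate_fraction=0.1))
    return lib, cp.curate(lib.records, "noisy")
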