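import numpy as np
import pytest

import cylmap as cm


@pytest.fixture(scope="session")
def patch_spec():
    """Small study spec with one mutual polymorphism patch inside lattice
    row 3 (residues 45..50 stay in one row of the 14x14 grid, so the patch
    is a contiguous strip on the interface)."""
    return cm.SyntheticSpec(
        seed=11,
        n_aa_hap=12,
        n_nt_hap=18,
        patches=(cm.PlantedPatch(45, 51, rate=0.8, syn_fraction=0.0),),
    )


@pytest.fixture(scope="session")
def population(patch_spec):
    n_res = patch_spec.res_grid[0] * patch_spec.res_grid[1]
    aln, truth = cm.make_population(patch_spec, n_res)
    return aln, truth


@pytest.fixture(scope="session")
def small_aln():
    """Hand-written 3-haplotype alignment with counts (3, 2, 1):

    rows (aa): MKL / MKV / MRL — column 0 monomorphic, 1 and 2 biallelic.
    """
    return cm.PopulationAlignment(
        aa=np.array([list("MKL"), list("MKV"), list("MRL")]),
        nt=np.array([list("ATGAAACTT"), list("ATGAAAGTT"), list("ATGAGACTT")]),
        counts=np.array([3, 2, 1]),
        ids=["h1", "h2", "h3"],
    )


@pytest.fixture(scope="session")
def oriented_dimer(patch_spec, population):
    aln, _ = population
    seq = "".join(aln.aa[0])
    a, b, truth = cm.make_dimer(patch_spec, seq, seq)
    a, b = cm.orient_complex(a, b)
    return a, b, truth


def brute_force_pi(aln: cm.PopulationAlignment, columns=None) -> float:
    """Independent O(N^2 L) oracle: expand copy counts into rows and average
    the pairwise mismatch fraction over the selected columns."""
    cols = np.arange(aln.n_columns) if columns is None else np.asarray(columns)
    rows = []
    for j in range(aln.n_rows):
        rows.extend(["".join(aln.aa[j, cols])] * int(aln.counts[j]))
    n = len(rows)
    total = 0.0
    pairs = 0
    for i in range(n):
        for j in range(i + 1, n):
            total += sum(a != b for a, b in zip(rows[i], rows[j])) / len(cols)
            pairs += 1
    return total / pairs


def random_alignment(rng, n_rows, n_cols, alphabet="ACDEFG-", max_count=4):
    aa = rng.choice(list(alphabet), size=(n_rows, n_cols))
    counts = rng.integers(1, max_count + 1, size=n_rows)
    return cm.PopulationAlignment(aa=aa, counts=counts)
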