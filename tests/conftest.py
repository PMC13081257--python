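import numpy as np
import pytest

from kinbench.fixtures import PEDIGREE_11, pedigree_12_inbred
from kinbench.pedigree import DEFAULT_GRID, Pedigree


@pytest.fixture(scope="session")
def grid():
    return DEFAULT_GRID


@pytest.fixture(scope="session")
def ped11():
    return Pedigree.from_text(PEDIGREE_11)


@pytest.fixture(scope="session")
def ped12():
    return Pedigree.from_text(pedigree_12_inbred("first_cousins"))


def mc_kinship(ped, n_loci=100_000, seed=0):
    """Monte-Carlo gene-dropping kinship oracle over unlinked loci.

    Founder alleles carry unique integer labels; each locus transmits
    independently.  Returns (phi_hat, se) dicts keyed by unordered pair.
    Independent of the package's kinship recursion.
    """
    rng = np.random.default_rng(seed)
    genomes = {}
    for k, fid in enumerate(ped.founders):
        row = np.empty((n_loci, 2), dtype=np.int64)
        row[:, 0] = 2 * k
        row[:, 1] = 2 * k + 1
        genomes[fid] = row
    for ind in ped.members:
        if ind.id in genomes or ind.id in ped.twin_of:
            continue
        pat = genomes[ind.father_id][
            np.arange(n_loci), rng.integers(2, size=n_loci)
        ]
        mat = genomes[ind.mother_id][
            np.arange(n_loci), rng.integers(2, size=n_loci)
        ]
        genomes[ind.id] = np.stack([pat, mat], axis=1)
    for twin, src in ped.twin_of.items():
        genomes[twin] = genomes[src]
    phi, se = {}, {}
    ids = ped.ids
    for a in range(len(ids)):
        for b in range(a, len(ids)):
            gi, gj = genomes[ids[a]], genomes[ids[b]]
            per_locus = np.zeros(n_loci)
            for x in range(2):
                for y in range(2):
                    per_locus += gi[:, x] == gj[:, y]
            per_locus /= 4.0
            key = (ids[a], ids[b])
            phi[key] = float(per_locus.mean())
            se[key] = float(per_locus.std(ddof=1) / np.sqrt(n_loci))
    return phi, se
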