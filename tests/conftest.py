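import numpy as np
import pandas as pd
import pytest

import pedvar as pv


def make_pedigree(rows):
    """Build a pedigree frame from (id, dam, sire, generation, sex) tuples."""
    df = pd.DataFrame(rows, columns=["id", "dam", "sire", "generation", "sex"])
    df["is_breeder"] = False
    df["extra_pair"] = False
    return df


@pytest.fixture(scope="session")
def halfsib_mating_pedigree():
    """3-generation pedigree containing a half-sib mating (inbred offspring).

    1 F and 2 M, 3 M are founders; 4 (dam 1, sire 2) and 5 (dam 1, sire 3)
    are maternal half sibs; 6 is the offspring of the half-sib mating
    4 x 5, so F_6 = 0.125.
    """
    return make_pedigree(
        [
            (1, 0, 0, 0, "F"),
            (2, 0, 0, 0, "M"),
            (3, 0, 0, 0, "M"),
            (4, 1, 2, 1, "F"),
            (5, 1, 3, 1, "M"),
            (6, 4, 5, 2, "F"),
        ]
    )


def gene_drop_relatedness(ped, n_drops=100_000, seed=0):
    """Monte-Carlo oracle for A: drop unique founder alleles down the pedigree.

    Returns (A_hat, mc_se) where A_hat[i, j] = 2 * theta_hat[i, j] for
    i != j and 1 + F_hat on the diagonal, with per-entry Monte-Carlo
    standard errors.  Independent of the tabular method.
    """
    rng = np.random.default_rng(seed)
    ids = ped["id"].to_numpy()
    pos = {int(i): k for k, i in enumerate(ids)}
    dam = np.array([pos.get(int(d), -1) for d in ped["dam"]])
    sire = np.array([pos.get(int(s), -1) for s in ped["sire"]])
    n = len(ids)

    alleles = np.zeros((n_drops, n, 2), dtype=np.int32)
    next_allele = 0
    for i in range(n):
        for side, p in ((0, dam[i]), (1, sire[i])):
            if p < 0:
                alleles[:, i, side] = next_allele
                next_allele += 1
            else:
                pick = rng.integers(0, 2, size=n_drops)
                alleles[:, i, side] = alleles[np.arange(n_drops), p, pick]

    A_hat = np.zeros((n, n))
    se = np.zeros((n, n))
    for i in range(n):
        for j in range(i, n):
            if i == j:
                # F_i: probability the two alleles of i are IBD
                ibd = (alleles[:, i, 0] == alleles[:, i, 1]).astype(float)
                est = 1.0 + ibd
            else:
                # theta: random allele from i vs random allele from j
                match = np.zeros(n_drops)
                for a in range(2):
                    for b in range(2):
                        match += alleles[:, i, a] == alleles[:, j, b]
                est = 2.0 * match / 4.0
            A_hat[i, j] = A_hat[j, i] = est.mean()
            se[i, j] = se[j, i] = est.std(ddof=1) / np.sqrt(n_drops)
    return A_hat, se


@pytest.fixture(scope="session")
def small_config():
    """A scaled-down population: the full generative structure, fast to fit."""
    return pv.SimulationConfig(
        pedigree=pv.PedigreeConfig(n_generations=5, size_range=(50, 70)),
        grid=pv.GridSpec(25, 25),
    )


@pytest.fixture(scope="session")
def small_population(small_config):
    return pv.simulate_population(small_config, seed=42)


@pytest.fixture(scope="session")
def small_matrices(small_population):
    return pv.build_all_matrices(small_population)
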