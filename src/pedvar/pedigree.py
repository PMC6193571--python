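"""Pedigree simulation and the additive genetic relatedness matrix.

The simulated population is semelparous with discrete, non-overlapping
generations.  Within each generation a fixed fraction of individuals is
selected at random and assigned to monogamous breeding pairs; offspring of
the next generation are allocated uniformly among those pairs.  A
configurable share of offspring are "extra-pair": one recorded parent is
replaced by a different breeder of the same sex, so that the social pair
and the genetic parents differ.

Generation 0 consists of phantom founders -- monogamous, unrelated,
non-inbred pairs that exist only to parent generation 1, giving the first
real generation full- and half-sib structure and well-defined maternal
effects.

The additive relatedness matrix A (entries ``A[i, j] = 2 * theta_ij`` with
theta the coefficient of coancestry; diagonal ``1 + F_i``) is computed by
the recursive tabular method, which accommodates inbreeding exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from pedvar.containers import LabeledMatrix

UNKNOWN = 0

PEDIGREE_COLUMNS = ["id", "dam", "sire", "generation", "sex", "is_breeder"]


@dataclass(frozen=True)
class PedigreeConfig:
    """Breeding-structure parameters.

    n_generations
        Number of non-phantom generations (generation labels 1..G).
    size_range
        Inclusive bounds for the uniform draw of each generation's size.
    breeder_fraction
        Share of each generation selected into breeding pairs.
    extra_pair_rate
        Share of offspring with one parent reselected; the count is
        deterministic (``round(rate * n_offspring)``), which parent is
        replaced and by whom is random.
    """

    n_generations: int = 10
    size_range: tuple[int, int] = (150, 250)
    breeder_fraction: float = 0.5
    extra_pair_rate: float = 0.10

    def __post_init__(self):
        lo, hi = self.size_range
        if self.n_generations < 1:
            raise ValueError("need at least one generation")
        if lo < 2 or hi < lo:
            raise ValueError("invalid generation size range")
        if not 0.0 <= self.extra_pair_rate <= 1.0:
            raise ValueError("extra-pair rate must be in [0, 1]")
        if not 0.0 < self.breeder_fraction <= 1.0:
            raise ValueError("breeder fraction must be in (0, 1]")
        # the smallest generation must still support at least one breeding pair
        if round(self.breeder_fraction * lo / 2) < 1:
            raise ValueError(
                "size range lower bound too small for the breeder fraction: "
                "cannot form a breeding pair"
            )


def _balanced_sexes(n: int, rng: np.random.Generator) -> np.ndarray:
    """n sexes, as close to 50/50 as possible, in random order."""
    sexes = np.array(["F", "M"] * ((n + 1) // 2))[:n]
    rng.shuffle(sexes)
    return sexes


def _make_pairs(ids, sexes, n_pairs, rng):
    """Randomly select n_pairs females and males and pair them monogamously."""
    females = ids[sexes == "F"]
    males = ids[sexes == "M"]
    if len(females) < n_pairs or len(males) < n_pairs:
        raise ValueError("not enough individuals of each sex to form pairs")
    dams = rng.choice(females, size=n_pairs, replace=False)
    sires = rng.choice(males, size=n_pairs, replace=False)
    return np.column_stack([dams, sires])


def simulate_pedigree(
    config: PedigreeConfig = PedigreeConfig(),
    seed: int | np.random.Generator = 0,
) -> pd.DataFrame:
    """Simulate the breeding structure.

    Returns a DataFrame with columns ``id, dam, sire, generation, sex,
    is_breeder, extra_pair`` in storage order (parents always precede
    offspring).  Phantom founders form generation 0 and have unknown (0)
    parents.  ``extra_pair`` marks offspring whose recorded parents differ
    from the social pair.
    """
    rng = np.random.default_rng(seed)
    lo, hi = config.size_range

    sizes = rng.integers(lo, hi + 1, size=config.n_generations + 1)
    # generation 0: phantom monogamous pairs, as many pairs as a typical
    # generation would produce, so generation 1 has realistic sibship sizes
    n_pairs0 = int(round(config.breeder_fraction * sizes[0] / 2))
    n_phantom = 2 * n_pairs0

    ids = list(range(1, n_phantom + 1))
    dam = [UNKNOWN] * n_phantom
    sire = [UNKNOWN] * n_phantom
    generation = [0] * n_phantom
    sex = ["F", "M"] * n_pairs0
    is_breeder = [True] * n_phantom
    extra_pair = [False] * n_phantom
    pairs = np.column_stack(
        [np.arange(1, n_phantom + 1, 2), np.arange(2, n_phantom + 1, 2)]
    )
    breeder_females = pairs[:, 0]
    breeder_males = pairs[:, 1]

    next_id = n_phantom + 1
    for g in range(1, config.n_generations + 1):
        n = int(sizes[g])
        gen_ids = np.arange(next_id, next_id + n)
        next_id += n
        gen_sex = _balanced_sexes(n, rng)

        pair_idx = rng.integers(0, len(pairs), size=n)
        gen_dam = pairs[pair_idx, 0].copy()
        gen_sire = pairs[pair_idx, 1].copy()

        # extra-pair events: exactly round(rate * n) offspring get one
        # parent reselected among same-sex breeders of the parental generation
        n_ep = int(round(config.extra_pair_rate * n))
        gen_ep = np.zeros(n, dtype=bool)
        if n_ep > 0:
            chosen = rng.choice(n, size=n_ep, replace=False)
            gen_ep[chosen] = True
            for k in chosen:
                if rng.random() < 0.5 and len(breeder_females) > 1:
                    pool = breeder_females[breeder_females != gen_dam[k]]
                    gen_dam[k] = rng.choice(pool)
                elif len(breeder_males) > 1:
                    pool = breeder_males[breeder_males != gen_sire[k]]
                    gen_sire[k] = rng.choice(pool)

        n_pairs = int(round(config.breeder_fraction * n / 2))
        if g < config.n_generations:
            pairs = _make_pairs(gen_ids, gen_sex, n_pairs, rng)
            breeder_females = pairs[:, 0]
            breeder_males = pairs[:, 1]
            gen_breeder = np.isin(gen_ids, pairs)
        else:
            gen_breeder = np.zeros(n, dtype=bool)

        ids.extend(gen_ids)
        dam.extend(gen_dam)
        sire.extend(gen_sire)
        generation.extend([g] * n)
        sex.extend(gen_sex)
        is_breeder.extend(gen_breeder)
        extra_pair.extend(gen_ep)

    return pd.DataFrame(
        {
            "id": np.array(ids, dtype=int),
            "dam": np.array(dam, dtype=int),
            "sire": np.array(sire, dtype=int),
            "generation": np.array(generation, dtype=int),
            "sex": sex,
            "is_breeder": np.array(is_breeder, dtype=bool),
            "extra_pair": np.array(extra_pair, dtype=bool),
        }
    )


def validate_pedigree(ped: pd.DataFrame) -> None:
    """Raise ValueError if the pedigree violates its structural invariants."""
    ids = ped["id"].to_numpy()
    if len(np.unique(ids)) != len(ids):
        raise ValueError("duplicate ids in pedigree")
    pos = {int(i): k for k, i in enumerate(ids)}
    sex = ped["sex"].to_numpy()
    gen = ped["generation"].to_numpy()
    for row, (i, d, s, g) in enumerate(
        zip(ids, ped["dam"].to_numpy(), ped["sire"].to_numpy(), gen)
    ):
        for parent, want_sex in ((d, "F"), (s, "M")):
            if parent == UNKNOWN:
                continue
            if int(parent) not in pos:
                raise ValueError(f"parent {parent} of {i} absent from pedigree")
            p = pos[int(parent)]
            if p >= row:
                raise ValueError(f"parent {parent} stored after offspring {i}")
            if sex[p] != want_sex:
                raise ValueError(f"parent {parent} of {i} has wrong sex")
            if gen[p] != g - 1:
                raise ValueError(
                    f"parent {parent} of {i} is not in the previous generation"
                )


def build_relatedness(ped: pd.DataFrame, validate: bool = True) -> LabeledMatrix:
    """Additive relatedness matrix A by the recursive tabular method.

    Covers every individual in the pedigree, phantom founders included.
    Diagonal entries are ``1 + F_i`` with F_i the inbreeding coefficient
    ``0.5 * A[dam, sire]``.
    """
    if validate:
        validate_pedigree(ped)
    ids = ped["id"].to_numpy()
    pos = {int(i): k for k, i in enumerate(ids)}
    dam = np.array([pos.get(int(d), -1) for d in ped["dam"]])
    sire = np.array([pos.get(int(s), -1) for s in ped["sire"]])
    n = len(ids)
    A = np.zeros((n, n))
    for i in range(n):
        d, s = dam[i], sire[i]
        if d >= 0 and s >= 0:
            if i > 0:
                row = 0.5 * (A[d, :i] + A[s, :i])
                A[i, :i] = row
                A[:i, i] = row
            A[i, i] = 1.0 + 0.5 * A[d, s]
        elif d >= 0 or s >= 0:
            p = d if d >= 0 else s
            if i > 0:
                row = 0.5 * A[p, :i]
                A[i, :i] = row
                A[:i, i] = row
            A[i, i] = 1.0
        else:
            A[i, i] = 1.0
    return LabeledMatrix(ids, A, kind="GENETIC")


def inbreeding_coefficients(ped: pd.DataFrame, A: LabeledMatrix | None = None) -> pd.Series:
    """Per-individual inbreeding coefficient F_i = diag(A)_i - 1."""
    if A is None:
        A = build_relatedness(ped)
    f = np.diag(A.values) - 1.0
    return pd.Series(f, index=ped["id"].to_numpy(), name="F")
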