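"""Breeding values, environmental effects, and phenotype composition.

Three continuous phenotypes are composed additively from independent
components, each simulated with mean 0 and variance ~1:

* trait 1 (tail-fin colour):  y1 = a + n + r
* trait 2 (body size):        y2 = a + n + Mn + r
* trait 3 (swimming speed):   y3 = a + Ma + n + Mn + r

where a is the individual's breeding value, n the direct environmental
effect (a linear combination of the L environmental variables), Mn the
maternal environmental effect (the same linear rule applied to the dam's
environment), Ma the dam's maternal genetic value (a second, independent
set of breeding values carried by the dam), and r an iid residual drawn
independently per trait.  No covariances between components are built in;
limited dispersal does induce a spatial n-Mn correlation, which is the
point of the exercise.

Breeding values follow the pedigree: founders are N(0, 1); an offspring
is the midparent average plus a Mendelian sampling deviation with
variance 0.5 * (1 - (F_dam + F_sire) / 2), which keeps the additive
covariance between any two individuals equal to their A entry.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from pedvar.pedigree import UNKNOWN, build_relatedness


def default_effect_weights(n_vars: int = 5) -> np.ndarray:
    """Equal weights beta_l = 1/sqrt(L): unit-norm, so that a weighted sum of
    independent unit-variance environments has variance ~1."""
    return np.full(n_vars, 1.0 / np.sqrt(n_vars))


def simulate_additive_values(
    ped: pd.DataFrame,
    seed: int | np.random.Generator = 0,
    inbreeding: pd.Series | None = None,
) -> pd.Series:
    """One additive (breeding) value per pedigree member.

    Used both for the direct breeding values a and -- with an independent
    seed -- for the maternal genetic values underlying Ma.  ``inbreeding``
    (F per id) is computed from the relatedness matrix when not supplied.
    """
    rng = np.random.default_rng(seed)
    if inbreeding is None:
        from pedvar.pedigree import inbreeding_coefficients

        inbreeding = inbreeding_coefficients(ped)
    ids = ped["id"].to_numpy()
    pos = {int(i): k for k, i in enumerate(ids)}
    F = inbreeding.loc[ids].to_numpy()
    a = np.zeros(len(ids))
    z = rng.standard_normal(len(ids))
    for i, (d, s) in enumerate(zip(ped["dam"].to_numpy(), ped["sire"].to_numpy())):
        if d == UNKNOWN and s == UNKNOWN:
            a[i] = z[i]
        else:
            pd_, ps = pos.get(int(d), -1), pos.get(int(s), -1)
            mid, msv = 0.0, 1.0
            if pd_ >= 0 and ps >= 0:
                mid = 0.5 * (a[pd_] + a[ps])
                msv = 0.5 * (1.0 - 0.5 * (F[pd_] + F[ps]))
            elif pd_ >= 0 or ps >= 0:
                p = pd_ if pd_ >= 0 else ps
                mid = 0.5 * a[p]
                msv = 0.75 - 0.25 * F[p]
            a[i] = mid + np.sqrt(msv) * z[i]
    return pd.Series(a, index=ids, name="a")


def environmental_effect(env: pd.DataFrame, weights: np.ndarray) -> pd.Series:
    """Direct environmental effect n_i = sum_l k_{l,i} * beta_l."""
    K = env.drop(columns="id").to_numpy()
    weights = np.asarray(weights, dtype=float)
    if K.shape[1] != len(weights):
        raise ValueError("weights length does not match environment variables")
    return pd.Series(K @ weights, index=env["id"].to_numpy(), name="n")


def compose_traits(
    ped: pd.DataFrame,
    env: pd.DataFrame,
    seed: int | np.random.Generator = 0,
    beta: np.ndarray | None = None,
    beta_m: np.ndarray | None = None,
    inbreeding: pd.Series | None = None,
) -> pd.DataFrame:
    """Simulate all components and compose the three phenotypes.

    Returns one row per non-phantom individual (phenotypes are not defined
    for phantom founders) with columns ``id, a, Ma, n, Mn, r1, r2, r3,
    y1, y2, y3``.  The stored components reconstruct each phenotype
    exactly.

    ``beta_m`` defaults to ``beta`` (maternal environmental effects use the
    same weighting as direct ones); pass an independent vector to decouple
    them.
    """
    rng = np.random.default_rng(seed)
    n_vars = env.shape[1] - 1
    if beta is None:
        beta = default_effect_weights(n_vars)
    if beta_m is None:
        beta_m = beta

    if inbreeding is None:
        from pedvar.pedigree import inbreeding_coefficients

        inbreeding = inbreeding_coefficients(ped)

    seeds = np.random.SeedSequence(
        rng.integers(0, 2**31 - 1)
    ).spawn(3)
    a = simulate_additive_values(ped, seeds[0], inbreeding)
    m = simulate_additive_values(ped, seeds[1], inbreeding)  # maternal genetic
    n_eff = environmental_effect(env, beta)
    mn_source = environmental_effect(env, beta_m)

    keep = ped["generation"].to_numpy() >= 1
    ids = ped["id"].to_numpy()[keep]
    dams = ped["dam"].to_numpy()[keep]
    if np.any(dams == UNKNOWN):
        raise ValueError("phenotyped individual with unknown dam")

    rr = np.random.default_rng(seeds[2])
    r = rr.standard_normal((len(ids), 3))

    out = pd.DataFrame({"id": ids})
    out["a"] = a.loc[ids].to_numpy()
    out["Ma"] = m.loc[dams].to_numpy()
    out["n"] = n_eff.loc[ids].to_numpy()
    out["Mn"] = mn_source.loc[dams].to_numpy()
    out["r1"], out["r2"], out["r3"] = r[:, 0], r[:, 1], r[:, 2]
    out["y1"] = out["a"] + out["n"] + out["r1"]
    out["y2"] = out["a"] + out["n"] + out["Mn"] + out["r2"]
    out["y3"] = out["a"] + out["Ma"] + out["n"] + out["Mn"] + out["r3"]
    return out
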