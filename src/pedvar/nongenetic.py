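"""Epiallele profiles and the distance-structured social network.

Epialleles are modelled as CpG-island methylation counts in [0, 20].
Three island classes are simulated:

* ``ENV`` islands respond to the environment the individual experiences
  itself: the count is Binomial(20, logistic(w . k_i)) with an
  island-specific, fixed, unit-norm weight vector w.
* ``MATERNAL`` islands are maternally transmissible: with a configurable
  reset probability the count is redrawn from the individual's own
  environment (same Binomial-logistic rule), otherwise the dam's count is
  copied verbatim.
* ``RANDOM`` islands are uniform integers on [0, 20], independent of
  everything -- pure noise columns.

The social network is a simple undirected graph over the non-phantom
generations.  Within a generation the connection probability decays
exponentially with spatial distance; between adjacent generations the
same probability is attenuated by a constant factor, except that each
mother-offspring pair connects with a fixed high probability regardless
of distance.  Generations further apart are never directly linked.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist
from scipy.special import expit

from pedvar.pedigree import UNKNOWN


@dataclass(frozen=True)
class EpialleleConfig:
    n_env: int = 100
    n_maternal: int = 30
    n_random: int = 100
    max_count: int = 20
    reset_prob: float = 0.5

    @property
    def n_islands(self) -> int:
        return self.n_env + self.n_maternal + self.n_random


@dataclass
class EpialleleTable:
    """Methylation counts (individuals x islands) plus per-island class labels."""

    counts: pd.DataFrame  # index: id; columns: isl_001..isl_NNN
    island_class: np.ndarray  # {"ENV", "MATERNAL", "RANDOM"} per island


def _island_counts(K: np.ndarray, w: np.ndarray, max_count: int, rng) -> np.ndarray:
    """Binomial-logistic response of one island to environments K (n x L)."""
    p = expit(K @ w)
    return rng.binomial(max_count, p)


def simulate_epialleles(
    env: pd.DataFrame,
    ped: pd.DataFrame,
    config: EpialleleConfig = EpialleleConfig(),
    seed: int | np.random.Generator = 0,
) -> EpialleleTable:
    """Simulate methylation counts for every individual in ``env``.

    ``env`` must cover all pedigree members (phantom founders included) so
    the maternal transmission chain is well defined from generation 1 on.
    """
    rng = np.random.default_rng(seed)
    ids = env["id"].to_numpy()
    K = env.drop(columns="id").to_numpy()
    n, L = K.shape
    pos = {int(i): k for k, i in enumerate(ids)}

    ped = ped.set_index("id", drop=False).loc[ids]
    gen = ped["generation"].to_numpy()
    dam = ped["dam"].to_numpy()

    classes = np.array(
        ["ENV"] * config.n_env
        + ["MATERNAL"] * config.n_maternal
        + ["RANDOM"] * config.n_random
    )
    counts = np.zeros((n, config.n_islands), dtype=int)
    col = 0

    for _ in range(config.n_env):
        w = rng.standard_normal(L)
        w /= np.linalg.norm(w)
        counts[:, col] = _island_counts(K, w, config.max_count, rng)
        col += 1

    for _ in range(config.n_maternal):
        w = rng.standard_normal(L)
        w /= np.linalg.norm(w)
        island = np.zeros(n, dtype=int)
        # transmission runs down the generations: founders always use the
        # own-environment rule, descendants copy the dam unless reset
        for g in np.sort(np.unique(gen)):
            mask = gen == g
            own = _island_counts(K[mask], w, config.max_count, rng)
            if g == gen.min():
                island[mask] = own
            else:
                reset = rng.random(mask.sum()) < config.reset_prob
                dam_idx = np.array([pos[int(d)] for d in dam[mask]])
                island[mask] = np.where(reset, own, island[dam_idx])
        counts[:, col] = island
        col += 1

    for _ in range(config.n_random):
        counts[:, col] = rng.integers(0, config.max_count + 1, size=n)
        col += 1

    width = len(str(config.n_islands))
    frame = pd.DataFrame(
        counts,
        index=pd.Index(ids, name="id"),
        columns=[f"isl_{j + 1:0{width}d}" for j in range(config.n_islands)],
    )
    return EpialleleTable(counts=frame, island_class=classes)


@dataclass(frozen=True)
class NetworkConfig:
    """Connection probabilities for the social network.

    base_prob
        Within-generation probability at distance 0 (p0).
    decay
        Distance scale lambda of the exponential decay exp(-d / lambda),
        in grid cells.
    attenuation
        Multiplier (< 1) applied between adjacent generations.
    mother_offspring_prob
        Connection probability for each mother-offspring pair, regardless
        of distance.
    """

    base_prob: float = 0.8
    decay: float = 4.0
    attenuation: float = 0.25
    mother_offspring_prob: float = 0.9


def simulate_network(
    loc: pd.DataFrame,
    ped: pd.DataFrame,
    config: NetworkConfig = NetworkConfig(),
    seed: int | np.random.Generator = 0,
) -> nx.Graph:
    """Simulate the social network over non-phantom individuals.

    Phantom founders (generation 0) carry no social data and are excluded,
    mirroring the missing-data convention for first-generation parents.
    """
    rng = np.random.default_rng(seed)
    ped = ped.set_index("id", drop=False).loc[loc["id"].to_numpy()]
    gen = ped["generation"].to_numpy()
    keep = gen >= 1
    ids = ped["id"].to_numpy()[keep]
    gen = gen[keep]
    dam = ped["dam"].to_numpy()[keep]
    xy = loc.set_index("id").loc[ids][["x", "y"]].to_numpy(dtype=float)

    G = nx.Graph()
    G.add_nodes_from(int(i) for i in ids)

    generations = np.sort(np.unique(gen))
    for gi, g in enumerate(generations):
        a = np.where(gen == g)[0]
        # within-generation links
        d = cdist(xy[a], xy[a])
        p = config.base_prob * np.exp(-d / config.decay)
        draw = rng.random((len(a), len(a)))
        for u, v in zip(*np.where(np.triu(draw < p, k=1))):
            G.add_edge(int(ids[a[u]]), int(ids[a[v]]))
        # links to the next generation (attenuated; mother-offspring special)
        if gi + 1 < len(generations) and generations[gi + 1] == g + 1:
            b = np.where(gen == g + 1)[0]
            d = cdist(xy[a], xy[b])
            p = config.attenuation * config.base_prob * np.exp(-d / config.decay)
            dam_map = {int(i): r for r, i in enumerate(ids[a])}
            for cidx, dmother in enumerate(dam[b]):
                r = dam_map.get(int(dmother))
                if r is not None:
                    p[r, cidx] = config.mother_offspring_prob
            draw = rng.random(d.shape)
            for u, v in zip(*np.where(draw < p)):
                G.add_edge(int(ids[a[u]]), int(ids[b[v]]))
    return G
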