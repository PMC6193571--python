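"""End-to-end orchestration: simulate, build matrices, fit model suites.

``simulate_population`` wires the simulator modules together with one
master config and seed.  ``run_suite`` fits, per replicate, the full set
of model variants for the three traits (13 models: four for tail-fin
colour, six for body size, three for swimming speed) and stacks the
results into a tidy report.  ``subsample_study`` refits the true models
on random subsets of the phenotyped individuals to show how estimates
and their standard errors degrade with data size.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from pedvar.containers import LabeledMatrix
from pedvar.environment import (
    EnvField,
    GridSpec,
    assign_environments,
    field_cholesky,
    place_individuals,
    simulate_env_field,
)
from pedvar.matrices import feature_similarity, make_psd, social_similarity
from pedvar.nongenetic import (
    EpialleleConfig,
    EpialleleTable,
    NetworkConfig,
    simulate_epialleles,
    simulate_network,
)
from pedvar.pedigree import PedigreeConfig, build_relatedness, simulate_pedigree
from pedvar.reml import FitResult, ModelSpec, RandomTerm, assemble, heritability, reml_fit
from pedvar.traits import compose_traits, default_effect_weights


@dataclass(frozen=True)
class SimulationConfig:
    """Master configuration for one simulated population."""

    pedigree: PedigreeConfig = PedigreeConfig()
    grid: GridSpec = GridSpec()
    phi: float = 0.15
    n_env_vars: int = 5
    dispersal_mu: float = 1.0
    dispersal_sigma2: float = 1.0
    epialleles: EpialleleConfig = EpialleleConfig()
    network: NetworkConfig = NetworkConfig()
    independent_maternal_weights: bool = False


@dataclass
class Population:
    """One simulated population with its true components and matrices."""

    config: SimulationConfig
    seed: int
    pedigree: pd.DataFrame
    locations: pd.DataFrame
    field: EnvField
    env: pd.DataFrame
    traits: pd.DataFrame
    A: LabeledMatrix
    epialleles: EpialleleTable | None = None
    network: nx.Graph | None = None

    @property
    def phenotyped_ids(self) -> np.ndarray:
        return self.traits["id"].to_numpy()


def simulate_population(
    config: SimulationConfig = SimulationConfig(),
    seed: int = 0,
    include_epialleles: bool = True,
    include_network: bool = True,
    field_chol: np.ndarray | None = None,
) -> Population:
    """Simulate one full population from a single seed.

    Set ``include_epialleles`` / ``include_network`` to False to skip
    components not needed downstream (they do not affect the phenotypes).
    ``field_chol`` can carry a precomputed Cholesky factor of the grid
    covariance when many replicates share a grid and phi.
    """
    ss = np.random.SeedSequence(seed)
    s_ped, s_field, s_loc, s_epi, s_net, s_traits = ss.spawn(6)

    ped = simulate_pedigree(config.pedigree, np.random.default_rng(s_ped))
    A = build_relatedness(ped, validate=False)
    inbreeding = pd.Series(np.diag(A.values) - 1.0, index=ped["id"].to_numpy())

    fld = simulate_env_field(
        config.grid,
        phi=config.phi,
        n_vars=config.n_env_vars,
        seed=np.random.default_rng(s_field),
        chol=field_chol,
    )
    loc = place_individuals(
        ped,
        config.grid,
        dispersal_mu=config.dispersal_mu,
        dispersal_sigma2=config.dispersal_sigma2,
        seed=np.random.default_rng(s_loc),
    )
    env = assign_environments(loc, fld)

    beta = default_effect_weights(config.n_env_vars)
    if config.independent_maternal_weights:
        rngw = np.random.default_rng(s_traits.spawn(1)[0])
        beta_m = rngw.standard_normal(config.n_env_vars)
        beta_m /= np.linalg.norm(beta_m)
    else:
        beta_m = None
    traits = compose_traits(
        ped,
        env,
        seed=np.random.default_rng(s_traits),
        beta=beta,
        beta_m=beta_m,
        inbreeding=inbreeding,
    )

    epi = (
        simulate_epialleles(env, ped, config.epialleles, np.random.default_rng(s_epi))
        if include_epialleles
        else None
    )
    net = (
        simulate_network(loc, ped, config.network, np.random.default_rng(s_net))
        if include_network
        else None
    )

    return Population(
        config=config,
        seed=seed,
        pedigree=ped,
        locations=loc,
        field=fld,
        env=env,
        traits=traits,
        A=A,
        epialleles=epi,
        network=net,
    )


def build_all_matrices(pop: Population, psd_floor: float = 1e-8) -> dict[str, LabeledMatrix]:
    """Covariance structures for fitting, PSD-repaired where needed.

    Nongenetic matrices cover the phenotyped individuals only (phantom
    founders have no environmental, epiallelic, or social data); A covers
    the whole pedigree.
    """
    ids = pop.phenotyped_ids
    mats = {"A": pop.A}
    env_sub = pop.env.set_index("id", drop=False).loc[ids].reset_index(drop=True)
    mats["Sn"] = make_psd(feature_similarity(env_sub, kind="ENV"), psd_floor)
    if pop.epialleles is not None:
        tab = pop.epialleles.counts.loc[ids].reset_index()
        mats["Sepi"] = make_psd(feature_similarity(tab, kind="EPI"), psd_floor)
    if pop.network is not None:
        mats["Sc"] = make_psd(social_similarity(pop.network, ids=ids), psd_floor)
    return mats


# the model variants fitted per trait (13 in total); terms are
# (name, covariance source, carrier)
MODEL_SUITE: dict[str, list[tuple[str, tuple[RandomTerm, ...]]]] = {
    "y1": [
        ("a_r", (RandomTerm("additive", "A"),)),
        ("a_n_r", (RandomTerm("additive", "A"), RandomTerm("env", "Sn"))),
        ("a_epi_r", (RandomTerm("additive", "A"), RandomTerm("epi", "Sepi"))),
        ("a_c_r", (RandomTerm("additive", "A"), RandomTerm("social", "Sc"))),
    ],
    "y2": [
        ("a_r", (RandomTerm("additive", "A"),)),
        ("a_n_r", (RandomTerm("additive", "A"), RandomTerm("env", "Sn"))),
        (
            "a_n_M_r",
            (
                RandomTerm("additive", "A"),
                RandomTerm("env", "Sn"),
                RandomTerm("maternal", "identity", "dam"),
            ),
        ),
        (
            "a_n_Mn_r",
            (
                RandomTerm("additive", "A"),
                RandomTerm("env", "Sn"),
                RandomTerm("maternal_env", "Sn", "dam"),
            ),
        ),
        (
            "a_epi_Mepi_r",
            (
                RandomTerm("additive", "A"),
                RandomTerm("epi", "Sepi"),
                RandomTerm("maternal_epi", "Sepi", "dam"),
            ),
        ),
        (
            "a_c_Mc_r",
            (
                RandomTerm("additive", "A"),
                RandomTerm("social", "Sc"),
                RandomTerm("maternal_social", "Sc", "dam"),
            ),
        ),
    ],
    "y3": [
        ("a_r", (RandomTerm("additive", "A"),)),
        (
            "a_n_M_r",
            (
                RandomTerm("additive", "A"),
                RandomTerm("env", "Sn"),
                RandomTerm("maternal", "identity", "dam"),
            ),
        ),
        (
            "a_Ma_n_Mn_r",
            (
                RandomTerm("additive", "A"),
                RandomTerm("maternal_genetic", "A", "dam"),
                RandomTerm("env", "Sn"),
                RandomTerm("maternal_env", "Sn", "dam"),
            ),
        ),
    ],
}

# the generating ("true") model for each trait
TRUE_MODELS = {"y1": "a_n_r", "y2": "a_n_Mn_r", "y3": "a_Ma_n_Mn_r"}


def fit_model(
    pop: Population,
    matrices: dict[str, LabeledMatrix],
    trait: str,
    terms: tuple[RandomTerm, ...],
    traits_table: pd.DataFrame | None = None,
    **fit_kwargs,
) -> FitResult:
    """Assemble and fit one model variant for one trait."""
    spec = ModelSpec(response=trait, random_terms=tuple(terms))
    table = pop.traits if traits_table is None else traits_table
    model = assemble(spec, table, pop.pedigree, matrices)
    return reml_fit(model, **fit_kwargs)


def _suite_rows(fit: FitResult, *, replicate, seed, trait, label) -> list[dict]:
    try:
        h2, h2_se = heritability(fit, "additive")
    except (ValueError, KeyError):
        h2, h2_se = np.nan, np.nan
    pw = fit.p_wald
    rows = []
    for k, term in enumerate(fit.term_names):
        rows.append(
            {
                "replicate": replicate,
                "seed": seed,
                "trait": trait,
                "model": label,
                "term": term,
                "estimate": fit.estimates[k],
                "se": fit.se[k],
                "p_wald": pw.get(term, np.nan),
                "h2": h2,
                "h2_se": h2_se,
                "loglik": fit.loglik,
                "converged": fit.converged,
                "n": fit.n,
            }
        )
    return rows


def run_suite(
    config: SimulationConfig = SimulationConfig(),
    seeds: list[int] = (0,),
    models: dict[str, list] | None = None,
) -> pd.DataFrame:
    """Simulate one population per seed and fit every model variant.

    Returns a tidy DataFrame with one row per replicate x trait x model x
    term.  Non-converged fits are recorded with their flag, never fatal.
    """
    models = MODEL_SUITE if models is None else models
    need_epi = any("Sepi" in {t.source for _, ts in ms for t in ts} for ms in models.values())
    need_net = any("Sc" in {t.source for _, ts in ms for t in ts} for ms in models.values())
    rows = []
    for rep, seed in enumerate(seeds):
        pop = simulate_population(
            config, seed, include_epialleles=need_epi, include_network=need_net
        )
        mats = build_all_matrices(pop)
        for trait, variants in models.items():
            for label, terms in variants:
                fit = fit_model(pop, mats, trait, terms)
                rows.extend(
                    _suite_rows(fit, replicate=rep, seed=seed, trait=trait, label=label)
                )
    return pd.DataFrame(rows)


def recovery_experiment(
    config: SimulationConfig = SimulationConfig(),
    seeds: list[int] = tuple(range(5)),
    extra_naive_seeds: list[int] = (),
) -> pd.DataFrame:
    """Replicated parameter-recovery study for the genetic/environmental suite.

    For each seed a fresh population is simulated and four models fitted:
    the true model of each trait (trait 1: genetic + environmental; trait
    2: + maternal environmental; trait 3: + maternal genetic) and the
    misspecified genetic-plus-residual model for trait 1 (which absorbs
    shared-environment variance into the genetic term).  ``extra_naive_seeds``
    adds replicates on which only the misspecified model is fitted.

    Epialleles and the social network are not simulated: these fits need
    only A and the environmental similarity matrix.
    """
    variants = {
        "y1": [("a_n_r", dict(MODEL_SUITE["y1"])["a_n_r"]),
               ("a_r", dict(MODEL_SUITE["y1"])["a_r"])],
        "y2": [("a_n_Mn_r", dict(MODEL_SUITE["y2"])["a_n_Mn_r"])],
        "y3": [("a_Ma_n_Mn_r", dict(MODEL_SUITE["y3"])["a_Ma_n_Mn_r"])],
    }
    naive_only = {"y1": [("a_r", dict(MODEL_SUITE["y1"])["a_r"])]}
    chol = field_cholesky(config.grid, config.phi)
    rows = []
    plan = [(s, variants) for s in seeds] + [(s, naive_only) for s in extra_naive_seeds]
    for rep, (seed, models) in enumerate(plan):
        pop = simulate_population(
            config, seed, include_epialleles=False, include_network=False,
            field_chol=chol,
        )
        needs_sn = any(
            t.source == "Sn" for ms in models.values() for _, ts in ms for t in ts
        )
        mats = {"A": pop.A}
        if needs_sn:
            mats = build_all_matrices(pop)
        for trait, ms in models.items():
            for label, terms in ms:
                fit = fit_model(pop, mats, trait, terms)
                rows.extend(
                    _suite_rows(fit, replicate=rep, seed=seed, trait=trait, label=label)
                )
    return pd.DataFrame(rows)


def subsample_study(
    config: SimulationConfig = SimulationConfig(),
    fractions: tuple[float, ...] = (0.25, 0.5, 0.75, 1.0),
    seeds: list[int] = tuple(range(10)),
) -> pd.DataFrame:
    """Data-requirements study: refit true models on subsets of phenotypes.

    For each replicate and fraction, a random share of phenotyped
    individuals keeps its phenotype record (the pedigree stays intact, so
    A is unchanged) and the true model of each trait is refitted.
    Fraction 1.0 reproduces the full-data fit.
    """
    if any(f <= 0 or f > 1 for f in fractions):
        raise ValueError("fractions must lie in (0, 1]")
    rows = []
    for rep, seed in enumerate(seeds):
        pop = simulate_population(
            config, seed, include_epialleles=False, include_network=False
        )
        mats = build_all_matrices(pop)
        sub_rng = np.random.default_rng(np.random.SeedSequence([seed, 7]))
        n_all = len(pop.traits)
        for frac in sorted(fractions):
            if frac == 1.0:
                table = pop.traits
            else:
                keep = sub_rng.choice(n_all, size=int(round(frac * n_all)), replace=False)
                table = pop.traits.iloc[np.sort(keep)].reset_index(drop=True)
            for trait, label in TRUE_MODELS.items():
                terms = dict(MODEL_SUITE[trait])[label]
                if any(t.source in ("Sepi", "Sc") for t in terms):
                    continue
                n_par = len(terms) + 2
                if len(table) < 5 * n_par:
                    rows.append(
                        {
                            "replicate": rep,
                            "seed": seed,
                            "fraction": frac,
                            "trait": trait,
                            "model": label,
                            "term": None,
                            "estimate": np.nan,
                            "se": np.nan,
                            "flag": "too_few_records",
                        }
                    )
                    continue
                fit = fit_model(pop, mats, trait, terms, traits_table=table)
                for row in _suite_rows(
                    fit, replicate=rep, seed=seed, trait=trait, label=label
                ):
                    row["fraction"] = frac
                    row["flag"] = "" if fit.converged else "not_converged"
                    rows.append(row)
    return pd.DataFrame(rows)
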