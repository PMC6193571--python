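"""Multiple-matrix animal model: assembly and AI-REML estimation.

The model is the linear mixed model

    y = X beta + sum_k Z_k u_k + r,      u_k ~ N(0, S_k V_k),   r ~ N(0, I V_r)

where each random term k carries an arbitrary symmetric PSD covariance
structure S_k over its levels: the additive relatedness matrix A for
genetic terms, a similarity matrix (environmental, epiallelic, social)
for nongenetic terms, or the identity for an unstructured grouping
factor.  A term's *carrier* decides the incidence matrix Z_k: ``self``
gives one level per record (Z = I for single observations per
individual); ``dam`` maps each record to its mother's level, so full and
maternal-half sibs load on the same column -- the construction for
maternal genetic (A over dams) and maternal environmental (S_n over
dams) variance.

Variance components are estimated by restricted maximum likelihood with
average-information (AI) updates, step-halving to keep the restricted
log-likelihood non-decreasing, and a positivity-preserving fixed-point
fallback when the AI step fails.  Everything is dense: the target
problems have n of a couple of thousand, where dense Cholesky
factorizations are fast and simple.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.linalg import cho_factor, cho_solve

from pedvar.containers import LabeledMatrix
from pedvar.pedigree import UNKNOWN


@dataclass(frozen=True)
class RandomTerm:
    """One random effect: a covariance source and a carrier.

    source is a key into the matrices dict handed to :func:`assemble`
    (e.g. ``"A"``, ``"Sn"``, ``"Sepi"``, ``"Sc"``, ``"identity"``);
    carrier is ``"self"`` or ``"dam"``.
    """

    name: str
    source: str
    carrier: str = "self"

    def __post_init__(self):
        if self.carrier not in ("self", "dam"):
            raise ValueError(f"unknown carrier {self.carrier!r}")


@dataclass(frozen=True)
class ModelSpec:
    response: str
    random_terms: tuple[RandomTerm, ...]

    def __post_init__(self):
        names = [t.name for t in self.random_terms]
        if len(set(names)) != len(names):
            raise ValueError("random term names must be unique")


@dataclass
class AssembledModel:
    """Numeric model pieces: y, X, and per-term level structure.

    For each random term the records-by-records covariance contribution
    G_k = Z_k S_k Z_k' is precomputed; Z_k itself is available through
    :meth:`incidence` (each row has a single 1).
    """

    y: np.ndarray
    X: np.ndarray
    term_names: list[str]
    G: list[np.ndarray]
    levels: list[np.ndarray]  # level ids per term
    level_index: list[np.ndarray]  # record -> level position per term
    record_ids: np.ndarray

    @property
    def n(self) -> int:
        return len(self.y)

    def incidence(self, k: int) -> np.ndarray:
        """Dense incidence matrix Z_k (records x levels)."""
        Z = np.zeros((self.n, len(self.levels[k])))
        Z[np.arange(self.n), self.level_index[k]] = 1.0
        return Z


def assemble(
    spec: ModelSpec,
    traits: pd.DataFrame,
    ped: pd.DataFrame,
    matrices: dict[str, LabeledMatrix],
) -> AssembledModel:
    """Build the numeric model for one response from the raw tables.

    ``matrices`` maps source names to PSD-repaired covariance structures;
    the special source ``"identity"`` needs no entry.  Records are the
    rows of ``traits``.  For dam carriers, dams absent from a similarity
    source (phantom founders) enter as extra levels with unit diagonal
    and zero off-diagonals, via :meth:`LabeledMatrix.reindex`.
    """
    ids = traits["id"].to_numpy()
    y = traits[spec.response].to_numpy(dtype=float)
    X = np.ones((len(y), 1))

    pedx = ped.set_index("id")
    dams = pedx.loc[ids, "dam"].to_numpy()

    term_names, Gs, levels, level_index = [], [], [], []
    for term in spec.random_terms:
        if term.carrier == "self":
            lev_ids = ids
            idx = np.arange(len(ids))
        else:
            if np.any(dams == UNKNOWN):
                bad = ids[dams == UNKNOWN][:5]
                raise ValueError(f"records with unresolvable dam: {bad}")
            lev_ids, idx = np.unique(dams, return_inverse=True)
        if term.source == "identity":
            S = np.eye(len(lev_ids))
        else:
            if term.source not in matrices:
                raise KeyError(f"no matrix supplied for source {term.source!r}")
            S = matrices[term.source].reindex(lev_ids).values
        Gs.append(S[np.ix_(idx, idx)])
        levels.append(np.asarray(lev_ids))
        level_index.append(idx)
        term_names.append(term.name)

    return AssembledModel(
        y=y,
        X=X,
        term_names=term_names,
        G=Gs,
        levels=levels,
        level_index=level_index,
        record_ids=ids,
    )


@dataclass
class FitResult:
    """REML estimates for one model fit.

    ``estimates``/``se`` are ordered as the model's random terms followed
    by ``"residual"``.  ``vcov`` is the asymptotic covariance of the
    variance estimates (inverse average-information matrix).  ``p_wald``
    holds one-sided Wald p-values per non-residual term; likelihood-ratio
    p-values come from :func:`lrt` on a pair of nested fits.
    """

    term_names: list[str]
    estimates: np.ndarray
    se: np.ndarray
    vcov: np.ndarray
    loglik: float
    converged: bool
    n_iter: int
    trace: list = field(repr=False)
    at_bound: np.ndarray = None
    n: int = 0

    @property
    def total_variance(self) -> float:
        return float(self.estimates.sum())

    def __getitem__(self, name: str) -> float:
        return float(self.estimates[self.term_names.index(name)])

    def se_of(self, name: str) -> float:
        return float(self.se[self.term_names.index(name)])

    @property
    def p_wald(self) -> dict[str, float]:
        out = {}
        for k, name in enumerate(self.term_names):
            if name == "residual":
                continue
            z = self.estimates[k] / self.se[k] if self.se[k] > 0 else np.inf
            out[name] = float(stats.norm.sf(z))
        return out

    def to_frame(self) -> pd.DataFrame:
        pw = self.p_wald
        return pd.DataFrame(
            {
                "term": self.term_names,
                "estimate": self.estimates,
                "se": self.se,
                "p_wald": [pw.get(t, np.nan) for t in self.term_names],
            }
        )


def _logl_pieces(theta: np.ndarray, model: AssembledModel):
    """Restricted log-likelihood and the projection pieces at theta."""
    n = model.n
    V = np.eye(n) * theta[-1]
    for t, G in zip(theta[:-1], model.G):
        V += t * G
    c, low = cho_factor(V, lower=True)
    logdetV = 2.0 * np.sum(np.log(np.diag(c)))
    Vinv = cho_solve((c, low), np.eye(n))
    X = model.X
    VinvX = Vinv @ X
    XtVinvX = X.T @ VinvX
    cx = np.linalg.cholesky(XtVinvX)
    logdetX = 2.0 * np.sum(np.log(np.diag(cx)))
    P = Vinv - VinvX @ np.linalg.solve(XtVinvX, VinvX.T)
    Py = P @ model.y
    yPy = float(model.y @ Py)
    logl = -0.5 * (logdetV + logdetX + yPy)
    return logl, P, Py


def restricted_loglik(params, model: AssembledModel) -> float:
    """Exact restricted log-likelihood (up to the usual constant).

    ``params`` orders the variance components as the model's random terms
    followed by the residual; all must be strictly positive.
    """
    theta = np.asarray(params, dtype=float)
    if np.any(theta <= 0):
        raise ValueError("variance parameters must be strictly positive")
    if len(theta) != len(model.G) + 1:
        raise ValueError("wrong number of parameters")
    return _logl_pieces(theta, model)[0]


def reml_fit(
    model: AssembledModel,
    max_iter: int = 100,
    tol_logl: float = 1e-8,
    tol_param: float = 1e-6,
    start: np.ndarray | None = None,
    verbose: bool = False,
) -> FitResult:
    """Average-information REML.

    Starts from an equal split of the sample phenotypic variance, takes AI
    (Newton-type) steps with step-halving so the restricted log-likelihood
    never decreases, and falls back to a positivity-preserving fixed-point
    update when the AI step is unusable.  Parameters are kept above a soft
    lower bound of 1e-6 * Var(y); estimates ending at the bound are
    flagged, not removed.
    """
    K = len(model.G)
    vary = float(np.var(model.y, ddof=1))
    if vary <= 0:
        raise ValueError("response is constant")
    if model.n < model.X.shape[1] + K + 1:
        raise ValueError("more parameters than records")
    bound = 1e-6 * vary
    theta = (
        np.full(K + 1, vary / (K + 1))
        if start is None
        else np.asarray(start, dtype=float).copy()
    )

    logl, P, Py = _logl_pieces(theta, model)
    trace = [(logl, theta.copy())]
    converged = False
    it = 0

    def scores_and_ai():
        # score_k = -0.5 * (tr(P G_k) - y'P G_k P y); AI from G_k P y vectors
        W = np.empty((model.n, K + 1))
        sc = np.empty(K + 1)
        for k in range(K):
            GPy = model.G[k] @ Py
            trPG = float(np.sum(P * model.G[k]))  # both symmetric
            sc[k] = -0.5 * (trPG - float(Py @ GPy))
            W[:, k] = GPy
        sc[K] = -0.5 * (float(np.trace(P)) - float(Py @ Py))
        W[:, K] = Py
        PW = P @ W
        AI = 0.5 * (W.T @ PW)
        return sc, AI

    for it in range(1, max_iter + 1):
        sc, AI = scores_and_ai()
        # Newton direction from the AI matrix; fall back if indefinite
        delta = None
        try:
            cai = np.linalg.cholesky(AI)
            delta = cho_solve((cai, True), sc)
        except np.linalg.LinAlgError:
            pass
        accepted = False
        if delta is not None:
            step = 1.0
            for _ in range(30):
                cand = np.maximum(theta + step * delta, bound)
                try:
                    cl, cP, cPy = _logl_pieces(cand, model)
                except np.linalg.LinAlgError:
                    step *= 0.5
                    continue
                if cl >= logl - 1e-12:
                    accepted = True
                    break
                step *= 0.5
        if not accepted:
            # fixed-point update theta_k <- theta_k * y'P G_k P y / tr(P G_k):
            # positive by construction and shares the AI stationary points
            num = np.empty(K + 1)
            den = np.empty(K + 1)
            for k in range(K):
                num[k] = float(Py @ (model.G[k] @ Py))
                den[k] = float(np.sum(P * model.G[k]))
            num[K] = float(Py @ Py)
            den[K] = float(np.trace(P))
            ratio = np.where(den > 0, num / np.maximum(den, 1e-300), 1.0)
            step = 1.0
            for _ in range(30):
                cand = np.maximum(theta * ratio**step, bound)
                try:
                    cl, cP, cPy = _logl_pieces(cand, model)
                except np.linalg.LinAlgError:
                    step *= 0.5
                    continue
                if cl >= logl - 1e-12:
                    accepted = True
                    break
                step *= 0.5
        if not accepted:
            break
        rel_param = np.max(np.abs(cand - theta) / np.maximum(np.abs(theta), bound))
        rel_logl = abs(cl - logl) / max(1.0, abs(logl))
        theta, new_logl, P, Py = cand, cl, cP, cPy
        trace.append((new_logl, theta.copy()))
        if verbose:
            print(f"iter {it:3d}  logL {new_logl:.8f}  theta {theta}")
        if rel_logl < tol_logl and rel_param < tol_param:
            converged = True
            logl = new_logl
            break
        logl = new_logl

    _, AI = scores_and_ai()
    try:
        vcov = np.linalg.inv(AI)
        se = np.sqrt(np.maximum(np.diag(vcov), 0.0))
    except np.linalg.LinAlgError:
        vcov = np.full((K + 1, K + 1), np.nan)
        se = np.full(K + 1, np.nan)

    return FitResult(
        term_names=list(model.term_names) + ["residual"],
        estimates=theta,
        se=se,
        vcov=vcov,
        loglik=logl,
        converged=converged,
        n_iter=it,
        trace=trace,
        at_bound=theta <= bound * (1 + 1e-9),
        n=model.n,
    )


def heritability(fit: FitResult, genetic_term: str = "additive") -> tuple[float, float]:
    """h^2 = V_genetic / V_p with a delta-method standard error.

    V_p is the sum of every estimated component including the residual.
    """
    vp = fit.total_variance
    if vp <= 0:
        raise ValueError("total variance is not positive")
    k = fit.term_names.index(genetic_term)
    va = fit.estimates[k]
    h2 = va / vp
    # gradient of va / vp wrt each component
    g = np.full(len(fit.estimates), -va / vp**2)
    g[k] += 1.0 / vp
    var_h2 = float(g @ fit.vcov @ g)
    return float(h2), float(np.sqrt(max(var_h2, 0.0)))


def lrt(full: FitResult, reduced: FitResult, tol: float = 1e-6) -> tuple[float, float]:
    """Likelihood-ratio test of one variance component on the boundary.

    Returns ``(statistic, p)`` with the statistic floored at zero and the
    p-value from the boundary mixture 0.5 * chi2_0 + 0.5 * chi2_1.
    """
    if len(reduced.term_names) != len(full.term_names) - 1:
        raise ValueError("reduced model must drop exactly one term")
    stat = 2.0 * (full.loglik - reduced.loglik)
    if stat < -tol * max(1.0, abs(full.loglik)):
        raise ValueError(
            "reduced model has higher restricted likelihood than the full model"
        )
    stat = max(stat, 0.0)
    p = 1.0 if stat == 0.0 else 0.5 * float(stats.chi2.sf(stat, df=1))
    return stat, p
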