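"""Nongenetic similarity matrices and positive-semidefinite repair.

Two similarity kernels are provided.  Feature-based similarity (used for
both the environmental matrix S_n and the epiallelic matrix S_epi)
centers and scales each feature column, computes pairwise Euclidean
distances d(i, j), and maps them to

    S(i, j) = 1 - d(i, j) / max(d),

so the diagonal is exactly 1 and the maximally distant pair scores
exactly 0.  Social similarity (S_c) maps unweighted geodesic distances
g(i, j) in the social network to S = 1 / (1 + g), with S = 1 on the
diagonal and S = 0 for pairs in different components.

Neither kernel guarantees positive semidefiniteness, which the mixed
model requires of a covariance structure (u ~ N(0, S * V)), so
:func:`make_psd` repairs a matrix by clipping negative eigenvalues and
restoring the unit diagonal by symmetric normalization.
"""

from __future__ import annotations

import logging
import warnings

import networkx as nx
import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from pedvar.containers import LabeledMatrix

logger = logging.getLogger(__name__)


def feature_similarity(table: pd.DataFrame, kind: str = "ENV") -> LabeledMatrix:
    """Similarity from per-individual feature vectors (``id`` + feature columns).

    Columns are centered and scaled to mean 0, variance 1 first, so the
    result is invariant to affine rescaling of any raw feature.  Constant
    columns (scale undefined) are dropped with a warning.
    """
    ids = table["id"].to_numpy()
    X = table.drop(columns="id").to_numpy(dtype=float)
    if len(ids) < 2 or X.shape[1] < 1:
        raise ValueError("need at least two individuals and one feature")
    sd = X.std(axis=0, ddof=1)
    const = sd == 0
    if const.any():
        warnings.warn(
            f"dropping {const.sum()} constant feature column(s); scale undefined",
            stacklevel=2,
        )
        X = X[:, ~const]
        sd = sd[~const]
        if X.shape[1] == 0:
            raise ValueError("all feature columns constant")
    X = (X - X.mean(axis=0)) / sd
    d = pdist(X)
    dmax = d.max()
    if dmax == 0:
        raise ValueError("all rows identical: maximum distance is zero")
    S = 1.0 - squareform(d) / dmax
    np.fill_diagonal(S, 1.0)
    return LabeledMatrix(ids, S, kind=kind)


def social_similarity(net: nx.Graph, ids=None) -> LabeledMatrix:
    """Similarity 1 / (1 + g) from unweighted geodesic distances g.

    ``ids`` fixes the row order (default: sorted nodes).  Pairs in
    different components get similarity 0; the diagonal is 1.
    """
    if ids is None:
        ids = np.array(sorted(net.nodes))
    else:
        ids = np.asarray(ids)
        missing = [i for i in ids if i not in net]
        if missing:
            raise ValueError(f"ids absent from network: {missing[:5]} ...")
    pos = {int(i): k for k, i in enumerate(ids)}
    n = len(ids)
    S = np.zeros((n, n))
    for source, lengths in nx.all_pairs_shortest_path_length(net):
        si = pos.get(int(source))
        if si is None:
            continue
        for target, g in lengths.items():
            ti = pos.get(int(target))
            if ti is not None and g > 0:
                S[si, ti] = 1.0 / (1.0 + g)
    S = np.maximum(S, S.T)
    np.fill_diagonal(S, 1.0)
    return LabeledMatrix(ids, S, kind="SOCIAL")


def identity_similarity(ids, kind: str = "IDENTITY") -> LabeledMatrix:
    """Identity covariance structure (iid levels), e.g. plain maternal identity."""
    ids = np.asarray(ids)
    return LabeledMatrix(ids, np.eye(len(ids)), kind=kind)


def make_psd(S: LabeledMatrix, floor: float = 1e-8) -> LabeledMatrix:
    """Repair a symmetric matrix to positive (semi)definiteness.

    Eigenvalues below ``floor`` are clipped to ``floor``; the matrix is
    reassembled and its diagonal restored to exactly 1 by symmetric
    normalization.  The maximum absolute entry change is logged.
    """
    M = 0.5 * (S.values + S.values.T)
    w, Q = np.linalg.eigh(M)
    if w[0] >= floor:
        out = M
    else:
        w = np.clip(w, floor, None)
        out = (Q * w) @ Q.T
        d = np.sqrt(np.diag(out))
        out = out / np.outer(d, d)
        out = 0.5 * (out + out.T)
    np.fill_diagonal(out, 1.0)
    delta = float(np.max(np.abs(out - S.values)))
    logger.info("make_psd(%s): max entry change %.3e", S.kind or "matrix", delta)
    return LabeledMatrix(S.ids, out, kind=S.kind)
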