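"""Latent-semantic characterization of medical codes.

Codes that indicate a common latent clinical state (insulin dispensings,
diabetes diagnoses, diabetic retinopathy, ...) co-occur across pregnancies.
A truncated SVD of the log-transformed pregnancy x code count matrix places
such codes close together: each code's vector is its right singular vector
scaled by the singular value, cosine similarity measures relatedness, and
agglomerative clustering on the angular distance arccos(cos)/pi groups
selected codes into interpretable clusters.

Conventions: counts enter as log(1 + count); the matrix is not centered
(classical latent-semantic-analysis practice, configurable); the retained
rank defaults to 500 but is capped at the matrix rank.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .simulate import ConfigError


@dataclass
class LatentSpace:
    """Reduced-rank code embedding from truncated SVD of log counts."""

    k: int
    singular_values: np.ndarray      # descending, non-negative
    code_vectors: np.ndarray         # codes x k (right vectors * sigma)
    codes: pd.DataFrame              # code metadata, aligned to rows


@dataclass
class CodeSimilarity:
    """Pairwise cosine and angular distance for a selected code subset."""

    codes: pd.DataFrame
    cosine: np.ndarray
    angular: np.ndarray              # arccos(clipped cosine) / pi, in [0, 1]
    zero_norm: np.ndarray            # flagged codes excluded from clustering


@dataclass
class CodeClustering:
    """Flat groups from average-linkage agglomeration at a distance cut."""

    linkage: np.ndarray
    labels: np.ndarray
    groups: pd.DataFrame             # group, members ("; "-joined), size
    cut: float


def build_latent_space(
    counts, codes: pd.DataFrame, k: int = 500,
    center: bool = False, seed: int = 0,
) -> LatentSpace:
    """Truncated SVD of log(1 + count) over all mapped codes.

    ``counts`` is the (pregnancies x codes) count matrix (sparse or dense);
    ``codes`` its column metadata.  Retains min(k, rank) components.  Small
    problems use an exact dense SVD; larger ones a seeded randomized solver.
    """
    if k < 1:
        raise ConfigError(f"rank k must be >= 1, got {k}")
    if sparse.issparse(counts):
        X = counts.copy().astype(float)
        X.data = np.log1p(X.data)
        n, d = X.shape
    else:
        X = np.log1p(np.asarray(counts, dtype=float))
        n, d = X.shape
    if n < 2 or d < 2:
        raise ConfigError("latent space needs at least 2 rows and 2 columns")
    if center:
        X = np.asarray(X.todense()) if sparse.issparse(X) else X
        X = X - X.mean(axis=0, keepdims=True)
    k_eff = min(k, n, d)

    if min(n, d) <= 800 or k_eff >= min(n, d) - 1:
        Xd = np.asarray(X.todense()) if sparse.issparse(X) else X
        _, s, vt = np.linalg.svd(Xd, full_matrices=False)
        s, vt = s[:k_eff], vt[:k_eff]
    else:
        from sklearn.decomposition import TruncatedSVD
        svd = TruncatedSVD(n_components=k_eff, random_state=seed)
        svd.fit(X)
        s, vt = svd.singular_values_, svd.components_
        order = np.argsort(-s)
        s, vt = s[order], vt[order]
    vectors = vt.T * s[None, :]
    return LatentSpace(k=k_eff, singular_values=s, code_vectors=vectors,
                       codes=codes.reset_index(drop=True))


def code_cosines(space: LatentSpace, selected=None) -> CodeSimilarity:
    """Pairwise cosine similarity of (selected) code vectors.

    Zero-norm vectors have undefined similarity; they are flagged and their
    rows/columns carry NaN, and clustering excludes them.
    """
    if selected is None:
        idx = np.arange(len(space.codes))
    else:
        pos = {c: i for i, c in enumerate(space.codes["code"])}
        missing = [c for c in selected if c not in pos]
        if missing:
            raise KeyError(f"codes not in latent space: {missing}")
        idx = np.array([pos[c] for c in selected])
    V = space.code_vectors[idx]
    norms = np.linalg.norm(V, axis=1)
    zero = norms < 1e-12
    safe = np.where(zero, 1.0, norms)
    U = V / safe[:, None]
    cos = np.clip(U @ U.T, -1.0, 1.0)
    np.fill_diagonal(cos, 1.0)
    cos[zero, :] = np.nan
    cos[:, zero] = np.nan
    ang = np.arccos(np.clip(cos, -1.0, 1.0)) / np.pi
    return CodeSimilarity(codes=space.codes.iloc[idx].reset_index(drop=True),
                          cosine=cos, angular=ang, zero_norm=zero)


def cluster_codes(sim: CodeSimilarity, cut: float,
                  method: str = "average") -> CodeClustering:
    """Agglomerative clustering of codes at an angular-distance cut in [0, 1].

    Zero-norm (flagged) codes are excluded and labelled -1.  Emits a grouping
    report: member code ids joined by "; " with the group size.
    """
    if not 0.0 <= cut <= 1.0:
        raise ConfigError(f"cut must be in [0, 1], got {cut}")
    if method not in ("single", "complete", "average"):
        raise ConfigError(f"unsupported linkage {method!r}")
    keep = ~sim.zero_norm
    labels = np.full(len(sim.codes), -1, dtype=np.int64)
    D = sim.angular[np.ix_(keep, keep)]
    if keep.sum() == 1:
        labels[keep] = 1
        Z = np.empty((0, 4))
    elif keep.sum() == 0:
        Z = np.empty((0, 4))
    else:
        # guard tiny asymmetries before condensing
        D = (D + D.T) / 2.0
        np.fill_diagonal(D, 0.0)
        Z = linkage(squareform(D, checks=False), method=method)
        labels[keep] = fcluster(Z, t=cut, criterion="distance")
    rows = []
    codes = sim.codes["code"].to_numpy()
    for g in sorted(set(labels[labels > 0])):
        members = codes[labels == g]
        rows.append({"group": int(g), "members": "; ".join(map(str, members)),
                     "size": int(len(members))})
    groups = pd.DataFrame(rows, columns=["group", "members", "size"])
    return CodeClustering(linkage=Z, labels=labels, groups=groups, cut=cut)
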