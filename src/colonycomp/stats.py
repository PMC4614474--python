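"""Ordination and permutation tests on shape-dissimilarity matrices.

Two tools for asking whether "winner" and "loser" founder cells differ in
the shapes of their Voronoi territories:

* non-metric multidimensional scaling (Kruskal): a 2-D map of the items in
  which inter-point distances reproduce, as well as possible, the *ranks*
  of the input dissimilarities; goodness of fit is Kruskal's stress-1,

      stress = sqrt( sum (d_ij - dhat_ij)^2 / sum d_ij^2 ),

  with dhat the best monotone (isotonic) transform of the dissimilarities;

* PERMANOVA: the observed group statistic is compared with its distribution
  under random relabelling.  The default statistic is the ratio of the mean
  between-group to the mean within-group pairwise distance (> 1 indicates
  group structure); the classical Anderson pseudo-F computed from sums of
  squared distances is available as an alternative.  p-values use the
  add-one estimator p = (1 + #{permuted >= observed}) / (B + 1), so the
  smallest attainable p is 1/(B+1).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.isotonic import IsotonicRegression
from sklearn.manifold import smacof
from scipy.spatial.distance import pdist, squareform

from .shapes import DissimilarityMatrix


@dataclass
class MDSEmbedding:
    ids: list
    coords: np.ndarray  # (n, dim)
    stress: float  # Kruskal stress-1
    restarts: int


@dataclass
class PermanovaResult:
    statistic: float
    n_permutations: int
    p_value: float
    variant: str


def kruskal_stress(D: np.ndarray, coords: np.ndarray) -> float:
    """Kruskal stress-1 of an embedding against a dissimilarity matrix.

    Embedded distances are regressed monotonically on the input
    dissimilarities; the residual norm is scaled by the embedded-distance
    norm.
    """
    delta = squareform(np.asarray(D), checks=False)
    d = pdist(coords)
    order = np.argsort(delta, kind="stable")
    iso = IsotonicRegression(increasing=True)
    dhat = np.empty_like(d)
    dhat[order] = iso.fit_transform(np.arange(len(d)), d[order])
    denom = float(np.sum(d**2))
    if denom == 0:
        return 0.0
    return float(np.sqrt(np.sum((d - dhat) ** 2) / denom))


def _classical_scaling(D: np.ndarray, dim: int) -> np.ndarray:
    """Torgerson classical scaling; used as one deterministic MDS start."""
    n = len(D)
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (D**2) @ J
    evals, evecs = np.linalg.eigh(B)
    idx = np.argsort(evals)[::-1][:dim]
    lam = np.clip(evals[idx], 0, None)
    return evecs[:, idx] * np.sqrt(lam)


def nonmetric_mds(
    D: DissimilarityMatrix,
    dim: int = 2,
    restarts: int = 8,
    tolerance: float = 1e-6,
    seed: int | None = None,
    max_iter: int = 500,
) -> MDSEmbedding:
    """Kruskal non-metric MDS by SMACOF with monotone regression.

    One start uses classical scaling (exact for Euclidean-realizable
    dissimilarities); the remaining ``restarts - 1`` use random
    configurations.  The embedding with the lowest Kruskal stress-1 wins.
    """
    v = np.asarray(D.values, dtype=float)
    n = len(v)
    if n < 3:
        raise ValueError("need at least 3 items")
    rng = np.random.default_rng(seed)
    inits = [_classical_scaling(v, dim)]
    for _ in range(max(0, restarts - 1)):
        inits.append(rng.normal(size=(n, dim)))
    best_coords, best_stress = None, np.inf
    for init in inits:
        coords, _ = smacof(
            v,
            metric=False,
            n_components=dim,
            init=init,
            n_init=1,
            max_iter=max_iter,
            eps=min(tolerance, 1e-9),
            normalized_stress=True,
        )
        s = kruskal_stress(v, coords)
        if s < best_stress:
            best_coords, best_stress = coords, s
    return MDSEmbedding(
        ids=list(D.ids), coords=best_coords, stress=best_stress, restarts=len(inits)
    )


def _ratio_statistic(d_condensed: np.ndarray, same_group: np.ndarray) -> float:
    within = d_condensed[same_group]
    between = d_condensed[~same_group]
    if len(within) == 0 or len(between) == 0:  # pragma: no cover - guarded upstream
        return np.nan
    mw = within.mean()
    if mw == 0:
        return np.inf
    return between.mean() / mw


def _pseudo_f_statistic(d2_condensed: np.ndarray, labels: np.ndarray) -> float:
    """Anderson's pseudo-F from squared distances (two groups)."""
    n = len(labels)
    ss_total = d2_condensed.sum() / n
    iu0, iu1 = np.triu_indices(n, k=1)
    ss_within = 0.0
    for g in np.unique(labels):
        members = labels == g
        pair_in_g = members[iu0] & members[iu1]
        ss_within += d2_condensed[pair_in_g].sum() / members.sum()
    a = len(np.unique(labels))
    ss_among = ss_total - ss_within
    if ss_within == 0:
        return np.inf
    return (ss_among / (a - 1)) / (ss_within / (n - a))


def permanova(
    D: DissimilarityMatrix,
    labels,
    n_permutations: int = 999,
    variant: str = "ratio",
    seed: int | None = None,
) -> PermanovaResult:
    """Two-group permutation test for location differences on a distance matrix.

    ``variant="ratio"``: mean between-group / mean within-group distance.
    ``variant="pseudo-f"``: Anderson's PERMANOVA pseudo-F.  Group labels are
    permuted ``n_permutations`` times; ties count toward significance.
    """
    labels = np.asarray(labels)
    if len(labels) != len(D):
        raise ValueError("labels must cover every item in the matrix")
    groups, counts = np.unique(labels, return_counts=True)
    if len(groups) != 2:
        raise ValueError(f"need exactly two groups, got {len(groups)}")
    if counts.min() < 2:
        raise ValueError("each group needs at least 2 members")
    if variant not in ("ratio", "pseudo-f"):
        raise ValueError(f"unknown variant {variant!r}")
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    rng = np.random.default_rng(seed)
    v = np.asarray(D.values, dtype=float)
    d = squareform(v, checks=False)
    iu0, iu1 = np.triu_indices(len(labels), k=1)

    if variant == "ratio":
        def stat(lab: np.ndarray) -> float:
            return _ratio_statistic(d, lab[iu0] == lab[iu1])
    else:
        d2 = d**2

        def stat(lab: np.ndarray) -> float:
            return _pseudo_f_statistic(d2, lab)

    observed = stat(labels)
    count = 0
    for _ in range(n_permutations):
        perm = rng.permutation(labels)
        if stat(perm) >= observed:
            count += 1
    p = (1 + count) / (n_permutations + 1)
    return PermanovaResult(
        statistic=float(observed),
        n_permutations=n_permutations,
        p_value=p,
        variant=variant,
    )
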