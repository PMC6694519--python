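"""Bray-Curtis dissimilarity, non-metric MDS, and multivariate beta-dispersion.

Bray-Curtis is only invariant to rescaling of a sample's abundances when
both samples are rescaled together; the pipeline therefore computes it on
per-sample proportions of the normalized table.

NMDS minimizes Kruskal stress-1,

    stress = sqrt( sum (d_ij - dhat_ij)^2 / sum d_ij^2 ),

where ``d`` are configuration distances and ``dhat`` the disparities from a
monotone (isotonic) regression of ``d`` on the rank order of the input
dissimilarities, with the *primary* approach to ties (tied dissimilarities
impose no order constraint).  Descent uses non-metric SMACOF from a
metric-scaling (PCoA) start plus random restarts, and a final quasi-Newton
polish of the exact stress-1 objective; the best configuration is returned.

Beta-dispersion follows the homogeneity-of-dispersions procedure: samples
are embedded by principal coordinates of the dissimilarity matrix, each
sample's distance to its group centroid is measured with squared
contributions from negative-eigenvalue axes subtracted (floored at zero
before the square root), and group differences in those distances are
tested by one-way ANOVA with a label-permutation null alongside the
parametric p-value.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats
from scipy.spatial.distance import pdist, squareform
from skbio import DistanceMatrix
from sklearn.base import BaseEstimator
from sklearn.isotonic import IsotonicRegression
from sklearn.manifold import smacof

from .tables import ValidationError


# --------------------------------------------------------------------- #
# Bray-Curtis
# --------------------------------------------------------------------- #

def bray_curtis(abundances, sample_ids=None) -> DistanceMatrix:
    """Bray-Curtis dissimilarities between the columns of an OTU x sample
    abundance matrix: d(x, y) = sum|x_i - y_i| / sum(x_i + y_i)."""
    x = np.asarray(abundances, dtype=float)
    if x.ndim != 2:
        raise ValidationError("expected a 2-D abundance matrix")
    if (x < 0).any():
        raise ValidationError("abundances must be non-negative")
    if (x.sum(axis=0) <= 0).any():
        bad = np.nonzero(x.sum(axis=0) <= 0)[0].tolist()
        raise ValidationError(f"all-zero samples at columns {bad}")
    d = squareform(pdist(x.T, metric="braycurtis"))
    ids = list(sample_ids) if sample_ids is not None else None
    return DistanceMatrix(d, ids=ids)


# --------------------------------------------------------------------- #
# NMDS
# --------------------------------------------------------------------- #

def _stress1_squared(coords: np.ndarray, dissim_condensed: np.ndarray) -> float:
    """Squared Kruskal stress-1 with primary tie-breaking.

    Sorting by (dissimilarity, configuration distance) means tied
    dissimilarities are free to follow the configuration, i.e. ties carry
    no monotonicity penalty.
    """
    d = pdist(coords)
    denom = (d**2).sum()
    if denom == 0:
        return np.inf
    order = np.lexsort((d, dissim_condensed))
    iso = IsotonicRegression(increasing=True)
    dhat = iso.fit_transform(np.arange(d.size), d[order])
    resid = ((d[order] - dhat) ** 2).sum()
    return resid / denom


def _pcoa_coords(d: np.ndarray, k: int) -> np.ndarray:
    """Classical (metric) scaling start configuration."""
    n = d.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    g = -0.5 * j @ (d**2) @ j
    vals, vecs = np.linalg.eigh(g)
    idx = np.argsort(vals)[::-1][:k]
    vals_k = np.clip(vals[idx], 0, None)
    return vecs[:, idx] * np.sqrt(vals_k)


@dataclass
class OrdinationResult:
    coordinates: np.ndarray  # samples x k
    stress: float  # Kruskal stress-1
    n_restarts_used: int
    converged: bool
    sample_ids: list | None = None


class NMDS(BaseEstimator):
    """Non-metric multidimensional scaling on a precomputed dissimilarity.

    scikit-learn-style estimator: ``fit(D)`` stores ``embedding_``,
    ``stress_`` (Kruskal stress-1), ``n_restarts_used_`` and ``converged_``.

    Parameters
    ----------
    n_components : target dimensionality (default 2).
    n_restarts : random restarts in addition to the PCoA start.
    max_iter, tol : SMACOF iteration cap and stress convergence tolerance.
    random_state : master seed; restart seeds are derived deterministically.
    """

    def __init__(
        self,
        n_components: int = 2,
        n_restarts: int = 20,
        max_iter: int = 300,
        tol: float = 1e-6,
        random_state: int | None = None,
    ):
        self.n_components = n_components
        self.n_restarts = n_restarts
        self.max_iter = max_iter
        self.tol = tol
        self.random_state = random_state

    def fit(self, X, y=None):
        d = np.asarray(X, dtype=float)
        n = d.shape[0]
        if d.shape != (n, n):
            raise ValidationError("expected a square dissimilarity matrix")
        if n < self.n_components + 1:
            raise ValidationError(
                f"need at least {self.n_components + 1} samples for "
                f"{self.n_components}-D ordination"
            )
        cond = squareform(d, checks=False)
        rng = np.random.default_rng(self.random_state)

        candidates = [_pcoa_coords(d, self.n_components)]
        for _ in range(self.n_restarts):
            candidates.append(
                rng.normal(size=(n, self.n_components))
            )

        best_coords, best_s2 = None, np.inf
        for i, init in enumerate(candidates):
            if np.ptp(cond) == 0:
                # all-equal dissimilarities: any configuration is optimal
                coords = init
            else:
                coords, _ = smacof(
                    d,
                    metric=False,
                    n_components=self.n_components,
                    init=init,
                    n_init=1,
                    max_iter=self.max_iter,
                    eps=self.tol * 1e-3,
                    random_state=int(rng.integers(2**31 - 1)),
                    normalized_stress=True,
                )
            s2 = _stress1_squared(coords, cond)
            if s2 < best_s2:
                best_coords, best_s2 = coords, s2

        # polish the exact stress-1 objective from the best SMACOF solution
        res = optimize.minimize(
            lambda flat: _stress1_squared(
                flat.reshape(n, self.n_components), cond
            ),
            best_coords.ravel(),
            method="L-BFGS-B",
            options={"maxiter": 500},
        )
        if res.fun < best_s2:
            best_coords, best_s2 = res.x.reshape(n, self.n_components), res.fun

        self.embedding_ = best_coords - best_coords.mean(axis=0)
        self.stress_ = float(np.sqrt(max(best_s2, 0.0)))
        self.n_restarts_used_ = len(candidates)
        self.converged_ = bool(res.success or best_s2 <= self.tol**2)
        return self

    def fit_transform(self, X, y=None):
        return self.fit(X).embedding_


def nmds(
    dist: DistanceMatrix | np.ndarray,
    k: int = 2,
    restarts: int = 20,
    seed: int | None = None,
) -> OrdinationResult:
    """Functional wrapper around :class:`NMDS`."""
    ids = list(dist.ids) if isinstance(dist, DistanceMatrix) else None
    d = dist.data if isinstance(dist, DistanceMatrix) else np.asarray(dist)
    est = NMDS(n_components=k, n_restarts=restarts, random_state=seed).fit(d)
    return OrdinationResult(
        coordinates=est.embedding_,
        stress=est.stress_,
        n_restarts_used=est.n_restarts_used_,
        converged=est.converged_,
        sample_ids=ids,
    )


# --------------------------------------------------------------------- #
# beta-dispersion
# --------------------------------------------------------------------- #

@dataclass
class DispersionResult:
    sample_ids: list
    groups: list
    distances: np.ndarray  # per-sample distance to group centroid
    group_means: dict
    F: float
    p_parametric: float
    p_perm: float
    n_permutations: int


def _centroid_distances(d: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """Distance of each sample to its group centroid in PCoA space,
    with the negative-eigenvalue correction."""
    n = d.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    g = -0.5 * j @ (d**2) @ j
    vals, vecs = np.linalg.eigh(g)
    tol = max(abs(vals).max(), 1.0) * 1e-10
    pos = vals > tol
    neg = vals < -tol
    x_pos = vecs[:, pos] * np.sqrt(vals[pos])
    x_neg = vecs[:, neg] * np.sqrt(-vals[neg])
    dist2 = np.zeros(n)
    for grp in np.unique(labels):
        m = labels == grp
        c_pos = x_pos[m].mean(axis=0)
        c_neg = x_neg[m].mean(axis=0) if x_neg.size else np.zeros(0)
        dist2[m] = ((x_pos[m] - c_pos) ** 2).sum(axis=1)
        if x_neg.size:
            dist2[m] -= ((x_neg[m] - c_neg) ** 2).sum(axis=1)
    return np.sqrt(np.clip(dist2, 0.0, None))


def _anova_f(values: np.ndarray, labels: np.ndarray) -> float:
    grand = values.mean()
    groups = [values[labels == g] for g in np.unique(labels)]
    ss_between = sum(len(g) * (g.mean() - grand) ** 2 for g in groups)
    ss_within = sum(((g - g.mean()) ** 2).sum() for g in groups)
    df_b = len(groups) - 1
    df_w = len(values) - len(groups)
    if ss_within == 0:
        return np.inf if ss_between > 0 else 0.0
    return (ss_between / df_b) / (ss_within / df_w)


class BetaDispersion(BaseEstimator):
    """Homogeneity-of-multivariate-dispersions test on a precomputed
    dissimilarity matrix.

    ``fit(D, y)`` stores per-sample ``distances_``, ``F_``,
    ``p_parametric_`` and the label-permutation ``p_perm_``.
    """

    def __init__(self, n_permutations: int = 999, random_state: int | None = None):
        self.n_permutations = n_permutations
        self.random_state = random_state

    def fit(self, X, y):
        d = np.asarray(X, dtype=float)
        labels = np.asarray(y)
        n = d.shape[0]
        if labels.shape[0] != n:
            raise ValidationError("one group label per sample required")
        uniq, counts = np.unique(labels, return_counts=True)
        if uniq.size < 2:
            raise ValidationError("need at least 2 groups")
        if (counts < 2).any():
            small = uniq[counts < 2].tolist()
            raise ValidationError(f"groups with fewer than 2 samples: {small}")

        dist = _centroid_distances(d, labels)
        f_obs = _anova_f(dist, labels)
        df_b = uniq.size - 1
        df_w = n - uniq.size
        p_param = float(stats.f.sf(f_obs, df_b, df_w)) if np.isfinite(f_obs) else 0.0

        # permute group labels over the fixed distances-to-centroid
        rng = np.random.default_rng(self.random_state)
        hits = 0
        for _ in range(self.n_permutations):
            f_perm = _anova_f(dist, rng.permutation(labels))
            if f_perm >= f_obs - 1e-12:
                hits += 1
        p_perm = (hits + 1) / (self.n_permutations + 1)

        self.distances_ = dist
        self.group_means_ = {
            str(g): float(dist[labels == g].mean()) for g in uniq
        }
        self.F_ = float(f_obs)
        self.p_parametric_ = p_param
        self.p_perm_ = float(p_perm)
        return self


def beta_dispersion(
    dist: DistanceMatrix | np.ndarray,
    groups,
    n_permutations: int = 999,
    seed: int | None = None,
) -> DispersionResult:
    """Functional wrapper around :class:`BetaDispersion`.

    ``groups`` is either a sequence of labels aligned with the matrix order
    or a mapping sample_id -> label (requires a skbio DistanceMatrix).
    """
    if isinstance(dist, DistanceMatrix):
        ids = list(dist.ids)
        d = dist.data
    else:
        d = np.asarray(dist)
        ids = list(range(d.shape[0]))
    if isinstance(groups, dict):
        labels = np.asarray([groups[i] for i in ids])
    else:
        labels = np.asarray(list(groups))
    est = BetaDispersion(n_permutations=n_permutations, random_state=seed).fit(d, labels)
    return DispersionResult(
        sample_ids=ids,
        groups=list(labels),
        distances=est.distances_,
        group_means=est.group_means_,
        F=est.F_,
        p_parametric=est.p_parametric_,
        p_perm=est.p_perm_,
        n_permutations=n_permutations,
    )
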