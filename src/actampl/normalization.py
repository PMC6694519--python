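"""Repeated-rarefaction normalization of uneven library depths.

Each library is subsampled without replacement (multivariate hypergeometric)
to a common depth — by default the smallest library size — and the subsample
is repeated ``iterations`` times (default 100) with the entrywise mean
carried downstream unrounded.  Diversity and dissimilarity computations act
on proportions, so integrality of the normalized table is not required;
Chao1 alone needs integer singleton/doubleton counts and is therefore
computed per iteration on the integer draws (see :mod:`actampl.alpha`).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from .tables import CountTable, ValidationError


def _check_depth(counts: np.ndarray, sample_ids, depth: int) -> None:
    sums = counts.sum(axis=0)
    short = np.asarray(sums < depth).nonzero()[0]
    if short.size:
        bad = [str(sample_ids[i]) for i in short]
        raise ValidationError(
            f"samples with fewer than depth={depth} reads: {bad}"
        )


def _draw_columns(
    counts: np.ndarray, depth: int, rng: np.random.Generator, replace: bool
) -> np.ndarray:
    """One rarefaction draw for every column of an integer count matrix."""
    out = np.empty_like(counts)
    for j in range(counts.shape[1]):
        col = counts[:, j]
        total = int(col.sum())
        if total == depth and not replace:
            out[:, j] = col
        elif replace:
            out[:, j] = rng.multinomial(depth, col / total)
        else:
            out[:, j] = rng.multivariate_hypergeometric(col, depth)
    return out


class RarefactionNormalizer(BaseEstimator, TransformerMixin):
    """Subsample every sample to a common read depth, repeatedly, and average.

    Follows the scikit-learn transformer protocol on arrays of shape
    ``(n_samples, n_otus)`` (samples as rows, per sklearn convention).
    :func:`rarefy_once` / :func:`rarefy_repeated` wrap it for
    :class:`~actampl.tables.CountTable` inputs in the package's native
    OTU-rows orientation.

    Parameters
    ----------
    depth :
        Target reads per sample, or ``"auto"`` for the smallest sample total
        seen at fit time.
    n_iterations :
        Number of independent subsampling draws averaged entrywise.
    with_replacement :
        Multinomial resampling instead of the default hypergeometric
        (without-replacement) subsampling.  Off by default: rarefaction of
        observed reads is a draw without replacement.
    random_state :
        Seed; identical inputs and seed give bit-identical output.
    """

    def __init__(
        self,
        depth: int | str = "auto",
        n_iterations: int = 100,
        with_replacement: bool = False,
        random_state: int | None = None,
    ):
        self.depth = depth
        self.n_iterations = n_iterations
        self.with_replacement = with_replacement
        self.random_state = random_state

    def fit(self, X, y=None):
        X = self._validate(X)
        if self.depth == "auto":
            self.depth_ = int(X.sum(axis=1).min())
        else:
            self.depth_ = int(self.depth)
            if self.depth_ < 1:
                raise ValidationError("depth must be a positive integer")
        if self.n_iterations < 1:
            raise ValidationError("n_iterations must be >= 1")
        return self

    def transform(self, X):
        check_is_fitted(self, "depth_")
        X = self._validate(X)
        counts = X.T  # internal orientation: OTU rows
        _check_depth(counts, list(range(counts.shape[1])), self.depth_)
        rng = np.random.default_rng(self.random_state)
        acc = np.zeros(counts.shape, dtype=float)
        for _ in range(self.n_iterations):
            acc += _draw_columns(counts, self.depth_, rng, self.with_replacement)
        return (acc / self.n_iterations).T

    @staticmethod
    def _validate(X) -> np.ndarray:
        X = np.asarray(X)
        if X.ndim != 2:
            raise ValidationError("expected a 2-D count matrix")
        if (X < 0).any() or not np.allclose(X, np.round(X)):
            raise ValidationError("counts must be non-negative integers")
        return np.round(X).astype(np.int64)


# --------------------------------------------------------------------- #
# CountTable-level wrappers
# --------------------------------------------------------------------- #

def rarefy_once(table: CountTable, depth: int, seed: int | None = None) -> CountTable:
    """A single without-replacement subsample of ``depth`` reads per sample."""
    if depth < 1:
        raise ValidationError("depth must be a positive integer")
    counts = table.data.to_numpy(dtype=np.int64)
    _check_depth(counts, table.sample_ids, depth)
    rng = np.random.default_rng(seed)
    drawn = _draw_columns(counts, depth, rng, replace=False)
    return CountTable(
        pd.DataFrame(drawn, index=table.data.index, columns=table.data.columns),
        table.sample_meta.copy(),
    )


def rarefy_repeated(
    table: CountTable,
    depth: int | None = None,
    iterations: int = 100,
    seed: int | None = None,
    with_replacement: bool = False,
) -> CountTable:
    """Entrywise mean of repeated rarefaction draws (the normalized table).

    ``depth=None`` uses the smallest library size.  Column sums of the result
    equal ``depth`` exactly (means of constant-sum draws).
    """
    if iterations < 1:
        raise ValidationError("iterations must be >= 1")
    if depth is None:
        depth = int(table.column_sums().min())
    est = RarefactionNormalizer(
        depth=depth,
        n_iterations=iterations,
        with_replacement=with_replacement,
        random_state=seed,
    )
    mean = est.fit_transform(table.data.to_numpy().T).T
    return CountTable(
        pd.DataFrame(mean, index=table.data.index, columns=table.data.columns),
        table.sample_meta.copy(),
        require_integer=False,
    )


def rarefaction_draws(
    table: CountTable, depth: int, iterations: int, seed: int | None = None
):
    """Yield the individual integer draws (used for per-iteration Chao1)."""
    counts = table.data.to_numpy(dtype=np.int64)
    _check_depth(counts, table.sample_ids, depth)
    rng = np.random.default_rng(seed)
    for _ in range(iterations):
        yield _draw_columns(counts, depth, rng, replace=False)
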