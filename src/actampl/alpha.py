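"""Per-sample alpha-diversity indices and the total-vs-active contrast.

Conventions (documented because the literature varies):

* Shannon ``H`` uses the natural logarithm (nats).
* Simpson ``D`` is the Gini–Simpson index ``1 - sum(p_i^2)``, so that a
  higher value means a more diverse community.
* Pielou evenness ``J = H / ln(S_obs)`` is undefined for a single-taxon
  sample and reported as NaN, never coerced to zero.
* Chao1 uses the classic estimator ``S_obs + F1^2 / (2 F2)`` and switches to
  the bias-corrected form ``S_obs + F1 (F1 - 1) / (2 (F2 + 1))`` when there
  are no doubletons.

All indices except Chao1 are scale-invariant, so they may be evaluated on
raw counts, rarefied means, or proportions interchangeably.  Chao1 depends
on integer singleton/doubleton counts and is computed per rarefaction
iteration and averaged.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .normalization import rarefaction_draws, rarefy_repeated
from .tables import CountTable, ValidationError


def _proportions(counts) -> np.ndarray:
    x = np.asarray(counts, dtype=float)
    if x.ndim != 1:
        raise ValidationError("expected a 1-D abundance vector")
    if (x < 0).any():
        raise ValidationError("abundances must be non-negative")
    total = x.sum()
    if total <= 0:
        raise ValidationError("all-zero abundance vector")
    return x / total


def shannon(counts) -> float:
    """Shannon index H = -sum p_i ln p_i (nats), over positive entries."""
    p = _proportions(counts)
    p = p[p > 0]
    return float(-(p * np.log(p)).sum())


def simpson(counts) -> float:
    """Gini–Simpson index D = 1 - sum p_i^2."""
    p = _proportions(counts)
    return float(1.0 - (p**2).sum())


def observed_richness(counts) -> int:
    x = np.asarray(counts, dtype=float)
    return int((x > 0).sum())


def pielou(counts) -> float:
    """Pielou evenness J = H / ln(S_obs); NaN for a single-taxon sample."""
    s = observed_richness(counts)
    if s < 2:
        return float("nan")
    return shannon(counts) / np.log(s)


def chao1(integer_counts) -> float:
    """Chao1 richness estimate from integer counts.

    Classic form when doubletons exist; bias-corrected form when F2 = 0.
    """
    x = np.asarray(integer_counts, dtype=float)
    if not np.allclose(x, np.round(x)):
        raise ValidationError("chao1 requires integer counts")
    x = np.round(x).astype(np.int64)
    if (x < 0).any():
        raise ValidationError("abundances must be non-negative")
    s_obs = int((x > 0).sum())
    f1 = int((x == 1).sum())
    f2 = int((x == 2).sum())
    if f2 > 0:
        return s_obs + f1 * f1 / (2.0 * f2)
    return s_obs + f1 * (f1 - 1) / 2.0


@dataclass
class AlphaDiversityRecord:
    sample_id: str
    H: float
    D: float
    J: float
    chao1: float
    observed_richness: int


def alpha_diversity_table(
    table: CountTable,
    depth: int | None = None,
    iterations: int = 100,
    seed: int | None = None,
) -> pd.DataFrame:
    """Per-sample indices on the repeatedly-rarefied table.

    H, D, J and observed richness are evaluated on the rarefied-mean table
    (scale-invariant); Chao1 is averaged over the per-iteration integer
    draws because singletons/doubletons are not defined on means.
    """
    if depth is None:
        depth = int(table.column_sums().min())
    mean_table = rarefy_repeated(table, depth=depth, iterations=iterations, seed=seed)
    chao_acc = np.zeros(len(table.sample_ids))
    for draw in rarefaction_draws(table, depth, iterations, seed=seed):
        chao_acc += [chao1(draw[:, j]) for j in range(draw.shape[1])]
    chao_mean = chao_acc / iterations
    rows = []
    for j, sample in enumerate(mean_table.sample_ids):
        col = mean_table.data[sample].to_numpy()
        rows.append(
            {
                "sample_id": sample,
                "station": table.station_of(sample),
                "library": table.sample_meta.loc[sample, "library"],
                "H": shannon(col),
                "D": simpson(col),
                "J": pielou(col),
                "chao1": chao_mean[j],
                "observed_richness": observed_richness(col),
            }
        )
    return pd.DataFrame(rows).set_index("sample_id")


def compare_alpha(
    dna_values, rna_values, index_name: str = ""
) -> dict:
    """Two-sided contrast of an alpha index between DNA and RNA libraries.

    Reports the Welch (unequal-variance) t-test, the classic Student t-test,
    and the equivalent one-way ANOVA (for two groups ``F = t_student**2``),
    plus the direction of the mean difference.
    """
    a = np.asarray(dna_values, dtype=float)
    b = np.asarray(rna_values, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValidationError("each library needs at least 2 samples")
    t_w, p_w = stats.ttest_ind(a, b, equal_var=False)
    t_s, p_s = stats.ttest_ind(a, b, equal_var=True)
    f_stat, p_f = stats.f_oneway(a, b)
    if np.allclose(a.mean(), b.mean()) and np.isnan(t_w):
        # degenerate: identical constant groups
        t_w = t_s = f_stat = 0.0
        p_w = p_s = p_f = 1.0
    direction = "RNA" if b.mean() > a.mean() else ("DNA" if a.mean() > b.mean() else "none")
    return {
        "index": index_name,
        "t_welch": float(t_w),
        "p_welch": float(p_w),
        "t_student": float(t_s),
        "p_student": float(p_s),
        "F": float(f_stat),
        "p_anova": float(p_f),
        "mean_dna": float(a.mean()),
        "mean_rna": float(b.mean()),
        "higher_in": direction,
    }


def alpha_contrast_table(alpha_df: pd.DataFrame) -> pd.DataFrame:
    """Contrast every index in an :func:`alpha_diversity_table` output."""
    dna = alpha_df[alpha_df["library"] == "DNA"]
    rna = alpha_df[alpha_df["library"] == "RNA"]
    rows = [
        compare_alpha(dna[idx].dropna(), rna[idx].dropna(), idx)
        for idx in ("H", "D", "J", "chao1")
    ]
    return pd.DataFrame(rows).set_index("index")
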