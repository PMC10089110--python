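"""Group comparison of cognitive scores with permutation maxT correction.

Two-sample t statistics (Welch by default) per score, with family-wise
error control by the permutation distribution of the maximum |t| across
scores: labels are permuted B times and the adjusted p-value of score j is
(1 + #{b : maxT_b >= |t_j|}) / (B + 1).  Raw per-score permutation
p-values use the same +1 smoothing, so every p lies in [1/(B+1), 1].
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["PermTestResult", "perm_maxT", "domain_correlation"]


@dataclass
class PermTestResult:
    scores: list[str]
    observed_t: np.ndarray
    p_raw: np.ndarray
    p_adjusted: np.ndarray
    n_permutations: int
    seed: int | None

    def table(self) -> pd.DataFrame:
        return pd.DataFrame({"score": self.scores, "t": self.observed_t,
                             "p_raw": self.p_raw,
                             "p_maxT": self.p_adjusted})


def _t_stats(data: np.ndarray, mask_a: np.ndarray, pooled: bool
             ) -> np.ndarray:
    """Two-sample t per column of data for groups mask_a vs ~mask_a."""
    a, b = data[mask_a], data[~mask_a]
    na, nb = len(a), len(b)
    ma, mb = a.mean(axis=0), b.mean(axis=0)
    va = a.var(axis=0, ddof=1)
    vb = b.var(axis=0, ddof=1)
    if pooled:
        sp2 = ((na - 1) * va + (nb - 1) * vb) / (na + nb - 2)
        se = np.sqrt(sp2 * (1 / na + 1 / nb))
    else:
        se = np.sqrt(va / na + vb / nb)
    with np.errstate(divide="ignore", invalid="ignore"):
        return (ma - mb) / se


def perm_maxT(
    scores_table: pd.DataFrame,
    group_labels: np.ndarray | pd.Series,
    n_permutations: int = 10_000,
    rng: np.random.Generator | int | None = None,
    pooled: bool = False,
) -> PermTestResult:
    """Permutation two-sample t-tests with maxT family-wise correction.

    ``scores_table`` holds one column per score (subjects in rows);
    ``group_labels`` the two-level group assignment.  Rows with missing
    scores are dropped.  ``pooled=False`` uses the Welch statistic.
    """
    labels = np.asarray(group_labels)
    data = scores_table.to_numpy(dtype=float)
    keep = ~np.isnan(data).any(axis=1)
    if keep.sum() < len(keep):
        import warnings
        warnings.warn(f"dropped {int((~keep).sum())} subjects with missing "
                      "scores")
        data, labels = data[keep], labels[keep]
    levels = np.unique(labels)
    if len(levels) != 2:
        raise ValueError("group_labels must have exactly two levels")
    mask_a = labels == levels[0]
    if mask_a.sum() < 2 or (~mask_a).sum() < 2:
        raise ValueError("need >= 2 subjects per group")
    const = np.flatnonzero(data.std(axis=0) == 0)
    if const.size:
        raise ValueError("constant score column(s): "
                         f"{[scores_table.columns[i] for i in const]}")

    seed = None
    if not isinstance(rng, np.random.Generator):
        seed = rng
        rng = np.random.default_rng(rng)

    t_obs = _t_stats(data, mask_a, pooled)
    B = int(n_permutations)
    if B < 1:
        raise ValueError("n_permutations must be >= 1")
    abs_obs = np.abs(t_obs)
    count_raw = np.zeros(data.shape[1])
    count_max = np.zeros(data.shape[1])
    n = len(labels)
    na = int(mask_a.sum())
    for _ in range(B):
        perm = rng.permutation(n)
        mask = np.zeros(n, dtype=bool)
        mask[perm[:na]] = True
        t_perm = np.abs(_t_stats(data, mask, pooled))
        count_raw += t_perm >= abs_obs
        count_max += t_perm.max() >= abs_obs
    p_raw = (1.0 + count_raw) / (B + 1.0)
    p_adj = (1.0 + count_max) / (B + 1.0)
    return PermTestResult(scores=list(scores_table.columns),
                          observed_t=t_obs, p_raw=p_raw, p_adjusted=p_adj,
                          n_permutations=B, seed=seed)


def domain_correlation(scores_table: pd.DataFrame) -> pd.DataFrame:
    """Pearson correlation matrix of the score columns across subjects."""
    data = scores_table.to_numpy(dtype=float)
    if data.shape[0] < 3:
        raise ValueError("need >= 3 subjects")
    sd = data.std(axis=0, ddof=1)
    zero = np.flatnonzero(sd == 0)
    if zero.size:
        raise ValueError("zero-variance score column(s): "
                         f"{[scores_table.columns[i] for i in zero]}")
    corr = np.corrcoef(data, rowvar=False)
    corr = 0.5 * (corr + corr.T)
    np.fill_diagonal(corr, 1.0)
    return pd.DataFrame(corr, index=scores_table.columns,
                        columns=scores_table.columns)
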