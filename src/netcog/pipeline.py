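"""End-to-end brain-behavior analysis on a cohort.

Runs the patient-group canonical correlation pipeline: vectorized EC
posterior means as X, the seven cognitive domain scores as Y, both
residualized on age, gender and medication; bagged stepwise feature
selection with inclusion frequencies; a final CCA on the top feature
sets with Wilks-Λ (Bartlett/Rao) and permutation inference; and repeated
k-fold cross-validation with in-fold re-selection.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .cca import (CCAModel, CVResult, SelectionResult, WilksResult,
                  backward_eliminate, cca_fit, cv_cca, ensemble_select,
                  forward_select, lambda_tests, perm_cca_test, residualize)
from .cohort import DOMAINS, Cohort, ec_feature_names

__all__ = ["BrainBehaviorResult", "brain_behavior_analysis",
           "stepwise_selector"]


@dataclass
class BrainBehaviorResult:
    selection: SelectionResult
    model: CCAModel
    wilks: WilksResult
    permutation_p: float | None
    cv: CVResult | None
    x_names: list[str]
    y_names: list[str]


def _covariate_matrix(cohort: Cohort, subjects: list[int]) -> np.ndarray:
    recs = [cohort.records[i] for i in subjects]
    age = np.array([r.age for r in recs])
    gender = np.array([1.0 if r.gender == "M" else 0.0 for r in recs])
    med = np.array([r.medication for r in recs])
    return np.column_stack([age, gender, med])


def stepwise_selector(max_x: int = 3, max_y: int = 3,
                      f_threshold: float = 1.0, alpha: float = 0.05):
    """Single-pass forward + backward selection, for in-fold use in CV."""

    def select(Xtr: np.ndarray, Ytr: np.ndarray):
        x_idx = forward_select(Xtr, Ytr, max_features=max_x,
                               f_threshold=f_threshold)
        if not x_idx:
            x_idx = forward_select(Xtr, Ytr, max_features=1,
                                   f_threshold=0.0)
        try:
            y_idx = backward_eliminate(Ytr, Xtr[:, x_idx], alpha=alpha)
        except ValueError:
            y_idx = list(range(Ytr.shape[1]))
        if len(y_idx) > max_y:
            y_idx = y_idx[:max_y]
        return x_idx, y_idx

    return select


def brain_behavior_analysis(
    cohort: Cohort,
    group: str = "SZ",
    n_resamples: int = 200,
    cap_fraction: float = 0.05,
    n_top_x: int = 3,
    n_top_y: int = 3,
    n_permutations: int = 0,
    cv_k: int = 5,
    cv_repeats: int = 0,
    seed: int = 0,
    ridge: float = 0.0,
) -> BrainBehaviorResult:
    """Run the full EC-cognition CCA pipeline on one group of a cohort.

    ``n_permutations`` and ``cv_repeats`` default to 0 (skip those
    stages); set them to run permutation inference on the final model
    and cross-validation with in-fold stepwise re-selection.
    """
    subjects = [i for i, r in enumerate(cohort.records) if r.group == group]
    if len(subjects) < 18:
        raise ValueError(f"too few {group} subjects for a stable model")
    X_all = cohort.ec_matrix()[subjects]
    cog = cohort.cognition_table().set_index("subject_id")
    ids = [cohort.records[i].subject_id for i in subjects]
    Y_all = cog.loc[ids, list(DOMAINS)].to_numpy(dtype=float)

    C = _covariate_matrix(cohort, subjects)
    X_adj = residualize(X_all, C)
    Y_adj = residualize(Y_all, C)
    # residualization can zero out degenerate columns; keep variance
    keep = X_adj.std(axis=0) > 1e-12
    x_index = np.flatnonzero(keep)
    X_adj = X_adj[:, keep]

    selection = ensemble_select(X_adj, Y_adj, n_resamples=n_resamples,
                                cap_fraction=cap_fraction, rng=seed,
                                n_top_x=n_top_x, n_top_y=n_top_y)
    Xs = X_adj[:, selection.top_x]
    Ys = Y_adj[:, selection.top_y]
    model = cca_fit(Xs, Ys, ridge=ridge)
    wilks = lambda_tests(model.canonical_correlations,
                         (model.n_samples, model.n_x, model.n_y))
    perm_p = None
    if n_permutations:
        perm_p = perm_cca_test(Xs, Ys, B=n_permutations,
                               rng=np.random.default_rng(
                                   np.random.SeedSequence([seed, 43])),
                               ridge=ridge)
    cv = None
    if cv_repeats:
        # feature selection is re-run inside every training fold so the
        # out-of-sample correlation is not biased by in-sample selection
        cv = cv_cca(X_adj, Y_adj, k=cv_k, n_repeats=cv_repeats,
                    rng=np.random.default_rng(
                        np.random.SeedSequence([seed, 47])),
                    selector=stepwise_selector(max_x=n_top_x,
                                               max_y=n_top_y),
                    ridge=ridge)

    names = ec_feature_names(cohort.layout)
    x_names = [names[x_index[j]] for j in selection.top_x]
    y_names = [DOMAINS[j] for j in selection.top_y]
    # re-express top_x in original 470-feature indexing
    selection.top_x = [int(x_index[j]) for j in selection.top_x]
    full_freq = np.zeros(len(names))
    full_freq[x_index] = selection.x_frequency
    selection.x_frequency = full_freq
    return BrainBehaviorResult(selection=selection, model=model,
                               wilks=wilks, permutation_p=perm_p, cv=cv,
                               x_names=x_names, y_names=y_names)
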