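"""Additive Shapley explanations of classifier output.

Each prediction decomposes as ``y_i = y_base + sum_j phi_ij`` where
``y_base`` is the expected model output over a background sample and
``phi_ij`` is the Shapley attribution of feature j in sample i; positive
attributions push the predicted value up.  Exact subset enumeration is
used for small feature sets (<= 12 features), Monte-Carlo permutation
sampling otherwise.  Cohort-level importance ranks features by mean |phi|.

Explanations are computed in the model's class-1 probability space.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import factorial

import numpy as np
import pandas as pd

MAX_EXACT_FEATURES = 12


@dataclass
class ShapExplanation:
    y_base: float
    phi: pd.Series
    y_i: float
    additivity_residual: float
    standard_error: pd.Series | None = None

    def to_dict(self) -> dict:
        return {
            "y_base": self.y_base,
            "y_i": self.y_i,
            "additivity_residual": self.additivity_residual,
            "phi": {k: float(v) for k, v in self.phi.items()},
        }


def _as_2d(background) -> np.ndarray:
    bg = np.asarray(background, dtype=float)
    if bg.ndim == 1:
        bg = bg[None, :]
    return bg


def shapley_exact(model_fn, x, background, feature_names=None) -> ShapExplanation:
    """Classic Shapley values by enumeration of all 2^k coalitions.

    Features absent from a coalition are marginalized by averaging the
    model output over the background rows.  Additivity is exact.
    """
    x = np.asarray(x, dtype=float).ravel()
    bg = _as_2d(background)
    k = x.size
    if k > MAX_EXACT_FEATURES:
        raise ValueError(
            f"{k} features exceed the exact-mode limit of {MAX_EXACT_FEATURES}; "
            "use shapley_mc"
        )
    names = list(feature_names) if feature_names is not None else list(range(k))

    # v(S) for every coalition, batched into a single model call
    n_sub = 1 << k
    hybrids = np.repeat(bg[None, :, :], n_sub, axis=0)  # (2^k, B, k)
    for j in range(k):
        members = (np.arange(n_sub) >> j) & 1
        hybrids[members == 1, :, j] = x[j]
    flat = hybrids.reshape(-1, k)
    out = np.asarray(model_fn(flat), dtype=float).reshape(n_sub, bg.shape[0])
    v = out.mean(axis=1)

    sizes = np.array([bin(s).count("1") for s in range(n_sub)])
    fact = [factorial(i) for i in range(k + 1)]
    phi = np.zeros(k)
    for s in range(n_sub):
        size = sizes[s]
        w = fact[size] * fact[k - size - 1] / fact[k]
        for j in range(k):
            if not (s >> j) & 1:
                phi[j] += w * (v[s | (1 << j)] - v[s])

    y_base = float(v[0])
    y_i = float(v[-1])
    residual = abs(y_i - y_base - float(phi.sum()))
    return ShapExplanation(
        y_base=y_base, phi=pd.Series(phi, index=names), y_i=y_i,
        additivity_residual=residual,
    )


def shapley_mc(
    model_fn, x, background, n_permutations: int = 200, seed: int = 0,
    feature_names=None, rows_per_permutation: int | None = None,
) -> ShapExplanation:
    """Permutation-sampling Shapley estimate with per-feature standard error.

    Walking through each sampled permutation, features switch from
    background to observed values and the output increments are credited to
    the switched feature.  Each walk is averaged over
    ``rows_per_permutation`` background rows (all of them by default),
    which reduces the background-sampling variance of the estimate.
    """
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    x = np.asarray(x, dtype=float).ravel()
    bg = _as_2d(background)
    k = x.size
    names = list(feature_names) if feature_names is not None else list(range(k))
    rng = np.random.default_rng(seed)
    n_rows = bg.shape[0] if rows_per_permutation is None else min(
        int(rows_per_permutation), bg.shape[0]
    )

    perms = np.array([rng.permutation(k) for _ in range(n_permutations)])

    # states of every walk: (perm, row, step, feature), one batched call
    states = np.empty((n_permutations, n_rows, k + 1, k))
    for p in range(n_permutations):
        if n_rows == bg.shape[0]:
            rows = bg
        else:
            rows = bg[rng.choice(bg.shape[0], n_rows, replace=False)]
        cur = rows.copy()
        states[p, :, 0] = cur
        for step, j in enumerate(perms[p], start=1):
            cur = cur.copy()
            cur[:, j] = x[j]
            states[p, :, step] = cur
    out = np.asarray(model_fn(states.reshape(-1, k)), dtype=float).reshape(
        n_permutations, n_rows, k + 1
    )
    # per-permutation increments, averaged over the background rows
    increments = np.diff(out, axis=2).mean(axis=1)

    contribs = np.zeros((n_permutations, k))
    for p in range(n_permutations):
        contribs[p, perms[p]] = increments[p]
    phi = contribs.mean(axis=0)
    se = contribs.std(axis=0, ddof=1) / np.sqrt(n_permutations) if n_permutations > 1 \
        else np.full(k, np.nan)

    y_base = float(out[:, :, 0].mean())
    y_i = float(out[:, :, -1].mean())
    residual = abs(y_i - y_base - float(phi.sum()))
    return ShapExplanation(
        y_base=y_base, phi=pd.Series(phi, index=names), y_i=y_i,
        additivity_residual=residual, standard_error=pd.Series(se, index=names),
    )


def explain_cohort(
    model_fn, table: pd.DataFrame, background: pd.DataFrame,
    n_permutations: int = 200, seed: int = 0, max_background: int = 100,
    rows_per_permutation: int | None = 10,
) -> list[ShapExplanation]:
    """Explain every row of a table; exact mode when the feature count allows."""
    bg = background.to_numpy()
    if len(bg) > max_background:
        rng = np.random.default_rng(seed)
        bg = bg[rng.choice(len(bg), max_background, replace=False)]
    names = list(table.columns)
    out = []
    for i, (_, row) in enumerate(table.iterrows()):
        x = row.to_numpy()
        if table.shape[1] <= MAX_EXACT_FEATURES:
            out.append(shapley_exact(model_fn, x, bg, feature_names=names))
        else:
            out.append(
                shapley_mc(
                    model_fn, x, bg, n_permutations=n_permutations,
                    seed=seed + i, feature_names=names,
                    rows_per_permutation=rows_per_permutation,
                )
            )
    return out


@dataclass
class ImportanceRanking:
    ranking: pd.DataFrame  # feature, mean_abs_phi, rank
    phi_matrix: pd.DataFrame  # samples x features, for beeswarm-style export

    def top_k(self, k: int = 20) -> pd.DataFrame:
        return self.ranking.head(k)


def importance_rank(explanations: list[ShapExplanation]) -> ImportanceRanking:
    """Rank features by mean |phi| over a cohort (stable order on ties)."""
    if not explanations:
        raise ValueError("need at least one explanation")
    phi_matrix = pd.DataFrame([e.phi for e in explanations]).reset_index(drop=True)
    mean_abs = phi_matrix.abs().mean(axis=0)
    order = np.argsort(-mean_abs.to_numpy(), kind="stable")
    ranking = pd.DataFrame(
        {
            "feature": mean_abs.index[order],
            "mean_abs_phi": mean_abs.to_numpy()[order],
        }
    )
    ranking["rank"] = np.arange(1, len(ranking) + 1)
    return ImportanceRanking(ranking=ranking, phi_matrix=phi_matrix)
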