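"""Permutational multivariate ANOVA (PERMANOVA) with sequential SS.

Partitions a distance matrix by a factorial model using Gower's
double-centered inner-product matrix G = -(1/2) J D^2 J: for nested
design matrices X_0 (intercept) ⊂ X_1 ⊂ ... the sequential (Type I) sum
of squares of term k is tr[(H_k - H_{k-1}) G] with H the orthogonal
projector onto the column space, the residual SS is tr[(I - H_full) G],
and pseudo-F_k = (SS_k / df_k) / (SS_res / df_res). Significance comes
from free permutation of sample identities (rows/columns of D),
p = (1 + #{F* >= F_obs}) / (1 + n_permutations).

The microcosm model, in its stated term order, is
U = O + D + O:D + O:D:N + t + O:t + D:t + O:D:t + O:D:N:t
with t a categorical timepoint factor. Terms aliased with earlier ones
(e.g. O:D:N collapses to N when nutrients occur only alongside oil and
dispersant) get 0 df and no test; a saturated model (residual df 0)
reports NaN F and p with an explicit note rather than failing.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import TOL, DistanceMatrix, SampleDesign

#: the microcosm model's term order
MODEL_TERMS = ["O", "D", "O:D", "O:D:N", "t", "O:t", "D:t", "O:D:t", "O:D:N:t"]

_RANK_TOL = 1e-8


def _dummy(levels: pd.Series) -> np.ndarray:
    """Treatment-coded dummies (first level by sorted order is reference)."""
    cats = sorted(levels.unique())
    return np.column_stack([(levels == c).to_numpy(float) for c in cats[1:]]) \
        if len(cats) > 1 else np.zeros((len(levels), 0))


def build_design(designs: list[SampleDesign],
                 time_linear: bool = False) -> list[tuple[str, np.ndarray]]:
    """Design-matrix blocks for the microcosm model, in formula order.

    Returns (term name, column block) pairs. ``t`` is categorical by
    default (one level per timepoint); ``time_linear`` switches it to a
    single ordinal column.
    """
    df = pd.DataFrame({
        "O": [d.O for d in designs],
        "D": [d.D for d in designs],
        "N": [d.N for d in designs],
        "t": [d.t_index for d in designs],
    })
    if df.isna().any().any():
        bad = [designs[i].sample_id for i in np.flatnonzero(df.isna().any(axis=1))]
        raise ValueError(f"missing factor value(s) for sample(s): {bad}")
    O = df["O"].to_numpy(float)[:, None]
    D = df["D"].to_numpy(float)[:, None]
    N = df["N"].to_numpy(float)[:, None]
    T = df["t"].to_numpy(float)[:, None] if time_linear else _dummy(df["t"])
    blocks = {
        "O": O,
        "D": D,
        "O:D": O * D,
        "O:D:N": O * D * N,
        "t": T,
        "O:t": O * T,
        "D:t": D * T,
        "O:D:t": O * D * T,
        "O:D:N:t": O * D * N * T,
    }
    return [(name, blocks[name]) for name in MODEL_TERMS]


@dataclass
class PermanovaReport:
    """Sequential-SS PERMANOVA table plus residual/total rows and notes."""

    table: pd.DataFrame  # term, df, SS, F, R2, p_value (+ Residual, Total rows)
    n_permutations: int
    seed: int | None
    notes: list[str] = field(default_factory=list)

    @property
    def total_ss(self) -> float:
        return float(self.table.loc[self.table["term"] == "Total", "SS"].iloc[0])


def _hat(X: np.ndarray) -> tuple[np.ndarray, int]:
    """Orthogonal projector onto col(X) and its rank, via SVD."""
    if X.shape[1] == 0:
        return np.zeros((X.shape[0], X.shape[0])), 0
    U, s, _ = np.linalg.svd(X, full_matrices=False)
    rank = int((s > _RANK_TOL * max(s.max(), 1.0)).sum())
    Ur = U[:, :rank]
    return Ur @ Ur.T, rank


def gower_matrix(D: np.ndarray) -> np.ndarray:
    """Double-centered inner-product matrix from a distance matrix."""
    n = D.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    A = -0.5 * D ** 2
    return J @ A @ J


def permanova_sequential(dist: DistanceMatrix,
                         terms: list[tuple[str, np.ndarray]],
                         n_perm: int = 999,
                         seed: int | None = None) -> PermanovaReport:
    """Sequential (Type I) PERMANOVA of a distance matrix.

    ``terms`` is an ordered list of (name, column block) pairs, e.g. from
    :func:`build_design`. Whole samples are permuted freely; p-values live
    on the grid k/(n_perm + 1) with minimum 1/(n_perm + 1). Deterministic
    for a fixed seed.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    n = len(dist.ids)
    for name, block in terms:
        if block.shape[0] != n:
            raise ValueError(f"term {name!r} has {block.shape[0]} rows for "
                             f"{n} samples")
    G = gower_matrix(dist.values)
    total_ss = float(np.trace(G))

    notes: list[str] = []
    X = np.ones((n, 1))
    H_prev, rank_prev = _hat(X)
    projectors, dfs, names = [], [], []
    for name, block in terms:
        X = np.hstack([X, block])
        H, rank = _hat(X)
        df_term = rank - rank_prev
        projectors.append(H - H_prev)
        dfs.append(df_term)
        names.append(name)
        if df_term == 0:
            notes.append(f"term {name!r} aliased with earlier terms (0 df); no test")
        H_prev, rank_prev = H, rank
    H_full, rank_full = H_prev, rank_prev
    R = np.eye(n) - H_full
    df_res = n - rank_full
    if df_res == 0:
        notes.append("model saturated (residual df 0); F and p undefined")

    ss_terms = np.array([float(np.sum(M * G)) for M in projectors])
    ss_res = float(np.sum(R * G))

    degenerate = abs(total_ss) <= max(TOL, 1e-12 * n)
    if degenerate:
        notes.append("total SS is zero (all distances equal); no test")

    with np.errstate(divide="ignore", invalid="ignore"):
        ms_res = np.float64(ss_res) / df_res if df_res > 0 else np.float64("nan")
        f_obs = np.array([
            (np.float64(ss) / df) / ms_res if df > 0 and df_res > 0
            else np.float64("nan")
            for ss, df in zip(ss_terms, dfs)
        ])

    rng = np.random.default_rng(seed)
    testable = [k for k in range(len(names))
                if dfs[k] > 0 and df_res > 0 and np.isfinite(f_obs[k])
                and not degenerate]
    exceed = np.zeros(len(names))
    if testable:
        for _ in range(n_perm):
            pi = rng.permutation(n)
            Gp = G[np.ix_(pi, pi)]
            with np.errstate(divide="ignore", invalid="ignore"):
                ms_res_p = np.float64(np.sum(R * Gp)) / df_res
                for k in testable:
                    f_p = (np.float64(np.sum(projectors[k] * Gp)) / dfs[k]) / ms_res_p
                    if f_p >= f_obs[k]:
                        exceed[k] += 1
    p = np.full(len(names), np.nan)
    for k in testable:
        p[k] = (1.0 + exceed[k]) / (1.0 + n_perm)

    rows = [
        {"term": name, "df": df, "SS": ss,
         "F": f, "R2": ss / total_ss if total_ss > 0 else np.nan,
         "p_value": pv}
        for name, df, ss, f, pv in zip(names, dfs, ss_terms, f_obs, p)
    ]
    rows.append({"term": "Residual", "df": df_res, "SS": ss_res,
                 "F": np.nan, "R2": ss_res / total_ss if total_ss > 0 else np.nan,
                 "p_value": np.nan})
    rows.append({"term": "Total", "df": n - 1, "SS": total_ss,
                 "F": np.nan, "R2": 1.0, "p_value": np.nan})
    table = pd.DataFrame(rows, columns=["term", "df", "SS", "F", "R2", "p_value"])

    if abs(ss_terms.sum() + ss_res - total_ss) > max(TOL, 1e-9 * max(abs(total_ss), 1)):
        raise AssertionError("SS decomposition does not sum to total SS")
    return PermanovaReport(table=table, n_permutations=n_perm, seed=seed, notes=notes)


def factor_term(labels) -> list[tuple[str, np.ndarray]]:
    """Single categorical factor as a one-term model (convenience)."""
    return [("factor", _dummy(pd.Series(list(labels))))]
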