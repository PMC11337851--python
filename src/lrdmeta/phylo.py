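"""Abundance-weighted phylogenetic beta-diversity (MPD and MNTD).

Between-sample phylogenetic distances over a patristic (branch-length
path) matrix from a reference tree:

* MPD (``comdist``): the abundance-weighted mean pairwise patristic
  distance between every taxon of one sample and every taxon of another.
* MNTD (``comdistnt``): the abundance-weighted mean distance from each
  taxon of one sample to its nearest phylogenetic neighbor in the other,
  symmetrized by averaging the two directions.

Weights are within-sample relative abundances renormalized over the
tree-covered taxa, so each sample contributes a proper distribution.
Self-comparisons are evaluated by the same formulas (MPD(A, A) is the
within-sample diversity and may be positive); downstream tests ignore
the diagonal.
"""

from __future__ import annotations

import numpy as np
import skbio

from .containers import CountTable, DistanceMatrix


def patristic_matrix(tree: skbio.TreeNode) -> DistanceMatrix:
    """Leaf-to-leaf sums of branch lengths along tree paths."""
    dm = tree.tip_tip_distances()
    return DistanceMatrix(list(dm.ids), np.asarray(dm.data, dtype=float), "patristic")


def _weights(table: CountTable, pat: DistanceMatrix) -> tuple[np.ndarray, np.ndarray]:
    """(weight matrix taxa x samples, patristic submatrix in table order)."""
    missing = [t for t in table.taxon_labels if t not in set(pat.ids)]
    if missing:
        raise ValueError(f"taxa missing from the tree/patristic matrix: {missing}")
    idx = [pat.ids.index(t) for t in table.taxon_labels]
    P = pat.values[np.ix_(idx, idx)]
    X = table.df.to_numpy(dtype=float)
    totals = X.sum(axis=0)
    empty = [s for s, tot in zip(table.sample_ids, totals) if tot <= 0]
    if empty:
        raise ValueError(f"empty sample(s): {empty}")
    return X / totals, P


def comdist_weighted(table: CountTable, pat: DistanceMatrix) -> DistanceMatrix:
    """Abundance-weighted MPD between all sample pairs.

    MPD(A, B) = sum_i sum_j p_iA p_jB pat(i, j).
    """
    W, P = _weights(table, pat)
    M = W.T @ P @ W
    M = (M + M.T) / 2  # exact symmetry against float jitter
    return DistanceMatrix(table.sample_ids, M, "mpd")


def comdistnt_weighted(table: CountTable, pat: DistanceMatrix, *,
                       exclude_conspecifics: bool = False,
                       symmetric: bool = True) -> DistanceMatrix:
    """Abundance-weighted MNTD between all sample pairs.

    Directional term D(A->B) = sum_i p_iA min_{j in B} pat(i, j), where j
    ranges over taxa present in B; a taxon shared by A and B contributes a
    zero nearest distance unless ``exclude_conspecifics``. The reported
    value is the average of the two directions (set ``symmetric=False``
    for max instead of mean — still a symmetric matrix).
    """
    W, P = _weights(table, pat)
    n_taxa, n_samples = W.shape
    present = W > 0
    out = np.zeros((n_samples, n_samples))
    for b in range(n_samples):
        cols = np.flatnonzero(present[:, b])
        Psub = P[:, cols]  # taxa x |B|
        if exclude_conspecifics:
            Psub = Psub.copy()
            for k, j in enumerate(cols):
                Psub[j, k] = np.inf
            nearest = np.min(Psub, axis=1)
            nearest[~np.isfinite(nearest)] = 0.0
        else:
            nearest = np.min(Psub, axis=1)
        # D(a -> b) for every a at once
        out[:, b] = nearest @ W
    mntd = (out + out.T) / 2 if symmetric else np.maximum(out, out.T)
    return DistanceMatrix(table.sample_ids, mntd, "mntd")
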