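"""Taxonomic beta-diversity and ordination.

Bray-Curtis dissimilarity as the abundance-weighted between-sample
measure, principal-coordinates analysis (classical metric scaling) for
its visualization, and the analytic (hypergeometric) rarefaction
expectation for species richness.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial.distance import pdist, squareform
from scipy.special import gammaln

from .containers import CountTable, DistanceMatrix, OrdinationResult


def bray_curtis_matrix(table: CountTable) -> DistanceMatrix:
    """All-pairs Bray-Curtis dissimilarity over the table's samples.

    BC(A, B) = sum_i |a_i - b_i| / sum_i (a_i + b_i); values in [0, 1].
    A pair of all-zero samples has no defined dissimilarity and is an error.
    """
    X = table.df.to_numpy(dtype=float).T  # samples x taxa
    if X.shape[0] < 2:
        raise ValueError("need at least two samples")
    zero = [s for s, row in zip(table.sample_ids, X) if row.sum() <= 0]
    if len(zero) >= 2:
        raise ValueError(f"Bray-Curtis undefined between all-zero samples: {zero}")
    d = squareform(pdist(X, metric="braycurtis"))
    return DistanceMatrix(table.sample_ids, d, "bray-curtis")


def pcoa(dist: DistanceMatrix, axes: int | None = None) -> OrdinationResult:
    """Principal-coordinates analysis (Gower's classical metric scaling).

    Eigendecomposes the double-centered matrix -(1/2) J D^2 J. Axes are
    ordered by descending eigenvalue; negative eigenvalues are reported in
    ``eigenvalues`` but their axes are excluded from the coordinates (no
    Cailliez/Lingoes correction). Requesting more axes than there are
    positive eigenvalues truncates with a recorded warning.
    """
    D = dist.values
    n = D.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    G = -0.5 * J @ (D ** 2) @ J
    eigvals, eigvecs = np.linalg.eigh((G + G.T) / 2)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]

    tol = max(np.abs(eigvals).max(initial=0.0), 1.0) * 1e-12
    pos = eigvals > tol
    n_pos = int(pos.sum())
    warnings: list[str] = []
    k = n_pos if axes is None else axes
    if k > n_pos:
        warnings.append(f"requested {k} axes but only {n_pos} positive "
                        f"eigenvalues; truncated")
        k = n_pos
    coords = eigvecs[:, :k] * np.sqrt(eigvals[:k]) if k else np.zeros((n, 0))
    pos_total = eigvals[pos].sum()
    prop = (eigvals[:k] / pos_total) if pos_total > 0 else np.zeros(k)
    return OrdinationResult(
        ids=list(dist.ids),
        coordinates=coords,
        eigenvalues=eigvals,
        proportion_explained=prop,
        warnings=warnings,
    )


def rarefy_richness(counts, depth: int) -> float:
    """Expected number of taxa seen in a random subsample of ``depth`` reads.

    E[S] = sum_i [1 - C(N - N_i, depth) / C(N, depth)] with N the total
    count — the without-replacement (hypergeometric) expectation, evaluated
    in log-gamma space for stability.
    """
    counts = np.asarray(counts)
    if not np.issubdtype(counts.dtype, np.integer):
        if not np.allclose(counts, np.round(counts)):
            raise ValueError("rarefaction requires integer counts")
        counts = np.round(counts).astype(int)
    if (counts < 0).any():
        raise ValueError("negative counts")
    counts = counts[counts > 0]
    total = int(counts.sum())
    depth = int(depth)
    if depth < 0:
        raise ValueError("depth must be nonnegative")
    if depth > total:
        raise ValueError(f"depth {depth} exceeds total count {total}")
    if depth == 0 or counts.size == 0:
        return 0.0

    def log_comb(n, k):
        return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)

    expected = 0.0
    denom = log_comb(total, depth)
    for n_i in counts:
        rest = total - int(n_i)
        if rest < depth:
            expected += 1.0  # taxon cannot be missed
        else:
            expected += 1.0 - np.exp(log_comb(rest, depth) - denom)
    return float(expected)


def rarefy_richness_sampled(counts, depth: int, n_draws: int = 100,
                            seed: int | None = None) -> float:
    """Monte-Carlo companion to :func:`rarefy_richness` (seeded subsampling)."""
    counts = np.asarray(counts, dtype=int)
    total = int(counts.sum())
    if depth > total:
        raise ValueError(f"depth {depth} exceeds total count {total}")
    rng = np.random.default_rng(seed)
    pool = np.repeat(np.arange(counts.size), counts)
    richness = [
        np.unique(rng.choice(pool, size=depth, replace=False)).size
        for _ in range(n_draws)
    ]
    return float(np.mean(richness))
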