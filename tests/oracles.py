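"""Independent brute-force oracles used by the test suite.

Everything here is written with explicit loops against first principles
(lineage walks, double sums), deliberately sharing no logic with the
package implementations it checks.
"""

import numpy as np
import pandas as pd


def merge_oracle(counts: pd.DataFrame, lineages: dict[str, list[str]],
                 T: float, rule: str = "any_sample"):
    """Ancestor-walk merge: per-leaf stop node, then antichain closure.

    ``lineages`` maps each row label to its full path root -> leaf. Returns
    (final label per row, aggregated counts DataFrame).
    """
    rel = counts / counts.sum(axis=0)

    # aggregated (subtree) relative abundance of every node, per sample
    mass: dict[str, np.ndarray] = {}
    for lab in counts.index:
        for node in lineages[lab]:
            mass.setdefault(node, np.zeros(counts.shape[1]))
            mass[node] = mass[node] + rel.loc[lab].to_numpy()

    def ok(node):
        m = mass[node]
        return m.max() >= T if rule == "any_sample" else m.min() >= T

    # walk each leaf up; stop at the first rank meeting the retention rule
    stop = {}
    for lab in counts.index:
        path = lineages[lab]
        chosen = path[0]  # root bucket fallback
        for node in reversed(path[1:]):  # leaf first, root-child last
            if ok(node):
                chosen = node
                break
        stop[lab] = chosen

    # antichain closure over non-root stop nodes
    root = next(iter(lineages.values()))[0]
    stops = {s for s in stop.values() if s != root}
    final = {}
    for lab in counts.index:
        if stop[lab] == root:
            final[lab] = root
            continue
        for node in lineages[lab]:
            if node in stops:
                final[lab] = node
                break

    agg: dict[str, np.ndarray] = {}
    order = []
    for lab in counts.index:
        f = final[lab]
        if f not in agg:
            agg[f] = np.zeros(counts.shape[1], dtype=counts.to_numpy().dtype)
            order.append(f)
        agg[f] = agg[f] + counts.loc[lab].to_numpy()
    out = pd.DataFrame([agg[f] for f in order], index=order, columns=counts.columns)
    return final, out


def mpd_oracle(weights: pd.DataFrame, pat: pd.DataFrame) -> np.ndarray:
    """Naive double-loop abundance-weighted MPD between all sample pairs."""
    samples = list(weights.columns)
    taxa = list(weights.index)
    out = np.zeros((len(samples), len(samples)))
    for a, sa in enumerate(samples):
        for b, sb in enumerate(samples):
            acc = 0.0
            for i in taxa:
                for j in taxa:
                    acc += weights.loc[i, sa] * weights.loc[j, sb] * pat.loc[i, j]
            out[a, b] = acc
    return out


def mntd_oracle(weights: pd.DataFrame, pat: pd.DataFrame) -> np.ndarray:
    """Naive nearest-neighbor abundance-weighted MNTD (symmetric average)."""
    samples = list(weights.columns)
    taxa = list(weights.index)

    def directional(sa, sb):
        present_b = [j for j in taxa if weights.loc[j, sb] > 0]
        acc = 0.0
        for i in taxa:
            if weights.loc[i, sa] > 0:
                acc += weights.loc[i, sa] * min(pat.loc[i, j] for j in present_b)
        return acc

    out = np.zeros((len(samples), len(samples)))
    for a, sa in enumerate(samples):
        for b, sb in enumerate(samples):
            out[a, b] = 0.5 * (directional(sa, sb) + directional(sb, sa))
    return out
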