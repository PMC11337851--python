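"""The LRD activity index: mean log2 RNA:DNA ratio per taxon and treatment.

For taxon *i* in treatment *j*, LRD_ij = (1/n) * sum_t log2(r_ijt / d_ijt),
where r and d are the relative abundances of the taxon in the
metatranscriptomic and 16S rRNA gene libraries at timepoint *t* and the
mean runs over the n timepoints the treatment actually has. A high LRD
marks taxa transcribing far in excess of their genomic standing stock
(high synthetic capacity); a low LRD marks taxa that are present but
largely silent.

Group classification (on the mean LRD):
  Group I   : mean LRD > 3.5      (greatest biosynthetic capacity)
  Group II  : |mean LRD| <= 3.5   (proportionate RNA and DNA signals)
  Group III : mean LRD < -3.5     (smallest biosynthetic capacity)
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import TOL, CountTable, SampleDesign

#: group boundary on |mean LRD|; the boundary itself belongs to Group II
GROUP_THRESHOLD = 3.5


def classify_lrd_group(lrd_mean: float) -> str:
    """Activity group from a (finite) mean LRD score."""
    if lrd_mean > GROUP_THRESHOLD:
        return "I"
    if lrd_mean < -GROUP_THRESHOLD:
        return "III"
    return "II"


def classify_lrd_groups(table: pd.DataFrame) -> pd.DataFrame:
    """(Re)assign the activity-group column of an LRD table.

    Requires finite ``lrd_mean`` values; returns a copy with ``group`` set.
    """
    if not np.isfinite(table["lrd_mean"]).all():
        raise ValueError("lrd_mean contains non-finite values")
    out = table.copy()
    out["group"] = [classify_lrd_group(v) for v in out["lrd_mean"]]
    return out


def average_replicates(table: CountTable, designs: list[SampleDesign]) -> CountTable:
    """Mean relative abundance per (treatment, timepoint) cell.

    Each output column ``{treatment}_t{t}`` is the arithmetic mean of its
    replicate columns' relative abundances, so columns still sum to 1.
    """
    by_id = {d.sample_id: d for d in designs}
    missing = [s for s in table.sample_ids if s not in by_id]
    if missing:
        raise ValueError(f"samples missing from design: {missing}")
    rel = table.relative_abundance().df

    cells: dict[tuple[str, int], list[str]] = {}
    for s in table.sample_ids:
        d = by_id[s]
        cells.setdefault((d.treatment, d.t_index), []).append(s)

    listed = {(d.treatment, d.t_index) for d in designs if d.sample_id in set(table.sample_ids)}
    empty = sorted(c for c in listed if not cells.get(c))
    if empty:
        raise ValueError(f"design cell(s) with zero replicates: {empty}")

    out = {}
    for (treatment, t), samples in sorted(cells.items()):
        out[f"{treatment}_t{t}"] = rel[samples].mean(axis=1)
    return CountTable(pd.DataFrame(out, index=rel.index))


@dataclass
class LRDResult:
    """Per-(taxon, treatment) LRD scores with their per-timepoint ratios."""

    table: pd.DataFrame     # taxon, treatment, lrd_mean, n_used, group
    per_time: pd.DataFrame  # taxon, treatment, t_index, log2_ratio
    skipped: pd.DataFrame   # rows with no admissible timepoint
    zero_policy: str = "drop"
    notes: list[str] = field(default_factory=list)

    def sorted_by_mean(self) -> pd.DataFrame:
        """Taxa sorted by descending mean of LRD scores (across treatments)."""
        order = (self.table.groupby("taxon")["lrd_mean"].mean()
                 .sort_values(ascending=False).index)
        t = self.table.set_index("taxon").loc[order].reset_index()
        return t


def _cell_grid(table: CountTable, designs: list[SampleDesign]) -> pd.DataFrame:
    avg = average_replicates(table, designs)
    cols = {}
    for c in avg.sample_ids:
        treatment, t = c.rsplit("_t", 1)
        cols[(treatment, int(t))] = avg.df[c]
    return pd.DataFrame(cols, index=avg.df.index)


def compute_lrd(rna: CountTable, dna: CountTable, designs: list[SampleDesign],
                zero_policy: str = "drop") -> LRDResult:
    """LRD scores from paired metatranscriptomic and 16S relative abundances.

    Both tables must share the (post-merge) taxon label set and resolve to
    the same (treatment, timepoint) grid through ``designs``. ``zero_policy``
    is ``drop`` (timepoints with r=0 or d=0 contribute nothing; n shrinks)
    or ``pseudocount`` (add half the smallest nonzero relative abundance of
    the respective table before taking ratios).
    """
    if zero_policy not in ("drop", "pseudocount"):
        raise ValueError(f"unknown zero_policy {zero_policy!r}")
    r_set, d_set = set(rna.taxon_labels), set(dna.taxon_labels)
    if r_set != d_set:
        diff = sorted(r_set.symmetric_difference(d_set))
        raise ValueError(f"taxon label sets differ between rna and dna: {diff}")

    r_grid = _cell_grid(rna, designs)
    d_grid = _cell_grid(dna, designs)
    if set(r_grid.columns) != set(d_grid.columns):
        diff = sorted(set(r_grid.columns).symmetric_difference(d_grid.columns))
        raise ValueError(f"(treatment, timepoint) grids differ: {diff}")
    d_grid = d_grid.loc[rna.taxon_labels, r_grid.columns]
    r_grid = r_grid.loc[rna.taxon_labels]

    notes: list[str] = []
    if zero_policy == "pseudocount":
        r_pc = 0.5 * r_grid.to_numpy()[r_grid.to_numpy() > 0].min()
        d_pc = 0.5 * d_grid.to_numpy()[d_grid.to_numpy() > 0].min()
        r_grid = r_grid + r_pc
        d_grid = d_grid + d_pc
        notes.append(f"pseudocounts: rna {r_pc:.3e}, dna {d_pc:.3e}")

    treatments = sorted({tr for tr, _ in r_grid.columns})
    rows, per_time, skipped = [], [], []
    for taxon in r_grid.index:
        for treatment in treatments:
            ts = sorted(t for tr, t in r_grid.columns if tr == treatment)
            ratios = []
            for t in ts:
                r_v = float(r_grid.loc[taxon, (treatment, t)])
                d_v = float(d_grid.loc[taxon, (treatment, t)])
                if r_v > 0 and d_v > 0:
                    ratios.append((t, np.log2(r_v / d_v)))
            if not ratios:
                skipped.append({"taxon": taxon, "treatment": treatment})
                continue
            mean = float(np.mean([v for _, v in ratios]))
            rows.append({
                "taxon": taxon, "treatment": treatment, "lrd_mean": mean,
                "n_used": len(ratios), "group": classify_lrd_group(mean),
            })
            per_time.extend(
                {"taxon": taxon, "treatment": treatment, "t_index": t,
                 "log2_ratio": v}
                for t, v in ratios
            )

    result = LRDResult(
        table=pd.DataFrame(rows, columns=["taxon", "treatment", "lrd_mean",
                                          "n_used", "group"]),
        per_time=pd.DataFrame(per_time, columns=["taxon", "treatment", "t_index",
                                                 "log2_ratio"]),
        skipped=pd.DataFrame(skipped, columns=["taxon", "treatment"]),
        zero_policy=zero_policy,
        notes=notes,
    )
    _check_consistency(result)
    return result


def _check_consistency(res: LRDResult) -> None:
    if res.table.empty:
        return
    means = res.per_time.groupby(["taxon", "treatment"])["log2_ratio"].mean()
    for row in res.table.itertuples():
        if abs(means.loc[(row.taxon, row.treatment)] - row.lrd_mean) > TOL:
            raise AssertionError("lrd_mean inconsistent with per-timepoint ratios")
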