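"""Taxonomic label canonicalization and threshold-driven rank merging.

Annotation pipelines emit taxonomic calls at mixed ranks and with variable
spellings. This module (i) resolves raw labels against a local reference
table into ranked lineages, and (ii) aggregates low-abundance calls into
higher-rank groups until every retained label reaches a minimum
relative-abundance resolution ``T`` (default 4%), so that downstream
community analyses operate on one compact, shared label set.

Merging semantics
-----------------
Retention of a label is judged on the per-sample relative abundance of its
*subtree* — the summed abundance of all table rows whose lineage passes
through it. Each input row is promoted one rank at a time (deepest ranks
first, re-evaluated each pass) until it sits at a node whose subtree meets
the retention rule; rows that never meet it end in the root-level bucket.
A final antichain closure reassigns every row to the shallowest retained
node on its lineage, so no output label is a strict descendant of another
and per-sample totals are conserved exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import CountTable

#: canonical rank order, root first
DEFAULT_RANKS = ["root", "domain", "phylum", "class", "order", "family", "genus"]

ROOT_NAME = "Root"
UNCLASSIFIED_NAME = "Unclassified"


def _norm(label: str) -> str:
    return str(label).strip().casefold()


@dataclass(frozen=True)
class TaxEntry:
    canonical: str
    rank: str
    parent: str | None  # canonical name of parent; None only for the root


class TaxonomyReference:
    """Mapping from raw labels (incl. synonyms) to ranked lineage paths.

    Built from rows of (label, canonical, rank, parent). The implicit root
    entry ``Root`` (rank ``root``) is always present; a reserved
    ``Unclassified`` child of the root receives unresolvable labels when
    the bucket policy is in effect.
    """

    def __init__(self, rows: list[tuple[str, str, str, str | None]],
                 ranks: list[str] = DEFAULT_RANKS):
        self.ranks = list(ranks)
        if self.ranks[0] != "root":
            self.ranks = ["root"] + self.ranks
        self._rank_depth = {r: i for i, r in enumerate(self.ranks)}
        self._entries: dict[str, TaxEntry] = {
            ROOT_NAME: TaxEntry(ROOT_NAME, "root", None),
            UNCLASSIFIED_NAME: TaxEntry(UNCLASSIFIED_NAME, self.ranks[1], ROOT_NAME),
        }
        self._labels: dict[str, list[str]] = {
            _norm(ROOT_NAME): [ROOT_NAME],
            _norm(UNCLASSIFIED_NAME): [UNCLASSIFIED_NAME],
        }
        for label, canonical, rank, parent in rows:
            canonical = str(canonical).strip()
            rank = str(rank).strip()
            if rank not in self._rank_depth:
                raise ValueError(f"unknown rank {rank!r} for {canonical!r}; "
                                 f"ranks: {self.ranks}")
            parent = ROOT_NAME if parent in (None, "", ROOT_NAME) else str(parent).strip()
            entry = TaxEntry(canonical, rank, parent)
            prev = self._entries.get(canonical)
            if prev is not None and prev != entry:
                raise ValueError(f"conflicting definitions for canonical {canonical!r}")
            self._entries[canonical] = entry
            self._labels.setdefault(_norm(label), [])
            if canonical not in self._labels[_norm(label)]:
                self._labels[_norm(label)].append(canonical)
            # the canonical spelling is always resolvable too
            self._labels.setdefault(_norm(canonical), [])
            if canonical not in self._labels[_norm(canonical)]:
                self._labels[_norm(canonical)].append(canonical)
        self._validate()

    def _validate(self) -> None:
        for name, e in self._entries.items():
            if name == ROOT_NAME:
                continue
            if e.parent not in self._entries:
                raise ValueError(f"{name!r}: parent {e.parent!r} not in reference")
            # walk to root, watching for cycles and rank inversions
            seen = {name}
            node = e
            while node.parent is not None:
                parent = self._entries[node.parent]
                if self._rank_depth[parent.rank] >= self._rank_depth[node.rank]:
                    raise ValueError(
                        f"{node.canonical!r} ({node.rank}) has parent "
                        f"{parent.canonical!r} ({parent.rank}) not closer to the root"
                    )
                if parent.canonical in seen:
                    raise ValueError(f"cycle in reference at {parent.canonical!r}")
                seen.add(parent.canonical)
                node = parent

    @classmethod
    def from_frame(cls, df: pd.DataFrame, ranks: list[str] = DEFAULT_RANKS
                   ) -> "TaxonomyReference":
        need = {"label", "canonical", "rank", "parent"}
        if not need.issubset(df.columns):
            raise ValueError(f"taxonomy reference needs columns {sorted(need)}")
        rows = [
            (r.label, r.canonical, r.rank,
             None if pd.isna(r.parent) else r.parent)
            for r in df.itertuples()
        ]
        return cls(rows, ranks)

    @classmethod
    def from_tsv(cls, path, ranks: list[str] = DEFAULT_RANKS) -> "TaxonomyReference":
        return cls.from_frame(pd.read_csv(path, sep="\t"), ranks)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for norm_label, canonicals in sorted(self._labels.items()):
            for c in canonicals:
                if c in (ROOT_NAME, UNCLASSIFIED_NAME):
                    continue
                e = self._entries[c]
                rows.append({"label": norm_label, "canonical": c,
                             "rank": e.rank, "parent": e.parent})
        return pd.DataFrame(rows)

    def entry(self, canonical: str) -> TaxEntry:
        return self._entries[canonical]

    def __contains__(self, canonical: str) -> bool:
        return canonical in self._entries

    def rank_depth(self, canonical: str) -> int:
        return self._rank_depth[self._entries[canonical].rank]

    def lineage(self, canonical: str) -> list[str]:
        """Full ranked path root -> canonical (inclusive both ends)."""
        path = [canonical]
        node = self._entries[canonical]
        while node.parent is not None:
            path.append(node.parent)
            node = self._entries[node.parent]
        return path[::-1]

    def domain_of(self, canonical: str) -> str | None:
        for anc in self.lineage(canonical):
            if anc not in (ROOT_NAME,) and self._entries[anc].rank == self.ranks[1]:
                return anc
        return None

    def resolve(self, label: str, *, unknown_policy: str = "error",
                majority_domain: str | None = None) -> str:
        """Resolve a raw label to one canonical name.

        Matching is case-insensitive and ignores surrounding whitespace.
        Homonyms (one label, several entries) prefer the entry under
        ``majority_domain``; still-ambiguous or unknown labels follow
        ``unknown_policy`` (``error`` or ``bucket`` -> ``Unclassified``).
        """
        candidates = self._labels.get(_norm(label), [])
        if len(candidates) == 1:
            return candidates[0]
        if len(candidates) > 1 and majority_domain is not None:
            hits = [c for c in candidates if self.domain_of(c) == majority_domain]
            if len(hits) == 1:
                return hits[0]
        if unknown_policy == "bucket":
            return UNCLASSIFIED_NAME
        if not candidates:
            raise KeyError(f"label {label!r} not found in taxonomy reference")
        raise KeyError(f"label {label!r} is ambiguous: {sorted(candidates)}")


def canonicalize_label(label: str, ref: TaxonomyReference, *,
                       unknown_policy: str = "error",
                       majority_domain: str | None = None) -> list[str]:
    """Full ranked lineage (root -> canonical entry) for a raw label."""
    return ref.lineage(ref.resolve(label, unknown_policy=unknown_policy,
                                   majority_domain=majority_domain))


@dataclass
class MergeConfig:
    """Parameters of the threshold merge.

    ``T`` is the minimum relative-abundance resolution in (0, 1);
    ``retention_rule`` is ``any_sample`` (>= T in at least one sample;
    the default, yielding one shared label set) or ``per_sample``
    (>= T in every sample); ``unknown_policy`` handles unresolvable labels.
    """

    T: float = 0.04
    retention_rule: str = "any_sample"
    unknown_policy: str = "error"

    def __post_init__(self):
        if not (0 < self.T < 1):
            raise ValueError(f"threshold T={self.T} must be in (0, 1)")
        if self.retention_rule not in ("any_sample", "per_sample"):
            raise ValueError(f"unknown retention_rule {self.retention_rule!r}")
        if self.unknown_policy not in ("error", "bucket"):
            raise ValueError(f"unknown unknown_policy {self.unknown_policy!r}")


@dataclass
class MergeReport:
    """Audit trail of one merge: row mapping, absorbed mass, pass count."""

    mapping: pd.DataFrame        # raw_label, canonical, final_label, final_rank
    merged_mass: pd.Series       # final label -> summed relative abundance over samples
    rounds: int = 0
    notes: list[str] = field(default_factory=list)


def _majority_domain(table: CountTable, ref: TaxonomyReference) -> str | None:
    """Domain carrying the largest total count among unambiguous labels."""
    totals: dict[str, float] = {}
    for label, row_sum in table.df.sum(axis=1).items():
        cands = ref._labels.get(_norm(label), [])
        if len(cands) == 1:
            dom = ref.domain_of(cands[0])
            if dom is not None:
                totals[dom] = totals.get(dom, 0.0) + float(row_sum)
    if not totals:
        return None
    return max(sorted(totals), key=lambda d: totals[d])


def merge_to_threshold(table: CountTable, ref: TaxonomyReference,
                       cfg: MergeConfig | None = None
                       ) -> tuple[CountTable, MergeReport]:
    """Merge low-abundance rows to higher ranks until resolution ``T`` is met.

    Returns the merged table (per-sample totals conserved exactly; integer
    dtype preserved for integer input) and a :class:`MergeReport` explaining
    every input row. Deterministic for fixed inputs.
    """
    cfg = cfg or MergeConfig()
    maj = _majority_domain(table, ref)

    raw_labels = table.taxon_labels
    canon = {
        lab: ref.resolve(lab, unknown_policy=cfg.unknown_policy, majority_domain=maj)
        for lab in raw_labels
    }
    lineages = {lab: ref.lineage(canon[lab]) for lab in raw_labels}

    rel = table.relative_abundance().df.to_numpy()

    # subtree relative abundance per node per sample (fixed for the whole merge)
    node_mass: dict[str, np.ndarray] = {}
    for i, lab in enumerate(raw_labels):
        for node in lineages[lab]:
            node_mass.setdefault(node, np.zeros(rel.shape[1]))
            node_mass[node] += rel[i]

    if cfg.retention_rule == "any_sample":
        def retained(node: str) -> bool:
            return bool(node_mass[node].max() >= cfg.T)
    else:  # per_sample
        def retained(node: str) -> bool:
            return bool(node_mass[node].min() >= cfg.T)

    # iterative promotion: one rank per pass, deepest assignments first
    assign = {lab: canon[lab] for lab in raw_labels}
    rounds = 0
    while True:
        changed = False
        for lab in sorted(assign, key=lambda s: -ref.rank_depth(assign[s])):
            node = assign[lab]
            if node != ROOT_NAME and not retained(node):
                assign[lab] = ref.entry(node).parent
                changed = True
        if not changed:
            break
        rounds += 1

    # antichain closure: shallowest retained stop-node on each row's lineage.
    # The root bucket is exempt — it only collects rows whose whole lineage
    # failed retention, and coexists with the retained labels.
    stop_nodes = set(assign.values()) - {ROOT_NAME}
    for lab in raw_labels:
        if assign[lab] == ROOT_NAME:
            continue
        for node in lineages[lab]:
            if node in stop_nodes:
                assign[lab] = node
                break

    # aggregate original counts by final label, in order of first appearance
    final_order: list[str] = []
    for lab in raw_labels:
        if assign[lab] not in final_order:
            final_order.append(assign[lab])
    out = pd.DataFrame(
        0, index=final_order, columns=table.sample_ids,
        dtype=table.df.to_numpy().dtype,
    )
    for lab in raw_labels:
        out.loc[assign[lab]] += table.df.loc[lab].to_numpy()
    out.index.name = "taxon"
    merged = CountTable(out)

    rel_out = merged.relative_abundance().df
    mapping = pd.DataFrame(
        {
            "raw_label": raw_labels,
            "canonical": [canon[lab] for lab in raw_labels],
            "final_label": [assign[lab] for lab in raw_labels],
            "final_rank": [ref.entry(assign[lab]).rank for lab in raw_labels],
        }
    )
    report = MergeReport(
        mapping=mapping,
        merged_mass=rel_out.sum(axis=1),
        rounds=rounds,
    )
    if maj is not None:
        report.notes.append(f"majority domain: {maj}")
    return merged, report
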