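"""Readers and writers for the pipeline's tab-separated artifacts.

Canonical on-disk formats: TSV count tables (taxon label column named
``taxon``), TSV sample metadata, square TSV distance matrices with a
``# flavor:`` header comment, newick trees, and YAML configs.
"""

from __future__ import annotations

import os

import numpy as np
import pandas as pd
import skbio
import yaml

from .containers import CountTable, DistanceMatrix, SampleDesign

_DESIGN_COLUMNS = ["sample_id", "treatment", "O", "D", "N", "t_index", "day", "replicate"]


def read_count_table(path: str | os.PathLike) -> CountTable:
    """Read a TSV count table: first column ``taxon``, remaining columns samples."""
    df = pd.read_csv(path, sep="\t", dtype={0: str})
    if df.shape[1] < 2:
        raise ValueError(f"{path}: count table needs a taxon column and >=1 sample")
    df = df.set_index(df.columns[0])
    df.index.name = "taxon"
    body = df.apply(pd.to_numeric, errors="coerce")
    bad = np.argwhere(body.isna().to_numpy())
    if bad.size:
        i, j = bad[0]
        raise ValueError(f"{path}: non-numeric entry at taxon {df.index[i]!r}, "
                         f"sample {df.columns[j]!r}")
    return CountTable(body)


def write_count_table(table: CountTable, path: str | os.PathLike) -> None:
    df = table.df.copy()
    df.index.name = "taxon"
    df.to_csv(path, sep="\t")


def read_design(path: str | os.PathLike) -> list[SampleDesign]:
    """Read sample metadata TSV with the canonical column set."""
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in _DESIGN_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing metadata column(s) {missing}")
    return [
        SampleDesign(
            sample_id=str(r.sample_id), treatment=str(r.treatment),
            O=int(r.O), D=int(r.D), N=int(r.N),
            t_index=int(r.t_index), day=int(r.day), replicate=int(r.replicate),
        )
        for r in df.itertuples()
    ]


def write_design(designs: list[SampleDesign], path: str | os.PathLike) -> None:
    from .containers import design_frame

    design_frame(designs).to_csv(path, sep="\t", index=False)


def read_tree(path: str | os.PathLike) -> skbio.TreeNode:
    """Read a newick tree; every edge must carry a branch length.

    Missing branch lengths are an error (no default-length guessing), as is
    a duplicated leaf name. Unrooted multifurcations are accepted.
    """
    tree = skbio.TreeNode.read(str(path), convert_underscores=False)
    return _validate_tree(tree)


def parse_newick(newick: str) -> skbio.TreeNode:
    """Parse a newick string under the same validation as :func:`read_tree`."""
    import io as _io

    tree = skbio.TreeNode.read(_io.StringIO(newick), convert_underscores=False)
    return _validate_tree(tree)


def _validate_tree(tree: skbio.TreeNode) -> skbio.TreeNode:
    names = [t.name for t in tree.tips()]
    if len(names) != len(set(names)):
        dup = sorted({n for n in names if names.count(n) > 1})
        raise ValueError(f"duplicate leaf name(s): {dup}")
    for node in tree.traverse(include_self=False):
        if node.length is None:
            who = node.name or "<internal node>"
            raise ValueError(f"missing branch length on edge above {who!r}")
        if node.length < 0:
            raise ValueError(f"negative branch length above {node.name!r}")
    return tree


def read_distance_matrix(path: str | os.PathLike) -> DistanceMatrix:
    """Read a square TSV distance matrix (optional ``# flavor: x`` first line)."""
    flavor = "bray-curtis"
    with open(path) as fh:
        first = fh.readline()
        if first.startswith("#"):
            if "flavor:" in first:
                flavor = first.split("flavor:", 1)[1].strip()
            df = pd.read_csv(fh, sep="\t", index_col=0)
        else:
            fh.seek(0)
            df = pd.read_csv(fh, sep="\t", index_col=0)
    return DistanceMatrix(list(df.columns), df.to_numpy(dtype=float), flavor)


def write_distance_matrix(dm: DistanceMatrix, path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        fh.write(f"# flavor: {dm.flavor}\n")
        dm.to_frame().to_csv(fh, sep="\t", index_label="id")


def read_config(path: str | os.PathLike) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError(f"{path}: config must be a mapping")
    return cfg
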