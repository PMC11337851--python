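"""End-to-end pipeline driver.

From a config (synthetic generation parameters or paths to count tables,
metadata, taxonomy and tree) the driver produces, in one output
directory: merged count tables, the LRD table, Bray-Curtis / MPD / MNTD
distance matrices, PCoA coordinates, PERMANOVA reports, and a
``manifest.json`` listing every artifact with its SHA-256 checksum.
Outputs are a pure function of (inputs, config, seed).
"""

from __future__ import annotations

import hashlib
import json
import os
from pathlib import Path

import pandas as pd

from . import io as lio
from .containers import CountTable, SampleDesign
from .diversity import bray_curtis_matrix, pcoa
from .lrd import compute_lrd
from .permanova import build_design, permanova_sequential
from .phylo import comdist_weighted, comdistnt_weighted, patristic_matrix
from .simulate import Effect, SimConfig, simulate_experiment, simulate_tree, taxonomy_reference
from .taxonomy import MergeConfig, TaxonomyReference, merge_to_threshold

_REQUIRED_KEYS = ["seed", "output_dir"]


def _require(cfg: dict, key: str):
    if key not in cfg:
        raise KeyError(f"config is missing required key {key!r}")
    return cfg[key]


def _sim_config(block: dict, seed: int) -> SimConfig:
    kwargs = {}
    for k in ("replicates_16s", "depth_rna", "depth_dna", "dispersion"):
        if k in block:
            kwargs[k] = block[k]
    cfg = SimConfig(seed=seed, **kwargs)
    if "effects" in block:
        cfg.effects = [
            Effect(
                taxon=e["taxon"], treatment=e["treatment"],
                timepoints=None if e.get("timepoints") in (None, "all")
                else tuple(e["timepoints"]),
                log2_rna_enrichment=float(e.get("log2_rna_enrichment", 0.0)),
                abundance_fold=float(e.get("abundance_fold", 1.0)),
            )
            for e in block["effects"]
        ]
    return cfg


def run_pipeline(config: dict | str | os.PathLike,
                 base_dir: str | os.PathLike | None = None) -> dict:
    """Run the full analysis; returns the manifest (also written to disk).

    ``config`` is a mapping or a YAML path with keys ``seed``,
    ``output_dir``, exactly one of ``synthetic`` / ``inputs``, and
    optional ``merge`` (threshold, retention, unknown_policy), ``lrd``
    (zero_policy) and ``permanova`` (permutations) blocks.
    """
    if not isinstance(config, dict):
        base_dir = base_dir or Path(config).parent
        config = lio.read_config(config)
    base = Path(base_dir) if base_dir is not None else Path.cwd()

    seed = int(_require(config, "seed"))
    out_dir = Path(_require(config, "output_dir"))
    if not out_dir.is_absolute():
        out_dir = base / out_dir
    out_dir.mkdir(parents=True, exist_ok=True)

    merge_block = config.get("merge", {})
    merge_cfg = MergeConfig(
        T=float(merge_block.get("threshold", 0.04)),
        retention_rule=merge_block.get("retention", "any_sample"),
        unknown_policy=merge_block.get("unknown_policy", "error"),
    )
    zero_policy = config.get("lrd", {}).get("zero_policy", "drop")
    n_perm = int(config.get("permanova", {}).get("permutations", 999))

    artifacts: dict[str, Path] = {}

    def emit(name: str, writer) -> None:
        path = out_dir / name
        writer(path)
        artifacts[name] = path

    # ---- inputs -----------------------------------------------------------
    synthetic = "synthetic" in config
    if synthetic == ("inputs" in config):
        raise KeyError("config must have exactly one of 'synthetic' or 'inputs'")
    if synthetic:
        sim_cfg = _sim_config(config["synthetic"] or {}, seed)
        rna, dna, designs, truth = simulate_experiment(sim_cfg)
        ref = taxonomy_reference(sim_cfg)
        emit("rna.tsv", lambda p: lio.write_count_table(rna, p))
        emit("dna.tsv", lambda p: lio.write_count_table(dna, p))
        emit("design.tsv", lambda p: lio.write_design(designs, p))
        emit("taxonomy.tsv", lambda p: ref.to_frame().to_csv(p, sep="\t", index=False))
        emit("truth.tsv", lambda p: truth.to_csv(p, sep="\t", index=False))
        tree_src = None
    else:
        inputs = config["inputs"]
        def _path(key):
            p = Path(_require(inputs, key))
            return p if p.is_absolute() else base / p
        rna = lio.read_count_table(_path("rna"))
        dna = lio.read_count_table(_path("dna"))
        designs = lio.read_design(_path("design"))
        ref = TaxonomyReference.from_tsv(_path("taxonomy"))
        tree_src = _path("tree")

    # ---- taxonomy merge (joint, so RNA and DNA share one label set) -------
    if set(rna.taxon_labels) != set(dna.taxon_labels):
        diff = sorted(set(rna.taxon_labels) ^ set(dna.taxon_labels))
        raise ValueError(f"rna and dna taxon sets differ: {diff}")
    joint = CountTable(pd.concat([rna.df, dna.df.loc[rna.taxon_labels]], axis=1))
    merged_joint, report = merge_to_threshold(joint, ref, merge_cfg)
    rna_m = CountTable(merged_joint.df[rna.sample_ids])
    dna_m = CountTable(merged_joint.df[dna.sample_ids])
    emit("merged_rna.tsv", lambda p: lio.write_count_table(rna_m, p))
    emit("merged_dna.tsv", lambda p: lio.write_count_table(dna_m, p))
    emit("merge_report.tsv", lambda p: report.mapping.to_csv(p, sep="\t", index=False))

    # ---- LRD --------------------------------------------------------------
    lrd_res = compute_lrd(rna_m, dna_m, designs, zero_policy=zero_policy)
    emit("lrd.tsv", lambda p: lrd_res.table.to_csv(p, sep="\t", index=False))
    emit("lrd_per_time.tsv",
         lambda p: lrd_res.per_time.to_csv(p, sep="\t", index=False))
    emit("lrd_skipped.tsv",
         lambda p: lrd_res.skipped.to_csv(p, sep="\t", index=False))

    # ---- tree over the merged label set -----------------------------------
    if tree_src is None:
        newick = simulate_tree(rna_m.taxon_labels, seed=seed + 1)
        tree = lio.parse_newick(newick)
        emit("tree.nwk", lambda p: Path(p).write_text(newick + "\n"))
    else:
        tree = lio.read_tree(tree_src)
    pat = patristic_matrix(tree)

    # ---- distance matrices + ordination -----------------------------------
    distances = {}
    for tag, table in (("rna", rna_m), ("dna", dna_m)):
        rel = table.relative_abundance()
        distances[f"bc_{tag}"] = bray_curtis_matrix(rel)
        distances[f"mpd_{tag}"] = comdist_weighted(rel, pat)
        distances[f"mntd_{tag}"] = comdistnt_weighted(rel, pat)
        ord_res = pcoa(distances[f"bc_{tag}"])
        emit(f"pcoa_bc_{tag}.tsv",
             lambda p, o=ord_res: o.to_frame().to_csv(p, sep="\t", index_label="id"))
        eig = pd.DataFrame({"eigenvalue": ord_res.eigenvalues})
        emit(f"pcoa_bc_{tag}_eigen.tsv",
             lambda p, e=eig: e.to_csv(p, sep="\t", index_label="axis"))
    for name, dm in distances.items():
        emit(f"{name}.tsv", lambda p, d=dm: lio.write_distance_matrix(d, p))

    # ---- PERMANOVA ---------------------------------------------------------
    by_id = {d.sample_id: d for d in designs}
    for i, (name, dm) in enumerate(sorted(distances.items())):
        sub = [by_id[s] for s in dm.ids]
        terms = build_design(sub)
        rep = permanova_sequential(dm, terms, n_perm=n_perm, seed=seed + 100 + i)
        def _write(p, r=rep):
            with open(p, "w") as fh:
                fh.write(f"# permutations: {r.n_permutations}; seed: {r.seed}\n")
                for note in r.notes:
                    fh.write(f"# note: {note}\n")
                r.table.to_csv(fh, sep="\t", index=False)
        emit(f"permanova_{name}.tsv", _write)

    # ---- manifest ----------------------------------------------------------
    manifest = {
        "artifacts": {
            name: {
                "sha256": hashlib.sha256(path.read_bytes()).hexdigest(),
                "bytes": path.stat().st_size,
            }
            for name, path in sorted(artifacts.items())
        },
        "seed": seed,
        "merge": {"threshold": merge_cfg.T, "retention": merge_cfg.retention_rule},
        "lrd": {"zero_policy": zero_policy},
        "permanova": {"permutations": n_perm},
    }
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return manifest
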