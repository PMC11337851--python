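"""Dirichlet-multinomial simulator for the oil/dispersant microcosm design.

Generates paired metatranscriptomic and 16S rRNA gene count tables, sample
metadata, a toy taxonomy reference and a random phylogeny with the
statistical structure the analysis assumes, so every pipeline stage is
testable without the study's sequencing archives.

Model
-----
Each (treatment, timepoint) cell has a latent community: base genus
abundances, multiplied by the abundance fold-changes of any planted
effects active in that cell, renormalized, and drawn through a
Dirichlet(concentration x adjusted base) to add compositional
overdispersion. 16S libraries are multinomial draws from that latent
composition (``replicates_16s`` per cell); the metatranscriptome is a
multinomial draw from the RNA composition, in which each effect taxon's
fraction is exactly 2^L times its DNA fraction (the complement is scaled
to keep a distribution), so a planted log2 enrichment L is recovered by
the LRD estimator without renormalization bias.

The default layout mirrors the microcosm study: treatments BC, DISP, WAF,
CEWAF at timepoints t0..t4 (days 0, 7, 17, 28, 42) and CEWAFN at t0, t1,
t4 only; triplicate 16S libraries and one RNA library per cell.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .containers import TIMEPOINT_DAYS, TREATMENT_FLAGS, CountTable, SampleDesign
from .taxonomy import TaxonomyReference

#: (genus, (domain, phylum, class, family)) lineages of the toy community
DEFAULT_LINEAGES: list[tuple[str, tuple[str, str, str, str]]] = [
    ("Colwellia", ("Bacteria", "Pseudomonadota", "Gammaproteobacteria", "Colwelliaceae")),
    ("Marinobacter", ("Bacteria", "Pseudomonadota", "Gammaproteobacteria", "Alteromonadaceae")),
    ("Bermanella", ("Bacteria", "Pseudomonadota", "Gammaproteobacteria", "Oceanospirillaceae")),
    ("Amphritea", ("Bacteria", "Pseudomonadota", "Gammaproteobacteria", "Oceanospirillaceae")),
    ("Balneatrix", ("Bacteria", "Pseudomonadota", "Gammaproteobacteria", "Oceanospirillaceae")),
    ("Methylophaga", ("Bacteria", "Pseudomonadota", "Gammaproteobacteria", "Piscirickettsiaceae")),
    ("Cycloclasticus", ("Bacteria", "Pseudomonadota", "Gammaproteobacteria", "Piscirickettsiaceae")),
    ("Pseudomonas", ("Bacteria", "Pseudomonadota", "Gammaproteobacteria", "Pseudomonadaceae")),
    ("Oleiphilus", ("Bacteria", "Pseudomonadota", "Gammaproteobacteria", "Oleiphilaceae")),
    ("Parvibaculum", ("Bacteria", "Pseudomonadota", "Alphaproteobacteria", "Parvibaculaceae")),
    ("Sulfitobacter", ("Bacteria", "Pseudomonadota", "Alphaproteobacteria", "Rhodobacteraceae")),
    ("Kordia", ("Bacteria", "Bacteroidota", "Flavobacteriia", "Flavobacteriaceae")),
    ("Polaribacter", ("Bacteria", "Bacteroidota", "Flavobacteriia", "Flavobacteriaceae")),
    ("Tenacibaculum", ("Bacteria", "Bacteroidota", "Flavobacteriia", "Flavobacteriaceae")),
    ("Nitrosopumilus", ("Archaea", "Thermoproteota", "Nitrososphaeria", "Nitrosopumilaceae")),
    ("Mimivirus", ("Viruses", "Nucleocytoviricota", "Megaviricetes", "Mimiviridae")),
]

#: base abundances aligned with DEFAULT_LINEAGES, positive and summing to 1;
#: strongly RNA-enriched taxa (Bermanella, Methylophaga) sit at low base
#: abundance so a 2^4 RNA enrichment stays well inside the unit simplex
DEFAULT_BASE = np.array(
    [0.16, 0.14, 0.015, 0.05, 0.04, 0.02, 0.07, 0.09,
     0.035, 0.03, 0.11, 0.06, 0.085, 0.08, 0.01, 0.005]
)

#: (treatment, timepoints or None=all available)
DEFAULT_LAYOUT: list[tuple[str, list[int]]] = [
    ("BC", [0, 1, 2, 3, 4]),
    ("DISP", [0, 1, 2, 3, 4]),
    ("WAF", [0, 1, 2, 3, 4]),
    ("CEWAF", [0, 1, 2, 3, 4]),
    ("CEWAFN", [0, 1, 4]),
]


@dataclass(frozen=True)
class Effect:
    """A planted perturbation for one taxon in one treatment.

    ``abundance_fold`` multiplies the taxon's base (DNA-side) abundance;
    ``log2_rna_enrichment`` (L) sets the RNA:DNA fraction ratio to exactly
    2^L. ``timepoints`` restricts the effect (None = every timepoint the
    treatment has).
    """

    taxon: str
    treatment: str
    timepoints: tuple[int, ...] | None = None
    log2_rna_enrichment: float = 0.0
    abundance_fold: float = 1.0

    def active(self, treatment: str, t: int) -> bool:
        return self.treatment == treatment and (
            self.timepoints is None or t in self.timepoints
        )


#: defaults emulating the study's planted structure: a dispersant bloom,
#: an oil-only bloom, a late dispersant responder, and RNA-enriched /
#: RNA-silent taxa for the activity groups
DEFAULT_EFFECTS: list[Effect] = [
    Effect("Colwellia", "DISP", (1, 2, 3, 4), abundance_fold=20.0),
    Effect("Colwellia", "CEWAF", (1, 2, 3, 4), abundance_fold=20.0),
    Effect("Colwellia", "CEWAFN", (1, 4), abundance_fold=20.0),
    Effect("Marinobacter", "WAF", (2, 3, 4), abundance_fold=8.0),
    Effect("Kordia", "DISP", (4,), abundance_fold=6.0),
    Effect("Methylophaga", "CEWAF", None, log2_rna_enrichment=4.0),
    Effect("Bermanella", "WAF", None, log2_rna_enrichment=4.0),
    Effect("Amphritea", "CEWAF", None, log2_rna_enrichment=-4.0),
    Effect("Oleiphilus", "WAF", None, log2_rna_enrichment=-4.0),
]


@dataclass
class SimConfig:
    """Configuration of one simulated microcosm experiment."""

    seed: int = 0
    lineages: list[tuple[str, tuple[str, ...]]] = field(
        default_factory=lambda: list(DEFAULT_LINEAGES))
    base_abundance: np.ndarray = field(default_factory=lambda: DEFAULT_BASE.copy())
    layout: list[tuple[str, list[int]]] = field(
        default_factory=lambda: [(t, list(ts)) for t, ts in DEFAULT_LAYOUT])
    replicates_16s: int = 3
    depth_rna: int = 100_000
    depth_dna: int = 100_000
    effects: list[Effect] = field(default_factory=lambda: list(DEFAULT_EFFECTS))
    dispersion: float = 500.0  # Dirichlet concentration; larger = less noise

    def __post_init__(self):
        base = np.asarray(self.base_abundance, dtype=float)
        if len(base) != len(self.lineages):
            raise ValueError("base_abundance length must match lineages")
        if (base <= 0).any():
            raise ValueError("base abundances must be positive")
        if abs(base.sum() - 1) > 1e-9:
            raise ValueError("base abundances must sum to 1")
        self.base_abundance = base
        taxa = {g for g, _ in self.lineages}
        treatments = {t for t, _ in self.layout}
        for e in self.effects:
            if e.taxon not in taxa:
                raise ValueError(f"effect references unknown taxon {e.taxon!r}")
            if e.treatment not in treatments:
                raise ValueError(f"effect references absent treatment {e.treatment!r}")

    @property
    def taxa(self) -> list[str]:
        return [g for g, _ in self.lineages]


def taxonomy_reference(cfg: SimConfig) -> TaxonomyReference:
    """Toy reference (domain/phylum/class/family/genus) over the config's taxa."""
    rows: list[tuple[str, str, str, str | None]] = []
    seen: set[tuple[str, str]] = set()
    ranks = ["domain", "phylum", "class", "family", "genus"]
    for genus, lineage in cfg.lineages:
        path = list(lineage) + [genus]
        parent: str | None = None
        for rank, name in zip(ranks, path):
            if (name, rank) not in seen:
                rows.append((name, name, rank, parent))
                seen.add((name, rank))
            parent = name
    return TaxonomyReference(rows, ranks=["root"] + ranks)


def _rna_fractions(p: np.ndarray, log2_enrich: np.ndarray) -> np.ndarray:
    """RNA composition with exact per-taxon 2^L fraction ratios.

    Effect taxa get q_i = 2^L_i p_i; the unaffected complement is scaled by
    a common factor so q sums to 1 (their shared offset is the price of
    keeping q a distribution).
    """
    mult = 2.0 ** log2_enrich
    hit = mult != 1.0
    mass_hit = float(p[hit] @ mult[hit])
    if mass_hit >= 1.0:
        raise ValueError("planted RNA enrichments exceed the unit simplex")
    q = p * mult
    rest = float(p[~hit].sum())
    if rest > 0:
        q[~hit] *= (1.0 - mass_hit) / rest
    return q


def simulate_experiment(cfg: SimConfig
                        ) -> tuple[CountTable, CountTable, list[SampleDesign],
                                   pd.DataFrame]:
    """Simulate paired RNA/16S count tables, metadata and the effect truth.

    Byte-identical output for a fixed config (seeded generator, fixed
    iteration order: treatments in layout order, timepoints ascending).
    """
    rng = np.random.default_rng(cfg.seed)
    taxa = cfg.taxa
    n_taxa = len(taxa)
    rna_cols: dict[str, np.ndarray] = {}
    dna_cols: dict[str, np.ndarray] = {}
    designs: list[SampleDesign] = []

    for treatment, timepoints in cfg.layout:
        O, D, N = TREATMENT_FLAGS[treatment]
        for t in sorted(timepoints):
            base = cfg.base_abundance.copy()
            enrich = np.zeros(n_taxa)
            for e in cfg.effects:
                if e.active(treatment, t):
                    i = taxa.index(e.taxon)
                    base[i] *= e.abundance_fold
                    enrich[i] += e.log2_rna_enrichment
            base /= base.sum()
            p_cell = rng.dirichlet(cfg.dispersion * base)
            # Dirichlet can underflow tiny fractions to 0; keep them positive
            p_cell = np.maximum(p_cell, 1e-12)
            p_cell /= p_cell.sum()
            q_cell = _rna_fractions(p_cell, enrich)

            rna_id = f"RNA_{treatment}_t{t}"
            rna_cols[rna_id] = rng.multinomial(cfg.depth_rna, q_cell)
            designs.append(SampleDesign(rna_id, treatment, O, D, N, t,
                                        TIMEPOINT_DAYS[t], replicate=1))
            for rep in range(1, cfg.replicates_16s + 1):
                dna_id = f"DNA_{treatment}_t{t}_r{rep}"
                dna_cols[dna_id] = rng.multinomial(cfg.depth_dna, p_cell)
                designs.append(SampleDesign(dna_id, treatment, O, D, N, t,
                                            TIMEPOINT_DAYS[t], replicate=rep))

    rna = CountTable(pd.DataFrame(rna_cols, index=taxa))
    dna = CountTable(pd.DataFrame(dna_cols, index=taxa))
    truth = pd.DataFrame(
        [
            {
                "taxon": e.taxon,
                "treatment": e.treatment,
                "timepoints": "all" if e.timepoints is None
                else ",".join(map(str, e.timepoints)),
                "log2_rna_enrichment": e.log2_rna_enrichment,
                "abundance_fold": e.abundance_fold,
            }
            for e in cfg.effects
        ],
        columns=["taxon", "treatment", "timepoints",
                 "log2_rna_enrichment", "abundance_fold"],
    )
    return rna, dna, designs, truth


def simulate_tree(taxa: list[str], seed: int | None = None) -> str:
    """Random rooted binary tree over the labels, as a newick string.

    Random sequential pair-joins with exponential branch lengths (mean
    0.5, floored at 0.01); deterministic for a fixed seed.
    """
    labels = [str(t) for t in taxa]
    if len(labels) < 2:
        raise ValueError("need at least 2 taxa for a tree")
    if len(set(labels)) != len(labels):
        raise ValueError("duplicate taxon labels")
    rng = np.random.default_rng(seed)
    nodes = list(labels)
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        right = nodes.pop(j)
        left = nodes.pop(i)
        bl, br = np.maximum(rng.exponential(0.5, size=2), 0.01)
        nodes.append(f"({left}:{bl:.6f},{right}:{br:.6f})")
    return nodes[0] + ";"


def null_config(seed: int = 0, **overrides) -> SimConfig:
    """Default layout with no planted effects (for null-behavior checks)."""
    cfg = SimConfig(seed=seed, effects=[], **overrides)
    return cfg


def with_seed(cfg: SimConfig, seed: int) -> SimConfig:
    return replace(cfg, seed=seed)
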