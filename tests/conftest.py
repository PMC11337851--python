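import numpy as np
import pandas as pd
import pytest

from lrdmeta import CountTable, TaxonomyReference


@pytest.fixture
def rng():
    return np.random.default_rng(20260925)


@pytest.fixture
def toy_ref() -> TaxonomyReference:
    """Small reference with a full Colwellia lineage, a synonym and a homonym.

    'Paradoxus' exists both as a bacterial and an archaeal genus to exercise
    majority-domain homonym resolution.
    """
    rows = [
        ("Bacteria", "Bacteria", "domain", None),
        ("Pseudomonadota", "Pseudomonadota", "phylum", "Bacteria"),
        ("Gammaproteobacteria", "Gammaproteobacteria", "class", "Pseudomonadota"),
        ("Colwelliaceae", "Colwelliaceae", "family", "Gammaproteobacteria"),
        ("Colwellia", "Colwellia", "genus", "Colwelliaceae"),
        ("Colwellia sp.", "Colwellia", "genus", "Colwelliaceae"),  # synonym
        ("Alteromonadaceae", "Alteromonadaceae", "family", "Gammaproteobacteria"),
        ("Marinobacter", "Marinobacter", "genus", "Alteromonadaceae"),
        ("Bacteroidota", "Bacteroidota", "phylum", "Bacteria"),
        ("Flavobacteriia", "Flavobacteriia", "class", "Bacteroidota"),
        ("Flavobacteriaceae", "Flavobacteriaceae", "family", "Flavobacteriia"),
        ("Kordia", "Kordia", "genus", "Flavobacteriaceae"),
        ("Archaea", "Archaea", "domain", None),
        ("Thermoproteota", "Thermoproteota", "phylum", "Archaea"),
        ("Nitrososphaeria", "Nitrososphaeria", "class", "Thermoproteota"),
        ("Nitrosopumilaceae", "Nitrosopumilaceae", "family", "Nitrososphaeria"),
        ("Paradoxus", "Paradoxus_B", "genus", "Colwelliaceae"),
        ("Paradoxus", "Paradoxus_A", "genus", "Nitrosopumilaceae"),
        ("Paradoxus_B", "Paradoxus_B", "genus", "Colwelliaceae"),
        ("Paradoxus_A", "Paradoxus_A", "genus", "Nitrosopumilaceae"),
    ]
    return TaxonomyReference(rows)


def random_taxonomy(rng, max_domains=3, max_families=3, max_leaves=10):
    """Random shallow taxonomy (root/domain/family/genus) plus known lineages.

    Returns (TaxonomyReference rows-compatible object, lineages) where
    lineages maps each genus to its full path ['Root', domain, family, genus]
    built independently of the package's lineage machinery.
    """
    rows, lineages = [], {}
    n_dom = rng.integers(1, max_domains + 1)
    leaf_id = 0
    for d in range(n_dom):
        dom = f"D{d}"
        rows.append((dom, dom, "domain", None))
        for f in range(rng.integers(1, max_families + 1)):
            fam = f"D{d}F{f}"
            rows.append((fam, fam, "family", dom))
            for _ in range(rng.integers(1, 4)):
                if leaf_id >= max_leaves:
                    break
                gen = f"G{leaf_id}"
                leaf_id += 1
                rows.append((gen, gen, "genus", fam))
                lineages[gen] = ["Root", dom, fam, gen]
    if not lineages:  # guarantee at least one leaf
        rows += [("D0", "D0", "domain", None), ("D0F0", "D0F0", "family", "D0"),
                 ("G0", "G0", "genus", "D0F0")]
        lineages["G0"] = ["Root", "D0", "D0F0", "G0"]
    ref = TaxonomyReference(rows, ranks=["root", "domain", "family", "genus"])
    return ref, lineages


def random_count_table(rng, labels, n_samples=None, max_count=200) -> CountTable:
    n_samples = n_samples or int(rng.integers(1, 5))
    counts = rng.integers(0, max_count, size=(len(labels), n_samples))
    # every sample needs at least one positive entry
    for j in range(n_samples):
        if counts[:, j].sum() == 0:
            counts[rng.integers(len(labels)), j] = 1
    cols = [f"S{j}" for j in range(n_samples)]
    return CountTable(pd.DataFrame(counts, index=list(labels), columns=cols))
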