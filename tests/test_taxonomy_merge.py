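import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from lrdmeta import CountTable, MergeConfig, TaxonomyReference, canonicalize_label, merge_to_threshold
from lrdmeta.taxonomy import ROOT_NAME, UNCLASSIFIED_NAME
from conftest import random_count_table, random_taxonomy
from oracles import merge_oracle


class TestCanonicalize:
    def test_full_lineage_lookup(self, toy_ref):
        path = canonicalize_label("Colwellia", toy_ref)
        assert path == ["Root", "Bacteria", "Pseudomonadota", "Gammaproteobacteria",
                        "Colwelliaceae", "Colwellia"]

    def test_case_and_whitespace_insensitive(self, toy_ref):
        assert canonicalize_label(" colwellia ", toy_ref) == \
            canonicalize_label("Colwellia", toy_ref)

    def test_synonym_resolves_to_same_path(self, toy_ref):
        assert canonicalize_label("Colwellia sp.", toy_ref) == \
            canonicalize_label("Colwellia", toy_ref)

    def test_unknown_label_policies(self, toy_ref):
        with pytest.raises(KeyError, match="NotARealTaxon"):
            canonicalize_label("NotARealTaxon", toy_ref)
        path = canonicalize_label("NotARealTaxon", toy_ref, unknown_policy="bucket")
        assert path == [ROOT_NAME, UNCLASSIFIED_NAME]

    def test_homonym_resolved_by_majority_domain(self, toy_ref):
        assert toy_ref.resolve("Paradoxus", majority_domain="Bacteria") == "Paradoxus_B"
        assert toy_ref.resolve("Paradoxus", majority_domain="Archaea") == "Paradoxus_A"
        with pytest.raises(KeyError, match="ambiguous"):
            toy_ref.resolve("Paradoxus")

    def test_cycle_in_reference_rejected(self):
        # a genus that is its own ancestor through a bogus rank inversion
        with pytest.raises(ValueError, match="not closer to the root|cycle"):
            TaxonomyReference(
                [("A", "A", "family", "B"), ("B", "B", "family", "A")],
                ranks=["root", "family"],
            )


def _sibling_fixture():
    """A (2% everywhere) and B (3% everywhere), children of family F."""
    ref = TaxonomyReference(
        [("D", "D", "domain", None), ("F", "F", "family", "D"),
         ("Q", "Q", "family", "D"), ("A", "A", "genus", "F"),
         ("B", "B", "genus", "F"), ("C", "C", "genus", "Q")],
        ranks=["root", "domain", "family", "genus"],
    )
    counts = pd.DataFrame({"S1": [2, 3, 95], "S2": [4, 6, 190]},
                          index=["A", "B", "C"])
    return ref, CountTable(counts)


class TestMerge:
    def test_low_abundance_siblings_merge_to_family(self):
        ref, table = _sibling_fixture()
        merged, report = merge_to_threshold(table, ref, MergeConfig(T=0.04))
        assert set(merged.taxon_labels) == {"F", "C"}
        rel = merged.relative_abundance().df
        assert rel.loc["F"].tolist() == pytest.approx([0.05, 0.05])
        mapping = dict(zip(report.mapping.raw_label, report.mapping.final_label))
        assert mapping == {"A": "F", "B": "F", "C": "C"}

    def test_abundant_in_one_sample_kept_under_any_sample(self):
        ref = TaxonomyReference(
            [("D", "D", "domain", None), ("F", "F", "family", "D"),
             ("A", "A", "genus", "F"), ("B", "B", "genus", "F")],
            ranks=["root", "domain", "family", "genus"],
        )
        # A: 50% in S1, 0% in S2; B carries the rest
        table = CountTable(pd.DataFrame({"S1": [50, 50], "S2": [0, 100]},
                                        index=["A", "B"]))
        merged, _ = merge_to_threshold(table, ref, MergeConfig(T=0.04))
        assert "A" in merged.taxon_labels

    def test_star_taxonomy_forces_root_bucket(self):
        labels = [f"G{i}" for i in range(100)]
        ref = TaxonomyReference([(g, g, "genus", None) for g in labels],
                                ranks=["root", "genus"])
        table = CountTable(pd.DataFrame({"S1": [1] * 100}, index=labels))
        merged, _ = merge_to_threshold(table, ref, MergeConfig(T=0.04))
        assert merged.taxon_labels == [ROOT_NAME]
        assert merged.df.loc[ROOT_NAME, "S1"] == 100

    def test_unknown_labels_bucketed(self, toy_ref):
        table = CountTable(pd.DataFrame({"S1": [60, 40]},
                                        index=["Colwellia", "NotARealTaxon"]))
        merged, report = merge_to_threshold(
            table, toy_ref, MergeConfig(T=0.04, unknown_policy="bucket"))
        assert UNCLASSIFIED_NAME in merged.taxon_labels

    def test_mapping_total_over_inputs(self, rng):
        ref, lineages = random_taxonomy(rng)
        table = random_count_table(rng, sorted(lineages))
        _, report = merge_to_threshold(table, ref, MergeConfig(T=0.1))
        assert sorted(report.mapping.raw_label) == sorted(table.taxon_labels)

    def test_no_output_label_descends_from_another(self, rng):
        for _ in range(30):
            ref, lineages = random_taxonomy(rng)
            table = random_count_table(rng, sorted(lineages))
            merged, _ = merge_to_threshold(table, ref, MergeConfig(T=0.08))
            labels = [l for l in merged.taxon_labels if l != ROOT_NAME]
            for a in labels:
                for b in labels:
                    if a != b:
                        assert a not in ref.lineage(b)[:-1]

    def test_idempotence(self, rng):
        for _ in range(20):
            ref, lineages = random_taxonomy(rng)
            table = random_count_table(rng, sorted(lineages))
            cfg = MergeConfig(T=0.07)
            once, _ = merge_to_threshold(table, ref, cfg)
            twice, _ = merge_to_threshold(once, ref, cfg)
            assert once.taxon_labels == twice.taxon_labels
            assert np.array_equal(once.df.to_numpy(), twice.df.to_numpy())

    def test_raising_threshold_never_adds_labels(self, rng):
        for _ in range(15):
            ref, lineages = random_taxonomy(rng)
            table = random_count_table(rng, sorted(lineages))
            sizes = [
                merge_to_threshold(table, ref, MergeConfig(T=t))[0].shape[0]
                for t in (0.02, 0.05, 0.1, 0.2, 0.4)
            ]
            assert sizes == sorted(sizes, reverse=True)

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(st.integers(min_value=0, max_value=10_000))
    def test_mass_conservation_exact(self, seed):
        rng = np.random.default_rng(seed)
        ref, lineages = random_taxonomy(rng)
        table = random_count_table(rng, sorted(lineages))
        merged, _ = merge_to_threshold(table, ref, MergeConfig(T=0.05))
        assert np.array_equal(table.df.sum(axis=0).to_numpy(),
                              merged.df.sum(axis=0).to_numpy())

    def test_matches_bruteforce_oracle(self, rng):
        for _ in range(50):
            ref, lineages = random_taxonomy(rng)
            table = random_count_table(rng, sorted(lineages))
            T = float(rng.choice([0.02, 0.05, 0.1, 0.2]))
            merged, report = merge_to_threshold(table, ref, MergeConfig(T=T))
            final_oracle, agg_oracle = merge_oracle(table.df, lineages, T)
            got = dict(zip(report.mapping.raw_label, report.mapping.final_label))
            assert got == final_oracle
            assert set(merged.taxon_labels) == set(agg_oracle.index)
            assert np.array_equal(
                merged.df.loc[agg_oracle.index].to_numpy(), agg_oracle.to_numpy())

    def test_per_sample_rule_is_stricter(self, rng):
        for _ in range(10):
            ref, lineages = random_taxonomy(rng)
            table = random_count_table(rng, sorted(lineages), n_samples=3)
            any_n = merge_to_threshold(
                table, ref, MergeConfig(T=0.1, retention_rule="any_sample"))[0].shape[0]
            per_n = merge_to_threshold(
                table, ref, MergeConfig(T=0.1, retention_rule="per_sample"))[0].shape[0]
            assert per_n <= any_n

    def test_threshold_validation(self):
        with pytest.raises(ValueError, match="T="):
            MergeConfig(T=0.0)
        with pytest.raises(ValueError, match="T="):
            MergeConfig(T=1.0)
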