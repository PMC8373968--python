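import itertools

import numpy as np
import pandas as pd
import pytest

from lncland.classify import (
    CATEGORIES,
    DECallMatrix,
    assemble_assignments,
    classify_atc,
    classify_differentiated,
    differentiated_union,
    intersection_report,
    validate_gene,
    validation_table,
)
from lncland.datasets import DataContractError
from lncland.de import contrast_name

ALL_GENES = ["g0"]


def table_for(de_genes, all_genes, contrast, lfc=2.0):
    return pd.DataFrame(
        {
            "gene_id": all_genes,
            "contrast": contrast,
            "log2fc": [lfc if g in de_genes else 0.0 for g in all_genes],
            "is_de": [g in de_genes for g in all_genes],
        }
    )


def build_calls(de_map, measured=None, all_genes=ALL_GENES):
    """de_map: {(dataset, contrast): set-of-DE-genes}."""
    calls = DECallMatrix()
    by_ds = {}
    for (ds, contrast), genes in de_map.items():
        by_ds.setdefault(ds, []).append(table_for(genes, all_genes, contrast))
    for ds, tables in by_ds.items():
        calls.add_table(ds, pd.concat(tables, ignore_index=True))
    for ds, genes in (measured or {}).items():
        calls.set_measured(ds, genes)
    return calls


class TestValidation:
    def test_full_truth_table_matches_enumerated_oracle(self):
        c = contrast_name("clPTC", "NT")
        for de_a, de_b, de_arr, measured in itertools.product([False, True], repeat=4):
            de_map = {
                ("rnaseqA", c): {"g0"} if de_a else set(),
                ("rnaseqB", c): {"g0"} if de_b else set(),
                ("array", c): {"g0"} if de_arr else set(),
            }
            calls = build_calls(de_map, {"array": {"g0"} if measured else set()})
            expected = (de_a and de_b and de_arr) or (de_a and de_b and not measured)
            got = validate_gene("g0", "clPTC", calls)
            assert got == expected, (de_a, de_b, de_arr, measured)

    def test_only_ptc_variants_are_validatable(self):
        calls = build_calls({})
        with pytest.raises(DataContractError):
            validate_gene("g0", "FTC", calls)


def diff_calls(pattern, between_de=(), validated=("clPTC", "fvPTC"), all_genes=ALL_GENES):
    """Primary-dataset call matrix for one gene with the given vs-NT pattern.

    ``between_de`` lists (a, b) pairs that are DE; every other between
    contrast exists but is null. Validation flags are set directly.
    """
    subtypes = ["FA", "FTC", "fvPTC", "clPTC"]
    de_map = {}
    for st in subtypes:
        de_map[("rnaseqA", contrast_name(st, "NT"))] = (
            {"g0"} if st in pattern else set()
        )
    for a, b in itertools.permutations(subtypes, 2):
        de_map[("rnaseqA", contrast_name(a, b))] = (
            {"g0"} if (a, b) in between_de else set()
        )
    calls = build_calls(de_map, all_genes=all_genes)
    val = pd.DataFrame(
        {
            "clPTC": ["clPTC" in validated],
            "fvPTC": ["fvPTC" in validated],
        },
        index=pd.Index(["g0"], name="gene_id"),
    )
    return calls, val


class TestCascade:
    def assign(self, *args, **kwargs):
        calls, val = diff_calls(*args, **kwargs)
        return classify_differentiated(["g0"], calls, val)["category"].iloc[0]

    def test_all_four_subtypes_validated_is_common_fa_wdtc(self):
        assert self.assign({"FA", "FTC", "fvPTC", "clPTC"}) == "common_FA_WDTC"

    def test_all_four_without_validation_is_none(self):
        assert self.assign({"FA", "FTC", "fvPTC", "clPTC"}, validated=()) == "none"

    def test_wdtc_needs_fa_contrast_in_both_ptc_variants(self):
        pattern = {"FTC", "fvPTC", "clPTC"}
        full = [("fvPTC", "FA"), ("clPTC", "FA")]
        assert self.assign(pattern, between_de=full) == "common_WDTC"
        assert self.assign(pattern, between_de=full[:1]) == "none"

    def test_papillary_needs_fa_and_ftc_contrasts(self):
        pattern = {"fvPTC", "clPTC"}
        full = [("fvPTC", "FA"), ("fvPTC", "FTC"), ("clPTC", "FA"), ("clPTC", "FTC")]
        assert self.assign(pattern, between_de=full) == "common_papillary"
        # failing one FTC clause drops to none (P is not a singleton)
        assert self.assign(pattern, between_de=full[:3]) == "none"

    def test_specific_clptc_needs_all_three_between_contrasts(self):
        pattern = {"clPTC"}
        full = [("clPTC", "fvPTC"), ("clPTC", "FTC"), ("clPTC", "FA")]
        assert self.assign(pattern, between_de=full) == "specific_clPTC"
        assert self.assign(pattern, between_de=full[:2]) == "none"

    def test_specific_ftc_requires_no_validation_and_no_fa_clause(self):
        got = self.assign(
            {"FTC"}, between_de=[("FTC", "clPTC"), ("FTC", "fvPTC")], validated=()
        )
        assert got == "specific_FTC"

    def test_unlisted_pattern_is_none(self):
        assert self.assign({"FA", "clPTC"}) == "none"

    def test_gene_order_does_not_change_assignments(self):
        genes = [f"g{i}" for i in range(6)]
        subtypes = ["FA", "FTC", "fvPTC", "clPTC"]
        de_map = {("rnaseqA", contrast_name(st, "NT")): {"g0", "g2"} for st in subtypes}
        for a, b in itertools.permutations(subtypes, 2):
            de_map[("rnaseqA", contrast_name(a, b))] = {"g3"}
        calls = build_calls(de_map, all_genes=genes)
        val = pd.DataFrame(
            {"clPTC": [True] * 6, "fvPTC": [True] * 6},
            index=pd.Index(genes, name="gene_id"),
        )
        fwd = classify_differentiated(genes, calls, val)
        rev = classify_differentiated(genes[::-1], calls, val)
        assert fwd["category"].sort_index().equals(rev["category"].sort_index())

    def test_missing_between_contrast_is_named(self):
        de_map = {
            ("rnaseqA", contrast_name(st, "NT")): ({"g0"} if st == "FTC" else set())
            for st in ["FA", "FTC", "fvPTC", "clPTC"]
        }
        calls = build_calls(de_map)
        val = pd.DataFrame(
            {"clPTC": [False], "fvPTC": [False]}, index=pd.Index(["g0"], name="gene_id")
        )
        with pytest.raises(DataContractError, match="FTC_vs_clPTC"):
            classify_differentiated(["g0"], calls, val)

    def test_removing_a_validation_call_never_creates_a_validated_category(self, rng):
        # validation is monotone in the DE calls of the confirming datasets
        # (second RNA-seq set and microarray): dropping one of those calls can
        # only switch validation off, so a "none" gene stays "none" for every
        # category that requires validation
        subtypes = ["FA", "FTC", "fvPTC", "clPTC"]
        validated_cats = {c for c in CATEGORIES if c not in ("specific_FTC", "specific_ATC")}
        for trial in range(60):
            pattern = {st for st in subtypes if rng.random() < 0.5}
            between = [
                p for p in itertools.permutations(subtypes, 2) if rng.random() < 0.5
            ]
            confirm = {
                (ds, st): rng.random() < 0.7
                for ds in ("rnaseqB", "array")
                for st in ("clPTC", "fvPTC")
            }

            def classify_with(confirm_calls):
                calls, _ = diff_calls(pattern, between)
                for (ds, st), de in confirm_calls.items():
                    calls.add_table(
                        ds, table_for({"g0"} if de else set(), ["g0"], contrast_name(st, "NT"))
                    )
                    calls.set_measured(ds, {"g0"})
                val = validation_table(["g0"], calls)
                return classify_differentiated(["g0"], calls, val)["category"].iloc[0]

            before = classify_with(confirm)
            if before != "none":
                continue
            on = [k for k, v in confirm.items() if v]
            if not on:
                continue
            drop = on[int(rng.integers(len(on)))]
            after = classify_with({**confirm, drop: False})
            assert after not in validated_cats


class TestAtcRule:
    def atc_calls(self, de_nt, de_cl, de_fv, all_genes):
        de_map = {
            ("array", contrast_name("ATC", "NT")): de_nt,
            ("array", contrast_name("ATC", "clPTC")): de_cl,
            ("array", contrast_name("ATC", "fvPTC")): de_fv,
        }
        return build_calls(de_map, all_genes=all_genes)

    def test_funnel_and_selection(self):
        genes = ["a", "b", "c", "d"]
        calls = self.atc_calls(
            de_nt={"a", "b", "c"},
            de_cl={"a", "b"},
            de_fv={"a"},
            all_genes=genes,
        )
        final, funnel = classify_atc(calls, differentiated_union={"b"})
        assert final == {"a"}
        assert funnel == {"de_vs_nt": 3, "after_subtraction": 2, "after_ptc_filter": 1}
        assert funnel["de_vs_nt"] >= funnel["after_subtraction"] >= funnel["after_ptc_filter"]

    def test_gene_de_in_a_differentiated_subtype_is_excluded(self):
        calls = self.atc_calls({"a"}, {"a"}, {"a"}, ["a"])
        final, _ = classify_atc(calls, differentiated_union={"a"})
        assert final == set()

    def test_both_ptc_contrasts_required(self):
        calls = self.atc_calls({"a"}, {"a"}, set(), ["a"])
        final, _ = classify_atc(calls, differentiated_union=set())
        assert final == set()

    def test_output_disjoint_from_differentiated_categories(self):
        genes = ["a", "b"]
        calls = self.atc_calls({"a", "b"}, {"a", "b"}, {"a", "b"}, genes)
        final, _ = classify_atc(calls, differentiated_union={"b"})
        diff_assign = pd.DataFrame(
            {"category": ["specific_clPTC"], "criteria_trace": [""]},
            index=pd.Index(["b"], name="gene_id"),
        )
        merged = assemble_assignments(diff_assign, final, genes)
        assert merged.loc["a", "category"] == "specific_ATC"
        assert merged.loc["b", "category"] == "specific_clPTC"


class TestReport:
    def test_counts_and_lfc_ordering(self):
        genes = ["a", "b", "c"]
        assign = pd.DataFrame(
            {"category": ["specific_clPTC", "specific_clPTC", "none"]},
            index=pd.Index(genes, name="gene_id"),
        )
        de_map = {
            ("rnaseqA", contrast_name("clPTC", "NT")): {"a", "b"},
        }
        calls = build_calls(de_map, all_genes=genes)
        # override log2fc so that b has the larger effect
        calls.tables[("rnaseqA", contrast_name("clPTC", "NT"))]["log2fc"] = [1.0, -3.0, 0.0]
        counts, lists = intersection_report(assign, calls)
        table = counts.set_index("category")["n_genes"]
        assert table["specific_clPTC"] == 2
        assert table.drop("specific_clPTC").sum() == 0
        assert lists["specific_clPTC"] == ["b", "a"]

    def test_empty_assignments_give_zero_counts(self):
        assign = pd.DataFrame(
            {"category": []}, index=pd.Index([], name="gene_id")
        )
        counts, lists = intersection_report(assign, build_calls({}))
        assert (counts["n_genes"] == 0).all()
        assert all(not v for v in lists.values())


def test_validation_table_shape():
    calls = build_calls(
        {
            ("rnaseqA", contrast_name("clPTC", "NT")): {"g0"},
            ("rnaseqB", contrast_name("clPTC", "NT")): {"g0"},
            ("array", contrast_name("clPTC", "NT")): {"g0"},
        }
    )
    tab = validation_table(["g0"], calls)
    assert tab.loc["g0", "clPTC"] and not tab.loc["g0", "fvPTC"]
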