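"""Key-position catalog integrity and the binder-classification rule engine."""

import dataclasses
import json

import pytest

from bitterevo.binding import (KeyPositionCatalog, chemically_similar,
                               classify_binder, conserved_count, load_catalog,
                               species_residue_map)


class TestCatalog:
    def test_mode_entry_counts(self, catalog):
        assert len(catalog.for_mode("R10")) == 12
        assert len(catalog.for_mode("R46")) == 15

    def test_distinct_and_shared_positions(self, catalog):
        labels_r10 = {e.bw_label for e in catalog.for_mode("R10")}
        labels_r46 = {e.bw_label for e in catalog.for_mode("R46")}
        assert len(labels_r10 | labels_r46) == 20
        assert len(labels_r10 & labels_r46) == 7

    def test_corrupted_catalog_rejected(self, catalog, tmp_path):
        entries = [dataclasses.asdict(e) for e in catalog.entries][:-1]  # drop one
        raw = {"entries": [
            {"bw": e["bw_label"], "mode": e["mode"], "key": e["key_residue"],
             "criticality": e["criticality"],
             "rules": [{"sub": r["substitution_class"], "effect": r["effect"]}
                       for r in e["effect_rules"]]}
            for e in entries]}
        p = tmp_path / "bad.json"
        p.write_text(json.dumps(raw))
        with pytest.raises(ValueError, match="counts"):
            load_catalog(p)


class TestChemicalSimilarity:
    @pytest.mark.parametrize("a,b", [("V", "I"), ("M", "I"), ("T", "S"), ("L", "F")])
    def test_similar_pairs(self, a, b):
        assert chemically_similar(a, b)

    @pytest.mark.parametrize("a,b", [("Q", "H"), ("E", "V"), ("K", "N"), ("E", "M")])
    def test_dissimilar_pairs(self, a, b):
        assert not chemically_similar(a, b)


class TestConservedCount:
    def test_common_ancestor_conserves_eleven_of_twenty(self, catalog, table1):
        n, total, _ = conserved_count(table1["N2"], catalog, mode="both")
        assert (n, total) == (11, 20)

    def test_recent_t2r10_ancestors_fully_conserved(self, catalog, table1):
        for node in ("N94", "N93", "N83", "N82"):
            n, total, _ = conserved_count(table1[node], catalog, mode="R10")
            assert (n, total) == (12, 12)

    def test_self_identity(self, catalog, table1):
        assert conserved_count(table1["hT2R10"], catalog, "R10")[:2] == (12, 12)
        assert conserved_count(table1["hT2R46"], catalog, "R46")[:2] == (15, 15)

    def test_n34_primary_predictions(self, catalog, table1):
        n, total, details = conserved_count(table1["N34"], catalog, mode="R46")
        assert (n, total) == (14, 15)
        assert details[0]["bw_label"] == "7.42"

    def test_n24_two_chemically_differing_positions(self, catalog, table1):
        n, total, details = conserved_count(table1["N24"], catalog, mode="R46")
        assert total - n == 2
        assert {d["bw_label"] for d in details} == {"2.65", "7.39"}
        assert all(not d["chemically_similar"] for d in details)

    def test_missing_label_reported(self, catalog, table1):
        residues = dict(table1["N2"])
        residues.pop("7.39")
        with pytest.raises(KeyError, match="7.39"):
            conserved_count(residues, catalog, mode="both")


class TestVerdictRegression:
    """Every per-taxon / per-node verdict stated in the published analysis."""

    def test_human_receptors_are_binders(self, catalog, table1):
        for receptor in ("hT2R10", "hT2R46"):
            assert classify_binder(table1[receptor], catalog).verdict == "binder"

    @pytest.mark.parametrize("node,expected", [
        ("N94", "binder"), ("N93", "binder"), ("N83", "binder"), ("N82", "binder"),
        ("N81", "uncertain"), ("N80", "non_binder"),
        ("N34", "reduced_binder"), ("N24", "reduced_binder"),
        ("N23", "reduced_binder"), ("N2", "non_binder"),
    ])
    def test_ancestor_verdicts(self, catalog, table1, node, expected):
        assert classify_binder(table1[node], catalog).verdict == expected

    def test_fourteen_species_with_identical_keys_are_binders(
            self, catalog, table1, species_variants):
        binders = [s for s, info in species_variants.items()
                   if info["mode"] == "R10" and not info["variations"]]
        assert len(binders) == 14
        for sp in binders:
            res = species_residue_map(sp, catalog, table1, species_variants)
            assert classify_binder(res, catalog).verdict == "binder"

    @pytest.mark.parametrize("species,expected", [
        ("Ssc_T2R10", "non_binder"),    # pig: Q93H + K174S
        ("Bta_T2R10", "non_binder"),    # cow: V89I + L178F
        ("Oar_T2R10", "non_binder"),    # sheep: V89I, Q175H, M263I, T266R
        ("Cja_T2R10", "uncertain"),     # marmoset: chemically similar variants
        ("Ggo_T2R46", "reduced_binder"),  # gorilla: N92S
        ("Ppa_T2R46", "reduced_binder"),  # bonobo: E253K
    ])
    def test_variant_species_verdicts(self, catalog, table1, species_variants,
                                      species, expected):
        res = species_residue_map(species, catalog, table1, species_variants)
        assert classify_binder(res, catalog).verdict == expected

    def test_mode_verdicts_ordering_invariant(self, catalog, table1):
        call = classify_binder(table1["N94"], catalog)
        assert call.verdict == max(call.mode_verdicts.values(),
                                   key=["non_binder", "uncertain",
                                        "reduced_binder", "binder"].index)


class TestEngineProperties:
    def test_determinism(self, catalog, table1):
        first = classify_binder(table1["N24"], catalog)
        second = classify_binder(dict(table1["N24"]), catalog)
        assert first.verdict == second.verdict
        assert first.mode_verdicts == second.mode_verdicts

    def test_abolishing_substitution_never_improves_verdict(self, catalog, table1):
        order = ["non_binder", "uncertain", "reduced_binder", "binder"]
        base = classify_binder(table1["hT2R46"], catalog)
        abolishing = {"7.39": "K", "7.42": "R", "7.43": "N"}
        for label, bad in abolishing.items():
            res = dict(table1["hT2R46"])
            res[label] = bad
            worse = classify_binder(res, catalog)
            assert order.index(worse.verdict) <= order.index(base.verdict)
            assert worse.mode_verdicts["R46"] == "non_binder"

    def test_tie_including_key_residue_softens_to_reduced(self, catalog, table1):
        # an unambiguous A268R abolishes; the tied prediction "R/A" does not
        res = dict(table1["hT2R46"])
        res["7.42"] = "R"
        assert classify_binder(res, catalog).mode_verdicts["R46"] == "non_binder"
        res["7.42"] = "R/A"
        assert classify_binder(res, catalog).mode_verdicts["R46"] != "non_binder"

    def test_evidence_lists_each_mismatch(self, catalog, table1):
        call = classify_binder(table1["N24"], catalog)
        r46_evidence = {e["bw_label"] for e in call.evidence if e["mode"] == "R46"}
        assert {"2.65", "7.39"} <= r46_evidence
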