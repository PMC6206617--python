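"""Dictionary loading and multi-label pattern annotation."""

import pytest

from invivoannot import (
    AssayRecord,
    CorpusSpec,
    DictionaryError,
    annotate_corpus,
    annotate_description,
    generate_corpus,
    identify_corpus,
    load_dictionary,
)


def entry_row(**overrides):
    row = dict(
        assay_class_id="AC_X",
        level1="Nervous System",
        level2="Group",
        level3="Model",
        source="Hock_2016",
        patterns=r"[Tt]est",
    )
    row.update(overrides)
    return row


class TestLoadDictionary:
    def test_seed_dictionary_loads_cleanly(self, seed_dict):
        assert len(seed_dict) >= 27
        assert all(e.compiled for e in seed_dict)
        # every class printed in the published mapping examples is present
        level3 = {e.level3 for e in seed_dict}
        for name in [
            "Radiant Heat Method",
            "Paw Edema Test",
            "Writhing Test for Analgesic Activity",
            "Experimental Colitis Inflammatory Gut Disease",
            "Carbon tetrachloride CCl4 Induced Liver Fibrosis in Rats",
            "L1210 Experimental Leukemia",
            "Lewis Lung Carcinoma",
        ]:
            assert name in level3

    def test_invalid_regex_names_class_and_pattern(self):
        with pytest.raises(DictionaryError, match=r"AC_X.*\(\[Tt\]ail"):
            load_dictionary([entry_row(patterns="([Tt]ail")])

    def test_duplicate_class_id_rejected(self):
        rows = [entry_row(assay_class_id="AC_001"),
                entry_row(assay_class_id="AC_001")]
        with pytest.raises(DictionaryError, match="duplicate"):
            load_dictionary(rows)

    @pytest.mark.parametrize("level", ["level1", "level2", "level3"])
    def test_empty_heading_rejected(self, level):
        with pytest.raises(DictionaryError, match=level):
            load_dictionary([entry_row(**{level: ""})])

    def test_unknown_source_rejected(self):
        with pytest.raises(DictionaryError, match="source"):
            load_dictionary([entry_row(source="Goodman_1990")])

    def test_phenotype_source_capitalisation_tolerated(self):
        d = load_dictionary([entry_row(source="Phenotype")])
        assert d["AC_X"].is_phenotype

    def test_ignore_case_flag(self):
        d = load_dictionary([entry_row(patterns="tail flick",
                                       pattern_flags="i")])
        assert annotate_description("TAIL FLICK latency", d)


class TestAnnotateDescription:
    def test_tail_flick_variants_fire_the_printed_pattern(self, seed_dict):
        for text in [
            "Analgesic activity in tail flick test, oral administration",
            "Compound was administered subcutaneously and was evaluated for"
            " opioid antagonist activity (versus morphine) by tail-flick"
            " (TF) antagonism test",
        ]:
            hits = {h.assay_class_id for h in
                    annotate_description(text, seed_dict)}
            assert "AC_RADIANT_HEAT" in hits

    def test_matched_text_is_description_substring(self, seed_dict):
        text = "Antioxidant activity against CCl4-induced hepatic injury model"
        for hit in annotate_description(text, seed_dict):
            assert hit.matched_text in text

    def test_no_model_phrase_yields_empty(self, seed_dict):
        text = ("Compound was evaluated for the time from injection to peak"
                " inhibition of the twitch response at 0.4 mg/kg dose")
        assert annotate_description(text, seed_dict) == []

    def test_empty_description_yields_empty(self, seed_dict):
        assert annotate_description("", seed_dict) == []

    def test_one_hit_per_entry_first_pattern_wins(self):
        d = load_dictionary(
            [entry_row(patterns="alpha|beta", assay_class_id="AC_M")]
        )
        hits = annotate_description("beta then alpha then beta", d)
        assert len(hits) == 1
        assert hits[0].pattern_index == 0
        assert hits[0].matched_text == "alpha"


class TestAnnotateCorpus:
    def test_worked_example_key_distribution(self, worked_example_table):
        """The published ten-description example: 2 model-only, 2
        phenotype-only, 4 both, 2 unannotated."""
        summaries = worked_example_table.summaries
        model_only = [s for s in summaries
                      if s.has_model_annotation and not s.has_phenotype_annotation]
        phen_only = [s for s in summaries
                     if s.has_phenotype_annotation and not s.has_model_annotation]
        both = [s for s in summaries
                if s.has_model_annotation and s.has_phenotype_annotation]
        unannotated = [s for s in summaries if not s.annotated]
        assert len(model_only) == 2
        assert len(phen_only) == 2
        assert len(both) == 4
        assert len(unannotated) == 2
        assert {s.assay_id for s in unannotated} == {
            "CHEMBL785102", "CHEMBL732935"
        }

    def test_annotated_flag_is_model_or_phenotype(self, worked_example_table):
        for s in worked_example_table.summaries:
            assert s.annotated == (
                s.has_model_annotation or s.has_phenotype_annotation
            )

    def test_deterministic_and_idempotent(self, worked_example_records,
                                          seed_dict):
        accepted, _ = identify_corpus(worked_example_records)
        t1 = annotate_corpus(accepted, seed_dict)
        t2 = annotate_corpus(accepted, seed_dict)
        assert t1.hits == t2.hits
        assert t1.summaries == t2.summaries

    def test_hits_sorted_for_reproducible_output(self, worked_example_table):
        keys = [(h.assay_id, h.assay_class_id)
                for h in worked_example_table.hits]
        assert keys == sorted(keys)

    def test_matches_bruteforce_scan_on_synthetic_corpus(self, seed_dict):
        """Oracle: apply every pattern of every entry to every description."""
        records, _ = generate_corpus(CorpusSpec(n_assays=300, seed=42))
        accepted, _ = identify_corpus(records)
        table = annotate_corpus(accepted, seed_dict)
        got = {(h.assay_id, h.assay_class_id) for h in table.hits}
        expected = {
            (record.assay_id, entry.assay_class_id)
            for record in accepted
            for entry in seed_dict
            if any(p.search(record.description) for p in entry.compiled)
        }
        assert got == expected

    def test_monotonicity_under_dictionary_growth(self, seed_dict):
        """Adding an entry never removes hits; removing never adds."""
        from invivoannot.dictionary import CompiledDictionary

        records = [
            AssayRecord("A1", "Analgesic activity in tail flick test"),
            AssayRecord("A2", "Writhing test after acetic acid challenge"),
        ]
        full = annotate_corpus(records, seed_dict)
        smaller = CompiledDictionary(list(seed_dict)[:10])
        partial = annotate_corpus(records, smaller)
        full_pairs = {(h.assay_id, h.assay_class_id) for h in full.hits}
        partial_pairs = {(h.assay_id, h.assay_class_id) for h in partial.hits}
        assert partial_pairs <= full_pairs
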