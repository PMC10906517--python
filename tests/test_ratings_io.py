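import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from gppca import (
    ConceptLexicon,
    RatingRecord,
    align_panels,
    average_panel,
    read_long_table,
    scale_unit_interval,
)
from gppca.ratings_io import RatingsPanel, read_wide, write_panel


def _write(tmp_path, name, text):
    path = tmp_path / name
    path.write_text(text)
    return path


class TestLexicon:
    def test_resolves_canonical_and_translated_labels(self, lexicon):
        assert lexicon.resolve("joy", "US") == "joy"
        assert lexicon.resolve("Desta", "ET") == "joy"

    def test_normalizes_whitespace_and_case(self, lexicon):
        assert lexicon.resolve("  Joy ", "US") == "joy"
        assert lexicon.resolve("FIRHAT", "ET") == "fear"

    def test_unknown_label_raises(self, lexicon):
        with pytest.raises(KeyError):
            lexicon.resolve("bliss", "US")

    def test_tsv_round_trip(self, lexicon, tmp_path):
        path = tmp_path / "lex.tsv"
        lexicon.to_tsv(path)
        back = ConceptLexicon.from_tsv(path)
        assert back.keys == lexicon.keys
        assert back.resolve("Desta", "ET") == "joy"

    def test_duplicate_keys_rejected(self):
        with pytest.raises(ValueError):
            ConceptLexicon(keys=("joy", "joy"))


class TestReadLongTable:
    HEADER = "stimulus_id,dataset,rater_id,concept,intensity\n"

    def test_toy_file_identity_read(self, tmp_path, lexicon):
        rows = [
            f"s{i},US,r1,{c},{v}"
            for i, (c, v) in enumerate(
                [("joy", 10), ("fear", 20), ("awe", 30)] * 2
            )
        ]
        path = _write(tmp_path, "t.csv", self.HEADER + "\n".join(rows))
        records = read_long_table(path, lexicon)
        assert len(records) == 6
        assert records[0] == RatingRecord("s0", "US", "r1", "joy", 10.0)

    def test_out_of_range_intensity_names_row(self, tmp_path, lexicon):
        path = _write(
            tmp_path, "t.csv", self.HEADER + "s1,US,r1,joy,50\ns2,US,r1,joy,120\n"
        )
        with pytest.raises(ValueError, match="row 3"):
            read_long_table(path, lexicon)

    def test_trailing_space_concept_matches_via_normalization(
        self, tmp_path, lexicon
    ):
        path = _write(tmp_path, "t.csv", self.HEADER + "s1,US,r1,Joy ,50\n")
        assert read_long_table(path, lexicon)[0].concept == "joy"

    def test_unknown_concept_names_row(self, tmp_path, lexicon):
        path = _write(tmp_path, "t.csv", self.HEADER + "s1,US,r1,bliss,50\n")
        with pytest.raises(ValueError, match="row 2"):
            read_long_table(path, lexicon)


class TestAveragePanel:
    def test_mean_of_two_ratings(self, lexicon):
        records = [
            RatingRecord("s1", "US", "r1", "joy", 50),
            RatingRecord("s1", "US", "r2", "joy", 100),
        ]
        panel = average_panel(records, lexicon)
        assert panel.values["US"][0, 0] == 75.0

    def test_unrated_concepts_count_as_zero(self, lexicon):
        # one rater selected only joy=80 among 3 concepts
        records = [RatingRecord("s1", "US", "r1", "joy", 80)]
        panel = average_panel(records, lexicon, unrated_as_zero=True)
        np.testing.assert_array_equal(panel.values["US"][0], [80.0, 0.0, 0.0])

    def test_zero_fill_denominator_is_rater_count(self, lexicon):
        # two raters; only one selected fear -> fear cell averages over both
        records = [
            RatingRecord("s1", "US", "r1", "joy", 80),
            RatingRecord("s1", "US", "r2", "joy", 40),
            RatingRecord("s1", "US", "r2", "fear", 60),
        ]
        panel = average_panel(records, lexicon, unrated_as_zero=True)
        np.testing.assert_allclose(panel.values["US"][0], [60.0, 30.0, 0.0])

    def test_rater_pooling_into_single_mean(self, lexicon):
        # self-report and perceiver records of one stimulus pool together
        records = [
            RatingRecord("s1", "US", "self", "joy", 90),
            RatingRecord("s1", "US", "p1", "joy", 30),
            RatingRecord("s1", "US", "p2", "joy", 60),
        ]
        panel = average_panel(records, lexicon)
        assert panel.values["US"][0, 0] == 60.0

    def test_empty_group_errors_without_zero_fill(self, lexicon):
        records = [RatingRecord("s1", "US", "r1", "joy", 50)]
        with pytest.raises(ValueError, match="s2"):
            average_panel(
                records, lexicon, stimuli=["s1", "s2"], unrated_as_zero=False
            )

    @given(perm_seed=st.integers(0, 2**31 - 1))
    @settings(max_examples=20, deadline=None)
    def test_record_order_invariance(self, perm_seed):
        lex = ConceptLexicon.identity(["a", "b"])
        records = [
            RatingRecord(f"s{i}", "US", f"r{j}", c, float(10 * i + j))
            for i in range(3)
            for j in range(3)
            for c in ("a", "b")
        ]
        shuffled = list(records)
        np.random.default_rng(perm_seed).shuffle(shuffled)
        p1 = average_panel(records, lex)
        p2 = average_panel(shuffled, lex)
        np.testing.assert_array_equal(p1.values["US"], p2.values["US"])


class TestScaleUnitInterval:
    def test_min_max_column(self):
        panel = RatingsPanel(
            stimuli=["a", "b", "c"], datasets=["d"], concepts=["x"],
            values={"d": np.array([[10.0], [20.0], [30.0]])},
        )
        scaled = scale_unit_interval(panel)
        np.testing.assert_allclose(scaled.values["d"][:, 0], [0.0, 0.5, 1.0])
        assert scaled.scaled

    def test_constant_column_zeroed_and_flagged(self):
        panel = RatingsPanel(
            stimuli=["a", "b", "c"], datasets=["d"], concepts=["x", "y"],
            values={"d": np.array([[5.0, 1], [5.0, 2], [5.0, 3]])},
        )
        scaled = scale_unit_interval(panel)
        np.testing.assert_array_equal(scaled.values["d"][:, 0], 0.0)
        np.testing.assert_array_equal(scaled.constant_columns["d"], [True, False])

    def test_scaling_is_per_dataset(self, rng):
        # the same concept is scaled by different ranges in each dataset
        panel = RatingsPanel(
            stimuli=list("abc"), datasets=["d1", "d2"], concepts=["x"],
            values={"d1": np.array([[0.0], [1], [2]]),
                    "d2": np.array([[0.0], [5], [10]])},
        )
        scaled = scale_unit_interval(panel)
        np.testing.assert_allclose(scaled.values["d1"], scaled.values["d2"])

    def test_idempotent(self, rng):
        panel = RatingsPanel(
            stimuli=[f"s{i}" for i in range(5)], datasets=["d"],
            concepts=["x", "y"], values={"d": rng.random((5, 2))},
        )
        once = scale_unit_interval(panel)
        twice = scale_unit_interval(once)
        np.testing.assert_allclose(
            once.values["d"], twice.values["d"], atol=1e-12
        )


class TestAlignPanels:
    def _panel(self, ids, dataset, rng):
        return RatingsPanel(
            stimuli=list(ids), datasets=[dataset], concepts=["x", "y"],
            values={dataset: rng.random((len(ids), 2))},
        )

    def test_too_few_shared_stimuli(self, rng):
        p1 = self._panel(["s1", "s2", "s3"], "a", rng)
        p2 = self._panel(["s2", "s3", "s4"], "b", rng)
        with pytest.raises(ValueError, match="shared stimuli"):
            align_panels(p1, p2)

    def test_order_canonicalized(self, rng):
        p1 = self._panel(["s1", "s2", "s3"], "a", rng)
        p2 = self._panel(["s3", "s1", "s2"], "b", rng)
        merged = align_panels(p1, p2)
        assert merged.stimuli == ["s1", "s2", "s3"]
        np.testing.assert_array_equal(
            merged.values["b"], p2.values["b"][[1, 2, 0]]
        )

    def test_idempotent(self, rng):
        p1 = self._panel(["s1", "s2", "s3", "s4"], "a", rng)
        p2 = self._panel(["s2", "s3", "s4", "s5"], "b", rng)
        once = align_panels(p1, p2)
        twice = align_panels(once)
        assert twice.stimuli == once.stimuli
        np.testing.assert_array_equal(twice.values["a"], once.values["a"])

    def test_duplicate_dataset_label_rejected(self, rng):
        p1 = self._panel(["s1", "s2", "s3"], "a", rng)
        p2 = self._panel(["s1", "s2", "s3"], "a", rng)
        with pytest.raises(ValueError, match="duplicate dataset"):
            align_panels(p1, p2)


def test_wide_round_trip(tmp_path, rng):
    panel = RatingsPanel(
        stimuli=["s1", "s2", "s3"], datasets=["US"], concepts=["joy", "fear"],
        values={"US": rng.random((3, 2))},
    )
    write_panel(panel, tmp_path)
    back = read_wide(tmp_path / "US.tsv", dataset="US")
    assert back.stimuli == panel.stimuli
    assert back.concepts == panel.concepts
    np.testing.assert_allclose(back.values["US"], panel.values["US"])
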