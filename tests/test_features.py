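"""Lexical similarity metrics, the candidate-pair filter, and feature vectors.

Each metric is checked against an independent brute-force oracle:
recursive matching-blocks for Ratcliff/Obershelp, dynamic-programming
edit distance for Levenshtein, explicit count-vector arithmetic for
cosine.
"""
import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from clinsts.core import SentencePair
from clinsts.features import (candidate_pair_filter, cosine_similarity,
                              extract_medications, levenshtein_similarity,
                              mean_lexical_similarity, medication_features,
                              phrasal_similarity_features, ratcliff_obershelp)

WORDS = st.text(alphabet="abcdxyz ", max_size=20)

# the first sample pair of the clinical similarity dataset's printed examples
PAIR1_A = "The patient was taken to the PACU in a stable condition."
PAIR1_B = ("The patient was taken to the post anesthesia care unit "
           "postoperatively for recovery.")


# -- independent oracles -------------------------------------------------------

def _ro_matches(a: str, b: str) -> int:
    """Recursive longest-common-substring total match count."""
    best_len, best = 0, (0, 0)
    for i in range(len(a)):
        for j in range(len(b)):
            k = 0
            while i + k < len(a) and j + k < len(b) and a[i + k] == b[j + k]:
                k += 1
            if k > best_len:
                best_len, best = k, (i, j)
    if best_len == 0:
        return 0
    i, j = best
    return (best_len + _ro_matches(a[:i], b[:j])
            + _ro_matches(a[i + best_len:], b[j + best_len:]))


def _dp_levenshtein(a: str, b: str) -> int:
    prev = list(range(len(b) + 1))
    for i, ca in enumerate(a, 1):
        cur = [i]
        for j, cb in enumerate(b, 1):
            cur.append(min(prev[j] + 1, cur[j - 1] + 1,
                           prev[j - 1] + (ca != cb)))
        prev = cur
    return prev[-1]


class TestLexicalMetrics:
    @pytest.mark.parametrize("metric", [ratcliff_obershelp,
                                        levenshtein_similarity,
                                        cosine_similarity])
    def test_identity_and_bounds(self, metric):
        assert metric("clinical note", "clinical note") == pytest.approx(1.0)
        assert 0.0 <= metric("abc xy", "qrs tu") <= 1.0

    @settings(derandomize=True, max_examples=50)
    @given(WORDS, WORDS)
    def test_symmetry(self, a, b):
        for metric in (ratcliff_obershelp, levenshtein_similarity,
                       cosine_similarity):
            assert metric(a, b) == pytest.approx(metric(b, a))

    def test_ratcliff_examples(self):
        assert ratcliff_obershelp("abc", "xyz") == 0.0
        # blocks: "bcd" matches, M=3, 2*3/(4+4)
        assert ratcliff_obershelp("abcd", "bcda") == pytest.approx(0.75)

    @settings(derandomize=True, max_examples=100)
    @given(st.text(alphabet="abcd", max_size=12), st.text(alphabet="abcd", max_size=12))
    def test_ratcliff_matches_recursive_oracle(self, a, b):
        if not a and not b:
            expected = 1.0
        else:
            # symmetrized: the larger of the two matching directions
            expected = 2.0 * max(_ro_matches(a, b), _ro_matches(b, a)) / (
                len(a) + len(b))
        assert ratcliff_obershelp(a, b) == pytest.approx(expected, abs=1e-12)

    def test_levenshtein_examples(self):
        assert levenshtein_similarity("kitten", "sitting") == pytest.approx(1 - 3 / 7)
        assert levenshtein_similarity("abc", "") == 0.0
        assert levenshtein_similarity("", "") == 1.0

    @settings(derandomize=True, max_examples=100)
    @given(st.text(alphabet="abcd", max_size=15), st.text(alphabet="abcd", max_size=15))
    def test_levenshtein_matches_dp_oracle(self, a, b):
        if not a and not b:
            expected = 1.0
        elif not a or not b:
            expected = 0.0
        else:
            expected = 1.0 - _dp_levenshtein(a, b) / max(len(a), len(b))
        assert levenshtein_similarity(a, b) == pytest.approx(expected, abs=1e-12)

    def test_cosine_examples(self):
        # "a b" vs "a c": dot=1, norms sqrt(2) each
        assert cosine_similarity("a b", "a c") == pytest.approx(0.5)
        assert cosine_similarity("alpha beta", "gamma delta") == 0.0
        assert cosine_similarity("", "anything") == 0.0


class TestCandidatePairFilter:
    def test_identical_pair_kept(self):
        pair = SentencePair("1", "same text", "same text")
        kept = candidate_pair_filter([pair])
        assert len(kept) == 1 and kept[0].lexical_mean == pytest.approx(1.0)

    def test_disjoint_pair_dropped(self):
        pair = SentencePair("1", "abc def", "xyz uvw qq")
        assert candidate_pair_filter([pair], threshold=0.45) == []

    def test_printed_sample_pair_passes(self):
        pair = SentencePair("t1-1", PAIR1_A, PAIR1_B)
        kept = candidate_pair_filter([pair], threshold=0.45)
        assert len(kept) == 1
        assert kept[0].lexical_mean >= 0.45
        assert kept[0].lexical_mean == pytest.approx(
            mean_lexical_similarity(PAIR1_A, PAIR1_B))

    def test_threshold_zero_keeps_everything(self):
        pairs = [SentencePair(str(i), "aa bb", t)
                 for i, t in enumerate(["aa bb", "zz", "qq ww"])]
        assert len(candidate_pair_filter(pairs, threshold=0.0)) == 3

    def test_threshold_outside_unit_interval_rejected(self):
        with pytest.raises(ValueError):
            candidate_pair_filter([], threshold=1.5)


LEXICON = ["aspirin", "albuterol", "ipratropium-albuterol", "metformin"]


class TestMedicationExtraction:
    def test_no_hits(self):
        assert extract_medications("no drugs here", LEXICON) == []

    def test_empty_lexicon_rejected(self):
        with pytest.raises(ValueError):
            extract_medications("text", [])

    def test_albuterol_inhalation(self):
        text = ("Albuterol [PROVENTIL/VENTOLIN] 90 mcg/Act HFA Aerosol 1-2 "
                "puffs by inhalation every 4 hours as needed.")
        mentions = extract_medications(text, ["albuterol"])
        assert len(mentions) == 1
        m = mentions[0]
        assert m.drug == "albuterol"
        assert m.route == "inhalation"
        assert m.strength == "90 mcg"
        assert m.dosage == "1-2 puffs"
        assert m.frequency == "every 4 hours"

    def test_aspirin_rule_trace(self):
        mentions = extract_medications("aspirin 81 mg by mouth daily", LEXICON)
        assert len(mentions) == 1
        m = mentions[0]
        assert (m.drug, m.strength, m.route, m.frequency) == (
            "aspirin", "81 mg", "mouth", "daily")
        assert m.dosage is None and m.duration is None

    def test_longest_match_first(self):
        mentions = extract_medications(
            "Ipratropium-Albuterol [COMBIVENT] 2 puffs", LEXICON)
        assert [m.drug for m in mentions] == ["ipratropium-albuterol"]


class TestFeatureVectors:
    def test_all_zero_without_medications(self):
        pair = SentencePair("1", "no meds", "none here either")
        feats = medication_features(pair, LEXICON)
        assert all(v == 0.0 for v in feats.values())

    def test_identity_medication_sentences(self):
        text = "aspirin 81 mg by mouth daily"
        feats = medication_features(SentencePair("1", text, text), LEXICON)
        assert feats["med_both_have"] == 1.0
        assert feats["med_name_jaccard"] == 1.0
        assert all(feats[k] == 1.0 for k in feats if k.endswith("agreement"))

    def test_partial_name_overlap(self):
        a = "Albuterol 90 mcg Aerosol 1-2 puffs by inhalation"
        b = "Ipratropium-Albuterol 18-103 mcg Aerosol 2 puffs by inhalation"
        feats = medication_features(SentencePair("1", a, b),
                                    ["albuterol", "ipratropium-albuterol"])
        assert feats["med_both_have"] == 1.0
        assert 0.0 < feats["med_name_jaccard"] < 1.0

    def test_phrasal_identity_maximal(self):
        pair = SentencePair("1", "a b c", "a b c")
        feats = phrasal_similarity_features(pair)
        assert all(v == pytest.approx(1.0) for v in feats.values())

    def test_phrasal_disjoint_zero_overlap(self):
        feats = phrasal_similarity_features(SentencePair("1", "aa bb", "cc dd"))
        assert feats["unigram_jaccard"] == 0.0
        assert feats["bigram_jaccard"] == 0.0

    def test_phrasal_unigram_example(self):
        feats = phrasal_similarity_features(SentencePair("1", "ab cd", "ab ce"))
        assert feats["unigram_jaccard"] == pytest.approx(1 / 3)

    def test_features_finite_and_name_aligned(self):
        from clinsts.features import featurize_pairs
        pairs = [SentencePair(str(i), f"aspirin {i} mg daily", "metformin oral")
                 for i in range(4)]
        table = featurize_pairs(pairs, LEXICON)
        assert np.isfinite(table.to_numpy(dtype=float)).all()
        assert list(table.index) == [p.id for p in pairs]
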