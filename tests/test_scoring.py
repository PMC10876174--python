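"""Classification rules: worked examples, oracle agreement, invariants."""

import itertools

import pytest

from acnscore.cohort import MitoticCount, ReticulinCategory
from acnscore.rules import DEFAULT_RULES
from acnscore.scoring import (MWCClass, RAClass, RAVariant, WCClass,
                              mwc_classify, mwc_microscopic_score, ra_classify,
                              score_panel, wieneke_class, wieneke_classify,
                              wieneke_score)

from conftest import make_case, random_case
from oracles import wieneke_score_by_enumeration

QN, QL, IT, BO = (ReticulinCategory.QUANTITATIVE, ReticulinCategory.QUALITATIVE,
                  ReticulinCategory.INTACT, ReticulinCategory.BOTH)


class TestWienekeScore:
    def test_all_negative_scores_zero(self):
        assert wieneke_score(make_case()) == 0

    def test_five_positive_criteria_score_five(self):
        case = make_case(necrosis=True, atypical=True, c20=20, c50=50,
                         vascular=True, capsular=True)
        assert wieneke_score(case) == 5

    def test_maximal_case_scores_nine(self):
        case = make_case(weight=3750, size=25, extra_adrenal=True,
                         vena_cava=True, vascular=True, capsular=True,
                         necrosis=True, c20=20, c50=50, atypical=True)
        assert wieneke_score(case) == 9

    def test_missing_criterion_gives_missing_score(self):
        case = make_case()
        case.weight_g = None
        assert wieneke_score(case) is None

    def test_class_decidable_despite_missing_items(self):
        """Four satisfied criteria force MALIGNANT whatever is missing."""
        case = make_case(necrosis=True, vascular=True, capsular=True,
                         atypical=True)
        case.weight_g = None
        assert wieneke_score(case) is None
        assert wieneke_class(case) is WCClass.MALIGNANT

    def test_class_undecidable_straddles_bands(self):
        case = make_case(necrosis=True, vascular=True)  # 2 true ...
        case.weight_g = None                            # ... 1 unknown
        assert wieneke_class(case) is None

    @pytest.mark.parametrize("score, expected", [
        (0, WCClass.BENIGN), (2, WCClass.BENIGN),
        (3, WCClass.INDETERMINATE),
        (4, WCClass.MALIGNANT), (9, WCClass.MALIGNANT),
    ])
    def test_class_bands(self, score, expected):
        assert wieneke_classify(score) is expected

    @pytest.mark.parametrize("score", [-1, 10])
    def test_out_of_range_score_rejected(self, score):
        with pytest.raises(ValueError):
            wieneke_classify(score)

    def test_agrees_with_independent_enumeration(self, rng):
        for i in range(300):
            case = random_case(rng, f"R-{i}")
            assert wieneke_score(case) == wieneke_score_by_enumeration(case)
            assert wieneke_classify(wieneke_score(case)) is wieneke_class(case)


class TestModifiedWieneke:
    def test_microscopic_score_counts_items(self):
        assert mwc_microscopic_score(make_case()) == 0
        assert mwc_microscopic_score(
            make_case(necrosis=True, vascular=True)) == 2
        assert mwc_microscopic_score(
            make_case(necrosis=True, vascular=True, capsular=True,
                      atypical=True, c20=20, c50=50)) == 5

    def test_missing_item_gives_missing_score(self):
        case = make_case()
        case.necrosis = None
        assert mwc_microscopic_score(case) is None

    def test_two_step_rule(self):
        assert mwc_classify(make_case()) is MWCClass.FAVORABLE
        assert mwc_classify(
            make_case(necrosis=True, vascular=True, capsular=True,
                      atypical=True, c20=20, c50=50)) is MWCClass.UNFAVORABLE
        borderline = make_case(necrosis=True, vascular=True, ki67=20.0)
        assert mwc_classify(borderline) is MWCClass.UNFAVORABLE
        borderline.ki67_percent = 10.0
        assert mwc_classify(borderline) is MWCClass.FAVORABLE

    def test_needed_ki67_missing_gives_missing_class(self):
        case = make_case(necrosis=True, vascular=True)
        case.ki67_percent = None
        assert mwc_classify(case) is None


class TestReticulinAlgorithm:
    def test_intact_framework_is_benign_despite_criteria(self):
        case = make_case(retic=IT, necrosis=True, c20=40, c50=100)
        assert ra_classify(case, RAVariant.ADULT) is RAClass.BENIGN
        assert ra_classify(case, RAVariant.PEDIATRIC) is RAClass.BENIGN

    def test_quantitative_alteration_plus_necrosis_is_malignant(self):
        case = make_case(retic=QN, necrosis=True)
        assert ra_classify(case, RAVariant.ADULT) is RAClass.MALIGNANT
        assert ra_classify(case, RAVariant.PEDIATRIC) is RAClass.MALIGNANT

    def test_cutoffs_separate_the_variants(self):
        """10/50 HPF exceeds the adult cutoff; 4/20 HPF not the pediatric."""
        case = make_case(retic=QL, c50=10, c20=4)
        assert ra_classify(case, RAVariant.ADULT) is RAClass.MALIGNANT
        assert ra_classify(case, RAVariant.PEDIATRIC) is RAClass.BENIGN

    def test_altered_without_criteria_is_benign(self):
        case = make_case(retic=QN, c50=2, c20=1)
        assert ra_classify(case, RAVariant.ADULT) is RAClass.BENIGN

    def test_missing_reticulin_gives_missing_class(self):
        case = make_case()
        case.reticulin = None
        assert ra_classify(case, RAVariant.ADULT) is None

    def test_intact_guarantee_exhaustive(self):
        """Intact reticulin forces benign over all binary-feature combos."""
        flags = ("necrosis", "vascular", "atypical", "capsular",
                 "extra_adrenal", "vena_cava")
        for combo in itertools.product([False, True], repeat=len(flags)):
            case = make_case(retic=IT, c50=100, c20=40,
                             **dict(zip(flags, combo)))
            assert ra_classify(case, RAVariant.ADULT) is RAClass.BENIGN
            assert ra_classify(case, RAVariant.PEDIATRIC) is RAClass.BENIGN

    def test_pediatric_malignant_implies_adult_malignant(self, rng):
        """Nesting on coherent cases (counts from one latent rate)."""
        for i in range(500):
            case = random_case(rng, f"N-{i}")
            if ra_classify(case, RAVariant.PEDIATRIC) is RAClass.MALIGNANT:
                assert ra_classify(case, RAVariant.ADULT) is RAClass.MALIGNANT


class TestMonotonicity:
    def test_raising_mitotic_count_never_moves_toward_benign(self, rng):
        order_wc = {WCClass.BENIGN: 0, WCClass.INDETERMINATE: 1,
                    WCClass.MALIGNANT: 2}
        order_mwc = {MWCClass.FAVORABLE: 0, MWCClass.UNFAVORABLE: 1}
        order_ra = {RAClass.BENIGN: 0, RAClass.MALIGNANT: 1}
        import copy
        for i in range(200):
            case = random_case(rng, f"M-{i}")
            bumped = copy.deepcopy(case)
            bumped.mitoses_per_20hpf = MitoticCount(
                case.mitoses_per_20hpf.count + int(rng.integers(1, 30)), 20)
            bumped.mitoses_per_50hpf = MitoticCount(
                case.mitoses_per_50hpf.count + int(rng.integers(1, 60)), 50)
            assert wieneke_score(bumped) >= wieneke_score(case)
            assert order_wc[wieneke_class(bumped)] >= order_wc[wieneke_class(case)]
            assert order_mwc[mwc_classify(bumped)] >= order_mwc[mwc_classify(case)]
            for variant in RAVariant:
                assert (order_ra[ra_classify(bumped, variant)]
                        >= order_ra[ra_classify(case, variant)])


class TestScorePanel:
    def test_fully_negative_case(self):
        panel = score_panel(make_case())
        assert panel.wc_score == 0
        assert panel.wc_class is WCClass.BENIGN
        assert panel.mwc_class is MWCClass.FAVORABLE
        assert panel.ara_class is RAClass.BENIGN
        assert panel.pra_class is RAClass.BENIGN

    def test_partial_evaluation(self):
        """Only reticulin-algorithm inputs present: RA classes set, WC missing."""
        case = make_case(retic=QN, necrosis=True)
        case.weight_g = None
        case.size_cm = None
        case.capsular_invasion = None
        panel = score_panel(case)
        assert panel.ara_class is RAClass.MALIGNANT
        assert panel.pra_class is RAClass.MALIGNANT
        assert panel.wc_score is None
        assert panel.mwc_microscopic_score is None
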