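from fractions import Fraction
from math import comb

import numpy as np
import pandas as pd
import pytest

from elegreet.gestures import (
    above_chance_test,
    attention_shares,
    classify_gestures,
    modality_deviation,
    tail_assessment,
    verdicts_to_frame,
)
from elegreet.records import to_frame

from conftest import make_signal


def binomial_tail_oracle(k, n, p=Fraction(1, 2)):
    """Exact rational upper-tail probability by direct enumeration."""
    p = Fraction(p)
    return float(
        sum(comb(n, i) * p**i * (1 - p) ** (n - i) for i in range(k, n + 1))
    )


class TestAboveChance:
    @pytest.mark.parametrize(
        "k,n,expected",
        [(10, 10, 1 / 1024), (0, 7, 1.0), (8, 10, 56 / 1024)],
    )
    def test_exact_tail_values(self, k, n, expected):
        assert above_chance_test(k, n) == pytest.approx(expected, rel=1e-12)

    @pytest.mark.parametrize("k,n", [(0, 5), (3, 9), (17, 20), (50, 60)])
    def test_matches_enumeration_oracle(self, k, n):
        assert above_chance_test(k, n) == pytest.approx(
            binomial_tail_oracle(k, n), rel=1e-12
        )

    def test_invalid_counts(self):
        with pytest.raises(ValueError):
            above_chance_test(5, 4)
        with pytest.raises(ValueError):
            above_chance_test(1, 0)


def typed_records(signal_type, modality, attend_yes, attend_no, check_yes=None,
                  check_no=0, articulator="ears"):
    """Build body acts with given recipient/signaller attention counts."""
    recs = []
    if check_yes is None:
        check_yes, check_no = attend_yes + attend_no, 0
    checks = ["yes"] * check_yes + ["no"] * check_no
    attends = ["yes"] * attend_yes + ["no"] * attend_no
    for i in range(max(len(checks), len(attends))):
        recs.append(
            make_signal(
                signal_type=signal_type,
                modality=modality,
                articulator=articulator,
                signaller_attending=checks[i % len(checks)],
                recipient_attending=attends[i % len(attends)],
                onset_s=float(i),
                offset_s=float(i) + 0.5,
            )
        )
    return recs


class TestClassifier:
    def test_attention_targeted_silent_visual_is_gesture(self):
        recs = typed_records("Ear-Spread", "silent_visual", 18, 2)
        v = classify_gestures(recs)["Ear-Spread"]
        assert v.checking_test.status == "pass"
        assert v.attending_test.status == "pass"
        assert v.verdict == "gesture"

    def test_tactile_exempt_from_both_tests(self):
        # signaller never checks, recipient never attends: still a gesture
        recs = typed_records(
            "Tail-Touch", "tactile", 0, 10, check_yes=0, check_no=10,
            articulator="tail",
        )
        v = classify_gestures(recs)["Tail-Touch"]
        assert v.checking_test.status == "exempt"
        assert v.attending_test.status == "exempt"
        assert v.verdict == "gesture"

    def test_audible_exempt_from_attending_only(self):
        recs = typed_records("Ear-Flapping", "audible", 5, 5)
        v = classify_gestures(recs)["Ear-Flapping"]
        assert v.attending_test.status == "exempt"
        assert v.checking_test.status == "pass"

    def test_chance_level_tail_type_rejected(self):
        # recipient attention at exactly chance rate: criterion 3 fails
        recs = typed_records(
            "Tail-Waggling", "olfactory_candidate", 10, 10, articulator="tail"
        )
        v = classify_gestures(recs)["Tail-Waggling"]
        assert v.attending_test.status == "fail"
        assert v.verdict == "not_gesture"

    def test_sparse_type_returns_insufficient_data(self):
        recs = typed_records("Rump-Present", "silent_visual", 2, 1)
        assert classify_gestures(recs)["Rump-Present"].verdict == "insufficient_data"

    def test_order_invariance(self):
        recs = typed_records("Ear-Spread", "silent_visual", 15, 5) + typed_records(
            "Tail-Waggling", "olfactory_candidate", 8, 8, articulator="tail"
        )
        forward = verdicts_to_frame(classify_gestures(recs))
        backward = verdicts_to_frame(classify_gestures(recs[::-1]))
        pd.testing.assert_frame_equal(forward, backward)

    def test_unknown_gaze_records_do_not_count_as_trials(self):
        recs = typed_records("Ear-Spread", "silent_visual", 12, 0)
        for i in range(6):
            recs.append(
                make_signal(
                    signal_type="Ear-Spread",
                    recipient_attending="unknown",
                    onset_s=100.0 + i,
                    offset_s=100.5 + i,
                )
            )
        v = classify_gestures(recs)["Ear-Spread"]
        assert v.attending_test.trials == 12


class TestDeviation:
    def test_reference_fixture_deviations(self, fixture_records):
        dev = modality_deviation(fixture_records).set_index(
            ["modality", "recipient_attending"]
        )
        assert dev.loc[("tactile", "yes"), "deviation_pct"] == pytest.approx(
            -31.2, abs=0.05
        )
        assert dev.loc[("silent_visual", "yes"), "deviation_pct"] == pytest.approx(
            2.7, abs=0.05
        )

    def test_hand_arithmetic_oracle(self, fixture_records):
        # tactile attending: (11/564)/(19/670) - 1; silent-visual: (344/564)/(398/670) - 1
        dev = modality_deviation(fixture_records).set_index(
            ["modality", "recipient_attending"]
        )
        assert dev.loc[("tactile", "yes"), "deviation_pct"] == pytest.approx(
            ((11 / 564) / (19 / 670) - 1) * 100, abs=1e-9
        )
        assert dev.loc[("silent_visual", "yes"), "deviation_pct"] == pytest.approx(
            ((344 / 564) / (398 / 670) - 1) * 100, abs=1e-9
        )

    def test_normalisation_identities(self, fixture_records):
        dev = modality_deviation(fixture_records)
        alphas = dev.drop_duplicates("modality")["alpha"]
        assert alphas.sum() == pytest.approx(1.0, abs=1e-12)
        for state, grp in dev.groupby("recipient_attending"):
            assert grp["beta"].sum() == pytest.approx(1.0, abs=1e-12)

    def test_weighted_mean_identity_and_opposite_signs(self, fixture_records):
        dev = modality_deviation(fixture_records)
        for modality, grp in dev.groupby("modality"):
            grp = grp.set_index("recipient_attending")
            w = grp["n_state"] / grp["n_state"].sum()
            assert (w * grp["beta"]).sum() == pytest.approx(
                grp["alpha"].iloc[0], abs=1e-12
            )
            d_yes, d_no = grp.loc["yes", "deviation_pct"], grp.loc["no", "deviation_pct"]
            assert d_yes * d_no <= 0

    def test_attention_independent_modalities_have_zero_deviation(self):
        recs = []
        for modality, n in (("silent_visual", 40), ("audible", 20)):
            recs += typed_records(f"T-{modality}", modality, n // 2, n // 2)
        dev = modality_deviation(recs)
        assert np.allclose(dev["deviation_pct"], 0.0, atol=1e-9)

    def test_attention_shares_on_fixture(self, fixture_records):
        shares = attention_shares(fixture_records).set_index("modality")
        assert shares.loc["silent_visual", "n"] == 398
        assert shares.loc["silent_visual", "n_attending"] == 344
        assert shares.loc["tactile", "share_attending"] == pytest.approx(11 / 19)


class TestTailAssessment:
    def tail_and_reference(self, tail_yes, tail_no, within_1m=False):
        tails = typed_records(
            "Tail-Waggling", "olfactory_candidate", tail_yes, tail_no,
            articulator="tail",
        )
        if within_1m:
            tails = [
                make_signal(
                    signal_type=r.signal_type, modality=r.modality,
                    articulator="tail", distance_m=0.5,
                    recipient_attending=r.recipient_attending,
                    onset_s=r.onset_s, offset_s=r.offset_s,
                )
                for r in tails
            ]
        refs = typed_records("Ear-Spread", "silent_visual", 30, 10)
        return tails + refs

    def test_attention_independent_tail_deviation_near_zero(self):
        # tail used at the same attending rate as the reference mix
        tails = typed_records(
            "Tail-Waggling", "olfactory_candidate", 30, 10, articulator="tail"
        )
        refs = typed_records("Ear-Spread", "silent_visual", 30, 10)
        res = tail_assessment(tails + refs, ["Tail-Waggling"])
        dev = res["deviation"].set_index("recipient_attending")
        assert dev["deviation_pct"].abs().max() == pytest.approx(0.0, abs=1e-9)

    def test_within_1m_share(self):
        recs = self.tail_and_reference(5, 5, within_1m=True)
        res = tail_assessment(recs, ["Tail-Waggling"])
        profile = res["distance_profile"].set_index("signal_type")
        assert profile.loc["Tail-Waggling", "share_within_1m"] == 1.0

    def test_response_coding(self):
        recs = self.tail_and_reference(4, 4)
        res = tail_assessment(recs, ["Tail-Waggling"])
        frame = res["model_frame"]
        assert set(frame["is_tail"]) == {0, 1}
        assert (
            frame.loc[frame["signal_type"] == "Ear-Spread", "is_tail"] == 0
        ).all()

    def test_no_tail_records_errors(self):
        refs = typed_records("Ear-Spread", "silent_visual", 5, 5)
        with pytest.raises(ValueError, match="tail"):
            tail_assessment(refs, ["Tail-Waggling"])
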