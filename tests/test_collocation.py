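from fractions import Fraction
from math import comb

import numpy as np
import pandas as pd
import pytest

from elegreet.collocation import (
    collocation_report,
    exact_binomial_tail,
    extract_bigrams,
    mdca,
)

from conftest import make_signal, make_vocal


def bigram_frame(*tokens):
    rows = [
        {"event_id": "e1", "first": a, "second": b, "vocal_first": True,
         "ordered_mode": True}
        for a, b in tokens
    ]
    return pd.DataFrame(rows)


def rational_tail(observed, trials, p: Fraction, upper: bool):
    """Exact rational binomial tail by full pmf enumeration."""
    rng = range(observed, trials + 1) if upper else range(0, observed + 1)
    return sum(
        comb(trials, i) * p**i * (1 - p) ** (trials - i) for i in rng
    )


class TestExtraction:
    def test_first_overlap_per_articulator_kept_only(self):
        recs = [
            make_vocal(onset_s=0.0, offset_s=4.0),
            make_signal(signal_type="Ear-Spread", onset_s=1.0, offset_s=2.0),
            make_signal(signal_type="Ears-Stiff", onset_s=2.0, offset_s=3.0),
        ]
        out = extract_bigrams(recs, "ordered_first_overlap")
        assert len(out) == 1
        assert (out.iloc[0]["first"], out.iloc[0]["second"]) == ("Rumble", "Ear-Spread")
        # order-free mode keeps both overlapping pairs
        both = extract_bigrams(recs, "all_cooccurring")
        assert len(both) == 2

    def test_different_articulators_both_kept(self):
        recs = [
            make_vocal(onset_s=0.0, offset_s=4.0),
            make_signal(signal_type="Ear-Spread", onset_s=1.0, offset_s=2.0),
            make_signal(
                signal_type="Trunk-Reach", articulator="trunk",
                onset_s=2.0, offset_s=3.0,
            ),
        ]
        out = extract_bigrams(recs, "ordered_first_overlap")
        assert set(out["second"]) == {"Ear-Spread", "Trunk-Reach"}

    def test_no_overlap_empty(self):
        recs = [
            make_vocal(onset_s=0.0, offset_s=1.0),
            make_signal(signal_type="Ear-Spread", onset_s=1.0, offset_s=2.0),
        ]
        assert extract_bigrams(recs, "ordered_first_overlap").empty

    def test_body_act_first_order(self):
        recs = [
            make_vocal(onset_s=2.0, offset_s=5.0),
            make_signal(signal_type="Ear-Flapping", modality="audible",
                        onset_s=0.0, offset_s=6.0),
        ]
        ordered = extract_bigrams(recs, "ordered_first_overlap")
        assert (ordered.iloc[0]["first"], ordered.iloc[0]["second"]) == (
            "Ear-Flapping", "Rumble",
        )
        assert not ordered.iloc[0]["vocal_first"]

    def test_cross_event_signals_never_pair(self):
        recs = [
            make_vocal(onset_s=0.0, offset_s=4.0, event_id="e1"),
            make_signal(signal_type="Ear-Spread", onset_s=1.0, offset_s=2.0,
                        event_id="e2"),
        ]
        assert extract_bigrams(recs).empty

    def test_negative_duration_rejected(self):
        import pandas as pd
        from elegreet.records import to_frame

        df = to_frame([make_vocal()])
        df.loc[0, "offset_s"] = -1.0
        with pytest.raises(ValueError, match="duration"):
            extract_bigrams(df)


class TestMDCA:
    def test_worked_corpus(self):
        table = bigram_frame(
            *([("A", "B")] * 8 + [("A", "C")] * 2 + [("D", "B")] * 2 + [("D", "C")] * 8)
        )
        res = mdca(table).set_index(["first", "second"])
        row = res.loc[("A", "B")]
        assert row["trials"] == 10
        assert row["expected_p"] == pytest.approx(0.5)
        assert row["observed"] == 8
        assert row["p_value"] == pytest.approx(56 / 1024, rel=1e-12)
        assert row["pbin"] == pytest.approx(-np.log10(56 / 1024), rel=1e-9)
        assert row["band"] == "ns"

    def test_single_repeated_bigram_degenerate(self):
        res = mdca(bigram_frame(*[("A", "B")] * 12))
        assert res.iloc[0]["expected_p"] == 1.0
        assert res.iloc[0]["p_value"] == 1.0
        assert res.iloc[0]["pbin"] == 0.0

    def test_repulsion_gets_negative_pbin(self):
        table = bigram_frame(
            *([("A", "B")] * 1 + [("A", "C")] * 19 + [("D", "B")] * 19 + [("D", "C")] * 1)
        )
        res = mdca(table).set_index(["first", "second"])
        assert res.loc[("A", "B"), "pbin"] < 0
        assert res.loc[("A", "C"), "pbin"] > 0

    def test_trials_partition_by_first_slot(self):
        rng = np.random.default_rng(0)
        toks = [
            (rng.choice(list("VWX")), rng.choice(list("bcde"))) for _ in range(200)
        ]
        table = bigram_frame(*toks)
        res = mdca(table)
        for first, grp in res.groupby("first"):
            assert grp["observed"].sum() == grp["trials"].iloc[0]

    @pytest.mark.parametrize("seed", [1, 2, 3])
    def test_pbin_matches_rational_enumeration(self, seed):
        """Signed pbin equals -log10 of the exact rational tail to 1e-9."""
        rng = np.random.default_rng(seed)
        toks = [
            (rng.choice(list("VW")), rng.choice(list("bcd"), p=[0.5, 0.3, 0.2]))
            for _ in range(300)
        ]
        table = bigram_frame(*toks)
        res = mdca(table)
        n_total = len(table)
        second_counts = table.groupby("second").size()
        for row in res.itertuples():
            p_frac = Fraction(int(second_counts[row.second]), n_total)
            upper = row.pbin >= 0
            oracle = float(rational_tail(row.observed, row.trials, p_frac, upper))
            want = 0.0 if oracle >= 1.0 else (1 if upper else -1) * -np.log10(oracle)
            assert row.pbin == pytest.approx(want, abs=1e-9)

    def test_doubling_counts_strengthens_attraction(self):
        table = bigram_frame(
            *([("A", "B")] * 9 + [("A", "C")] * 1 + [("D", "B")] * 1 + [("D", "C")] * 9)
        )
        res1 = mdca(table).set_index(["first", "second"])
        res2 = mdca(pd.concat([table, table], ignore_index=True)).set_index(
            ["first", "second"]
        )
        assert res2.loc[("A", "B"), "expected_p"] == res1.loc[("A", "B"), "expected_p"]
        assert res2.loc[("A", "B"), "pbin"] >= res1.loc[("A", "B"), "pbin"]

    def test_empty_table_errors(self):
        with pytest.raises(ValueError):
            mdca(pd.DataFrame(columns=["first", "second"]))

    def test_holm_option_weakens_bands(self):
        rng = np.random.default_rng(4)
        toks = [("V", rng.choice(list("bc"))) for _ in range(40)] + [
            ("W", rng.choice(list("bc"))) for _ in range(40)
        ]
        table = bigram_frame(*toks)
        raw = mdca(table)
        holm = mdca(table, holm=True)
        order = {"ns": 0, "p<.05": 1, "p<.01": 2, "p<.001": 3}
        assert all(
            order[h] <= order[r] for r, h in zip(raw["band"], holm["band"])
        )


class TestNullCalibration:
    def test_small_corpora_are_conservative(self):
        """Tiny tables with self-estimated margins flag well under 5%."""
        rng = np.random.default_rng(99)
        flagged = trials = 0
        for _ in range(300):
            toks = [
                (rng.choice(list("VW")), rng.choice(list("bc")))
                for _ in range(60)
            ]
            res = mdca(bigram_frame(*toks))
            flagged += int((res["pbin"].abs() > 1.30103).sum())
            trials += len(res)
        assert flagged / trials < 0.05

    def test_large_corpora_flag_about_five_percent(self):
        """With many types and long corpora the null rate settles near the
        nominal 5%."""
        rng = np.random.default_rng(98)
        firsts = [f"V{i}" for i in range(5)]
        seconds = [f"b{i}" for i in range(6)]
        flagged = trials = 0
        for _ in range(120):
            toks = pd.DataFrame(
                {
                    "event_id": "e",
                    "first": rng.choice(firsts, 1000),
                    "second": rng.choice(seconds, 1000),
                    "vocal_first": True,
                    "ordered_mode": True,
                }
            )
            res = mdca(toks)
            flagged += int((res["pbin"].abs() > 1.30103).sum())
            trials += len(res)
        assert 0.02 < flagged / trials < 0.09


class TestReport:
    def test_blank_cells_for_nonsignificant(self):
        strong = bigram_frame(
            *([("V", "b")] * 30 + [("V", "c")] * 2 + [("W", "b")] * 2 + [("W", "c")] * 30)
        )
        weak = bigram_frame(
            *([("V", "b")] * 9 + [("V", "c")] * 7 + [("W", "b")] * 7 + [("W", "c")] * 9)
        )
        rep = collocation_report(mdca(strong), mdca(weak))
        assert (rep["pbin_all"] == "").all()
        assert (rep["pbin_ordered"] != "").any()

    def test_exact_tail_direction(self):
        p, sign = exact_binomial_tail(8, 10, 0.5)
        assert sign == 1 and p == pytest.approx(56 / 1024)
        p, sign = exact_binomial_tail(2, 10, 0.5)
        assert sign == -1 and p == pytest.approx(56 / 1024)
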