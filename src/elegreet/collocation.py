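"""Collocation analysis of vocal-gestural combinations (MDCA).

Borrowed from corpus linguistics: treat each temporally overlapping
(vocalisation, body act) pair as a bigram token and ask which pairings
occur more (attraction) or less (repulsion) often than their slot
marginals predict.  Multiple Distinctive Collocation Analysis runs a
one-tailed exact binomial test per bigram type: for bigram (A, B), the
trials are all tokens with A in the first slot, the expected success
probability is B's share of the second slot across the whole corpus, and
the tail is taken in the direction of the deviation.  The headline score is
``pbin = -log10(p)``, signed positive for attraction and negative for
repulsion, with conventional significance bands at |pbin| > 1.30103, 2 and
3 (p < .05, .01, .001).

Two extraction modes match the two analysis questions.  The order-aware
mode (MDCA1) keeps, for each vocalisation, only the first overlapping body
act per articulator — successive same-articulator acts are not free to
start while the previous one runs, which would distort order statistics.
The order-free mode (MDCA2) keeps every overlapping pair.  In both modes
the bigram slots are filled in onset order, so the two orders of a pair are
distinct rows.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .records import as_frame

SIGNIFICANCE_BANDS = ((3.0, "p<.001"), (2.0, "p<.01"), (1.30103, "p<.05"))

BIGRAM_COLUMNS = ("event_id", "first", "second", "vocal_first", "ordered_mode")


def _band(pbin: float) -> str:
    mag = abs(pbin)
    for threshold, label in SIGNIFICANCE_BANDS:
        if mag > threshold:
            return label
    return "ns"


def extract_bigrams(records, mode: str = "ordered_first_overlap") -> pd.DataFrame:
    """Extract vocalisation/body-act bigrams from overlapping signals.

    ``mode="ordered_first_overlap"`` keeps only the first overlapping body
    act per articulator for each vocalisation; ``mode="all_cooccurring"``
    keeps every overlapping pair.  Slots are ordered by onset (ties go to
    the vocalisation).  Overlap is on half-open [onset, offset) intervals
    within the same event.  Records must have non-negative durations.
    """
    if mode not in ("ordered_first_overlap", "all_cooccurring"):
        raise ValueError(f"unknown mode {mode!r}")
    df = as_frame(records)
    if (df["offset_s"] < df["onset_s"]).any():
        bad = df.index[df["offset_s"] < df["onset_s"]][0]
        raise ValueError(f"negative duration at row {bad}")
    rows = []
    for event_id, ev in df.groupby("event_id", sort=True):
        vocs = ev[ev["category"] == "vocalisation"]
        acts = ev[ev["category"] == "body_act"]
        for voc in vocs.itertuples(index=False):
            overlapping = acts[
                (acts["onset_s"] < voc.offset_s) & (voc.onset_s < acts["offset_s"])
            ].sort_values(["onset_s", "offset_s"], kind="stable")
            if mode == "ordered_first_overlap":
                overlapping = overlapping.groupby("articulator", sort=False).head(1)
            for act in overlapping.itertuples(index=False):
                vocal_first = voc.onset_s <= act.onset_s
                first, second = (
                    (voc.signal_type, act.signal_type)
                    if vocal_first
                    else (act.signal_type, voc.signal_type)
                )
                rows.append(
                    {
                        "event_id": event_id,
                        "first": first,
                        "second": second,
                        "vocal_first": vocal_first,
                        "ordered_mode": mode == "ordered_first_overlap",
                    }
                )
    return pd.DataFrame(rows, columns=list(BIGRAM_COLUMNS))


@dataclass(frozen=True)
class CollocationResult:
    """Attraction/repulsion of one bigram type against its slot marginals."""

    first: str
    second: str
    observed: int
    trials: int
    expected_p: float
    p_value: float
    pbin: float
    band: str


def exact_binomial_tail(observed: int, trials: int, p: float) -> tuple[float, int]:
    """One-tailed exact binomial p in the direction of the deviation.

    Returns (p_value, sign): sign +1 for at-or-above expectation (upper
    tail), -1 for below (lower tail).  Ties on the expectation use the
    upper tail.
    """
    expected = trials * p
    if observed >= expected:
        return float(stats.binom.sf(observed - 1, trials, p)), 1
    return float(stats.binom.cdf(observed, trials, p)), -1


def mdca(bigrams: pd.DataFrame, holm: bool = False) -> pd.DataFrame:
    """Run the collocation analysis over a bigram table.

    One row per bigram type with observed count, first-slot trials,
    expected probability from the second-slot marginal, the one-tailed
    exact binomial p, the signed pbin and its significance band.  Sorted by
    descending pbin.  With ``holm`` the p-values are Holm-adjusted before
    banding (off by default: raw bands are the field convention here).
    """
    if len(bigrams) == 0:
        raise ValueError("empty bigram table")
    counts = bigrams.groupby(["first", "second"]).size()
    first_totals = bigrams.groupby("first").size()
    second_share = bigrams.groupby("second").size() / len(bigrams)
    results = []
    for (first, second), observed in counts.items():
        trials = int(first_totals[first])
        p_exp = float(second_share[second])
        p_val, sign = exact_binomial_tail(int(observed), trials, p_exp)
        pbin = 0.0 if p_val >= 1.0 else sign * -np.log10(max(p_val, 1e-300))
        results.append(
            {
                "first": first,
                "second": second,
                "observed": int(observed),
                "trials": trials,
                "expected_p": p_exp,
                "p_value": p_val,
                "pbin": pbin,
                "band": _band(pbin),
            }
        )
    out = pd.DataFrame(results).sort_values(
        "pbin", ascending=False, kind="stable"
    ).reset_index(drop=True)
    if holm:
        from statsmodels.stats.multitest import multipletests

        _, adj, _, _ = multipletests(out["p_value"], method="holm")
        out["p_holm"] = adj
        out["band"] = [
            _band(np.sign(pb) * -np.log10(max(p, 1e-300)) if p < 1 else 0.0)
            for pb, p in zip(out["pbin"], adj)
        ]
    return out


def collocation_report(
    results_ordered: pd.DataFrame, results_all: pd.DataFrame
) -> pd.DataFrame:
    """Merge the order-aware and order-free analyses into one report table.

    Keyed by (first, second); a pbin cell is blank when that bigram is not
    significant (band "ns") or absent in that analysis, mirroring the
    conventional presentation.
    """

    def significant(res, col):
        sig = res[res["band"] != "ns"][["first", "second", "pbin"]]
        return sig.rename(columns={"pbin": col})

    merged = significant(results_ordered, "pbin_ordered").merge(
        significant(results_all, "pbin_all"), on=["first", "second"], how="outer"
    )
    merged = merged.sort_values(["first", "second"], kind="stable").reset_index(
        drop=True
    )
    for col in ("pbin_ordered", "pbin_all"):
        merged[col] = merged[col].map(
            lambda v: "" if pd.isna(v) else f"{v:.3f}"
        )
    return merged
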