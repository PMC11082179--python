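"""Audience-directedness: are body acts gestures aimed at a watching recipient?

A body-act type counts as an audience-directed gesture when (1) it is used
socially, in the presence of a recipient; (2) the signaller visually checks
the recipient more often than chance when producing it — waived for tactile
types, which deliver their information through contact; and (3) for types
whose only channel is vision, the recipient is visually attending more
often than chance — waived for audible and tactile types, which a
non-watching recipient still perceives.  "Above chance" is an exact
one-tailed binomial test against a configurable chance level (default 0.5,
the neutral point of a binary attention state).

The percentage-deviation statistic quantifies active modality adjustment:
with ``alpha_m`` the share of modality *m* among all body acts and
``beta_m|s`` its share within attention state *s*, the deviation is
``(beta/alpha - 1) x 100`` — positive when a modality is over-used in that
state relative to its overall rate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import math

import numpy as np
import pandas as pd
from scipy import stats

from .records import as_frame

#: Modalities whose information requires a watching recipient; the
#: olfactory-candidate tail types are a-priori silent-visual, so the
#: recipient-attention criterion applies to them too.
VISUAL_ONLY_MODALITIES = ("silent_visual", "olfactory_candidate")

#: Distance bins (metres) for profiling where a body-act type is used.
DISTANCE_BINS = (0.0, 1.0, 3.0, 10.0, 100.0)


def above_chance_test(successes: int, trials: int, chance_p: float = 0.5) -> float:
    """Exact upper-tail binomial probability P(X >= successes | trials, p)."""
    if not (0 <= successes <= trials) or trials < 1:
        raise ValueError(f"invalid counts: {successes}/{trials}")
    if not (0.0 <= chance_p <= 1.0):
        raise ValueError("chance_p must be a probability")
    return float(stats.binom.sf(successes - 1, trials, chance_p))


@dataclass
class CriterionResult:
    successes: int = 0
    trials: int = 0
    p_value: float = float("nan")
    status: str = "not_run"  # pass | fail | exempt | insufficient_data


@dataclass
class GestureVerdict:
    """Per-type outcome of the three audience-directedness criteria."""

    signal_type: str
    modality: str
    n_records: int
    social_use: bool
    checking_test: CriterionResult = field(default_factory=CriterionResult)
    attending_test: CriterionResult = field(default_factory=CriterionResult)
    verdict: str = "insufficient_data"  # gesture | not_gesture | insufficient_data


def _run_criterion(outcomes: pd.Series, chance_p: float, alpha: float,
                   min_records: int) -> CriterionResult:
    known = outcomes[outcomes.isin(("yes", "no"))]
    res = CriterionResult(successes=int((known == "yes").sum()), trials=len(known))
    if res.trials < min_records:
        res.status = "insufficient_data"
        return res
    res.p_value = above_chance_test(res.successes, res.trials, chance_p)
    res.status = "pass" if res.p_value < alpha else "fail"
    return res


def classify_gestures(
    records,
    chance_p: float = 0.5,
    alpha: float = 0.05,
    min_records: int = 5,
) -> dict[str, GestureVerdict]:
    """Classify every body-act type in ``records`` against the three criteria.

    Trials for each binomial criterion count only productions where the
    relevant gaze state was codeable.  Types with fewer than ``min_records``
    usable trials on any applicable criterion return ``insufficient_data``
    (exact tests at trivial n cannot discriminate).  Order of records is
    irrelevant.
    """
    df = as_frame(records)
    body = df[df["category"] == "body_act"]
    verdicts: dict[str, GestureVerdict] = {}
    for sig_type, grp in body.groupby("signal_type", sort=True):
        modality = grp["modality"].iloc[0]
        v = GestureVerdict(
            signal_type=sig_type,
            modality=modality,
            n_records=len(grp),
            social_use=len(grp) > 0,
        )
        # criterion 2: signaller checks the recipient; tactile exempt
        if modality == "tactile":
            v.checking_test.status = "exempt"
        else:
            v.checking_test = _run_criterion(
                grp["signaller_attending"], chance_p, alpha, min_records
            )
        # criterion 3: recipient attending; audible and tactile exempt
        if modality in VISUAL_ONLY_MODALITIES:
            v.attending_test = _run_criterion(
                grp["recipient_attending"], chance_p, alpha, min_records
            )
        else:
            v.attending_test.status = "exempt"
        statuses = {v.checking_test.status, v.attending_test.status}
        if "insufficient_data" in statuses:
            v.verdict = "insufficient_data"
        elif "fail" in statuses or not v.social_use:
            v.verdict = "not_gesture"
        else:
            v.verdict = "gesture"
        verdicts[sig_type] = v
    return verdicts


def verdicts_to_frame(verdicts: dict[str, GestureVerdict]) -> pd.DataFrame:
    rows = []
    for v in verdicts.values():
        rows.append(
            {
                "signal_type": v.signal_type,
                "modality": v.modality,
                "n_records": v.n_records,
                "social_use": v.social_use,
                "checking_status": v.checking_test.status,
                "checking_p": v.checking_test.p_value,
                "attending_status": v.attending_test.status,
                "attending_p": v.attending_test.p_value,
                "verdict": v.verdict,
            }
        )
    return pd.DataFrame(rows)


def modality_deviation(records, modalities=None) -> pd.DataFrame:
    """Percentage deviation of each body-act modality by attention state.

    Uses body acts with a known recipient-attention state.  ``alpha`` is a
    modality's share of that full set; ``beta`` its share within each state;
    deviation = (beta/alpha - 1) x 100.  Modalities absent from the data are
    omitted.  Within every attention state the betas sum to 1, as do the
    alphas overall, and the state-weighted mean of the betas returns alpha.
    """
    df = as_frame(records)
    body = df[
        (df["category"] == "body_act")
        & df["recipient_attending"].isin(("yes", "no"))
    ]
    if modalities is not None:
        body = body[body["modality"].isin(modalities)]
    if body.empty:
        raise ValueError("no body acts with known recipient attention")
    n_total = len(body)
    alpha = body["modality"].value_counts() / n_total
    rows = []
    for state in ("yes", "no"):
        sub = body[body["recipient_attending"] == state]
        beta = sub["modality"].value_counts() / max(len(sub), 1)
        for m in alpha.index:
            b = float(beta.get(m, 0.0))
            rows.append(
                {
                    "modality": m,
                    "recipient_attending": state,
                    "alpha": float(alpha[m]),
                    "beta": b,
                    "n_state": len(sub),
                    "deviation_pct": (b / alpha[m] - 1.0) * 100.0,
                }
            )
    return pd.DataFrame(rows)


def attention_shares(records) -> pd.DataFrame:
    """Per-modality share of body acts produced to an attending recipient."""
    df = as_frame(records)
    body = df[
        (df["category"] == "body_act")
        & df["recipient_attending"].isin(("yes", "no"))
    ]
    rows = []
    for m, grp in body.groupby("modality", sort=True):
        n = len(grp)
        k = int((grp["recipient_attending"] == "yes").sum())
        rows.append(
            {"modality": m, "n": n, "n_attending": k, "share_attending": k / n}
        )
    return pd.DataFrame(rows)


def tail_assessment(records, tail_types, reference_types=None) -> dict:
    """Assess whether tail body-act types behave like visual gestures.

    Builds the binary modelling frame (response 1 = tail type, 0 = reference
    silent-visual type; predictor = recipient attending; grouping =
    signaller), the percentage deviation of tail-type use by attention state
    against the pooled tail+reference distribution, and per-type distance
    profiles with the share of cases within 1 m (candidate olfactory use).
    Cases with unknown recipient attention are excluded from the frame and
    the deviation, but kept in the distance profile.
    """
    tail_types = set(tail_types)
    if not tail_types:
        raise ValueError("no tail types given")
    df = as_frame(records)
    body = df[df["category"] == "body_act"]
    if not (body["signal_type"].isin(tail_types)).any():
        raise ValueError("records contain no tail-type cases")
    if reference_types is None:
        reference_types = set(
            body.loc[body["modality"] == "silent_visual", "signal_type"]
        ) - tail_types
    reference_types = set(reference_types)
    pool = body[body["signal_type"].isin(tail_types | reference_types)]
    known = pool[pool["recipient_attending"].isin(("yes", "no"))].copy()
    known["is_tail"] = known["signal_type"].isin(tail_types).astype(int)
    known["attending"] = (known["recipient_attending"] == "yes").astype(int)
    model_frame = known[
        ["event_id", "signaller_id", "signal_type", "is_tail", "attending"]
    ].reset_index(drop=True)

    alpha_tail = known["is_tail"].mean()
    dev_rows = []
    for state in ("yes", "no"):
        sub = known[known["recipient_attending"] == state]
        beta = sub["is_tail"].mean() if len(sub) else float("nan")
        dev_rows.append(
            {
                "recipient_attending": state,
                "alpha": float(alpha_tail),
                "beta": float(beta),
                "n_state": len(sub),
                "deviation_pct": (beta / alpha_tail - 1.0) * 100.0
                if alpha_tail > 0
                else float("nan"),
            }
        )

    tails = body[body["signal_type"].isin(tail_types)]
    profile_rows = []
    labels = [
        f"[{DISTANCE_BINS[i]:g},{DISTANCE_BINS[i + 1]:g})"
        for i in range(len(DISTANCE_BINS) - 1)
    ]
    for sig_type, grp in tails.groupby("signal_type", sort=True):
        d = grp["distance_m"].to_numpy(float)
        d = d[~np.isnan(d)]
        binned = (
            pd.cut(d, DISTANCE_BINS, right=False, labels=labels, include_lowest=True)
            .value_counts()
            .reindex(labels, fill_value=0)
            if len(d)
            else pd.Series(0, index=labels)
        )
        profile_rows.append(
            {
                "signal_type": sig_type,
                "n_with_distance": len(d),
                "share_within_1m": float((d < 1.0).mean()) if len(d) else math.nan,
                **{str(k): int(vv) for k, vv in binned.items()},
            }
        )
    return {
        "model_frame": model_frame,
        "deviation": pd.DataFrame(dev_rows),
        "distance_profile": pd.DataFrame(profile_rows),
        "n_cases": len(model_frame),
    }
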