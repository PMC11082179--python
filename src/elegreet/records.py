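"""Core data model for coded greeting-communication annotations.

A coded dataset is a sequence of :class:`SignalRecord` rows, one per signal
(a vocalisation or a body act) produced by a signaller towards a recipient
during a separation-reunion greeting event.  Times are seconds from the
start of the event; signal intervals are half-open ``[onset, offset)`` so
that back-to-back signals do not overlap.  Visual-attention states and
distances are coded at signal onset.  ``unknown`` is an explicit level
throughout and is never silently dropped: operations that exclude unknowns
say so in their contract.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, fields, replace
from typing import Iterable, Sequence

import pandas as pd

CATEGORIES = ("vocalisation", "body_act")
ARTICULATORS = ("ears", "trunk", "tail", "head", "body", "vocal_tract")
MODALITIES = ("silent_visual", "audible", "tactile", "olfactory_candidate", "vocal")
BODY_ACT_MODALITIES = ("silent_visual", "audible", "tactile", "olfactory_candidate")
ATTENTION_LEVELS = ("yes", "no", "unknown")
AWARENESS_LEVELS = ("yes", "unknown")
OLFACTORY_LEVELS = ("present", "absent", "unknown")

#: Mean adult body length used to convert coded body-length counts to metres.
DEFAULT_BODY_LENGTH_M = 3.0

SIGNAL_COLUMNS = (
    "event_id",
    "signaller_id",
    "recipient_id",
    "signal_type",
    "category",
    "articulator",
    "modality",
    "onset_s",
    "offset_s",
    "signaller_attending",
    "recipient_attending",
    "distance_m",
    "signaller_aware_of_recipient",
)


class ValidationError(ValueError):
    """A record violates the data-model invariants."""


@dataclass(frozen=True, eq=False)
class SignalRecord:
    """One coded signal: identity, type, timing, modality, attention, distance.

    ``distance_m`` is ``nan`` when the signaller-recipient distance was not
    codeable; all other unknowns use the string level ``"unknown"``.
    Equality is field-wise with ``nan`` distances comparing equal, so a
    written-and-reloaded record equals its source.
    """

    event_id: str
    signaller_id: str
    recipient_id: str
    signal_type: str
    category: str
    articulator: str
    modality: str
    onset_s: float
    offset_s: float
    signaller_attending: str = "unknown"
    recipient_attending: str = "unknown"
    distance_m: float = math.nan
    signaller_aware_of_recipient: str = "yes"

    def validate(self) -> "SignalRecord":
        if self.signaller_id == self.recipient_id:
            raise ValidationError(
                f"signaller and recipient identical ({self.signaller_id!r})"
            )
        if self.category not in CATEGORIES:
            raise ValidationError(f"unknown category {self.category!r}")
        if self.articulator not in ARTICULATORS:
            raise ValidationError(f"unknown articulator {self.articulator!r}")
        if self.modality not in MODALITIES:
            raise ValidationError(f"unknown modality {self.modality!r}")
        if not (self.offset_s >= self.onset_s):
            raise ValidationError(
                f"offset {self.offset_s} precedes onset {self.onset_s} "
                f"for {self.signal_type!r} in event {self.event_id!r}"
            )
        if self.category == "vocalisation":
            if self.modality != "vocal" or self.articulator != "vocal_tract":
                raise ValidationError(
                    "vocalisations must carry modality='vocal' and "
                    f"articulator='vocal_tract' (got {self.modality!r}, "
                    f"{self.articulator!r})"
                )
        elif self.modality == "vocal" or self.articulator == "vocal_tract":
            raise ValidationError("body acts cannot be vocal/vocal_tract")
        if self.signaller_attending not in ATTENTION_LEVELS:
            raise ValidationError(
                f"bad signaller_attending {self.signaller_attending!r}"
            )
        if self.recipient_attending not in ATTENTION_LEVELS:
            raise ValidationError(
                f"bad recipient_attending {self.recipient_attending!r}"
            )
        if self.signaller_aware_of_recipient not in AWARENESS_LEVELS:
            raise ValidationError(
                f"bad signaller_aware_of_recipient "
                f"{self.signaller_aware_of_recipient!r}"
            )
        if not math.isnan(self.distance_m) and self.distance_m < 0:
            raise ValidationError(f"negative distance {self.distance_m}")
        return self

    def __eq__(self, other):
        if not isinstance(other, SignalRecord):
            return NotImplemented
        for f in fields(self):
            a, b = getattr(self, f.name), getattr(other, f.name)
            if isinstance(a, float) and isinstance(b, float):
                if a != b and not (math.isnan(a) and math.isnan(b)):
                    return False
            elif a != b:
                return False
        return True

    def __hash__(self):
        return hash((self.event_id, self.signaller_id, self.signal_type,
                     self.onset_s, self.offset_s))

    @property
    def duration_s(self) -> float:
        return self.offset_s - self.onset_s

    def overlaps(self, other: "SignalRecord") -> bool:
        """Half-open interval overlap within the same event."""
        if self.event_id != other.event_id:
            return False
        return self.onset_s < other.offset_s and other.onset_s < self.offset_s


@dataclass(frozen=True)
class EventRecord:
    """One greeting event: the dyad, its span, and olfactory behaviour use."""

    event_id: str
    signaller_id: str
    recipient_id: str
    olfactory_behaviour: str = "unknown"
    start_s: float = 0.0
    end_s: float = math.nan

    def validate(self) -> "EventRecord":
        if self.signaller_id == self.recipient_id:
            raise ValidationError("event dyad members identical")
        if self.olfactory_behaviour not in OLFACTORY_LEVELS:
            raise ValidationError(
                f"bad olfactory_behaviour {self.olfactory_behaviour!r}"
            )
        return self


def validate_records(records: Iterable[SignalRecord]) -> list[SignalRecord]:
    """Validate every record, reporting the first failure with its index."""
    out = []
    for i, rec in enumerate(records):
        try:
            out.append(rec.validate())
        except ValidationError as err:
            raise ValidationError(f"record {i}: {err}") from None
    return out


def body_lengths_to_metres(
    n_body_lengths: float, body_length_m: float = DEFAULT_BODY_LENGTH_M
) -> float:
    """Convert a coded body-length count to metres.

    Field coders estimate signaller-recipient distance in adult body lengths;
    the default conversion factor is the 3 m mean body length of the study
    animals and is configurable for other populations.
    """
    if body_length_m <= 0:
        raise ValueError("body_length_m must be positive")
    if n_body_lengths < 0:
        raise ValueError("body-length count cannot be negative")
    return n_body_lengths * body_length_m


def to_frame(records: Sequence[SignalRecord]) -> pd.DataFrame:
    """Signal records as a tidy DataFrame with the canonical column order."""
    return pd.DataFrame(
        [[getattr(r, c) for c in SIGNAL_COLUMNS] for r in records],
        columns=list(SIGNAL_COLUMNS),
    )


def from_frame(df: pd.DataFrame, validate: bool = True) -> list[SignalRecord]:
    """Build signal records from a DataFrame carrying the canonical columns."""
    missing = [c for c in SIGNAL_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"missing required columns: {missing}")
    field_types = {f.name: f.type for f in fields(SignalRecord)}
    recs = []
    for row in df.itertuples(index=False):
        kw = {c: getattr(row, c) for c in SIGNAL_COLUMNS}
        for c in ("onset_s", "offset_s", "distance_m"):
            kw[c] = float(kw[c]) if kw[c] == kw[c] else math.nan
        for c in SIGNAL_COLUMNS:
            if c not in ("onset_s", "offset_s", "distance_m"):
                kw[c] = str(kw[c])
        recs.append(SignalRecord(**kw))
    if validate:
        recs = validate_records(recs)
    return recs


def as_frame(records) -> pd.DataFrame:
    """Accept either a DataFrame or a sequence of records; return a frame."""
    if isinstance(records, pd.DataFrame):
        return records
    return to_frame(list(records))


def replace_record(record: SignalRecord, **changes) -> SignalRecord:
    return replace(record, **changes)
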