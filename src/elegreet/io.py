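"""Reading, writing, and filtering coded-signal tables.

Tables travel as CSV/TSV with the canonical :data:`~elegreet.records.SIGNAL_COLUMNS`
header, or as ELAN ``.eaf`` XML where a configurable mapping names one
alignable tier per column.  The case-exclusion step mirrors standard field
practice: body acts coded beyond the recipient's plausible detection range
are dropped, as are cases where the signaller may not have known the
recipient was present, and every removal is logged by reason.
"""

from __future__ import annotations

import json
import math
import xml.etree.ElementTree as ET
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .records import (
    SIGNAL_COLUMNS,
    SignalRecord,
    ValidationError,
    from_frame,
    to_frame,
    validate_records,
)


class SchemaError(ValidationError):
    """The file lacks a required column or carries an unusable value."""


_NUMERIC = ("onset_s", "offset_s", "distance_m")


def load_signals(path, dialect: str = "csv", eaf_config: dict | None = None,
                 validate: bool = True) -> list[SignalRecord]:
    """Load coded signals from ``path``.

    Parameters
    ----------
    path:
        File to read.
    dialect:
        ``"csv"``, ``"tsv"`` or ``"eaf"``.
    eaf_config:
        For EAF input, a mapping ``column -> tier name``; see
        :func:`read_eaf`.
    validate:
        Check data-model invariants after parsing.

    Raises a :class:`SchemaError` naming the column when a required column
    is absent, and a row-level error carrying the 1-based data line number
    when a time or distance fails to parse.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if dialect == "eaf":
        df = read_eaf(path, eaf_config or {})
    elif dialect in ("csv", "tsv"):
        sep = "\t" if dialect == "tsv" else ","
        df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
        missing = [c for c in SIGNAL_COLUMNS if c not in df.columns]
        if missing:
            raise SchemaError(f"missing required column(s): {', '.join(missing)}")
        for col in _NUMERIC:
            parsed = pd.to_numeric(df[col].replace("", "nan"), errors="coerce")
            blank = df[col].isin(("", "nan", "NA", "NaN", "unknown"))
            bad = parsed.isna() & ~blank
            if bad.any():
                line = int(bad.idxmax()) + 1
                raise SchemaError(
                    f"unparseable value {df[col][bad.idxmax()]!r} in column "
                    f"{col!r} at data line {line}"
                )
            df[col] = parsed
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    return from_frame(df, validate=validate)


def write_signals(records: Sequence[SignalRecord] | pd.DataFrame, path,
                  dialect: str = "csv") -> None:
    """Write signals as CSV/TSV with the canonical header; round-trip safe."""
    df = records if isinstance(records, pd.DataFrame) else to_frame(list(records))
    sep = "\t" if dialect == "tsv" else ","
    df.to_csv(path, sep=sep, index=False)


# ---------------------------------------------------------------------------
# ELAN EAF import/export
# ---------------------------------------------------------------------------

#: Default column -> tier-name mapping for EAF files written by this package.
DEFAULT_EAF_TIERS = {c: c for c in SIGNAL_COLUMNS if c not in ("onset_s", "offset_s")}


def read_eaf(path, tier_map: dict | None = None) -> pd.DataFrame:
    """Read an ELAN ``.eaf`` annotation document into a signal table.

    The expected layout is one alignable tier per column (the convention
    :func:`write_eaf` produces): every tier holds one annotation per signal,
    in the same order, and onset/offset come from the time slots of the
    ``signal_type`` tier.  ``tier_map`` maps canonical column names to tier
    ids for documents coded under different tier names.
    """
    tiers = dict(DEFAULT_EAF_TIERS)
    tiers.update(tier_map or {})
    root = ET.parse(path).getroot()
    slots = {
        ts.get("TIME_SLOT_ID"): float(ts.get("TIME_VALUE")) / 1000.0
        for ts in root.iter("TIME_SLOT")
    }
    by_tier: dict[str, list] = {}
    spans: dict[str, list] = {}
    for tier in root.iter("TIER"):
        tid = tier.get("TIER_ID")
        values, times = [], []
        for ann in tier.iter("ALIGNABLE_ANNOTATION"):
            val = ann.find("ANNOTATION_VALUE")
            values.append(val.text if val is not None and val.text else "")
            times.append(
                (slots[ann.get("TIME_SLOT_REF1")], slots[ann.get("TIME_SLOT_REF2")])
            )
        by_tier[tid] = values
        spans[tid] = times
    type_tier = tiers["signal_type"]
    if type_tier not in by_tier:
        raise SchemaError(f"missing required column(s): signal_type "
                          f"(no tier {type_tier!r})")
    n = len(by_tier[type_tier])
    data = {}
    for col, tid in tiers.items():
        if tid not in by_tier:
            raise SchemaError(f"missing required column(s): {col} (no tier {tid!r})")
        if len(by_tier[tid]) != n:
            raise SchemaError(
                f"tier {tid!r} has {len(by_tier[tid])} annotations, "
                f"expected {n}"
            )
        data[col] = by_tier[tid]
    df = pd.DataFrame(data)
    df["onset_s"] = [t[0] for t in spans[type_tier]]
    df["offset_s"] = [t[1] for t in spans[type_tier]]
    df["distance_m"] = pd.to_numeric(
        df["distance_m"].replace("", "nan"), errors="coerce"
    )
    return df[list(SIGNAL_COLUMNS)]


def write_eaf(records: Sequence[SignalRecord], path) -> None:
    """Write signals as a minimal ELAN document, one alignable tier per column."""
    df = to_frame(list(records))
    root = ET.Element(
        "ANNOTATION_DOCUMENT",
        {"AUTHOR": "elegreet", "FORMAT": "3.0", "VERSION": "3.0"},
    )
    header = ET.SubElement(root, "HEADER", {"TIME_UNITS": "milliseconds"})
    time_order = ET.SubElement(root, "TIME_ORDER")
    slot_ids = []
    for i, row in df.iterrows():
        ids = []
        for j, t in enumerate((row.onset_s, row.offset_s)):
            sid = f"ts{2 * i + j + 1}"
            ET.SubElement(
                time_order, "TIME_SLOT",
                {"TIME_SLOT_ID": sid, "TIME_VALUE": str(int(round(t * 1000)))},
            )
            ids.append(sid)
        slot_ids.append(ids)
    ann_id = 0
    for col in DEFAULT_EAF_TIERS:
        tier = ET.SubElement(
            root, "TIER", {"TIER_ID": col, "LINGUISTIC_TYPE_REF": "default-lt"}
        )
        for i, value in enumerate(df[col]):
            ann_id += 1
            ann = ET.SubElement(tier, "ANNOTATION")
            al = ET.SubElement(
                ann, "ALIGNABLE_ANNOTATION",
                {
                    "ANNOTATION_ID": f"a{ann_id}",
                    "TIME_SLOT_REF1": slot_ids[i][0],
                    "TIME_SLOT_REF2": slot_ids[i][1],
                },
            )
            v = ET.SubElement(al, "ANNOTATION_VALUE")
            txt = "" if (isinstance(value, float) and math.isnan(value)) else str(value)
            v.text = txt
    ET.SubElement(
        root, "LINGUISTIC_TYPE",
        {"LINGUISTIC_TYPE_ID": "default-lt", "TIME_ALIGNABLE": "true"},
    )
    ET.ElementTree(root).write(path, encoding="UTF-8", xml_declaration=True)


# ---------------------------------------------------------------------------
# Case exclusions
# ---------------------------------------------------------------------------


@dataclass
class ExclusionLog:
    """Counts of removed records by reason, JSON-serialisable."""

    n_input: int = 0
    n_retained: int = 0
    by_reason: dict = field(default_factory=dict)

    def to_json(self, path=None) -> str:
        payload = json.dumps(
            {
                "n_input": self.n_input,
                "n_retained": self.n_retained,
                "excluded_by_reason": self.by_reason,
            },
            indent=2,
        )
        if path is not None:
            Path(path).write_text(payload)
        return payload


def apply_exclusions(
    records: Iterable[SignalRecord],
    max_distance_m: float = 100.0,
    require_awareness: bool = True,
    distance_applies_to: str = "body_act",
) -> tuple[list[SignalRecord], ExclusionLog]:
    """Apply the standard case exclusions before any analysis.

    Removes body acts produced when the recipient was farther than
    ``max_distance_m`` (beyond plausible visual detection range; vocalisations
    are kept by default since they carry regardless of distance, set
    ``distance_applies_to="all"`` to drop them too), and, when
    ``require_awareness`` is set, cases where it is unknown whether the
    signaller was aware of the recipient's presence.  Records with unknown
    distance are retained: distance cannot disqualify what it cannot measure.

    Returns the retained records (input order preserved) and an
    :class:`ExclusionLog` with counts by reason.  Idempotent: running it on
    its own output removes nothing.
    """
    if max_distance_m < 0:
        raise ValueError("max_distance_m must be non-negative")
    if distance_applies_to not in ("body_act", "all"):
        raise ValueError("distance_applies_to must be 'body_act' or 'all'")
    records = list(records)
    retained: list[SignalRecord] = []
    log = ExclusionLog(n_input=len(records), by_reason={"distance": 0, "awareness": 0})
    for rec in records:
        in_scope = distance_applies_to == "all" or rec.category == "body_act"
        if in_scope and not math.isnan(rec.distance_m) and rec.distance_m > max_distance_m:
            log.by_reason["distance"] += 1
            continue
        if require_awareness and rec.signaller_aware_of_recipient == "unknown":
            log.by_reason["awareness"] += 1
            continue
        retained.append(rec)
    log.n_retained = len(retained)
    return retained, log
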