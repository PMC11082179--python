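"""Nearest-neighbour association indices from focal-scan data.

During all-day focal follows the observer notes, at fixed scan intervals,
which group member is currently nearest the focal animal.  The
nearest-neighbour index ``NN_AB`` is the proportion of focal A's scans in
which B was the nearest neighbour — a simple directed measure of dyadic
association.  Partners whose index rises a quarter standard deviation above
the focal's mean index count as strong associates; the symmetrised average
of the two directed indices serves as a dyadic bond-strength covariate in
the combination models.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

SCAN_COLUMNS = ("focal_id", "scan_id", "nearest_neighbour_id")


class UndefinedIndexError(ValueError):
    """The requested index has no scans to be computed from."""


def validate_scans(scans: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in SCAN_COLUMNS if c not in scans.columns]
    if missing:
        raise ValueError(f"scan table missing columns: {missing}")
    if (scans["focal_id"] == scans["nearest_neighbour_id"]).any():
        raise ValueError("focal recorded as its own nearest neighbour")
    return scans


def nn_index(scans: pd.DataFrame, focal, partner) -> float:
    """Proportion of ``focal``'s scans in which ``partner`` was nearest."""
    validate_scans(scans)
    mine = scans[scans["focal_id"] == focal]
    if len(mine) == 0:
        raise UndefinedIndexError(f"no scans for focal {focal!r}")
    return float((mine["nearest_neighbour_id"] == partner).sum() / len(mine))


def nn_matrix(scans: pd.DataFrame, individuals=None) -> pd.DataFrame:
    """All directed indices as a square frame, focals on rows.

    Rows for focals with zero scans are NaN; the diagonal is NaN.  Each
    defined row sums to at most 1 (exactly 1 when every scan's neighbour is
    among ``individuals``).
    """
    validate_scans(scans)
    if individuals is None:
        individuals = sorted(
            set(scans["focal_id"]) | set(scans["nearest_neighbour_id"])
        )
    individuals = list(individuals)
    mat = pd.DataFrame(np.nan, index=individuals, columns=individuals, dtype=float)
    counts = scans.groupby("focal_id").size()
    hits = scans.groupby(["focal_id", "nearest_neighbour_id"]).size()
    for a in individuals:
        if a not in counts.index:
            continue
        total = counts[a]
        for b in individuals:
            if a == b:
                continue
            mat.loc[a, b] = hits.get((a, b), 0) / total
    mat.index.name = "focal_id"
    return mat


def strong_associates(
    matrix: pd.DataFrame, focal, sd_multiplier: float = 0.25, pool: str = "focal"
) -> set:
    """Partners whose index exceeds mean + ``sd_multiplier``·sd (strictly).

    ``pool="focal"`` takes mean and sample (n-1) standard deviation over the
    focal's own row of directed indices; ``pool="global"`` pools every
    defined off-diagonal index in the matrix before thresholding.
    """
    row = matrix.loc[focal].drop(labels=[focal], errors="ignore").dropna()
    if len(row) < 2:
        raise UndefinedIndexError(
            f"fewer than two partners with defined indices for {focal!r}"
        )
    if pool == "focal":
        ref = row.to_numpy(float)
    elif pool == "global":
        off = matrix.to_numpy(float).copy()
        np.fill_diagonal(off, np.nan)
        ref = off[~np.isnan(off)]
    else:
        raise ValueError("pool must be 'focal' or 'global'")
    threshold = ref.mean() + sd_multiplier * ref.std(ddof=1)
    return {b for b, v in row.items() if v > threshold}


def dyad_strength(matrix: pd.DataFrame, a, b) -> float:
    """Symmetrised association: (NN_ab + NN_ba) / 2.

    z-transformation of this covariate is done within each modelling sample
    by the models module, not here.
    """
    ab = matrix.loc[a, b]
    ba = matrix.loc[b, a]
    if np.isnan(ab) or np.isnan(ba):
        raise UndefinedIndexError(f"directed index undefined for dyad ({a!r}, {b!r})")
    return float((ab + ba) / 2.0)
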