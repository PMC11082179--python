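"""Inter-observer reliability for categorical coding decisions.

Behavioural codings are only as good as their repeatability: a second,
independently trained coder re-codes a subset of items and agreement beyond
chance is summarised with Cohen's kappa, per variable (signal type,
signaller attention, recipient attention), unweighted because the
categories are nominal.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
from sklearn.metrics import cohen_kappa_score


def cohen_kappa(codes_a: Sequence, codes_b: Sequence) -> float:
    """Cohen's kappa between two coders over the same items.

    kappa = (p_o - p_e) / (1 - p_e), with expected agreement p_e from the
    product of the coders' marginal category frequencies.  The degenerate
    case p_e = 1 (both coders constant) returns 1.0 when the codes agree
    exactly and 0.0 otherwise — agreement on a single repeated label carries
    no chance-corrected information, but it is not disagreement.
    """
    a = np.asarray(codes_a)
    b = np.asarray(codes_b)
    if a.shape != b.shape:
        raise ValueError(f"code vectors differ in length: {a.shape} vs {b.shape}")
    if a.size == 0:
        raise ValueError("code vectors are empty")
    if len(set(a)) == 1 and len(set(b)) == 1:
        return 1.0 if a[0] == b[0] else 0.0
    return float(cohen_kappa_score(a, b))


def reliability_table(
    coder_a: Mapping[str, Sequence], coder_b: Mapping[str, Sequence]
) -> dict[str, float]:
    """Kappa per coded variable; both mappings must share their keys."""
    if set(coder_a) != set(coder_b):
        raise ValueError("coders report different variables")
    return {var: cohen_kappa(coder_a[var], coder_b[var]) for var in coder_a}
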