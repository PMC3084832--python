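"""Reactive- and specific-well calling against the positive-control threshold.

A culture well is *reactive* when its relative absorbance (sample OD over the
plate's mean positive-control OD) is strictly greater than the threshold,
0.75 by default — i.e. the supernatant binds the target cells at more than
75 % of the positive-control antibody's signal.  A clone is *tumor-specific*
when it is reactive on at least one melanoma line and on none of the normal
lines (melanocytes, fibroblasts) screened alongside.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

DEFAULT_THRESHOLD = 0.75


@dataclass
class CallResult:
    reactive: bool
    relative_absorbance: float
    threshold: float = DEFAULT_THRESHOLD
    per_line: dict = field(default_factory=dict)


def call_reactive(relative_absorbance, threshold: float = DEFAULT_THRESHOLD):
    """True iff relative absorbance is strictly greater than the threshold.

    Vectorized over array input. The strict inequality means a well sitting
    exactly at the threshold is not called.
    """
    if not 0 < threshold <= 1:
        raise ValueError(f"threshold must be in (0, 1], got {threshold}")
    ra = np.asarray(relative_absorbance, dtype=float)
    if (ra < 0).any():
        raise ValueError("relative absorbance must be non-negative")
    out = ra > threshold
    return bool(out) if out.ndim == 0 else out


def call_specific(calls_by_line: dict, melanoma_lines, normal_lines) -> bool:
    """Tumor specificity from per-cell-line reactive calls.

    True iff reactive on >= 1 melanoma line and on zero normal lines.  Both
    line sets must be non-empty and present in ``calls_by_line``.
    """
    melanoma_lines = list(melanoma_lines)
    normal_lines = list(normal_lines)
    if not melanoma_lines or not normal_lines:
        raise ValueError("need at least one melanoma line and one normal line")
    missing = [l for l in melanoma_lines + normal_lines if l not in calls_by_line]
    if missing:
        raise ValueError(f"no calls for cell lines: {missing}")
    return any(bool(calls_by_line[l]) for l in melanoma_lines) and not any(
        bool(calls_by_line[l]) for l in normal_lines
    )


def reactive_percent(calls, rounded: bool = True) -> float:
    """Percent of cultures called reactive, rounded half-up to an integer.

    Set ``rounded=False`` for the raw percentage.
    """
    calls = np.asarray(calls, dtype=bool)
    if calls.size == 0:
        raise ValueError("reactive_percent needs at least one culture")
    pct = 100.0 * calls.sum() / calls.size
    if not rounded:
        return float(pct)
    return float(np.floor(pct + 0.5))
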