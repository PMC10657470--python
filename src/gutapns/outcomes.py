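"""Scoring and diagnosis rules for the three post-trauma instruments.

* PCL-5 — 20 items scored 0-4, summed to a 0-80 raw PTSD severity score.
* PROMIS Depression 8b — reported as a t-score (population mean 50, SD 10).
* Somatic symptoms — 12 yes/no items (Rivermead post-concussion set),
  summed to a 0-12 count.

Diagnosis cuts follow the operational grouping used downstream: PTSD
raw score strictly greater than 31, depression t-score at or above 60
(one SD above the population mean). Both cuts are parameters so other
conventions can be applied.
"""

from __future__ import annotations

import math
from collections.abc import Sequence

__all__ = [
    "PCL5_MAX",
    "PTSD_CUT",
    "DEPRESSION_CUT",
    "N_SOMATIC_ITEMS",
    "score_pcl5",
    "diagnose_ptsd",
    "diagnose_depression",
    "count_somatic",
]

PCL5_MAX = 80
PTSD_CUT = 31  # diagnosis iff raw score > cut
DEPRESSION_CUT = 60.0  # diagnosis iff t-score >= cut
N_SOMATIC_ITEMS = 12


def score_pcl5(items: Sequence[int]) -> int:
    """Sum the 20 PCL-5 item responses (each 0-4) into the raw score."""
    if len(items) != 20:
        raise ValueError(f"PCL-5 has 20 items, got {len(items)}")
    for i, item in enumerate(items):
        if int(item) != item or not 0 <= item <= 4:
            raise ValueError(f"item {i}: response {item!r} outside 0-4")
    return int(sum(items))


def diagnose_ptsd(pcl5_raw: float, cut: int = PTSD_CUT) -> bool:
    """Positive PTSD screen iff the raw score exceeds ``cut`` (default 31)."""
    if not 0 <= pcl5_raw <= PCL5_MAX:
        raise ValueError(f"PCL-5 raw score {pcl5_raw!r} outside [0, {PCL5_MAX}]")
    return pcl5_raw > cut


def diagnose_depression(promis_t: float, cut: float = DEPRESSION_CUT) -> bool:
    """Positive depression screen iff the t-score is at least ``cut`` (default 60)."""
    if not math.isfinite(promis_t):
        raise ValueError(f"non-finite t-score {promis_t!r}")
    return promis_t >= cut


def count_somatic(responses: Sequence[bool]) -> int:
    """Count positive responses among the 12 somatic-symptom items."""
    if len(responses) != N_SOMATIC_ITEMS:
        raise ValueError(f"expected {N_SOMATIC_ITEMS} responses, got {len(responses)}")
    return int(sum(bool(r) for r in responses))
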