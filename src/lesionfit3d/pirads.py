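"""PI-RADS v2.1 size-criterion rescoring.

PI-RADS v2.1 separates assessment category 4 from 5 by a tumour maximum
diameter cut-off of 1.5 cm.  When 3D measurement yields a TMD at or above
the cut-off, a score-3 or score-4 lesion is rescored to 5 (the observed
clinical behaviour this package models upgrades from both 3 and 4; a
stricter reading that only upgrades score-4 lesions is available via
``upgrade_from=(4,)``).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import pandas as pd

from .errors import ValidationError

__all__ = ["RescoreResult", "apply_size_criterion", "rescore_cohort", "round_half_away"]

VALID_SCORES = (3, 4, 5)
DEFAULT_THRESHOLD_CM = 1.5


def round_half_away(x: float) -> int:
    """Round to nearest integer, halves away from zero."""
    return int(math.floor(abs(x) + 0.5)) * (1 if x >= 0 else -1)


def apply_size_criterion(
    initial_score: int,
    tmd_cm: float,
    threshold_cm: float = DEFAULT_THRESHOLD_CM,
    upgrade_from: tuple[int, ...] = (3, 4),
) -> int:
    """Final score after the tumour-size criterion (inclusive >= threshold)."""
    if initial_score not in VALID_SCORES:
        raise ValidationError(f"initial_score must be one of {VALID_SCORES}, got {initial_score}")
    if not tmd_cm > 0:
        raise ValidationError(f"tmd_cm must be positive, got {tmd_cm}")
    if not threshold_cm > 0:
        raise ValidationError(f"threshold_cm must be positive, got {threshold_cm}")
    if initial_score in upgrade_from and tmd_cm >= threshold_cm:
        return 5
    return int(initial_score)


@dataclass(frozen=True)
class RescoreResult:
    """Per-subject rescoring plus cohort-level upgrade counts/percentages."""

    per_subject: pd.DataFrame
    n_3_to_5: int
    n_4_to_5: int
    pct_3_to_5: int
    pct_4_to_5: int
    denominators: dict[int, int]
    threshold_cm: float

    def to_dict(self) -> dict:
        return {
            "n_3_to_5": self.n_3_to_5,
            "n_4_to_5": self.n_4_to_5,
            "pct_3_to_5": self.pct_3_to_5,
            "pct_4_to_5": self.pct_4_to_5,
            "denominators": {str(k): v for k, v in self.denominators.items()},
            "threshold_cm": self.threshold_cm,
            "subjects": self.per_subject.to_dict(orient="records"),
        }


def rescore_cohort(
    table: pd.DataFrame,
    denominators: dict[int, int],
    threshold_cm: float = DEFAULT_THRESHOLD_CM,
    upgrade_from: tuple[int, ...] = (3, 4),
    tmd_column: str = "auto_tmd_cm",
) -> RescoreResult:
    """Apply the size criterion to every cohort row and count upgrades.

    Percentages use the supplied per-score cohort denominators (the study
    cohort may be larger than the rows whose scores changed) and are rounded
    half away from zero.
    """
    table = table.copy()
    final = [
        apply_size_criterion(int(row.initial_score), float(getattr(row, tmd_column)),
                             threshold_cm, upgrade_from)
        for row in table.itertuples()
    ]
    table["final_score"] = final
    table["upgraded"] = table["final_score"] > table["initial_score"]

    counts = {}
    for s in (3, 4):
        counts[s] = int(((table["initial_score"] == s) & (table["final_score"] == 5)).sum())
    pcts = {}
    for s in (3, 4):
        den = denominators.get(s, 0)
        if counts[s] > 0 and den < counts[s]:
            raise ValidationError(
                f"denominator {den} for score {s} is smaller than its upgrade count {counts[s]}"
            )
        pcts[s] = round_half_away(100.0 * counts[s] / den) if den > 0 else 0
    return RescoreResult(
        per_subject=table,
        n_3_to_5=counts[3],
        n_4_to_5=counts[4],
        pct_3_to_5=pcts[3],
        pct_4_to_5=pcts[4],
        denominators={3: denominators.get(3, 0), 4: denominators.get(4, 0)},
        threshold_cm=threshold_cm,
    )
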