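"""Cohort/image accounting arithmetic with publication-style rounding.

All percentages and ratios reported by the pipeline are rounded half-up
to the printed precision (so 74.5% prints as 75%), matching how clinical
journals round enrollment and acquisition counts.
"""

from __future__ import annotations

import decimal
from dataclasses import dataclass


def round_half_up(value: float, decimals: int = 0) -> float:
    """Round with ties away from zero at ``decimals`` places (0.5 -> 1)."""
    q = decimal.Decimal(1).scaleb(-decimals)
    d = decimal.Decimal(repr(value)).quantize(q, rounding=decimal.ROUND_HALF_UP)
    return float(d)


def percent(numerator: float, denominator: float, decimals: int = 0) -> float:
    """``numerator / denominator`` as a half-up-rounded percentage."""
    if denominator == 0:
        raise ZeroDivisionError("percentage with zero denominator")
    return round_half_up(100.0 * numerator / denominator, decimals)


def ratio(numerator: float, denominator: float, decimals: int = 1) -> float:
    """Plain ratio rounded half-up (e.g. videos per analyzable time point)."""
    if denominator == 0:
        raise ZeroDivisionError("ratio with zero denominator")
    return round_half_up(numerator / denominator, decimals)


@dataclass(frozen=True)
class ImageAccounting:
    """Acquisition bookkeeping counts for a three-time-point imaging study."""

    parent_trial_n: int
    enrolled_n: int
    analyzable_subjects_n: int
    images_n: int
    analyzable_time_points_n: int
    attempted_time_points_n: int
    attempts_by_time: dict[int, int]
    successes_by_time: dict[int, int]

    def enrollment_pct(self, decimals: int = 1) -> float:
        return percent(self.enrolled_n, self.parent_trial_n, decimals)

    def analyzable_subject_pct(self, decimals: int = 0) -> float:
        return percent(self.analyzable_subjects_n, self.enrolled_n, decimals)

    def videos_per_time_point(self, decimals: int = 1) -> float:
        return ratio(self.images_n, self.analyzable_time_points_n, decimals)

    def quality_pass_pct(self, decimals: int = 0) -> float:
        return percent(
            self.analyzable_time_points_n, self.attempted_time_points_n, decimals
        )

    def success_pct_by_time(self, decimals: int = 0) -> dict[int, float]:
        return {
            tp: percent(self.successes_by_time[tp], self.attempts_by_time[tp],
                        decimals)
            for tp in sorted(self.attempts_by_time)
        }


__all__ = ["ImageAccounting", "percent", "ratio", "round_half_up"]
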