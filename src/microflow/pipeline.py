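"""Stage glue: traces -> per-clip metrics -> subject-time-point metrics."""

from __future__ import annotations

from collections import defaultdict
from typing import Optional, Sequence

import pandas as pd

from .config import ScoreConfig
from .metrics import aggregate_time_point, rank_and_select_clips, score_clip
from .model import Clip, MetricSet


def score_traces(
    clips: Sequence[Clip],
    config: Optional[ScoreConfig] = None,
    select: bool = True,
) -> list[tuple[str, int, str, MetricSet]]:
    """Quality-select and score clips; one row per selected clip.

    With ``select=False`` every clip is scored regardless of quality
    flags or duration.
    """
    cfg = config or ScoreConfig()
    by_key: dict[tuple[str, int], list[Clip]] = defaultdict(list)
    for c in clips:
        by_key[(c.subject_id, c.time_point_h)].append(c)
    rows = []
    for (sid, tp), group in sorted(by_key.items()):
        chosen = (
            rank_and_select_clips(group, max_n=cfg.max_clips_per_time_point)
            if select else group
        )
        for c in chosen:
            rows.append((sid, tp, c.clip_id, score_clip(
                c, tie_break=cfg.tie_break, empty_quadrant=cfg.empty_quadrant,
                de_backer_small_only=cfg.de_backer_small_only,
            )))
    return rows


def aggregate_metrics(
    clip_rows: Sequence[tuple[str, int, str, MetricSet]] | pd.DataFrame,
) -> list[tuple[str, int, MetricSet]]:
    """Average per-clip metrics to one MetricSet per subject-time-point."""
    if isinstance(clip_rows, pd.DataFrame):
        from .io import metrics_table_to_sets

        triples = metrics_table_to_sets(clip_rows)
    else:
        triples = [(sid, tp, ms) for sid, tp, _cid, ms in clip_rows]
    grouped: dict[tuple[str, int], list[MetricSet]] = defaultdict(list)
    for sid, tp, ms in triples:
        grouped[(sid, tp)].append(ms)
    return [
        (sid, tp, aggregate_time_point(sets))
        for (sid, tp), sets in sorted(grouped.items())
    ]


__all__ = ["score_traces", "aggregate_metrics"]
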