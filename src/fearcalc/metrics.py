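"""Behavioural scoring and per-CS axonal activity statistics.

Freezing is scored as the percentage of CS time covered by freezing bouts.
The learning index multiplies the CS+ freezing percentage by the
discrimination index ``(f+ - f-)/(f+ + f-)``; an animal is a learner when
the recall CS+ index exceeds 20%.  Axonal activity during conditioning is
summarised per CS presentation by the number of detected transients and by
the cumulative ΔF/F (sum of peak amplitudes of transients within the CS);
Δcumulative — mean cumulative ΔF/F during CS− minus that during CS+ —
quantifies the asymmetry of amygdalar input between and during pairings,
and is correlated against recall freezing across a cohort.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .imaging import CalciumEvent
from .stimuli import CS_MINUS, CS_PLUS, ConditioningSchedule, Epoch

__all__ = [
    "FreezingRecord",
    "SessionScores",
    "freezing_percent",
    "learning_index",
    "classify_learner",
    "per_cs_counts",
    "cumulative_dff",
    "learning_correlation",
]

LEARNER_THRESHOLD_PCT = 20.0


@dataclass
class FreezingRecord:
    """Freezing bouts of one animal in one session."""

    animal_id: str
    session: str  # habituation | conditioning | recall
    bouts: list[tuple[float, float]]  # (start_s, end_s)

    def __post_init__(self):
        bouts = sorted((float(a), float(b)) for a, b in self.bouts)
        for (a0, b0), (a1, _) in zip(bouts, bouts[1:]):
            if a1 < b0 - 1e-9:
                raise ValueError("freezing bouts must not overlap")
        for a, b in bouts:
            if b < a:
                raise ValueError("bout end before start")
        self.bouts = bouts


@dataclass
class SessionScores:
    """Per-animal summary of one conditioning/recall pair."""

    animal_id: str
    freezing_cs_plus: float  # %
    freezing_cs_minus: float  # %
    learning_index: float  # %
    learner: bool
    per_cs_counts: dict = field(default_factory=dict)
    cumulative_dff: dict = field(default_factory=dict)
    mean_cumulative_cs_plus: float = float("nan")
    mean_cumulative_cs_minus: float = float("nan")
    delta_cumulative: float = float("nan")


def _overlap(bout: tuple[float, float], epoch: Epoch) -> float:
    return max(0.0, min(bout[1], epoch.offset) - max(bout[0], epoch.onset))


def freezing_percent(record: FreezingRecord, epochs: Sequence[Epoch]) -> float:
    """Summed bout/epoch overlap as % of total epoch duration."""
    total = sum(e.duration for e in epochs)
    if total <= 0:
        raise ValueError("total epoch duration must be > 0")
    frozen = sum(_overlap(b, e) for b in record.bouts for e in epochs)
    return 100.0 * frozen / total


def learning_index(
    freezing_cs: float, f_plus: float, f_minus: float
) -> float:
    """``freezing_cs × (f+ − f−)/(f+ + f−)`` in percent.

    With no freezing in either condition the discrimination is undefined
    and the index is reported as 0.
    """
    denom = f_plus + f_minus
    if denom <= 0:
        return 0.0
    return freezing_cs * (f_plus - f_minus) / denom


def classify_learner(
    index_cs_plus: float, threshold: float = LEARNER_THRESHOLD_PCT
) -> bool:
    """Learner iff the recall CS+ learning index is strictly above 20%."""
    return bool(index_cs_plus > threshold)


def per_cs_counts(
    events: Sequence[CalciumEvent],
    schedule: ConditioningSchedule,
) -> pd.DataFrame:
    """Transient counts per (epoch, ROI); peak-time, half-open ``[on, off)``.

    Returns one row per epoch per ROI with columns ``label``, ``epoch_index``
    (1-based within its label, 0 for baseline), ``roi_id``, ``count``.  The
    first CS+ (index 1) is the pairing monitored before any footshock.
    Events outside every epoch are tallied under label ``outside``.
    """
    max_t = max((e.peak_s for e in events), default=0.0)
    if events and max_t > schedule.duration + 1e-6:
        raise ValueError("event times exceed the schedule duration")
    rois = sorted({e.roi_id for e in events})
    label_counter: dict[str, int] = {}
    rows = []
    assigned = {id(e): False for e in events}
    for epoch in schedule.epochs:
        idx = label_counter.get(epoch.label, 0) + 1
        label_counter[epoch.label] = idx
        for roi in rois or ["all"]:
            count = 0
            for e in events:
                if e.roi_id != roi and rois:
                    continue
                if epoch.onset <= e.peak_s < epoch.offset:
                    count += 1
                    assigned[id(e)] = True
            rows.append(
                {
                    "label": epoch.label,
                    "epoch_index": 0 if epoch.label == "baseline" else idx,
                    "roi_id": roi,
                    "onset_s": epoch.onset,
                    "count": count,
                }
            )
    for roi in rois or ["all"]:
        count = sum(
            1
            for e in events
            if (e.roi_id == roi or not rois) and not assigned[id(e)]
        )
        rows.append(
            {"label": "outside", "epoch_index": 0, "roi_id": roi,
             "onset_s": float("nan"), "count": count}
        )
    return pd.DataFrame(rows)


def cumulative_dff(
    events: Sequence[CalciumEvent],
    schedule: ConditioningSchedule,
    n_rois: int | None = None,
) -> tuple[dict, float, float, float]:
    """Per-CS summed transient amplitudes and the Δcumulative statistic.

    Returns ``(per_epoch, mean_cs_plus, mean_cs_minus, delta_cumulative)``
    where ``per_epoch`` maps ``(label, epoch_index)`` to the per-ROI mean of
    the summed peak ΔF/F of transients whose peak falls in that CS (i.e.
    the bouton-averaged cumulative ΔF/F), and
    ``delta_cumulative = mean_cs_minus - mean_cs_plus``.  ``n_rois``
    defaults to the number of distinct ROIs among ``events``; pass it
    explicitly when some ROIs contributed no events.
    """
    if n_rois is None:
        n_rois = max(1, len({e.roi_id for e in events}))
    per_epoch: dict[tuple[str, int], float] = {}
    for label in (CS_PLUS, CS_MINUS):
        for i, epoch in enumerate(schedule.by_label(label), start=1):
            total = sum(
                e.amplitude_dff
                for e in events
                if epoch.onset <= e.peak_s < epoch.offset
            )
            per_epoch[(label, i)] = total / n_rois
    plus = [v for (lab, _), v in per_epoch.items() if lab == CS_PLUS]
    minus = [v for (lab, _), v in per_epoch.items() if lab == CS_MINUS]
    mean_plus = float(np.mean(plus)) if plus else 0.0
    mean_minus = float(np.mean(minus)) if minus else 0.0
    return per_epoch, mean_plus, mean_minus, mean_minus - mean_plus


def learning_correlation(cohort: pd.DataFrame) -> tuple[float, float, float]:
    """OLS of recall freezing % on Δcumulative across animals.

    ``cohort`` needs columns ``delta_cumulative`` and ``freezing_pct``.
    Returns ``(slope, intercept, r_squared)``.
    """
    if len(cohort) < 3:
        raise ValueError("need at least 3 animals")
    x = np.asarray(cohort["delta_cumulative"], float)
    y = np.asarray(cohort["freezing_pct"], float)
    if np.ptp(x) == 0:
        raise ValueError("zero variance in delta_cumulative")
    fit = stats.linregress(x, y)
    return float(fit.slope), float(fit.intercept), float(fit.rvalue**2)
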