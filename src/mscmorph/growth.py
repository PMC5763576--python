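"""Population-doubling arithmetic and senescence flagging.

One population doubling (PD) is one two-fold expansion of the culture:
``PD = log2(N_H / N_1)`` with seeded and harvested densities in
cells/cm².  Cumulative PD sums successive passages of one donor; the
rate is PD per day in culture.  A culture is flagged senescent at the
first passage whose confluency stays below 30% after two weeks.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "PassageRecord",
    "GrowthCurve",
    "CultureFailureError",
    "population_doubling",
    "cumulative_pd",
    "flag_senescence",
]


class CultureFailureError(ValueError):
    """Harvest count of zero: PD undefined for this passage."""


@dataclass(frozen=True)
class PassageRecord:
    """Seeding/harvest bookkeeping for one passage of one donor.

    At passage 0 the seeded density is the CFU-F colony count of the
    original aspirate (colonies/cm²), entered directly.
    """

    donor: str
    passage: int
    seeded_density: float  # N_1, cells/cm²
    harvested_density: float  # N_H, cells/cm²
    days_in_culture: float
    confluency_at_harvest: float | None = None

    def __post_init__(self) -> None:
        if self.seeded_density <= 0:
            raise ValueError("seeded density must be positive")
        if self.harvested_density < 0:
            raise ValueError("harvested density must be nonnegative")
        if self.days_in_culture <= 0:
            raise ValueError("days in culture must be positive")


@dataclass
class GrowthCurve:
    donor: str
    passages: list[int] = field(default_factory=list)
    pd_per_passage: list[float] = field(default_factory=list)
    cumulative_pd: list[float] = field(default_factory=list)
    pd_per_day: list[float] = field(default_factory=list)
    days: list[float] = field(default_factory=list)
    senescent_at: int | None = None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "donor": self.donor,
                "passage": self.passages,
                "pd": self.pd_per_passage,
                "cumulative_pd": self.cumulative_pd,
                "pd_per_day": self.pd_per_day,
                "days": self.days,
            }
        )


def population_doubling(record: PassageRecord) -> float:
    """``log2(N_H/N_1)`` for one passage; zero harvest is a culture failure."""
    if record.harvested_density == 0:
        raise CultureFailureError(
            f"donor {record.donor} passage {record.passage}: zero harvest, PD undefined"
        )
    return math.log2(record.harvested_density / record.seeded_density)


def cumulative_pd(records: list[PassageRecord]) -> GrowthCurve:
    """Running PD sum over one donor's passage series (ordered by passage).

    Gaps in the passage numbering are tolerated with a warning; the sum
    simply continues over the recorded passages.
    """
    if not records:
        return GrowthCurve(donor="")
    donors = {r.donor for r in records}
    if len(donors) > 1:
        raise ValueError(f"records span multiple donors: {sorted(donors)}")
    ordered = sorted(records, key=lambda r: r.passage)
    gaps = [
        (a.passage, b.passage)
        for a, b in zip(ordered, ordered[1:])
        if b.passage - a.passage > 1
    ]
    if gaps:
        warnings.warn(f"passage gaps {gaps}; cumulative sum continues", stacklevel=2)
    curve = GrowthCurve(donor=ordered[0].donor)
    total = 0.0
    for rec in ordered:
        pd_value = population_doubling(rec)
        total += pd_value
        curve.passages.append(rec.passage)
        curve.pd_per_passage.append(pd_value)
        curve.cumulative_pd.append(total)
        curve.pd_per_day.append(pd_value / rec.days_in_culture)
        curve.days.append(rec.days_in_culture)
    curve.senescent_at = flag_senescence(ordered)
    return curve


def flag_senescence(
    records: list[PassageRecord],
    max_confluency: float = 0.30,
    min_days: float = 14.0,
) -> int | None:
    """First passage with confluency below 30% sustained for two weeks.

    Both clauses must hold at harvest: the passage lasted at least
    ``min_days`` and confluency was still under ``max_confluency``.
    Records without confluency are not evaluable and are skipped with a
    warning.
    """
    for rec in sorted(records, key=lambda r: r.passage):
        conf = rec.confluency_at_harvest
        if conf is None or (isinstance(conf, float) and np.isnan(conf)):
            warnings.warn(
                f"donor {rec.donor} passage {rec.passage}: confluency missing, "
                "senescence rule not evaluable",
                stacklevel=2,
            )
            continue
        if rec.days_in_culture >= min_days and conf < max_confluency:
            return rec.passage
    return None
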