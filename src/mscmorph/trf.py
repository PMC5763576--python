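"""Mean telomere length from terminal restriction fragment densitometry.

A Southern-blot lane is a profile of optical density (OD) versus
migration position.  A molecular-weight ladder maps position to fragment
length (log-linear interpolation, the standard gel migration model), the
baseline is removed with a rolling-minimum estimate, and the mean TRF is
the OD-weighted mean fragment length

    mean TRF = Σ(ODᵢ · Lᵢ) / Σ(ODᵢ)

summed over profile samples i whose lengths fall in the analysis window
(3–20 kbp by default, both ends inclusive).  Telomere shortening rates
are per-donor regression slopes of mean TRF (in bp) on cumulative
population doublings, reported as positive bp lost per PD.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "LadderCalibration",
    "LaneProfile",
    "TRFResult",
    "calibrate_ladder",
    "subtract_background",
    "mean_trf",
    "shortening_rate",
    "DEFAULT_WINDOW_KBP",
]

DEFAULT_WINDOW_KBP = (3.0, 20.0)


class CalibrationError(ValueError):
    pass


@dataclass(frozen=True)
class LadderCalibration:
    """Monotone position→length map from ladder rungs (log-linear)."""

    rung_positions: np.ndarray
    rung_lengths: np.ndarray  # kbp, decreasing with position

    @property
    def position_span(self) -> tuple[float, float]:
        return float(self.rung_positions[0]), float(self.rung_positions[-1])

    @property
    def length_span(self) -> tuple[float, float]:
        return float(self.rung_lengths.min()), float(self.rung_lengths.max())

    def position_to_length(self, positions) -> np.ndarray:
        """kbp at the given migration positions; refuses extrapolation."""
        p = np.asarray(positions, dtype=float)
        lo, hi = self.position_span
        if np.any(p < lo - 1e-9) or np.any(p > hi + 1e-9):
            raise CalibrationError(
                f"position outside calibrated span [{lo}, {hi}]; extrapolation refused"
            )
        return 10.0 ** np.interp(p, self.rung_positions, np.log10(self.rung_lengths))

    def length_to_position(self, lengths) -> np.ndarray:
        """Inverse map; defined on the rung length span only."""
        L = np.asarray(lengths, dtype=float)
        lo, hi = self.length_span
        if np.any(L < lo - 1e-9) or np.any(L > hi + 1e-9):
            raise CalibrationError(
                f"length outside calibrated span [{lo}, {hi}] kbp; extrapolation refused"
            )
        # log10(length) decreases with position: interpolate on reversed axes
        return np.interp(
            np.log10(L),
            np.log10(self.rung_lengths[::-1]),
            self.rung_positions[::-1],
        )


def calibrate_ladder(rungs) -> LadderCalibration:
    """Fit the position→kbp map from ``(position, kbp)`` rung pairs.

    Requires at least three rungs, strictly monotone positions and
    strictly opposite-monotone lengths (long fragments migrate least).
    """
    rungs = sorted((float(p), float(L)) for p, L in rungs)
    if len(rungs) < 3:
        raise CalibrationError("at least 3 ladder rungs required")
    pos = np.array([p for p, _ in rungs])
    lengths = np.array([L for _, L in rungs])
    if np.any(np.diff(pos) <= 0):
        raise CalibrationError("rung positions must be strictly monotone")
    if np.any(np.diff(lengths) >= 0):
        raise CalibrationError("rung lengths must decrease strictly with position")
    if np.any(lengths <= 0):
        raise CalibrationError("rung lengths must be positive")
    return LadderCalibration(rung_positions=pos, rung_lengths=lengths)


@dataclass
class LaneProfile:
    """OD versus migration position for one gel lane."""

    positions: np.ndarray
    od: np.ndarray
    lane_id: str = "lane"

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        self.od = np.asarray(self.od, dtype=float)
        if self.positions.shape != self.od.shape or self.positions.ndim != 1:
            raise ValueError("positions and od must be equal-length 1-D arrays")

    @classmethod
    def from_csv(cls, path, lane_id: str | None = None) -> "LaneProfile":
        df = pd.read_csv(path)
        return cls(
            positions=df.iloc[:, 0].to_numpy(),
            od=df.iloc[:, 1].to_numpy(),
            lane_id=lane_id or str(path),
        )


@dataclass(frozen=True)
class TRFResult:
    mean_trf: float  # kbp
    window: tuple[float, float]
    lane_id: str
    qc_flags: tuple[str, ...] = field(default_factory=tuple)


def subtract_background(
    profile: LaneProfile, window: int = 51
) -> LaneProfile:
    """Remove the slowly varying film baseline with a rolling minimum.

    The rolling minimum (width ``window`` samples) is smoothed with a
    moving average of the same width and subtracted; negative residuals
    are clipped to zero.
    """
    from scipy.ndimage import minimum_filter1d, uniform_filter1d

    n = profile.od.size
    if window < 3:
        raise ValueError("window must be >= 3 samples")
    if window > n:
        raise ValueError(f"window ({window}) longer than profile ({n})")
    baseline = uniform_filter1d(
        minimum_filter1d(profile.od, size=window, mode="nearest"),
        size=window,
        mode="nearest",
    )
    od = np.clip(profile.od - baseline, 0.0, None)
    return LaneProfile(positions=profile.positions.copy(), od=od, lane_id=profile.lane_id)


def mean_trf(
    profile: LaneProfile,
    cal: LadderCalibration,
    window: tuple[float, float] = DEFAULT_WINDOW_KBP,
) -> TRFResult:
    """OD-weighted mean fragment length within the analysis window.

    Profile samples outside the ladder's calibrated span are excluded
    (flagged) rather than extrapolated; zero total OD inside the window
    is an error ("no telomeric signal").
    """
    if np.any(profile.od < 0):
        raise ValueError("negative OD; subtract the background first")
    lo_p, hi_p = cal.position_span
    in_span = (profile.positions >= lo_p) & (profile.positions <= hi_p)
    flags = []
    if not in_span.all():
        flags.append("samples_outside_ladder_span")
    lengths = np.full(profile.positions.shape, np.nan)
    lengths[in_span] = cal.position_to_length(profile.positions[in_span])
    lo, hi = window
    # inclusive bounds with a float-roundtrip tolerance so a band at
    # exactly 3 or 20 kbp is never dropped by interpolation noise
    eps = 1e-9
    sel = in_span & (lengths >= lo - eps) & (lengths <= hi + eps)
    total = profile.od[sel].sum()
    if not sel.any() or total <= 0:
        raise ValueError(f"no telomeric signal in the {window} kbp window")
    outside_fraction = profile.od[~sel].sum() / max(profile.od.sum(), 1e-300)
    if outside_fraction > 0.5:
        flags.append("majority_signal_outside_window")
    value = float(np.sum(profile.od[sel] * lengths[sel]) / total)
    return TRFResult(mean_trf=value, window=window, lane_id=profile.lane_id, qc_flags=tuple(flags))


def shortening_rate(results: pd.DataFrame) -> tuple[float, float, pd.Series]:
    """Cohort telomere shortening rate in bp per population doubling.

    ``results`` needs columns ``donor``, ``pd`` (cumulative population
    doublings) and ``mean_trf`` (kbp).  Per donor, an ordinary
    least-squares slope of length (bp) on PD is computed and sign-flipped
    so shortening is positive; donors with fewer than two timepoints are
    excluded with a warning.  Returns ``(mean, sd, per_donor_rates)``
    with the SD across donors (ddof=1; NaN for a single donor).
    """
    rates = {}
    for donor, sub in results.groupby("donor"):
        if len(sub) < 2:
            warnings.warn(f"donor {donor}: single timepoint, excluded", stacklevel=2)
            continue
        slope = np.polyfit(sub["pd"].to_numpy(), sub["mean_trf"].to_numpy() * 1000.0, 1)[0]
        rates[donor] = -slope
    if not rates:
        raise ValueError("no donor with >= 2 timepoints")
    series = pd.Series(rates, name="bp_per_pd")
    sd = float(series.std(ddof=1)) if len(series) > 1 else float("nan")
    return float(series.mean()), sd, series
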