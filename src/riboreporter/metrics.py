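"""Reporter-assay statistics.

Central quantity: fold induction (FI) of total luciferase activity.  For a
technical triplicate at 0 mM fluoride and a triplicate at x mM, each well's
OD-normalized luminescence lum/OD is summed over timepoints m..n,

    F = sum_{i=m..n} (lum/OD)(i)                       (per well)

and FI is the ratio of the triplicate means of those totals,

    FI = av(F_x) / av(F_0),

i.e. with-ligand over without-ligand, so an inducing riboswitch gives
FI > 1.  The uncertainty combines the two triplicates' relative standard
deviations in quadrature (first-order propagation for a ratio of
independent means):

    sigma_FI = FI * sqrt( (sd(F_0)/av(F_0))^2 + (sd(F_x)/av(F_x))^2 ).

Standard deviations are sample (n-1) SDs throughout.

For constructs whose luminescence is close to background, a restricted time
window can be found automatically: the rolling mean over ~1 h of triplicate
luminescence (nine data points at 20-min sampling: 3 consecutive timepoints
x 3 wells) must exceed the same nine points' SD for at least 2 h in a row.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import DataError
from .plate_io import WellSeries

__all__ = [
    "FoldInductionResult",
    "BackgroundWindowConfig",
    "normalized_expression",
    "total_activity",
    "fold_induction",
    "fi_error",
    "peak_lum_over_od",
    "average_lum_over_od",
    "above_background_window",
    "restricted_fold_induction",
    "parse_window",
]

OD_FLOOR = 1e-4


@dataclass(frozen=True)
class FoldInductionResult:
    """Fold induction of total luciferase activity with propagated error.

    ``f_minus``/``f_plus`` are the triplicate means of the per-well totals
    without/with ligand; ``m``/``n`` the inclusive post-crop summation
    bounds; ``window`` the (start_min, end_min) restriction, if any.
    """

    FI: float
    sigma_FI: float
    m: int
    n: int
    f_minus: float
    f_plus: float
    sd_F0: float
    av_F0: float
    sd_Fx: float
    av_Fx: float
    window: tuple[float, float] | None = None
    totals_F0: tuple[float, ...] = field(default_factory=tuple)
    totals_Fx: tuple[float, ...] = field(default_factory=tuple)


@dataclass(frozen=True)
class BackgroundWindowConfig:
    """Above-background window detection parameters.

    rolling_points: data points per rolling block; 9 = 3 consecutive
        timepoints x 3 replicate wells, about 1 h at 20-min sampling.
    persistence_hours: minimum run length of above-background blocks.
    interval_min: nominal sampling interval, minutes.
    """

    rolling_points: int = 9
    persistence_hours: float = 2.0
    interval_min: float = 20.0

    def __post_init__(self):
        if self.rolling_points < 2:
            raise ValueError("rolling_points must be >= 2")
        if self.persistence_hours <= 0:
            raise ValueError("persistence_hours must be > 0")

    def timepoints_per_block(self, n_wells: int) -> int:
        k = int(round(self.rolling_points / max(n_wells, 1)))
        return max(k, 1)


def normalized_expression(w: WellSeries, od_floor: float = OD_FLOOR) -> np.ndarray:
    """Element-wise lum/OD on the well's grid.

    OD values below ``od_floor`` are invalid for division (they would make
    lum/OD blow up); their timepoints are reported in the error.
    """
    bad = np.nonzero(w.od < od_floor)[0]
    if bad.size:
        raise DataError(
            f"well {w.well_id}: OD below {od_floor} at timepoint indices {bad.tolist()}"
        )
    return w.lum / w.od


def total_activity(x: np.ndarray, m: int, n: int) -> float:
    """Sum of a lum/OD series over inclusive index bounds [m, n]."""
    x = np.asarray(x, dtype=float)
    if not (0 <= m <= n < len(x)):
        raise DataError(f"summation bounds [{m}, {n}] out of range for length {len(x)}")
    return float(np.sum(x[m : n + 1]))


def fi_error(FI: float, sd_F0: float, av_F0: float, sd_Fx: float, av_Fx: float) -> float:
    """Propagated SD of FI from the two triplicates' dispersions.

    sigma_FI = FI * sqrt((sd_F0/av_F0)^2 + (sd_Fx/av_Fx)^2)
    """
    if av_F0 == 0 or av_Fx == 0:
        raise DataError("fi_error: zero triplicate mean")
    return abs(FI) * float(np.hypot(sd_F0 / av_F0, sd_Fx / av_Fx))


def _well_totals(group: list[WellSeries], m: int, n: int) -> np.ndarray:
    return np.array([total_activity(normalized_expression(w), m, n) for w in group])


def fold_induction(
    group0: list[WellSeries],
    groupx: list[WellSeries],
    m: int = 0,
    n: int | None = None,
    window: tuple[float, float] | None = None,
) -> FoldInductionResult:
    """Fold induction between a 0 mM group and an x mM group.

    Both groups must be cropped and harmonized to one post-crop length; the
    summation runs over post-crop indices ``m..n`` (``n`` defaults to the
    last index).  Requires >= 2 wells per group (the SD is undefined
    otherwise) and a positive without-ligand mean total.
    """
    if len(group0) < 2 or len(groupx) < 2:
        raise DataError("fold_induction needs >= 2 wells per group")
    lengths = {len(w) for w in group0} | {len(w) for w in groupx}
    if len(lengths) != 1:
        raise DataError(f"groups not harmonized: lengths {sorted(lengths)}")
    length = lengths.pop()
    if length == 0:
        raise DataError("empty series in fold_induction")
    if n is None:
        n = length - 1

    totals0 = _well_totals(group0, m, n)
    totalsx = _well_totals(groupx, m, n)
    av_F0 = float(np.mean(totals0))
    av_Fx = float(np.mean(totalsx))
    sd_F0 = float(np.std(totals0, ddof=1))
    sd_Fx = float(np.std(totalsx, ddof=1))
    if av_F0 <= 0:
        raise DataError(f"without-ligand mean total activity is {av_F0}; FI undefined")
    FI = av_Fx / av_F0
    return FoldInductionResult(
        FI=FI,
        sigma_FI=fi_error(FI, sd_F0, av_F0, sd_Fx, av_Fx),
        m=m,
        n=n,
        f_minus=av_F0,
        f_plus=av_Fx,
        sd_F0=sd_F0,
        av_F0=av_F0,
        sd_Fx=sd_Fx,
        av_Fx=av_Fx,
        window=window,
        totals_F0=tuple(totals0),
        totals_Fx=tuple(totalsx),
    )


def peak_lum_over_od(group: list[WellSeries] | WellSeries) -> tuple[float, float]:
    """Peak expression: max raw luminescence divided by the same timepoint's OD.

    The peak timepoint is located on RAW luminescence (not on lum/OD); ties
    break to the earliest timepoint.  For a group, wells are pooled and the
    single highest reading wins.  Returns ``(peak_lum_over_od, peak_time)``.
    """
    wells = [group] if isinstance(group, WellSeries) else list(group)
    if not wells or any(len(w) == 0 for w in wells):
        raise DataError("peak_lum_over_od: empty series")
    best = None
    for w in wells:
        i = int(np.argmax(w.lum))  # argmax returns the first maximum
        cand = (w.lum[i], -w.times[i], w.well_id, i, w)
        if best is None or (cand[0], cand[1]) > (best[0], best[1]):
            best = cand
    lum_max, _, _, i, w = best
    if w.od[i] < OD_FLOOR:
        raise DataError(f"well {w.well_id}: OD too small at peak for normalization")
    return float(lum_max / w.od[i]), float(w.times[i])


def average_lum_over_od(group: list[WellSeries]) -> float:
    """Triplicate-average expression as a ratio of means.

    (mean of all lum readings over all wells and timepoints) divided by
    (mean of all od readings over all wells and timepoints) — NOT the mean
    of per-timepoint lum/OD ratios.
    """
    if not group:
        raise DataError("average_lum_over_od: empty group")
    lengths = {len(w) for w in group}
    if len(lengths) != 1:
        raise DataError("average_lum_over_od: group not harmonized")
    all_lum = np.concatenate([w.lum for w in group])
    all_od = np.concatenate([w.od for w in group])
    mean_od = float(np.mean(all_od))
    if abs(mean_od) < OD_FLOOR:
        raise DataError("average_lum_over_od: mean OD is ~0")
    return float(np.mean(all_lum)) / mean_od


def above_background_window(
    group: list[WellSeries],
    cfg: BackgroundWindowConfig | None = None,
) -> list[tuple[float, float]]:
    """Find time windows where triplicate luminescence is above background.

    A rolling block pools ``k`` consecutive timepoints across all wells of
    the group (k chosen so the block holds ~``rolling_points`` readings;
    with triplicates and the default 9 that is 3 timepoints, about 1 h at
    20-min sampling).  A block is above background when the mean of its
    readings exceeds their sample SD.  Blocks advance one timepoint at a
    time (overlapping).  Maximal runs of consecutive above-background blocks
    whose time span reaches ``persistence_hours`` are reported as
    ``(start_time, end_time)`` on the group's common grid.
    """
    cfg = cfg or BackgroundWindowConfig()
    if not group:
        raise DataError("above_background_window: empty group")
    lengths = {len(w) for w in group}
    if len(lengths) != 1:
        raise DataError("above_background_window: group not harmonized")
    length = lengths.pop()
    k = cfg.timepoints_per_block(len(group))
    if length < k:
        raise DataError(f"series of length {length} shorter than one {k}-timepoint block")
    times = group[0].times
    lum = np.stack([w.lum for w in group])  # wells x timepoints

    n_blocks = length - k + 1
    above = np.empty(n_blocks, dtype=bool)
    for b in range(n_blocks):
        block = lum[:, b : b + k].ravel()
        above[b] = np.mean(block) > np.std(block, ddof=1)

    windows: list[tuple[float, float]] = []
    min_span = cfg.persistence_hours * 60.0
    b = 0
    while b < n_blocks:
        if not above[b]:
            b += 1
            continue
        start = b
        while b < n_blocks and above[b]:
            b += 1
        end = b - 1  # last above block in the run
        t0, t1 = float(times[start]), float(times[end + k - 1])
        if t1 - t0 >= min_span:
            windows.append((t0, t1))
    return windows


def _window_to_bounds(times: np.ndarray, window: tuple[float, float]) -> tuple[int, int]:
    start, end = window
    idx = np.nonzero((times >= start) & (times <= end))[0]
    if idx.size == 0:
        raise DataError(f"window {window} does not intersect the time grid")
    return int(idx[0]), int(idx[-1])


def restricted_fold_induction(
    group0: list[WellSeries],
    groupx: list[WellSeries],
    window: tuple[float, float],
) -> FoldInductionResult:
    """Fold induction restricted to a time window.

    The window (minutes, inclusive) is mapped to grid indices on the groups'
    shared grid; the computation is then identical to :func:`fold_induction`
    with those summation bounds, and the window is recorded in the result.
    Windows typically come from :func:`above_background_window` but may be
    user-supplied (e.g. 22h00-29h20, via :func:`parse_window`).
    """
    if not group0:
        raise DataError("restricted_fold_induction: empty group")
    m, n = _window_to_bounds(group0[0].times, window)
    return fold_induction(group0, groupx, m=m, n=n, window=window)


def parse_window(text: str) -> tuple[float, float]:
    """Parse ``"22:00-29:20"`` or ``"22h00-29h20"`` into minutes.

    Hours may exceed 24 (assay clocks run 30-60 h).
    """
    try:
        lo, hi = text.strip().split("-")
        out = []
        for part in (lo, hi):
            part = part.strip().lower().replace("h", ":")
            if ":" in part:
                h, m = part.split(":")
                out.append(float(h) * 60 + float(m or 0))
            else:
                out.append(float(part) * 60)
        start, end = out
    except (ValueError, AttributeError) as exc:
        raise ValueError(f"cannot parse window {text!r}; expected like '22h00-29h20'") from exc
    if end <= start:
        raise ValueError(f"window {text!r} is empty or reversed")
    return start, end
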