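"""Preprocessing of reporter time-courses.

The pipeline is: (1) subtract the per-timepoint mean of the blank wells from
every sample well (both luminescence and OD600 — media luminesce and absorb
a little); (2) crop each well to start at the first reading with OD600 at or
above a growth gate (default 0.1), so integration windows begin once a
culture is actually growing; (3) truncate all wells of one comparison to the
same number of post-crop timepoints; (4) summarize stationary-phase biomass
as the mean of the last readings of the OD curve (default tail: 58 points).

Negative post-subtraction values are kept by default so that summed
statistics stay unbiased; ``clip_zero`` exists for display purposes only.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np

from .errors import DataError
from .plate_io import PlateLayout, WellSeries

__all__ = [
    "PreprocessConfig",
    "subtract_blanks",
    "crop_to_growth",
    "harmonize_length",
    "plateau_od",
]


@dataclass(frozen=True)
class PreprocessConfig:
    """Knobs for the preprocessing stage.

    od_start_threshold : OD600 units; a well's analysis window opens at the
        first reading >= this value (default 0.1).
    plateau_tail_points : number of final OD readings averaged for the
        plateau estimate (default 58).
    negative_policy : 'keep' retains negative blank-subtracted values,
        'clip_zero' floors them at 0.
    """

    od_start_threshold: float = 0.1
    plateau_tail_points: int = 58
    negative_policy: str = "keep"

    def __post_init__(self):
        if self.od_start_threshold <= 0:
            raise ValueError("od_start_threshold must be > 0")
        if self.plateau_tail_points < 1:
            raise ValueError("plateau_tail_points must be >= 1")
        if self.negative_policy not in ("keep", "clip_zero"):
            raise ValueError("negative_policy must be 'keep' or 'clip_zero'")


def subtract_blanks(
    series: dict[str, WellSeries],
    layout: PlateLayout,
    cfg: PreprocessConfig | None = None,
) -> dict[str, WellSeries]:
    """Subtract the per-timepoint blank mean from every sample well.

    Both luminescence and OD are corrected.  Blank wells must share the
    sample wells' time grid and are removed from the returned set.
    """
    cfg = cfg or PreprocessConfig()
    blank_ids = [w for w in layout.blanks() if w in series]
    if not blank_ids:
        raise DataError("no blank wells present in the data")
    blanks = [series[w] for w in blank_ids]
    grid = blanks[0].times
    for b in blanks[1:]:
        if not np.array_equal(b.times, grid):
            raise DataError(f"blank well {b.well_id} is not on the shared time grid")
    blank_lum = np.mean([b.lum for b in blanks], axis=0)
    blank_od = np.mean([b.od for b in blanks], axis=0)

    out: dict[str, WellSeries] = {}
    negatives = []
    for well_id, s in series.items():
        meta = layout.wells.get(well_id)
        if well_id in blank_ids or (meta is not None and meta.is_blank):
            continue
        if not np.array_equal(s.times, grid):
            raise DataError(f"well {well_id} is not on the blanks' time grid")
        lum = s.lum - blank_lum
        od = s.od - blank_od
        if np.any(lum < 0):
            negatives.append(well_id)
        if cfg.negative_policy == "clip_zero":
            lum = np.clip(lum, 0.0, None)
            od = np.clip(od, 0.0, None)
        out[well_id] = replace(s, lum=lum, od=od)
    if negatives and cfg.negative_policy == "keep":
        warnings.warn(
            f"negative blank-subtracted luminescence retained for wells {sorted(negatives)}"
        )
    return out


def crop_to_growth(w: WellSeries, cfg: PreprocessConfig | None = None) -> WellSeries:
    """Crop a well to start at its first reading with OD >= the growth gate.

    Cropping is per-well, on each well's own clock.  If the gate is never
    reached the returned series is empty and a warning is issued; downstream
    steps exclude such wells.
    """
    cfg = cfg or PreprocessConfig()
    idx = np.nonzero(w.od >= cfg.od_start_threshold)[0]
    if idx.size == 0:
        warnings.warn(
            f"well {w.well_id}: OD never reached {cfg.od_start_threshold}; series emptied"
        )
        return w.slice(len(w), len(w))
    return w.slice(int(idx[0]))


def harmonize_length(groups: dict[str, list[WellSeries]]) -> dict[str, list[WellSeries]]:
    """Truncate every series of a comparison to the shortest post-crop length.

    Each series keeps its first ``n*`` points, where ``n*`` is the minimum
    length across all wells of all groups being compared, so that summation
    statistics use the same number of timepoints everywhere.
    """
    lengths = []
    for name, members in groups.items():
        for s in members:
            if len(s) == 0:
                raise DataError(f"well {s.well_id} (group {name}) has an empty series")
            lengths.append(len(s))
    if not lengths:
        raise DataError("no series to harmonize")
    n_star = min(lengths)
    return {name: [s.slice(0, n_star) for s in members] for name, members in groups.items()}


def plateau_od(w: WellSeries, cfg: PreprocessConfig | None = None) -> float:
    """Stationary-phase OD: mean of the final ``plateau_tail_points`` OD readings.

    Series shorter than the tail are averaged whole, with a warning.
    """
    cfg = cfg or PreprocessConfig()
    if len(w) == 0:
        raise DataError(f"well {w.well_id}: empty series has no plateau")
    k = min(cfg.plateau_tail_points, len(w))
    if len(w) < cfg.plateau_tail_points:
        warnings.warn(
            f"well {w.well_id}: only {len(w)} readings available for a "
            f"{cfg.plateau_tail_points}-point plateau tail"
        )
    tail = w.od[-k:]
    if np.all(tail == tail[0]):  # constant plateaus stay exact
        return float(tail[0])
    return float(np.mean(tail))
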