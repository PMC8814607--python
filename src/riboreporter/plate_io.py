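"""Reading, writing and validating microplate reporter time-courses.

The on-disk model is a long-format table with one row per (well, timepoint)
carrying a luminescence reading (RLU) and an OD600 reading, plus a separate
plate-layout file mapping wells to sample metadata (construct, fluoride
concentration, technical-replicate group, blank flag).  Times are stored in
minutes from assay start; plate readers in this class of assay record every
20 minutes for 30-60 h.

No resampling or interpolation is ever performed: all wells of one plate are
expected to share a single nominal time grid, and the summation statistics
downstream are only meaningful on the grid the instrument produced.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import yaml

from .errors import ConfigError, DataError, FormatError

__all__ = [
    "WellSeries",
    "SampleMeta",
    "PlateLayout",
    "Dialect",
    "LONG_CSV",
    "ValidationReport",
    "read_timecourse",
    "write_timecourse",
    "read_layout",
    "write_layout",
    "validate_plate",
]


@dataclass(frozen=True)
class WellSeries:
    """One well's aligned time grid with luminescence and OD600 readings.

    Parameters
    ----------
    well_id : str
        Plate coordinate, e.g. ``"A1"``.
    times : ndarray
        Minutes from assay start; strictly increasing, nominally uniform.
    lum : ndarray
        Luminescence per timepoint, RLU.  May be negative only after blank
        subtraction.
    od : ndarray
        Optical density at 600 nm per timepoint (dimensionless).
    """

    well_id: str
    times: np.ndarray
    lum: np.ndarray
    od: np.ndarray

    def __post_init__(self):
        times = np.asarray(self.times, dtype=float)
        lum = np.asarray(self.lum, dtype=float)
        od = np.asarray(self.od, dtype=float)
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "lum", lum)
        object.__setattr__(self, "od", od)
        if not (len(times) == len(lum) == len(od)):
            raise DataError(
                f"well {self.well_id}: times/lum/od lengths differ "
                f"({len(times)}/{len(lum)}/{len(od)})"
            )
        if len(times) > 1 and not np.all(np.diff(times) > 0):
            raise DataError(f"well {self.well_id}: times not strictly increasing")
        if not (np.all(np.isfinite(lum)) and np.all(np.isfinite(od))):
            raise DataError(f"well {self.well_id}: non-finite readings")

    def __len__(self) -> int:
        return len(self.times)

    def slice(self, start: int, stop: int | None = None) -> "WellSeries":
        """Return the sub-series of points ``start:stop`` (numpy slicing rules)."""
        sl = slice(start, stop)
        return replace(self, times=self.times[sl], lum=self.lum[sl], od=self.od[sl])

    def equals(self, other: "WellSeries") -> bool:
        return (
            self.well_id == other.well_id
            and np.array_equal(self.times, other.times)
            and np.array_equal(self.lum, other.lum)
            and np.array_equal(self.od, other.od)
        )


@dataclass(frozen=True)
class SampleMeta:
    """Metadata for one well: what grows in it and under which condition."""

    strain: str = ""
    construct: str = ""
    promoter: str = ""
    utr: str = ""
    ligand_mM: float = 0.0
    replicate_group: str = ""
    is_blank: bool = False

    def __post_init__(self):
        if self.ligand_mM < 0:
            raise ConfigError(f"ligand_mM must be >= 0, got {self.ligand_mM}")


@dataclass
class PlateLayout:
    """Map from well id to :class:`SampleMeta`."""

    wells: dict[str, SampleMeta] = field(default_factory=dict)

    def __post_init__(self):
        for group, members in self.groups().items():
            if not members:
                raise ConfigError(f"replicate_group {group!r} has no wells")

    def groups(self) -> dict[str, list[str]]:
        """Non-blank replicate groups, each mapped to its sorted well ids."""
        out: dict[str, list[str]] = {}
        for well_id, meta in self.wells.items():
            if meta.is_blank or not meta.replicate_group:
                continue
            out.setdefault(meta.replicate_group, []).append(well_id)
        return {g: sorted(ws) for g, ws in out.items()}

    def blanks(self) -> list[str]:
        return sorted(w for w, m in self.wells.items() if m.is_blank)

    def group_meta(self, group: str) -> SampleMeta:
        for meta in self.wells.values():
            if meta.replicate_group == group and not meta.is_blank:
                return meta
        raise ConfigError(f"unknown replicate_group {group!r}")


@dataclass(frozen=True)
class Dialect:
    """Column-name mapping for a long-format plate-reader export."""

    name: str = "long_csv"
    well: str = "well"
    time: str = "time_min"
    lum: str = "lum"
    od: str = "od"


LONG_CSV = Dialect()

_DIALECTS = {"long_csv": LONG_CSV}


def _resolve_dialect(dialect: Dialect | str | None) -> Dialect:
    if dialect is None:
        return LONG_CSV
    if isinstance(dialect, Dialect):
        return dialect
    try:
        return _DIALECTS[dialect]
    except KeyError:
        raise ConfigError(f"unknown dialect {dialect!r}") from None


def read_timecourse(
    path,
    dialect: Dialect | str | None = None,
    interval_min: float | None = 20.0,
) -> dict[str, WellSeries]:
    """Read a long-format plate-reader export into per-well series.

    Rows are sorted by time within each well, so the input row order does not
    matter.  Rows with missing values are rejected (not imputed).  When
    ``interval_min`` is given, grid uniformity is checked against it and
    deviations raise a warning (never resampled).
    """
    dia = _resolve_dialect(dialect)
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in (dia.well, dia.time, dia.lum, dia.od) if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing column(s) {missing}; found {list(df.columns)}")
    if df[[dia.well, dia.time, dia.lum, dia.od]].isna().any().any():
        bad = df[df[[dia.well, dia.time, dia.lum, dia.od]].isna().any(axis=1)]
        raise DataError(f"{path}: rows with missing values for wells {sorted(bad[dia.well].unique())}")

    out: dict[str, WellSeries] = {}
    for well_id, grp in df.groupby(dia.well, sort=True):
        grp = grp.sort_values(dia.time, kind="mergesort")
        t = grp[dia.time].to_numpy(dtype=float)
        if len(t) > 1 and np.any(np.diff(t) <= 0):
            raise DataError(f"{path}: duplicated or non-monotone time for well {well_id}")
        out[str(well_id)] = WellSeries(
            well_id=str(well_id),
            times=t,
            lum=grp[dia.lum].to_numpy(dtype=float),
            od=grp[dia.od].to_numpy(dtype=float),
        )

    grids = {w: (len(s), s.times[0] if len(s) else None) for w, s in out.items()}
    if len({g for g in grids.values()}) > 1:
        warnings.warn("wells are not all on the same time grid; no resampling performed")
    if interval_min is not None:
        for w, s in out.items():
            if len(s) > 1 and not np.allclose(np.diff(s.times), interval_min):
                warnings.warn(
                    f"well {w}: grid spacing deviates from declared {interval_min} min interval"
                )
                break
    return out


def write_timecourse(series: dict[str, WellSeries], path, dialect: Dialect | str | None = None) -> None:
    """Write per-well series back to the long CSV format (round-trip safe)."""
    dia = _resolve_dialect(dialect)
    rows = []
    for well_id in sorted(series):
        s = series[well_id]
        for t, l, o in zip(s.times, s.lum, s.od):
            rows.append({dia.well: well_id, dia.time: t, dia.lum: l, dia.od: o})
    df = pd.DataFrame(rows, columns=[dia.well, dia.time, dia.lum, dia.od])
    # repr-level float precision so text round-trips are exact
    df.to_csv(path, index=False, float_format=lambda v: repr(float(v)))


def _meta_from_record(well_id: str, rec: dict) -> SampleMeta:
    known = {"strain", "construct", "promoter", "utr", "ligand_mM", "replicate_group", "is_blank"}
    unknown = set(rec) - known
    if unknown:
        raise ConfigError(f"well {well_id}: unknown layout keys {sorted(unknown)}")
    try:
        return SampleMeta(
            strain=str(rec.get("strain", "") or ""),
            construct=str(rec.get("construct", "") or ""),
            promoter=str(rec.get("promoter", "") or ""),
            utr=str(rec.get("utr", "") or ""),
            ligand_mM=float(rec.get("ligand_mM", 0.0) or 0.0),
            replicate_group=str(rec.get("replicate_group", "") or ""),
            is_blank=bool(rec.get("is_blank", False)),
        )
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"well {well_id}: bad metadata ({exc})") from exc


def read_layout(path) -> PlateLayout:
    """Read a plate layout from YAML (``wells: {A1: {...}}``) or long CSV.

    A well listed twice, a negative ligand concentration, or a declared
    replicate group with zero wells is a configuration error.
    """
    path = str(path)
    if path.endswith((".yaml", ".yml")):
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        if not isinstance(doc, dict) or "wells" not in doc:
            raise ConfigError(f"{path}: layout YAML must have a top-level 'wells' mapping")
        wells = {}
        for well_id, rec in doc["wells"].items():
            wells[str(well_id)] = _meta_from_record(str(well_id), rec or {})
        declared = doc.get("groups")
        layout = PlateLayout(wells=wells)
        if declared:
            present = set(layout.groups())
            for g in declared:
                if g not in present:
                    raise ConfigError(f"{path}: declared replicate_group {g!r} has no wells")
        return layout

    df = pd.read_csv(path)
    if "well" not in df.columns:
        raise ConfigError(f"{path}: layout CSV needs a 'well' column")
    dup = df["well"][df["well"].duplicated()]
    if not dup.empty:
        raise ConfigError(f"{path}: well(s) listed twice: {sorted(dup.unique())}")
    wells = {}
    for rec in df.to_dict("records"):
        well_id = str(rec.pop("well"))
        rec = {k: v for k, v in rec.items() if not (isinstance(v, float) and np.isnan(v))}
        wells[well_id] = _meta_from_record(well_id, rec)
    return PlateLayout(wells=wells)


def write_layout(layout: PlateLayout, path) -> None:
    """Serialize a layout to YAML in a stable key order."""
    doc = {"wells": {}}
    for well_id in sorted(layout.wells):
        m = layout.wells[well_id]
        rec = {}
        if m.is_blank:
            rec["is_blank"] = True
        else:
            for key in ("strain", "construct", "promoter", "utr"):
                if getattr(m, key):
                    rec[key] = getattr(m, key)
            rec["ligand_mM"] = float(m.ligand_mM)
            rec["replicate_group"] = m.replicate_group
        doc["wells"][well_id] = rec
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=True)


@dataclass
class ValidationReport:
    """Report-only reconciliation of a layout against the measured wells."""

    missing_from_data: list[str] = field(default_factory=list)
    unassigned_wells: list[str] = field(default_factory=list)
    group_size_warnings: dict[str, int] = field(default_factory=dict)

    @property
    def ok(self) -> bool:
        return not (self.missing_from_data or self.unassigned_wells or self.group_size_warnings)

    def lines(self) -> list[str]:
        out = []
        for w in self.missing_from_data:
            out.append(f"layout well {w} missing from data")
        for w in self.unassigned_wells:
            out.append(f"data well {w} not assigned in layout")
        for g, n in self.group_size_warnings.items():
            out.append(f"warning: replicate_group {g} has {n} wells (expected 3)")
        return out


def validate_plate(layout: PlateLayout, series: dict[str, WellSeries]) -> ValidationReport:
    """Reconcile layout vs data; triplicates are expected but not enforced."""
    rep = ValidationReport()
    rep.missing_from_data = sorted(set(layout.wells) - set(series))
    rep.unassigned_wells = sorted(set(series) - set(layout.wells))
    for group, members in layout.groups().items():
        if len(members) != 3:
            rep.group_size_warnings[group] = len(members)
    return rep
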