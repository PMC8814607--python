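"""Model/Results interface over the reporter-assay pipeline.

:class:`ReporterAssay` is built from a plate of measured wells plus its
layout (statsmodels-style: the model holds data and configuration), and
``fit()`` runs blank subtraction, growth-gated cropping, timepoint
harmonization and the fold-induction statistic for every 0-mM-vs-x-mM
comparison, returning a :class:`ReporterAssayResults` with the estimates,
their propagated uncertainties, per-well diagnostics and a ``summary()``
table.

>>> assay = ReporterAssay.from_csv("plate.csv", "layout.yaml")
>>> res = assay.fit()
>>> print(res.summary())
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import metrics, preprocess
from .errors import ConfigError, DataError
from .metrics import BackgroundWindowConfig, FoldInductionResult
from .plate_io import (
    PlateLayout,
    ValidationReport,
    WellSeries,
    read_layout,
    read_timecourse,
    validate_plate,
)
from .preprocess import PreprocessConfig

__all__ = ["ReporterAssay", "ReporterAssayResults"]


class ReporterAssay:
    """A riboswitch reporter plate assay ready for analysis.

    Parameters
    ----------
    series : dict[str, WellSeries]
        Raw measured wells (blanks included).
    layout : PlateLayout
        Well-to-sample mapping.
    config : PreprocessConfig, optional
        Blank/crop/plateau settings (defaults: OD gate 0.1, 58-point tail).
    window_config : BackgroundWindowConfig, optional
        Above-background window detection settings.
    """

    def __init__(
        self,
        series: dict[str, WellSeries],
        layout: PlateLayout,
        config: PreprocessConfig | None = None,
        window_config: BackgroundWindowConfig | None = None,
    ):
        self.series = dict(series)
        self.layout = layout
        self.config = config or PreprocessConfig()
        self.window_config = window_config or BackgroundWindowConfig()

    @classmethod
    def from_csv(cls, data_path, layout_path, dialect=None, **kwargs) -> "ReporterAssay":
        """Build an assay from a long-format CSV export and a layout file."""
        return cls(read_timecourse(data_path, dialect=dialect), read_layout(layout_path), **kwargs)

    # ------------------------------------------------------------------ #

    def validate(self) -> ValidationReport:
        """Reconcile layout against data (report-only)."""
        return validate_plate(self.layout, self.series)

    def default_pairs(self) -> list[tuple[str, str]]:
        """All (0 mM group, x mM group) comparisons sharing a construct."""
        by_construct: dict[tuple[str, str], dict[str, tuple[float, str]]] = {}
        for group in self.layout.groups():
            meta = self.layout.group_meta(group)
            by_construct.setdefault((meta.strain, meta.construct), {})[group] = meta.ligand_mM
        pairs = []
        for groups in by_construct.values():
            zeros = [g for g, c in groups.items() if c == 0]
            if not zeros:
                continue
            g0 = sorted(zeros)[0]
            for gx, conc in sorted(groups.items(), key=lambda kv: kv[1]):
                if conc > 0:
                    pairs.append((g0, gx))
        return pairs

    def _cropped_groups(self) -> dict[str, list[WellSeries]]:
        corrected = preprocess.subtract_blanks(self.series, self.layout, self.config)
        groups: dict[str, list[WellSeries]] = {}
        for group, members in self.layout.groups().items():
            cropped = [
                preprocess.crop_to_growth(corrected[w], self.config)
                for w in members
                if w in corrected
            ]
            groups[group] = [s for s in cropped if len(s)]
        return groups

    def fit(
        self,
        pairs: list[tuple[str, str]] | None = None,
        windows: dict[tuple[str, str], tuple[float, float]] | None = None,
        auto_window: bool = False,
    ) -> "ReporterAssayResults":
        """Run the full analysis.

        Parameters
        ----------
        pairs : list of (group0, groupx), optional
            Comparisons to run; defaults to every same-construct
            0-mM-vs-x-mM pairing in the layout.
        windows : mapping pair -> (start_min, end_min), optional
            Explicit restricted windows for specific comparisons.
        auto_window : bool
            Detect the above-background window on the with-ligand group and
            restrict the summation to the longest one (for constructs whose
            signal is close to background).
        """
        if pairs is None:
            pairs = self.default_pairs()
        if not pairs:
            raise ConfigError("no comparison pairs: layout has no 0 mM vs x mM groups")
        windows = dict(windows or {})
        groups = self._cropped_groups()
        for g0, gx in pairs:
            for g in (g0, gx):
                if g not in groups:
                    raise ConfigError(f"comparison references unknown replicate_group {g!r}")
                if not groups[g]:
                    raise DataError(f"replicate_group {g!r} has no wells that reached the OD gate")

        rows = []
        fi_results: dict[tuple[str, str], FoldInductionResult] = {}
        for g0, gx in pairs:
            pair_groups = preprocess.harmonize_length({g0: groups[g0], gx: groups[gx]})
            w0, wx = pair_groups[g0], pair_groups[gx]
            window = windows.get((g0, gx))
            if window is None and auto_window:
                found = metrics.above_background_window(wx, self.window_config)
                if found:
                    window = max(found, key=lambda w: w[1] - w[0])
            if window is not None:
                fi = metrics.restricted_fold_induction(w0, wx, window)
            else:
                fi = metrics.fold_induction(w0, wx)
            fi_results[(g0, gx)] = fi
            peak0, peak0_t = metrics.peak_lum_over_od(w0)
            peakx, peakx_t = metrics.peak_lum_over_od(wx)
            rows.append(
                {
                    "group0": g0,
                    "groupx": gx,
                    "ligand_mM": self.layout.group_meta(gx).ligand_mM,
                    "FI": fi.FI,
                    "sigma_FI": fi.sigma_FI,
                    "m": fi.m,
                    "n": fi.n,
                    "window_start_min": fi.window[0] if fi.window else np.nan,
                    "window_end_min": fi.window[1] if fi.window else np.nan,
                    "peak_lum_od_0": peak0,
                    "peak_time_min_0": peak0_t,
                    "peak_lum_od_x": peakx,
                    "peak_time_min_x": peakx_t,
                    "avg_lum_od_0": metrics.average_lum_over_od(w0),
                    "avg_lum_od_x": metrics.average_lum_over_od(wx),
                }
            )

        per_well_rows = []
        for group, members in sorted(groups.items()):
            for w in members:
                per_well_rows.append(
                    {
                        "well": w.well_id,
                        "replicate_group": group,
                        "crop_start_min": float(w.times[0]),
                        "n_points": len(w),
                        "plateau_od": preprocess.plateau_od(w, self.config),
                    }
                )
        return ReporterAssayResults(
            model=self,
            table=pd.DataFrame(rows),
            per_well=pd.DataFrame(per_well_rows),
            fold_inductions=fi_results,
            validation=self.validate(),
        )


@dataclass
class ReporterAssayResults:
    """Results of :meth:`ReporterAssay.fit`.

    ``table`` has one row per comparison (FI, sigma_FI, summation bounds,
    window, peak and average lum/OD per group); ``per_well`` carries crop
    times, post-crop lengths and plateau ODs; ``fold_inductions`` maps each
    pair to its full :class:`~riboreporter.metrics.FoldInductionResult`.
    """

    model: ReporterAssay
    table: pd.DataFrame
    per_well: pd.DataFrame
    fold_inductions: dict[tuple[str, str], FoldInductionResult]
    validation: ValidationReport = field(default_factory=ValidationReport)

    def summary(self) -> str:
        """Human-readable summary of fold inductions and diagnostics."""
        lines = ["Riboswitch reporter assay — fold induction of total luciferase activity", ""]
        cols = ["group0", "groupx", "ligand_mM", "FI", "sigma_FI", "m", "n"]
        lines.append(self.table[cols].to_string(index=False, float_format=lambda v: f"{v:.4g}"))
        lines.append("")
        lines.append(
            self.per_well.to_string(index=False, float_format=lambda v: f"{v:.4g}")
        )
        if not self.validation.ok:
            lines.append("")
            lines.append("Plate validation notes:")
            lines.extend("  " + ln for ln in self.validation.lines())
        return "\n".join(lines)

    def to_dict(self) -> dict:
        table = self.table.astype(object).where(pd.notna(self.table), None)
        return {
            "comparisons": table.to_dict(orient="records"),
            "per_well": self.per_well.to_dict(orient="records"),
            "validation": self.validation.lines(),
        }

    def to_json(self, path=None) -> str:
        text = json.dumps(self.to_dict(), indent=2, sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    def plot_timecourses(self, groups: list[str] | None = None, ax=None):
        """Plot blank-subtracted, cropped lum/OD time-courses per group mean."""
        import matplotlib.pyplot as plt

        cropped = self.model._cropped_groups()
        if groups is None:
            groups = sorted(cropped)
        if ax is None:
            _, ax = plt.subplots()
        for g in groups:
            members = cropped.get(g, [])
            if not members:
                continue
            members = preprocess.harmonize_length({g: members})[g]
            rel_t = members[0].times - members[0].times[0]
            mean_norm = np.mean([metrics.normalized_expression(w) for w in members], axis=0)
            ax.plot(rel_t / 60.0, mean_norm, label=g)
        ax.set_xlabel("time since OD gate (h)")
        ax.set_ylabel("lum / OD600 (RLU)")
        ax.legend(fontsize="small")
        return ax
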