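"""Synthetic microplate reporter assays.

Generates complete plates — triplicate sample wells across fluoride
concentrations plus blank wells — with the statistical structure the
analysis assumes:

* logistic growth from an initial OD600 of ~0.06 to a plateau;
* a fluoride-riboswitch dose response (Hill form, in vitro KD ~ 50 uM)
  driven by *intracellular* fluoride, which lags the media concentration
  because export pumps actively remove it — hence the mM-range media
  threshold despite the uM-range KD, and a transient overshoot of
  intracellular fluoride (the "oscillating expression" seen in real
  assays) as pump capacity catches up;
* luminescence proportional to (per-cell expression x biomass), with
  multiplicative lognormal measurement noise, plus additive OD noise and a
  constant instrument/media background for blanks.

Everything is deterministic under a fixed seed, down to the serialized CSV
and YAML files, so round-trip and pipeline tests need no stored fixtures.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.integrate import solve_ivp

from .plate_io import PlateLayout, SampleMeta, WellSeries, write_layout, write_timecourse

__all__ = [
    "GrowthParams",
    "RiboswitchParams",
    "FluorideParams",
    "NoiseParams",
    "SimulationConfig",
    "config_for_induction_ratio",
    "simulate_growth",
    "intracellular_fluoride",
    "simulate_expression",
    "simulate_plate",
    "write_plate",
]


@dataclass(frozen=True)
class GrowthParams:
    """Logistic growth: lag, then exponential at ``rate_per_h`` saturating
    at ``carrying_od``; cultures are inoculated at OD ~ 0.06."""

    lag_h: float = 2.0
    rate_per_h: float = 0.5
    carrying_od: float = 1.0
    initial_od: float = 0.06

    def __post_init__(self):
        if min(self.lag_h, self.rate_per_h) < 0 or self.carrying_od <= 0 or self.initial_od <= 0:
            raise ValueError("growth parameters must be non-negative (carrying/initial OD > 0)")


@dataclass(frozen=True)
class RiboswitchParams:
    """Hill-type dose response of the riboswitch to intracellular fluoride.

    ``leak`` is the fraction of full expression in the OFF state;
    saturating fluoride raises expression to leak + (1-leak)*max_fold of
    the leak-normalized scale, i.e. the effective ON/OFF ratio is
    1 + (1-leak)*max_fold/leak.  KD defaults to 50 uM, the typical in
    vitro affinity of fluoride riboswitches.
    """

    leak: float = 0.04
    max_fold: float = 1.0
    kd_um: float = 50.0
    hill: float = 2.0

    def __post_init__(self):
        if not (0 < self.leak <= 1):
            raise ValueError("leak must be in (0, 1]")
        if self.max_fold < 0 or self.kd_um <= 0 or self.hill < 1:
            raise ValueError("max_fold >= 0, kd_um > 0, hill >= 1 required")

    @property
    def on_off_ratio(self) -> float:
        """Expression ratio at saturating vs zero intracellular fluoride."""
        return (self.leak + (1 - self.leak) * self.max_fold) / self.leak

    def response(self, f_in_um: np.ndarray) -> np.ndarray:
        f = np.asarray(f_in_um, dtype=float)
        occ = np.where(
            f > 0, f**self.hill / (self.kd_um**self.hill + f**self.hill), 0.0
        )
        return self.leak + (1 - self.leak) * self.max_fold * occ


@dataclass(frozen=True)
class FluorideParams:
    """Intracellular fluoride dynamics.

    dF/dt = import_rate * F_media - Vmax * E(t) * F / (Km + F), F in uM,
    where E(t) = 1 - exp(-t/pump_tau_h) is the export capacity ramping up
    as the cell induces its fluoride exporters.  Import is passive and
    proportional to the media concentration (mM); export is saturable.
    With a slow pump ramp the solution overshoots, then relaxes — the
    damped excursion real assays show.
    """

    media_mM: float = 0.0
    import_rate: float = 20.0  # uM/h per mM media
    export_rate: float = 400.0  # Vmax, uM/h at full pump capacity
    export_km_um: float = 100.0
    pump_tau_h: float = 1.0

    def __post_init__(self):
        if min(self.media_mM, self.import_rate, self.export_rate, self.pump_tau_h) < 0:
            raise ValueError("fluoride rates must be >= 0")
        if self.export_km_um <= 0:
            raise ValueError("export_km_um must be > 0")


@dataclass(frozen=True)
class NoiseParams:
    """lum_cv: multiplicative lognormal CV on luminescence; od_sd: additive
    Gaussian SD on OD readings."""

    lum_cv: float = 0.05
    od_sd: float = 0.003

    def __post_init__(self):
        if self.lum_cv < 0 or self.od_sd < 0:
            raise ValueError("noise parameters must be >= 0")


@dataclass(frozen=True)
class SimulationConfig:
    """Full description of one synthetic plate run.

    ``fluoride_mM`` lists the media concentrations, each measured in
    triplicate against the shared 0 mM reference; a 0 entry is added
    automatically if missing.  ``toxicity`` > 0 penalizes growth rate in
    proportion to expression level (OFF by default) to emulate reporter
    burden.  30 h at 20-min intervals gives 91 timepoints per well.
    """

    growth: GrowthParams = field(default_factory=GrowthParams)
    riboswitch: RiboswitchParams = field(default_factory=RiboswitchParams)
    fluoride: FluorideParams = field(default_factory=FluorideParams)
    noise: NoiseParams = field(default_factory=NoiseParams)
    promoter_strength: float = 2.0e5  # RLU per OD unit at full expression
    onset_h: float = 2.0
    blank_level: float = 100.0  # RLU background common to every well
    blank_od: float = 0.04  # media absorbance
    fluoride_mM: tuple[float, ...] = (0.0, 8.0, 16.0, 31.0, 62.0)
    replicates: int = 3
    n_blanks: int = 3
    duration_h: float = 30.0
    interval_min: float = 20.0
    toxicity: float = 0.0
    construct: str = "P1_FRS_lux"
    strain: str = "host"
    seed: int = 0

    def __post_init__(self):
        if self.duration_h * 60 / self.interval_min < 89:
            raise ValueError("duration/interval must yield >= 90 timepoints")
        if self.replicates < 1 or self.n_blanks < 1:
            raise ValueError("need >= 1 replicate and >= 1 blank well")
        if min(self.promoter_strength, self.onset_h, self.blank_level, self.toxicity) < 0:
            raise ValueError("promoter_strength/onset_h/blank_level/toxicity must be >= 0")

    @property
    def time_grid_min(self) -> np.ndarray:
        n = int(round(self.duration_h * 60 / self.interval_min)) + 1
        return np.arange(n) * self.interval_min

    def group_name(self, media_mM: float) -> str:
        label = f"{media_mM:g}".replace(".", "p")
        return f"{self.construct}_F{label}"


def config_from_dict(doc: dict) -> SimulationConfig:
    """Build a :class:`SimulationConfig` from a (YAML-loaded) nested mapping.

    Top-level keys mirror the dataclass fields; ``growth``, ``riboswitch``,
    ``fluoride`` and ``noise`` take nested mappings.
    """
    doc = dict(doc or {})
    nested = {
        "growth": GrowthParams,
        "riboswitch": RiboswitchParams,
        "fluoride": FluorideParams,
        "noise": NoiseParams,
    }
    kwargs = {}
    for key, cls in nested.items():
        if key in doc:
            sub = doc.pop(key)
            unknown = set(sub) - set(cls.__dataclass_fields__)
            if unknown:
                raise ValueError(f"unknown {key} keys: {sorted(unknown)}")
            kwargs[key] = cls(**sub)
    if "fluoride_mM" in doc:
        doc["fluoride_mM"] = tuple(float(c) for c in doc["fluoride_mM"])
    unknown = set(doc) - set(SimulationConfig.__dataclass_fields__)
    if unknown:
        raise ValueError(f"unknown simulation keys: {sorted(unknown)}")
    return SimulationConfig(**kwargs, **doc)


def config_for_induction_ratio(ratio: float, **overrides) -> SimulationConfig:
    """Config whose saturating ON/OFF expression ratio equals ``ratio``.

    Keeps the default leak and solves for max_fold; with a saturating media
    concentration (e.g. 62 mM) the fold induction recovered by the analysis
    should match ``ratio`` up to noise.
    """
    if ratio < 1:
        raise ValueError("induction ratio must be >= 1")
    base = SimulationConfig(**overrides)
    leak = base.riboswitch.leak
    max_fold = leak * (ratio - 1) / (1 - leak) if leak < 1 else 0.0
    return replace(base, riboswitch=replace(base.riboswitch, max_fold=max_fold))


def _logistic_od(cfg: SimulationConfig, t_h: np.ndarray, rate_per_h: float) -> np.ndarray:
    g = cfg.growth
    t_eff = np.clip(t_h - g.lag_h, 0.0, None)
    k, o0 = g.carrying_od, g.initial_od
    return k * o0 / (o0 + (k - o0) * np.exp(-rate_per_h * t_eff))


def simulate_growth(cfg: SimulationConfig, rng: np.random.Generator | None = None) -> np.ndarray:
    """Logistic OD600 trajectory on the config's grid, with additive noise.

    Noise-free output is monotone non-decreasing with limit carrying_od.
    """
    t_h = cfg.time_grid_min / 60.0
    od = _logistic_od(cfg, t_h, cfg.growth.rate_per_h)
    if rng is not None and cfg.noise.od_sd > 0:
        od = od + rng.normal(0.0, cfg.noise.od_sd, size=od.shape)
    return od


def intracellular_fluoride(cfg: SimulationConfig, t_grid_min: np.ndarray | None = None) -> np.ndarray:
    """Intracellular fluoride (uM) on the grid, from the import/export ODE.

    media 0 gives identically zero; export_rate 0 gives the linear closed
    form import_rate * media_mM * t.
    """
    fl = cfg.fluoride
    t_min = cfg.time_grid_min if t_grid_min is None else np.asarray(t_grid_min, dtype=float)
    t_h = t_min / 60.0
    if fl.media_mM == 0:
        return np.zeros_like(t_h)
    a = fl.import_rate * fl.media_mM
    if fl.export_rate == 0:
        return a * t_h

    def rhs(t, y):
        e = 1.0 - np.exp(-t / fl.pump_tau_h) if fl.pump_tau_h > 0 else 1.0
        f = max(y[0], 0.0)
        return [a - fl.export_rate * e * f / (fl.export_km_um + f)]

    sol = solve_ivp(
        rhs,
        (t_h[0], t_h[-1]),
        [0.0],
        t_eval=t_h,
        rtol=1e-8,
        atol=1e-10,
        method="RK45",
    )
    return np.clip(sol.y[0], 0.0, None)


def simulate_expression(
    cfg: SimulationConfig,
    od: np.ndarray,
    f_in_um: np.ndarray,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Luminescence series: promoter x riboswitch response x biomass x noise.

    Expression is zero before ``onset_h`` (cells transitioning from the
    wash into expression media); noise is multiplicative lognormal with
    unit mean.
    """
    t_h = cfg.time_grid_min / 60.0
    resp = cfg.riboswitch.response(f_in_um)
    lum = cfg.promoter_strength * resp * np.asarray(od, dtype=float)
    lum = np.where(t_h < cfg.onset_h, 0.0, lum)
    if rng is not None and cfg.noise.lum_cv > 0:
        sigma = np.sqrt(np.log1p(cfg.noise.lum_cv**2))
        lum = lum * rng.lognormal(-0.5 * sigma**2, sigma, size=lum.shape)
    return lum


_ROWS = "ABCDEFGH"


def _well_name(i: int) -> str:
    row, col = divmod(i, 12)
    if row >= len(_ROWS):
        raise ValueError("plate layout exceeds 96 wells")
    return f"{_ROWS[row]}{col + 1}"


def simulate_plate(cfg: SimulationConfig) -> tuple[dict[str, WellSeries], PlateLayout]:
    """Simulate a full plate: triplicates per fluoride concentration + blanks.

    Measured readings include the shared instrument/media background
    (``blank_level`` RLU, ``blank_od`` OD), so blank subtraction is a real
    operation on these data.  Deterministic for a fixed ``cfg.seed``.
    """
    rng = np.random.default_rng(cfg.seed)
    t = cfg.time_grid_min
    concs = list(cfg.fluoride_mM)
    if 0.0 not in concs:
        concs = [0.0] + concs
    series: dict[str, WellSeries] = {}
    wells: dict[str, SampleMeta] = {}
    i = 0

    for conc in concs:
        fl = replace(cfg.fluoride, media_mM=conc)
        f_in = intracellular_fluoride(replace(cfg, fluoride=fl), t)
        # toxicity: growth rate reduced in proportion to mean relative expression
        rate = cfg.growth.rate_per_h
        if cfg.toxicity > 0:
            denom = cfg.riboswitch.leak + (1 - cfg.riboswitch.leak) * cfg.riboswitch.max_fold
            burden = float(np.mean(cfg.riboswitch.response(f_in))) / max(denom, 1e-12)
            rate = max(rate * (1.0 - cfg.toxicity * burden), 0.0)
        group = cfg.group_name(conc)
        for rep in range(cfg.replicates):
            od_true = _logistic_od(cfg, t / 60.0, rate)
            if cfg.noise.od_sd > 0:
                od_true = od_true + rng.normal(0.0, cfg.noise.od_sd, size=od_true.shape)
            lum_true = simulate_expression(cfg, np.clip(od_true, 0.0, None), f_in, rng)
            background = np.full_like(lum_true, cfg.blank_level)
            if cfg.noise.lum_cv > 0 and cfg.blank_level > 0:
                sigma = np.sqrt(np.log1p(cfg.noise.lum_cv**2))
                background = background * rng.lognormal(-0.5 * sigma**2, sigma, size=lum_true.shape)
            well_id = _well_name(i)
            i += 1
            series[well_id] = WellSeries(
                well_id=well_id,
                times=t.astype(float),
                lum=lum_true + background,
                od=od_true + cfg.blank_od,
            )
            wells[well_id] = SampleMeta(
                strain=cfg.strain,
                construct=cfg.construct,
                promoter="P1",
                utr="F_RS",
                ligand_mM=conc,
                replicate_group=group,
            )

    for _ in range(cfg.n_blanks):
        well_id = _well_name(i)
        i += 1
        lum = np.full_like(t, cfg.blank_level, dtype=float)
        od = np.full_like(t, cfg.blank_od, dtype=float)
        if cfg.noise.lum_cv > 0:
            sigma = np.sqrt(np.log1p(cfg.noise.lum_cv**2))
            lum = lum * rng.lognormal(-0.5 * sigma**2, sigma, size=lum.shape)
        if cfg.noise.od_sd > 0:
            od = od + rng.normal(0.0, cfg.noise.od_sd, size=od.shape)
        series[well_id] = WellSeries(well_id=well_id, times=t.astype(float), lum=lum, od=od)
        wells[well_id] = SampleMeta(is_blank=True)

    return series, PlateLayout(wells=wells)


def write_plate(cfg: SimulationConfig, data_path, layout_path) -> None:
    """Simulate a plate and serialize it to the long CSV + YAML layout formats."""
    series, layout = simulate_plate(cfg)
    write_timecourse(series, data_path)
    write_layout(layout, layout_path)
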