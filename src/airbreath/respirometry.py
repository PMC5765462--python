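"""Bimodal intermittent-flow respirometry analysis.

Turns raw two-phase (air + water) optode logs from stopped-flow
respirometry into per-fish metabolic traits:

* per-cycle oxygen uptake from air (MO2,air) and water (MO2,water), from
  OLS slopes of the O2 decline during each closed period;
* routine metabolic rate (RMR) as the air + water sum per cycle;
* standard metabolic rate (SMR) as a low quantile of the RMR series
  (quantile method, default q = 0.12);
* the percentage of total uptake obtained from air (%MO2,air);
* air-phase volume calibration from N2-bolus dilution.

Air-phase oxygen is handled in kPa, water-phase in % air saturation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import CalibrationError, InsufficientDataError, UndefinedStatisticError
from .oxygen import R_GAS, o2_solubility

__all__ = [
    "RespirometerGeometry",
    "OptodeTrace",
    "CycleMeasurement",
    "MetabolicProfile",
    "calibrate_air_volume",
    "segment_cycles",
    "fit_slope",
    "mo2_air",
    "mo2_water",
    "smr_quantile",
    "pct_air",
    "analyze_chamber",
    "read_optode_log",
    "profiles_to_frame",
    "cycles_to_frame",
]

#: Tolerance (kPa/hr or %sat/hr) above which a positive closed-phase slope
#: is flagged as anomalous rather than treated as measurement noise.
POSITIVE_SLOPE_TOL = 0.05


@dataclass
class RespirometerGeometry:
    """Physical geometry of one bimodal respirometer.

    Volumes in litres, mass in kg, temperature in °C, pressure in kPa.
    The effective water volume is what remains of the total after the
    air phase and the fish body (mass / density, density 1.0 kg/L by
    default) are subtracted.
    """

    total_volume: float = 2.5
    air_volume: float = 0.2
    fish_mass: float = 0.064
    temperature: float = 26.5
    barometric_pressure: float = 101.325
    fish_density: float = 1.0

    def __post_init__(self) -> None:
        if self.total_volume <= 0 or self.air_volume <= 0 or self.fish_mass <= 0:
            raise ValueError("volumes and mass must be positive")
        if not (20.0 <= self.temperature <= 32.0):
            raise ValueError(
                f"temperature {self.temperature} °C outside sanity band [20, 32]"
            )
        if self.water_volume_effective <= 0:
            raise ValueError("air volume + fish volume exceed total volume")

    @property
    def fish_volume(self) -> float:
        return self.fish_mass / self.fish_density

    @property
    def water_volume_effective(self) -> float:
        return self.total_volume - self.air_volume - self.fish_volume

    @property
    def temperature_k(self) -> float:
        return self.temperature + 273.15


@dataclass
class OptodeTrace:
    """One chamber's two-phase oxygen time series.

    ``samples`` is a tidy frame with columns time_s, phase ('air'|'water')
    and value (kPa for air, % air saturation for water).  The cycle
    schedule is (closed_duration, flush_duration) in seconds.
    """

    chamber_id: str
    samples: pd.DataFrame
    closed_duration: float = 600.0
    flush_duration: float = 300.0

    def __post_init__(self) -> None:
        if self.closed_duration <= 0 or self.flush_duration <= 0:
            raise ValueError("cycle schedule durations must be positive")
        required = {"time_s", "phase", "value"}
        missing = required - set(self.samples.columns)
        if missing:
            raise ValueError(f"trace missing columns: {sorted(missing)}")
        for _, sub in self.samples.groupby("phase"):
            t = sub["time_s"].to_numpy()
            if np.any(np.diff(t) <= 0):
                raise ValueError("times must be strictly increasing within phase")

    @property
    def period(self) -> float:
        return self.closed_duration + self.flush_duration

    @property
    def span(self) -> float:
        t = self.samples["time_s"]
        return float(t.max() - t.min())


@dataclass
class CycleMeasurement:
    """Slopes and uptake rates for one closed-phase measurement cycle."""

    cycle_index: int
    slope_air: float  # kPa · hr⁻¹
    slope_water: float  # %sat · hr⁻¹
    r2_air: float
    r2_water: float
    mo2_air: float  # mmol O2 · kg⁻¹ · hr⁻¹
    mo2_water: float
    flagged: bool = False
    flag_reason: str = ""

    @property
    def rmr_cycle(self) -> float:
        return self.mo2_air + self.mo2_water


@dataclass
class MetabolicProfile:
    """Per-fish metabolic traits over the analysis window."""

    fish_id: str
    cycles: list[CycleMeasurement]
    rmr: float
    smr: float
    pct_air: float
    q: float = 0.12
    mass: float = float("nan")
    metadata: dict = field(default_factory=dict)

    @property
    def n_cycles(self) -> int:
        return len(self.cycles)


def calibrate_air_volume(bolus_volume, p_before, p_after):
    """Air-phase volume (mL) from an N2-bolus dilution test.

    A bolus of pure N2 injected into a well-mixed, isobarically vented
    air space of volume V dilutes the O2 partial pressure from
    ``p_before`` to ``p_after = p_before · V / (V + V_bolus)``.  Inverting:

        V = V_bolus · p_after / (p_before − p_after)

    Arrays are accepted for multi-bolus protocols; per-bolus estimates
    are returned elementwise (average them for the chamber value).
    """
    vb = np.asarray(bolus_volume, dtype=float)
    p0 = np.asarray(p_before, dtype=float)
    p1 = np.asarray(p_after, dtype=float)
    if np.any(vb <= 0) or np.any(p0 <= 0) or np.any(p1 <= 0):
        raise CalibrationError("bolus volume and pressures must be positive")
    if np.any(p1 >= p0):
        raise CalibrationError("no dilution detected (p_after >= p_before)")
    v = vb * p1 / (p0 - p1)
    return float(v) if v.ndim == 0 else v


def segment_cycles(
    trace: OptodeTrace, settle_skip: float = 60.0
) -> list[tuple[float, float]]:
    """Closed-phase measurement windows for every complete cycle.

    Each window is (start, end) in trace time; the first ``settle_skip``
    seconds of the closed phase are excluded to discard the mixing lag
    after flushing ends.  Windows are aligned with the cycle schedule
    starting at the first sample; the number of windows is
    floor(span / period).
    """
    if settle_skip < 0 or settle_skip >= trace.closed_duration:
        raise ValueError("settle_skip must be in [0, closed_duration)")
    n = int(np.floor(trace.span / trace.period))
    if n == 0:
        warnings.warn(
            f"trace for {trace.chamber_id} spans {trace.span:.0f} s, "
            f"shorter than one {trace.period:.0f}-s cycle; no windows",
            stacklevel=2,
        )
        return []
    t0 = float(trace.samples["time_s"].min())
    return [
        (t0 + k * trace.period + settle_skip, t0 + k * trace.period + trace.closed_duration)
        for k in range(n)
    ]


def fit_slope(times, values) -> tuple[float, float]:
    """OLS slope of an O2 decline, converted to per-hour, with r².

    No filtering is applied: the caller decides what to do with poor
    fits.  A constant series returns slope 0 with r² 0.
    """
    t = np.asarray(times, dtype=float)
    y = np.asarray(values, dtype=float)
    if t.size < 3:
        raise InsufficientDataError(f"need >= 3 samples to fit a slope, got {t.size}")
    if np.ptp(y) == 0.0:
        return 0.0, 0.0
    res = stats.linregress(t, y)
    return float(res.slope * 3600.0), float(res.rvalue**2)


def mo2_air(slope_air: float, geom: RespirometerGeometry) -> float:
    """Aerial oxygen uptake (mmol O2 · kg⁻¹ · hr⁻¹) from the air-phase slope.

    Ideal-gas conversion of the kPa/hr decline in the sealed air space:
    uptake = (−slope · V_air) / (R · T) / mass.  Positive slopes within
    :data:`POSITIVE_SLOPE_TOL` are treated as zero uptake; larger
    positive slopes should be flagged by the caller.
    """
    rate = (-slope_air * geom.air_volume) / (R_GAS * geom.temperature_k)
    return max(rate, 0.0) / geom.fish_mass


def mo2_water(
    slope_water: float, geom: RespirometerGeometry, solubility: float
) -> float:
    """Aquatic oxygen uptake (mmol O2 · kg⁻¹ · hr⁻¹) from the water slope.

    ``slope_water`` is in % air saturation per hour; ``solubility`` is the
    O2 content of air-saturated water in mmol/L at trial temperature and
    pressure (see :func:`airbreath.oxygen.o2_solubility`).
    """
    if solubility <= 0:
        raise ValueError("solubility must be positive")
    rate = (-slope_water / 100.0) * solubility * geom.water_volume_effective
    return max(rate, 0.0) / geom.fish_mass


def smr_quantile(rmr_series: Sequence[float], q: float = 0.12) -> float:
    """Standard metabolic rate as the q-th quantile of the RMR series.

    The quantile method assumes a proportion q of routine measurements
    fall below true SMR through temporal variability and measurement
    error.  Linear interpolation between order statistics.
    """
    arr = np.asarray(rmr_series, dtype=float)
    if arr.size == 0:
        raise InsufficientDataError("empty RMR series")
    if not (0.0 < q < 0.5):
        raise ValueError(f"q must be in (0, 0.5), got {q}")
    if arr.size < 20:
        warnings.warn(
            f"only {arr.size} RMR measures; quantile SMR is unstable below ~20",
            stacklevel=2,
        )
    return float(np.quantile(arr, q, method="linear"))


def pct_air(cycles: Iterable[CycleMeasurement]) -> float:
    """Percentage of total oxygen uptake obtained from the air phase."""
    cycles = list(cycles)
    if not cycles:
        raise InsufficientDataError("no cycles")
    total_air = sum(c.mo2_air for c in cycles)
    total = sum(c.mo2_air + c.mo2_water for c in cycles)
    if total <= 0:
        raise UndefinedStatisticError("zero total oxygen uptake")
    return 100.0 * total_air / total


def analyze_chamber(
    trace: OptodeTrace,
    geom: RespirometerGeometry,
    *,
    q: float = 0.12,
    settle_skip: float = 60.0,
    solubility: float | None = None,
    r2_min: float | None = None,
    window_hours: tuple[float, float] | None = None,
) -> MetabolicProfile:
    """Full per-chamber reduction: cycles → slopes → MO2 → RMR/SMR/%MO2,air.

    Parameters
    ----------
    solubility : mmol O2/L at 100 % air saturation; computed from trial
        temperature and pressure when omitted.
    r2_min : optional fit-quality threshold; cycles whose water- or
        air-phase r² falls below it are excluded from the summary
        statistics (none excluded by default) with the count recorded
        in metadata.
    window_hours : restrict the analysis to cycles whose closed-phase
        midpoint lies in [lo, hi) hours from trace start.
    """
    if solubility is None:
        solubility = o2_solubility(geom.temperature, geom.barometric_pressure)
    windows = segment_cycles(trace, settle_skip=settle_skip)
    air = trace.samples[trace.samples["phase"] == "air"]
    wat = trace.samples[trace.samples["phase"] == "water"]
    t0 = float(trace.samples["time_s"].min())

    cycles: list[CycleMeasurement] = []
    for k, (lo, hi) in enumerate(windows):
        if window_hours is not None:
            mid_h = ((lo + hi) / 2.0 - t0) / 3600.0
            if not (window_hours[0] <= mid_h < window_hours[1]):
                continue
        a = air[(air["time_s"] >= lo) & (air["time_s"] < hi)]
        w = wat[(wat["time_s"] >= lo) & (wat["time_s"] < hi)]
        sa, r2a = fit_slope(a["time_s"], a["value"])
        sw, r2w = fit_slope(w["time_s"], w["value"])
        flagged = False
        reason = ""
        if sa > POSITIVE_SLOPE_TOL or sw > POSITIVE_SLOPE_TOL:
            flagged = True
            reason = "O2 increase in closed phase"
        cycles.append(
            CycleMeasurement(
                cycle_index=k,
                slope_air=sa,
                slope_water=sw,
                r2_air=r2a,
                r2_water=r2w,
                mo2_air=mo2_air(sa, geom),
                mo2_water=mo2_water(sw, geom, solubility),
                flagged=flagged,
                flag_reason=reason,
            )
        )

    kept = cycles
    n_rejected = 0
    if r2_min is not None:
        kept = [c for c in cycles if c.r2_air >= r2_min and c.r2_water >= r2_min]
        n_rejected = len(cycles) - len(kept)
    if not kept:
        raise InsufficientDataError(f"no usable cycles for {trace.chamber_id}")

    rmr_series = [c.rmr_cycle for c in kept]
    return MetabolicProfile(
        fish_id=trace.chamber_id,
        cycles=cycles,
        rmr=float(np.mean(rmr_series)),
        smr=smr_quantile(rmr_series, q=q),
        pct_air=pct_air(kept),
        q=q,
        mass=geom.fish_mass,
        metadata={
            "settle_skip_s": settle_skip,
            "solubility_mmol_l": solubility,
            "quantile_interpolation": "linear",
            "fish_volume_subtracted": True,
            "r2_min": r2_min,
            "n_cycles_rejected": n_rejected,
        },
    )


def read_optode_log(
    path, closed_duration: float = 600.0, flush_duration: float = 300.0
) -> dict[str, OptodeTrace]:
    """Read a delimited optode log into one trace per chamber.

    Expected columns: time_s, chamber_id, phase, unit, value (one row per
    sample).  Units must be kPa in the air phase and pct_sat in the water
    phase; anything else is rejected rather than silently converted.
    """
    df = pd.read_csv(path)
    required = {"time_s", "chamber_id", "phase", "unit", "value"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"optode log missing columns: {sorted(missing)}")
    bad_air = df[(df["phase"] == "air") & (df["unit"] != "kPa")]
    bad_wat = df[(df["phase"] == "water") & (df["unit"] != "pct_sat")]
    if len(bad_air) or len(bad_wat):
        raise ValueError("unexpected units: air must be kPa, water pct_sat")
    traces = {}
    for cid, sub in df.groupby("chamber_id", sort=True):
        traces[str(cid)] = OptodeTrace(
            chamber_id=str(cid),
            samples=sub[["time_s", "phase", "value"]].sort_values("time_s").reset_index(drop=True),
            closed_duration=closed_duration,
            flush_duration=flush_duration,
        )
    return traces


def profiles_to_frame(profiles: Iterable[MetabolicProfile]) -> pd.DataFrame:
    """Tidy per-fish trait table (one row per fish)."""
    return pd.DataFrame(
        [
            {
                "fish_id": p.fish_id,
                "mass": p.mass,
                "rmr": p.rmr,
                "smr": p.smr,
                "pct_air": p.pct_air,
                "n_cycles": p.n_cycles,
                "q": p.q,
            }
            for p in profiles
        ]
    )


def cycles_to_frame(profiles: Iterable[MetabolicProfile]) -> pd.DataFrame:
    """Companion per-cycle table across fish."""
    rows = []
    for p in profiles:
        for c in p.cycles:
            rows.append(
                {
                    "fish_id": p.fish_id,
                    "cycle_index": c.cycle_index,
                    "slope_air": c.slope_air,
                    "slope_water": c.slope_water,
                    "r2_air": c.r2_air,
                    "r2_water": c.r2_water,
                    "mo2_air": c.mo2_air,
                    "mo2_water": c.mo2_water,
                    "rmr_cycle": c.rmr_cycle,
                    "flagged": c.flagged,
                }
            )
    return pd.DataFrame(rows)
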