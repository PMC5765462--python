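"""Synthetic study generator with known ground truth.

Emulates the full design of the group air-breathing study — 11 groups of
4 fish, bimodal respirometry (68 stopped-flow cycles over 17 hr), and
15-min behavioural trials at five aquatic oxygen levels (100, 80, 60,
40, 20% air saturation) plus a recovery observation — so that every
pipeline stage can be tested against known truth without any real data.

Respirometry traces are forward-simulated from a per-fish true SMR and
air/water partition: each cycle's routine rate is SMR times one plus a
right-skewed activity surcharge, converted to closed-phase O2 declines
through the same ideal-gas / solubility physics the analysis inverts,
plus sensor noise and a decaying mixing artefact at the start of each
closed phase.

Behavioural trials are a marked self-exciting point process: per-fish
Poisson attacks (one designated dominant with a multiplied rate, and a
lognormal group-level aggression multiplier), baseline Poisson breaths
whose rate rises as oxygen falls, breaths triggered by attacks (actor
and target, short exponential lag), and follower breaths after any
primary breath (uniform lag).  Trigger lags are truncated at the 5-s
proximity window so the trigger probabilities are directly identified
by the proximity-attribution statistics.  Follower breaths do not
themselves recruit followers (single generation), which keeps the
cascade finite at any follow probability.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd

from .ethogram import BehaviourEvent, Trial
from .oxygen import R_GAS, o2_solubility, po2_air_saturated_kpa
from .respirometry import RespirometerGeometry

__all__ = [
    "RespirometrySimConfig",
    "PhysiologyConfig",
    "BehaviourConfig",
    "SimConfig",
    "SimTruth",
    "StudyData",
    "simulate_respirometry",
    "simulate_group_trial",
    "simulate_isolation_trial",
    "simulate_study",
    "simulate_trait_table",
    "simulate_analysis_table",
]


@dataclass
class RespirometrySimConfig:
    """Stopped-flow trace generation parameters."""

    n_cycles: int = 68
    closed_duration: float = 600.0
    flush_duration: float = 300.0
    sample_interval: float = 5.0
    flush_sample_interval: float = 30.0
    noise_sd_air_kpa: float = 0.015
    noise_sd_water_pct: float = 0.10
    settle_amplitude_air_kpa: float = 0.10
    settle_amplitude_water_pct: float = 0.50
    settle_tau: float = 20.0
    # activity surcharge: resting cycles sit just above SMR, active ones
    # carry a right-skewed (exponential) surcharge
    p_rest: float = 0.25
    rest_surcharge_max: float = 0.03
    active_surcharge_mean: float = 0.35
    active_surcharge_floor: float = 0.03
    pct_air_cycle_sd: float = 2.0

    @property
    def period(self) -> float:
        return self.closed_duration + self.flush_duration


@dataclass
class PhysiologyConfig:
    """True trait distributions across fish."""

    smr_mean: float = 2.5  # mmol O2 kg-1 hr-1
    smr_cv: float = 0.20  # lognormal coefficient of variation
    pct_air_mean: float = 35.0
    pct_air_sd: float = 8.0
    mass_mean: float = 0.0641  # kg
    mass_sd: float = 0.0113


@dataclass
class BehaviourConfig:
    """Event-stream generation parameters (rates per 15-min trial)."""

    breath_rate: float = 3.0  # baseline breaths per fish per trial at normoxia
    breath_rate_cv: float = 0.5  # among-individual lognormal CV of the baseline
    breath_hypoxia_slope: float = 0.4  # fractional rate increase at 20% sat
    attack_rate: float = 1.5  # subordinate attacks per fish per trial
    attack_hypoxia_slope: float = 0.4
    dominant_multiplier: float = 5.0
    group_aggression_sigma: float = 0.6  # lognormal sd of group multiplier
    push_rate: float = 1.0
    p_avoid_given_attack: float = 0.5
    p_breath_given_attack: float = 0.35
    p_follow: float = 0.03
    lag_scale: float = 2.0  # s, exponential, truncated at window
    follow_window: float = 5.0  # s, uniform follower lag
    activity_intercept: float = 50.0
    activity_per_attack: float = 30.0
    activity_noise_sd: float = 15.0
    facilitation: float = 6.0  # group baseline rate / isolation rate


@dataclass
class SimConfig:
    """Full study replica configuration.  ``seed`` is mandatory."""

    seed: int
    n_groups: int = 11
    group_size: int = 4
    oxygen_levels: tuple = (100, 80, 60, 40, 20)
    include_recovery: bool = True
    trial_duration: float = 900.0
    temperature: float = 26.5
    barometric_pressure: float = 101.325
    respirometry: RespirometrySimConfig = field(default_factory=RespirometrySimConfig)
    physiology: PhysiologyConfig = field(default_factory=PhysiologyConfig)
    behaviour: BehaviourConfig = field(default_factory=BehaviourConfig)

    def __post_init__(self) -> None:
        b = self.behaviour
        for p in (b.p_avoid_given_attack, b.p_breath_given_attack, b.p_follow):
            if not (0.0 <= p <= 1.0):
                raise ValueError("probabilities must be in [0, 1]")
        if b.lag_scale <= 0:
            raise ValueError("lag scale must be positive")
        for rate in (b.breath_rate, b.attack_rate, b.push_rate):
            if rate < 0:
                raise ValueError("rates must be non-negative")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class SimTruth:
    """Ground-truth parameters serialised alongside generated data."""

    fish: pd.DataFrame  # fish_id, group_id, smr, pct_air, mass, attack_rate, dominant
    groups: pd.DataFrame  # group_id, aggression_multiplier, dominant_id
    params: dict

    def to_json(self) -> str:
        return json.dumps(
            {
                "fish": self.fish.to_dict(orient="records"),
                "groups": self.groups.to_dict(orient="records"),
                "params": self.params,
            },
            indent=1,
            sort_keys=True,
        )

    def write(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(self.to_json())


def _oxygen_numeric(level) -> float:
    return 100.0 if str(level) == "recovery" else float(level)


def _hypoxia_factor(level, slope: float) -> float:
    ox = _oxygen_numeric(level)
    return 1.0 + slope * (100.0 - ox) / 80.0


def draw_fish_truth(cfg: SimConfig, rng: np.random.Generator) -> SimTruth:
    """Draw per-fish true traits and per-group aggression structure."""
    phys, beh = cfg.physiology, cfg.behaviour
    sigma = np.sqrt(np.log(1.0 + phys.smr_cv**2))
    rows, grows = [], []
    for g in range(cfg.n_groups):
        gid = f"g{g + 1:02d}"
        mult = float(np.exp(rng.normal(-0.5 * beh.group_aggression_sigma**2,
                                       beh.group_aggression_sigma)))
        dom = int(rng.integers(cfg.group_size))
        dom_id = f"{gid}f{dom + 1}"
        grows.append({"group_id": gid, "aggression_multiplier": mult,
                      "dominant_id": dom_id})
        sigma_b = np.sqrt(np.log(1.0 + beh.breath_rate_cv**2))
        for i in range(cfg.group_size):
            fid = f"{gid}f{i + 1}"
            is_dom = i == dom
            rows.append(
                {
                    "fish_id": fid,
                    "group_id": gid,
                    "smr": float(phys.smr_mean * np.exp(rng.normal(-0.5 * sigma**2, sigma))),
                    "pct_air": float(np.clip(rng.normal(phys.pct_air_mean, phys.pct_air_sd), 2.0, 98.0)),
                    "mass": float(np.clip(rng.normal(phys.mass_mean, phys.mass_sd), 0.02, None)),
                    "attack_rate": float(
                        beh.attack_rate * mult * (beh.dominant_multiplier if is_dom else 1.0)
                    ),
                    "breath_rate": float(
                        beh.breath_rate * np.exp(rng.normal(-0.5 * sigma_b**2, sigma_b))
                    ),
                    "dominant": bool(is_dom),
                }
            )
    return SimTruth(
        fish=pd.DataFrame(rows),
        groups=pd.DataFrame(grows),
        params={
            "p_breath_given_attack": beh.p_breath_given_attack,
            "p_follow": beh.p_follow,
            "lag_scale": beh.lag_scale,
            "facilitation": beh.facilitation,
            "seed": cfg.seed,
        },
    )


# ---------------------------------------------------------------------------
# Respirometry traces


def simulate_fish_trace(
    cfg: SimConfig,
    fish_id: str,
    smr: float,
    pct_air_true: float,
    mass: float,
    rng: np.random.Generator,
    geometry: RespirometerGeometry | None = None,
) -> pd.DataFrame:
    """Forward-simulate one chamber's two-phase optode log (tidy rows)."""
    rs = cfg.respirometry
    geom = geometry or RespirometerGeometry(
        fish_mass=mass, temperature=cfg.temperature,
        barometric_pressure=cfg.barometric_pressure,
    )
    sol = o2_solubility(cfg.temperature, cfg.barometric_pressure)
    p_amb = po2_air_saturated_kpa(cfg.temperature, cfg.barometric_pressure)

    n_rest = rng.random(rs.n_cycles) < rs.p_rest
    surcharge = np.where(
        n_rest,
        rng.uniform(0.0, rs.rest_surcharge_max, rs.n_cycles),
        rs.active_surcharge_floor + rng.exponential(rs.active_surcharge_mean, rs.n_cycles),
    )
    rmr_cycle = smr * (1.0 + surcharge)
    pct_cycle = np.clip(
        rng.normal(pct_air_true, rs.pct_air_cycle_sd, rs.n_cycles), 0.5, 99.5
    )
    mo2a = rmr_cycle * pct_cycle / 100.0
    mo2w = rmr_cycle - mo2a
    slope_air = -mo2a * mass * R_GAS * geom.temperature_k / geom.air_volume  # kPa/hr
    slope_wat = -mo2w * mass * 100.0 / (sol * geom.water_volume_effective)  # %sat/hr

    t_closed = np.arange(0.0, rs.closed_duration, rs.sample_interval)
    t_flush = np.arange(rs.closed_duration, rs.period, rs.flush_sample_interval)
    settle = np.exp(-t_closed / rs.settle_tau)

    frames = []
    for k in range(rs.n_cycles):
        t0 = k * rs.period
        air_closed = (
            p_amb
            + slope_air[k] * t_closed / 3600.0
            + rs.settle_amplitude_air_kpa * settle
            + rng.normal(0.0, rs.noise_sd_air_kpa, t_closed.size)
        )
        wat_closed = (
            100.0
            + slope_wat[k] * t_closed / 3600.0
            + rs.settle_amplitude_water_pct * settle
            + rng.normal(0.0, rs.noise_sd_water_pct, t_closed.size)
        )
        air_flush = p_amb + rng.normal(0.0, rs.noise_sd_air_kpa, t_flush.size)
        wat_flush = 100.0 + rng.normal(0.0, rs.noise_sd_water_pct, t_flush.size)
        frames.append(
            pd.DataFrame(
                {
                    "time_s": np.concatenate([t0 + t_closed, t0 + t_flush] * 2),
                    "phase": ["air"] * (t_closed.size + t_flush.size)
                    + ["water"] * (t_closed.size + t_flush.size),
                    "value": np.concatenate(
                        [air_closed, air_flush, wat_closed, wat_flush]
                    ),
                }
            )
        )
    # terminal sample so the trace spans exactly n_cycles full periods
    t_end = rs.n_cycles * rs.period
    frames.append(
        pd.DataFrame(
            {
                "time_s": [t_end, t_end],
                "phase": ["air", "water"],
                "value": [
                    p_amb + rng.normal(0.0, rs.noise_sd_air_kpa),
                    100.0 + rng.normal(0.0, rs.noise_sd_water_pct),
                ],
            }
        )
    )
    df = pd.concat(frames, ignore_index=True)
    df.insert(1, "chamber_id", fish_id)
    df.insert(3, "unit", np.where(df["phase"] == "air", "kPa", "pct_sat"))
    return df


def simulate_respirometry(
    cfg: SimConfig,
    rng: np.random.Generator | None = None,
    truth: SimTruth | None = None,
) -> tuple[pd.DataFrame, SimTruth]:
    """Optode logs for every fish in the study, with ground truth."""
    rng = np.random.default_rng(cfg.seed) if rng is None else rng
    truth = draw_fish_truth(cfg, rng) if truth is None else truth
    logs = [
        simulate_fish_trace(cfg, r.fish_id, r.smr, r.pct_air, r.mass, rng)
        for r in truth.fish.itertuples()
    ]
    return pd.concat(logs, ignore_index=True), truth


# ---------------------------------------------------------------------------
# Behavioural trials


def _truncated_exp(rng: np.random.Generator, scale: float, upper: float) -> float:
    """Exponential lag conditioned on being <= upper (inverse CDF)."""
    u = rng.random()
    return float(-scale * np.log1p(-u * (1.0 - np.exp(-upper / scale))))


def simulate_group_trial(
    cfg: SimConfig,
    group_id: str,
    oxygen_level,
    rng: np.random.Generator,
    truth: SimTruth,
) -> Trial:
    """One 15-min group trial as a marked self-exciting point process."""
    beh = cfg.behaviour
    dur = cfg.trial_duration
    fish = truth.fish[truth.fish["group_id"] == group_id]
    roster = tuple(fish["fish_id"])
    gmult = float(
        truth.groups.set_index("group_id").loc[group_id, "aggression_multiplier"]
    )
    ox_attack = _hypoxia_factor(oxygen_level, beh.attack_hypoxia_slope)
    ox_breath = _hypoxia_factor(oxygen_level, beh.breath_hypoxia_slope)

    events: list[BehaviourEvent] = []
    attacks: list[BehaviourEvent] = []
    for r in fish.itertuples():
        n = rng.poisson(r.attack_rate * ox_attack)
        others = [f for f in roster if f != r.fish_id]
        for t in np.sort(rng.uniform(0.0, dur, n)):
            attacks.append(
                BehaviourEvent(float(t), r.fish_id, "attack",
                               target_id=str(rng.choice(others)))
            )
    for r in fish.itertuples():
        n = rng.poisson(beh.push_rate * gmult)
        others = [f for f in roster if f != r.fish_id]
        for t in rng.uniform(0.0, dur, n):
            events.append(
                BehaviourEvent(float(t), r.fish_id, "push",
                               target_id=str(rng.choice(others)))
            )
    for a in attacks:
        if a.target_id and rng.random() < beh.p_avoid_given_attack:
            t = a.time + rng.uniform(0.0, 2.0)
            if t <= dur:
                events.append(BehaviourEvent(t, a.target_id, "avoid"))

    primary: list[BehaviourEvent] = []
    for r in fish.itertuples():
        n = rng.poisson(r.breath_rate * ox_breath)
        for t in rng.uniform(0.0, dur, n):
            primary.append(BehaviourEvent(float(t), r.fish_id, "breath"))
    for a in attacks:
        for who in (a.fish_id, a.target_id):
            if who and rng.random() < beh.p_breath_given_attack:
                t = a.time + _truncated_exp(rng, beh.lag_scale, beh.follow_window)
                if t <= dur:
                    primary.append(BehaviourEvent(t, who, "breath"))
    followers: list[BehaviourEvent] = []
    for b in sorted(primary, key=lambda e: e.time):
        for f in roster:
            if f != b.fish_id and rng.random() < beh.p_follow:
                t = b.time + rng.uniform(np.nextafter(0.0, 1.0), beh.follow_window)
                if t <= dur:
                    followers.append(BehaviourEvent(t, f, "breath"))

    events += attacks + primary + followers
    n_attacks = {f: sum(1 for a in attacks if a.fish_id == f) for f in roster}
    activity = {
        f: float(
            max(
                beh.activity_intercept
                + beh.activity_per_attack * n_attacks[f]
                + rng.normal(0.0, beh.activity_noise_sd),
                0.0,
            )
        )
        for f in roster
    }
    return Trial(
        group_id=group_id,
        oxygen_level=str(oxygen_level),
        roster=roster,
        events=events,
        duration=dur,
        activity=activity,
        trial_id=f"{group_id}_{oxygen_level}",
    )


def simulate_isolation_trial(
    cfg: SimConfig,
    fish_id: str,
    oxygen_level,
    rng: np.random.Generator,
    breath_rate: float | None = None,
) -> Trial:
    """Single-fish observation: Poisson breaths at the social-facilitation-
    reduced baseline rate, increasing with hypoxia.  ``breath_rate`` is the
    fish's group-context baseline (defaults to the population baseline)."""
    beh = cfg.behaviour
    base = beh.breath_rate if breath_rate is None else breath_rate
    rate = base * _hypoxia_factor(oxygen_level, beh.breath_hypoxia_slope)
    rate /= beh.facilitation
    n = rng.poisson(rate)
    events = [
        BehaviourEvent(float(t), fish_id, "breath")
        for t in rng.uniform(0.0, cfg.trial_duration, n)
    ]
    return Trial(
        group_id=f"iso_{fish_id}",
        oxygen_level=str(oxygen_level),
        roster=(fish_id,),
        events=events,
        duration=cfg.trial_duration,
        activity={},
        trial_id=f"iso_{fish_id}_{oxygen_level}",
    )


@dataclass
class StudyData:
    """Everything one simulated study produces."""

    config: SimConfig
    truth: SimTruth
    optode_log: pd.DataFrame
    group_trials: list[Trial]
    isolation_trials: list[Trial]

    def write(self, outdir) -> None:
        from pathlib import Path

        from .ethogram import trials_to_event_frame

        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        self.optode_log.to_csv(out / "optode_log.csv", index=False)
        trials_to_event_frame(self.group_trials).to_csv(
            out / "group_events.csv", index=False
        )
        trials_to_event_frame(self.isolation_trials).to_csv(
            out / "isolation_events.csv", index=False
        )
        rows = [
            {"trial_id": tr.trial_id, "fish_id": f, "distance": d}
            for tr in self.group_trials
            for f, d in tr.activity.items()
        ]
        pd.DataFrame(rows).to_csv(out / "activity.csv", index=False)
        self.truth.write(out / "sim_truth.json")


def simulate_study(cfg: SimConfig, with_respirometry: bool = True) -> StudyData:
    """Simulate the complete study design from one seed."""
    rng = np.random.default_rng(cfg.seed)
    truth = draw_fish_truth(cfg, rng)
    optode = pd.DataFrame()
    if with_respirometry:
        optode, _ = simulate_respirometry(cfg, rng, truth)
    levels = list(cfg.oxygen_levels) + (["recovery"] if cfg.include_recovery else [])
    group_trials = [
        simulate_group_trial(cfg, gid, lvl, rng, truth)
        for gid in truth.groups["group_id"]
        for lvl in levels
    ]
    rates = dict(zip(truth.fish["fish_id"], truth.fish["breath_rate"]))
    isolation_trials = [
        simulate_isolation_trial(cfg, fid, lvl, rng, breath_rate=rates[fid])
        for fid in truth.fish["fish_id"]
        for lvl in (100, 20)
    ]
    return StudyData(cfg, truth, optode, group_trials, isolation_trials)


# ---------------------------------------------------------------------------
# Direct trait-table generators (for the mixed-model layer)


def simulate_trait_table(
    seed: int,
    n_groups: int = 11,
    group_size: int = 4,
    n_obs: int = 5,
    v_id: float = 0.3,
    v_group: float = 0.1,
    v_resid: float = 0.6,
    v_slope: float = 0.0,
    mean: float = 2.0,
    obs_effects: np.ndarray | None = None,
) -> pd.DataFrame:
    """Repeated-measures table with exactly known variance components.

    One row per fish × observation level; ``y = mean + level effect +
    group effect + id effect [+ id slope × standardised level] +
    residual`` with the stated variances.  ``oxygen_level`` is a
    categorical label for the observation level; ``v_slope > 0`` adds
    per-individual slope heterogeneity over the (standardised) numeric
    oxygen level.
    """
    rng = np.random.default_rng(seed)
    levels = [100, 80, 60, 40, 20][:n_obs] if n_obs <= 5 else list(range(n_obs))
    nums = np.array([_oxygen_numeric(lv) for lv in levels])
    z = (nums - nums.mean()) / (nums.std() or 1.0)
    eff = np.zeros(n_obs) if obs_effects is None else np.asarray(obs_effects)
    rows = []
    for g in range(n_groups):
        ge = rng.normal(0.0, np.sqrt(v_group))
        for i in range(group_size):
            ie = rng.normal(0.0, np.sqrt(v_id))
            se = rng.normal(0.0, np.sqrt(v_slope)) if v_slope > 0 else 0.0
            fid = f"g{g + 1:02d}f{i + 1}"
            for k in range(n_obs):
                rows.append(
                    {
                        "group_id": f"g{g + 1:02d}",
                        "fish_id": fid,
                        "oxygen_level": str(levels[k]),
                        "oxygen_num": float(nums[k]),
                        "y": mean + eff[k] + ge + ie + se * z[k]
                        + rng.normal(0.0, np.sqrt(v_resid)),
                    }
                )
    return pd.DataFrame(rows)


def simulate_analysis_table(
    seed: int,
    n_groups: int = 11,
    group_size: int = 4,
    activity_coef: float = 2.095,
    attacks_coef: float = 1.687,
    smr_coef: float = 0.0,
    mass_coef: float = 0.0,
    pct_air_coef: float = 0.0,
    oxygen_effects: dict | None = None,
    v_id: float = 1.0,
    v_group: float = 0.5,
    v_resid: float = 4.0,
    intercept: float = 2.0,
) -> pd.DataFrame:
    """Fish × oxygen-level analysis table with a known fixed-effect pattern.

    Default coefficients reproduce the study's effect structure: breaths
    respond to (log) activity and (log1p) attacks, while SMR, mass and
    %MO2,air are null.  Covariates are drawn with realistic spread and
    attacks/activity correlated through the dominance structure.
    """
    rng = np.random.default_rng(seed)
    ox_eff = oxygen_effects or {"100": 0.0, "80": 0.0, "60": 0.0, "40": 0.3, "20": 0.6}
    rows = []
    for g in range(n_groups):
        gid = f"g{g + 1:02d}"
        ge = rng.normal(0.0, np.sqrt(v_group))
        gmult = np.exp(rng.normal(0.0, 0.5))
        dom = rng.integers(group_size)
        for i in range(group_size):
            fid = f"{gid}f{i + 1}"
            ie = rng.normal(0.0, np.sqrt(v_id))
            smr_log = rng.normal(np.log(2.5), 0.2)
            mass_log = rng.normal(np.log(64.0), 0.17)
            pct_air = np.clip(rng.normal(35.0, 8.0), 2.0, 98.0)
            base_attack = 1.5 * gmult * (5.0 if i == dom else 1.0)
            for lvl, eff in ox_eff.items():
                attacks = rng.poisson(base_attack * _hypoxia_factor(lvl, 0.4))
                # multiplicative activity noise keeps activity and attacks
                # correlated but separately identifiable on the log scale
                activity = (50.0 + 20.0 * attacks) * np.exp(rng.normal(0.0, 0.5))
                attacks_log = np.log1p(attacks)
                activity_log = np.log(activity)
                y = (
                    intercept
                    + activity_coef * activity_log
                    + attacks_coef * attacks_log
                    + smr_coef * smr_log
                    + mass_coef * mass_log
                    + pct_air_coef * pct_air
                    + eff
                    + ge
                    + ie
                    + rng.normal(0.0, np.sqrt(v_resid))
                )
                rows.append(
                    {
                        "group_id": gid,
                        "fish_id": fid,
                        "oxygen_level": str(lvl),
                        "oxygen_num": float(lvl),
                        "breaths": y,
                        "attacks": attacks,
                        "attacks_log": attacks_log,
                        "activity": activity,
                        "activity_log": activity_log,
                        "smr_log": smr_log,
                        "mass_log": mass_log,
                        "pct_air": pct_air,
                    }
                )
    return pd.DataFrame(rows)
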