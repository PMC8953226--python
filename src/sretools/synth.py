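"""Seeded synthetic famine stimulus-response datasets with known ground truth.

The raw fermentation data behind the reference study are not packaged with
it, so this module emulates the complete experiment: a glucose-limited
chemostat at D = 0.1 1/h (22.5 g/L feed, 1.7 L) runs at its reference
steady state, receives a single 2-min feed stop, and is then driven with
repeated 2-min-off / 7-min-on cycles.  From the simulated state the
generator derives true volumetric O2/CO2 rates, converts them to off-gas
mole fractions, smears them with first-order-plus-delay sensor models,
samples them on the 1-min logging grid and adds sensor noise.  Intracellular
metabolite responses are phenomenological (piecewise first-order relaxation
with optional damped overshoot pulses — the qualitative decay / delayed
recovery / AMP-ADP overshoot shapes), emitted as noisy triplicates.

Everything is a pure function of the scenario spec: a fixed seed reproduces
the bundle bit-exactly, and noise settings never change the ground truth.

Metabolite defaults use printed steady-state and famine levels where the
study reports them (ATP, FBP, NADH, the NADP couple, ...); the remaining
levels are order-of-magnitude synthetic placeholders.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import offgas, physiology, reactor
from .offgas import SensorModel
from .reactor import FeedSchedule, KineticParams, ReactorParams, StateTrajectory

#: Total N of 15 g/L ammonium sulfate feed, mmol/L.
FEED_AMMONIA_MMOL_L = 2.0 * 15.0 / 132.14 * 1000.0


# ---------------------------------------------------------------------------
# Metabolite response model
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MetaboliteDynamics:
    """Phenomenological famine response of one metabolite pool.

    During the feed-off window the pool relaxes first-order from ``steady``
    towards ``famine`` with time constant ``famine_tau_s``; after feed
    resumption it relaxes towards ``recovered`` (default: back to
    ``steady``) with ``recovery_tau_s``.  ``overshoot_amp`` adds an
    alpha-pulse a*x*exp(1-x), x = (t - t_off)/overshoot_tau_s, anchored at
    the famine start — the AMP/ADP/IMP-type transient that peaks during or
    just after starvation and then damps away.
    """

    steady: float                 # umol/g_DMB
    famine: float                 # umol/g_DMB
    famine_tau_s: float = 30.0
    recovery_tau_s: float = 90.0
    overshoot_amp: float = 0.0
    overshoot_tau_s: float = 100.0
    recovered: float | None = None   # post-perturbation level, default steady

    def value(self, t_s, famine_start_s: float = 0.0, famine_end_s: float = 120.0):
        """Noise-free pool size at time(s) ``t_s`` (seconds)."""
        t = np.asarray(t_s, dtype=float)
        out = np.full(t.shape, float(self.steady))
        end_level = self.recovered if self.recovered is not None else self.steady

        in_famine = (t >= famine_start_s) & (t < famine_end_s)
        dt_f = t - famine_start_s
        out = np.where(
            in_famine,
            self.steady + (self.famine - self.steady)
            * (1.0 - np.exp(-dt_f / self.famine_tau_s)),
            out,
        )
        c_end = (self.steady + (self.famine - self.steady)
                 * (1.0 - math.exp(-(famine_end_s - famine_start_s) / self.famine_tau_s)))
        after = t >= famine_end_s
        dt_r = t - famine_end_s
        out = np.where(
            after,
            end_level + (c_end - end_level) * np.exp(-dt_r / self.recovery_tau_s),
            out,
        )
        if self.overshoot_amp != 0.0:
            x = (t - famine_start_s) / self.overshoot_tau_s
            pulse = np.where(x > 0, self.overshoot_amp * x * np.exp(1.0 - x), 0.0)
            out = out + pulse
        return np.maximum(out, 0.0) if out.ndim else max(float(out), 0.0)


def default_metabolite_specs() -> dict[str, MetaboliteDynamics]:
    """Central-catabolism, redox and adenylate panel with famine shapes.

    Levels marked "printed" in the comments come from the study's reported
    means; all other levels are synthetic order-of-magnitude placeholders.
    """
    M = MetaboliteDynamics
    return {
        # upper glycolysis: follow extracellular glucose
        "G6P": M(2.0, 0.5),
        "Hex6P": M(1.0, 0.3),
        "T6P": M(0.5, 0.35, recovery_tau_s=120.0),
        "FBP": M(0.36, 0.14),                       # printed 0.36 -> 0.14
        # lower glycolysis: nearly unperturbed
        "2/3PG": M(1.5, 1.40),
        "PEP": M(1.2, 1.10),
        "PYR": M(1.0, 0.6),
        # pentose phosphate pathway: delayed recovery
        "6PGA": M(0.30, 0.10, recovery_tau_s=240.0),
        "P5P": M(0.60, 0.25, recovery_tau_s=240.0),
        # TCA
        "CIT_ISOCIT": M(4.0, 4.0),
        "aKG": M(1.0, 0.30, recovery_tau_s=180.0),
        # storage / anabolic links (stable on this time scale)
        "UDP-glucose": M(1.5, 1.5),
        "trehalose": M(150.0, 150.0),
        "glycogen": M(300.0, 300.0),
        # adenylates: printed ATP 8.12 -> 3.56; AMP 3.9-fold peak; ADP dip+peak
        "ATP": M(8.12, 3.56),
        "ADP": M(1.30, 0.90, overshoot_amp=0.80, overshoot_tau_s=110.0,
                 recovered=1.10),
        "AMP": M(0.30, 0.30, overshoot_amp=0.87, overshoot_tau_s=100.0),
        # purine salvage: peaks trail AMP by about a minute
        "IMP": M(0.10, 0.10, overshoot_amp=0.15, overshoot_tau_s=140.0),
        "INO": M(0.05, 0.05, overshoot_amp=0.10, overshoot_tau_s=170.0,
                 recovered=0.08),
        "HYX": M(0.02, 0.02, overshoot_amp=0.05, overshoot_tau_s=170.0),
        # nicotinamide couples: NADH printed 0.17, relaxes to 0.10;
        # NADP couple printed total 0.36 at ratio 1.28
        "NADH": M(0.17, 0.06, recovery_tau_s=400.0, recovered=0.10),
        "NAD": M(3.53, 3.53),
        "NADPH": M(0.2015, 0.2015),
        "NADP": M(0.1585, 0.10, recovery_tau_s=150.0),
    }


# ---------------------------------------------------------------------------
# Scenario
# ---------------------------------------------------------------------------

@dataclass
class ScenarioSpec:
    """Complete description of a synthetic stimulus-response experiment.

    The defaults are the reference operating point: continuous feed at
    2.83 mL/min establishing the reference steady state, one 2-min feed
    stop, then 2/7-min cycles at 3.64 mL/min.  Sensor models default to the
    apparent line dynamics (90-s lag behind a 180-s delay) rather than the
    55-s nominal instruments, since tubing and foam traps act as additional
    mixing chambers.  Gas exchange follows uptake through first-order
    biological lags, and a maintenance-respiration floor is calibrated per
    gas so the dynamic-steady-state cycle amplitudes equal the target
    magnitudes (22.8 and 12.3 mmol/L/h).  The gas logging clock is offset
    from the feed-cycle clock, as unsynchronised instruments are in a real
    rig.
    """

    reactor: ReactorParams = field(default_factory=ReactorParams)
    kinetics: KineticParams = field(default_factory=KineticParams)
    cycles: FeedSchedule = field(default_factory=lambda: FeedSchedule(
        mode="intermittent", cycle_period=9.0, off_duration=2.0, on_rate=3.64))
    # apparent line dynamics: mixing chambers make the rig slower than the
    # 55-s nominal sensors (delay of minutes, inflated time constant)
    sensor_o2: SensorModel = SensorModel(delay=180.0, time_constant=90.0)
    sensor_co2: SensorModel = SensorModel(delay=180.0, time_constant=90.0)

    ref_duration_h: float = 0.5
    recovery_min: float = 30.0
    n_cycles: int = 5
    sim_dt_s: float = 1.0
    gas_sampling_s: float = 60.0
    gas_clock_offset_s: float = 15.0

    # gas exchange responds to uptake through intracellular buffering
    # (redox/TCA pools; additionally bicarbonate for CO2), modelled as a
    # first-order lag, and a maintenance floor keeps respiring when uptake
    # stops; the floors are calibrated so the dynamic-steady-state cycle
    # amplitudes match the targets below
    resp_tau_o2_s: float = 60.0
    resp_tau_co2_s: float = 90.0
    target_amplitude_o2: float = 22.8   # mmol/L/h
    target_amplitude_co2: float = 12.3  # mmol/L/h

    metabolites: dict[str, MetaboliteDynamics] = field(
        default_factory=default_metabolite_specs)
    metabolite_times_min: tuple[float, ...] = (
        0.0, 0.5, 1.0, 1.5, 2.0, 2.5, 3.0, 4.0, 5.0, 6.0, 7.0, 8.0, 9.0,
        30.0, 60.0, 120.0, 240.0, 360.0)

    replicates: int = 3
    gas_noise_sd: float = 3e-5          # absolute, mole fraction
    metabolite_noise_sd: float = 0.08   # relative
    biomass_noise_sd: float = 0.005     # relative
    flow_noise_sd: float = 0.003        # relative
    glucose_noise_sd: float = 0.02      # relative
    ammonia_noise_sd: float = 0.01      # relative
    seed: int = 1

    def __post_init__(self) -> None:
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        for name in ("gas_noise_sd", "metabolite_noise_sd", "biomass_noise_sd",
                     "flow_noise_sd", "glucose_noise_sd", "ammonia_noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.resp_tau_o2_s < 0 or self.resp_tau_co2_s < 0:
            raise ValueError("respiration time constants must be >= 0")
        if self.target_amplitude_o2 <= 0 or self.target_amplitude_co2 <= 0:
            raise ValueError("target amplitudes must be positive")


# ---------------------------------------------------------------------------
# Dataset bundle
# ---------------------------------------------------------------------------

@dataclass
class SyntheticDataset:
    """Generated observables plus the ground truth that produced them."""

    trajectory: pd.DataFrame      # 1-s grid: time_s, glucose, biomass, feed, regime
    gas: pd.DataFrame             # logged grid: time_s, y_o2, y_co2 (noisy, smeared)
    gas_true: pd.DataFrame        # logged grid: true volumetric rates
    metabolites: pd.DataFrame     # tidy replicate panel
    measurements: pd.DataFrame    # per-replicate process measurements
    step_o2: pd.DataFrame         # sensor step experiment (O2 channel)
    experiment: dict              # design metadata the analyst legitimately knows
    ground_truth: dict            # generator-internal truth for validation

    def write(self, directory) -> None:
        """Write the bundle as the delimited-text files the pipeline reads."""
        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        self.trajectory.to_csv(d / "trajectory.csv", index=False)
        self.gas.to_csv(d / "offgas.csv", index=False)
        self.gas_true.to_csv(d / "offgas_true.csv", index=False)
        self.metabolites.to_csv(d / "metabolites.csv", index=False)
        self.measurements.to_csv(d / "measurements.csv", index=False)
        self.step_o2.to_csv(d / "step_o2.csv", index=False)
        (d / "experiment.json").write_text(json.dumps(self.experiment, indent=2))
        (d / "ground_truth.json").write_text(json.dumps(self.ground_truth, indent=2))


def _steady_state(spec: ScenarioSpec):
    """Exact continuous-feed operating point implied by the scenario."""
    params, kin = spec.reactor, spec.kinetics
    schedule = FeedSchedule(mode="continuous")
    D = physiology.average_dilution(schedule, params)
    cs_ss = kin.steady_state_glucose(D)
    x_ss = kin.yield_xs * (params.feed_glucose - cs_ss * reactor.GLUCOSE_MOLAR_MASS * 1e-6)
    return D, cs_ss, x_ss


def _stoichiometric_rates(spec: ScenarioSpec, D: float, x_ss: float):
    """Specific rate set that closes C, N and electron balances exactly."""
    kin = spec.kinetics
    q_glc = D / (kin.yield_xs * reactor.GLUCOSE_MOLAR_MASS * 1e-3)   # mmol/g/h
    bio = physiology.BIOMASS_DEFAULT
    mu_cmol = D / bio.cmol_mass * 1000.0                              # mmol_C/g/h
    q_co2 = 6.0 * q_glc - mu_cmol
    q_o2 = (physiology.GLUCOSE.gamma_per_cmol * 6.0 * q_glc
            - bio.gamma_per_cmol * mu_cmol) / 4.0
    q_nh3 = (bio.N / bio.C) * mu_cmol
    return {"q_glucose": q_glc, "q_oxygen": q_o2, "q_co2": q_co2, "q_ammonia": q_nh3}


def generate_sre_dataset(spec: ScenarioSpec) -> SyntheticDataset:
    """Simulate the full experiment and emit the observable bundle.

    Phases: reference steady state (continuous feed), a single 2-min feed
    stop followed by continuous-feed recovery, then ``n_cycles`` intermittent
    2/7-min cycles.  See the module docstring for the observation model.
    """
    params, kin = spec.reactor, spec.kinetics
    dt = spec.sim_dt_s
    D, cs_ss, x_ss = _steady_state(spec)
    rates = _stoichiometric_rates(spec, D, x_ss)

    # --- phase simulation on the fine grid -------------------------------
    continuous = FeedSchedule(mode="continuous")
    single_period_min = spec.cycles.off_duration + spec.recovery_min
    single = FeedSchedule(mode="intermittent", cycle_period=single_period_min,
                          off_duration=spec.cycles.off_duration,
                          on_rate=params.base_feed_rate)

    traj_rs = reactor.simulate_chemostat(
        params, continuous, kin, init=(cs_ss, x_ss),
        duration=spec.ref_duration_h, dt=dt)
    traj_single = reactor.simulate_chemostat(
        params, single, kin,
        init=(traj_rs.glucose[-1], traj_rs.biomass[-1]),
        duration=single_period_min / 60.0, dt=dt)
    traj_ds = reactor.simulate_chemostat(
        params, spec.cycles, kin,
        init=(traj_single.glucose[-1], traj_single.biomass[-1]),
        duration=spec.n_cycles * spec.cycles.cycle_period / 60.0, dt=dt)

    t_rs_end = float(traj_rs.time[-1])
    t_ds_start = t_rs_end + float(traj_single.time[-1])
    time = np.concatenate([
        traj_rs.time,
        t_rs_end + traj_single.time[1:],
        t_ds_start + traj_ds.time[1:],
    ])
    glucose = np.concatenate([traj_rs.glucose, traj_single.glucose[1:], traj_ds.glucose[1:]])
    biomass = np.concatenate([traj_rs.biomass, traj_single.biomass[1:], traj_ds.biomass[1:]])
    feed_on = np.concatenate([traj_rs.feed_active, traj_single.feed_active[1:],
                              traj_ds.feed_active[1:]])
    traj = StateTrajectory(time=time, glucose=glucose, biomass=biomass,
                           volume=params.working_volume, feed_active=feed_on)

    # --- true gas rates ---------------------------------------------------
    uptake = kin.uptake_rate(glucose) * biomass          # mmol/L/h volumetric
    u_ss = rates["q_glucose"] * x_ss
    y_og = rates["q_oxygen"] / rates["q_glucose"]        # mol O2 per mol glc
    y_cg = rates["q_co2"] / rates["q_glucose"]

    log_t = np.arange(spec.gas_clock_offset_s, time[-1] + 1e-9, spec.gas_sampling_s)
    idx = np.searchsorted(time, log_t - 1e-9)
    period_s = spec.cycles.cycle_period * 60.0

    def true_rate(yield_per_glc, resp_tau, target_amp):
        # biologically lagged volumetric rate, then a maintenance floor
        # calibrated so the DS cycle amplitude hits the target
        q_unfloored = yield_per_glc * uptake
        if resp_tau > 0:
            q_unfloored = offgas.convolve_sensor(
                time, q_unfloored, SensorModel(delay=0.0, time_constant=resp_tau))
        amps = offgas.cycle_amplitudes(log_t, q_unfloored[idx], period_s,
                                       t_start=t_ds_start)
        floor = 0.0
        if amps.size and amps.mean() > target_amp:
            floor = 1.0 - target_amp / amps.mean()
        return floor * yield_per_glc * u_ss + (1.0 - floor) * q_unfloored, floor

    q_o2_true, floor_o2 = true_rate(y_og, spec.resp_tau_o2_s, spec.target_amplitude_o2)
    q_co2_true, floor_co2 = true_rate(y_cg, spec.resp_tau_co2_s, spec.target_amplitude_co2)

    y_o2_true, y_co2_true = offgas.fractions_from_rates(
        q_o2_true, q_co2_true, volume=params.working_volume,
        gas_flow_in=params.gas_flow_in)

    # --- sensor smearing, logging grid, noise ----------------------------
    y_o2_meas = offgas.convolve_sensor(time, y_o2_true, spec.sensor_o2)
    y_co2_meas = offgas.convolve_sensor(time, y_co2_true, spec.sensor_co2)
    seeds = np.random.SeedSequence(spec.seed).spawn(4)
    rng_gas, rng_met, rng_proc, rng_step = (np.random.default_rng(s) for s in seeds)

    def log_channel(y, rng):
        sampled = y[idx]
        noisy = sampled + rng.normal(0.0, spec.gas_noise_sd, sampled.shape)
        return np.clip(noisy, 0.0, 1.0)

    gas = pd.DataFrame({
        "time_s": log_t,
        "y_o2": log_channel(y_o2_meas, rng_gas),
        "y_co2": log_channel(y_co2_meas, rng_gas),
    })
    gas_true = pd.DataFrame({
        "time_s": log_t,
        "q_o2_mmol_L_h": q_o2_true[idx],
        "q_co2_mmol_L_h": q_co2_true[idx],
    })

    # --- metabolite panel (non-adapted clock: 0 = single feed stop) ------
    famine_len_s = spec.cycles.off_duration * 60.0
    t_met = np.asarray(spec.metabolite_times_min, dtype=float) * 60.0
    rows = []
    truth_met = {}
    for name, dyn in spec.metabolites.items():
        truth = dyn.value(t_met, famine_start_s=0.0, famine_end_s=famine_len_s)
        truth_met[name] = {str(tm): float(v)
                           for tm, v in zip(spec.metabolite_times_min, truth)}
        for rep in range(1, spec.replicates + 1):
            noise = rng_met.normal(0.0, spec.metabolite_noise_sd, truth.shape)
            vals = np.maximum(truth * (1.0 + noise), 0.0)
            for tm, v in zip(spec.metabolite_times_min, vals):
                rows.append((tm, name, rep, v))
    metabolites = pd.DataFrame(rows, columns=list(
        ("sample_time_min", "metabolite", "replicate", "value_umol_gDMB")))

    # --- process measurements (replicate steady-state determinations) ----
    feed_n = FEED_AMMONIA_MMOL_L
    res_n = feed_n - rates["q_ammonia"] * x_ss / D
    n = spec.replicates

    def noisy(value, rel_sd, rng):
        return value * (1.0 + rng.normal(0.0, rel_sd, n))

    measurements = pd.DataFrame({
        "replicate": np.arange(1, n + 1),
        "feed_rate_mL_min": noisy(params.base_feed_rate, spec.flow_noise_sd, rng_proc),
        "biomass_g_L": noisy(x_ss, spec.biomass_noise_sd, rng_proc),
        "residual_glucose_umol_L": noisy(cs_ss, spec.glucose_noise_sd, rng_proc),
        "feed_glucose_g_L": np.full(n, params.feed_glucose),
        "feed_ammonia_mmol_L": np.full(n, feed_n),
        "residual_ammonia_mmol_L": noisy(res_n, spec.ammonia_noise_sd, rng_proc),
        "other_carbon_mmol_L": np.zeros(n),
    })

    # --- sensor step experiment (noise in amplitude units) ----------------
    step_amp = 0.02
    step = make_step_experiment(spec.sensor_o2, noise_sd=spec.gas_noise_sd / step_amp,
                                rng=rng_step, amplitude=step_amp,
                                baseline=offgas.AIR_O2_FRACTION - step_amp,
                                dt=spec.gas_sampling_s, step_time=600.0)

    ds_amp_o2 = offgas.cycle_amplitudes(log_t, q_o2_true[idx], period_s,
                                        t_start=t_ds_start)
    ds_amp_co2 = offgas.cycle_amplitudes(log_t, q_co2_true[idx], period_s,
                                         t_start=t_ds_start)

    experiment = {
        "working_volume_L": params.working_volume,
        "feed_glucose_g_L": params.feed_glucose,
        "base_feed_rate_mL_min": params.base_feed_rate,
        "gas_flow_in_NL_min": params.gas_flow_in,
        "inlet_o2": offgas.AIR_O2_FRACTION,
        "inlet_co2": offgas.AIR_CO2_FRACTION,
        "cycle_period_min": spec.cycles.cycle_period,
        "off_duration_min": spec.cycles.off_duration,
        "on_rate_mL_min": spec.cycles.on_rate,
        "phase_rs_end_s": t_rs_end,
        "phase_ds_start_s": t_ds_start,
        "sensor_o2": {"delay_s": spec.sensor_o2.delay,
                      "time_constant_s": spec.sensor_o2.time_constant},
        "sensor_co2": {"delay_s": spec.sensor_co2.delay,
                       "time_constant_s": spec.sensor_co2.time_constant},
        "step_time_s": float(step.attrs["step_time_s"]),
        "gas_sampling_s": spec.gas_sampling_s,
    }
    ground_truth = {
        "seed": spec.seed,
        "respiration_floor_o2": floor_o2,
        "respiration_floor_co2": floor_co2,
        "dilution_rate_h": D,
        "steady_glucose_umol_L": cs_ss,
        "steady_biomass_g_L": x_ss,
        "specific_rates_mmol_g_h": rates,
        "Q_o2_steady_mmol_L_h": float(rates["q_oxygen"] * x_ss),
        "Q_co2_steady_mmol_L_h": float(rates["q_co2"] * x_ss),
        "ds_cycle_amplitude_o2_mmol_L_h": float(ds_amp_o2.mean()) if ds_amp_o2.size else None,
        "ds_cycle_amplitude_co2_mmol_L_h": float(ds_amp_co2.mean()) if ds_amp_co2.size else None,
        "metabolite_levels": truth_met,
    }

    traj_df = traj.to_frame(kin)
    return SyntheticDataset(
        trajectory=traj_df, gas=gas, gas_true=gas_true,
        metabolites=metabolites, measurements=measurements, step_o2=step,
        experiment=experiment, ground_truth=ground_truth,
    )


# ---------------------------------------------------------------------------
# Step experiments
# ---------------------------------------------------------------------------

def make_step_experiment(
    model: SensorModel,
    noise_sd: float = 0.0,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    dt: float = 1.0,
    step_time: float = 120.0,
    baseline: float = 0.0,
    amplitude: float = 1.0,
    duration: float | None = None,
) -> pd.DataFrame:
    """Synthetic sensor step experiment (water-filled reactor, gas step).

    Returns a DataFrame with columns ``time_s`` and ``response``; the true
    model and step time are stored in ``DataFrame.attrs``.  ``noise_sd`` is
    additive, in units of the step amplitude.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    if duration is None:
        duration = step_time + model.delay + 8.0 * max(model.time_constant, dt) + 60.0
    time = np.arange(0.0, duration + 1e-9, dt)
    x = np.where(time >= step_time, baseline + amplitude, baseline)
    y = offgas.convolve_sensor(time, x, model)
    if noise_sd > 0:
        y = y + rng.normal(0.0, noise_sd * abs(amplitude), y.shape)
    df = pd.DataFrame({"time_s": time, "response": y})
    df.attrs["step_time_s"] = float(step_time)
    df.attrs["true_delay_s"] = float(model.delay)
    df.attrs["true_time_constant_s"] = float(model.time_constant)
    return df
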