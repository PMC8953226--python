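"""End-to-end analysis: bundle in, physiology + metabolome report out.

Consumes the delimited-text bundle layout written by
:meth:`sretools.synth.SyntheticDataset.write` (or assembled from real
measurements in the same formats):

* ``experiment.json`` — design metadata (geometry, schedule, sensors),
* ``measurements.csv`` — replicate steady-state process measurements,
* ``offgas.csv`` — logged O2/CO2 mole fractions,
* ``metabolites.csv`` — tidy replicate metabolite panel,
* ``step_o2.csv`` (optional) — sensor step experiment.

and produces the balance table, the steady-state kinetics comparison table,
charge-ratio time series, the MDS coordinate table and a JSON summary of
headline quantities.  The run is deterministic: identical inputs give
byte-identical outputs.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import metabolome, offgas, physiology
from .io import PipelineConfig, read_timeseries, write_table
from .offgas import GasSeries, SensorModel
from .physiology import PhenotypeRecord
from .reactor import FeedSchedule, ReactorParams

logger = logging.getLogger("sretools")

REQUIRED_FILES = ("experiment.json", "measurements.csv", "offgas.csv", "metabolites.csv")


@dataclass
class PipelineResult:
    balances: pd.DataFrame         # recoveries per steady state
    kinetics_table: pd.DataFrame   # RS vs DS comparison
    charges: pd.DataFrame          # AEC + reduction charges over time
    mds_coordinates: pd.DataFrame
    relaxation: pd.DataFrame
    summary: dict

    def tables(self) -> dict[str, pd.DataFrame]:
        return {
            "table_balances": self.balances,
            "table_kinetics": self.kinetics_table,
            "charges": self.charges,
            "mds_coordinates": self.mds_coordinates,
            "relaxation": self.relaxation,
        }


def _require_files(input_dir: Path) -> None:
    missing = [name for name in REQUIRED_FILES if not (input_dir / name).exists()]
    if missing:
        raise FileNotFoundError(
            f"input bundle {input_dir} is missing required file(s): "
            + ", ".join(missing))


def analyze_gas(
    gas_df: pd.DataFrame,
    experiment: dict,
    sensor_o2: SensorModel,
    sensor_co2: SensorModel,
) -> pd.DataFrame:
    """Deconvolve logged mole fractions and convert to volumetric rates.

    Returns a frame with raw and deconvolved rates; the trailing samples
    that the dead-time shift cannot reconstruct are dropped.
    """
    t = gas_df["time_s"].to_numpy(dtype=float)
    dt = float(np.diff(t).mean())
    y_o2_dec = offgas.deconvolve_signal(t, gas_df["y_o2"].to_numpy(float), sensor_o2)
    y_co2_dec = offgas.deconvolve_signal(t, gas_df["y_co2"].to_numpy(float), sensor_co2)
    nd = max(int(round(sensor_o2.delay / dt)), int(round(sensor_co2.delay / dt)))
    valid = len(t) - nd if nd > 0 else len(t)

    def rates(y_o2, y_co2):
        series = GasSeries(
            time=t[:valid], y_o2=np.clip(y_o2[:valid], 0, 1),
            y_co2=np.clip(y_co2[:valid], 0, 1),
            inlet_o2=experiment["inlet_o2"], inlet_co2=experiment["inlet_co2"],
            gas_flow_in=experiment["gas_flow_in_NL_min"])
        return offgas.gas_transfer_rates(series, experiment["working_volume_L"])

    q_o2_raw, q_co2_raw = rates(gas_df["y_o2"].to_numpy(float),
                                gas_df["y_co2"].to_numpy(float))
    q_o2, q_co2 = rates(y_o2_dec, y_co2_dec)
    return pd.DataFrame({
        "time_s": t[:valid],
        "q_o2_raw": q_o2_raw, "q_co2_raw": q_co2_raw,
        "q_o2": q_o2, "q_co2": q_co2,
    })


def _phenotype(measurements: pd.DataFrame, D, q_o2: float, q_co2: float) -> PhenotypeRecord:
    return physiology.specific_rates(
        dilution_rate=D,
        biomass_g_L=measurements["biomass_g_L"].to_numpy(float),
        feed_glucose_g_L=float(measurements["feed_glucose_g_L"].iloc[0]),
        residual_glucose_umol_L=measurements["residual_glucose_umol_L"].to_numpy(float),
        Q_oxygen=q_o2, Q_co2=q_co2,
        feed_ammonia_mmol_L=float(measurements["feed_ammonia_mmol_L"].iloc[0]),
        residual_ammonia_mmol_L=measurements["residual_ammonia_mmol_L"].to_numpy(float),
        other_carbon_mmol_L=measurements["other_carbon_mmol_L"].to_numpy(float),
    )


def charge_series(panel: metabolome.MetabolitePanel) -> pd.DataFrame:
    """AEC and reduction charges per sample time (replicate means + sds)."""
    stats = panel.replicate_stats().set_index(["sample_time_min", "metabolite"])
    rows = []
    for t in panel.times:
        def get(name, col="mean"):
            try:
                return float(stats.loc[(t, name), col])
            except KeyError:
                return float("nan")
        atp, adp, amp = (get(n) for n in ("ATP", "ADP", "AMP"))
        row = {"sample_time_min": t}
        if not any(np.isnan([atp, adp, amp])):
            row["aec"] = metabolome.energy_charge(atp, adp, amp)
            row["aec_sd"] = metabolome.energy_charge_sd(
                atp, adp, amp, *(get(n, "sd") for n in ("ATP", "ADP", "AMP")))
            row["axp_total"] = atp + adp + amp
        nadh, nad, nadph, nadp = (get(n) for n in ("NADH", "NAD", "NADPH", "NADP"))
        if not any(np.isnan([nadh, nad, nadph, nadp])):
            cs = metabolome.reduction_charges(
                nadh, nad, nadph, nadp,
                sds=tuple(get(n, "sd") for n in ("NADH", "NAD", "NADPH", "NADP")))
            row["catabolic_charge"] = cs.catabolic_charge
            row["anabolic_charge"] = cs.anabolic_charge
            row["nadph_nadp_ratio"] = cs.nadph_nadp_ratio
        rows.append(row)
    return pd.DataFrame(rows)


def run_pipeline(
    config: PipelineConfig,
    input_dir,
    output_dir=None,
) -> PipelineResult:
    """Execute simulate-free analysis of a measurement bundle.

    Validation failures (missing files, schema errors) abort before any
    computation; see the module docstring for the bundle layout.
    """
    input_dir = Path(input_dir)
    _require_files(input_dir)
    experiment = json.loads((input_dir / "experiment.json").read_text())
    measurements = pd.read_csv(input_dir / "measurements.csv")
    gas_df = read_timeseries(input_dir / "offgas.csv", ("time_s", "y_o2", "y_co2"))
    panel = metabolome.MetabolitePanel.from_csv(input_dir / "metabolites.csv")

    # sensor models: identified from the bundled step experiment when present
    sensor_o2, sensor_co2 = config.sensors["o2"], config.sensors["co2"]
    step_path = input_dir / "step_o2.csv"
    if step_path.exists() and "step_time_s" in experiment:
        step = read_timeseries(step_path, ("time_s", "response"))
        sensor_o2 = offgas.identify_sensor_model(
            step["time_s"].to_numpy(float), step["response"].to_numpy(float),
            step_time=experiment["step_time_s"])
        sensor_co2 = sensor_o2
        logger.info("identified sensor model: delay=%.1f s tau=%.1f s",
                    sensor_o2.delay, sensor_o2.time_constant)

    gas = analyze_gas(gas_df, experiment, sensor_o2, sensor_co2)

    # --- steady-state windows --------------------------------------------
    volume = experiment["working_volume_L"]
    rs_end = experiment["phase_rs_end_s"]
    ds_start = experiment["phase_ds_start_s"]
    period_s = experiment["cycle_period_min"] * 60.0

    # keep the steady window clear of the first transition: the regularized
    # deconvolution is a global fit and can pre-ring slightly ahead of an edge
    margin = sensor_o2.delay + 2.0 * sensor_o2.time_constant
    rs_mask = gas["time_s"] < rs_end - margin
    ds_mask = gas["time_s"] >= ds_start
    if not rs_mask.any() or not ds_mask.any():
        raise ValueError("gas series does not cover both steady-state windows")

    flow = measurements["feed_rate_mL_min"].to_numpy(float)
    D_rs = flow / 1000.0 * 60.0 / volume
    D_ds = physiology.average_dilution(
        FeedSchedule(mode="intermittent",
                     cycle_period=experiment["cycle_period_min"],
                     off_duration=experiment["off_duration_min"],
                     on_rate=experiment["on_rate_mL_min"]),
        ReactorParams(working_volume=volume,
                      feed_glucose=experiment["feed_glucose_g_L"],
                      base_feed_rate=experiment["base_feed_rate_mL_min"],
                      gas_flow_in=experiment["gas_flow_in_NL_min"]))

    rs = _phenotype(measurements, D_rs,
                    float(gas.loc[rs_mask, "q_o2"].mean()),
                    float(gas.loc[rs_mask, "q_co2"].mean()))
    ds = _phenotype(measurements, np.full(len(measurements), D_ds),
                    float(gas.loc[ds_mask, "q_o2"].mean()),
                    float(gas.loc[ds_mask, "q_co2"].mean()))

    bal_rows = []
    for label, rec in (("RS", rs), ("DS", ds)):
        rep = physiology.recoveries(rec)
        bal_rows.append({
            "steady_state": label,
            "carbon_recovery_pct": rep.carbon_recovery,
            "carbon_sd": rep.carbon_sd,
            "nitrogen_recovery_pct": rep.nitrogen_recovery,
            "nitrogen_sd": rep.nitrogen_sd,
            "ave_recovery_pct": rep.ave_recovery,
            "ave_sd": rep.ave_sd,
        })
    balances = pd.DataFrame(bal_rows)
    kinetics_table = physiology.phenotype_table(rs, ds)

    # --- gas cycle amplitudes at the dynamic steady state ----------------
    t_gas = gas["time_s"].to_numpy(float)
    ds_t0 = t_gas[t_gas >= ds_start][0]
    amp_o2 = offgas.cycle_amplitudes(t_gas, gas["q_o2"].to_numpy(float),
                                     period_s, t_start=ds_t0)
    amp_co2 = offgas.cycle_amplitudes(t_gas, gas["q_co2"].to_numpy(float),
                                      period_s, t_start=ds_t0)
    amp_o2_raw = offgas.cycle_amplitudes(t_gas, gas["q_o2_raw"].to_numpy(float),
                                         period_s, t_start=ds_t0)
    amp_co2_raw = offgas.cycle_amplitudes(t_gas, gas["q_co2_raw"].to_numpy(float),
                                          period_s, t_start=ds_t0)

    # --- metabolome -------------------------------------------------------
    charges = charge_series(panel)
    include = config.metabolome.get("include")
    exclude = set(config.metabolome.get("exclude") or [])
    matrix = panel.mean_matrix(include=include)
    matrix = matrix[[c for c in matrix.columns if c not in exclude]]
    norm = metabolome.minmax_normalize(matrix)
    dist = metabolome.distance_matrix(norm)
    mds = metabolome.classical_mds(dist, k=int(config.metabolome.get("mds_dimensions", 2)))
    coords = mds.coordinates.copy()
    coords.insert(0, "sample_time_min", coords.index)
    for j, frac in enumerate(mds.variance_fraction):
        coords[f"dim{j + 1}_variance_fraction"] = frac

    times = list(panel.times)
    attractor = 9.0 if 9.0 in times else times[-1]
    relax = metabolome.relaxation_metrics(mds, reference_label=times[0],
                                          attractor_label=attractor)
    relaxation = relax.distances.copy()
    relaxation.insert(0, "sample_time_min", relaxation.index)

    summary = {
        "dilution_rate_rs_h": float(np.mean(D_rs)),
        "dilution_rate_ds_h": float(D_ds),
        "q_glucose_rs": rs.q_glucose.mean,
        "q_oxygen_rs": rs.q_oxygen.mean,
        "q_co2_rs": rs.q_co2.mean,
        "carbon_recovery_rs_pct": float(balances.loc[0, "carbon_recovery_pct"]),
        "nitrogen_recovery_rs_pct": float(balances.loc[0, "nitrogen_recovery_pct"]),
        "ave_recovery_rs_pct": float(balances.loc[0, "ave_recovery_pct"]),
        "ds_amplitude_o2_mmol_L_h": float(amp_o2.mean()) if amp_o2.size else None,
        "ds_amplitude_co2_mmol_L_h": float(amp_co2.mean()) if amp_co2.size else None,
        "ds_amplitude_o2_raw_mmol_L_h": float(amp_o2_raw.mean()) if amp_o2_raw.size else None,
        "ds_amplitude_co2_raw_mmol_L_h": float(amp_co2_raw.mean()) if amp_co2_raw.size else None,
        "sensor_delay_s": sensor_o2.delay,
        "sensor_time_constant_s": sensor_o2.time_constant,
        "mds_variance_fraction": [float(f) for f in mds.variance_fraction],
        "metabolome_converged_to_attractor": relax.monotone_convergence,
    }

    result = PipelineResult(balances=balances, kinetics_table=kinetics_table,
                            charges=charges, mds_coordinates=coords,
                            relaxation=relaxation, summary=summary)
    if output_dir is not None:
        write_report(result, output_dir)
    return result


def write_report(result: PipelineResult, output_dir) -> None:
    """Write all result tables as CSV plus a human-readable summary."""
    out = Path(output_dir)
    out.mkdir(parents=True, exist_ok=True)
    for name, df in result.tables().items():
        write_table(df, out / f"{name}.csv")
    (out / "summary.json").write_text(json.dumps(result.summary, indent=2) + "\n")
    lines = ["Stimulus-response experiment report", "=" * 36, ""]
    lines.append("Balance closures (%):")
    lines.append(result.balances.to_string(index=False, float_format="%.2f"))
    lines.append("")
    lines.append("Steady-state kinetics (uptake rates rendered negative):")
    lines.append(result.kinetics_table.to_string(index=False))
    lines.append("")
    for key, val in result.summary.items():
        lines.append(f"{key}: {val}")
    (out / "report.txt").write_text("\n".join(lines) + "\n")
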