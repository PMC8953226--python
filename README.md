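# sretools

Quantitative physiology and metabolome-relaxation analysis for chemostat
**famine stimulus-response experiments** (SRE) in *Saccharomyces
cerevisiae* — and, more generally, for any glucose-limited culture exposed
to repeated feed interruptions.

Industrial-scale bioreactors mix imperfectly: cells circulating through a
large vessel repeatedly traverse zones where glucose is exhausted, so a
"steady" carbon-limited process is, from the cell's perspective, a train of
limitation → starvation → limitation transitions. Scale-down experiments
reproduce this in the lab by running a chemostat at dilution rate
D = 0.1 h⁻¹ and switching the feed off for 2 minutes out of every 9 (feed-on
rate raised to 3.64 mL·min⁻¹ so the average D is unchanged). `sretools`
implements the complete quantitative analysis of such an experiment:

* **`sretools.reactor`** — chemostat simulation with intermittent feeding
  (Monod uptake q_s = q_max·C/(K_M + C), yield-coupled growth, RK4),
  metabolic-regime classification (overflow > 207 µmol/L, starvation
  < 53 µmol/L), residence-time fractions of glucose lifelines and
  semilogarithmic depletion slopes.
* **`sretools.offgas`** — first-order-plus-delay sensor identification from
  step experiments, forward smearing, regularized deconvolution, and
  O₂/CO₂ transfer rates Q from the inert-gas balance.
* **`sretools.physiology`** — biomass-specific rates (−q_glucose,
  −q_oxygen, q_CO₂, …), carbon / nitrogen / available-electron recoveries by
  degree-of-reduction balancing (γ_X = 4.2 for CH₁.₈O₀.₅N₀.₂),
  q_ATP = 2·q_glc + 2·(P/O)·q_O₂, and Welch tests between steady states.
* **`sretools.metabolome`** — adenylate energy charge
  (ATP + ½ADP)/(ATP + ADP + AMP), catabolic and anabolic reduction charges
  NADH/(NADH + NAD⁺) and NADPH/(NADPH + NADP⁺), min–max normalisation,
  Euclidean distances and classical (Torgerson) MDS trajectories of the
  metabolome relaxation, with distance-to-attractor metrics.
* **`sretools.synth`** — a seeded generator that emulates the whole
  experiment (glucose trajectories, sensor-smeared off-gas logs, triplicate
  metabolite panels) with known ground truth, so every pipeline stage is
  testable without external data.
* **`sretools.pipeline` / `sretools` CLI** — the stages wired into one
  deterministic, config-driven run.

See `docs/methods.md` for the models, defaults and their rationale.

## Worked example

Generate a synthetic experiment (seeded, with ground truth) and analyse it:

```bash
sretools synth generate --seed 1 --out demo/bundle
sretools report --dir demo/bundle --out demo/report
```

The report command prints a JSON summary (abridged):

```
{
  "dilution_rate_rs_h": 0.10001614204925903,
  "q_glucose_rs": 1.1279531510331253,
  "q_oxygen_rs": 2.4851636852311443,
  "carbon_recovery_rs_pct": 99.73574779774323,
  "ds_amplitude_o2_mmol_L_h": 22.491739543518367,
  "ds_amplitude_o2_raw_mmol_L_h": 13.112282087417203,
  "sensor_delay_s": 180.0,
  "sensor_time_constant_s": 90.03763358413104,
  "metabolome_converged_to_attractor": true
}
```

Reading these numbers: the pipeline re-estimated the dilution rate
(0.1000 h⁻¹) from the noisy flow readings; the glucose uptake rate is
1.13 mmol·g⁻¹·h⁻¹; the carbon balance closes at 99.7% under measurement
noise (exactly 100.0% if the bundle is generated with `--no-noise`). The
off-gas section shows why deconvolution matters: the O₂ cycle amplitude
recovered after inverting the identified sensor dynamics (delay 180 s,
τ ≈ 90 s) is 22.5 mmol·L⁻¹·h⁻¹ — within 2% of the ground truth — while the
raw smeared signal would report only 13.1, a 42% underestimate. The final
flag records that the metabolome MDS trajectory converges monotonically onto
its attractor sample.

`demo/report/` also contains `table_balances.csv` (recoveries per steady
state), `table_kinetics.csv` (the RS vs DS rate comparison with Welch
p-values and the "n.s." convention), `charges.csv` (energy and redox charges
over time), `mds_coordinates.csv` and `relaxation.csv`.

Individual stages are available as subcommands (`simulate`,
`offgas identify|deconvolve`, `rates`, `balance`,
`metabolome charges|mds`, `synth generate`) and, more flexibly, as library
functions:

```python
from sretools import FeedSchedule, ReactorParams, average_dilution
average_dilution(FeedSchedule(mode="intermittent"), ReactorParams())
# 0.0999... — the 7-of-9-min schedule at 3.64 mL/min in 1.7 L
```

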