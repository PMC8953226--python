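"""Biomass-specific rates, elemental balancing and steady-state comparison.

Converts reconciled process measurements (feed, harvest, off-gas, biomass)
into the biomass-specific rate set of a chemostat steady state, closes
carbon / nitrogen / available-electron balances with the degree-of-reduction
convention (gamma(C)=4, gamma(H)=1, gamma(O)=-2, gamma(N)=-3 for an ammonia
nitrogen source), estimates the ATP production rate from a P/O ratio, and
compares two steady states with Welch's unequal-variance t-test.

Sign convention: uptake rates are stored as positive magnitudes; report
renderers prefix a minus where the conventional tabulation does.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import t as t_dist

from .reactor import GLUCOSE_MOLAR_MASS, FeedSchedule, ReactorParams

# ---------------------------------------------------------------------------
# Elemental compositions
# ---------------------------------------------------------------------------

#: Electrons available per atom when burning to CO2, H2O and NH3.
_GAMMA = {"C": 4.0, "H": 1.0, "O": -2.0, "N": -3.0}
_ATOMIC_MASS = {"C": 12.011, "H": 1.008, "O": 15.999, "N": 14.007}


@dataclass(frozen=True)
class ElementalComposition:
    """Elemental formula C_c H_h O_o N_n of one flow compound."""

    C: float
    H: float
    O: float = 0.0
    N: float = 0.0

    @property
    def gamma_total(self) -> float:
        """Degree of reduction of the whole molecule (ammonia N convention)."""
        return (_GAMMA["C"] * self.C + _GAMMA["H"] * self.H
                + _GAMMA["O"] * self.O + _GAMMA["N"] * self.N)

    @property
    def gamma_per_cmol(self) -> float:
        if self.C == 0:
            raise ValueError("gamma per C-mol undefined for carbon-free compounds")
        return self.gamma_total / self.C

    @property
    def cmol_mass(self) -> float:
        """Mass of one C-mol, g."""
        if self.C == 0:
            raise ValueError("C-mol mass undefined for carbon-free compounds")
        return (_ATOMIC_MASS["C"] * self.C + _ATOMIC_MASS["H"] * self.H
                + _ATOMIC_MASS["O"] * self.O + _ATOMIC_MASS["N"] * self.N) / self.C


GLUCOSE = ElementalComposition(C=6, H=12, O=6)
#: Standard yeast C-mol formula; the source dataset does not print its own.
BIOMASS_DEFAULT = ElementalComposition(C=1, H=1.8, O=0.5, N=0.2)


# ---------------------------------------------------------------------------
# Rate containers
# ---------------------------------------------------------------------------

class Measurement:
    """Replicate values of one measured quantity."""

    __slots__ = ("values",)

    def __init__(self, values):
        arr = np.atleast_1d(np.asarray(values, dtype=float))
        if arr.size < 1 or not np.all(np.isfinite(arr)):
            raise ValueError("measurement needs at least one finite value")
        self.values = arr

    @classmethod
    def from_summary(cls, mean: float, sd: float, n: int = 3) -> "Measurement":
        """Deterministic replicate set matching a printed mean +/- sd.

        For n = 3 the set {m - sd, m, m + sd} reproduces mean and sample
        standard deviation exactly; for n = 2, {m - sd/sqrt(2), m + sd/sqrt(2)}.
        """
        if sd < 0:
            raise ValueError("sd must be >= 0")
        if n == 3:
            return cls([mean - sd, mean, mean + sd])
        if n == 2:
            h = sd / math.sqrt(2.0)
            return cls([mean - h, mean + h])
        if n == 1:
            return cls([mean])
        raise ValueError("summary reconstruction supports n in {1, 2, 3}")

    @property
    def mean(self) -> float:
        return float(self.values.mean())

    @property
    def sd(self) -> float:
        return 0.0 if self.values.size < 2 else float(self.values.std(ddof=1))

    @property
    def n(self) -> int:
        return int(self.values.size)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"Measurement(mean={self.mean:.4g}, sd={self.sd:.2g}, n={self.n})"


@dataclass
class PhenotypeRecord:
    """Biomass-specific rate and yield set of one steady state.

    Rates in mmol g_DMB^-1 h^-1 (magnitudes; uptake positive), D in 1/h,
    yield in g_DMB per g glucose.  Any entry may be None when unmeasured.
    """

    D: Measurement | None = None
    Y_xs: Measurement | None = None
    q_glucose: Measurement | None = None
    q_oxygen: Measurement | None = None
    q_co2: Measurement | None = None
    q_ammonia: Measurement | None = None
    q_other_carbon: Measurement | None = None   # mmol_C g^-1 h^-1

    def require(self, *names: str) -> None:
        missing = [n for n in names if getattr(self, n) is None]
        if missing:
            raise ValueError(f"PhenotypeRecord is missing: {', '.join(missing)}")


@dataclass(frozen=True)
class BalanceReport:
    """Carbon, nitrogen and available-electron recoveries in percent."""

    carbon_recovery: float
    nitrogen_recovery: float
    ave_recovery: float
    carbon_sd: float = 0.0
    nitrogen_sd: float = 0.0
    ave_sd: float = 0.0

    def as_dict(self) -> dict[str, float]:
        return {
            "carbon_recovery_pct": self.carbon_recovery,
            "nitrogen_recovery_pct": self.nitrogen_recovery,
            "ave_recovery_pct": self.ave_recovery,
        }


# ---------------------------------------------------------------------------
# Rates
# ---------------------------------------------------------------------------

def specific_rates(
    *,
    dilution_rate,
    biomass_g_L,
    feed_glucose_g_L: float,
    residual_glucose_umol_L=0.0,
    Q_oxygen=None,
    Q_co2=None,
    feed_ammonia_mmol_L: float | None = None,
    residual_ammonia_mmol_L=None,
    other_carbon_mmol_L=None,
) -> PhenotypeRecord:
    """Biomass-specific rates from steady-state process measurements.

    Scalar or per-replicate array inputs are accepted; replicates are
    combined elementwise (all arrays must broadcast).  ``Q_oxygen`` and
    ``Q_co2`` are volumetric rates in mmol L^-1 h^-1 (e.g. from
    :func:`sretools.offgas.gas_transfer_rates`, averaged over the steady
    window); dissolved species as concentrations, converted with the
    dilution rate.
    """
    D = np.atleast_1d(np.asarray(dilution_rate, dtype=float))
    X = np.atleast_1d(np.asarray(biomass_g_L, dtype=float))
    if np.any(X <= 0):
        raise ValueError("biomass must be strictly positive")
    if np.any(D < 0) or feed_glucose_g_L < 0:
        raise ValueError("flows must be non-negative")
    res = np.atleast_1d(np.asarray(residual_glucose_umol_L, dtype=float))
    delta_glc_g_L = feed_glucose_g_L - res * GLUCOSE_MOLAR_MASS * 1e-6
    if np.any(delta_glc_g_L < 0):
        raise ValueError("residual glucose exceeds the feed concentration")

    q_glc = D * delta_glc_g_L / (X * GLUCOSE_MOLAR_MASS * 1e-3)  # mmol/g/h
    y_xs = D / q_glc / (GLUCOSE_MOLAR_MASS * 1e-3)

    rec = PhenotypeRecord(
        D=Measurement(np.broadcast_arrays(D, X)[0]),
        Y_xs=Measurement(y_xs),
        q_glucose=Measurement(q_glc),
    )
    if Q_oxygen is not None:
        rec.q_oxygen = Measurement(np.asarray(Q_oxygen, dtype=float) / X)
    if Q_co2 is not None:
        rec.q_co2 = Measurement(np.asarray(Q_co2, dtype=float) / X)
    if feed_ammonia_mmol_L is not None and residual_ammonia_mmol_L is not None:
        dn = feed_ammonia_mmol_L - np.atleast_1d(np.asarray(residual_ammonia_mmol_L, float))
        if np.any(dn < 0):
            raise ValueError("residual ammonia exceeds the feed concentration")
        rec.q_ammonia = Measurement(D * dn / X)
    if other_carbon_mmol_L is not None:
        oc = np.atleast_1d(np.asarray(other_carbon_mmol_L, dtype=float))
        rec.q_other_carbon = Measurement(D * oc / X)
    return rec


def rate_yield(numerator: Measurement, denominator: Measurement) -> Measurement:
    """Elementwise ratio of two replicate rate sets (e.g. Y_O2/glucose)."""
    a, b = np.broadcast_arrays(numerator.values, denominator.values)
    if np.any(b == 0):
        raise ValueError("yield denominator contains zeros")
    return Measurement(a / b)


# ---------------------------------------------------------------------------
# Balances
# ---------------------------------------------------------------------------

def recoveries(
    record: PhenotypeRecord,
    biomass_composition: ElementalComposition = BIOMASS_DEFAULT,
    substrate: ElementalComposition = GLUCOSE,
) -> BalanceReport:
    """Close the carbon, nitrogen and available-electron balances.

    Carbon out comprises CO2, biomass carbon (growth at rate D with the
    given C-mol composition) and the lumped "other carbon" leak; carbon in
    is the glucose actually consumed (q_glucose is net of residual).
    Nitrogen balances biomass N against ammonia uptake.  Available
    electrons: gamma_X per biomass C-mol plus 4 electrons per O2 consumed
    against gamma = 4 per glucose C-mol.

    Replicates propagate elementwise; recoveries are percent, mean +/- sd.
    """
    record.require("D", "q_glucose", "q_oxygen", "q_co2")
    D = record.D.values
    q_glc = record.q_glucose.values
    q_o2 = record.q_oxygen.values
    q_co2 = record.q_co2.values
    q_nh3 = record.q_ammonia.values if record.q_ammonia is not None else 0.0
    q_oc = record.q_other_carbon.values if record.q_other_carbon is not None else 0.0

    mu_cmol = D / biomass_composition.cmol_mass * 1000.0   # mmol_C g^-1 h^-1
    c_in = substrate.C * q_glc
    c_out = q_co2 + mu_cmol + q_oc
    carbon = c_out / c_in * 100.0

    n_per_cmol = biomass_composition.N / biomass_composition.C
    if record.q_ammonia is not None:
        nitrogen = (n_per_cmol * mu_cmol) / q_nh3 * 100.0
    else:
        nitrogen = np.full_like(np.atleast_1d(carbon), np.nan)

    ave_out = biomass_composition.gamma_per_cmol * mu_cmol + 4.0 * q_o2
    ave_in = substrate.gamma_per_cmol * substrate.C * q_glc
    ave = ave_out / ave_in * 100.0

    def _ms(x):
        x = np.atleast_1d(np.asarray(x, dtype=float))
        sd = 0.0 if x.size < 2 else float(np.std(x, ddof=1))
        return float(np.mean(x)), sd

    c_m, c_s = _ms(carbon)
    n_m, n_s = _ms(nitrogen)
    a_m, a_s = _ms(ave)
    return BalanceReport(carbon_recovery=c_m, nitrogen_recovery=n_m,
                         ave_recovery=a_m, carbon_sd=c_s,
                         nitrogen_sd=n_s, ave_sd=a_s)


# ---------------------------------------------------------------------------
# ATP demand and storage-carbon arithmetic
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class QATPEstimate:
    """ATP production rate with the accounting that produced it.

    The formula is deliberately explicit in the report because different
    P/O conventions and growth-coupled corrections change the number by a
    few percent.
    """

    value: float            # mmol ATP g_DMB^-1 h^-1
    p_o_ratio: float
    slp_per_glucose: float
    formula: str


def qATP_estimate(
    q_glucose: float,
    q_oxygen: float,
    p_o_ratio: float = 1.08,
    slp_per_glucose: float = 2.0,
) -> QATPEstimate:
    """ATP production rate for fully respiratory glucose metabolism.

    Substrate-level phosphorylation contributes ``slp_per_glucose`` mol ATP
    per mol glucose; oxidative phosphorylation contributes ``p_o_ratio`` mol
    ATP per mol O atoms, i.e. 2 * P/O per mol O2.
    """
    if q_glucose < 0 or q_oxygen < 0:
        raise ValueError("rates must be non-negative magnitudes")
    value = slp_per_glucose * q_glucose + 2.0 * p_o_ratio * q_oxygen
    formula = (f"q_ATP = {slp_per_glucose:g}*q_glucose + 2*{p_o_ratio:g}*q_oxygen "
               f"= {slp_per_glucose:g}*{q_glucose:g} + {2 * p_o_ratio:g}*{q_oxygen:g}")
    return QATPEstimate(value=value, p_o_ratio=p_o_ratio,
                        slp_per_glucose=slp_per_glucose, formula=formula)


def storage_carbon_yield_effect(
    delta_storage_c: float,
    biomass_c: float = 0.04,
) -> float:
    """Fractional biomass-yield change implied by a storage-carbon change.

    ``delta_storage_c`` is the change of the storage-carbohydrate pool in
    mol_C per g_DMB; ``biomass_c`` the carbon content of biomass (default
    0.04 mol_C/g).  Returns delta/biomass_c, e.g. 0.04 for a 4% drop.
    """
    if biomass_c <= 0:
        raise ValueError("biomass_c must be positive")
    return delta_storage_c / biomass_c


# ---------------------------------------------------------------------------
# Steady-state comparison
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class WelchResult:
    p_value: float
    percent_change: float
    t_statistic: float
    df: float

    @property
    def significant(self) -> bool:
        return self.p_value <= 0.05

    @property
    def change_label(self) -> str:
        """Percent change, or "n.s." when p > 0.05 (tabulation convention)."""
        return f"{self.percent_change:+.1f}" if self.significant else "n.s."


def welch_compare(a, b) -> WelchResult:
    """Two-sided Welch t-test with Satterthwaite degrees of freedom.

    ``a`` and ``b`` are replicate value arrays (or Measurements); the
    percent change is (mean_b - mean_a)/mean_a * 100.  If both groups have
    zero variance and equal means, p = 1 by convention.
    """
    if isinstance(a, Measurement):
        a = a.values
    if isinstance(b, Measurement):
        b = b.values
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("Welch test needs at least two replicates per group")
    ma, mb = a.mean(), b.mean()
    va, vb = a.var(ddof=1), b.var(ddof=1)
    na, nb = a.size, b.size
    change = (mb - ma) / ma * 100.0 if ma != 0 else math.inf
    se2 = va / na + vb / nb
    if se2 == 0:
        if ma == mb:
            return WelchResult(p_value=1.0, percent_change=0.0,
                               t_statistic=0.0, df=float(na + nb - 2))
        return WelchResult(p_value=0.0, percent_change=change,
                           t_statistic=math.inf, df=float(na + nb - 2))
    t_stat = (mb - ma) / math.sqrt(se2)
    df = se2 ** 2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    p = 2.0 * float(t_dist.sf(abs(t_stat), df))
    return WelchResult(p_value=p, percent_change=change, t_statistic=t_stat, df=df)


# ---------------------------------------------------------------------------
# Operating-point arithmetic
# ---------------------------------------------------------------------------

def average_dilution(schedule: FeedSchedule, params: ReactorParams) -> float:
    """Cycle-averaged dilution rate in 1/h.

    Continuous mode uses the base feed rate; intermittent mode averages the
    on-rate over the duty cycle (7 of 9 min in the reference schedule).
    """
    if schedule.mode == "continuous":
        mean_flow = params.base_feed_rate
    else:
        duty = 1.0 - schedule.off_duration / schedule.cycle_period
        mean_flow = schedule.on_rate * duty
    return mean_flow / 1000.0 * 60.0 / params.working_volume


def required_on_rate(continuous_rate: float, schedule: FeedSchedule) -> float:
    """Feed-on rate that matches a continuous rate over the duty cycle."""
    duty = 1.0 - schedule.off_duration / schedule.cycle_period
    if duty <= 0:
        raise ValueError("schedule has zero feed-on time")
    return continuous_rate / duty


# ---------------------------------------------------------------------------
# Report tables
# ---------------------------------------------------------------------------

_TABLE_ROWS = [
    ("D", "D", "1/h", False),
    ("Y_xs", "Y_DMB/glucose", "g_DMB/g_glucose", False),
    ("q_glucose", "-q_glucose", "mmol/g_DMB/h", True),
    ("q_oxygen", "-q_oxygen", "mmol/g_DMB/h", True),
    ("q_co2", "q_carbon_dioxide", "mmol/g_DMB/h", False),
    ("q_ammonia", "-q_ammonia", "mmol/g_DMB/h", True),
    ("q_other_carbon", "q_other_carbon", "mmol_C/g_DMB/h", False),
]


def phenotype_table(reference: PhenotypeRecord, perturbed: PhenotypeRecord,
                    extra_yields: bool = True) -> pd.DataFrame:
    """Side-by-side steady-state comparison (kinetics-table layout).

    Columns: parameter, dimension, both states as mean +/- sd, percent
    change ("n.s." when p > 0.05) and the Welch p-value.  Uptake rates are
    rendered with a leading minus (stored as magnitudes).
    """
    rows = []

    def add_row(name, dim, ma: Measurement | None, mb: Measurement | None, negate):
        if ma is None or mb is None:
            return
        sign = -1.0 if negate else 1.0
        res = welch_compare(ma, mb) if min(ma.n, mb.n) >= 2 else None
        rows.append({
            "parameter": name,
            "dimension": dim,
            "reference": f"{sign * ma.mean:.3f} ± {ma.sd:.3f}",
            "perturbed": f"{sign * mb.mean:.3f} ± {mb.sd:.3f}",
            "change_pct": res.change_label if res is not None else "",
            "p_value": round(res.p_value, 4) if res is not None else float("nan"),
        })

    for attr, name, dim, negate in _TABLE_ROWS:
        add_row(name, dim, getattr(reference, attr), getattr(perturbed, attr), negate)
    if extra_yields and all(r.q_oxygen is not None and r.q_glucose is not None
                            for r in (reference, perturbed)):
        add_row("Y_oxygen/glucose", "mol/mol",
                rate_yield(reference.q_oxygen, reference.q_glucose),
                rate_yield(perturbed.q_oxygen, perturbed.q_glucose), False)
    return pd.DataFrame(rows)
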