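"""Energy/redox charge ratios and distance-based relaxation analysis.

Takes absolutely quantified intracellular metabolite panels (umol per g dry
biomass, replicated time series) and derives:

* the adenylate energy charge AEC = (ATP + ADP/2)/(ATP + ADP + AMP),
* anabolic and catabolic reduction charges NADPH/(NADPH + NADP+) and
  NADH/(NADH + NAD+),
* min-max normalised concentration matrices, Euclidean sample distances and
  a classical (Torgerson) metric MDS embedding limited to k dimensions,
* relaxation metrics (distance to a reference and to an attractor sample)
  describing how the metabolome returns to a steady state after a famine
  perturbation.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

#: Correction factors for AxP species quantified by HILIC against the
#: reference method (peak-tailing compensation).
AXP_FACTORS = {"ATP": 2.71, "ADP": 1.88, "AMP": 1.21}

TIDY_COLUMNS = ("sample_time_min", "metabolite", "replicate", "value_umol_gDMB")


# ---------------------------------------------------------------------------
# Panel container
# ---------------------------------------------------------------------------

@dataclass
class MetabolitePanel:
    """Replicated metabolite x time concentration panel in tidy form.

    ``data`` holds one row per (sample time, metabolite, replicate) with the
    concentration in umol/g_DMB.  Concentrations must be non-negative and
    metabolite names unique per (time, replicate).
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in TIDY_COLUMNS if c not in self.data.columns]
        if missing:
            raise ValueError(f"panel is missing columns: {', '.join(missing)}")
        if (self.data["value_umol_gDMB"] < 0).any():
            raise ValueError("concentrations must be non-negative")
        dup = self.data.duplicated(subset=["sample_time_min", "metabolite", "replicate"])
        if dup.any():
            raise ValueError("duplicate (time, metabolite, replicate) entries")

    @property
    def times(self) -> np.ndarray:
        return np.sort(self.data["sample_time_min"].unique())

    @property
    def metabolites(self) -> list[str]:
        return sorted(self.data["metabolite"].unique())

    def mean_matrix(self, include: list[str] | None = None) -> pd.DataFrame:
        """Samples x metabolites matrix of replicate means.

        ``include`` restricts (and orders) the metabolite columns — the
        conventional way to drop analytes excluded from an ordination.
        Cells average whatever replicates are available.
        """
        wide = (self.data
                .groupby(["sample_time_min", "metabolite"])["value_umol_gDMB"]
                .mean().unstack("metabolite"))
        if include is not None:
            unknown = set(include) - set(wide.columns)
            if unknown:
                raise KeyError(f"unknown metabolites: {sorted(unknown)}")
            wide = wide[include]
        return wide.sort_index()

    def replicate_stats(self) -> pd.DataFrame:
        """Per (time, metabolite): mean, sd, n of replicates."""
        g = self.data.groupby(["sample_time_min", "metabolite"])["value_umol_gDMB"]
        out = g.agg(mean="mean", sd=lambda v: v.std(ddof=1), n="count").reset_index()
        return out

    @classmethod
    def from_csv(cls, path) -> "MetabolitePanel":
        return cls(pd.read_csv(path))

    def to_csv(self, path) -> None:
        self.data.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Charge ratios
# ---------------------------------------------------------------------------

def energy_charge(atp: float, adp: float, amp: float) -> float:
    """Adenylate energy charge (ATP + ADP/2)/(ATP + ADP + AMP) in [0, 1]."""
    if atp < 0 or adp < 0 or amp < 0:
        raise ValueError("adenylate pools must be non-negative")
    total = atp + adp + amp
    if total <= 0:
        raise ValueError("adenylate pool is empty")
    return (atp + 0.5 * adp) / total


def energy_charge_sd(atp, adp, amp, sd_atp, sd_adp, sd_amp) -> float:
    """First-order (delta-method) standard deviation of the AEC."""
    total = atp + adp + amp
    aec = (atp + 0.5 * adp) / total
    d_atp = (1.0 - aec) / total
    d_adp = (0.5 - aec) / total
    d_amp = -aec / total
    return math.sqrt((d_atp * sd_atp) ** 2 + (d_adp * sd_adp) ** 2
                     + (d_amp * sd_amp) ** 2)


@dataclass(frozen=True)
class ChargeSet:
    """Redox charge ratios of the two nicotinamide couples.

    ``catabolic_charge`` = NADH/(NADH + NAD+), ``anabolic_charge`` =
    NADPH/(NADPH + NADP+); totals and reduced/oxidised ratios included.
    Standard deviations are first-order propagated when pool sds are given.
    """

    catabolic_charge: float
    anabolic_charge: float
    catabolic_total: float
    anabolic_total: float
    nadh_nad_ratio: float
    nadph_nadp_ratio: float
    catabolic_charge_sd: float = 0.0
    anabolic_charge_sd: float = 0.0


def _couple_charge(red: float, ox: float, sd_red: float, sd_ox: float):
    total = red + ox
    if total <= 0:
        raise ValueError("redox couple pool is empty")
    charge = red / total
    # delta method for red/(red+ox)
    sd = math.sqrt((ox * sd_red) ** 2 + (red * sd_ox) ** 2) / total ** 2
    ratio = math.inf if ox == 0 else red / ox
    return charge, sd, total, ratio


def reduction_charges(
    nadh: float, nad: float, nadph: float, nadp: float,
    sds: tuple[float, float, float, float] | None = None,
) -> ChargeSet:
    """Catabolic and anabolic reduction charges from the four pool sizes.

    ``sds`` optionally gives (sd_nadh, sd_nad, sd_nadph, sd_nadp) for
    first-order uncertainty propagation on the charges.
    """
    for v in (nadh, nad, nadph, nadp):
        if v < 0:
            raise ValueError("pool sizes must be non-negative")
    s = sds if sds is not None else (0.0, 0.0, 0.0, 0.0)
    cat, cat_sd, cat_tot, cat_ratio = _couple_charge(nadh, nad, s[0], s[1])
    ana, ana_sd, ana_tot, ana_ratio = _couple_charge(nadph, nadp, s[2], s[3])
    return ChargeSet(
        catabolic_charge=cat, anabolic_charge=ana,
        catabolic_total=cat_tot, anabolic_total=ana_tot,
        nadh_nad_ratio=cat_ratio, nadph_nadp_ratio=ana_ratio,
        catabolic_charge_sd=cat_sd, anabolic_charge_sd=ana_sd,
    )


def axp_normalize(concentrations: dict, factors: dict | None = None) -> dict:
    """Apply species-specific correction factors to AxP concentrations.

    ``concentrations`` maps species name -> value (scalar or array); every
    key must have a factor (defaults: ATP 2.71, ADP 1.88, AMP 1.21).
    """
    f = AXP_FACTORS if factors is None else factors
    unknown = set(concentrations) - set(f)
    if unknown:
        raise KeyError(f"no normalization factor for: {sorted(unknown)}")
    out = {}
    for k, v in concentrations.items():
        arr = np.asarray(v, dtype=float)
        if np.any(arr < 0):
            raise ValueError("concentrations must be non-negative")
        scaled = arr * f[k]
        out[k] = float(scaled) if np.ndim(v) == 0 else scaled
    return out


# ---------------------------------------------------------------------------
# Normalisation, distances, MDS
# ---------------------------------------------------------------------------

def minmax_normalize(matrix: pd.DataFrame) -> pd.DataFrame:
    """Per-metabolite (column) min-max scaling to [0, 1].

    Constant columns map to 0 (convention: a metabolite without variation
    carries no distance information).  Requires at least two samples.
    """
    if len(matrix) < 2:
        raise ValueError("min-max normalization needs at least two samples")
    lo = matrix.min(axis=0)
    span = matrix.max(axis=0) - lo
    out = (matrix - lo).div(span.replace(0.0, np.nan), axis=1)
    return out.fillna(0.0)


def distance_matrix(matrix: pd.DataFrame, pairwise_complete: bool = False) -> pd.DataFrame:
    """Euclidean distances between sample rows.

    NaN cells raise unless ``pairwise_complete`` is set, in which case each
    pair is compared over its jointly observed metabolites and the squared
    distance is rescaled by n_total/n_observed (the standard
    pairwise-complete Euclidean estimate).
    """
    X = matrix.to_numpy(dtype=float)
    if np.isnan(X).any():
        if not pairwise_complete:
            raise ValueError("matrix contains NaN; enable pairwise_complete or impute")
        from sklearn.metrics.pairwise import nan_euclidean_distances
        D = nan_euclidean_distances(X)
        np.fill_diagonal(D, 0.0)
    else:
        D = squareform(pdist(X, metric="euclidean"))
    return pd.DataFrame(D, index=matrix.index, columns=matrix.index)


@dataclass
class MDSResult:
    """Classical-MDS embedding of a sample distance matrix.

    ``coordinates`` has one row per sample and up to k columns; axes are
    ordered by decreasing eigenvalue and their share of the total positive
    eigenvalue mass is in ``variance_fraction``.
    """

    coordinates: pd.DataFrame
    eigenvalues: np.ndarray
    variance_fraction: np.ndarray

    def distances(self) -> pd.DataFrame:
        """Pairwise Euclidean distances within the embedding."""
        return distance_matrix(self.coordinates)


def classical_mds(distances: pd.DataFrame | np.ndarray, k: int = 2) -> MDSResult:
    """Torgerson scaling of a symmetric distance matrix.

    Double-centres the squared distances, B = -1/2 * J D^2 J, and embeds the
    samples on the top-k eigenvectors scaled by the square roots of their
    eigenvalues.  If fewer than k positive eigenvalues exist, fewer columns
    are returned with a warning.  Axis signs are fixed deterministically:
    the first coordinate of each axis whose magnitude exceeds 1e-12 is made
    positive (eigenvectors are otherwise sign-ambiguous).
    """
    if isinstance(distances, pd.DataFrame):
        labels = list(distances.index)
        D = distances.to_numpy(dtype=float)
    else:
        D = np.asarray(distances, dtype=float)
        labels = list(range(D.shape[0]))
    if D.ndim != 2 or D.shape[0] != D.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(D, D.T, atol=1e-10):
        raise ValueError("distance matrix must be symmetric")
    if not np.allclose(np.diag(D), 0.0, atol=1e-10):
        raise ValueError("distance matrix must have a zero diagonal")

    n = D.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (D ** 2) @ J
    eigval, eigvec = np.linalg.eigh(B)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]

    positive = eigval > max(1e-12, 1e-12 * abs(eigval[0]))
    n_pos = int(positive.sum())
    k_eff = min(k, n_pos)
    if k_eff < k:
        warnings.warn(
            f"only {n_pos} positive eigenvalues; returning {k_eff} axes instead of {k}",
            RuntimeWarning, stacklevel=2,
        )
    coords = eigvec[:, :k_eff] * np.sqrt(eigval[:k_eff])
    for j in range(k_eff):
        col = coords[:, j]
        nz = np.flatnonzero(np.abs(col) > 1e-12)
        if nz.size and col[nz[0]] < 0:
            coords[:, j] = -col
    total_pos = eigval[positive].sum()
    frac = eigval[:k_eff] / total_pos if total_pos > 0 else np.zeros(k_eff)
    return MDSResult(
        coordinates=pd.DataFrame(coords, index=labels,
                                 columns=[f"dim{j + 1}" for j in range(k_eff)]),
        eigenvalues=eigval,
        variance_fraction=frac,
    )


# ---------------------------------------------------------------------------
# Relaxation metrics
# ---------------------------------------------------------------------------

@dataclass
class RelaxationResult:
    """Distances of every sample to the reference and attractor anchors.

    ``monotone_convergence`` is True when the distance to the attractor is
    non-increasing over the trailing ``tail`` samples — the signature of a
    trajectory that has settled onto the attractor.
    """

    distances: pd.DataFrame    # columns: to_reference, to_attractor
    monotone_convergence: bool


def relaxation_metrics(
    mds: MDSResult,
    reference_label,
    attractor_label,
    tail: int = 3,
) -> RelaxationResult:
    """Per-sample embedding distances to a reference and an attractor sample."""
    coords = mds.coordinates
    for label in (reference_label, attractor_label):
        if label not in coords.index:
            raise KeyError(f"label {label!r} not present in the embedding")
    ref = coords.loc[reference_label].to_numpy(dtype=float)
    att = coords.loc[attractor_label].to_numpy(dtype=float)
    X = coords.to_numpy(dtype=float)
    d_ref = np.linalg.norm(X - ref, axis=1)
    d_att = np.linalg.norm(X - att, axis=1)
    df = pd.DataFrame({"to_reference": d_ref, "to_attractor": d_att},
                      index=coords.index)
    tail = max(2, min(tail, len(df)))
    suffix = d_att[-tail:]
    monotone = bool(np.all(np.diff(suffix) <= 1e-12))
    return RelaxationResult(distances=df, monotone_convergence=monotone)
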