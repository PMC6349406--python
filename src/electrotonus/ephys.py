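"""Statistics for site-level uncaging datasets.

A dataset holds, for one neuron of one cell type (PD, LP, VD or GM),
a set of uncaging sites with their path distance to the recording site
and the evoked response amplitude ΔV at several holding potentials V_m.
The pipeline estimates each site's apparent reversal potential as the
x-intercept of the ΔV–V_m regression, regresses per-site quantities on
distance, normalizes within neurons for cross-neuron display, summarizes
groups (mean, SD, CV = SD/|mean|), compares cell types with a one-way
ANOVA, and quantifies identity-line agreement by RMSE.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

CELL_TYPES = ("PD", "LP", "VD", "GM")
QC_R_THRESHOLD = 0.85


@dataclass
class UncagingSite:
    """One photo-uncaging site: distance to the recording electrode and
    signed response amplitudes at the holding potentials probed."""

    site_id: str
    distance_um: float
    vm_mV: np.ndarray
    dv_mV: np.ndarray
    branch_id: str = ""
    max_amplitude_mV: Optional[float] = None  # |response| at −50 mV holding

    def __post_init__(self):
        self.vm_mV = np.asarray(self.vm_mV, dtype=float)
        self.dv_mV = np.asarray(self.dv_mV, dtype=float)
        if self.vm_mV.shape != self.dv_mV.shape:
            raise ValueError("vm and dv must have equal length")
        if self.distance_um < 0:
            raise ValueError("distance must be non-negative")


@dataclass
class NeuronDataset:
    neuron_id: str
    cell_type: str
    sites: list = field(default_factory=list)

    def __post_init__(self):
        if self.cell_type not in CELL_TYPES:
            raise ValueError(f"cell type must be one of {CELL_TYPES}")
        if len(self.sites) == 0:
            raise ValueError("dataset needs at least one site")


@dataclass(frozen=True)
class ReversalEstimate:
    E_rev: float       # mV, x-intercept of the ΔV–V_m fit
    slope: float       # mV per mV
    r: float           # Pearson correlation
    qc_pass: bool      # |r| > 0.85

    def __post_init__(self):
        if self.qc_pass != (abs(self.r) > QC_R_THRESHOLD):
            raise ValueError("qc flag inconsistent with r")


@dataclass(frozen=True)
class RegressionResult:
    slope: float       # response units per µm
    intercept: float
    r: float
    p: float
    mse: float         # residual sum of squares / n
    n: int


@dataclass(frozen=True)
class GroupStats:
    mean: float
    sd: float          # sample SD (n−1)
    cv: float          # SD / |mean|
    n: int


@dataclass(frozen=True)
class AnovaResult:
    F: float
    df_between: int
    df_within: int
    p: float


@dataclass(frozen=True)
class IdentityFit:
    rmse: float        # √mean((y − x)²)
    n: int


def estimate_reversal(site: UncagingSite) -> ReversalEstimate:
    """Apparent reversal potential from the ΔV–V_m regression.

    ΔV crosses zero where the holding potential equals the synaptic
    driving-force null, so E_rev = −intercept/slope of the OLS fit.
    """
    vm, dv = site.vm_mV, site.dv_mV
    if np.unique(vm).size < 2:
        raise ValueError("need at least two distinct holding potentials")
    fit = stats.linregress(vm, dv)
    if fit.slope == 0 or not np.isfinite(fit.slope):
        raise ValueError("reversal undefined: degenerate fit")
    e_rev = -fit.intercept / fit.slope
    r = float(fit.rvalue)
    return ReversalEstimate(E_rev=float(e_rev), slope=float(fit.slope),
                            r=r, qc_pass=abs(r) > QC_R_THRESHOLD)


def _site_value(site: UncagingSite, response: str) -> float:
    if response == "amplitude":
        if site.max_amplitude_mV is None:
            raise ValueError(f"site {site.site_id} has no amplitude record")
        return site.max_amplitude_mV
    if response == "reversal":
        return estimate_reversal(site).E_rev
    raise ValueError("response must be 'amplitude' or 'reversal'")


def fit_distance_regression(dataset: NeuronDataset,
                            response: str = "amplitude") -> RegressionResult:
    """OLS of a per-site quantity on distance to the recording site.

    ``response`` selects the maximal response amplitude (at −50 mV) or
    the apparent reversal potential.  p is the two-sided t test on the
    slope; MSE is the residual sum of squares divided by n.
    """
    if len(dataset.sites) < 3:
        raise ValueError("need at least three sites")
    x = np.array([s.distance_um for s in dataset.sites], dtype=float)
    if np.unique(x).size < 2:
        raise ValueError("all distances identical")
    y = np.array([_site_value(s, response) for s in dataset.sites])
    if np.allclose(y, y[0]):
        # constant response: zero slope, perfect fit, no correlation
        return RegressionResult(slope=0.0, intercept=float(y[0]), r=0.0,
                                p=1.0, mse=0.0, n=x.size)
    fit = stats.linregress(x, y)
    resid = y - (fit.slope * x + fit.intercept)
    return RegressionResult(slope=float(fit.slope),
                            intercept=float(fit.intercept),
                            r=float(fit.rvalue), p=float(fit.pvalue),
                            mse=float(np.sum(resid**2) / x.size), n=x.size)


def normalize_within_neuron(dataset: NeuronDataset) -> pd.DataFrame:
    """Per-site table with within-neuron normalized columns.

    Amplitudes are normalized to the neuron's maximum response and
    negated (−1 = the largest response, matching the inhibitory display
    convention); apparent reversals are divided by the neuron's mean
    (1 = the mean).
    """
    amps = np.array([_site_value(s, "amplitude") for s in dataset.sites])
    revs = np.array([_site_value(s, "reversal") for s in dataset.sites])
    max_amp = amps.max()
    mean_rev = revs.mean()
    if max_amp == 0:
        raise ValueError("zero maximum amplitude")
    if mean_rev == 0:
        raise ValueError("zero mean reversal potential")
    return pd.DataFrame({
        "neuron_id": dataset.neuron_id,
        "cell_type": dataset.cell_type,
        "site_id": [s.site_id for s in dataset.sites],
        "distance_um": [s.distance_um for s in dataset.sites],
        "amplitude_mV": amps,
        "e_rev_mV": revs,
        "norm_amplitude": -amps / max_amp,
        "norm_e_rev": revs / mean_rev,
    })


def group_stats(values: Sequence[float]) -> GroupStats:
    """Mean, sample SD and coefficient of variation (SD/|mean|)."""
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ValueError("need at least two values")
    mean = float(v.mean())
    sd = float(v.std(ddof=1))
    if mean == 0:
        raise ValueError("CV undefined for zero mean")
    return GroupStats(mean=mean, sd=sd, cv=sd / abs(mean), n=v.size)


def one_way_anova(groups: Mapping[str, Sequence[float]]) -> AnovaResult:
    """Classical fixed-effects one-way ANOVA across labeled groups."""
    arrays = [np.asarray(g, dtype=float) for g in groups.values()]
    k = len(arrays)
    if k < 2:
        raise ValueError("need at least two groups")
    n = sum(a.size for a in arrays)
    if n <= k:
        raise ValueError("need more observations than groups")
    if all(np.allclose(a, a[0]) for a in arrays if a.size):
        raise ValueError("F undefined: zero within-group variance everywhere")
    f, p = stats.f_oneway(*arrays)
    return AnovaResult(F=float(f), df_between=k - 1, df_within=n - k,
                       p=float(p))


def identity_line_rmse(x: Sequence[float], y: Sequence[float]) -> IdentityFit:
    """Root-mean-square deviation of (x, y) pairs from the line y = x."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or x.shape != y.shape:
        raise ValueError("need non-empty paired data")
    return IdentityFit(rmse=float(np.sqrt(np.mean((y - x) ** 2))), n=x.size)


# ---------------------------------------------------------------------------
# CSV schema: one row per response
# ---------------------------------------------------------------------------

DATASET_COLUMNS = ("neuron_id", "cell_type", "site_id", "branch_id",
                   "distance_um", "vm_mV", "dv_mV")


def dataset_to_frame(dataset: NeuronDataset) -> pd.DataFrame:
    rows = []
    for s in dataset.sites:
        for vm, dv in zip(s.vm_mV, s.dv_mV):
            rows.append({"neuron_id": dataset.neuron_id,
                         "cell_type": dataset.cell_type,
                         "site_id": s.site_id, "branch_id": s.branch_id,
                         "distance_um": s.distance_um,
                         "vm_mV": vm, "dv_mV": dv})
    return pd.DataFrame(rows, columns=list(DATASET_COLUMNS))


def dataset_from_frame(frame: pd.DataFrame) -> list:
    """Rebuild NeuronDataset objects from the long CSV schema."""
    out = []
    for (nid, ctype), g in frame.groupby(["neuron_id", "cell_type"],
                                         sort=False):
        sites = []
        for sid, sg in g.groupby("site_id", sort=False):
            sites.append(UncagingSite(
                site_id=str(sid),
                distance_um=float(sg["distance_um"].iloc[0]),
                branch_id=str(sg["branch_id"].iloc[0]),
                vm_mV=sg["vm_mV"].to_numpy(),
                dv_mV=sg["dv_mV"].to_numpy(),
                max_amplitude_mV=_amp_at_minus50(sg),
            ))
        out.append(NeuronDataset(neuron_id=str(nid), cell_type=str(ctype),
                                 sites=sites))
    return out


def _amp_at_minus50(site_frame: pd.DataFrame) -> Optional[float]:
    at50 = site_frame[np.isclose(site_frame["vm_mV"], -50.0)]
    if len(at50):
        return float(np.abs(at50["dv_mV"]).mean())
    return None
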