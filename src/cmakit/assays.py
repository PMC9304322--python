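"""Quantitative assay models: FP binding EC50, non-compartmental PK,
unit conversions, and pulse-chase proteolysis fractions.

Binding
-------
Fluorescence polarization (FP) titrations of a fluorescein-labeled
co-repressor peptide (probe, nominally 5 nM) against serial dilutions of the
RARalpha ligand-binding domain give polarization (mP) that rises with the
bound fraction.  Two regression models are offered:

* ``logistic`` -- the 4-parameter logistic in log concentration, the common
  "EC50 by nonlinear regression" model;
* ``one-site-depletion`` -- the exact one-site equilibrium that accounts for
  probe depletion by solving the binding quadratic; appropriate when probe
  and receptor concentrations are commensurate near the curve foot.  Its
  reported EC50 is Kd + probe/2, the receptor concentration at half-maximal
  bound fraction.

Pharmacokinetics
----------------
Standard non-compartmental analysis: Cmax/Tmax by inspection, AUC by the
linear trapezoid, terminal slope by least squares on log concentration over
the last k points, t1/2 = ln2/|slope|, AUC_inf = AUC_last + C_last/|slope|.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import optimize, stats

# --------------------------------------------------------------------------
# fluorescence polarization binding
# --------------------------------------------------------------------------


@dataclass
class BindingCurve:
    """A receptor titration: concentrations (uM, ascending) vs polarization (mP)."""

    concentrations_uM: np.ndarray
    polarization_mP: np.ndarray
    probe_conc_nM: float = 5.0
    ligand: str = ""
    replicate: int = 0

    def __post_init__(self) -> None:
        c = np.asarray(self.concentrations_uM, dtype=float)
        p = np.asarray(self.polarization_mP, dtype=float)
        if c.shape != p.shape or c.ndim != 1:
            raise ValueError("concentration and polarization vectors must match 1-D shapes")
        if (c <= 0).any():
            raise ValueError("concentrations must be strictly positive")
        order = np.argsort(c)
        self.concentrations_uM = c[order]
        self.polarization_mP = p[order]


@dataclass
class BindingFit:
    ec50_uM: float
    bottom_mP: float
    top_mP: float
    hill_slope: float | None
    model: str
    residual_sd: float
    extrapolated: bool
    unreliable: bool
    ci_uM: tuple[float, float] | None = None
    params: dict = field(default_factory=dict)


def logistic4(conc: np.ndarray, bottom: float, top: float, log10_ec50: float, hill: float) -> np.ndarray:
    """4PL in log10 concentration: bottom + (top-bottom)/(1 + (EC50/x)^hill)."""
    x = np.log10(conc)
    return bottom + (top - bottom) / (1.0 + 10 ** (hill * (log10_ec50 - x)))


def one_site_depletion(conc: np.ndarray, bottom: float, top: float, kd_uM: float, probe_uM: float) -> np.ndarray:
    """Polarization under exact one-site equilibrium with probe depletion.

    Bound probe fraction solves [RL]^2 - (R+L+Kd)[RL] + R*L = 0 with the
    physical (smaller) root.
    """
    r = np.asarray(conc, dtype=float)
    s = r + probe_uM + kd_uM
    bound = (s - np.sqrt(s * s - 4.0 * r * probe_uM)) / 2.0
    fb = bound / probe_uM
    return bottom + (top - bottom) * fb


def fit_binding_ec50(
    curve: BindingCurve,
    model: str = "logistic",
    n_boot: int = 0,
    seed: int | None = None,
) -> BindingFit:
    """Least-squares fit of an FP titration; EC50 at half-maximal signal change.

    ``n_boot > 0`` adds a residual-bootstrap 95% CI (seeded).  The fit is
    flagged ``extrapolated`` when the EC50 falls outside the tested
    concentration range and ``unreliable`` when the fitted dynamic range does
    not clear the residual noise (no transition in range).
    """
    c = curve.concentrations_uM
    y = curve.polarization_mP
    if len(c) < 5:
        raise ValueError("need at least 5 titration points")
    if model not in ("logistic", "one-site-depletion"):
        raise ValueError(f"unknown model {model!r}")

    span = y.max() - y.min()
    p0_bottom, p0_top = float(y[0]), float(y[-1])

    if model == "logistic":
        p0 = [p0_bottom, p0_top, float(np.mean(np.log10(c))), 1.0]
        bounds = ([-np.inf, -np.inf, np.log10(c.min()) - 6, 0.05],
                  [np.inf, np.inf, np.log10(c.max()) + 6, 20.0])
        fitfun = logistic4
    else:
        probe_uM = curve.probe_conc_nM * 1e-3

        def fitfun(conc, bottom, top, log10_kd):  # type: ignore[misc]
            return one_site_depletion(conc, bottom, top, 10 ** log10_kd, probe_uM)

        p0 = [p0_bottom, p0_top, float(np.mean(np.log10(c)))]
        bounds = ([-np.inf, -np.inf, np.log10(c.min()) - 9],
                  [np.inf, np.inf, np.log10(c.max()) + 9])

    popt, _ = optimize.curve_fit(fitfun, c, y, p0=p0, bounds=bounds, maxfev=20000,
                                 xtol=1e-14, ftol=1e-14)
    resid = y - fitfun(c, *popt)
    dof = max(len(y) - len(popt), 1)
    residual_sd = float(np.sqrt(np.sum(resid**2) / dof))

    def extract(popt_: np.ndarray) -> tuple[float, float, float, float | None]:
        if model == "logistic":
            bottom, top, log_ec50, hill = popt_
            return 10 ** float(log_ec50), float(bottom), float(top), float(hill)
        bottom, top, log_kd = popt_
        return 10 ** float(log_kd) + curve.probe_conc_nM * 1e-3 / 2.0, float(bottom), float(top), None

    ec50, bottom, top, hill = extract(popt)
    ci = None
    if n_boot > 0:
        rng = np.random.default_rng(seed)
        fitted = y - resid
        boots = []
        for _ in range(n_boot):
            yb = fitted + rng.choice(resid, size=len(resid), replace=True)
            try:
                pb, _ = optimize.curve_fit(fitfun, c, yb, p0=popt, bounds=bounds, maxfev=5000)
            except RuntimeError:
                continue
            boots.append(extract(pb)[0])
        if len(boots) >= max(20, n_boot // 2):
            ci = tuple(np.percentile(boots, [2.5, 97.5]))

    return BindingFit(
        ec50_uM=ec50,
        bottom_mP=bottom,
        top_mP=top,
        hill_slope=hill,
        model=model,
        residual_sd=residual_sd,
        extrapolated=not (c.min() <= ec50 <= c.max()),
        unreliable=abs(top - bottom) < 5.0 * residual_sd or span == 0,
        ci_uM=ci,
        params={"popt": popt.tolist(), "probe_conc_nM": curve.probe_conc_nM},
    )


# --------------------------------------------------------------------------
# non-compartmental pharmacokinetics
# --------------------------------------------------------------------------


@dataclass
class PKProfile:
    """A concentration-time series for one matrix/route."""

    times_h: np.ndarray
    concentrations: np.ndarray   # ng/mL (plasma) or ng/g (tissue)
    matrix: str = "plasma"       # plasma | brain | ...
    route: str = "IV"            # IV | PO | IP
    dose_mg_per_kg: float = 1.0
    compound: str = ""

    def __post_init__(self) -> None:
        t = np.asarray(self.times_h, dtype=float)
        c = np.asarray(self.concentrations, dtype=float)
        if t.ndim != 1 or t.shape != c.shape:
            raise ValueError("times and concentrations must be matching 1-D vectors")
        if len(t) < 3:
            raise ValueError("need at least 3 time points")
        if not (np.diff(t) > 0).all():
            raise ValueError("times must be strictly increasing")
        if (c < 0).any():
            raise ValueError("concentrations must be non-negative")
        self.times_h, self.concentrations = t, c


@dataclass
class PKResult:
    cmax: float
    tmax_h: float
    auc_last: float
    auc_inf: float | None
    t_half_h: float | None
    terminal_slope: float | None
    terminal_r2: float | None
    flags: list[str]
    matrix: str
    route: str
    dose_mg_per_kg: float
    compound: str = ""


def nca_parameters(profile: PKProfile, terminal_points: int = 3) -> PKResult:
    """Non-compartmental summary of a concentration-time profile.

    Terminal-phase selection is explicit: the last ``terminal_points``
    strictly positive concentrations are regressed on the log scale.  A
    non-negative terminal slope leaves t1/2 and AUC_inf undefined and flags
    the result instead of raising.
    """
    if terminal_points < 3:
        raise ValueError("terminal regression needs >= 3 points")
    t, c = profile.times_h, profile.concentrations
    if (c > 0).sum() < 3:
        raise ValueError("need at least 3 positive concentrations")

    imax = int(np.argmax(c))
    cmax, tmax = float(c[imax]), float(t[imax])
    auc_last = float(np.trapezoid(c, t))

    pos = c > 0
    t_pos, c_pos = t[pos], c[pos]
    flags: list[str] = []
    if terminal_points > len(t_pos):
        flags.append("terminal_points_truncated")
        terminal_points = len(t_pos)
    tt, cc = t_pos[-terminal_points:], c_pos[-terminal_points:]
    reg = stats.linregress(tt, np.log(cc))
    slope = float(reg.slope)
    r2 = float(reg.rvalue**2) if np.isfinite(reg.rvalue) else None

    if slope >= 0:
        flags.append("nonnegative_terminal_slope")
        t_half = None
        auc_inf = None
    else:
        t_half = float(np.log(2) / abs(slope))
        auc_inf = auc_last + float(c_pos[-1] / abs(slope))
    return PKResult(
        cmax=cmax, tmax_h=tmax, auc_last=auc_last, auc_inf=auc_inf,
        t_half_h=t_half, terminal_slope=slope if slope < 0 else None,
        terminal_r2=r2, flags=flags,
        matrix=profile.matrix, route=profile.route,
        dose_mg_per_kg=profile.dose_mg_per_kg, compound=profile.compound,
    )


def matrix_ratio(result_a: PKResult, result_b: PKResult, metric: str = "AUC") -> float:
    """Exposure ratio (e.g. brain/plasma) on a shared compound/route/dose."""
    for attr in ("route", "dose_mg_per_kg", "compound"):
        if getattr(result_a, attr) != getattr(result_b, attr):
            raise ValueError(f"mismatched {attr}: {getattr(result_a, attr)!r} vs {getattr(result_b, attr)!r}")
    if metric == "AUC":
        num, den = result_a.auc_last, result_b.auc_last
    elif metric == "Cmax":
        num, den = result_a.cmax, result_b.cmax
    else:
        raise ValueError(f"unknown metric {metric!r}")
    if den == 0:
        raise ZeroDivisionError(f"zero denominator {metric}")
    return float(num / den)


def ng_per_g_to_micromolar(conc_ng_per_g: float, molecular_weight: float, tissue_density: float = 1.0) -> float:
    """Convert a tissue concentration in ng/g to uM assuming a tissue density.

    ng/g x (g tissue/mL) = ng/mL = ug/L; dividing by MW (g/mol = ug/umol)
    gives umol/L.  Density defaults to 1 g/mL.
    """
    if molecular_weight <= 0:
        raise ValueError("molecular weight must be positive")
    if tissue_density <= 0:
        raise ValueError("tissue density must be positive")
    return float(conc_ng_per_g * tissue_density / molecular_weight)


def micromolar_to_ng_per_g(conc_uM: float, molecular_weight: float, tissue_density: float = 1.0) -> float:
    """Inverse of :func:`ng_per_g_to_micromolar`."""
    if molecular_weight <= 0:
        raise ValueError("molecular weight must be positive")
    if tissue_density <= 0:
        raise ValueError("tissue density must be positive")
    return float(conc_uM * molecular_weight / tissue_density)


# --------------------------------------------------------------------------
# pulse-chase proteolysis
# --------------------------------------------------------------------------


@dataclass
class ProteolysisRecord:
    """Radiolabel pulse-chase counts at successive chase times.

    ``soluble_dpm`` is acid-soluble radioactivity (degraded protein released
    to the medium); ``precipitable_dpm`` is the remaining acid-precipitable
    (intact protein) pool; ``condition`` labels the inhibitor regime.
    """

    times_h: np.ndarray
    soluble_dpm: np.ndarray
    precipitable_dpm: np.ndarray
    condition: str = "none"

    def __post_init__(self) -> None:
        t = np.asarray(self.times_h, dtype=float)
        s = np.asarray(self.soluble_dpm, dtype=float)
        p = np.asarray(self.precipitable_dpm, dtype=float)
        if not (t.shape == s.shape == p.shape) or t.ndim != 1:
            raise ValueError("time/soluble/precipitable vectors must match")
        if len(t) < 2:
            raise ValueError("need at least two chase time points")
        if (s < 0).any() or (p < 0).any():
            raise ValueError("dpm counts must be non-negative")
        self.times_h, self.soluble_dpm, self.precipitable_dpm = t, s, p


def percent_proteolysis(record: ProteolysisRecord, t: float) -> float:
    """Percent of labeled protein degraded by chase time ``t``:
    100 * soluble / (soluble + precipitable) at that time point."""
    idx = np.flatnonzero(np.isclose(record.times_h, t))
    if len(idx) == 0:
        raise KeyError(f"time {t} not in record (times: {record.times_h.tolist()})")
    i = int(idx[0])
    s, p = record.soluble_dpm[i], record.precipitable_dpm[i]
    total = s + p
    if total == 0:
        raise ValueError(f"zero total radioactivity at t={t}")
    return float(100.0 * s / total)


@dataclass
class PathwayFraction:
    sensitive_points: float      # percentage points of degradation lost to the inhibitor
    sensitive_share: float       # fraction of total degradation attributed to the pathway
    negative: bool               # inhibitor value exceeded total; reported, not clamped


def pathway_fraction(total_percent: float, with_inhibitor_percent: float) -> PathwayFraction:
    """Inhibitor-sensitive share of proteolysis.

    ``total_percent`` is degradation without inhibitor; ``with_inhibitor``
    the residual under a pathway blocker (e.g. lysosomal NH4Cl/leupeptin or a
    macroautophagy ULK inhibitor).  Negative differences are flagged, never
    silently clamped.
    """
    for v, name in ((total_percent, "total"), (with_inhibitor_percent, "with_inhibitor")):
        if not 0 <= v <= 100:
            raise ValueError(f"{name} percent out of [0, 100]: {v}")
    if total_percent == 0 and with_inhibitor_percent > 0:
        raise ValueError("total degradation is 0 but inhibitor condition is positive")
    points = total_percent - with_inhibitor_percent
    share = points / total_percent if total_percent > 0 else 0.0
    return PathwayFraction(points, share, negative=points < 0)
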