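"""Constrained Hill-model fitting of inhibition assays.

The dose–response model is

    activity(c) = 100 / (1 + (c / IC50) ** alpha)      [% of control]

with the 100%-activity-at-zero-inhibitor constraint built into the
functional form (activity(0) ≡ 100), as in standard kinase-assay fitting:
activity is 100% without inhibitor, 50% at c = IC50, and falls to zero at
saturating inhibitor for any positive Hill coefficient alpha.
IC50 (half-inhibition concentration) and the Hill coefficient alpha are
the only free parameters; the fit runs on untransformed activities with
IC50 parameterized on a log scale for conditioning.  Standard errors come
from the linearized covariance at the optimum.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares


@dataclass
class DoseResponseData:
    """One condition's assay table: concentrations (nM), mean % activity,
    replicate SD, replicate count."""

    condition: str
    conc: np.ndarray
    activity: np.ndarray
    sd: np.ndarray
    n_replicates: int = 1
    replicates: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.conc = np.asarray(self.conc, dtype=float)
        self.activity = np.asarray(self.activity, dtype=float)
        self.sd = np.asarray(self.sd, dtype=float)
        if np.any(self.conc < 0):
            raise ValueError("concentrations must be non-negative")
        if not np.all(np.isfinite(self.activity)):
            raise ValueError("activities must be finite")


@dataclass
class HillFit:
    ic50: float
    alpha: float
    ic50_se: float
    alpha_se: float
    rss: float
    converged: bool
    n_points: int
    condition: str = ""
    message: str = ""
    warnings_: list = field(default_factory=list)


def hill_activity(conc, ic50: float, alpha: float):
    """Evaluate the model; concentration 0 returns exactly 100."""
    c = np.asarray(conc, dtype=float)
    out = np.empty_like(c)
    pos = c > 0
    out[pos] = 100.0 / (1.0 + (c[pos] / ic50) ** alpha)
    out[~pos] = 100.0
    return out if out.ndim else float(out)


def predict_activity(fit: HillFit, conc):
    """% activity predicted by a fitted model."""
    return hill_activity(conc, fit.ic50, fit.alpha)


def fit_hill(data: DoseResponseData, weighted: bool = False,
             alpha_max: float = 10.0) -> HillFit:
    """Nonlinear least-squares fit of the constrained Hill model.

    Zero-concentration points are the constraint, not data, and are
    excluded from the residuals.  IC50 starts at the concentration whose
    activity is nearest 50% and alpha at 1; bounds keep IC50 within
    [min conc / 100, max conc × 100] and alpha in (0, ``alpha_max``].
    With ``weighted=True`` residuals are divided by the replicate SD
    (inverse-variance weighting).
    """
    pos = data.conc > 0
    c = data.conc[pos]
    a = data.activity[pos]
    if len(np.unique(c)) < 3:
        raise ValueError("need at least 3 distinct positive concentrations")
    warns = []
    if np.all(a > 90.0) or np.all(a < 10.0):
        warns.append("ill-conditioned: all activities on one plateau")
        warnings.warn(warns[-1])
    w = np.ones_like(a)
    if weighted:
        sd = data.sd[pos]
        if np.any(sd <= 0):
            warns.append("non-positive replicate SD; weighting skipped")
            warnings.warn(warns[-1])
        else:
            w = 1.0 / sd

    ic50_0 = c[np.argmin(np.abs(a - 50.0))]
    lo_ic50, hi_ic50 = c.min() / 100.0, c.max() * 100.0
    ic50_0 = min(max(ic50_0, lo_ic50), hi_ic50)

    def resid(p):
        log_ic50, alpha = p
        return w * (hill_activity(c, math.exp(log_ic50), alpha) - a)

    res = least_squares(
        resid, x0=[math.log(ic50_0), 1.0],
        bounds=([math.log(lo_ic50), 1e-6], [math.log(hi_ic50), alpha_max]),
        xtol=1e-14, ftol=1e-14, gtol=1e-14)
    ic50 = math.exp(res.x[0])
    alpha = float(res.x[1])
    rss = float(2.0 * res.cost)

    # linearized covariance: sigma^2 (J^T J)^-1, then delta-method for IC50
    dof = max(len(c) - 2, 1)
    sigma2 = rss / dof
    jtj = res.jac.T @ res.jac
    try:
        cov = sigma2 * np.linalg.inv(jtj)
        log_ic50_se = math.sqrt(max(cov[0, 0], 0.0))
        ic50_se = ic50 * log_ic50_se
        alpha_se = math.sqrt(max(cov[1, 1], 0.0))
    except np.linalg.LinAlgError:
        ic50_se = alpha_se = float("nan")
    return HillFit(ic50=ic50, alpha=alpha, ic50_se=ic50_se,
                   alpha_se=alpha_se, rss=rss,
                   converged=bool(res.success), n_points=len(c),
                   condition=data.condition, message=res.message,
                   warnings_=warns)


def ic50_shift(fit_a: HillFit, fit_b: HillFit) -> dict:
    """Fold change of IC50 between two conditions (b relative to a) with
    the propagated standard error of the ratio."""
    if not (fit_a.converged and fit_b.converged):
        raise ValueError("both fits must have converged")
    ratio = fit_b.ic50 / fit_a.ic50
    rel = np.hypot(
        fit_a.ic50_se / fit_a.ic50 if fit_a.ic50 else 0.0,
        fit_b.ic50_se / fit_b.ic50 if fit_b.ic50 else 0.0)
    return {"ratio": float(ratio),
            "log10_shift": float(np.log10(ratio)),
            "ratio_se": float(ratio * rel)}


def read_dose_response_csv(path) -> dict[str, DoseResponseData]:
    """Read an assay CSV (condition, conc_nM, activity_pct, sd_pct, n)
    into one DoseResponseData per condition."""
    import pandas as pd

    df = pd.read_csv(path)
    required = {"condition", "conc_nM", "activity_pct", "sd_pct", "n"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    out = {}
    for cond, grp in df.groupby("condition", sort=False):
        out[str(cond)] = DoseResponseData(
            condition=str(cond),
            conc=grp["conc_nM"].to_numpy(float),
            activity=grp["activity_pct"].to_numpy(float),
            sd=grp["sd_pct"].to_numpy(float),
            n_replicates=int(grp["n"].iloc[0]))
    return out
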