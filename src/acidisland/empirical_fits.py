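"""Distance-decay regressions for deposition chemistry.

Two empirical forms are fitted against distance x (km) to the nearest
large city:

* power law y = a * x**b for concentrations and fluxes — fitted by
  ordinary least squares on (ln x, ln y), which assumes multiplicative
  lognormal scatter (deposition data are positive and right-skewed, and
  are summarized by geometric means). An optional nonlinear
  least-squares (NLS) refinement on the original scale is available.
* logarithmic curve pH = c + d * ln x for pH, by OLS of pH on ln x;
  d > 0 means pH falls toward the city.

Each fit carries n, R² (on its own fitting scale), and the two-sided
p-value of the slope from the log-log/log-linear regression, judged
significant at P < 0.05 per curve without multiple-testing correction.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import statsmodels.api as sm
from scipy.optimize import curve_fit

from .chem_units import Ion, Kind, conc_to_flux, ph_to_h
from .errors import FitError
from .site_records import Medium, SiteRecord

logger = logging.getLogger(__name__)

#: Two-parameter fit with at least one residual degree of freedom.
MIN_POINTS = 3
SIGNIFICANCE_LEVEL = 0.05

QUANTITIES = (Ion.H, Ion.SO4, Ion.NO3, Ion.NH4)


@dataclass(frozen=True)
class PowerLawFit:
    """Fitted y = a * x**b with log-scale inference.

    ``r_squared`` refers to the fitting scale recorded in ``method``:
    log-log for "loglog_ols", original scale for "nls". ``sigma_log`` is
    the residual standard deviation of ln y about the log-log line.
    """

    a: float
    b: float
    n: int
    r_squared: float
    p_value: float
    sigma_log: float
    method: str = "loglog_ols"
    se_ln_a: float = float("nan")
    se_b: float = float("nan")
    ci_ln_a: tuple[float, float] = (float("nan"), float("nan"))
    ci_b: tuple[float, float] = (float("nan"), float("nan"))
    n_rejected: int = 0

    @property
    def significant(self) -> bool:
        return self.p_value < SIGNIFICANCE_LEVEL

    def predict(self, x):
        return self.a * np.asarray(x, dtype=float) ** self.b

    def to_dict(self) -> dict:
        return {
            "form": "power_law", "a": self.a, "b": self.b, "n": self.n,
            "r_squared": self.r_squared, "p_value": self.p_value,
            "sigma_log": self.sigma_log, "method": self.method,
            "se_ln_a": self.se_ln_a, "se_b": self.se_b,
            "significant": self.significant,
        }


@dataclass(frozen=True)
class LogFit:
    """Fitted pH = c + d * ln x."""

    c: float
    d: float
    n: int
    r_squared: float
    p_value: float
    se_c: float = float("nan")
    se_d: float = float("nan")

    @property
    def significant(self) -> bool:
        return self.p_value < SIGNIFICANCE_LEVEL

    def predict(self, x):
        return self.c + self.d * np.log(np.asarray(x, dtype=float))

    def to_dict(self) -> dict:
        return {
            "form": "log_curve", "c": self.c, "d": self.d, "n": self.n,
            "r_squared": self.r_squared, "p_value": self.p_value,
            "significant": self.significant,
        }


def _ols(xdesign: np.ndarray, y: np.ndarray):
    """OLS of y on [1, xdesign] with nan-safe R²/p for degenerate data."""
    X = sm.add_constant(xdesign)
    res = sm.OLS(y, X).fit()
    intercept, slope = map(float, res.params)
    r2 = float(res.rsquared)
    p = float(res.pvalues[1])
    resid = y - res.fittedvalues
    if not math.isfinite(r2):
        # zero-variance response: the line y = const fits exactly
        r2 = 1.0 if float(np.max(np.abs(resid))) < 1e-12 else 0.0
    if not math.isfinite(p):
        p = 1.0
    se = res.bse
    ci = res.conf_int(alpha=0.05)
    ci = np.asarray(ci)
    sigma = float(np.sqrt(np.sum(resid**2) / max(len(y) - 2, 1)))
    return intercept, slope, r2, p, (float(se[0]), float(se[1])), (
        (float(ci[0, 0]), float(ci[0, 1])),
        (float(ci[1, 0]), float(ci[1, 1])),
    ), sigma


def fit_power_law(
    x: Sequence[float], y: Sequence[float], method: str = "loglog_ols"
) -> PowerLawFit:
    """Fit y = a * x**b against distance x.

    Default "loglog_ols": OLS on (ln x, ln y); a = exp(intercept),
    b = slope. "nls": Levenberg-Marquardt least squares on the original
    scale, initialized from the log-log fit (R² then refers to the
    original scale; slope inference stays with the log-log regression).
    Non-positive y values cannot be log-transformed and are rejected with
    a logged count.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise FitError("x and y must have the same length")
    if np.any(x <= 0):
        raise FitError("all distances must be > 0")
    keep = y > 0
    n_rejected = int(np.sum(~keep))
    if n_rejected:
        logger.warning("fit_power_law: rejecting %d non-positive y value(s)", n_rejected)
    x, y = x[keep], y[keep]
    if len(x) < MIN_POINTS:
        raise FitError(f"power-law fit needs n >= {MIN_POINTS}, got {len(x)}")
    lnx, lny = np.log(x), np.log(y)
    if np.ptp(lnx) == 0:
        raise FitError("degenerate design: zero variance in ln x")
    ln_a, b, r2, p, (se_a, se_b), (ci_a, ci_b), sigma = _ols(lnx, lny)
    a = math.exp(ln_a)
    if method == "loglog_ols":
        return PowerLawFit(
            a=a, b=b, n=len(x), r_squared=r2, p_value=p, sigma_log=sigma,
            method="loglog_ols", se_ln_a=se_a, se_b=se_b,
            ci_ln_a=ci_a, ci_b=ci_b, n_rejected=n_rejected,
        )
    if method == "nls":
        popt, _ = curve_fit(
            lambda xx, aa, bb: aa * xx**bb, x, y, p0=[a, b], maxfev=10000
        )
        a_nls, b_nls = map(float, popt)
        resid = y - a_nls * x**b_nls
        sst = float(np.sum((y - y.mean()) ** 2))
        r2_orig = 1.0 - float(np.sum(resid**2)) / sst if sst > 0 else 1.0
        return PowerLawFit(
            a=a_nls, b=b_nls, n=len(x), r_squared=r2_orig, p_value=p,
            sigma_log=sigma, method="nls", se_ln_a=se_a, se_b=se_b,
            ci_ln_a=ci_a, ci_b=ci_b, n_rejected=n_rejected,
        )
    raise FitError(f"unknown fitting method {method!r}")


def fit_log_curve(x: Sequence[float], ph: Sequence[float]) -> LogFit:
    """Fit pH = c + d * ln x by OLS of pH on ln distance."""
    x = np.asarray(x, dtype=float)
    ph = np.asarray(ph, dtype=float)
    if x.shape != ph.shape:
        raise FitError("x and ph must have the same length")
    if np.any(x <= 0):
        raise FitError("all distances must be > 0")
    if len(x) < MIN_POINTS:
        raise FitError(f"log-curve fit needs n >= {MIN_POINTS}, got {len(x)}")
    lnx = np.log(x)
    if np.ptp(lnx) == 0:
        raise FitError("degenerate design: zero variance in ln x")
    c, d, r2, p, (se_c, se_d), _, _ = _ols(lnx, ph)
    return LogFit(c=c, d=d, n=len(x), r_squared=r2, p_value=p, se_c=se_c, se_d=se_d)


# ---------------------------------------------------------------------------
# Full fit table


@dataclass
class FitTable:
    """All distance-decay fits for one analysis.

    Keys: ("bulk"|"throughfall", "ph") -> LogFit and
    ("bulk"|"throughfall", ion, "concentration"|"flux") -> PowerLawFit.
    Cells with too few points are recorded in ``unavailable`` instead of
    raising, so a ragged site table still yields a partial table.
    """

    fits: dict = field(default_factory=dict)
    unavailable: list = field(default_factory=list)

    @property
    def n_fits(self) -> int:
        return len(self.fits)

    def get(self, medium, quantity, kind=None):
        key = _key(medium, quantity, kind)
        return self.fits.get(key)

    def to_dict(self) -> dict:
        out: dict = {m.value: {"ph": None, "concentration": {}, "flux": {}} for m in Medium}
        for key, fit in self.fits.items():
            if key[1] == "ph":
                out[key[0]]["ph"] = fit.to_dict()
            else:
                out[key[0]][key[2]][key[1]] = fit.to_dict()
        out["unavailable"] = ["/".join(k) for k in self.unavailable]
        return out


def _key(medium, quantity, kind=None):
    m = medium.value if isinstance(medium, Medium) else str(medium)
    if quantity == "ph":
        return (m, "ph")
    q = quantity.value if isinstance(quantity, Ion) else str(quantity)
    k = kind.value if isinstance(kind, Kind) else str(kind)
    return (m, q, k)


def _series(records: list[SiteRecord], dist: Mapping[str, float], ion: Ion, kind: Kind):
    xs, ys = [], []
    for rec in records:
        x = dist.get(rec.site_id)
        if x is None:
            continue
        if ion is Ion.H:
            if rec.ph is None:
                continue
            y = ph_to_h(rec.ph)
        else:
            conc = {Ion.SO4: rec.conc_so4, Ion.NO3: rec.conc_no3, Ion.NH4: rec.conc_nh4}[ion]
            if conc is None:
                continue
            y = conc
        if kind is Kind.FLUX:
            y = conc_to_flux(y, rec.precipitation)
        xs.append(x)
        ys.append(y)
    return np.asarray(xs), np.asarray(ys)


def fit_all(
    records: Iterable[SiteRecord],
    distances: Iterable,
    method: str = "loglog_ols",
) -> FitTable:
    """Fit the full table: per medium, one pH log curve plus one power law
    per ion (H+, SO4, NO3, NH4) and kind (concentration, flux) — 18 fits
    when every quantity is measured in both media.

    ``distances`` is a list of DistanceAssignments (or any objects with
    site_id/distance_km). Per-ion null filtering happens here, so per-ion
    n may differ. Cells with fewer than 3 usable points are skipped and
    listed in ``unavailable``. H+ concentrations are derived from site pH.
    """
    records = list(records)
    dist = {d.site_id: d.distance_km for d in distances}
    table = FitTable()
    for medium in Medium:
        med_records = [r for r in records if r.medium is medium]
        # pH log curve
        xs = [dist[r.site_id] for r in med_records if r.ph is not None and r.site_id in dist]
        phs = [r.ph for r in med_records if r.ph is not None and r.site_id in dist]
        key = _key(medium, "ph")
        try:
            table.fits[key] = fit_log_curve(xs, phs)
        except FitError as exc:
            logger.warning("fit unavailable for %s: %s", key, exc)
            table.unavailable.append(key)
        # power laws
        for ion in QUANTITIES:
            for kind in (Kind.CONCENTRATION, Kind.FLUX):
                key = _key(medium, ion, kind)
                x, y = _series(med_records, dist, ion, kind)
                try:
                    table.fits[key] = fit_power_law(x, y, method=method)
                except FitError as exc:
                    logger.warning("fit unavailable for %s: %s", key, exc)
                    table.unavailable.append(key)
    return table
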