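"""Arrival-delay mixed models with Ornstein-Uhlenbeck residuals.

The response is the (scaled) number of days between the thermal-
growing-season onset and an arrival event.  The conditional model has
nested random intercepts (year of observation within individual) and an
OU correlation over arrival days within each individual-year; the
marginal covariance of one individual's records is

    V = s2_ind * J  +  s2_indyear * blockdiag(J_year)
        +  s2_ou * exp(-|t_i - t_j| / rho)  (within individual-year)
        +  s2_resid * I

and the multivariate-normal likelihood is maximized numerically with
the fixed effects profiled out by generalized least squares.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import cho_factor, cho_solve
from scipy.optimize import minimize
from scipy.stats import norm

log = logging.getLogger(__name__)

#: Variables z-scored before modelling (when present).
SCALED_VARIABLES = (
    "delta_arrival_d",
    "tgs_deviation",
    "max_longitude",
    "max_latitude",
    "distance_traveled",
    "gdd_at_arrival",
)


# ---------------------------------------------------------------------------
# dataset assembly
# ---------------------------------------------------------------------------

def annotate_arrivals(events: pd.DataFrame, grid) -> pd.DataFrame:
    """Attach TGS onset/deviation (nearest cell) and the arrival delay.

    Also accumulates the growing degree days between onset and arrival
    (``gdd_at_arrival``, the alternative response).  Events over cells
    with undefined onset, or for years missing from the grid, are
    dropped (logged).
    """
    from .phenology import growing_degree_days

    rows = []
    for _, r in events.iterrows():
        ann = grid.annotate(float(r["lon"]), float(r["lat"]), int(r["year"]))
        if not np.isfinite(ann["onset"]):
            log.info(
                "dropping event %s/%s site %s: no phenology",
                r["individual_id"], r["year"], r.get("site_id"),
            )
            continue
        row = dict(r)
        row["tgs_onset"] = ann["onset"]
        row["tgs_deviation"] = ann["deviation"]
        row["delta_arrival_d"] = float(r["arrival_doy"]) - ann["onset"]
        if ann.get("daily") is not None and r["arrival_doy"] >= ann["onset"]:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                row["gdd_at_arrival"] = growing_degree_days(
                    ann["daily"],
                    t_ref=grid.t_ref,
                    from_doy=int(ann["onset"]),
                    to_doy=int(r["arrival_doy"]) + 1,
                )
        rows.append(row)
    return pd.DataFrame(rows).reset_index(drop=True)


def derive_covariates(
    records: pd.DataFrame,
    end_proj_x: dict | None = None,
    scale: bool = True,
) -> tuple[pd.DataFrame, dict]:
    """Add per-individual-year covariates and z-score model variables.

    ``max_longitude`` is the largest corridor-axis coordinate reached
    that spring (the end location's coordinate may be supplied via
    ``end_proj_x``, keyed by (individual_id, year), since the bird
    reaches it even when it is not an arrival event).
    ``distance_traveled`` is the cumulative distance at each event.
    Scaling parameters are returned for back-transformation.
    """
    df = records.copy()
    key = list(zip(df["individual_id"], df["year"]))
    maxes = {}
    for k, x in zip(key, df["proj_x"]):
        maxes[k] = max(maxes.get(k, -np.inf), float(x))
    if end_proj_x:
        for k, x in end_proj_x.items():
            if k in maxes:
                maxes[k] = max(maxes[k], float(x))
    df["max_longitude"] = [maxes[k] for k in key]
    if "proj_y" in df:
        lat_max = df.groupby(["individual_id", "year"])["proj_y"].transform("max")
        df["max_latitude"] = lat_max  # projected "latitude" substitute
    if "distance_traveled" not in df:
        df["distance_traveled"] = df["cum_distance_km"]

    scaling: dict[str, tuple[float, float]] = {}
    if scale:
        for col in SCALED_VARIABLES:
            if col not in df:
                continue
            mu = float(df[col].mean())
            sd = float(df[col].std(ddof=0))
            if sd == 0.0:
                sd = 1.0
            scaling[col] = (mu, sd)
            df[col + "_scaled"] = (df[col] - mu) / sd
    return df, scaling


# ---------------------------------------------------------------------------
# the Gaussian mixed model
# ---------------------------------------------------------------------------

@dataclass
class LmmSpec:
    """Random/covariance structure switches."""

    include_individual: bool = True
    include_individual_year: bool = True
    include_ou: bool = True
    reml: bool = False
    maxiter: int = 400


@dataclass
class LmmFit:
    fe_names: list
    beta: np.ndarray
    se: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    z: np.ndarray
    varcomp: dict
    ou_range: float
    loglik: float
    converged: bool
    spec: LmmSpec
    scaling: dict = field(default_factory=dict)
    fitted_fixed: np.ndarray | None = None
    marginal_r2: float | None = None

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "term": self.fe_names,
                "estimate": self.beta,
                "ci_low": self.ci_low,
                "ci_high": self.ci_high,
                "z": self.z,
            }
        )


def ou_correlation(t: np.ndarray, rho: float) -> np.ndarray:
    """exp(-|t_i - t_j| / rho); identity in the limit rho -> 0."""
    t = np.asarray(t, dtype=float)
    if rho <= 0.0:
        return np.eye(len(t))
    return np.exp(-np.abs(t[:, None] - t[None, :]) / rho)


def _blocks(individual, individual_year):
    """Row indices per outermost (individual) block, preserving order."""
    individual = np.asarray(individual)
    order = {}
    for i, g in enumerate(individual):
        order.setdefault(g, []).append(i)
    return [np.array(ix) for ix in order.values()]


def _block_cov(idx, individual_year, time, th, spec: LmmSpec):
    n = len(idx)
    V = np.full((n, n), th.get("s2_individual", 0.0))
    iy = np.asarray(individual_year)[idx]
    same_iy = iy[:, None] == iy[None, :]
    V += th.get("s2_individual_year", 0.0) * same_iy
    if spec.include_ou:
        tt = np.asarray(time, dtype=float)[idx]
        V += th["s2_ou"] * ou_correlation(tt, th["rho"]) * same_iy
    V += th["s2_resid"] * np.eye(n)
    return V


def _theta_names(spec: LmmSpec):
    names = []
    if spec.include_individual:
        names.append("s2_individual")
    if spec.include_individual_year:
        names.append("s2_individual_year")
    if spec.include_ou:
        names += ["s2_ou", "rho"]
    names.append("s2_resid")
    return names


def _profiled_negloglik(log_theta, y, X, blocks, individual_year, time, spec):
    names = _theta_names(spec)
    th = dict(zip(names, np.exp(log_theta)))
    th.setdefault("s2_individual", 0.0)
    th.setdefault("s2_individual_year", 0.0)

    p = X.shape[1]
    xtvx = np.zeros((p, p))
    xtvy = np.zeros(p)
    logdet = 0.0
    chos = []
    for idx in blocks:
        V = _block_cov(idx, individual_year, time, th, spec)
        try:
            c, low = cho_factor(V, lower=True)
        except np.linalg.LinAlgError:
            return 1e12, None, None
        chos.append((idx, (c, low)))
        logdet += 2.0 * np.sum(np.log(np.diag(c)))
        Vi_X = cho_solve((c, low), X[idx])
        xtvx += X[idx].T @ Vi_X
        xtvy += Vi_X.T @ y[idx]
    try:
        beta = np.linalg.solve(xtvx, xtvy)
    except np.linalg.LinAlgError:
        return 1e12, None, None
    quad = 0.0
    for idx, cl in chos:
        r = y[idx] - X[idx] @ beta
        quad += r @ cho_solve(cl, r)
    n = len(y)
    nll = 0.5 * (logdet + quad + n * np.log(2.0 * np.pi))
    if spec.reml:
        sign, ld = np.linalg.slogdet(xtvx)
        if sign <= 0:
            return 1e12, None, None
        nll += 0.5 * ld
    return nll, beta, xtvx


def fit_gaussian_lmm(
    y: np.ndarray,
    X: np.ndarray,
    fe_names: list,
    individual,
    individual_year,
    time=None,
    spec: LmmSpec | None = None,
    scaling: dict | None = None,
) -> LmmFit:
    """ML (or REML) fit of the marginal Gaussian model described above.

    ``individual`` and ``individual_year`` are group labels per row;
    ``time`` is the OU time variable (arrival day of year), required
    when the spec includes the OU term.
    """
    spec = spec or LmmSpec()
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    if spec.include_ou and time is None:
        raise ValueError("OU structure requires a time variable")
    if len(pd.unique(np.asarray(individual))) < 2:
        raise ValueError("need at least two groups")
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError(
            "rank-deficient fixed-effect design; a covariate is constant "
            "or collinear"
        )
    blocks = _blocks(individual, individual_year)

    names = _theta_names(spec)
    vary = max(float(np.var(y)), 1e-8)
    init = {
        "s2_individual": vary / 4,
        "s2_individual_year": vary / 4,
        "s2_ou": vary / 4,
        "rho": 5.0,
        "s2_resid": vary / 2,
    }
    x0 = np.log([init[n] for n in names])

    def obj(lt):
        return _profiled_negloglik(lt, y, X, blocks, individual_year, time, spec)[0]

    res = minimize(
        obj,
        x0,
        method="L-BFGS-B",
        # lower bound keeps block covariances numerically well-conditioned
        bounds=[(-16.0, 16.0)] * len(x0),
        options={"maxiter": spec.maxiter, "ftol": 1e-12, "gtol": 1e-9},
    )
    nll, beta, xtvx = _profiled_negloglik(
        res.x, y, X, blocks, individual_year, time, spec
    )
    if beta is None:
        raise RuntimeError("mixed-model likelihood degenerate at the optimum")
    th = dict(zip(names, np.exp(res.x)))
    cov_beta = np.linalg.inv(xtvx)
    se = np.sqrt(np.diag(cov_beta))
    zcrit = norm.ppf(0.975)

    varcomp = {k: v for k, v in th.items() if k != "rho"}
    for k in ("s2_individual", "s2_individual_year", "s2_ou"):
        varcomp.setdefault(k, 0.0)
    if not res.success:
        warnings.warn(f"LMM optimizer did not report convergence: {res.message}")
    boundary = [k for k, v in th.items() if k != "rho" and v < 1e-9]
    if boundary:
        log.info("variance components at boundary: %s", boundary)

    return LmmFit(
        fe_names=list(fe_names),
        beta=beta,
        se=se,
        ci_low=beta - zcrit * se,
        ci_high=beta + zcrit * se,
        z=beta / se,
        varcomp=varcomp,
        ou_range=float(th.get("rho", 0.0)),
        loglik=float(-nll),
        converged=bool(res.success),
        spec=spec,
        scaling=dict(scaling or {}),
        fitted_fixed=X @ beta,
    )


# ---------------------------------------------------------------------------
# the arrival-delay model variants
# ---------------------------------------------------------------------------

def build_design(
    records: pd.DataFrame,
    variant: str = "full",
    predictor: str = "max_longitude",
):
    """Fixed-effect design matrix for the arrival-delay model.

    ``full``: cell-means capture-site intercepts, TGS deviation, the
    migration-distance predictor, and a per-site interaction of that
    predictor with distance traveled.  ``last_arrival``: one intercept,
    TGS deviation, the predictor (fit on one event per individual-year,
    without the OU structure).  ``predictor`` selects the corridor
    coordinate (``max_longitude``, default) or its across-corridor
    substitute (``max_latitude``).
    """
    if predictor not in ("max_longitude", "max_latitude"):
        raise ValueError(f"unknown predictor {predictor!r}")
    dev = records["tgs_deviation_scaled"].to_numpy()
    mlon = records[predictor + "_scaled"].to_numpy()
    if variant == "full":
        dist = records["distance_traveled_scaled"].to_numpy()
        sites = sorted(records["capture_site"].unique())
        cols, names = [], []
        for s in sites:
            cols.append((records["capture_site"] == s).to_numpy(dtype=float))
            names.append(f"intercept[{s}]")
        cols += [dev, mlon]
        names += ["tgs_deviation", predictor]
        for s in sites:
            ind = (records["capture_site"] == s).to_numpy(dtype=float)
            cols.append(mlon * dist * ind)
            names.append(f"{predictor}:distance_traveled[{s}]")
        return np.column_stack(cols), names
    if variant == "last_arrival":
        X = np.column_stack([np.ones(len(records)), dev, mlon])
        return X, ["intercept", "tgs_deviation", predictor]
    raise ValueError(f"unknown variant {variant!r}")


def fit_lmm_ou(
    records: pd.DataFrame,
    variant: str = "full",
    response: str = "delta_arrival_d_scaled",
    predictor: str = "max_longitude",
    scaling: dict | None = None,
    spec: LmmSpec | None = None,
) -> LmmFit:
    """Fit an arrival-delay model variant on an annotated dataset.

    ``records`` must carry the scaled covariates from
    :func:`derive_covariates` plus ``capture_site``, ``individual_id``,
    ``year`` and ``arrival_doy``.  ``response`` may point at the GDD
    alternative (``gdd_at_arrival_scaled``) and ``predictor`` at the
    maximum-latitude substitute.
    """
    df = records
    if variant == "last_arrival":
        df = (
            df.sort_values("arrival_doy")
            .groupby(["individual_id", "year"], as_index=False)
            .last()
        )
        if spec is None:
            spec = LmmSpec(include_individual_year=False, include_ou=False)
    X, names = build_design(df, variant, predictor)
    idy = [f"{i}/{y}" for i, y in zip(df["individual_id"], df["year"])]
    return fit_gaussian_lmm(
        df[response].to_numpy(),
        X,
        names,
        individual=df["individual_id"].to_numpy(),
        individual_year=np.array(idy),
        time=df["arrival_doy"].to_numpy(dtype=float),
        spec=spec,
        scaling=scaling,
    )


def marginal_r2(fit: LmmFit, records: pd.DataFrame | None = None) -> float:
    """Share of total variance attributed to the fixed effects.

    var(X beta) / (var(X beta) + all random-intercept variances + OU
    variance + residual variance).
    """
    if fit.fitted_fixed is None:
        raise ValueError("fit carries no fixed-effect predictions")
    var_f = float(np.var(fit.fitted_fixed))
    var_r = float(sum(fit.varcomp.values()))
    total = var_f + var_r
    if total <= 0.0:
        raise ValueError("zero total variance")
    return var_f / total


def predict_delta_arrival(fit: LmmFit, scenarios: pd.DataFrame) -> np.ndarray:
    """Population-level predictions in (unscaled) days.

    ``scenarios`` rows provide raw-scale ``capture_site``,
    ``max_longitude``, ``distance_traveled`` and ``tgs_deviation``; the
    stored scaling is applied to covariates and inverted on the
    response.  Random effects are set to zero.
    """
    sc = fit.scaling

    def scaled(col):
        mu, sd = sc.get(col, (0.0, 1.0))
        return (scenarios[col].to_numpy(dtype=float) - mu) / sd

    for col in ("max_longitude", "distance_traveled", "tgs_deviation"):
        if col in sc:
            lo = scenarios[col].min()
            hi = scenarios[col].max()
            mu, sd = sc[col]
            if lo < mu - 4 * sd or hi > mu + 4 * sd:
                warnings.warn(f"scenario {col} far outside the fitted range")

    dev, mlon = scaled("tgs_deviation"), scaled("max_longitude")
    eta = np.zeros(len(scenarios))
    names = fit.fe_names
    b = dict(zip(names, fit.beta))
    if "intercept" in b:
        eta += b["intercept"]
    else:
        for s in scenarios["capture_site"]:
            if f"intercept[{s}]" not in b:
                raise ValueError(f"no intercept for capture site {s!r}")
        eta += np.array([b[f"intercept[{s}]"] for s in scenarios["capture_site"]])
    eta += b["tgs_deviation"] * dev + b["max_longitude"] * mlon
    if any(n.startswith("max_longitude:distance_traveled") for n in names):
        dist = scaled("distance_traveled")
        inter = np.array(
            [
                b[f"max_longitude:distance_traveled[{s}]"]
                for s in scenarios["capture_site"]
            ]
        )
        eta += inter * mlon * dist
    mu, sd = sc.get("delta_arrival_d", (0.0, 1.0))
    return mu + sd * eta
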