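"""Monthly soil-temperature mixed model: design, fit, partitioning, transfer.

Monthly mean soil temperature (soilT) is modelled as a linear mixed model on
downscaled macroclimate (mT), daily cumulative absorbed shortwave radiation
(rad), monthly frequency of snow-free days (sfd, %), square-root distance from
the glacier forefront (dg, m), tree cover (tc, 0/1), permafrost occurrence
(pf, 0/1) and burying depth (d, cm), with snow-season interactions
(sfd with mT, rad, dg and d; tc with rad) and a random intercept per glacier:

    soilT ~ mT + rad + sfd + dg + tc + pf + d
            + sfd:mT + sfd:rad + sfd:dg + sfd:d + tc:rad + (1 | gl)

Months with snowpack decoupling (sfd <= 20%) are discarded; continuous
predictors are standardized to zero mean / unit variance on the training table
and the standardization is frozen for validation and projection.  Transfer is
assessed by leave-one-glacier-out refits whose average fixed coefficients
predict unseen glaciers without a random effect.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy as sch
import statsmodels.api as sm
from scipy.spatial.distance import pdist
from scipy.stats import pearsonr

from .loggers import LoggerSeries
from .weights import AgreementStats, WeightScheme, build_weights, weighted_stats

log = logging.getLogger(__name__)

#: Continuous predictors standardized for the fit (dg after sqrt transform).
CONTINUOUS_PREDICTORS = ("mT", "rad", "sfd", "dg", "d")

#: Binary predictors entering untouched.
BINARY_PREDICTORS = ("tc", "pf")

#: Interaction terms, built from the (standardized) main-effect columns.
INTERACTIONS = (("sfd", "mT"), ("sfd", "rad"), ("sfd", "dg"), ("sfd", "d"), ("tc", "rad"))

#: Fixed-effect design columns, in order.
FIXED_TERMS = (
    "intercept",
    "mT",
    "rad",
    "sfd",
    "dg",
    "tc",
    "pf",
    "d",
    "sfd:mT",
    "sfd:rad",
    "sfd:dg",
    "sfd:d",
    "tc:rad",
)

#: Months with sfd at or below this (%) are snow-decoupled and discarded.
SFD_CUTOFF = 20.0

#: Minimum fraction of expected records for a monthly mean to be retained.
COMPLETENESS_MIN = 0.9


def aggregate_monthly(trace: LoggerSeries, min_completeness: float = COMPLETENESS_MIN) -> pd.DataFrame:
    """Monthly means from a logger trace, dropping incompletely sampled months.

    Completeness is records present over (nominal frequency x days in month);
    months below ``min_completeness`` are removed before averaging.
    """
    if trace.nominal_frequency < 1:
        raise ValueError("trace has no declared nominal recording frequency")
    rec = trace.records
    if rec.index.tz is not None:
        rec = rec.tz_localize(None)
    per = rec.index.to_period("M")
    grp = rec.groupby(per)
    counts = grp.count()
    days = counts.index.days_in_month
    completeness = counts / (trace.nominal_frequency * days)
    means = grp.mean()
    out = pd.DataFrame(
        {
            "station_id": trace.station_id,
            "glacier_id": trace.glacier_id,
            "region": trace.region,
            "year": counts.index.year,
            "month": counts.index.month,
            "soilT": means.to_numpy(),
            "completeness": completeness.to_numpy(),
            "n_records": counts.to_numpy(),
        }
    ).reset_index(drop=True)
    return out[out["completeness"] >= min_completeness].reset_index(drop=True)


def monthly_extremes(trace: LoggerSeries, min_records: int = 20) -> pd.DataFrame:
    """Monthly minimum/maximum as the 5% and 95% quantiles of the month's records."""
    rec = trace.records
    if rec.index.tz is not None:
        rec = rec.tz_localize(None)
    grp = rec.groupby(rec.index.to_period("M"))
    rows = []
    for per, vals in grp:
        if len(vals) < min_records:
            continue
        rows.append(
            {
                "station_id": trace.station_id,
                "year": per.year,
                "month": per.month,
                "t_min": float(np.quantile(vals, 0.05)),  # type-7 linear interpolation
                "t_max": float(np.quantile(vals, 0.95)),
            }
        )
    return pd.DataFrame(rows, columns=["station_id", "year", "month", "t_min", "t_max"])


@dataclass
class Standardization:
    """Frozen per-predictor mean/sd from the training table (dg after sqrt)."""

    means: dict[str, float]
    sds: dict[str, float]

    def __post_init__(self) -> None:
        for k, s in self.sds.items():
            if not s > 0:
                raise ValueError(f"zero variance in predictor {k!r}; cannot standardize")

    @classmethod
    def from_table(cls, table: pd.DataFrame, columns=CONTINUOUS_PREDICTORS) -> "Standardization":
        work = table.copy()
        work["dg"] = np.sqrt(work["dg"])
        means = {c: float(work[c].mean()) for c in columns}
        sds = {c: float(work[c].std(ddof=1)) for c in columns}
        return cls(means=means, sds=sds)

    def apply(self, table: pd.DataFrame) -> pd.DataFrame:
        out = table.copy()
        out["dg"] = np.sqrt(out["dg"])
        for c in self.means:
            out[c] = (out[c] - self.means[c]) / self.sds[c]
        return out


@dataclass
class DesignMatrix:
    """Standardized fixed-effect design plus grouping and provenance."""

    X: pd.DataFrame  # columns = FIXED_TERMS
    y: pd.Series | None
    groups: pd.Series  # glacier label per row
    standardization: Standardization
    raw: pd.DataFrame  # filtered raw rows the design was built from
    training_ranges: pd.DataFrame  # per-predictor raw min/max (post-transform dg)

    @property
    def n_glaciers(self) -> int:
        return int(self.groups.nunique())


def build_design(
    table: pd.DataFrame,
    standardization: Standardization | None = None,
    sfd_cutoff: float = SFD_CUTOFF,
    already_standardized: bool = False,
) -> DesignMatrix:
    """Fixed-effect design matrix of the soil model from a monthly table.

    ``table`` needs columns mT, rad, sfd, dg, tc, pf, d, glacier_id and
    (optionally) soilT.  Rows with sfd <= ``sfd_cutoff`` are excluded *before*
    standardization; dg is square-root transformed; continuous predictors are
    standardized with ``standardization`` (or one computed from this table).
    """
    required = set(CONTINUOUS_PREDICTORS) | set(BINARY_PREDICTORS) | {"glacier_id"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"table is missing covariate column(s) {sorted(missing)}")
    bad = table[list(CONTINUOUS_PREDICTORS)].isna().any(axis=1)
    if bad.any():
        raise ValueError(f"unresolvable covariates for rows {list(table.index[bad])[:10]}")
    if already_standardized:
        # sfd is already on the z scale; the cutoff was applied upstream
        kept = table.reset_index(drop=True)
    else:
        kept = table[table["sfd"] > sfd_cutoff].reset_index(drop=True)
    if kept.empty:
        raise ValueError(f"no rows remain after the sfd > {sfd_cutoff}% filter")
    if already_standardized:
        if standardization is None:
            raise ValueError("pre-standardized input still requires the Standardization object")
        std_tab = kept.copy()
    else:
        if standardization is None:
            standardization = Standardization.from_table(kept)
        std_tab = standardization.apply(kept)
    X = pd.DataFrame(index=std_tab.index)
    X["intercept"] = 1.0
    for c in ("mT", "rad", "sfd", "dg", "tc", "pf", "d"):
        X[c] = std_tab[c].astype(float)
    for a, b in INTERACTIONS:
        X[f"{a}:{b}"] = std_tab[a].astype(float) * std_tab[b].astype(float)
    y = std_tab["soilT"].astype(float) if "soilT" in std_tab else None
    raw_ranges = kept.copy()
    if not already_standardized:
        raw_ranges["dg"] = np.sqrt(raw_ranges["dg"])
    ranges = pd.DataFrame(
        {
            "min": {c: float(raw_ranges[c].min()) for c in CONTINUOUS_PREDICTORS},
            "max": {c: float(raw_ranges[c].max()) for c in CONTINUOUS_PREDICTORS},
        }
    )
    return DesignMatrix(
        X=X[list(FIXED_TERMS)],
        y=y,
        groups=std_tab["glacier_id"],
        standardization=standardization,
        raw=kept,
        training_ranges=ranges,
    )


@dataclass
class FitSummary:
    params: pd.Series
    bse: pd.Series
    conf_int: pd.DataFrame  # columns lo, hi (95%)
    var_fixed: float
    var_glacier: float
    var_residual: float
    r2m: float
    r2c: float
    converged: bool
    n_obs: int
    n_glaciers: int

    @property
    def glacier_intercept_sd(self) -> float:
        return float(np.sqrt(self.var_glacier))


def _mixedlm_result(design: DesignMatrix, reml: bool = True):
    """REML fit with optimizer fallbacks; raises on genuine non-convergence."""
    if design.y is None:
        raise ValueError("design has no response column")
    if design.n_glaciers < 2:
        raise ValueError("need at least 2 glaciers for a glacier random intercept")
    model = sm.MixedLM(design.y, design.X, groups=design.groups)
    res, last_error = None, "no optimizer succeeded"
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for method in (None, "lbfgs", "powell"):
            kwargs = {} if method is None else {"method": method}
            try:
                cand = model.fit(reml=reml, **kwargs)
            except (np.linalg.LinAlgError, ValueError) as exc:
                last_error = str(exc)
                continue
            res = cand
            if res.converged:
                break
    if res is None:
        raise RuntimeError(f"mixed model could not be fitted: {last_error}")
    if not res.converged:
        if np.all(np.isfinite(res.fe_params)):
            # boundary fits (e.g. group variance -> 0) end flagged as
            # non-converged; accept them when the estimates are finite
            log.warning("mixed model stopped at a variance boundary; estimates retained")
        else:
            raise RuntimeError(
                f"mixed model did not converge; optimizer summary:\n{res.summary()}"
            )
    return res


def fit_lmm(design: DesignMatrix, reml: bool = True) -> FitSummary:
    """REML fit of the mixed model with a single glacier random intercept.

    R2m = var(fixed predictor) / (var(fixed) + var(glacier) + var(residual));
    R2c adds the glacier variance to the numerator (Nakagawa-Schielzeth).
    """
    res = _mixedlm_result(design, reml=reml)
    params = res.fe_params
    eta = design.X.to_numpy() @ params.to_numpy()
    var_fixed = float(np.var(eta))
    var_gl = float(res.cov_re.iloc[0, 0])
    var_res = float(res.scale)
    total = var_fixed + var_gl + var_res
    ci = res.conf_int().loc[params.index]
    ci.columns = ["lo", "hi"]
    return FitSummary(
        params=params,
        bse=res.bse.loc[params.index],
        conf_int=ci,
        var_fixed=var_fixed,
        var_glacier=var_gl,
        var_residual=var_res,
        r2m=var_fixed / total,
        r2c=(var_fixed + var_gl) / total,
        converged=bool(res.converged),
        n_obs=int(len(design.y)),
        n_glaciers=design.n_glaciers,
    )


def predict_fixed(X: pd.DataFrame, params: pd.Series) -> np.ndarray:
    """Population-level prediction (no random effect) from a design matrix."""
    return X[list(params.index)].to_numpy() @ params.to_numpy()


def semi_partial_r2(
    fit: FitSummary,
    design: DesignMatrix,
    n_bootstrap: int = 1000,
    seed: int | None = None,
) -> pd.DataFrame:
    """Variance uniquely explained by each fixed term.

    For each term the model is refitted without that column and the drop in
    the variance of the linear predictor, relative to the full model's total
    variance, is the term's semi-partial R2 (so variance shared with the
    remaining terms is reabsorbed and contributes nothing).  Bootstrap
    intervals resample glaciers (the grouping unit) with replacement,
    re-evaluating the fitted full and reduced linear predictors on the
    resampled rows.
    """
    rng = np.random.default_rng(seed)
    X = design.X
    beta = fit.params
    terms = [t for t in FIXED_TERMS if t != "intercept"]
    reduced_eta: dict[str, np.ndarray] = {}
    for t in terms:
        Xr = X.drop(columns=t)
        sub = DesignMatrix(
            X=Xr, y=design.y, groups=design.groups,
            standardization=design.standardization, raw=design.raw,
            training_ranges=design.training_ranges,
        )
        try:
            red = _mixedlm_result(sub).fe_params
            reduced_eta[t] = Xr.to_numpy() @ red.to_numpy()
        except RuntimeError:
            reduced_eta[t] = np.full(len(X), np.nan)
    eta_full_all = X.to_numpy() @ beta.to_numpy()

    def _sp(rows: np.ndarray) -> dict[str, float]:
        eta_full = eta_full_all[rows]
        denom = np.var(eta_full) + fit.var_glacier + fit.var_residual
        full = np.var(eta_full) / denom
        return {t: full - np.var(reduced_eta[t][rows]) / denom for t in terms}

    point = _sp(np.arange(len(X)))
    glaciers = design.groups.to_numpy()
    uniq = np.unique(glaciers)
    boots = {t: [] for t in terms}
    for _ in range(n_bootstrap):
        chosen = rng.choice(uniq, size=len(uniq), replace=True)
        rows = np.concatenate([np.flatnonzero(glaciers == g) for g in chosen])
        bs = _sp(rows)
        for t in terms:
            boots[t].append(bs[t])
    rows_out = []
    for t in terms:
        arr = np.asarray(boots[t]) if n_bootstrap else np.asarray([point[t]])
        rows_out.append(
            {
                "term": t,
                "semi_partial_r2": point[t],
                "ci_lo": float(np.quantile(arr, 0.025)),
                "ci_hi": float(np.quantile(arr, 0.975)),
            }
        )
    return pd.DataFrame(rows_out)


def permutation_importance(
    fit: FitSummary,
    design: DesignMatrix,
    n_perm: int = 1000,
    seed: int | None = None,
) -> pd.DataFrame:
    """Joint additive+interactive importance of each raw predictor, as 1 - r.

    A predictor column is permuted in the raw table, the design (including its
    interactions) rebuilt with the frozen standardization, and the permuted
    population-level predictions correlated with the original ones; importance
    is the mean over permutations of 1 - Pearson r.
    """
    rng = np.random.default_rng(seed)
    base_pred = predict_fixed(design.X, fit.params)
    predictors = list(CONTINUOUS_PREDICTORS) + list(BINARY_PREDICTORS)
    rows = []
    for p in predictors:
        scores = []
        for _ in range(n_perm):
            shuffled = design.raw.copy()
            shuffled[p] = rng.permutation(shuffled[p].to_numpy())
            d2 = build_design(
                shuffled, standardization=design.standardization, sfd_cutoff=-np.inf
            )
            perm_pred = predict_fixed(d2.X, fit.params)
            if np.ptp(perm_pred) == 0 or np.ptp(base_pred) == 0:
                scores.append(np.nan)
            else:
                scores.append(1.0 - pearsonr(base_pred, perm_pred)[0])
        rows.append({"predictor": p, "importance": float(np.nanmean(scores))
                     if not np.all(np.isnan(scores)) else float("nan")})
    return pd.DataFrame(rows)


@dataclass
class LooResult:
    coefficients: pd.DataFrame  # one row per held-out glacier
    mean_coefficients: pd.Series
    predictions: pd.Series  # per design row, from the mean coefficients
    converged: pd.Series  # per fold


def loo_by_glacier(design: DesignMatrix, reml: bool = True) -> LooResult:
    """Leave-one-glacier-out refits; average coefficients predict new glaciers.

    Each fold drops one glacier and refits; the arithmetic mean of the
    per-fold fixed coefficients (standardized scale) is the transferable
    coefficient vector, applied without any random effect.
    """
    glaciers = design.groups.unique()
    if len(glaciers) < 3:
        raise ValueError("leave-one-out by glacier needs at least 3 glaciers")
    coef_rows, ok = {}, {}
    for g in glaciers:
        keep = design.groups != g
        sub = DesignMatrix(
            X=design.X[keep],
            y=design.y[keep],
            groups=design.groups[keep],
            standardization=design.standardization,
            raw=design.raw[keep.to_numpy()],
            training_ranges=design.training_ranges,
        )
        try:
            fold = fit_lmm(sub, reml=reml)
            coef_rows[g] = fold.params
            ok[g] = True
        except RuntimeError:
            log.warning("LOO fold holding out %s did not converge; excluded from the mean", g)
            ok[g] = False
    coefs = pd.DataFrame(coef_rows).T
    mean_coefs = coefs.mean(axis=0)
    preds = pd.Series(predict_fixed(design.X, mean_coefs), index=design.X.index)
    return LooResult(
        coefficients=coefs,
        mean_coefficients=mean_coefs,
        predictions=preds,
        converged=pd.Series(ok),
    )


def cluster_stations(x: np.ndarray, y: np.ndarray, max_distance: float = 1000.0) -> np.ndarray:
    """Single-linkage clusters joining all stations within ``max_distance`` m."""
    pts = np.column_stack([np.asarray(x, float), np.asarray(y, float)])
    if len(pts) == 1:
        return np.array([1])
    link = sch.linkage(pdist(pts), method="single")
    return sch.fcluster(link, t=max_distance, criterion="distance")


def validate(
    observed,
    predicted,
    region,
    group,
    sfd,
) -> tuple[AgreementStats, WeightScheme]:
    """Weighted agreement between observed and predicted monthly temperatures."""
    scheme = build_weights(region=region, group=group, sfd=sfd)
    stats = weighted_stats(observed, predicted, scheme.weights)
    return stats, scheme


def sfd_cutoff_diagnostics(
    table: pd.DataFrame,
    cutoffs=(0.0, 10.0, 20.0, 30.0),
    min_rows: int = 100,
) -> pd.DataFrame:
    """Residual structure of the fit at increasing sfd cutoffs.

    Reports, per cutoff, the slope of residuals on fitted values and a
    heteroscedasticity index (correlation of |residual| with fitted values);
    snow decoupling shows up as structure that fades as the cutoff rises.
    """
    rows = []
    for cut in cutoffs:
        sub = table[table["sfd"] > cut]
        if len(sub) < min_rows:
            log.warning("cutoff %s%% leaves %d rows (<%d); skipped", cut, len(sub), min_rows)
            continue
        design = build_design(sub.reset_index(drop=True), sfd_cutoff=cut)
        fit = fit_lmm(design)
        fitted = predict_fixed(design.X, fit.params)
        resid = design.y.to_numpy() - fitted
        slope = np.polyfit(fitted, resid, 1)[0]
        het = pearsonr(fitted, np.abs(resid))[0] if np.ptp(np.abs(resid)) > 0 else 0.0
        rows.append(
            {
                "cutoff": cut,
                "n": len(sub),
                "resid_trend_slope": float(slope),
                "heteroscedasticity": float(het),
                "r2m": fit.r2m,
            }
        )
    return pd.DataFrame(rows)
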