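"""Serial-dilution reverse-phase protein microarray (RPPM) quantification.

Each sample is printed as a 1:1 serial dilution series; spot fluorescence
versus relative concentration follows an asymmetric five-parameter logistic
(5PL) in log-log coordinates:

    y(x) = D + (A − D) / (1 + 10^{B·(x_mid − x)})^G

with x = log10(relative concentration) (dilution step k ⇒ x = −k·log10 2,
x = 0 the undiluted print) and y = log10(net fluorescence). The pipeline:

  1. background-correct and filter spots (SNR < 2 or net < 10 excluded);
  2. fit a slide-wide 5PL master curve to all included spots;
  3. remove outliers by a ROUT-style procedure (robust residual scale +
     per-point t-tests controlled by Benjamini–Hochberg FDR at Q) and
     refine the master curve;
  4. fit each sample with the four shape parameters (A, D, B, G) frozen at
     the refined master values, leaving only the location x_mid free;
  5. quantify each sample as the y-intercept of the tangent at the curve's
     maximum-slope point extrapolated to x = 0.

For the 5PL above, the maximum-slope point and tangent have closed forms:
the slope dy/dx = (A−D)·G·B·ln10 · u/(1+u)^{G+1} with u = 10^{B(x_mid−x)}
is maximal at u* = 1/G, i.e. x* = x_mid + log10(G)/B, where

    slope* = (A−D)·B·ln10 · (1 + 1/G)^{−(G+1)}
    y(x*)  = D + (A−D)·(1 + 1/G)^{−G}
    y-intercept = y(x*) − slope*·x*
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import optimize, stats
from statsmodels.stats.multitest import multipletests

from .group_stats import summarize

__all__ = [
    "FiveParamLogistic",
    "MasterFit",
    "SampleQuant",
    "LOG10_2",
    "preprocess_spots",
    "fivepl_eval",
    "fit_master",
    "remove_outliers_fdr",
    "fit_samples",
    "quantify",
    "run_rppm_pipeline",
]

LOG10_2 = math.log10(2.0)
LN10 = math.log(10.0)

SNR_MIN = 2.0
NET_MIN = 10.0


class RppmError(RuntimeError):
    """An RPPM pipeline stage failed; the stage name prefixes the message."""


@dataclass(frozen=True)
class FiveParamLogistic:
    """5PL parameters in log-log space.

    A/D: upper/lower asymptote (log10 intensity); B: slope factor per
    log10 concentration; G: asymmetry (> 0); x_mid: location.
    """

    A: float
    D: float
    B: float
    G: float
    x_mid: float

    def __post_init__(self) -> None:
        if not (self.A > self.D):
            raise ValueError("5PL requires A > D")
        if self.B <= 0 or self.G <= 0:
            raise ValueError("5PL requires B > 0 and G > 0")

    def as_array(self) -> np.ndarray:
        return np.array([self.A, self.D, self.B, self.G, self.x_mid])


@dataclass
class MasterFit:
    params: FiveParamLogistic
    rsdr: float
    n_used: int
    rss: float
    excluded_points: pd.DataFrame | None = None


@dataclass(frozen=True)
class SampleQuant:
    sample_id: object
    x_mid_sample: float
    slope_linear: float
    y_intercept: float
    fit_rss: float
    n_points: int


def fivepl_eval(p: FiveParamLogistic, x) -> np.ndarray | float:
    """Evaluate the 5PL: y = D + (A−D)/(1 + 10^{B(x_mid−x)})^G."""
    x = np.asarray(x, dtype=float)
    z = p.B * (p.x_mid - x)
    # clip the exponent so extreme dilutions saturate instead of overflowing
    u = np.power(10.0, np.clip(z, -300, 300))
    y = p.D + (p.A - p.D) / np.power(1.0 + u, p.G)
    return float(y) if y.ndim == 0 else y


def _fivepl_vec(theta: np.ndarray, x: np.ndarray) -> np.ndarray:
    a, d, b, g, xm = theta
    u = np.power(10.0, np.clip(b * (xm - x), -300, 300))
    return d + (a - d) / np.power(1.0 + u, g)


def preprocess_spots(
    raw: pd.DataFrame,
    snr_min: float = SNR_MIN,
    net_min: float = NET_MIN,
    average_replicates: bool = True,
) -> pd.DataFrame:
    """Background-correct, average replicate depositions, and filter spots.

    Adds columns: net (foreground − background), included, and for included
    rows the log-log fitting coordinates x = −dilution_step·log10 2 and
    y = log10(net). Spots indiscernible from background (snr < 2 or
    net < 10) are marked included = False.
    """
    required = {"sample_id", "dilution_step", "fg", "bg", "snr"}
    missing = required - set(raw.columns)
    if missing:
        raise RppmError(f"preprocess: missing columns {sorted(missing)}")
    df = raw.copy()
    if "block" not in df.columns:
        df["block"] = 1
    if (df["dilution_step"] < 0).any():
        raise RppmError("preprocess: negative dilution_step")

    if average_replicates:
        keys = ["sample_id", "block", "dilution_step"]
        if df.duplicated(keys).any():
            agg = {c: "mean" for c in ("fg", "bg", "snr") if c in df.columns}
            extra = [c for c in df.columns if c not in keys + list(agg)]
            for c in extra:
                agg[c] = "first"
            df = df.groupby(keys, as_index=False, sort=True).agg(agg)

    df["net"] = df["fg"] - df["bg"]
    if not np.all(np.isfinite(df["net"])):
        raise RppmError("preprocess: non-finite net intensity")
    df["included"] = (df["snr"] >= snr_min) & (df["net"] >= net_min)
    if not df["included"].any():
        raise RppmError("preprocess: empty table after filtering")
    df["x"] = -df["dilution_step"].astype(float) * LOG10_2
    df["y"] = np.where(df["included"], np.log10(df["net"].where(df["net"] > 0, 1.0)), np.nan)
    df = df.reset_index(drop=True)
    df["row_id"] = df.index
    return df


def _init_params(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    a0 = float(y.max())
    d0 = float(y.min())
    if a0 <= d0:
        a0 = d0 + 1.0
    return np.array([a0, d0, 1.0, 1.0, float(np.median(x))])


_BOUNDS = (
    np.array([-np.inf, -np.inf, 1e-3, 1e-3, -np.inf]),
    np.array([np.inf, np.inf, 50.0, 50.0, np.inf]),
)


def fit_master(points: pd.DataFrame) -> MasterFit:
    """Fit the slide-wide 5PL master curve to all included spots.

    Plain nonlinear least squares in log-log space, initialised from the
    data (A₀ = max y, D₀ = min y, x_mid₀ = median x, B₀ = G₀ = 1) with a
    few perturbed restarts if the first solve fails to converge.
    """
    inc = points[points["included"]]
    x = inc["x"].to_numpy(dtype=float)
    y = inc["y"].to_numpy(dtype=float)
    if x.size < 8:
        raise RppmError(f"master: need >= 8 included points, have {x.size}")
    if np.unique(inc["dilution_step"]).size < 3:
        raise RppmError("master: need >= 3 distinct dilution steps")

    theta0 = _init_params(x, y)
    best = None
    rng = np.random.default_rng(0)  # deterministic restart perturbations
    for attempt in range(6):
        t0 = theta0 if attempt == 0 else theta0 * (1 + 0.2 * rng.standard_normal(5))
        t0 = np.clip(t0, _BOUNDS[0] + 1e-6, _BOUNDS[1] - 1e-6)
        try:
            res = optimize.least_squares(
                lambda th: _fivepl_vec(th, x) - y,
                t0,
                bounds=_BOUNDS,
                method="trf",
                x_scale="jac",
                xtol=1e-15,
                ftol=1e-15,
                gtol=1e-15,
                max_nfev=20000,
            )
        except Exception:  # singular jacobian etc.; retry perturbed
            continue
        if res.success and (best is None or res.cost < best.cost):
            best = res
    if best is None:
        raise RppmError("master: master fit failed to converge after restarts")

    a, d, b, g, xm = best.x
    if a <= d:  # fell into the decreasing branch; reject
        raise RppmError("master: fit collapsed (A <= D)")
    params = FiveParamLogistic(A=float(a), D=float(d), B=float(b), G=float(g), x_mid=float(xm))
    resid = _fivepl_vec(best.x, x) - y
    rsdr = _robust_scale(resid, k_params=5)
    return MasterFit(params=params, rsdr=rsdr, n_used=int(x.size), rss=float(np.sum(resid**2)))


def _robust_scale(residuals: np.ndarray, k_params: int) -> float:
    """RSDR: 68.27th percentile of |residuals| corrected for fitted
    parameters by the factor N/(N−K)."""
    n = residuals.size
    if n <= k_params:
        raise RppmError("outliers: too few points for robust scale")
    p68 = float(np.percentile(np.abs(residuals), 68.27))
    return p68 * n / (n - k_params)


def remove_outliers_fdr(
    points: pd.DataFrame, fit: MasterFit, q: float = 0.01
) -> tuple[pd.DataFrame, MasterFit]:
    """ROUT-style outlier exclusion and master-curve refinement.

    Each included spot's residual from the master curve is scaled by the
    robust RSDR; two-sided p-values from the t distribution (N−K df) enter
    a Benjamini–Hochberg step at rate ``q``. Flagged spots are marked
    included = False and the master curve is refit on the remainder (the
    refit equals the initial fit when nothing is flagged).

    Returns the updated table and the refined MasterFit, whose
    ``excluded_points`` lists flagged rows with residual and q-value.
    """
    df = points.copy()
    inc = df["included"].to_numpy()
    x = df.loc[df["included"], "x"].to_numpy(dtype=float)
    y = df.loc[df["included"], "y"].to_numpy(dtype=float)
    n, k = x.size, 5
    resid = fivepl_eval(fit.params, x) - y
    rsdr = _robust_scale(resid, k_params=k)
    if rsdr == 0.0:  # perfect fit: nothing can be an outlier
        flags = np.zeros(n, dtype=bool)
        qvals = np.ones(n)
    else:
        tvals = np.abs(resid) / rsdr
        pvals = 2.0 * stats.t.sf(tvals, df=n - k)
        flags, qvals = multipletests(pvals, alpha=q, method="fdr_bh")[:2]
    if flags.all():
        raise RppmError("outliers: degenerate outlier removal (all points flagged)")

    excluded = pd.DataFrame(
        {
            "row_id": df.loc[df["included"], "row_id"].to_numpy()[flags],
            "residual": resid[flags],
            "q_value": qvals[flags],
        }
    )
    flagged_ids = set(excluded["row_id"].tolist())
    df["outlier"] = df["row_id"].isin(flagged_ids)
    df.loc[df["outlier"], "included"] = False

    if flags.any():
        refit = fit_master(df)
    else:
        refit = MasterFit(
            params=fit.params, rsdr=fit.rsdr, n_used=fit.n_used, rss=fit.rss
        )
    refit.excluded_points = excluded
    refit.rsdr = _robust_scale(
        fivepl_eval(refit.params, df.loc[df["included"], "x"].to_numpy())
        - df.loc[df["included"], "y"].to_numpy(),
        k_params=k,
    )
    _ = inc  # original inclusion retained in 'outlier' column
    return df, refit


def _fit_xmid(shape: FiveParamLogistic, x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """1-D least squares over x_mid with all shape parameters frozen.

    The profile RSS in x_mid can be shallow and multimodal at the dilution
    series' ends, so a dense vectorised grid (±4 decades around the master
    location) picks the basin and a bounded scalar minimisation refines it.
    """
    grid = shape.x_mid + np.linspace(-4.0, 4.0, 1601)
    u = np.power(10.0, np.clip(shape.B * (grid[:, None] - x[None, :]), -300, 300))
    pred = shape.D + (shape.A - shape.D) / np.power(1.0 + u, shape.G)
    rss_grid = ((pred - y[None, :]) ** 2).sum(axis=1)
    i = int(np.argmin(rss_grid))
    lo, hi = grid[max(i - 1, 0)], grid[min(i + 1, grid.size - 1)]

    def rss(xm: float) -> float:
        p = replace(shape, x_mid=float(xm))
        return float(np.sum((fivepl_eval(p, x) - y) ** 2))

    sol = optimize.minimize_scalar(
        rss, bounds=(lo, hi), method="bounded", options={"xatol": 1e-13}
    )
    return float(sol.x), float(sol.fun)


def fit_samples(
    points: pd.DataFrame, master: MasterFit, min_points: int = 3
) -> pd.DataFrame:
    """Per-sample 5PL fits with shared shape.

    A, D, B and G are frozen at the refined master values; only the
    location x_mid is fitted per sample (1-D least squares initialised at
    the master x_mid). Samples with fewer than ``min_points`` included
    spots are skipped with a warning row (x_mid NaN).

    Returns a DataFrame: sample_id, x_mid, rss, n_points, fitted.
    """
    mp = master.params
    rows = []
    for sample_id, sub in points[points["included"]].groupby("sample_id", sort=True):
        x = sub["x"].to_numpy(dtype=float)
        y = sub["y"].to_numpy(dtype=float)
        if x.size < min_points:
            rows.append(
                {"sample_id": sample_id, "x_mid": math.nan, "rss": math.nan,
                 "n_points": int(x.size), "fitted": False}
            )
            continue

        xm, rss = _fit_xmid(mp, x, y)
        rows.append(
            {
                "sample_id": sample_id,
                "x_mid": xm,
                "rss": rss,
                "n_points": int(x.size),
                "fitted": True,
            }
        )
    return pd.DataFrame(rows)


def max_slope_point(p: FiveParamLogistic) -> tuple[float, float]:
    """Location x* of the 5PL's maximum slope and the slope there.

    Closed form (derived in the module docstring): x* = x_mid + log10(G)/B,
    slope* = (A−D)·B·ln10·(1+1/G)^{−(G+1)}.
    """
    x_star = p.x_mid + math.log10(p.G) / p.B
    slope = (p.A - p.D) * p.B * LN10 * (1.0 + 1.0 / p.G) ** (-(p.G + 1.0))
    return x_star, slope


def quantify(sample_row: pd.Series | dict, master: MasterFit) -> SampleQuant:
    """Tangent y-intercept quantification of one fitted sample.

    The tangent to the sample's curve (shared shape, fitted x_mid) at its
    maximum-slope point is extrapolated to x = 0 (the undiluted print);
    its value there, in log10 fluorescence units, is the abundance readout.
    """
    xm = float(sample_row["x_mid"])
    p = replace(master.params, x_mid=xm)
    x_star, slope = max_slope_point(p)
    y_star = fivepl_eval(p, x_star)
    y0 = y_star + slope * (0.0 - x_star)
    return SampleQuant(
        sample_id=sample_row["sample_id"],
        x_mid_sample=xm,
        slope_linear=slope,
        y_intercept=float(y0),
        fit_rss=float(sample_row.get("rss", math.nan)),
        n_points=int(sample_row.get("n_points", 0)),
    )


def run_rppm_pipeline(
    raw: pd.DataFrame, q: float = 0.01
) -> tuple[pd.DataFrame, pd.DataFrame | None, MasterFit]:
    """Full quantification: preprocess → master → FDR refine → samples →
    y-intercepts.

    Returns (per-sample table, group summary or None, refined MasterFit).
    The group summary (mean ± SEM of y-intercepts per group) is produced
    when the input carries a ``group`` column.
    """
    try:
        spots = preprocess_spots(raw)
    except RppmError:
        raise
    except Exception as exc:  # pragma: no cover - defensive
        raise RppmError(f"preprocess: {exc}") from exc

    master0 = fit_master(spots)
    spots, master = remove_outliers_fdr(spots, master0, q=q)
    sample_fits = fit_samples(spots, master)

    quants = []
    for _, row in sample_fits.iterrows():
        if not row["fitted"]:
            continue
        sq = quantify(row, master)
        quants.append(
            {
                "sample_id": sq.sample_id,
                "x_mid": sq.x_mid_sample,
                "slope_linear": sq.slope_linear,
                "y_intercept": sq.y_intercept,
                "fit_rss": sq.fit_rss,
                "n_points": sq.n_points,
            }
        )
    out = pd.DataFrame(quants)
    if out.empty:
        raise RppmError("samples: no sample could be fitted")

    summary = None
    if "group" in raw.columns:
        groups = raw[["sample_id", "group"]].drop_duplicates("sample_id")
        merged = out.merge(groups, on="sample_id", how="left")
        rows = []
        for gname, sub in merged.groupby("group", sort=True):
            mean, sem = summarize(sub["y_intercept"].to_numpy())
            rows.append({"group": gname, "mean": mean, "sem": sem, "n": len(sub)})
        summary = pd.DataFrame(rows)
    return out, summary, master
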