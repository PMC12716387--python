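"""Standardized major axis (SMA) allometry of cuticle vs. body volume.

Cuticle volume scales with body volume; on log10-log10 axes the scaling
exponent is the slope of a symmetric line fit. SMA (also called reduced
major axis) minimizes deviations in both variables, which is appropriate
when neither volume is an error-free predictor:

    b = sign(r) * s_y / s_x,        a = mean(y) - b * mean(x)

with the 100(1-alpha)% slope confidence interval

    b * (sqrt(B + 1) +/- sqrt(B)),  B = F_{1,n-2}(1-alpha) * (1 - r^2) / (n - 2).

The slope test against a null value b0 (e.g. b0 = 1, isometry) is based on
the sample correlation between the residual scores y - b0*x and the axis
scores y + b0*x, which is zero under H0 and t-distributed on n-2 degrees of
freedom after the usual transformation. The common-slope (heterogeneity)
test across groups is the Bartlett-corrected likelihood-ratio statistic,
chi-square with (groups - 1) df; a permutation variant is available.

"Size-standardized cuticle investment" is the vertical residual of a
species' log10 cuticle volume from its caste's SMA line on log10 body
volume: positive residuals mean more cuticle than expected for the body
size.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "SpeciesRecord",
    "SMAFit",
    "SlopeTest",
    "sma_fit",
    "test_slope_equals",
    "test_common_slope",
    "species_means",
    "standardized_investment",
    "caste_correlation",
    "compare_to_reference",
]


@dataclass(frozen=True)
class SpeciesRecord:
    """Mean volumes for one species x caste cell."""

    species: str
    caste: str
    cuticle_volume_um3: float
    body_volume_um3: float
    n_specimens: int = 1

    def __post_init__(self) -> None:
        if self.cuticle_volume_um3 <= 0 or self.body_volume_um3 <= 0:
            raise ValueError("volumes must be positive")


@dataclass
class SMAFit:
    """A fitted standardized-major-axis line on (x, y) = log10 volumes."""

    slope: float
    intercept: float
    ci: tuple[float, float]
    r2: float
    n: int
    residuals: np.ndarray
    group: str = ""
    alpha: float = 0.05
    x: np.ndarray = field(default_factory=lambda: np.empty(0), repr=False)
    y: np.ndarray = field(default_factory=lambda: np.empty(0), repr=False)


@dataclass(frozen=True)
class SlopeTest:
    """Result of a slope hypothesis test."""

    null: str
    statistic: float
    p_value: float
    groups: tuple[str, ...] = ()
    degenerate: bool = False

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0):
            raise ValueError("p-value outside [0, 1]")


def _validate_xy(x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1D arrays of equal length")
    if len(x) < 3:
        raise ValueError("at least 3 points required")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("non-finite values in input")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance in x or y")
    return x, y


def sma_fit(
    x: np.ndarray, y: np.ndarray, alpha: float = 0.05, group: str = ""
) -> SMAFit:
    """Fit a standardized major axis line to (x, y).

    ``x`` and ``y`` are typically log10 body and cuticle volumes. Residuals
    are vertical, y - (a + b*x); they sum to zero because the fitted line
    passes through the centroid (mean(x), mean(y)).
    """
    x, y = _validate_xy(x, y)
    n = len(x)
    sx = x.std(ddof=1)
    sy = y.std(ddof=1)
    r = float(np.corrcoef(x, y)[0, 1])
    sign = 1.0 if r >= 0 else -1.0
    b = sign * sy / sx
    a = float(y.mean() - b * x.mean())
    r2 = r * r
    B = stats.f.ppf(1 - alpha, 1, n - 2) * max(1 - r2, 0.0) / (n - 2)
    ci = (b * (np.sqrt(B + 1) - np.sqrt(B)), b * (np.sqrt(B + 1) + np.sqrt(B)))
    if b < 0:
        ci = (ci[1], ci[0])
    resid = y - (a + b * x)
    return SMAFit(
        slope=float(b),
        intercept=a,
        ci=(float(ci[0]), float(ci[1])),
        r2=float(r2),
        n=n,
        residuals=resid,
        group=group,
        alpha=alpha,
        x=x,
        y=y,
    )


def test_slope_equals(fit: SMAFit, b0: float = 1.0) -> SlopeTest:
    """Test H0: SMA slope equals ``b0`` (b0 = 1 is the isometry test).

    Under H0 the residual scores u = y - b0*x and axis scores v = y + b0*x
    are uncorrelated; the test is the t-test on corr(u, v) with n-2 df. An
    exact slope-b0 line has zero residual variance and is reported as
    degenerate with p = 1 by convention.
    """
    if b0 == 0:
        raise ValueError("null slope must be nonzero")
    if fit.x.size == 0:
        raise ValueError("fit does not carry its data; refit with sma_fit")
    x, y, n = fit.x, fit.y, fit.n
    u = y - b0 * x
    v = y + b0 * x
    if np.ptp(u) == 0 or np.ptp(v) == 0:
        return SlopeTest(
            null=f"slope={b0}", statistic=np.inf, p_value=1.0,
            groups=(fit.group,), degenerate=True,
        )
    r = float(np.corrcoef(u, v)[0, 1])
    r = float(np.clip(r, -1.0, 1.0))
    if abs(r) == 1.0:
        return SlopeTest(
            null=f"slope={b0}", statistic=np.inf, p_value=0.0, groups=(fit.group,)
        )
    t = r * np.sqrt((n - 2) / (1 - r * r))
    p = 2 * stats.t.sf(abs(t), n - 2)
    return SlopeTest(null=f"slope={b0}", statistic=float(t), p_value=float(p),
                     groups=(fit.group,))


def _lr_at_slope(fits: list[SMAFit], b: float) -> float:
    """Bartlett-corrected -2 log LR for a common slope b across groups."""
    total = 0.0
    for f in fits:
        u = f.y - b * f.x
        v = f.y + b * f.x
        su, sv = u.std(ddof=1), v.std(ddof=1)
        if su == 0 or sv == 0:
            r2 = 1.0
        else:
            r = float(np.corrcoef(u, v)[0, 1])
            r2 = min(r * r, 1 - 1e-15)
        total += -(f.n - 2.5) * np.log1p(-r2)
    return total


def test_common_slope(
    fits: list[SMAFit],
    method: str = "lr",
    n_permutations: int = 2000,
    seed: int = 0,
) -> SlopeTest:
    """Test whether several groups share one SMA slope.

    ``method="lr"``: the likelihood-ratio heterogeneity statistic, minimized
    over the candidate common slope, compared to chi-square with
    (groups - 1) df. ``method="permutation"``: the same statistic compared
    to its distribution under random reassignment of group labels
    (``n_permutations`` shuffles, seeded).
    """
    if len(fits) < 2:
        raise ValueError("need at least 2 groups")
    for f in fits:
        if f.x.size == 0 or f.n < 3:
            raise ValueError(f"group {f.group!r} is degenerate or lacks data")
        if np.ptp(f.x) == 0 or np.ptp(f.y) == 0:
            raise ValueError(f"group {f.group!r} has zero variance")
    groups = tuple(f.group for f in fits)
    slopes = [abs(f.slope) for f in fits]
    lo, hi = min(slopes) * 0.5, max(slopes) * 2.0
    sign = np.sign(np.median([f.slope for f in fits])) or 1.0

    def objective(b: float) -> float:
        return _lr_at_slope(fits, sign * b)

    res = optimize.minimize_scalar(objective, bounds=(lo, hi), method="bounded")
    stat = float(res.fun)
    df = len(fits) - 1
    if method == "lr":
        p = float(stats.chi2.sf(stat, df))
    elif method == "permutation":
        rng = np.random.default_rng(seed)
        xs = np.concatenate([f.x for f in fits])
        ys = np.concatenate([f.y for f in fits])
        sizes = [f.n for f in fits]
        exceed = 0
        for _ in range(n_permutations):
            perm = rng.permutation(len(xs))
            start = 0
            pf = []
            for sz, g in zip(sizes, groups):
                idx = perm[start : start + sz]
                start += sz
                pf.append(sma_fit(xs[idx], ys[idx], group=g))
            pres = optimize.minimize_scalar(
                lambda b: _lr_at_slope(pf, sign * b), bounds=(lo, hi), method="bounded"
            )
            if pres.fun >= stat:
                exceed += 1
        p = (exceed + 1) / (n_permutations + 1)
    else:
        raise ValueError("method must be 'lr' or 'permutation'")
    return SlopeTest(null="common slope", statistic=stat, p_value=float(p),
                     groups=groups)


def species_means(
    df: pd.DataFrame,
    log_then_mean: bool = False,
) -> pd.DataFrame:
    """Average specimen volumes to one record per species x caste.

    Input columns: species, caste, cuticle_volume_um3, body_volume_um3.
    Default is the arithmetic mean of the volumes, then log10 downstream
    (``log_then_mean=True`` averages log10 volumes instead — i.e. geometric
    means).
    """
    required = {"species", "caste", "cuticle_volume_um3", "body_volume_um3"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"missing columns: {sorted(missing)}")
    work = df.copy()
    if log_then_mean:
        work["cuticle_volume_um3"] = np.log10(work["cuticle_volume_um3"])
        work["body_volume_um3"] = np.log10(work["body_volume_um3"])
    out = (
        work.groupby(["species", "caste"], as_index=False)
        .agg(
            cuticle_volume_um3=("cuticle_volume_um3", "mean"),
            body_volume_um3=("body_volume_um3", "mean"),
            n_specimens=("species", "size"),
        )
    )
    if log_then_mean:
        out["cuticle_volume_um3"] = 10 ** out["cuticle_volume_um3"]
        out["body_volume_um3"] = 10 ** out["body_volume_um3"]
    return out


def standardized_investment(
    records: pd.DataFrame, caste: str, alpha: float = 0.05
) -> tuple[pd.Series, SMAFit]:
    """Size-standardized cuticle investment for one caste.

    Fits the caste's species-mean log10 cuticle volume against log10 body
    volume by SMA and returns the vertical residuals (indexed by species)
    with the fit kept for provenance. Positive residual = more cuticle than
    expected at that body size.
    """
    sub = records[records["caste"] == caste]
    if len(sub) < 3:
        raise ValueError(f"fewer than 3 species with caste {caste!r}")
    x = np.log10(sub["body_volume_um3"].to_numpy(dtype=float))
    y = np.log10(sub["cuticle_volume_um3"].to_numpy(dtype=float))
    fit = sma_fit(x, y, alpha=alpha, group=caste)
    res = pd.Series(fit.residuals, index=sub["species"].to_numpy(), name=caste)
    return res, fit


def caste_correlation(
    res_a: pd.Series, res_b: pd.Series
) -> tuple[float, float, float, int]:
    """Correlation of size-standardized investment between two castes.

    Matches species present in both residual series and returns
    (r2, SMA slope, Pearson p-value, n matched species).
    """
    common = res_a.index.intersection(res_b.index)
    if len(common) < 3:
        raise ValueError("fewer than 3 matched species")
    a = res_a.loc[common].to_numpy(dtype=float)
    b = res_b.loc[common].to_numpy(dtype=float)
    r, p = stats.pearsonr(a, b)
    fit = sma_fit(a, b)
    return float(r * r), float(fit.slope), float(p), int(len(common))


def compare_to_reference(
    auto: pd.DataFrame, ref: pd.DataFrame
) -> tuple[float, float, pd.DataFrame]:
    """Validate automated volumes against an independent reference.

    Both frames need columns specimen_id, cuticle_volume_um3,
    body_volume_um3. Returns (r2 of cuticle volumes, r2 of cuticle/body
    ratios, per-specimen comparison table).
    """
    merged = auto.merge(ref, on="specimen_id", suffixes=("_auto", "_ref"))
    if len(merged) == 0:
        raise ValueError("no matching specimen ids")
    if len(merged) < 2:
        raise ValueError("at least 2 matched specimens required for a correlation")
    va = merged["cuticle_volume_um3_auto"].to_numpy(dtype=float)
    vr = merged["cuticle_volume_um3_ref"].to_numpy(dtype=float)
    ra = va / merged["body_volume_um3_auto"].to_numpy(dtype=float)
    rr = vr / merged["body_volume_um3_ref"].to_numpy(dtype=float)
    merged["ratio_auto"], merged["ratio_ref"] = ra, rr
    merged["cuticle_volume_delta"] = va - vr
    merged["ratio_delta"] = ra - rr

    def _r2(u: np.ndarray, v: np.ndarray) -> float:
        if np.ptp(u) == 0 and np.ptp(v) == 0:
            return 1.0  # identical constants: perfect agreement
        if np.ptp(u) == 0 or np.ptp(v) == 0:
            return 0.0
        return float(np.corrcoef(u, v)[0, 1] ** 2)

    return _r2(va, vr), _r2(ra, rr), merged
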