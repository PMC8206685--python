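"""Geographic distances and trend regressions.

Introgression signals are regressed on distance from an African origin:
great-circle (haversine) distances for ocean-crossing comparisons, or
land-route distances built from a configurable waypoint chain (e.g. through
the Levant, and across Beringia for the Americas) when an overland path is
wanted.  Fits are ordinary least squares via statsmodels/scipy: a simple
trend (statistic ~ distance), a multiple regression of the Neanderthal
signal on the Denisovan signal and distance with their interaction, and a
by-region model (statistic ~ distance x region) whose interaction term tests
whether regions share a common slope.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

EARTH_RADIUS_KM = 6371.0

#: default origins used by the analysis recipes
CAIRO = (30.0, 31.0)
ADDIS_ABABA = (9.03, 38.74)

#: a coarse overland waypoint chain: Levant -> central Asia -> Beringia
DEFAULT_WAYPOINTS = {
    "levant": (33.5, 36.3),
    "central_asia": (41.3, 69.3),
    "beringia": (65.5, -169.0),
}


@dataclass
class TrendFit:
    """Regression output: coefficient table, correlation and fit diagnostics."""

    formula: str
    coefficients: pd.DataFrame  # index = term; columns: estimate, se, p
    r: float
    r2: float
    n: int
    residual_sd: float
    defined: bool = True
    interaction_p: float | None = None
    notes: list = field(default_factory=list)

    def coef(self, term: str) -> float:
        return float(self.coefficients.loc[term, "estimate"])

    def pvalue(self, term: str) -> float:
        return float(self.coefficients.loc[term, "p"])

    def conf_int(self, term: str, alpha: float = 0.05) -> tuple[float, float]:
        from scipy import stats

        est = self.coef(term)
        se = float(self.coefficients.loc[term, "se"])
        dof = max(self.n - len(self.coefficients), 1)
        half = stats.t.ppf(1 - alpha / 2, dof) * se
        return est - half, est + half


def _check_coord(coord) -> tuple[float, float]:
    lat, lon = float(coord[0]), float(coord[1])
    if abs(lat) > 90 or abs(lon) > 180:
        raise ValueError(f"invalid coordinate (lat={lat}, lon={lon})")
    return lat, lon


def great_circle_distance(coord_a, coord_b, radius_km: float = EARTH_RADIUS_KM) -> float:
    """Haversine great-circle distance in km between (lat, lon) points in
    decimal degrees."""
    lat1, lon1 = _check_coord(coord_a)
    lat2, lon2 = _check_coord(coord_b)
    p1, p2 = math.radians(lat1), math.radians(lat2)
    dp = math.radians(lat2 - lat1)
    dl = math.radians(lon2 - lon1)
    a = math.sin(dp / 2) ** 2 + math.cos(p1) * math.cos(p2) * math.sin(dl / 2) ** 2
    return 2 * radius_km * math.asin(min(1.0, math.sqrt(a)))


def land_route_distance(origin, dest, waypoints=(),
                        radius_km: float = EARTH_RADIUS_KM) -> float:
    """Distance along a chain of great-circle legs origin -> waypoints -> dest.

    With no waypoints this reduces to the plain great-circle distance; the
    waypoint chain is how overland routing constraints (coastal routes,
    Beringia) are expressed.
    """
    chain = [origin, *waypoints, dest]
    return sum(great_circle_distance(a, b, radius_km=radius_km)
               for a, b in zip(chain, chain[1:]))


def _ols_fit(df: pd.DataFrame, formula: str) -> tuple:
    import statsmodels.formula.api as smf

    model = smf.ols(formula, data=df)
    res = model.fit()
    coefs = pd.DataFrame({"estimate": res.params, "se": res.bse, "p": res.pvalues})
    return res, coefs


def fit_trend(x, y, x_name: str = "distance", y_name: str = "statistic") -> TrendFit:
    """Ordinary least squares of y on x with Pearson r and two-sided p.

    Requires at least three complete cases; zero variance in x yields a
    flagged (undefined) fit instead of an exception.
    """
    from scipy import stats

    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    keep = ~np.isnan(x) & ~np.isnan(y)
    x, y = x[keep], y[keep]
    n = int(x.size)
    formula = f"{y_name} ~ {x_name}"
    if n < 3:
        raise ValueError(f"need at least 3 complete cases, got {n}")
    empty = pd.DataFrame(columns=["estimate", "se", "p"])
    if np.ptp(x) == 0:
        return TrendFit(formula, empty, float("nan"), float("nan"), n,
                        float("nan"), defined=False, notes=["zero variance in x"])
    lr = stats.linregress(x, y)
    resid = y - (lr.intercept + lr.slope * x)
    dof = max(n - 2, 1)
    coefs = pd.DataFrame(
        {"estimate": [lr.intercept, lr.slope],
         "se": [lr.intercept_stderr, lr.stderr],
         "p": [2 * stats.t.sf(abs(lr.intercept / lr.intercept_stderr), dof)
               if lr.intercept_stderr > 0 else float("nan"),
               lr.pvalue]},
        index=["Intercept", x_name])
    return TrendFit(formula, coefs, float(lr.rvalue), float(lr.rvalue**2), n,
                    float(np.sqrt((resid**2).sum() / dof)))


def fit_interaction_model(nd_nea, nd_den, distance) -> TrendFit:
    """Multiple regression nd_NEA ~ nd_DEN + distance + nd_DEN:distance.

    Reports per-term p-values; the interaction term tests whether the
    relation between the two archaic signals changes with distance from
    Africa.  Collinear/degenerate designs yield a flagged fit.
    """
    df = pd.DataFrame({"nd_nea": np.asarray(nd_nea, dtype=float),
                       "nd_den": np.asarray(nd_den, dtype=float),
                       "distance": np.asarray(distance, dtype=float)}).dropna()
    n = len(df)
    formula = "nd_nea ~ nd_den * distance"
    if n < 5:
        raise ValueError(f"need at least 5 complete cases, got {n}")
    if df["nd_den"].nunique() < 2 or df["distance"].nunique() < 2:
        return TrendFit(formula, pd.DataFrame(columns=["estimate", "se", "p"]),
                        float("nan"), float("nan"), n, float("nan"),
                        defined=False, notes=["degenerate predictor"])
    res, coefs = _ols_fit(df, formula)
    if np.linalg.cond(res.model.exog) > 1e12:
        return TrendFit(formula, coefs, float("nan"), float("nan"), n,
                        float("nan"), defined=False, notes=["collinear design"])
    r = float(np.sign(res.params.get("nd_den", 0.0)) * np.sqrt(res.rsquared))
    return TrendFit(formula, coefs, r, float(res.rsquared), n,
                    float(np.sqrt(res.mse_resid)),
                    interaction_p=float(res.pvalues["nd_den:distance"]))


def fit_region_glm(values, distance, regions,
                   min_points_per_region: int = 3) -> TrendFit:
    """Linear model ``statistic ~ distance * region`` with the
    distance-by-region interaction reported as the parallel-slopes test.

    Regions with fewer than ``min_points_per_region`` complete cases are
    excluded (counted in the notes); a single remaining region falls back to
    :func:`fit_trend` with a warning.
    """
    import statsmodels.api as sm

    df = pd.DataFrame({"value": np.asarray(values, dtype=float),
                       "distance": np.asarray(distance, dtype=float),
                       "region": pd.Series(regions, dtype="object")}).dropna()
    counts = df.groupby("region").size()
    small = counts[counts < min_points_per_region]
    notes = []
    if len(small):
        notes.append(f"excluded regions with <{min_points_per_region} points: "
                     f"{sorted(small.index)}")
        df = df[~df["region"].isin(small.index)]
    if df["region"].nunique() < 2:
        warnings.warn("only one region remains; falling back to a common trend fit")
        fit = fit_trend(df["distance"], df["value"])
        fit.notes.extend(notes + ["single region: no interaction test"])
        return fit
    res, coefs = _ols_fit(df, "value ~ distance * C(region)")
    anova = sm.stats.anova_lm(res, typ=2)
    interaction_p = float(anova.loc["distance:C(region)", "PR(>F)"])
    r = float(np.sign(res.params.get("distance", 0.0)) * np.sqrt(res.rsquared))
    return TrendFit("value ~ distance * C(region)", coefs, r,
                    float(res.rsquared), len(df), float(np.sqrt(res.mse_resid)),
                    interaction_p=interaction_p, notes=notes)
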