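"""Isoscape construction: screening, semivariograms, ordinary kriging,
and a bootstrap (empirical-Bayes-style) uncertainty scheme.

Per isotope: records are screened for outliers (IQR fence), split 70/30
stratified by subpopulation, detrended by a low-order polynomial in
lon/lat, and interpolated by ordinary kriging of the residuals under a
fitted semivariogram (exponential, spherical, or the Matern "K-Bessel"
family; nu = 0.5 recovers the exponential model exactly). Semivariogram
uncertainty is propagated EBK-style by refitting on random record subsets
and pooling the per-subset kriging predictions and variances. All
distances are great-circle km; grids are geographic degrees.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd
from scipy.linalg import lu_factor, lu_solve
from scipy.optimize import least_squares
from scipy.special import gamma as gamma_fn, kv
from sklearn.base import BaseEstimator, RegressorMixin

from ._geo import pairwise_haversine_km
from .raster import Grid, Raster

VARIOGRAM_MODELS = ("exponential", "spherical", "kbessel")


@dataclass(frozen=True)
class VariogramModel:
    """Isotropic semivariogram gamma(h) with nugget, partial sill and range.

    ``range_km`` is the e-folding scale for the exponential/K-Bessel
    families (practical range ~3x) and the true range for the spherical
    model. ``shape`` is the Matern smoothness nu (K-Bessel only).
    """

    model: str
    nugget: float
    partial_sill: float
    range_km: float
    shape: float = 0.5

    def __post_init__(self):
        if self.model not in VARIOGRAM_MODELS:
            raise ValueError(f"unknown variogram model {self.model!r}")
        if self.nugget < 0 or self.partial_sill < 0:
            raise ValueError("nugget and partial sill must be >= 0")
        if self.range_km <= 0:
            raise ValueError("range must be > 0")
        if self.model == "kbessel" and self.shape <= 0:
            raise ValueError("K-Bessel shape nu must be > 0")

    def __call__(self, h):
        h = np.asarray(h, dtype=float)
        a = self.range_km
        if self.model == "exponential":
            struct = 1.0 - np.exp(-h / a)
        elif self.model == "spherical":
            hr = np.minimum(h / a, 1.0)
            struct = 1.5 * hr - 0.5 * hr ** 3
        else:  # kbessel / Matern
            nu = self.shape
            x = h / a
            with np.errstate(invalid="ignore", over="ignore", under="ignore"):
                corr = (2.0 ** (1.0 - nu) / gamma_fn(nu)) * x ** nu * kv(nu, x)
            corr = np.where(h > 0, np.nan_to_num(corr, nan=0.0), 1.0)
            struct = 1.0 - corr
        gamma = self.nugget + self.partial_sill * struct
        return np.where(h == 0, self.nugget, gamma)

    @property
    def sill(self):
        return self.nugget + self.partial_sill


@dataclass
class Isoscape:
    """Kriged prediction surface and its standard-error surface."""

    isotope: str
    grid: Grid
    prediction: Raster
    prediction_se: Raster
    trend_coefficients: np.ndarray
    variogram: VariogramModel
    n_records: int = 0
    n_sims: int = 1

    def __post_init__(self):
        se = self.prediction_se.values
        if np.any(se[np.isfinite(se)] < 0):
            raise ValueError("prediction SE must be non-negative")


# ---------------------------------------------------------------------------
# screening and splitting

def outlier_filter(records: pd.DataFrame, isotope: str, k: float = 3.0):
    """Drop records outside [Q1 - k*IQR, Q3 + k*IQR] of the isotope.

    Quartiles use linear interpolation. Returns (kept records, removed ids);
    a zero IQR keeps everything and warns.
    """
    df = records.dropna(subset=[isotope])
    if len(df) < 5:
        raise ValueError("outlier screening needs at least five records")
    vals = df[isotope].to_numpy(dtype=float)
    q1, q3 = np.percentile(vals, [25, 75])
    iqr = q3 - q1
    if iqr == 0:
        warnings.warn(f"zero IQR for {isotope}; no outlier screening applied")
        return records.reset_index(drop=True), []
    lo, hi = q1 - k * iqr, q3 + k * iqr
    out = (vals < lo) | (vals > hi)
    removed = df.loc[out, "id"].tolist()
    kept = records[~records["id"].isin(removed)].reset_index(drop=True)
    return kept, removed


def stratified_split(records: pd.DataFrame, train_frac: float = 0.7, seed: int = 0,
                     stratify_by: str = "subpopulation"):
    """Per-stratum simple random split into train and test sets.

    Train size per stratum is round(train_frac * n), with at least one
    record on each side. Disjoint and exhaustive.
    """
    if not 0.0 < train_frac < 1.0:
        raise ValueError("train_frac must lie strictly between 0 and 1")
    rng = np.random.default_rng(seed)
    train_idx = []
    for _, grp in records.groupby(stratify_by, sort=True):
        n = len(grp)
        if n < 2:
            raise ValueError(f"stratum with n = {n} < 2 cannot be split")
        n_train = int(np.clip(round(train_frac * n), 1, n - 1))
        perm = rng.permutation(grp.index.to_numpy())
        train_idx.extend(perm[:n_train])
    train_mask = records.index.isin(train_idx)
    return (records[train_mask].reset_index(drop=True),
            records[~train_mask].reset_index(drop=True))


# ---------------------------------------------------------------------------
# detrending

def _trend_design(lon, lat, order: int):
    lon = np.asarray(lon, dtype=float)
    lat = np.asarray(lat, dtype=float)
    cols = [np.ones_like(lon)]
    if order >= 1:
        cols += [lon, lat]
    if order >= 2:
        cols += [lon ** 2, lon * lat, lat ** 2]
    return np.column_stack(cols)


def detrend(records: pd.DataFrame, isotope: str, order: int = 1):
    """Remove a polynomial surface (default planar) fit by OLS.

    Returns (records with a ``residual`` column, coefficient vector).
    """
    df = records.dropna(subset=[isotope]).reset_index(drop=True)
    if len(df) < 4:
        raise ValueError("detrending needs at least four records")
    x = _trend_design(df["lon"], df["lat"], order)
    if np.linalg.matrix_rank(x) < x.shape[1]:
        raise ValueError("degenerate record locations; trend surface unidentifiable")
    beta, *_ = np.linalg.lstsq(x, df[isotope].to_numpy(dtype=float), rcond=None)
    out = df.copy()
    out["residual"] = df[isotope].to_numpy(dtype=float) - x @ beta
    return out, beta


def evaluate_trend(beta: np.ndarray, lon, lat):
    order = {1: 0, 3: 1, 6: 2}[len(beta)]
    return _trend_design(np.ravel(lon), np.ravel(lat), order) @ beta


# ---------------------------------------------------------------------------
# variograms

def empirical_variogram(records: pd.DataFrame, value_col: str = "residual",
                        n_lags: int = 15, max_dist: float | None = None) -> pd.DataFrame:
    """Matheron estimator gamma(h) = sum (z_i - z_j)^2 / (2 N(h)) on
    great-circle-distance bins. Empty bins are dropped with a warning.
    Returns a lag table (h_km, gamma, n_pairs)."""
    if len(records) < 10:
        raise ValueError("empirical variogram needs at least ten records")
    z = records[value_col].to_numpy(dtype=float)
    d = pairwise_haversine_km(records["lon"].to_numpy(), records["lat"].to_numpy())
    iu = np.triu_indices(len(z), k=1)
    dists = d[iu]
    sqd = (z[iu[0]] - z[iu[1]]) ** 2
    if max_dist is None:
        max_dist = dists.max() / 3.0
    edges = np.linspace(0.0, max_dist, n_lags + 1)
    rows = []
    for i in range(n_lags):
        sel = (dists > edges[i]) & (dists <= edges[i + 1])
        if not sel.any():
            warnings.warn(f"empty variogram bin ({edges[i]:.0f}, {edges[i + 1]:.0f}] km dropped")
            continue
        rows.append({
            "h_km": dists[sel].mean(),
            "gamma": sqd[sel].sum() / (2.0 * sel.sum()),
            "n_pairs": int(sel.sum()),
        })
    return pd.DataFrame(rows)


def fit_variogram(lag_table: pd.DataFrame, model: str = "kbessel") -> VariogramModel:
    """Weighted least squares (weights N(h)/h^2) over nugget, partial sill,
    range (and shape nu in [0.2, 5] for K-Bessel)."""
    if model not in VARIOGRAM_MODELS:
        raise ValueError(f"unknown variogram model {model!r}")
    if len(lag_table) < 4:
        raise ValueError("variogram fitting needs at least four usable lags")
    h = lag_table["h_km"].to_numpy(dtype=float)
    g = lag_table["gamma"].to_numpy(dtype=float)
    w = np.sqrt(lag_table["n_pairs"].to_numpy(dtype=float)) / h
    gmax = max(g.max(), 1e-12)
    hmax = h.max()

    kbessel = model == "kbessel"

    def residuals(theta):
        nugget, psill, rng_km = theta[:3]
        shape = theta[3] if kbessel else 0.5
        vm = VariogramModel(model, nugget, psill, rng_km, shape)
        return w * (vm(h) - g)

    x0 = [max(g[0] * 0.5, 1e-6 * gmax), max(gmax - g[0] * 0.5, 1e-6 * gmax), hmax / 3.0]
    lo = [0.0, 0.0, hmax * 1e-3]
    hi = [2.0 * gmax, 4.0 * gmax, hmax * 10.0]
    if kbessel:
        x0, lo, hi = x0 + [0.5], lo + [0.2], hi + [5.0]
    try:
        sol = least_squares(residuals, x0, bounds=(lo, hi), method="trf")
    except Exception as exc:  # pragma: no cover - optimizer pathologies
        raise RuntimeError(f"variogram fit failed: {exc}") from exc
    if not sol.success:
        raise RuntimeError(f"variogram fit did not converge: {sol.message}")
    nugget, psill, rng_km = sol.x[:3]
    shape = sol.x[3] if kbessel else 0.5
    return VariogramModel(model, float(nugget), float(psill), float(rng_km), float(shape))


# ---------------------------------------------------------------------------
# ordinary kriging

class OrdinaryKriging(BaseEstimator, RegressorMixin):
    """Ordinary kriging under a fixed semivariogram.

    Solves, per prediction point, [Gamma 1; 1' 0][w; m] = [gamma0; 1] on
    the (up to ``max_neighbors`` nearest) observations; the predictor is
    w'z with kriging variance w'gamma0 + m. When all observations are used
    for every point the system is factorised once.

    Parameters
    ----------
    variogram : VariogramModel
    max_neighbors : int
        Nearest-observation cap per prediction point (default 100).
    jitter_deg : float
        Duplicate observation locations are jittered by this amount in
        degrees (set to 0 to raise instead).
    """

    def __init__(self, variogram: VariogramModel = None, max_neighbors: int = 100,
                 jitter_deg: float = 1e-4):
        self.variogram = variogram
        self.max_neighbors = max_neighbors
        self.jitter_deg = jitter_deg

    def fit(self, coords, z):
        """coords: (n, 2) array of (lon, lat); z: observed values."""
        coords = np.asarray(coords, dtype=float)
        z = np.asarray(z, dtype=float)
        if self.variogram is None:
            raise ValueError("a VariogramModel is required")
        if coords.ndim != 2 or coords.shape[1] != 2 or len(coords) != len(z):
            raise ValueError("coords must be (n, 2) lon/lat matching z")
        if len(z) < 2:
            raise ValueError("kriging needs at least two observations")
        # resolve exactly duplicated locations
        _, first = np.unique(coords.round(12), axis=0, return_index=True)
        if len(first) < len(coords):
            if self.jitter_deg <= 0:
                raise ValueError("duplicate observation locations")
            rng = np.random.default_rng(0)
            dup = np.setdiff1d(np.arange(len(coords)), first)
            coords = coords.copy()
            coords[dup] += rng.uniform(-self.jitter_deg, self.jitter_deg, (len(dup), 2))
        self.coords_ = coords
        self.z_ = z
        self._dist = pairwise_haversine_km(coords[:, 0], coords[:, 1])
        if len(z) <= self.max_neighbors:
            self._factor = lu_factor(self._augmented(self._dist))
        else:
            self._factor = None
        return self

    def _augmented(self, dist):
        # Semivariogram system with a zero diagonal: gamma(0) = 0 between an
        # observation and itself, while off-diagonal (and RHS) terms keep the
        # nugget as the h -> 0+ limit. The nugget then acts as a
        # measurement-error filter (smoothing kriging); with nugget = 0 the
        # predictor interpolates the data exactly.
        n = dist.shape[0]
        a = np.empty((n + 1, n + 1))
        a[:n, :n] = self.variogram(dist)
        np.fill_diagonal(a[:n, :n], 0.0)
        # small diagonal regularisation keeps the zero-nugget system solvable
        a[:n, :n] -= np.eye(n) * 1e-10 * max(self.variogram.sill, 1.0)
        a[n, :n] = a[:n, n] = 1.0
        a[n, n] = 0.0
        return a

    def weights(self, lon, lat):
        """Kriging weights and Lagrange multiplier for one prediction point
        (uses all observations; exposed for verification)."""
        g0 = self.variogram(pairwise_haversine_km(
            self.coords_[:, 0], self.coords_[:, 1], [lon], [lat]).ravel())
        a = self._augmented(self._dist)
        sol = np.linalg.solve(a, np.append(g0, 1.0))
        return sol[:-1], sol[-1]

    def predict(self, coords, return_std=False):
        coords = np.asarray(coords, dtype=float).reshape(-1, 2)
        n = len(self.z_)
        g0 = self.variogram(pairwise_haversine_km(
            self.coords_[:, 0], self.coords_[:, 1], coords[:, 0], coords[:, 1]))
        if self._factor is not None:
            rhs = np.vstack([g0, np.ones(len(coords))])
            sol = lu_solve(self._factor, rhs)
            w, m = sol[:n], sol[n]
            pred = w.T @ self.z_
            var = np.einsum("ij,ij->j", w, g0) + m
        else:
            pred = np.empty(len(coords))
            var = np.empty(len(coords))
            for i, (lon, lat) in enumerate(coords):
                d0 = pairwise_haversine_km(
                    self.coords_[:, 0], self.coords_[:, 1], [lon], [lat]).ravel()
                nb = np.argsort(d0)[: self.max_neighbors]
                a = np.empty((len(nb) + 1, len(nb) + 1))
                a[:-1, :-1] = self.variogram(self._dist[np.ix_(nb, nb)])
                np.fill_diagonal(a[:-1, :-1], 0.0)
                a[:-1, :-1] -= np.eye(len(nb)) * 1e-10 * max(self.variogram.sill, 1.0)
                a[-1, :-1] = a[:-1, -1] = 1.0
                a[-1, -1] = 0.0
                sol = np.linalg.solve(a, np.append(self.variogram(d0[nb]), 1.0))
                pred[i] = sol[:-1] @ self.z_[nb]
                var[i] = sol[:-1] @ self.variogram(d0[nb]) + sol[-1]
        if return_std:
            return pred, np.sqrt(np.clip(var, 0.0, None))
        return pred


def krige_predict(records: pd.DataFrame, variogram: VariogramModel, grid: Grid,
                  value_col: str = "residual", max_neighbors: int = 100):
    """Ordinary kriging of a record column onto a grid.

    Returns (prediction Raster, kriging-SE Raster) of the residual surface
    (any trend must be added back by the caller).
    """
    ok = OrdinaryKriging(variogram, max_neighbors=max_neighbors)
    ok.fit(records[["lon", "lat"]].to_numpy(dtype=float),
           records[value_col].to_numpy(dtype=float))
    lon, lat = grid.meshgrid()
    pred, se = ok.predict(np.column_stack([lon.ravel(), lat.ravel()]), return_std=True)
    return (Raster(grid, pred.reshape(grid.nrows, grid.ncols)),
            Raster(grid, se.reshape(grid.nrows, grid.ncols)))


# ---------------------------------------------------------------------------
# EBK-style bootstrap surface

def ebk_surface(records: pd.DataFrame, isotope: str, grid: Grid, n_sims: int = 100,
                subset_size: int = 100, seed: int = 0, model: str = "kbessel",
                trend_order: int = 1, n_lags: int = 15,
                max_neighbors: int = 100) -> Isoscape:
    """Bootstrap kriging surface with semivariogram-uncertainty propagation.

    Repeats ``n_sims`` times: draw ``subset_size`` records without
    replacement (all records if fewer), detrend, fit the semivariogram,
    krige the residuals, add the trend back. The reported prediction is
    the across-simulation mean; the reported SE combines the mean kriging
    variance with the between-simulation variance of the predictions.
    """
    df = records.dropna(subset=[isotope]).reset_index(drop=True)
    if len(df) < 20:
        raise ValueError("EBK-style surface needs at least 20 records")
    rng = np.random.default_rng(seed)
    lon, lat = grid.meshgrid()
    preds, kvars, coefs, vgs = [], [], [], []
    failures = 0
    for _ in range(n_sims):
        take = (rng.choice(len(df), subset_size, replace=False)
                if subset_size < len(df) else np.arange(len(df)))
        sub = df.iloc[np.sort(take)].reset_index(drop=True)
        try:
            resid, beta = detrend(sub, isotope, order=trend_order)
            lag = empirical_variogram(resid)
            vg = fit_variogram(lag, model=model)
            p, s = krige_predict(resid, vg, grid, max_neighbors=max_neighbors)
        except (ValueError, RuntimeError):
            failures += 1
            continue
        trend = evaluate_trend(beta, lon, lat).reshape(grid.nrows, grid.ncols)
        preds.append(p.values + trend)
        kvars.append(s.values ** 2)
        coefs.append(beta)
        vgs.append(vg)
    if failures > n_sims / 2:
        raise RuntimeError(f"{failures}/{n_sims} simulations failed variogram fitting")
    preds = np.asarray(preds)
    kvars = np.asarray(kvars)
    prediction = preds.mean(axis=0)
    between = preds.var(axis=0, ddof=1) if len(preds) > 1 else np.zeros_like(prediction)
    se = np.sqrt(kvars.mean(axis=0) + between)
    params = np.median([[v.nugget, v.partial_sill, v.range_km, v.shape] for v in vgs], axis=0)
    pooled = VariogramModel(model, *map(float, params))
    return Isoscape(isotope, grid, Raster(grid, prediction), Raster(grid, se),
                    np.mean(coefs, axis=0), pooled, n_records=len(df), n_sims=len(preds))


# ---------------------------------------------------------------------------
# raster alignment

@dataclass
class RasterStack:
    """Aligned per-isotope prediction (and SE) rasters on one shared grid."""

    grid: Grid
    predictions: dict[str, Raster]
    errors: dict[str, Raster] = dc_field(default_factory=dict)

    @property
    def isotopes(self):
        return list(self.predictions)

    @property
    def mask(self):
        """True where any layer is nodata."""
        m = np.zeros((self.grid.nrows, self.grid.ncols), dtype=bool)
        for r in self.predictions.values():
            m |= r.mask
        return m

    def to_matrix(self, isotopes=None):
        """(n_unmasked_cells, n_isotopes) matrix plus the flat cell indices."""
        isotopes = isotopes or self.isotopes
        keep = ~self.mask.ravel()
        cols = [self.predictions[i].values.ravel()[keep] for i in isotopes]
        return np.column_stack(cols), np.flatnonzero(keep)


def align_rasters(isoscapes: list[Isoscape]) -> RasterStack:
    """Crop to the common extent and bilinearly resample every surface to
    the coarsest grid; cells missing any isotope are masked in all layers."""
    if not isoscapes:
        raise ValueError("no isoscapes to align")
    lon_min = max(s.grid.lon_min for s in isoscapes)
    lat_min = max(s.grid.lat_min for s in isoscapes)
    lon_max = min(s.grid.lon_max for s in isoscapes)
    lat_max = min(s.grid.lat_max for s in isoscapes)
    if lon_max <= lon_min or lat_max <= lat_min:
        raise ValueError("isoscape extents do not overlap")
    cell = max(s.grid.cell for s in isoscapes)
    target = Grid.from_bbox((lon_min, lat_min, lon_max, lat_max), cell)
    lon, lat = target.meshgrid()
    preds, errs = {}, {}
    for s in isoscapes:
        pv = s.prediction.interp(lon.ravel(), lat.ravel()).reshape(lon.shape)
        ev = s.prediction_se.interp(lon.ravel(), lat.ravel()).reshape(lon.shape)
        preds[s.isotope] = Raster(target, pv)
        errs[s.isotope] = Raster(target, np.clip(ev, 0.0, None))
    combined = np.zeros(lon.shape, dtype=bool)
    for r in preds.values():
        combined |= r.mask
    for key in preds:
        preds[key].values[combined] = np.nan
        errs[key].values[combined] = np.nan
    return RasterStack(target, preds, errs)
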