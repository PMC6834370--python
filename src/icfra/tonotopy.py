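"""Tonotopic-gradient fitting over the dorsal IC surface.

Each neuron's position (x medial->lateral, y posterior->anterior, in µm
from the SC/IC contact point at the midline) is projected onto an axis at
angle theta from the medial-lateral axis, r = x cos(theta) + y sin(theta),
and log10 of the characteristic frequency (in Hz) is modelled as a
polynomial in r.  The fit minimizes

    sum_cells ( log10(CF_Hz) - sum_i a_i r^i )^2

jointly over theta and a0..a4.  For fixed theta the inner problem is
linear, so theta is profiled on a fine grid with an exact least-squares
solve per angle, then polished locally - deterministic, with no dependence
on optimizer initialization.  theta is canonicalized to [0, pi): the axis
at theta + pi is the same line with r negated (odd coefficients flip sign).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import minimize_scalar

from .core_io import get_logger

__all__ = [
    "TonotopyFit",
    "project",
    "fit",
    "min_cf_position",
    "cross_validate",
    "binned_summaries",
    "depth_cf_correlation",
    "soma_diameter",
    "summarize_by_genotype",
]

logger = get_logger(__name__)


@dataclass
class TonotopyFit:
    theta_rad: float
    coeffs: np.ndarray                   # a0..a_order, decades * um^-i
    variance_explained: float
    r_um: np.ndarray = field(repr=False)
    order: int = 4
    min_position_um: float = np.nan
    cv_summary: dict | None = None

    @property
    def theta_deg(self) -> float:
        return float(np.degrees(self.theta_rad))

    def predict_log10_cf_hz(self, r_um) -> np.ndarray:
        return np.polynomial.polynomial.polyval(np.asarray(r_um, float), self.coeffs)


def project(x_um, y_um, theta_rad: float) -> np.ndarray:
    """Projected distance r = x cos(theta) + y sin(theta) (µm)."""
    return np.asarray(x_um, float) * np.cos(theta_rad) + np.asarray(
        y_um, float
    ) * np.sin(theta_rad)


_R_SCALE_UM = 1000.0  # solve in units of mm to keep the Vandermonde well conditioned


def _solve_for_theta(x, y, logcf, theta, order):
    r = project(x, y, theta)
    V = np.vander(r / _R_SCALE_UM, order + 1, increasing=True)
    b, *_ = np.linalg.lstsq(V, logcf, rcond=None)
    rss = float(np.sum((V @ b - logcf) ** 2))
    coeffs = b / _R_SCALE_UM ** np.arange(order + 1)
    return coeffs, rss, r


def fit(
    x_um,
    y_um,
    cf_khz,
    order: int = 4,
    theta_step_deg: float = 0.5,
    compute_min: bool = True,
) -> TonotopyFit:
    """Joint angle + polynomial fit of log10(CF in Hz) versus projection.

    Requires at least 25 cells with positive CF.  Degenerate geometry (all
    cells collinear) is fitted anyway with a warning.
    """
    x = np.asarray(x_um, float)
    y = np.asarray(y_um, float)
    cf = np.asarray(cf_khz, float)
    keep = np.isfinite(x) & np.isfinite(y) & np.isfinite(cf) & (cf > 0)
    x, y, cf = x[keep], y[keep], cf[keep]
    if len(x) < 25:
        raise ValueError("need >= 25 cells with a CF for the tonotopy fit")
    logcf = np.log10(cf * 1000.0)

    spread = min(np.std(x), np.std(y))
    if spread == 0:
        logger.warning("degenerate geometry: cells collinear along an axis")

    thetas = np.radians(np.arange(0.0, 180.0, theta_step_deg))
    rss_prof = np.array(
        [_solve_for_theta(x, y, logcf, th, order)[1] for th in thetas]
    )
    i_best = int(np.argmin(rss_prof))
    th0 = thetas[i_best]
    half = np.radians(theta_step_deg)
    res = minimize_scalar(
        lambda th: _solve_for_theta(x, y, logcf, th, order)[1],
        bounds=(th0 - half, th0 + half),
        method="bounded",
        options={"xatol": 1e-6},
    )
    theta = float(res.x)
    # canonicalize to [0, pi); theta + pi is the same axis with r -> -r
    theta_c = theta % np.pi
    coeffs, rss, r = _solve_for_theta(x, y, logcf, theta_c, order)
    tss = float(np.sum((logcf - logcf.mean()) ** 2))
    ve = 1.0 - rss / tss if tss > 0 else np.nan

    out = TonotopyFit(
        theta_rad=theta_c,
        coeffs=np.asarray(coeffs),
        variance_explained=ve,
        r_um=r,
        order=order,
    )
    if compute_min and order >= 2:
        try:
            out.min_position_um = min_cf_position(
                out.coeffs, (float(r.min()), float(r.max()))
            )
        except ValueError:
            pass
    return out


def min_cf_position(coeffs, range_um: tuple[float, float]) -> float:
    """Interior local minimum of the fitted polynomial on a range (µm).

    The polynomial is scanned densely, the best interior local minimum is
    polished with a bounded scalar minimizer, and a positive second
    derivative is verified.  A monotone polynomial raises, naming the
    direction.
    """
    coeffs = np.asarray(coeffs, float)
    if len(coeffs) < 3:
        raise ValueError("polynomial order must be >= 2 for an interior minimum")
    lo, hi = range_um
    poly = np.polynomial.Polynomial(coeffs)
    grid = np.linspace(lo, hi, 4001)
    vals = poly(grid)
    interior = np.flatnonzero(
        (vals[1:-1] <= vals[:-2]) & (vals[1:-1] <= vals[2:])
    ) + 1
    if len(interior) == 0:
        direction = "increasing" if vals[-1] > vals[0] else "decreasing"
        raise ValueError(
            f"no interior minimum on [{lo}, {hi}] µm; polynomial is {direction}"
        )
    i = interior[np.argmin(vals[interior])]
    step = grid[1] - grid[0]
    res = minimize_scalar(
        poly,
        bounds=(max(grid[i] - step, lo), min(grid[i] + step, hi)),
        method="bounded",
        options={"xatol": 1e-8},
    )
    r_min = float(res.x)
    if poly.deriv(2)(r_min) <= 0:
        raise ValueError("located extremum is not a minimum")
    return r_min


def cross_validate(
    x_um, y_um, cf_khz, order: int = 4, train_fraction: float = 0.7, seed: int = 0
) -> dict:
    """Random 70/30 split; fit on the training set, report variance
    explained on both sets (test uses the training fit's theta and
    coefficients)."""
    x = np.asarray(x_um, float)
    y = np.asarray(y_um, float)
    cf = np.asarray(cf_khz, float)
    n = len(x)
    if n < 50:
        raise ValueError("need >= 50 cells for cross-validation")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    n_train = int(round(train_fraction * n))
    tr, te = perm[:n_train], perm[n_train:]
    f = fit(x[tr], y[tr], cf[tr], order=order, compute_min=False)

    def ve(idx):
        logcf = np.log10(cf[idx] * 1000.0)
        pred = f.predict_log10_cf_hz(project(x[idx], y[idx], f.theta_rad))
        tss = float(np.sum((logcf - logcf.mean()) ** 2))
        return 1.0 - float(np.sum((pred - logcf) ** 2)) / tss if tss > 0 else np.nan

    return {
        "train_variance_explained": ve(tr),
        "test_variance_explained": ve(te),
        "n_train": len(tr),
        "n_test": len(te),
        "theta_rad": f.theta_rad,
    }


# --------------------------------------------------------------------------
# Spatial summaries
# --------------------------------------------------------------------------

def _bin_key(values: np.ndarray, bin_um: float) -> np.ndarray:
    """Half-open bins [k*bin, (k+1)*bin); an edge value joins the upper bin."""
    return np.floor(np.asarray(values, float) / bin_um).astype(int)


def binned_summaries(
    table: pd.DataFrame,
    theta_rad: float,
    cf_bin_um: float = 75.0,
    class_axis_bin_um: float = 50.0,
    class_ortho_bin_um: float = 100.0,
) -> dict[str, pd.DataFrame]:
    """Geometric-mean CF along the tonotopic axis (75 µm bins) and FRA-class
    proportions along the axis (50 µm) and orthogonal to it (100 µm).

    ``table`` needs columns x_um, y_um and cf_khz and/or fra_type.  Empty
    bins are simply absent from the output.
    """
    df = table.copy()
    df["r_um"] = project(df["x_um"], df["y_um"], theta_rad)
    df["r_ortho_um"] = project(df["x_um"], df["y_um"], theta_rad + np.pi / 2.0)
    out: dict[str, pd.DataFrame] = {}

    if "cf_khz" in df:
        sub = df[df["cf_khz"] > 0].copy()
        sub["bin"] = _bin_key(sub["r_um"], cf_bin_um)
        g = sub.groupby("bin")["cf_khz"]
        out["cf"] = pd.DataFrame(
            {
                "r_lo_um": g.mean().index * cf_bin_um,
                "r_center_um": g.mean().index * cf_bin_um + cf_bin_um / 2.0,
                "n": g.size(),
                "cf_geomean_khz": np.exp(g.apply(lambda v: np.mean(np.log(v)))),
            }
        ).reset_index(drop=True)

    if "fra_type" in df:
        for key, col, width in (
            ("class_axis", "r_um", class_axis_bin_um),
            ("class_ortho", "r_ortho_um", class_ortho_bin_um),
        ):
            sub = df.copy()
            sub["bin"] = _bin_key(sub[col], width)
            counts = sub.groupby(["bin", "fra_type"]).size().unstack(fill_value=0)
            props = counts.div(counts.sum(axis=1), axis=0)
            props.insert(0, "n", counts.sum(axis=1))
            props.insert(0, "r_center_um", props.index * width + width / 2.0)
            out[key] = props.reset_index(drop=True)
    return out


def depth_cf_correlation(
    depth_um, cf_khz, r_um=None, strip_um: tuple[float, float] | None = None
) -> tuple[float, int]:
    """Pearson correlation between imaging depth and log10(CF), optionally
    restricted to cells in a projected-distance strip (e.g. 525-725 µm)."""
    depth = np.asarray(depth_um, float)
    cf = np.asarray(cf_khz, float)
    keep = np.isfinite(depth) & np.isfinite(cf) & (cf > 0)
    if strip_um is not None:
        if r_um is None:
            raise ValueError("strip restriction needs projected distances")
        r = np.asarray(r_um, float)
        keep &= (r >= strip_um[0]) & (r <= strip_um[1])
    depth, cf = depth[keep], cf[keep]
    if len(depth) < 3:
        raise ValueError("need at least 3 cells for a correlation")
    r_val, _ = stats.pearsonr(depth, np.log10(cf))
    return float(r_val), int(len(depth))


def soma_diameter(area_um2, formula: str = "circle") -> np.ndarray:
    """Estimated soma diameter from ROI area.

    "circle" (default): d = 2 sqrt(A/pi), exact for a circular ROI.
    "4_over_pi": d = (4/pi) sqrt(A), an alternative scaling convention.
    """
    area = np.asarray(area_um2, float)
    if np.any(area <= 0):
        raise ValueError("area must be positive")
    if formula == "circle":
        return 2.0 * np.sqrt(area / np.pi)
    if formula == "4_over_pi":
        return (4.0 / np.pi) * np.sqrt(area)
    raise ValueError("formula must be 'circle' or '4_over_pi'")


def summarize_by_genotype(
    table: pd.DataFrame, value: str = "diameter_um"
) -> pd.DataFrame:
    """Mean and s.d. of a column per genotype (plus counts)."""
    g = table.groupby("genotype")[value]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return pd.DataFrame({"mean": g.mean(), "sd": g.std(ddof=1), "n": g.size()})
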