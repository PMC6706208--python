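"""Plant-community statistics: indicator values, turnover, and variation
partitioning.

The community layer links the lidar light proxies to vegetation surveys:

* Braun-Blanquet cover-abundance classes are converted to percent cover via
  interval midpoints;
* the abundance-weighted mean Landolt light value (L_light, 1-5) summarizes
  the light conditions a plot's community indicates;
* species turnover between plots is the Simpson dissimilarity
  ``beta_sim = min(b, c) / (a + min(b, c))`` on presence-absence data, the
  nestedness-insensitive turnover component of beta diversity;
* distance-based redundancy analysis (db-RDA: principal coordinates of the
  Gower-centered dissimilarity matrix, then a least-squares projection onto
  the covariates) yields the variance fraction explained by a covariate
  group, and three-group variation partitioning decomposes the adjusted R^2
  (Ezekiel) into independent and shared fractions by inclusion-exclusion.
  Negative fractions are floored at zero for display only; raw values are
  retained and always sum (with the residual) to exactly 1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "BRAUN_BLANQUET_MIDPOINTS",
    "CommunityMatrix",
    "VarpartResult",
    "braun_blanquet_to_cover",
    "weighted_indicator_mean",
    "proxy_regression",
    "simpson_dissimilarity",
    "db_rda",
    "adjusted_r2",
    "variation_partition",
]

#: Percent-cover midpoints for the Braun-Blanquet cover-abundance classes.
BRAUN_BLANQUET_MIDPOINTS = {
    "r": 0.1,
    "+": 0.5,
    "1": 2.5,
    "2": 15.0,
    "2a": 10.0,
    "2b": 20.5,
    "3": 37.5,
    "4": 62.5,
    "5": 87.5,
}


@dataclass
class CommunityMatrix:
    """Plot x species percent-cover abundances with species light values.

    ``abundance``: DataFrame (plots x species, percent cover >= 0);
    ``landolt_l``: Series indexed by species, integer 1-5 or NaN (missing).
    """

    abundance: pd.DataFrame
    landolt_l: pd.Series

    def __post_init__(self) -> None:
        if (self.abundance.to_numpy() < 0).any():
            raise ValueError("abundances must be non-negative")
        self.landolt_l = self.landolt_l.reindex(self.abundance.columns)

    @property
    def presence(self) -> pd.DataFrame:
        return self.abundance > 0

    def l_light(self) -> pd.Series:
        """Abundance-weighted mean Landolt light value per plot."""
        return pd.Series(
            {
                plot: weighted_indicator_mean(row.to_numpy(), self.landolt_l.to_numpy())
                for plot, row in self.abundance.iterrows()
            },
            name="l_light",
        )


def braun_blanquet_to_cover(class_label: str) -> float:
    """Percent cover midpoint of a Braun-Blanquet class label."""
    key = str(class_label).strip()
    try:
        return BRAUN_BLANQUET_MIDPOINTS[key]
    except KeyError:
        raise ValueError(f"unknown Braun-Blanquet class: {class_label!r}") from None


def weighted_indicator_mean(abundances, l_values) -> float:
    """Abundance-weighted mean indicator value; species without an indicator
    value are excluded from both numerator and denominator."""
    a = np.asarray(abundances, dtype=float)
    l = np.asarray(l_values, dtype=float)
    ok = (a > 0) & np.isfinite(l)
    if not ok.any():
        raise ValueError("no species with both abundance and an indicator value")
    return float((a[ok] * l[ok]).sum() / a[ok].sum())


def proxy_regression(l_light, log_proxy) -> dict:
    """OLS of community light values on a log-scale light proxy."""
    y = np.asarray(l_light, dtype=float)
    x = np.asarray(log_proxy, dtype=float)
    if len(y) < 3:
        raise ValueError("need at least 3 plots")
    if np.ptp(x) == 0:
        raise ValueError("proxy is constant across plots")
    res = stats.linregress(x, y)
    return {
        "slope": res.slope,
        "intercept": res.intercept,
        "r2": res.rvalue**2,
        "p": res.pvalue,
    }


# ---------------------------------------------------------------------------
# turnover
# ---------------------------------------------------------------------------


def simpson_dissimilarity(presence) -> pd.DataFrame:
    """Pairwise Simpson dissimilarity (turnover) on a plots x species
    presence-absence matrix.  Pairs sharing nothing and with no turnover
    (both empty, or one empty) get 0 by convention only when
    a + min(b, c) = 0."""
    P = pd.DataFrame(presence).astype(bool)
    if P.shape[0] < 2:
        raise ValueError("need at least 2 plots")
    M = P.to_numpy().astype(np.int64)
    shared = M @ M.T                      # a
    richness = M.sum(axis=1)
    b = richness[:, None] - shared        # unique to plot i
    c = richness[None, :] - shared        # unique to plot j
    mn = np.minimum(b, c)
    denom = shared + mn
    with np.errstate(invalid="ignore", divide="ignore"):
        d = np.where(denom > 0, mn / np.where(denom > 0, denom, 1), 0.0)
    np.fill_diagonal(d, 0.0)
    return pd.DataFrame(d, index=P.index, columns=P.index)


# ---------------------------------------------------------------------------
# db-RDA and variation partitioning
# ---------------------------------------------------------------------------

_EIG_TOL = 1e-9


def _principal_coordinates(D: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """PCoA of a dissimilarity matrix: Gower-center -D^2/2, keep axes with
    positive eigenvalues (negative axes dropped, no correction)."""
    n = D.shape[0]
    A = -0.5 * D**2
    J = np.eye(n) - np.ones((n, n)) / n
    G = J @ A @ J
    vals, vecs = np.linalg.eigh((G + G.T) / 2)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    pos = vals > _EIG_TOL * max(vals.max(), 1.0)
    return vecs[:, pos] * np.sqrt(vals[pos]), vals[pos]


def _design_matrix(X) -> np.ndarray:
    X = pd.DataFrame(X).apply(pd.to_numeric)
    M = X.to_numpy(dtype=float)
    M = M - M.mean(axis=0)
    # drop collinear columns (QR diagonal test, greedy re-selection)
    _, r = np.linalg.qr(M)
    keep = np.abs(np.diag(r)) > 1e-10 * max(np.abs(np.diag(r)).max(), 1.0)
    if not keep.all():
        warnings.warn("dropping collinear covariate columns", stacklevel=3)
        # greedy re-selection preserving original order
        cols: list[int] = []
        for j in range(M.shape[1]):
            trial = M[:, cols + [j]]
            if np.linalg.matrix_rank(trial, tol=1e-8) > len(cols):
                cols.append(j)
        M = M[:, cols]
    return M


def db_rda(D, X) -> dict:
    """Distance-based RDA: fraction of the (positive-eigenvalue) inertia of
    the dissimilarity matrix explained by the covariates.

    Returns dict(r2, adj_r2, n, p) with p = number of independent covariate
    columns actually used.
    """
    D = np.asarray(pd.DataFrame(D), dtype=float)
    if D.shape[0] != D.shape[1]:
        raise ValueError("dissimilarity matrix must be square")
    Y, vals = _principal_coordinates(D)
    M = _design_matrix(X)
    n, p = D.shape[0], M.shape[1]
    if n <= p + 1:
        raise ValueError("too few plots for the covariate count")
    # least-squares projection of the (already centered) coordinates onto M
    beta, *_ = np.linalg.lstsq(M, Y, rcond=None)
    fitted = M @ beta
    total = vals.sum()
    r2 = float((fitted**2).sum() / total)
    return {"r2": r2, "adj_r2": adjusted_r2(r2, n, p), "n": n, "p": p}


def adjusted_r2(r2: float, n: int, p: int) -> float:
    """Ezekiel's adjusted R^2: 1 - (1 - R^2)(n - 1)/(n - p - 1)."""
    if n <= p + 1:
        raise ValueError("adjusted R^2 requires n > p + 1")
    return float(1.0 - (1.0 - r2) * (n - 1) / (n - p - 1))


@dataclass
class VarpartResult:
    """Three-group variation partition of a dissimilarity matrix.

    ``fractions`` holds the raw inclusion-exclusion values keyed
    'a'..'g' ('a','b','c' = independent fractions of groups 1..3; 'd' =
    shared 1&2, 'e' = shared 2&3, 'f' = shared 1&3, 'g' = shared by all)
    plus 'residual'.  ``floored()`` gives the reporting view with negatives
    set to zero.  ``model_adj_r2`` holds the adjusted R^2 of the 7 models.
    """

    group_names: tuple[str, str, str]
    fractions: dict = field(default_factory=dict)
    model_adj_r2: dict = field(default_factory=dict)

    def floored(self) -> dict:
        return {
            k: (max(v, 0.0) if k != "residual" else v)
            for k, v in self.fractions.items()
        }

    def independent(self, group: str) -> float:
        return self.fractions["abc"[self.group_names.index(group)]]

    def shared(self, g1: str, g2: str) -> float:
        i, j = sorted((self.group_names.index(g1), self.group_names.index(g2)))
        return self.fractions[{(0, 1): "d", (1, 2): "e", (0, 2): "f"}[(i, j)]]

    def to_frame(self) -> pd.DataFrame:
        pretty = {
            "a": f"{self.group_names[0]} | others",
            "b": f"{self.group_names[1]} | others",
            "c": f"{self.group_names[2]} | others",
            "d": f"{self.group_names[0]} & {self.group_names[1]}",
            "e": f"{self.group_names[1]} & {self.group_names[2]}",
            "f": f"{self.group_names[0]} & {self.group_names[2]}",
            "g": "all three",
            "residual": "residual",
        }
        floored = self.floored()
        return pd.DataFrame(
            {
                "fraction": list(pretty.values()),
                "raw": [self.fractions[k] for k in pretty],
                "reported": [floored[k] for k in pretty],
            }
        )


def variation_partition(D, groups: dict) -> VarpartResult:
    """Partition the variance of a dissimilarity matrix among three covariate
    groups via db-RDA adjusted R^2 of the 7 group unions.

    ``groups`` maps three group names to covariate DataFrames sharing the
    plot order of ``D``.  Raw fractions plus the residual sum to 1 exactly.
    """
    if len(groups) != 3:
        raise ValueError("variation_partition requires exactly 3 groups")
    names = tuple(groups)
    frames = {k: pd.DataFrame(v) for k, v in groups.items()}
    for k, f in frames.items():
        if f.shape[1] == 0:
            raise ValueError(f"covariate group {k!r} is empty")

    def fit(*keys) -> float:
        X = pd.concat([frames[k] for k in keys], axis=1)
        return db_rda(D, X)["adj_r2"]

    A, B, C = names
    R = {
        A: fit(A), B: fit(B), C: fit(C),
        A + "+" + B: fit(A, B),
        A + "+" + C: fit(A, C),
        B + "+" + C: fit(B, C),
        A + "+" + B + "+" + C: fit(A, B, C),
    }
    rabc = R[A + "+" + B + "+" + C]
    a = rabc - R[B + "+" + C]
    b = rabc - R[A + "+" + C]
    c = rabc - R[A + "+" + B]
    d = rabc - R[C] - a - b
    e = rabc - R[A] - b - c
    f = rabc - R[B] - a - c
    g = rabc - (a + b + c + d + e + f)
    fractions = {
        "a": a, "b": b, "c": c, "d": d, "e": e, "f": f, "g": g,
        "residual": 1.0 - rabc,
    }
    return VarpartResult(names, fractions, R)
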