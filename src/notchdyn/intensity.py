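"""Classification of Notch-reporter intensity distributions.

Single-cell mean nuclear reporter intensities from the progenitor pool are
bimodal on a log scale: a low mode (stem-like, NRE^low) and a high mode
(enteroblast, NRE^hi).  A two-component Gaussian mixture fitted to
log10-intensities summarizes each condition; the equal-posterior decision
boundary between the two component means separates NRE^low from NRE^hi cells,
and marker-defined subsets (Delta+, PH3+) are cross-tabulated against those
labels.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.mixture import GaussianMixture

from .exceptions import BoundaryUndefinedError, DataError, FitWarning, ParameterError

__all__ = [
    "GmmFit",
    "ClassifiedPopulation",
    "fit_bimodal_gmm",
    "decision_boundary",
    "posterior_probabilities",
    "classify_cells",
    "subpopulation_proportions",
    "log_histogram",
    "ks_compare",
]

logger = logging.getLogger(__name__)

LABEL_LOW = "NRE_low"
LABEL_HI = "NRE_hi"


@dataclass
class GmmFit:
    """A fitted (or constructed) two-component univariate Gaussian mixture.

    Component 0 is always the lower-mean (NRE^low) component.  All parameters
    are on the log10-intensity scale unless ``scale == 'linear'``.
    """

    weights: np.ndarray
    means: np.ndarray
    sds: np.ndarray
    boundary: float
    loglik: float = np.nan
    seed: int | None = None
    n_restarts: int | None = None
    scale: str = "log10"
    degenerate: bool = False

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        self.means = np.asarray(self.means, dtype=float)
        self.sds = np.asarray(self.sds, dtype=float)
        if self.weights.shape != (2,) or self.means.shape != (2,) or self.sds.shape != (2,):
            raise ParameterError("GmmFit requires exactly two components")
        if not np.isclose(self.weights.sum(), 1.0) or np.any(self.weights <= 0):
            raise ParameterError(f"weights must be positive and sum to 1, got {self.weights}")
        if not self.means[0] < self.means[1]:
            raise ParameterError("components must be ordered by mean (means[0] < means[1])")
        if np.any(self.sds <= 0):
            raise ParameterError(f"sds must be > 0, got {self.sds}")


@dataclass
class ClassifiedPopulation:
    """Per-cell labels and posteriors plus the fit that produced them."""

    frame: pd.DataFrame
    fit: GmmFit
    n_rejected: int = 0


def _to_fit_scale(intensities: np.ndarray, scale: str) -> np.ndarray:
    if scale == "log10":
        return np.log10(intensities)
    if scale == "linear":
        return intensities.astype(float)
    raise ParameterError(f"scale must be 'log10' or 'linear', got {scale!r}")


def fit_bimodal_gmm(
    intensities: np.ndarray,
    seed: int = 0,
    n_restarts: int = 20,
    min_samples: int = 20,
    var_floor: float = 1e-4,
    scale: str = "log10",
) -> GmmFit:
    """EM fit of a two-component Gaussian mixture to reporter intensities.

    Intensities are log10-transformed before fitting (the bimodality and
    near-Gaussian component shapes appear on the log scale); pass
    ``scale='linear'`` to fit raw values instead.  The best of ``n_restarts``
    k-means-initialized EM runs (by log-likelihood) is kept, components are
    ordered by mean, and the equal-posterior decision boundary is located
    between the means.  Deterministic given ``seed``.
    """
    intensities = np.asarray(intensities, dtype=float).ravel()
    if intensities.size < min_samples:
        raise DataError(f"need at least {min_samples} intensities, got {intensities.size}")
    if np.any(intensities <= 0) and scale == "log10":
        raise DataError("intensities must be > 0 for log10 fitting")
    x = _to_fit_scale(intensities, scale)[:, None]
    gm = GaussianMixture(
        n_components=2,
        covariance_type="full",
        n_init=n_restarts,
        init_params="kmeans",
        reg_covar=var_floor,
        random_state=seed,
        max_iter=500,
    ).fit(x)
    order = np.argsort(gm.means_.ravel())
    weights = gm.weights_.ravel()[order]
    means = gm.means_.ravel()[order]
    sds = np.sqrt(gm.covariances_.ravel()[order])
    loglik = float(gm.score(x) * x.shape[0])
    degenerate = bool(
        np.any(gm.covariances_.ravel() <= var_floor * 1.001)
        or np.isclose(means[0], means[1], atol=1e-6)
        or np.any(weights < 1e-3)
    )
    fit = GmmFit(
        weights=weights, means=means, sds=sds, boundary=np.nan, loglik=loglik,
        seed=seed, n_restarts=n_restarts, scale=scale, degenerate=degenerate,
    )
    if degenerate:
        warnings.warn(
            f"degenerate mixture fit (weights={weights}, means={means}, sds={sds})",
            FitWarning,
            stacklevel=2,
        )
        return fit
    fit.boundary = decision_boundary(fit)
    return fit


def _log_posterior_diff(fit: GmmFit, x: float) -> float:
    lo = np.log(fit.weights[0]) + stats.norm.logpdf(x, fit.means[0], fit.sds[0])
    hi = np.log(fit.weights[1]) + stats.norm.logpdf(x, fit.means[1], fit.sds[1])
    return lo - hi


def decision_boundary(fit: GmmFit, tol: float = 1e-8) -> float:
    """Equal-posterior threshold: the root of w0*phi0(x) = w1*phi1(x) in (mu0, mu1).

    Bisection on the log-posterior difference; raises
    :class:`BoundaryUndefinedError` when the components overlap so severely
    that no crossing exists between the means.
    """
    lo, hi = float(fit.means[0]), float(fit.means[1])
    f_lo, f_hi = _log_posterior_diff(fit, lo), _log_posterior_diff(fit, hi)
    if not (f_lo > 0 > f_hi):
        raise BoundaryUndefinedError(
            f"no equal-posterior crossing in ({lo}, {hi}): f(mu0)={f_lo:.3g}, f(mu1)={f_hi:.3g}"
        )
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if _log_posterior_diff(fit, mid) > 0:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def posterior_probabilities(fit: GmmFit, values: np.ndarray) -> np.ndarray:
    """Posterior P(component | x) for values on the fit scale; shape (n, 2)."""
    values = np.asarray(values, dtype=float)
    logp = np.stack(
        [
            np.log(fit.weights[k]) + stats.norm.logpdf(values, fit.means[k], fit.sds[k])
            for k in (0, 1)
        ],
        axis=-1,
    )
    logp -= logp.max(axis=-1, keepdims=True)
    p = np.exp(logp)
    return p / p.sum(axis=-1, keepdims=True)


def classify_cells(records: pd.DataFrame, fit: GmmFit) -> ClassifiedPopulation:
    """Label each cell NRE_low / NRE_hi against a mixture fit.

    A cell is NRE_hi iff its intensity (on the fit scale) is strictly above
    the decision boundary; cells exactly at the boundary are NRE_low.  Any
    fit may be supplied, so marker subsets or other genotypes can be scored
    against a reference condition's mixture.  Rows with non-positive
    intensity are rejected (logged), not silently dropped into a class.
    """
    if len(records) == 0:
        raise DataError("records must be non-empty")
    if "intensity" not in records.columns:
        raise DataError("records must have an 'intensity' column")
    if not np.isfinite(fit.boundary):
        raise BoundaryUndefinedError("fit has no defined decision boundary")
    valid = records["intensity"] > 0
    n_rejected = int((~valid).sum())
    if n_rejected:
        logger.warning(
            "rejected %d record(s) with non-positive intensity (rows %s)",
            n_rejected,
            list(records.index[~valid][:10]),
        )
    out = records.loc[valid].copy()
    x = _to_fit_scale(out["intensity"].to_numpy(dtype=float), fit.scale)
    post = posterior_probabilities(fit, x)
    out["posterior_low"] = post[:, 0]
    out["posterior_hi"] = post[:, 1]
    out["label"] = np.where(x > fit.boundary, LABEL_HI, LABEL_LOW)
    return ClassifiedPopulation(frame=out, fit=fit, n_rejected=n_rejected)


def subpopulation_proportions(classified: ClassifiedPopulation, marker: str) -> pd.Series:
    """Cross-tabulate a boolean marker column against NRE_low/NRE_hi labels.

    Returns exact integer counts plus the derived proportions: what fraction
    of marker+ cells are NRE_hi (and NRE_low), and what fraction of NRE_hi
    cells are marker+.  Proportions with a zero denominator are NaN
    ("undefined"), never 0.
    """
    df = classified.frame
    if marker not in df.columns:
        raise DataError(f"marker column {marker!r} not present")
    flag = df[marker].astype(bool)
    is_hi = df["label"] == LABEL_HI
    n_marker = int(flag.sum())
    n_hi = int(is_hi.sum())
    n_marker_hi = int((flag & is_hi).sum())
    n_marker_low = n_marker - n_marker_hi

    def frac(num: int, den: int) -> float:
        return num / den if den > 0 else np.nan

    return pd.Series(
        {
            "marker": marker,
            "n_total": len(df),
            "n_marker": n_marker,
            "n_hi": n_hi,
            "n_marker_hi": n_marker_hi,
            "n_marker_low": n_marker_low,
            "frac_marker_hi": frac(n_marker_hi, n_marker),
            "frac_marker_low": frac(n_marker_low, n_marker),
            "frac_hi_marker": frac(n_marker_hi, n_hi),
        }
    )


def log_histogram(
    intensities: np.ndarray, bin_exponent_width: float = 0.04
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Histogram with bins uniform in log10 space (width 0.04 or 0.05 decades).

    Bin edges sit at integer multiples of the exponent width so histograms
    from different samples share a common grid.  Returns
    ``(log10_edges, counts, proportions)``.
    """
    if bin_exponent_width <= 0:
        raise ParameterError(f"bin width must be > 0, got {bin_exponent_width}")
    intensities = np.asarray(intensities, dtype=float).ravel()
    if intensities.size == 0 or np.any(intensities <= 0):
        raise DataError("intensities must be non-empty and > 0")
    logx = np.log10(intensities)
    w = bin_exponent_width
    first = np.floor(logx.min() / w)
    last = np.ceil(logx.max() / w)
    if last == first:
        last = first + 1
    edges = np.arange(first, last + 1) * w
    counts, _ = np.histogram(logx, bins=edges)
    return edges, counts, counts / counts.sum()


def ks_compare(sample_a: np.ndarray, sample_b: np.ndarray) -> tuple[float, float]:
    """Two-sample Kolmogorov-Smirnov test (D statistic and asymptotic p-value)."""
    a = np.asarray(sample_a, dtype=float).ravel()
    b = np.asarray(sample_b, dtype=float).ravel()
    if a.size == 0 or b.size == 0:
        raise DataError("both samples must be non-empty")
    res = stats.ks_2samp(a, b, method="asymp")
    return float(res.statistic), float(res.pvalue)
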