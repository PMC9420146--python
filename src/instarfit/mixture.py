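"""Univariate Gaussian mixture fitting and instar boundary derivation.

Each component of the fitted mixture is interpreted as one larval instar:
head-capsule width is approximately normal within an instar and jumps
between instars, so the observed widths form a multi-peak frequency
distribution. The number of components is chosen by BIC, and the dividing
point between two adjacent instars is the head-capsule width at which the
two weighted normal curves intersect.

Fitting is by maximum likelihood (EM) on the raw measurements, which is
independent of any histogram binning. A histogram mode
(:func:`fit_mixture_histogram`) fits a sum of scaled Gaussian curves to
bin counts by nonlinear least squares for users who want the
curve-to-histogram procedure instead; amplitudes are normalized to mixing
weights afterwards.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy import optimize
from scipy.special import logsumexp
from scipy.stats import norm

from .data_io import HCWDataset, HCWHistogram

#: Component standard deviations below this floor (μm) are treated as a
#: degenerate collapse onto a few points — below instrument precision.
SD_FLOOR = 1.0

_MAX_RESTARTS = 10


class DegenerateFitError(RuntimeError):
    """EM collapsed to a degenerate component on every allowed restart."""


class BoundaryError(RuntimeError):
    """No weighted-density crossing exists between two adjacent means."""


@dataclass(frozen=True)
class GaussianComponent:
    """One weighted normal component: ``weight × N(mean, sd²)``."""

    weight: float
    mean: float
    sd: float

    def __post_init__(self) -> None:
        if not 0 < self.weight <= 1:
            raise ValueError(f"weight must be in (0, 1], got {self.weight}")
        if self.sd <= 0:
            raise ValueError(f"sd must be > 0, got {self.sd}")


def component_density(c: GaussianComponent, x: float | np.ndarray) -> float | np.ndarray:
    """Weighted normal density ``w·N(x | μ, σ)``; integrates to ``w``."""
    return c.weight * norm.pdf(x, loc=c.mean, scale=c.sd)


@dataclass(frozen=True)
class MixtureModel:
    """A fitted k-component normal mixture, components sorted by mean."""

    components: tuple[GaussianComponent, ...]
    n: int
    loglik: float
    converged: bool
    loglik_trace: tuple[float, ...] = ()
    selection_table: tuple[dict, ...] | None = None

    def __post_init__(self) -> None:
        comps = tuple(self.components)
        weights = np.array([c.weight for c in comps])
        means = np.array([c.mean for c in comps])
        if abs(weights.sum() - 1.0) > 1e-8:
            raise ValueError(f"weights sum to {weights.sum()}, not 1")
        if np.any(np.diff(means) <= 0):
            raise ValueError("component means must be strictly increasing")
        object.__setattr__(self, "components", comps)
        object.__setattr__(self, "loglik_trace", tuple(self.loglik_trace))

    @property
    def k(self) -> int:
        return len(self.components)

    @property
    def weights(self) -> np.ndarray:
        return np.array([c.weight for c in self.components])

    @property
    def means(self) -> np.ndarray:
        return np.array([c.mean for c in self.components])

    @property
    def sds(self) -> np.ndarray:
        return np.array([c.sd for c in self.components])

    @property
    def bic(self) -> float:
        """Bayesian information criterion, ``-2·loglik + (3k−1)·ln n``."""
        n_params = 3 * self.k - 1
        return -2.0 * self.loglik + n_params * np.log(self.n)

    def pdf(self, x: float | np.ndarray) -> float | np.ndarray:
        """Mixture density at ``x``."""
        x = np.asarray(x, dtype=float)
        return sum(component_density(c, x) for c in self.components)

    def to_json(self, path: str | Path | None = None, seed: int | None = None) -> str:
        doc = {
            "k": self.k,
            "weights": self.weights.tolist(),
            "means": self.means.tolist(),
            "sds": self.sds.tolist(),
            "loglik": self.loglik,
            "n": self.n,
            "converged": self.converged,
            "seed": seed,
        }
        text = json.dumps(doc, indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(text + "\n", encoding="utf-8")
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "MixtureModel":
        if isinstance(source, Path) or not str(source).lstrip().startswith("{"):
            text = Path(source).read_text(encoding="utf-8")
        else:
            text = str(source)
        doc = json.loads(text)
        comps = tuple(
            GaussianComponent(w, m, s)
            for w, m, s in zip(doc["weights"], doc["means"], doc["sds"])
        )
        return cls(
            components=comps,
            n=int(doc["n"]),
            loglik=float(doc["loglik"]),
            converged=bool(doc["converged"]),
        )


def _as_values(data: HCWDataset | np.ndarray) -> np.ndarray:
    if isinstance(data, HCWDataset):
        return data.values
    return np.asarray(data, dtype=float)


def _em_once(
    x: np.ndarray,
    means: np.ndarray,
    sds: np.ndarray,
    weights: np.ndarray,
    max_iter: int,
    tol: float,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, list[float], bool]:
    """One EM run from the given start; returns params, trace, converged.

    Raises DegenerateFitError if any SD falls below the floor.
    """
    n = x.size
    trace: list[float] = []
    converged = False
    prev = -np.inf
    for _ in range(max_iter):
        # E-step in log space for stability
        log_dens = norm.logpdf(x[:, None], loc=means[None, :], scale=sds[None, :])
        log_joint = np.log(weights)[None, :] + log_dens
        log_norm = logsumexp(log_joint, axis=1)
        loglik = float(log_norm.sum())
        trace.append(loglik)
        resp = np.exp(log_joint - log_norm[:, None])
        # M-step
        nk = resp.sum(axis=0)
        if np.any(nk < 1e-10):
            raise DegenerateFitError("a component lost all responsibility")
        weights = nk / n
        means = (resp * x[:, None]).sum(axis=0) / nk
        var = (resp * (x[:, None] - means[None, :]) ** 2).sum(axis=0) / nk
        # constrained M-step: sd bounded below by the 1 μm floor, which
        # prevents a component from spiking onto a handful of points;
        # clamping to the boundary is the constrained maximizer, so EM
        # monotonicity is preserved
        sds = np.maximum(np.sqrt(var), SD_FLOOR)
        if abs(loglik - prev) < tol:
            converged = True
            break
        prev = loglik
    return means, sds, weights, trace, converged


def fit_mixture(
    data: HCWDataset | np.ndarray,
    k: int,
    seed: int = 0,
    max_iter: int = 500,
    tol: float = 1e-8,
) -> MixtureModel:
    """Fit a k-component normal mixture by EM on the raw measurements.

    Initialization places component means at the ``(i+0.5)/k`` sample
    quantiles with the pooled sample SD and equal weights. Component SDs
    are bounded below by a 1 μm floor (below instrument precision), which
    prevents likelihood blow-up from a component collapsing onto a few
    points. A degenerate run — a component losing all responsibility
    mass, or component means tying — restarts the fit (up to 10 times)
    from seeded, jittered means; exhausting restarts raises
    :class:`DegenerateFitError`. The log-likelihood is non-decreasing
    across EM iterations and is recorded in ``loglik_trace``.

    For ``k=1`` this converges immediately to the sample mean and the
    maximum-likelihood (ddof 0) standard deviation.
    """
    x = _as_values(data)
    n = x.size
    if k < 1:
        raise ValueError("k must be >= 1")
    if n < 3 * k:
        raise ValueError(f"need n >= 3k observations, got n={n}, k={k}")

    rng = np.random.default_rng(seed)
    q = (np.arange(k) + 0.5) / k
    base_means = np.quantile(x, q)
    pooled_sd = max(float(np.std(x)), SD_FLOOR)
    span = float(x.max() - x.min()) or 1.0

    last_err: Exception | None = None
    for attempt in range(_MAX_RESTARTS + 1):
        if attempt == 0:
            means0 = base_means.copy()
        else:
            means0 = np.sort(base_means + rng.normal(0.0, 0.05 * span, size=k))
        sds0 = np.full(k, pooled_sd)
        weights0 = np.full(k, 1.0 / k)
        try:
            means, sds, weights, trace, converged = _em_once(
                x, means0, sds0, weights0, max_iter, tol
            )
        except DegenerateFitError as err:
            last_err = err
            continue
        order = np.argsort(means)
        means, sds, weights = means[order], sds[order], weights[order]
        if k > 1 and np.any(np.diff(means) <= 0):
            last_err = DegenerateFitError("tied component means")
            continue
        weights = weights / weights.sum()  # renormalize rounding drift
        comps = tuple(
            GaussianComponent(float(w), float(m), float(s))
            for w, m, s in zip(weights, means, sds)
        )
        return MixtureModel(
            components=comps,
            n=n,
            loglik=trace[-1],
            converged=converged,
            loglik_trace=tuple(trace),
        )
    raise DegenerateFitError(
        f"EM failed after {_MAX_RESTARTS} restarts (k={k}): {last_err}"
    )


def select_components(
    data: HCWDataset | np.ndarray,
    k_min: int = 1,
    k_max: int = 5,
    seed: int = 0,
    max_iter: int = 500,
    tol: float = 1e-8,
) -> MixtureModel:
    """Fit mixtures for each k in ``[k_min, k_max]`` and return the BIC winner.

    Ties break toward smaller k. The returned model carries a
    ``selection_table`` attribute with per-k log-likelihood and BIC so the
    user can inspect the whole profile (and replicate a visual peak count).
    Individual k failures are recorded; if every k fails, the last error
    propagates.
    """
    if not 1 <= k_min <= k_max:
        raise ValueError("need 1 <= k_min <= k_max")
    x = _as_values(data)
    if x.size < 3 * k_max:
        raise ValueError(f"need n >= 3·k_max observations, got n={x.size}")

    table: list[dict] = []
    best: MixtureModel | None = None
    last_err: Exception | None = None
    for k in range(k_min, k_max + 1):
        try:
            model = fit_mixture(x, k, seed=seed, max_iter=max_iter, tol=tol)
        except (DegenerateFitError, ValueError) as err:
            table.append({"k": k, "loglik": None, "bic": None, "error": str(err)})
            last_err = err
            continue
        table.append(
            {"k": k, "loglik": model.loglik, "bic": model.bic,
             "converged": model.converged}
        )
        if best is None or model.bic < best.bic:  # strict: ties keep smaller k
            best = model
    if best is None:
        raise DegenerateFitError(f"every k in [{k_min}, {k_max}] failed: {last_err}")
    return replace(best, selection_table=tuple(table))


def fit_mixture_histogram(
    hist: HCWHistogram,
    k: int,
    seed: int = 0,
    max_iter: int = 10000,
) -> MixtureModel:
    """Fit k scaled Gaussian curves to histogram bin counts by least squares.

    This mirrors the curve-to-histogram procedure of graphing software:
    each peak is parameterized by amplitude, centre, and width, and the sum
    of curves is fitted to the bin counts at bin centres. Amplitudes are
    converted to mixing weights via ``w ∝ amplitude·sd`` (the area under a
    scaled Gaussian) and normalized to sum to 1.
    """
    centers = hist.centers
    counts = hist.counts.astype(float)
    n = int(hist.counts.sum())
    if n < 3 * k:
        raise ValueError(f"need n >= 3k observations in histogram, got n={n}")

    def curve(x: np.ndarray, *params: float) -> np.ndarray:
        total = np.zeros_like(x)
        for j in range(k):
            amp, mu, sd = params[3 * j : 3 * j + 3]
            total = total + amp * np.exp(-0.5 * ((x - mu) / sd) ** 2)
        return total

    q = (np.arange(k) + 0.5) / k
    # crude quantile init from the binned mass
    cum = np.cumsum(counts) / counts.sum()
    mu0 = np.interp(q, cum, centers)
    sd0 = max(float(np.sqrt(np.cov(centers, aweights=np.maximum(counts, 1e-9)))), SD_FLOOR)
    amp0 = counts.max() / k
    p0 = np.ravel([[amp0, m, sd0 / k] for m in mu0])
    lower = np.ravel([[0.0, centers.min(), SD_FLOOR] for _ in range(k)])
    upper = np.ravel([[np.inf, centers.max(), np.inf] for _ in range(k)])
    try:
        with warnings.catch_warnings():
            # overparameterized k can leave the covariance singular; the
            # point estimate is still usable for BIC comparison
            warnings.simplefilter("ignore", optimize.OptimizeWarning)
            popt, _ = optimize.curve_fit(
                curve, centers, counts, p0=p0, bounds=(lower, upper), maxfev=max_iter
            )
        converged = True
    except RuntimeError:
        popt, converged = p0, False

    amps = popt[0::3]
    means = popt[1::3]
    sds = np.maximum(popt[2::3], SD_FLOOR)
    areas = amps * sds  # ∝ component area; √(2π) cancels in normalization
    weights = areas / areas.sum()
    order = np.argsort(means)
    means, sds, weights = means[order], sds[order], weights[order]
    if np.any(np.diff(means) <= 0):
        raise DegenerateFitError("histogram fit produced tied component means")
    comps = tuple(
        GaussianComponent(float(w), float(m), float(s))
        for w, m, s in zip(weights, means, sds)
    )
    # log-likelihood of the binned data under the normalized mixture, at
    # bin centres, so BIC remains comparable across k in histogram mode
    model = MixtureModel(components=comps, n=n, loglik=0.0, converged=converged)
    log_dens = np.log(np.maximum(model.pdf(centers), 1e-300))
    return replace(model, loglik=float((counts * log_dens).sum()))


def _crossing(
    c1: GaussianComponent, c2: GaussianComponent, weighted: bool = True
) -> float:
    """Solve ``w1·N(x|μ1,σ1) = w2·N(x|μ2,σ2)`` for x strictly in (μ1, μ2).

    The log-density equality is quadratic in x for unequal SDs and linear
    for equal SDs. Of the (up to two) roots, the one strictly between the
    means is kept; if both lie inside (guarded against, though impossible
    for crossing curves with this parameterization), the one nearer the
    midpoint wins.
    """
    mu1, mu2 = c1.mean, c2.mean
    s1, s2 = c1.sd**2, c2.sd**2
    w1 = c1.weight if weighted else 1.0
    w2 = c2.weight if weighted else 1.0
    rhs = 2.0 * np.log((w2 * c1.sd) / (w1 * c2.sd))
    # (x-μ2)²/s2 - (x-μ1)²/s1 = rhs
    a = 1.0 / s2 - 1.0 / s1
    b = -2.0 * (mu2 / s2 - mu1 / s1)
    c = mu2**2 / s2 - mu1**2 / s1 - rhs
    if abs(a) < 1e-300 or c1.sd == c2.sd:
        roots = np.array([-c / b])
    else:
        disc = b * b - 4.0 * a * c
        if disc < 0:
            roots = np.array([])
        else:
            sq = np.sqrt(disc)
            roots = np.array([(-b - sq) / (2 * a), (-b + sq) / (2 * a)])
    inside = roots[(roots > mu1) & (roots < mu2)]
    if inside.size == 0:
        raise BoundaryError(
            f"no density crossing between means {mu1:.2f} and {mu2:.2f} μm "
            "(extreme weight imbalance?); consider the unweighted boundary mode"
        )
    if inside.size > 1:
        mid = 0.5 * (mu1 + mu2)
        inside = inside[[np.argmin(np.abs(inside - mid))]]
    return float(inside[0])


def intersection_boundaries(model: MixtureModel, weighted: bool = True) -> np.ndarray:
    """Instar boundaries: crossings of each adjacent pair of weighted curves.

    Returns ``k−1`` strictly increasing values, each strictly between its
    flanking pair of component means. ``weighted=False`` intersects the
    unit-weight curves instead.
    """
    if model.k < 2:
        raise ValueError("need at least 2 components for boundaries")
    bounds = [
        _crossing(model.components[i], model.components[i + 1], weighted=weighted)
        for i in range(model.k - 1)
    ]
    out = np.array(bounds)
    if np.any(np.diff(out) <= 0):
        raise BoundaryError("boundaries are not strictly increasing")
    return out


@dataclass(frozen=True)
class InstarPartition:
    """Instar boundaries (μm) and per-individual instar assignments (1..k).

    A value exactly equal to a boundary joins the lower instar: intervals
    are open on the left and closed on the right.
    """

    boundaries: np.ndarray
    assignments: np.ndarray

    def __post_init__(self) -> None:
        boundaries = np.asarray(self.boundaries, dtype=float)
        assignments = np.asarray(self.assignments, dtype=int)
        if boundaries.size and np.any(np.diff(boundaries) <= 0):
            raise ValueError("boundaries must be strictly increasing")
        if assignments.size and (
            assignments.min() < 1 or assignments.max() > boundaries.size + 1
        ):
            raise ValueError("assignments out of 1..k range")
        object.__setattr__(self, "boundaries", boundaries)
        object.__setattr__(self, "assignments", assignments)

    @property
    def k(self) -> int:
        return int(self.boundaries.size + 1)

    def counts(self) -> np.ndarray:
        """Per-instar membership counts (length k; sums to n)."""
        return np.bincount(self.assignments, minlength=self.k + 1)[1:]


def assign_instars(
    data: HCWDataset | np.ndarray, boundaries: Sequence[float] | np.ndarray
) -> InstarPartition:
    """Assign each individual to the instar interval its width falls in.

    Instar i is the half-open interval ``(boundary_{i−1}, boundary_i]``
    with sentinels −∞ and +∞, so every value receives exactly one label.
    """
    x = _as_values(data)
    boundaries = np.asarray(boundaries, dtype=float)
    labels = np.searchsorted(boundaries, x, side="left") + 1
    return InstarPartition(boundaries=boundaries, assignments=labels)
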