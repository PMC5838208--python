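"""Univariate Gaussian mixture fitting by EM with BIC model selection.

The genome-wide distribution of per-site Hodges-Lehmann shifts is modelled as
f(x) = sum_k w_k phi(x; mu_k, sigma_k). The EM iteration is the standard
responsibility / weighted-moment update; the component count K is chosen by
scanning a range of K and minimising BIC = -2*ll + nu*ln(n) with
nu = 3K - 1 free parameters (K means, K standard deviations, K - 1 free
weights). Component standard deviations are floored at ``SIGMA_FLOOR``:
narrower components on a [-1, 1] shift scale are numerical artifacts.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.stats import norm

SIGMA_FLOOR = 1e-4
W_FLOOR = 1e-4
DEFAULT_TOL = 1e-8
DEFAULT_MAX_ITER = 1000
MAX_RESTARTS = 5


class FitError(RuntimeError):
    """Raised when EM cannot produce a usable model."""


@dataclass
class GaussianMixture1D:
    """A K-component univariate Gaussian mixture (means, sds, weights)."""

    mu: np.ndarray
    sigma: np.ndarray
    w: np.ndarray

    def __post_init__(self) -> None:
        self.mu = np.asarray(self.mu, dtype=float)
        self.sigma = np.asarray(self.sigma, dtype=float)
        self.w = np.asarray(self.w, dtype=float)
        if not (self.mu.shape == self.sigma.shape == self.w.shape) or self.mu.ndim != 1:
            raise ValueError("mu, sigma, w must be 1-D arrays of equal length")
        if self.K < 1:
            raise ValueError("need at least one component")
        if (self.sigma <= 0).any():
            raise ValueError("non-positive sigma")
        if (self.w <= 0).any():
            raise ValueError("non-positive weight")
        if abs(self.w.sum() - 1.0) > 1e-9:
            raise ValueError(f"weights sum to {self.w.sum()}, not 1")

    @property
    def K(self) -> int:
        return self.mu.size

    def sorted_by_mean(self) -> "GaussianMixture1D":
        order = np.argsort(self.mu, kind="stable")
        return GaussianMixture1D(self.mu[order], self.sigma[order], self.w[order])

    def pdf(self, x) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        return (self.w[:, None] * norm.pdf(x[None, :], self.mu[:, None], self.sigma[:, None])).sum(axis=0)

    def component_densities(self, x) -> np.ndarray:
        """K x len(x) matrix of weighted component densities w_k phi_k(x)."""
        x = np.atleast_1d(np.asarray(x, dtype=float))
        return self.w[:, None] * norm.pdf(x[None, :], self.mu[:, None], self.sigma[:, None])

    def log_likelihood(self, x) -> float:
        return float(np.log(self.pdf(np.asarray(x, dtype=float))).sum())

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        comp = rng.choice(self.K, size=n, p=self.w)
        return rng.normal(self.mu[comp], self.sigma[comp])

    def to_dict(self) -> dict:
        m = self.sorted_by_mean()
        return {
            "K": m.K,
            "components": [
                {"mean": float(mu), "sd": float(sd), "weight": float(w)}
                for mu, sd, w in zip(m.mu, m.sigma, m.w)
            ],
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1))

    @classmethod
    def from_dict(cls, d: dict) -> "GaussianMixture1D":
        comps = d["components"]
        return cls(
            np.array([c["mean"] for c in comps]),
            np.array([c["sd"] for c in comps]),
            np.array([c["weight"] for c in comps]),
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "GaussianMixture1D":
        return cls.from_dict(json.loads(Path(path).read_text()))


@dataclass
class MixtureFitReport:
    """Diagnostics of one fit / model scan."""

    bic_by_k: dict[int, float] = field(default_factory=dict)
    selected_k: int = 0
    log_likelihood: float = float("nan")
    iterations: int = 0
    converged: bool = False
    seed: int | None = None
    ll_trajectory: list[float] = field(default_factory=list)


def initialize_components(x: Sequence[float], K: int, seed: int = 0, jitter: float = 0.0) -> GaussianMixture1D:
    """Deterministic quantile initialisation.

    Component means sit at the (k - 0.5)/K sample quantiles, all components
    share sigma = sample sd / K, weights are equal. ``jitter`` perturbs the
    quantile levels (used by restart logic); identical seeds give identical
    initialisations.
    """
    x = np.asarray(x, dtype=float)
    if K > x.size:
        raise ValueError(f"K={K} exceeds sample size {x.size}")
    q = (np.arange(K) + 0.5) / K
    if jitter > 0:
        rng = np.random.default_rng(seed)
        q = np.clip(q + rng.uniform(-jitter, jitter, size=K), 0.0, 1.0)
        q.sort()
    mu = np.quantile(x, q)
    sd = max(float(x.std()) / K, SIGMA_FLOOR)
    return GaussianMixture1D(mu, np.full(K, sd), np.full(K, 1.0 / K))


def _log_pdf_matrix(m: GaussianMixture1D, x: np.ndarray) -> np.ndarray:
    """K x n matrix of log(w_k phi_k(x))."""
    z = (x[None, :] - m.mu[:, None]) / m.sigma[:, None]
    return (
        np.log(m.w)[:, None]
        - np.log(m.sigma)[:, None]
        - 0.5 * np.log(2 * np.pi)
        - 0.5 * z**2
    )


def em_fit(
    x: Sequence[float],
    K: int,
    init: GaussianMixture1D | None = None,
    tol: float = DEFAULT_TOL,
    max_iter: int = DEFAULT_MAX_ITER,
    seed: int = 0,
    max_restarts: int = MAX_RESTARTS,
) -> tuple[GaussianMixture1D, MixtureFitReport]:
    """Fit a K-component mixture by EM.

    Iterates the responsibility (E) and weighted-moment (M) steps until the
    relative log-likelihood change drops below ``tol`` or ``max_iter`` is hit.
    Sigmas are clamped at ``SIGMA_FLOOR``. If a component's weight collapses
    below ``W_FLOOR`` the fit restarts from a jittered initialisation, at most
    ``max_restarts`` times.
    """
    x = np.asarray(x, dtype=float)
    x = x[~np.isnan(x)]
    if x.size <= 3 * K:
        raise FitError(f"need more than {3 * K} observations to fit K={K}, got {x.size}")
    failures: list[str] = []
    for attempt in range(max_restarts + 1):
        m = init if (init is not None and attempt == 0) else initialize_components(
            x, K, seed=seed + attempt, jitter=0.0 if attempt == 0 else 0.4 / K
        )
        try:
            return _em_once(x, m, tol, max_iter, seed)
        except FitError as exc:
            failures.append(f"attempt {attempt}: {exc}")
    raise FitError("EM failed after restarts: " + "; ".join(failures))


def _em_once(
    x: np.ndarray,
    m: GaussianMixture1D,
    tol: float,
    max_iter: int,
    seed: int,
    weights: np.ndarray | None = None,
) -> tuple[GaussianMixture1D, MixtureFitReport]:
    """One EM run; ``weights`` turns the sample into weighted observations
    (used for the histogram-accelerated search) without changing the update
    equations — weighted EM is still an ascent on the weighted likelihood."""
    mu, sigma, w = m.mu.copy(), m.sigma.copy(), m.w.copy()
    wt = np.ones_like(x) if weights is None else weights
    n = float(wt.sum())
    trajectory: list[float] = []
    ll_prev = -np.inf
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        model = GaussianMixture1D(mu, sigma, w)
        logp = _log_pdf_matrix(model, x)
        mx = logp.max(axis=0)
        lse = mx + np.log(np.exp(logp - mx).sum(axis=0))
        ll = float((wt * lse).sum())
        trajectory.append(ll)
        resp = np.exp(logp - lse) * wt[None, :]  # K x n weighted responsibilities
        nk = resp.sum(axis=1)
        if (nk / n < W_FLOOR).any():
            raise FitError("component weight collapsed")
        mu = (resp @ x) / nk
        var = (resp @ x**2) / nk - mu**2
        sigma = np.sqrt(np.maximum(var, SIGMA_FLOOR**2))
        w = nk / n
        if np.isfinite(ll_prev) and abs(ll - ll_prev) <= tol * abs(ll_prev):
            converged = True
            break
        ll_prev = ll
    fitted = GaussianMixture1D(mu, sigma, w).sorted_by_mean()
    report = MixtureFitReport(
        selected_k=fitted.K,
        log_likelihood=trajectory[-1],
        iterations=it,
        converged=converged,
        seed=seed,
        ll_trajectory=trajectory,
    )
    return fitted, report


#: Samples larger than this are histogram-binned for the multistart search.
BIN_THRESHOLD = 10_000
N_BINS = 2_000
DEFAULT_N_STARTS = 8


def _multistart_inits(
    x: np.ndarray, K: int, seed: int, n_starts: int
) -> list[GaussianMixture1D]:
    """A family of starting points for the multistart search.

    Deterministic members: uniform quantile spacing and normal-score quantile
    spacings (which reach into heavy tails); the remainder are seeded random
    quantile levels with random common-sigma scales.
    """
    sd = max(float(x.std()), SIGMA_FLOOR)
    starts: list[GaussianMixture1D] = []

    def from_levels(levels: np.ndarray, sigma: float) -> GaussianMixture1D:
        mu = np.quantile(x, np.clip(levels, 0.0, 1.0))
        return GaussianMixture1D(mu, np.full(K, max(sigma, SIGMA_FLOOR)), np.full(K, 1.0 / K))

    starts.append(from_levels((np.arange(K) + 0.5) / K, sd / K))
    for c in (0.5, 1.0, 1.5):
        levels = norm.cdf((np.arange(K) - (K - 1) / 2.0) * c)
        starts.append(from_levels(levels, sd / K))
    rng = np.random.default_rng(seed)
    while len(starts) < n_starts:
        levels = np.sort(rng.random(K))
        scale = sd * np.exp(rng.uniform(np.log(1.0 / K), 0.0))
        starts.append(from_levels(levels, scale))
    return starts[:n_starts]


def fit_mixture(
    x: Sequence[float],
    K: int,
    seed: int = 0,
    n_starts: int = DEFAULT_N_STARTS,
    tol: float = DEFAULT_TOL,
    max_iter: int = DEFAULT_MAX_ITER,
) -> tuple[GaussianMixture1D, MixtureFitReport]:
    """Multistart EM: the production fitting path.

    Every start is run to convergence on a histogram-weighted version of the
    sample (``N_BINS`` equal-width bins once n exceeds ``BIN_THRESHOLD``; the
    raw sample below that); the best start by likelihood is then polished on
    the full sample. Deterministic given ``seed``.
    """
    x = np.asarray(x, dtype=float)
    x = x[~np.isnan(x)]
    if x.size <= 3 * K:
        raise FitError(f"need more than {3 * K} observations to fit K={K}, got {x.size}")
    if x.size > BIN_THRESHOLD:
        counts, edges = np.histogram(x, bins=N_BINS)
        centers = 0.5 * (edges[:-1] + edges[1:])
        keep = counts > 0
        search_x, search_w = centers[keep], counts[keep].astype(float)
    else:
        search_x, search_w = x, None

    best: tuple[float, GaussianMixture1D] | None = None
    for init in _multistart_inits(x, K, seed, n_starts):
        try:
            m, rep = _em_once(search_x, init, tol, 8 * max_iter, seed, weights=search_w)
        except FitError:
            continue
        if best is None or rep.log_likelihood > best[0]:
            best = (rep.log_likelihood, m)
    if best is None:
        raise FitError(f"every start collapsed for K={K}")
    model, report = _em_once(x, best[1], tol, max_iter, seed)
    return model, report


def bic(ll: float, K: int, n: int) -> float:
    """BIC = -2 ll + nu ln(n) with nu = 3K - 1 free parameters."""
    if n <= 0:
        raise ValueError("n must be positive")
    nu = 3 * K - 1
    return -2.0 * ll + nu * np.log(n)


def scan_models(
    x: Sequence[float],
    K_range: Sequence[int] = tuple(range(1, 11)),
    seed: int = 0,
    tol: float = DEFAULT_TOL,
    max_iter: int = DEFAULT_MAX_ITER,
) -> list[tuple[int, float, GaussianMixture1D, MixtureFitReport]]:
    """Fit every K in ``K_range``; return (K, BIC, model, report) per success,
    sorted by K. Raises only when every K fails."""
    x = np.asarray(x, dtype=float)
    if len(K_range) == 0:
        raise ValueError("empty K range")
    out: list[tuple[int, float, GaussianMixture1D, MixtureFitReport]] = []
    failures: list[str] = []
    for K in sorted(K_range):
        try:
            if K == 1:
                model, rep = em_fit(x, K, tol=tol, max_iter=max_iter, seed=seed)
            else:
                model, rep = fit_mixture(x, K, seed=seed, tol=tol, max_iter=max_iter)
        except FitError as exc:
            failures.append(f"K={K}: {exc}")
            continue
        out.append((K, bic(rep.log_likelihood, K, x.size), model, rep))
    if not out:
        raise FitError("all mixture fits failed: " + "; ".join(failures))
    return out


def select_model(
    x: Sequence[float],
    K_range: Sequence[int] = tuple(range(1, 11)),
    seed: int = 0,
    tol: float = DEFAULT_TOL,
    max_iter: int = DEFAULT_MAX_ITER,
) -> tuple[GaussianMixture1D, MixtureFitReport]:
    """Fit every K in ``K_range`` and return the BIC-minimising model.

    Ties are broken toward the smaller K. Raises only when every K fails.
    """
    scan = scan_models(x, K_range, seed=seed, tol=tol, max_iter=max_iter)
    K, _, model, rep = min(scan, key=lambda t: (t[1], t[0]))
    rep.bic_by_k = {k: b for k, b, _, _ in scan}
    rep.selected_k = K
    return model, rep
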