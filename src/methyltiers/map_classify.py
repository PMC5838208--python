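"""Data-driven tier cutoffs via the maximum-probability criterion.

Given the mixture fitted to the genome-wide shift distribution, the real line
is partitioned by which weighted component density w_k phi_k(x) is largest.
The partition boundaries on the positive side are the data-driven cutoffs
separating no-change / medium / high / extreme-high up-methylation; the same
rule applied on the negative side yields down-methylation cutoffs when the
model supports them. Sites are then classified into nested "at least" tiers:
a site is at least medium up-methylated when its shift is significantly above
the first cutoff, and so on.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .gmm1d import GaussianMixture1D
from .site_stats import ContingencyTable, STATUS_LEVELS

TIER_LABELS = ("medium", "high", "extreme")
TIER_ORDER = {"none": 0, "significant": 1, "medium": 2, "high": 3, "extreme": 4}

Direction = Literal["up", "down", "none"]

GRID_STEP = 1e-5
BISECT_TOL = 1e-12


class ModelShapeError(ValueError):
    """Raised when the mixture is too coarse to define the requested tiers."""


@dataclass
class TierCutoffs:
    """Ordered tier boundaries in shift (delta-beta) units.

    ``up`` = (b_medium, b_high, b_extreme), strictly increasing, all > 0.
    ``down`` mirrors on the negative side (strictly decreasing from 0) when
    the model supports it. ``provenance`` records which component pair
    (indices in the mean-sorted model) generated each boundary.
    """

    up: tuple[float, float, float]
    down: tuple[float, ...] | None = None
    provenance: list[dict] = field(default_factory=list)

    def __post_init__(self) -> None:
        b1, b2, b3 = self.up
        if not (0 < b1 < b2 < b3):
            raise ValueError(f"up cutoffs must be increasing and positive, got {self.up}")
        if self.down is not None:
            if any(d >= 0 for d in self.down) or list(self.down) != sorted(self.down, reverse=True):
                raise ValueError(f"down cutoffs must decrease from 0, got {self.down}")

    def to_dict(self) -> dict:
        return {
            "up": [float(b) for b in self.up],
            "down": None if self.down is None else [float(b) for b in self.down],
            "provenance": self.provenance,
        }


@dataclass
class TierCall:
    """Direction and nested tier of one site."""

    site_id: str
    direction: Direction
    tier: str

    def __post_init__(self) -> None:
        if self.tier not in TIER_ORDER:
            raise ValueError(f"unknown tier {self.tier!r}")
        if self.tier != "none" and self.direction == "none":
            raise ValueError("a tiered site must have a direction")


def component_intersections(
    c1: tuple[float, float, float], c2: tuple[float, float, float]
) -> list[float]:
    """Crossing points of two weighted Gaussian densities.

    Solves w1 phi(x; mu1, s1) = w2 phi(x; mu2, s2) via the quadratic obtained
    by equating log-densities: two roots when s1 != s2, one when the sigmas
    coincide, possibly none.
    """
    mu1, s1, w1 = c1
    mu2, s2, w2 = c2
    if s1 <= 0 or s2 <= 0:
        raise ValueError("non-positive sigma")
    if (mu1, s1, w1) == (mu2, s2, w2):
        raise ValueError("identical components intersect everywhere")
    # log w1 - log s1 - (x-mu1)^2/(2 s1^2) = log w2 - log s2 - (x-mu2)^2/(2 s2^2)
    a = 1.0 / (2 * s2**2) - 1.0 / (2 * s1**2)
    b = mu1 / s1**2 - mu2 / s2**2
    c = mu2**2 / (2 * s2**2) - mu1**2 / (2 * s1**2) + np.log(w1 / w2) + np.log(s2 / s1)
    if abs(a) < 1e-300:
        if abs(b) < 1e-300:
            return []
        return [-c / b]
    disc = b**2 - 4 * a * c
    if disc < 0:
        return []
    r = np.sqrt(disc)
    return sorted(((-b - r) / (2 * a), (-b + r) / (2 * a)))


def map_partition(
    m: GaussianMixture1D, grid_step: float = GRID_STEP
) -> list[tuple[float, int, int]]:
    """Partition the real line by the dominating weighted component.

    Returns ``(boundary, left_component, right_component)`` triples ordered
    left to right; component indices refer to the mean-sorted model. A dense
    grid scan locates every change of argmax_k w_k phi_k(x); each change point
    is then refined by bisection on the two swapping components' density
    difference.
    """
    if m.K < 2:
        raise ModelShapeError("a MAP partition needs at least two components")
    ms = m.sorted_by_mean()
    lo = float((ms.mu - 6 * ms.sigma).min())
    hi = float((ms.mu + 6 * ms.sigma).max())
    n = int(np.ceil((hi - lo) / grid_step)) + 1
    x = np.linspace(lo, hi, n)
    dens = ms.component_densities(x)
    am = np.argmax(dens, axis=0)
    out: list[tuple[float, int, int]] = []
    for idx in np.nonzero(np.diff(am))[0]:
        left, right = int(am[idx]), int(am[idx + 1])
        b = _bisect_crossing(ms, left, right, x[idx], x[idx + 1])
        out.append((b, left, right))
    return out


def _bisect_crossing(
    m: GaussianMixture1D, k1: int, k2: int, lo: float, hi: float
) -> float:
    """Refine the crossing of weighted densities k1 (dominant at lo) and k2."""

    def diff(x: float) -> float:
        d = m.component_densities(np.array([x]))
        return float(d[k1, 0] - d[k2, 0])

    f_lo = diff(lo)
    if f_lo == 0.0:
        return lo
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        f_mid = diff(mid)
        if abs(f_mid) < BISECT_TOL or (hi - lo) < 1e-15:
            return mid
        if (f_mid > 0) == (f_lo > 0):
            lo, f_lo = mid, f_mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def derive_tier_cutoffs(m: GaussianMixture1D, grid_step: float = GRID_STEP) -> TierCutoffs:
    """Tier cutoffs from the MAP partition of the fitted mixture.

    Up cutoffs are the first three partition boundaries at x > 0 (everything
    beyond the third is merged into the extreme tier); down cutoffs are the
    mirrored reading of the negative-side boundaries when at least three
    exist, else absent.
    """
    bounds = map_partition(m, grid_step=grid_step)
    # a boundary within one grid step of zero is the up/down split itself
    # (e.g. in a mixture symmetric about 0) and belongs to neither side
    pos = [b for b in bounds if b[0] > grid_step]
    neg = [b for b in bounds if b[0] < -grid_step]
    if len(pos) < 3:
        raise ModelShapeError(
            f"model has only {len(pos)} positive-side MAP boundaries; "
            "at least 3 are needed for medium/high/extreme tiers"
        )
    up = tuple(b[0] for b in pos[:3])
    prov = [
        {"side": "up", "boundary": float(b), "left": l, "right": r}
        for b, l, r in pos[:3]
    ]
    down = None
    if len(neg) >= 3:
        down = tuple(b[0] for b in neg[-3:][::-1])  # closest-to-zero first
        prov += [
            {"side": "down", "boundary": float(b), "left": l, "right": r}
            for b, l, r in neg[-3:]
        ]
    return TierCutoffs(up=up, down=down, provenance=prov)


def shifted_p_column(direction: str, label: str) -> str:
    """Column name for the shifted-test p-value at one tier cutoff."""
    return f"p_{direction}_{label}"


def classify_sites(
    results: pd.DataFrame,
    cutoffs: TierCutoffs,
    alpha: float = 0.025,
    use_q: bool = False,
    tier_rule: Literal["shifted_test", "hl_filter"] = "shifted_test",
) -> list[TierCall]:
    """Classify every site into a direction and a nested tier.

    ``results`` must carry columns ``site_id``, ``hl``, ``p_up``, ``p_down``
    (and ``q_up``/``q_down`` when ``use_q``); under the default
    ``shifted_test`` rule it must also carry the shifted-test p-value columns
    ``p_up_medium`` / ``p_up_high`` / ``p_up_extreme`` (and the ``p_down_*``
    mirror when down cutoffs exist). A site is tiered at a cutoff when the
    shifted test at that cutoff rejects at ``alpha`` and its point estimate
    exceeds the cutoff; ``hl_filter`` instead thresholds the point estimate of
    sites already significant at shift zero.
    """
    if tier_rule == "shifted_test":
        for lab in TIER_LABELS:
            if shifted_p_column("up", lab) not in results.columns:
                raise KeyError(f"missing shifted-test column {shifted_p_column('up', lab)!r}")
    p_up = results["q_up"] if use_q else results["p_up"]
    p_down = results["q_down"] if use_q else results["p_down"]
    calls: list[TierCall] = []
    for i, row in enumerate(results.itertuples(index=False)):
        hl = row.hl
        if p_up.iat[i] < alpha:
            direction: Direction = "up"
            tier = "significant"
            for lab, cut in zip(TIER_LABELS, cutoffs.up):
                if tier_rule == "shifted_test":
                    ok = getattr(row, shifted_p_column("up", lab)) < alpha and hl > cut
                else:
                    ok = hl > cut
                if ok:
                    tier = lab
        elif p_down.iat[i] < alpha:
            direction = "down"
            tier = "significant"
            if cutoffs.down is not None:
                for lab, cut in zip(TIER_LABELS, cutoffs.down):
                    if tier_rule == "shifted_test":
                        col = shifted_p_column("down", lab)
                        ok = col in results.columns and getattr(row, col) < alpha and hl < cut
                    else:
                        ok = hl < cut
                    if ok:
                        tier = lab
        else:
            direction, tier = "none", "none"
        calls.append(TierCall(site_id=row.site_id, direction=direction, tier=tier))
    return calls


def tier_counts(calls: Sequence[TierCall], direction: Direction = "up") -> dict[str, int]:
    """Nested 'at least' counts: significant, at-least-medium, at-least-high,
    extreme (each includes the deeper tiers)."""
    levels = [TIER_ORDER[c.tier] for c in calls if c.direction == direction]
    return {
        "significant": sum(l >= 1 for l in levels),
        "at_least_medium": sum(l >= 2 for l in levels),
        "at_least_high": sum(l >= 3 for l in levels),
        "extreme_high": sum(l >= 4 for l in levels),
    }


def status_contingency(
    ref_status: Sequence[str],
    case_status: Sequence[str],
    direction: Sequence[str],
) -> dict:
    """Cross-tabulate baseline status against case status and change direction.

    Returns the 3x3 reference-vs-case status table, the 3x3 dynamics table
    (reference status x change direction), and the two dynamics-class counts:
    *enhancement/diminution* (a low site going further down, or a high site
    going further up) and *compensation* (a low site going up, or a high site
    going down).
    """
    ref_status = np.asarray(ref_status, dtype=object)
    case_status = np.asarray(case_status, dtype=object)
    direction = np.asarray(direction, dtype=object)
    status_counts = np.zeros((3, 3))
    for i, r in enumerate(STATUS_LEVELS):
        for j, c in enumerate(STATUS_LEVELS):
            status_counts[i, j] = np.sum((ref_status == r) & (case_status == c))
    dir_levels = ("down", "none", "up")
    dyn_counts = np.zeros((3, 3))
    for i, r in enumerate(STATUS_LEVELS):
        for j, d in enumerate(dir_levels):
            dyn_counts[i, j] = np.sum((ref_status == r) & (direction == d))
    enhancement = int(
        np.sum((ref_status == "low") & (direction == "down"))
        + np.sum((ref_status == "high") & (direction == "up"))
    )
    compensation = int(
        np.sum((ref_status == "low") & (direction == "up"))
        + np.sum((ref_status == "high") & (direction == "down"))
    )
    return {
        "status_table": ContingencyTable(STATUS_LEVELS, STATUS_LEVELS, status_counts),
        "dynamics_table": ContingencyTable(STATUS_LEVELS, dir_levels, dyn_counts),
        "enhancement_diminution": enhancement,
        "compensation": compensation,
    }
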