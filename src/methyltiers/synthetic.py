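"""Synthetic two-group methylation datasets with known ground truth.

The generator emulates the shape of the motivating 450K study: a reference
group of 5 samples versus a case group of 14, sites whose baseline beta
values sit in two modes near 0.1 and 0.9 (the characteristic bimodal 450K
beta shape), genes laid out along chromosomes with promoter-side (TSS) and
body sites, and a fraction of genes carrying a coherent planted case-group
shift. Per-sample noise is beta-distributed — reparameterised by (mean,
concentration) — so generated values respect the [0, 1] support at the
modes, which Gaussian noise would not.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .beta_io import CASE, REF, BetaMatrix, FeatureIntervals, SiteAnnotation
from .gmm1d import GaussianMixture1D
from .reference import PUBLISHED_UP_CUTOFFS


@dataclass
class SimulationSpec:
    """Study-shaped simulation parameters.

    Defaults mirror the motivating study's design: 5 reference vs 14 case
    samples. ``effect_mixture`` draws a per-site background shift (None means
    a flat null, delta = 0); ``planted_genes`` is the fraction of genes whose
    TSS and body sites all receive the coherent shift ``planted_delta``.
    ``noise_conc`` is the beta-noise concentration: replicate SD at a mean of
    0.5 is sqrt(0.25 / (noise_conc + 1)), about 0.05 at the default 100,
    matching typical 450K replicate scatter.
    """

    n_sites: int = 20_000
    n_ref: int = 5
    n_case: int = 14
    effect_mixture: GaussianMixture1D | None = None
    baseline_modes: tuple[float, float] = (0.1, 0.9)
    baseline_weights: tuple[float, float] = (0.55, 0.45)
    baseline_conc: float = 30.0
    noise_conc: float = 100.0
    n_genes: int = 0  # 0: derived as n_sites // 12
    sites_per_tss: int = 3
    sites_per_body: int = 4
    planted_genes: float = 0.0
    planted_delta: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_sites, self.n_ref, self.n_case) <= 0:
            raise ValueError("counts must be positive")
        if not 0 <= self.planted_genes <= 1:
            raise ValueError("planted_genes must be a fraction in [0, 1]")
        if self.n_genes == 0:
            self.n_genes = max(1, self.n_sites // 12)


def _beta_draw(rng: np.random.Generator, mean: np.ndarray, conc: float) -> np.ndarray:
    """Beta(mean * conc, (1 - mean) * conc) draws, elementwise."""
    m = np.clip(mean, 1e-3, 1 - 1e-3)
    return rng.beta(m * conc, (1 - m) * conc)


def simulate_dataset(
    spec: SimulationSpec,
) -> tuple[BetaMatrix, list[SiteAnnotation], FeatureIntervals, pd.DataFrame]:
    """Generate a beta matrix, annotations, interval features and the truth table.

    Each site gets a baseline drawn from the bimodal baseline distribution
    and a true shift delta (0, a background draw from ``effect_mixture``, or
    the planted regional shift). Reference samples are beta-noise around the
    baseline, case samples around clip(baseline + delta). The truth table
    records every site's gene, true delta and true tier under the published
    cutoffs, plus each gene's planted status.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_sites

    gene_sites = spec.sites_per_tss + spec.sites_per_body
    n_genic = min(spec.n_genes * gene_sites, n)
    n_genes = n_genic // gene_sites
    n_genic = n_genes * gene_sites
    if n_genes == 0:
        raise ValueError("spec leaves no room for a single gene")

    # baseline: two beta-distributed modes
    mode = rng.random(n) < spec.baseline_weights[0]
    mode_mean = np.where(mode, spec.baseline_modes[0], spec.baseline_modes[1])
    baseline = _beta_draw(rng, mode_mean, spec.baseline_conc)

    # true shifts
    delta = np.zeros(n)
    if spec.effect_mixture is not None:
        delta = spec.effect_mixture.sample(n, rng)
    n_planted = int(round(spec.planted_genes * n_genes))
    planted_gene_idx = rng.choice(n_genes, size=n_planted, replace=False)
    planted_gene_set = set(int(g) for g in planted_gene_idx)
    gene_of_site = np.full(n, -1)
    gene_of_site[:n_genic] = np.repeat(np.arange(n_genes), gene_sites)
    planted_site = np.isin(gene_of_site, planted_gene_idx)
    delta[planted_site] = spec.planted_delta

    ref_mean = baseline
    case_mean = np.clip(baseline + delta, 0.0, 1.0)
    if np.all((case_mean <= 0.0) | (case_mean >= 1.0)):
        raise ValueError("infeasible spec: every shifted mean leaves (0, 1)")

    ref_vals = _beta_draw(rng, np.repeat(ref_mean[:, None], spec.n_ref, axis=1), spec.noise_conc)
    case_vals = _beta_draw(rng, np.repeat(case_mean[:, None], spec.n_case, axis=1), spec.noise_conc)

    site_ids = [f"cg{i:08d}" for i in range(n)]
    ref_ids = [f"HSC_{j + 1}" for j in range(spec.n_ref)]
    case_ids = [f"AML_{j + 1}" for j in range(spec.n_case)]
    beta = BetaMatrix(
        site_ids=site_ids,
        sample_ids=ref_ids + case_ids,
        values=np.concatenate([ref_vals, case_vals], axis=1),
        groups={**{s: REF for s in ref_ids}, **{s: CASE for s in case_ids}},
    )

    # gene layout: genes tiled along chromosomes, 60 bp between sites,
    # TSS sites first then body sites; leftover sites are intergenic.
    annotations: list[SiteAnnotation] = []
    genes_per_chrom = max(1, n_genes // 4)
    tss_groups = ["TSS200", "TSS1500", "5'UTR"]
    body_groups = ["1stExon", "Body", "3'UTR"]
    positions: list[tuple[str, int]] = []
    for g in range(n_genes):
        chrom = str(1 + g // genes_per_chrom)
        start = 10_000 + (g % genes_per_chrom) * 10_000
        for k in range(gene_sites):
            positions.append((chrom, start + k * 60))
    for i in range(n):
        if gene_of_site[i] >= 0:
            g = int(gene_of_site[i])
            within = i - g * gene_sites
            chrom, pos = positions[i]
            if within < spec.sites_per_tss:
                group = tss_groups[within % len(tss_groups)]
            else:
                group = body_groups[(within - spec.sites_per_tss) % len(body_groups)]
            annotations.append(
                SiteAnnotation(
                    site_id=site_ids[i],
                    chrom=chrom,
                    pos=pos + 1,  # 1-based manifest coordinate
                    gene_names=[f"GENE{g:05d}"],
                    gene_groups=[group],
                    cpg_island_relation="Island" if within < spec.sites_per_tss else "OpenSea",
                )
            )
        else:
            annotations.append(
                SiteAnnotation(
                    site_id=site_ids[i],
                    chrom="9",
                    pos=50_000 + (i - n_genic) * 500 + 1,
                    cpg_island_relation="OpenSea",
                )
            )

    # one enhancer-like interval per 10th gene, spanning that gene's sites
    feats = []
    for g in range(0, n_genes, 10):
        first = g * gene_sites
        chrom, start_pos = positions[first]
        feats.append(
            (f"enh{g:05d}", chrom, start_pos, start_pos + gene_sites * 60)
        )
    features = FeatureIntervals(kind="enhancer", records=feats)

    truth = pd.DataFrame(
        {
            "site_id": site_ids,
            "gene": [f"GENE{int(g):05d}" if g >= 0 else "" for g in gene_of_site],
            "true_delta": delta,
            "true_tier": [_tier_of(d) for d in delta],
            "planted": planted_site,
        }
    )
    truth.attrs["planted_genes"] = sorted(f"GENE{g:05d}" for g in planted_gene_set)
    return beta, annotations, features, truth


def _tier_of(delta: float, cutoffs: Sequence[float] = PUBLISHED_UP_CUTOFFS) -> str:
    if delta <= 0:
        return "none"
    labels = ["significant", "medium", "high", "extreme"]
    tier = "significant"
    for lab, cut in zip(labels[1:], cutoffs):
        if delta > cut:
            tier = lab
    return tier


def worked_example_fixture() -> tuple[BetaMatrix, list[SiteAnnotation], FeatureIntervals, pd.DataFrame]:
    """A tiny deterministic dataset: 36 sites, 3 genes, 5 vs 14 samples.

    Gene GENE00002 carries a strong planted up-shift (delta = 0.12), the
    other genes and all intergenic sites are null. Small enough that every
    statistic can be checked by hand or by exhaustive enumeration.
    """
    spec = SimulationSpec(
        n_sites=36,
        n_genes=3,
        sites_per_tss=3,
        sites_per_body=4,
        planted_genes=1 / 3,
        planted_delta=0.12,
        seed=20_452,
    )
    return simulate_dataset(spec)
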