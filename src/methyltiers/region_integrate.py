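"""Stouffer integration of site-level evidence to genes and genomic features.

One-sided site p-values are translated to gene TSS / gene Body regions (and
to arbitrary interval features such as lincRNAs, enhancers or transposable
elements) by Stouffer's method: Z = sum_i Phi^{-1}(1 - p_i) / sqrt(k). Up and
down directions are combined strictly separately, and Storey's correction is
applied across regions within one (region kind, direction) stratum.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm

from .beta_io import BODY, TSS, SiteAnnotation
from .map_classify import TIER_LABELS, TIER_ORDER, TierCutoffs, shifted_p_column
from .site_stats import clip_p, storey_qvalues

GENE_TSS = "gene-TSS"
GENE_BODY = "gene-Body"

_TSS_GROUPS_KIND = {"TSS1500": GENE_TSS, "TSS200": GENE_TSS, "5'UTR": GENE_TSS, "5′UTR": GENE_TSS}
_BODY_GROUPS_KIND = {"1stExon": GENE_BODY, "Body": GENE_BODY, "3'UTR": GENE_BODY, "3′UTR": GENE_BODY}
_GROUP_KIND = {**_TSS_GROUPS_KIND, **_BODY_GROUPS_KIND}


def stouffer_combine(p_list: Sequence[float]) -> tuple[float, float]:
    """Combine one-sided p-values: Z = sum Phi^{-1}(1-p_i)/sqrt(k), p = 1-Phi(Z)."""
    p = np.asarray(p_list, dtype=float)
    if p.size == 0:
        raise ValueError("cannot combine an empty p-value list")
    z = norm.isf(clip_p(p))
    Z = float(z.sum() / np.sqrt(p.size))
    return Z, float(norm.sf(Z))


def gene_region_membership(
    annotations: Sequence[SiteAnnotation],
) -> dict[tuple[str, str], list[str]]:
    """Map (gene, region kind) -> member site ids.

    A site contributes to gene G's TSS region iff one of its (gene, group)
    pairs maps G to a TSS-class group; likewise for Body. A site annotated to
    several genes contributes to each; a site is counted once per (gene,
    kind) even if several of its groups point there.
    """
    members: dict[tuple[str, str], list[str]] = {}
    for ann in annotations:
        seen: set[tuple[str, str]] = set()
        for gene, group in zip(ann.gene_names, ann.gene_groups):
            kind = _GROUP_KIND.get(group)
            if kind is None or (gene, kind) in seen:
                continue
            seen.add((gene, kind))
            members.setdefault((gene, kind), []).append(ann.site_id)
    return members


def _combine_membership(
    site_results: pd.DataFrame,
    members: Mapping[tuple[str, str], list[str]],
) -> pd.DataFrame:
    res = site_results.set_index("site_id")
    rows = []
    for (fid, kind), site_ids in members.items():
        sub = res.loc[res.index.intersection(site_ids)]
        if sub.empty:
            continue
        z_up, p_up = stouffer_combine(sub["p_up"].to_numpy())
        z_down, p_down = stouffer_combine(sub["p_down"].to_numpy())
        row = {
            "feature_id": fid,
            "kind": kind,
            "n_sites": len(sub),
            "z_up": z_up,
            "p_up": p_up,
            "z_down": z_down,
            "p_down": p_down,
        }
        for direction in ("up", "down"):
            for lab in TIER_LABELS:
                col = shifted_p_column(direction, lab)
                if col in sub.columns and not sub[col].isna().any():
                    row[f"z_{col}"], row[col] = stouffer_combine(sub[col].to_numpy())
        rows.append(row)
    df = pd.DataFrame(rows)
    if df.empty:
        return df
    for direction in ("up", "down"):
        df[f"q_{direction}"] = np.nan
        for kind, idx in df.groupby("kind").groups.items():
            q, _ = storey_qvalues(df.loc[idx, f"p_{direction}"].to_numpy())
            df.loc[idx, f"q_{direction}"] = q
    return df.sort_values(["kind", "feature_id"]).reset_index(drop=True)


def integrate_gene_regions(
    site_results: pd.DataFrame, annotations: Sequence[SiteAnnotation]
) -> pd.DataFrame:
    """One combined result per (gene, TSS/Body region) with >= 1 tested site."""
    return _combine_membership(site_results, gene_region_membership(annotations))


def integrate_features(
    site_results: pd.DataFrame, feature_map: Mapping[str, list[str]], kind: str
) -> pd.DataFrame:
    """One combined result per interval feature containing >= 1 tested site."""
    members = {(fid, kind): sites for fid, sites in feature_map.items()}
    return _combine_membership(site_results, members)


def tier_regions(
    regions: pd.DataFrame,
    cutoffs: TierCutoffs,
    alpha: float = 0.025,
) -> pd.DataFrame:
    """Assign nested tiers to regions from their combined shifted-test p-values.

    Per direction, the region tier is the deepest cutoff whose combined
    shifted-test p-value is below ``alpha``; a region significant at shift
    zero but at no cutoff is tiered 'significant'.
    """
    regions = regions.copy()
    for direction, have_cutoffs in (("up", True), ("down", cutoffs.down is not None)):
        tiers = []
        for row in regions.itertuples(index=False):
            p0 = getattr(row, f"p_{direction}")
            if p0 >= alpha:
                tiers.append("none")
                continue
            tier = "significant"
            if have_cutoffs:
                for lab in TIER_LABELS:
                    col = shifted_p_column(direction, lab)
                    p_shift = getattr(row, col, None)
                    if p_shift is None or pd.isna(p_shift):
                        raise KeyError(f"missing combined shifted p-value column {col!r}")
                    if p_shift < alpha:
                        tier = lab
            tiers.append(tier)
        regions[f"tier_{direction}"] = tiers
    return regions


def region_tier_counts(regions: pd.DataFrame, direction: str = "up") -> dict[str, int]:
    """Nested 'at least' region counts per direction."""
    levels = regions[f"tier_{direction}"].map(TIER_ORDER)
    return {
        "significant": int((levels >= 1).sum()),
        "at_least_medium": int((levels >= 2).sum()),
        "at_least_high": int((levels >= 3).sum()),
        "extreme_high": int((levels >= 4).sum()),
    }
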