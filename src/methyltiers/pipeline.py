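"""End-to-end orchestration: sites -> mixture -> cutoffs -> regions.

``compute_site_results`` produces the per-site statistics table (HL shift,
one-sided rank-sum p-values, per-group status calls, Storey q-values and
shifted-test p-values at the tier cutoffs); ``run_sites`` / ``run_gmm`` /
``run_regions`` / ``run_all`` wrap the stages with file I/O so the pipeline
can be driven from the command line, a YAML config, or Python.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from . import beta_io, gmm1d, map_classify, region_integrate, site_stats
from .beta_io import CASE, REF, BetaMatrix, SiteAnnotation
from .gmm1d import GaussianMixture1D, MixtureFitReport
from .map_classify import TIER_LABELS, TierCutoffs, shifted_p_column

log = logging.getLogger("methyltiers")


@dataclass
class PipelineConfig:
    """All pipeline knobs in one place; defaults follow the method as published."""

    alpha_one_sided: float = 0.025
    alpha_two_sided: float = 0.05
    K_range: tuple[int, ...] = tuple(range(1, 11))
    seed: int = 0
    tier_rule: str = "shifted_test"  # or "hl_filter"
    test_family: str = "nonparametric"  # or "t"
    use_q_for_direction: bool = False
    exact_n_max: int = site_stats.EXACT_N_MAX

    def __post_init__(self) -> None:
        if not (0 < self.alpha_one_sided < 1 and 0 < self.alpha_two_sided < 1):
            raise ValueError("significance levels must lie in (0, 1)")
        if len(self.K_range) == 0:
            raise ValueError("empty K range")
        if self.tier_rule not in {"shifted_test", "hl_filter"}:
            raise ValueError(f"unknown tier rule {self.tier_rule!r}")
        if self.test_family not in {"nonparametric", "t"}:
            raise ValueError(f"unknown test family {self.test_family!r}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if "K_range" in raw:
            raw["K_range"] = tuple(raw["K_range"])
        return cls(**raw)

    def digest(self) -> str:
        return hashlib.sha256(json.dumps(asdict(self), sort_keys=True, default=str).encode()).hexdigest()[:12]


def _welch_p(case_mat: np.ndarray, ref_mat: np.ndarray, shift: float, side: str) -> np.ndarray:
    from scipy import stats as sps

    res = sps.ttest_ind(
        case_mat - shift, ref_mat, axis=1, equal_var=False, nan_policy="omit",
        alternative="greater" if side == "greater" else "less",
    )
    return np.asarray(res.pvalue)


def compute_site_results(
    beta: BetaMatrix,
    cutoffs: TierCutoffs | None = None,
    config: PipelineConfig | None = None,
) -> pd.DataFrame:
    """Per-site statistics table.

    Always computed: HL shift, one-sided p_up / p_down (case vs reference),
    per-group low/medium/high status, Storey q_up / q_down. When ``cutoffs``
    are given, the location-shifted tests at each cutoff are added as
    ``p_up_medium`` .. ``p_down_extreme`` columns for tier classification.
    """
    cfg = config or PipelineConfig()
    case = beta.group_values(CASE)
    ref = beta.group_values(REF)

    out = pd.DataFrame({"site_id": beta.site_ids})
    out["hl"] = site_stats.hodges_lehmann_rows(case, ref)
    if cfg.test_family == "t":
        out["p_up"] = _welch_p(case, ref, 0.0, "greater")
        out["p_down"] = _welch_p(case, ref, 0.0, "less")
    else:
        out["p_up"] = site_stats.rank_sum_test_rows(case, ref, 0.0, "greater", cfg.exact_n_max)
        out["p_down"] = site_stats.rank_sum_test_rows(case, ref, 0.0, "less", cfg.exact_n_max)
    out["status_ref"] = site_stats.methylation_status_rows(ref, cfg.alpha_one_sided, cfg.test_family)
    out["status_case"] = site_stats.methylation_status_rows(case, cfg.alpha_one_sided, cfg.test_family)
    out["q_up"], _ = site_stats.storey_qvalues(out["p_up"].to_numpy())
    out["q_down"], _ = site_stats.storey_qvalues(out["p_down"].to_numpy())

    if cutoffs is not None:
        for lab, cut in zip(TIER_LABELS, cutoffs.up):
            if cfg.test_family == "t":
                out[shifted_p_column("up", lab)] = _welch_p(case, ref, cut, "greater")
            else:
                out[shifted_p_column("up", lab)] = site_stats.rank_sum_test_rows(
                    case, ref, cut, "greater", cfg.exact_n_max
                )
        if cutoffs.down is not None:
            for lab, cut in zip(TIER_LABELS, cutoffs.down):
                if cfg.test_family == "t":
                    out[shifted_p_column("down", lab)] = _welch_p(case, ref, cut, "less")
                else:
                    out[shifted_p_column("down", lab)] = site_stats.rank_sum_test_rows(
                        case, ref, cut, "less", cfg.exact_n_max
                    )
    return out


def attach_tier_calls(
    results: pd.DataFrame, cutoffs: TierCutoffs, config: PipelineConfig | None = None
) -> pd.DataFrame:
    cfg = config or PipelineConfig()
    calls = map_classify.classify_sites(
        results, cutoffs, alpha=cfg.alpha_one_sided,
        use_q=cfg.use_q_for_direction, tier_rule=cfg.tier_rule,
    )
    results = results.copy()
    results["direction"] = [c.direction for c in calls]
    results["tier"] = [c.tier for c in calls]
    return results


# ---------------------------------------------------------------------------
# file-level stages
# ---------------------------------------------------------------------------

def run_sites(
    config: PipelineConfig,
    matrix_path: str | Path,
    groups_path: str | Path,
    out_tsv: str | Path,
) -> pd.DataFrame:
    """Stage 1: per-site statistics (no cutoffs yet) written as TSV."""
    beta = beta_io.read_beta_matrix(matrix_path, groups_path)
    log.info("sites: %d sites, %d samples", beta.n_sites, len(beta.sample_ids))
    res = compute_site_results(beta, cutoffs=None, config=config)
    res.to_csv(out_tsv, sep="\t", index=False)
    return res


def run_gmm(
    config: PipelineConfig,
    site_tsv: str | Path,
    model_json: str | Path,
    cutoffs_json: str | Path,
) -> tuple[GaussianMixture1D, TierCutoffs, MixtureFitReport]:
    """Stage 2: fit the HL mixture, select K by BIC, derive the MAP cutoffs.

    Among the scanned component counts, the BIC-best model is preferred; if
    its maximum-probability partition is too coarse to define the three
    up-methylation tiers (fewer than three positive boundaries), the next-best
    model by BIC that does support them is used instead.
    """
    hl = pd.read_csv(site_tsv, sep="\t")["hl"].to_numpy()
    scan = gmm1d.scan_models(hl, K_range=config.K_range, seed=config.seed)
    bics = {k: b for k, b, _, _ in scan}
    errors = []
    for K, score, model, report in sorted(scan, key=lambda t: (t[1], t[0])):
        try:
            cutoffs = map_classify.derive_tier_cutoffs(model)
        except map_classify.ModelShapeError as exc:
            errors.append(f"K={K}: {exc}")
            continue
        report.bic_by_k = bics
        report.selected_k = K
        log.info("gmm: selected K=%d (BIC scan over %s)", K, sorted(bics))
        model.to_json(model_json)
        Path(cutoffs_json).write_text(json.dumps(cutoffs.to_dict(), indent=1))
        return model, cutoffs, report
    raise map_classify.ModelShapeError(
        "no scanned mixture supports three up-methylation tiers: " + "; ".join(errors)
    )


def run_regions(
    config: PipelineConfig,
    matrix_path: str | Path,
    groups_path: str | Path,
    cutoffs_json: str | Path,
    annotation_path: str | Path,
    out_site_tsv: str | Path,
    out_region_tsv: str | Path,
    feature_paths: dict[str, str | Path] | None = None,
) -> pd.DataFrame:
    """Stage 3: shifted tests at the cutoffs, site tier calls, gene- and
    feature-level Stouffer integration and region tiers."""
    beta = beta_io.read_beta_matrix(matrix_path, groups_path)
    raw = json.loads(Path(cutoffs_json).read_text())
    cutoffs = TierCutoffs(
        up=tuple(raw["up"]),
        down=None if raw.get("down") is None else tuple(raw["down"]),
        provenance=raw.get("provenance", []),
    )
    res = compute_site_results(beta, cutoffs=cutoffs, config=config)
    res = attach_tier_calls(res, cutoffs, config)
    res.to_csv(out_site_tsv, sep="\t", index=False)

    annotations = beta_io.read_annotation(annotation_path)
    regions = region_integrate.integrate_gene_regions(res, annotations)
    frames = [] if regions.empty else [regions]
    for kind, path in (feature_paths or {}).items():
        feats = beta_io.read_intervals(path, kind)
        fmap = beta_io.map_sites_to_features(annotations, feats)
        fres = region_integrate.integrate_features(res, fmap, kind)
        if not fres.empty:
            frames.append(fres)
    all_regions = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame()
    if not all_regions.empty:
        all_regions = region_integrate.tier_regions(all_regions, cutoffs, config.alpha_one_sided)
    all_regions.to_csv(out_region_tsv, sep="\t", index=False)
    return all_regions


def run_all(
    config: PipelineConfig,
    matrix_path: str | Path,
    groups_path: str | Path,
    annotation_path: str | Path,
    out_dir: str | Path,
    feature_paths: dict[str, str | Path] | None = None,
) -> dict:
    """Full pipeline; writes every artifact plus a JSON run manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    run_sites(config, matrix_path, groups_path, out / "sites.tsv")
    model, cutoffs, report = run_gmm(
        config, out / "sites.tsv", out / "model.json", out / "cutoffs.json"
    )
    regions = run_regions(
        config, matrix_path, groups_path, out / "cutoffs.json", annotation_path,
        out / "sites_tiered.tsv", out / "regions.tsv", feature_paths,
    )
    manifest = {
        "config": asdict(config),
        "config_digest": config.digest(),
        "selected_K": model.K,
        "cutoffs": cutoffs.to_dict(),
        "n_regions": int(len(regions)),
        "converged": report.converged,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, default=str))
    log.info("run_all: wrote %s", out)
    return manifest
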