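"""Site-level statistics on the tiny worked example.

Builds the bundled 36-site / 3-gene dataset (5 reference vs 14 case samples,
one gene carrying a planted +0.12 beta shift), computes per-site
Hodges-Lehmann shifts and one-sided rank-sum p-values, and integrates the
site evidence to gene TSS/Body regions with Stouffer's method.
"""

import numpy as np

from methyltiers import compute_site_results, integrate_gene_regions, worked_example_fixture
from methyltiers.pipeline import PipelineConfig

beta, annotations, features, truth = worked_example_fixture()
print(f"dataset: {beta.n_sites} sites x {len(beta.sample_ids)} samples; "
      f"planted gene: {truth.attrs['planted_genes']}")

results = compute_site_results(beta, config=PipelineConfig())

planted_sites = truth.loc[truth.planted, "site_id"]
mask = results.site_id.isin(planted_sites)
print(f"\nmean HL shift, planted sites: {results.loc[mask, 'hl'].mean():+.3f} "
      f"(true shift +0.12)")
print(f"mean HL shift, null sites:    {results.loc[~mask, 'hl'].mean():+.3f} (true 0)")

regions = integrate_gene_regions(results, annotations)
print("\ngene-level Stouffer integration (up-methylation):")
for row in regions.itertuples(index=False):
    print(f"  {row.feature_id} {row.kind:9s} n_sites={row.n_sites} "
          f"Z_up={row.z_up:+6.2f} p_up={row.p_up:.2e} q_up={row.q_up:.3f}")
print("\nA large positive Z with small q marks a region whose CpG sites are "
      "coherently up-methylated in the case group; the planted gene should "
      "stand out in both its TSS and Body regions.")
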