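"""Data-driven tier cutoffs from the published shift-distribution mixture.

Takes the published 8-component Gaussian mixture of the genome-wide
Hodges-Lehmann shift distribution (HSC vs AML, Illumina 450K) and derives
the maximum-probability boundaries that separate no-change / medium / high /
extreme-high up-methylation.
"""

from methyltiers import derive_tier_cutoffs
from methyltiers.reference import PUBLISHED_UP_CUTOFFS, hl_reference_mixture

mixture = hl_reference_mixture()
print("mixture components (sorted by mean):")
for mu, sd, w in zip(*(getattr(mixture.sorted_by_mean(), a) for a in ("mu", "sigma", "w"))):
    print(f"  mean {mu:+.4f}  sd {sd:.4f}  weight {w:.4f}")

cutoffs = derive_tier_cutoffs(mixture)
print("\nup-methylation tier boundaries (delta-beta):")
labels = ("at least medium", "at least high", "extreme high")
for label, got, pub in zip(labels, cutoffs.up, PUBLISHED_UP_CUTOFFS):
    print(f"  {label:16s}: {got:.4f}   (published {pub})")
print("\nEach boundary is the point where the dominating weighted component "
      "density changes — left of it one mixture component explains the shift "
      "best, right of it the next, stronger one does.")
print("\ndown-methylation boundaries (same rule on the negative side):")
print("  " + ", ".join(f"{b:.4f}" for b in cutoffs.down))
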