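"""Published genome-wide reference values from the HSC-vs-AML 450K study.

The method was developed on GEO series GSE63409: Infinium
HumanMethylation450 beta values for 485,512 CpG sites in 5 hematopoietic
stem-cell (HSC) samples from healthy donors and 14 AML samples. The study's
published summary values bundled here — the low/medium/high methylation-status
contingency tables, the 8-component Gaussian mixture fitted to the
genome-wide Hodges-Lehmann shift distribution, and the tier cutoffs that
mixture implies — serve as desk-scale inputs for validating the statistics
without downloading the array data.
"""

from __future__ import annotations

import numpy as np

from .gmm1d import GaussianMixture1D
from .site_stats import STATUS_LEVELS, ContingencyTable

#: 5 HSC (reference) vs 14 AML (case) samples, 485,512 CpG sites.
N_REF_SAMPLES = 5
N_CASE_SAMPLES = 14
N_SITES_450K = 485_512

#: Whole-genome cross-tabulation of site methylation status, HSC rows
#: (low/medium/high) by AML columns.
WHOLE_GENOME_STATUS_TABLE = ContingencyTable(
    STATUS_LEVELS,
    STATUS_LEVELS,
    np.array(
        [
            [191_043, 14_739, 2_985],
            [5_668, 11_286, 33_931],
            [2_297, 10_093, 213_470],
        ]
    ),
)

#: The same cross-tabulation split by genomic region class.
REGION_STATUS_TABLES = {
    "TSS": ContingencyTable(
        STATUS_LEVELS,
        STATUS_LEVELS,
        np.array(
            [
                [121_393, 5_693, 1_059],
                [2_101, 3_578, 8_643],
                [614, 2_741, 43_702],
            ]
        ),
    ),
    "BODY": ContingencyTable(
        STATUS_LEVELS,
        STATUS_LEVELS,
        np.array(
            [
                [73_494, 5_874, 1_300],
                [2_417, 4_639, 16_438],
                [1_087, 4_661, 117_122],
            ]
        ),
    ),
    "INTERGENIC": ContingencyTable(
        STATUS_LEVELS,
        STATUS_LEVELS,
        np.array(
            [
                [13_548, 3_295, 711],
                [1_154, 3_065, 9_893],
                [559, 2_722, 58_573],
            ]
        ),
    ),
}

#: Published Cramer's V values for the four tables above.
PUBLISHED_CRAMERS_V = {
    "whole_genome": 0.6667,
    "TSS": 0.6692,
    "BODY": 0.6658,
    "INTERGENIC": 0.6119,
}


def hl_reference_mixture() -> GaussianMixture1D:
    """The published 8-component mixture of the genome-wide HL distribution.

    Parameters as printed (4 decimals); the four heaviest components carry
    87.80% of the weight and sit near shifts of 0.00, 0.01, 0.03 and 0.04.
    """
    params = [
        # (mean, sd, weight)
        (0.0128, 0.0189, 0.2645),
        (0.0019, 0.0051, 0.2148),
        (0.0348, 0.0334, 0.2045),
        (0.0427, 0.0748, 0.1942),
        (0.1792, 0.1269, 0.0597),
        (-0.1248, 0.1107, 0.0358),
        (-0.3006, 0.1940, 0.0158),
        (0.3818, 0.1775, 0.0107),
    ]
    return GaussianMixture1D(
        mu=np.array([p[0] for p in params]),
        sigma=np.array([p[1] for p in params]),
        w=np.array([p[2] for p in params]),
    )


#: Published up-methylation tier cutoffs derived from the mixture above
#: (at-least-medium, at-least-high, extreme-high), in delta-beta units.
PUBLISHED_UP_CUTOFFS = (0.0096, 0.0372, 0.0819)
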