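"""Published summary tables from the large multi-cohort LTL EWAS that this
pipeline models, frozen as in-repo constants.

These are *inputs* for internal-consistency checks, not outputs of this
package: the top-30 CpG table carries the printed global and group-specific
meta-Z scores (rounded to one decimal as published), and the stratum table
carries the 16 stratum sample sizes.  Group sample sizes are European male
1,389; African male 697; European female 2,095; African female 1,532
(total 5,713; the consensus-network cohorts FHS+JHS+WHI total 3,329).
"""

from __future__ import annotations

import pandas as pd

GROUP_SIZES = {
    "EuropeanMale": 1389,
    "AfricanMale": 697,
    "EuropeanFemale": 2095,
    "AfricanFemale": 1532,
}

# cpg, global Z, then group Z in the order of GROUP_SIZES
_TOP30 = [
    ("cg08899667", -10.1, -5.2, -6.0, -5.1, -4.2),
    ("cg02980249", -8.7, -5.8, -4.0, -4.8, -3.4),
    ("cg02597894", -8.1, -4.8, -4.2, -5.2, -2.7),
    ("cg04368724", -8.0, -3.0, -5.0, -4.2, -4.0),
    ("cg04018738", -8.0, -3.6, -4.6, -4.4, -3.5),
    ("cg24771152", -7.8, -3.8, -4.3, -4.0, -3.7),
    ("cg20507228", -9.2, -5.4, -5.7, -3.6, -3.5),
    ("cg08972170", -9.0, -3.7, -4.9, -4.1, -5.4),
    ("cg27343900", -8.8, -6.1, -5.1, -4.2, -2.4),
    ("cg10549018", -8.6, -5.3, -3.9, -4.5, -4.0),
    ("cg26709300", -8.6, -3.9, -5.4, -2.4, -4.8),
    ("cg27106909", -8.5, -5.6, -5.1, -2.5, -3.4),
    ("cg12798040", -8.5, -5.4, -5.4, -4.1, -2.2),
    ("cg02194129", -8.3, -4.9, -5.0, -4.3, -2.6),
    ("cg19841423", -8.4, -5.0, -5.5, -3.7, -2.7),
    ("cg02810967", 8.3, 4.4, 5.4, 4.1, 2.8),
    ("cg19935065", -8.1, -3.5, -4.9, -5.0, -3.2),
    ("cg11093760", -8.1, -5.9, -4.1, -3.3, -3.1),
    ("cg19097500", -8.1, -5.4, -3.7, -3.7, -3.6),
    ("cg09626867", -8.1, -5.2, -4.1, -4.5, -2.8),
    ("cg04509882", -8.1, -5.5, -4.3, -3.3, -3.1),
    ("cg23661483", -8.0, -3.7, -4.3, -5.4, -3.3),
    ("cg01012082", -8.0, -4.7, -4.0, -4.4, -3.4),
    ("cg21461082", 8.0, 2.9, 4.4, 4.5, 4.4),
    ("cg25921609", -7.9, -5.2, -3.6, -4.5, -3.1),
    ("cg24420089", -7.8, -3.4, -5.8, -2.3, -3.5),
    ("cg07414525", -7.8, -3.5, -3.0, -3.5, -5.8),
    ("cg14817906", -7.7, -4.4, -4.1, -3.9, -3.2),
    ("cg04860432", -7.7, -5.8, -4.3, -2.3, -2.7),
    ("cg23570810", 7.7, 4.2, 4.2, 4.2, 3.0),
]

# cis-mQTL overlap of the fully-adjusted significant CpGs, against the
# shared-autosomal-probe background
MQTL_OVERLAP = {"N": 441_870, "K": 54_942, "n": 823, "k": 188}

#: Published subtelomeric positive-correlation proportions among the
#: significant CpGs (percent) and the 2x2 chi-squared p-value.
SUBTELOMERIC_POSITIVE = {"subtel_pct": 17.1, "nonsubtel_pct": 9.9, "p": 0.01}

#: Counts echoing the published proportions, for exercising the 2x2 test
#: without the (access-controlled) per-CpG supplement: 24/140 subtelomeric
#: and 68/683 non-subtelomeric CpGs positively correlated with LTL.
SUBTELOMERIC_STANDIN_COUNTS = {
    "subtel_positive": 24, "subtel_total": 140,
    "nonsubtel_positive": 68, "nonsubtel_total": 683,
}


def top30_table() -> pd.DataFrame:
    """Top-30 CpG meta-Z table (columns: cpg, z_global, one per group)."""
    cols = ["cpg", "z_global", *GROUP_SIZES]
    return pd.DataFrame(_TOP30, columns=cols)
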