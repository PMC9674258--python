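"""Reference summary tables of the integrated 46,612-trio ASD/DD cohort.

The study design this pipeline targets pooled 15,560 ASD and 31,052 DD
probands plus 5,241 unaffected siblings; these constants carry the published
per-group sample sizes and per-class DNV counts, the per-gene DD/ASD
contingency counts of the diagnostic-specificity screen, and a few per-gene
sex-resolved counts.  They serve as fixed validation inputs for the burden
and bookkeeping arithmetic — none of them is used by the statistical
machinery itself.
"""

from __future__ import annotations

import pandas as pd

#: Per-group sample sizes and DNV class counts (probands grouped by primary
#: diagnosis and by sex; NDD = ASD + DD).
COHORT_SUMMARY = pd.DataFrame(
    [
        ("ASD", 15_560, 1_661, 9_187, 1_454),
        ("DD", 31_052, 4_931, 20_588, 4_084),
        ("NDD", 46_612, 6_592, 29_775, 5_538),
        ("sibling", 5_241, 329, 2_999, 408),
        ("male", 29_704, 3_820, 18_590, 3_343),
        ("female", 16_530, 2_716, 10_986, 2_149),
    ],
    columns=["group", "samples", "dnLGD", "dnMIS", "dnMIS30"],
).set_index("group")

N_ASD = 15_560
N_DD = 31_052
N_NDD = 46_612
N_SIBLING = 5_241
N_MALE = 29_704
N_FEMALE = 16_530

#: Genome-wide totals of the harmonized DNV set (probands + siblings).
TOTAL_DNLGD = 6_921
TOTAL_DNMIS = 32_774
TOTAL_DNMIS30 = 5_946
TOTAL_DNSYN = 11_706

#: Per-gene DNV counts (LGD, MIS) in the DD and ASD cohorts for genes of the
#: DD-versus-ASD burden screen.
DD_VS_ASD_COUNTS = pd.DataFrame(
    [
        ("ARID1B", 106, 13, 12, 10),
        ("DDX3X", 50, 65, 1, 4),
        ("KMT2A", 64, 26, 6, 3),
        ("DYRK1A", 64, 16, 4, 0),
        ("SATB2", 32, 36, 0, 5),
        ("KCNQ2", 0, 45, 0, 1),
        ("GATAD2B", 39, 3, 0, 0),
        ("KIF1A", 0, 42, 0, 0),
    ],
    columns=["gene", "dd_lgd", "dd_mis", "asd_lgd", "asd_mis"],
).set_index("gene")

#: CHD8 DNV counts used for the ASD-versus-DD fold-enrichment example.
CHD8_ASD_DNVS = 18 + 12   # dnLGD + dnMIS in ASD probands
CHD8_DD_DNVS = 19 + 8     # dnLGD + dnMIS in DD probands

#: Sex-resolved DNV counts for X-linked genes of the sex-burden screen.
SEX_COUNTS = pd.DataFrame(
    [
        ("DDX3X", "X", 117, 2),
        ("HDAC8", "X", 22, 0),
        ("PDHA1", "X", 19, 2),
    ],
    columns=["gene", "chrom", "female_dnvs", "male_dnvs"],
).set_index("gene")

#: Gene universes of the three enrichment models and the Bonferroni design.
MODEL_UNIVERSE = {"CH": 18_946, "TRI": 19_618, "WPT": 18_762}
BONFERRONI_GENES = 19_618
BONFERRONI_TESTS = 7
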