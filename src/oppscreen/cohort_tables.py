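"""Published baseline tables of the motivating screening cohort.

These printed summary tables (counts and mean +/- sd summaries of the
1048-subject health-check cohort) are inputs to the statistics examples
and the reproduction script: sex x dataset and bone-mass-category x
dataset contingency tables, the sex x age-decade table, and the per-sex
BMD summaries of the 30-39-year age band.
"""

from __future__ import annotations

from .evalstats import SummaryGroup

# rows: male, female; columns: training / validation / test datasets
SEX_BY_DATASET = ((305, 62, 238),
                  (225, 38, 180))

# rows: normal, osteopenia, osteoporosis; columns: training / validation / test
BMD_CATEGORY_BY_DATASET = ((310, 60, 251),
                           (150, 30, 116),
                           (70, 10, 51))

# rows: male, female; columns: age decades <30, 30-39, ..., 80-89, >=90
AGE_GROUPS = ("<30", "30-39", "40-49", "50-59", "60-69", "70-79", "80-89", ">=90")
SEX_BY_AGE_GROUP = ((40, 85, 157, 207, 57, 41, 17, 1),
                    (20, 80, 99, 115, 60, 45, 23, 1))

# BMD (mg/cm3) summaries of the 30-39-year band, by sex
BMD_30_39_MALE = SummaryGroup(n=85, mean=160.27, sd=28.37)
BMD_30_39_FEMALE = SummaryGroup(n=80, mean=177.08, sd=23.22)

# overall per-age-decade BMD summaries (n, mean, sd) for ANOVA-style checks
BMD_BY_AGE_GROUP = (
    SummaryGroup(n=60, mean=175.96, sd=28.27),
    SummaryGroup(n=165, mean=168.42, sd=28.26),
    SummaryGroup(n=256, mean=148.27, sd=27.58),
    SummaryGroup(n=322, mean=121.83, sd=32.53),
    SummaryGroup(n=117, mean=94.46, sd=28.42),
    SummaryGroup(n=86, mean=83.83, sd=33.16),
    SummaryGroup(n=40, mean=66.49, sd=31.20),
    SummaryGroup(n=2, mean=38.78, sd=20.80),
)
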