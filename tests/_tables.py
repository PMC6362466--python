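"""Reconstruction of published one-year registry table blocks as cohorts.

The printed characteristics tables give, per level of each variable, the
case count and the number treated by mastectomy.  Expanding those cells
into a cohort of minimal case records lets the descriptive machinery be run
against the printed numbers directly."""

from conftest import make_case, make_cohort

# Table blocks: variable -> list of (level, field overrides, n, n_mastectomy)
STAGE_BLOCK = [
    ("0", dict(stage="0", behavior="in_situ"), 5451, 1439),
    ("I", dict(stage="I"), 10673, 2988),
    ("II", dict(stage="II"), 6353, 2796),
    ("III", dict(stage="III"), 1940, 1306),
    ("IV", dict(stage="IV"), 1097, 188),
    ("NA", dict(stage="NA"), 503, 85),
]

SIZE_BLOCK = [
    ("0.0-0.9", dict(tumor_size_cm=0.5), 5236, 1271),
    ("1.0-1.9", dict(tumor_size_cm=1.5), 8172, 2407),
    ("2.0-2.9", dict(tumor_size_cm=2.5), 4308, 1655),
    ("3.0-3.9", dict(tumor_size_cm=3.5), 2033, 911),
    ("4.0-4.9", dict(tumor_size_cm=4.5), 1100, 563),
    ("5.0+", dict(tumor_size_cm=5.5), 2043, 1280),
    ("NA", dict(tumor_size_cm=None), 3125, 715),
]

AGE_BLOCK = [
    ("40-49", dict(age_years=45), 4392, 1956),
    ("50-64", dict(age_years=55), 10284, 3519),
    ("65-84", dict(age_years=70), 10062, 3003),
    ("85+", dict(age_years=90), 1279, 324),
]

# post-rule-out totals as printed (total row of the eligible-cases table)
ELIGIBLE_TOTAL = (20229, 5829)

# in situ composition: DCIS vs other in situ histologies
IN_SITU_DCIS = 4666
IN_SITU_TOTAL = 5451


def cohort_from_block(block):
    records = []
    i = 0
    for _, overrides, n, events in block:
        for j in range(n):
            records.append(
                make_case(
                    f"r{i}",
                    surgery_class="mastectomy" if j < events else "bcs",
                    **overrides,
                )
            )
            i += 1
    return make_cohort(records)


def cohort_from_total(n, events):
    return cohort_from_block([("all", {}, n, events)])


def in_situ_cohort():
    """In situ cases split into DCIS (code 8500) and lobular carcinoma in
    situ (code 8520), benign on every rule-out field."""
    records = [
        make_case(f"d{i}", behavior="in_situ", stage="0", histology_icdo3=8500,
                  tumor_size_cm=1.0, nodes_positive=0)
        for i in range(IN_SITU_DCIS)
    ] + [
        make_case(f"l{i}", behavior="in_situ", stage="0", histology_icdo3=8520,
                  tumor_size_cm=1.0, nodes_positive=0)
        for i in range(IN_SITU_TOTAL - IN_SITU_DCIS)
    ]
    return make_cohort(records)
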