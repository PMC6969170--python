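"""Published per-cohort drug-usage reference.

Counts of drug-category users reported for three Dutch cohorts — a general
population cohort (n=1124 analysed), an IBD patient cohort (n=454) and an IBS
case-control cohort (n=305).  These printed counts serve two roles: worked
examples for :func:`drugmwas.io_profiles.summarize_drug_usage`, and prevalence
targets for the synthetic generator's published-cohort preset.

Counts and printed percentages are stored exactly as published.  Two printed
cells disagree with their recomputed value (anti-TNFα in the IBD cohort prints
25% where 119/454 rounds to 26%; the antibiotics row's IBS cell prints 3%
where 7/305 rounds to 2%); the discrepancies are preserved, not corrected —
recomputed percentages come from ``summarize_drug_usage``.
"""

from __future__ import annotations

import pandas as pd

COHORTS = ("population", "IBD", "IBS")

COHORT_SIZES = {"population": 1124, "IBD": 454, "IBS": 305}

#: median / mean number of drug categories per participant, as published
DRUGS_PER_PARTICIPANT = {
    "population": {"median": 0, "mean": 1.03},
    "IBD": {"median": 2, "mean": 2.35},
    "IBS": {"median": 1, "mean": 1.6},
}

#: drugs used in a single cohort only; fitted there but never meta-combined
SINGLE_COHORT_DRUGS = ("thiopurines", "anti-TNFa")

# drug -> ((n_users, printed %) for population, IBD, IBS)
_USAGE = {
    "ACE inhibitors": ((44, 4), (24, 5), (7, 2)),
    "alpha blockers": ((10, 1), (3, 1), (7, 2)),
    "AngII receptor antagonist": ((33, 3), (10, 3), (17, 6)),
    "anti-androgen oral contraceptive": ((14, 1), (2, 0), (6, 2)),
    "anti-epileptics": ((5, 0), (5, 1), (7, 2)),
    "antihistamine": ((69, 6), (15, 4), (14, 5)),
    "anti-TNFa": ((1, 0), (119, 25), (0, 0)),
    "antibiotics merged": ((13, 1), (12, 3), (7, 3)),
    "benzodiazepine derivatives related": ((25, 2), (16, 4), (13, 5)),
    "beta blockers": ((61, 5), (34, 8), (23, 8)),
    "beta sympathomimetic inhaler": ((64, 6), (16, 4), (16, 6)),
    "bisphosphonates": ((10, 1), (13, 3), (4, 1)),
    "Ca-channel blocker": ((21, 2), (10, 2), (14, 5)),
    "calcium": ((14, 1), (76, 17), (8, 3)),
    "iron preparations": ((7, 1), (15, 3), (1, 0)),
    "folic acid": ((7, 1), (31, 7), (0, 0)),
    "insulin": ((4, 0), (11, 2), (0, 0)),
    "IUD that includes hormones": ((60, 5), (5, 1), (1, 0)),
    "K-saving diuretic": ((7, 1), (9, 2), (1, 0)),
    "laxatives": ((21, 2), (30, 7), (27, 9)),
    "levothyroxine": ((26, 2), (10, 2), (5, 2)),
    "melatonin": ((6, 1), (4, 1), (1, 0)),
    "mesalazines": ((2, 0), (162, 36), (2, 1)),
    "metformin": ((15, 1), (7, 2), (6, 2)),
    "methylphenidate": ((6, 1), (5, 1), (1, 0)),
    "NSAID": ((42, 4), (21, 5), (22, 7)),
    "opiate": ((13, 1), (22, 5), (7, 2)),
    "oral anti-diabetics": ((8, 1), (8, 2), (4, 1)),
    "oral contraceptive": ((113, 10), (55, 12), (32, 11)),
    "oral steroid": ((5, 0), (79, 17), (4, 1)),
    "other antidepressant": ((9, 1), (10, 2), (3, 1)),
    "paracetamol": ((11, 1), (42, 9), (42, 14)),
    "platelet aggregation inhibitor": ((32, 3), (27, 6), (18, 6)),
    "PPI": ((93, 8), (108, 24), (48, 16)),
    "SSRI antidepressant": ((28, 2), (10, 2), (30, 10)),
    "statin": ((55, 5), (28, 6), (26, 9)),
    "steroid inhaler": ((57, 5), (17, 4), (17, 6)),
    "steroid nose spray": ((55, 5), (6, 1), (7, 2)),
    "thiazide diuretic": ((43, 4), (17, 4), (17, 6)),
    "thiopurines": ((0, 0), (151, 33), (0, 0)),
    "tricyclic antidepressant": ((10, 1), (16, 4), (2, 1)),
    "triptans": ((20, 2), (5, 1), (2, 1)),
    "vitamin D": ((14, 1), (70, 15), (3, 1)),
    "vitamin K antagonist": ((5, 0), (7, 2), (6, 2)),
}


def usage_table() -> pd.DataFrame:
    """Long-format published usage: cohort, drug, n_users, printed_percent."""
    rows = []
    for drug, cells in _USAGE.items():
        for cohort, (n_users, printed) in zip(COHORTS, cells):
            rows.append(
                {"cohort": cohort, "drug": drug, "n_users": n_users, "printed_percent": printed}
            )
    return pd.DataFrame(rows)


def prevalence(cohort: str, drug: str) -> float:
    """Published user fraction for a drug in a cohort."""
    idx = COHORTS.index(cohort)
    return _USAGE[drug][idx][0] / COHORT_SIZES[cohort]


def total_analysed() -> int:
    """Total analysed samples across the three cohorts."""
    return sum(COHORT_SIZES.values())
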