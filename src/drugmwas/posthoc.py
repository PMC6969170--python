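"""Follow-up analyses on significant drug-microbiome associations.

Three families of contrasts:

* species-stratified pathway contributions — which contributor species drive
  a pathway's association with a drug (rank test per contributor, users vs
  non-users, BH over contributors);
* feature-feature Spearman correlations (e.g., a drug-associated pathway
  against the species suspected to carry it);
* dosage and subtype contrasts — users dichotomised at a per-drug daily-dose
  threshold (high = dose >= threshold; 40 mg/day for PPIs, 1000 mg/day for
  metformin), and subtype users against participants free of the whole
  parent category.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._stats import bh_adjust, rank_sum_test, spearman
from .io_profiles import ProfileTable, SampleMetadata

log = logging.getLogger(__name__)

#: per-drug minimum daily dose (mg/day) defining the high-dose group
DOSE_THRESHOLDS = {"PPI": 40.0, "metformin": 1000.0}

MIN_SUBTYPE_USERS = 5


@dataclass
class ContrastResult:
    cohort: str
    feature: str
    contrast: str
    group_a: str
    group_b: str
    n_a: int
    n_b: int
    p: float
    direction: str
    fdr: float | None = None


def _log_relative(values: pd.DataFrame) -> pd.DataFrame:
    """Within-sample relative abundance, natural log, zeros kept at zero."""
    totals = values.sum(axis=1)
    rel = values.div(totals.where(totals > 0, 1.0), axis=0)
    arr = rel.to_numpy(dtype=float)
    out = np.where(arr > 0, np.log(np.where(arr > 0, arr, 1.0)), 0.0)
    return pd.DataFrame(out, index=values.index, columns=values.columns)


def stratified_contribution_test(
    stratified: ProfileTable,
    pathway: str,
    meta: SampleMetadata,
    drug: str,
    cohort: str | None = None,
) -> pd.DataFrame:
    """Rank-test every contributor species of one pathway, users vs non-users.

    Stratified rows follow ``"PWY|g__Genus.s__species"`` (an
    ``"|unclassified"`` contributor is allowed).  Contributor abundances are
    normalised to within-sample relative abundance over the stratified table
    and log-transformed with zeros kept, then tested two-sided with BH over
    contributors.  Output is sorted by direction and significance, one row
    per contributor.
    """
    cols = [c for c in stratified.feature_ids if c.split("|", 1)[0] == pathway]
    if not cols:
        raise ValueError(f"no stratified rows found for pathway {pathway!r}")
    idx = meta.frame.index
    if cohort is not None:
        idx = idx[meta.frame["cohort"] == cohort]
    values = _log_relative(stratified.data.loc[idx])
    exposure = meta.drugs.loc[idx, drug]
    users = idx[exposure == 1]
    non = idx[exposure == 0]
    if len(users) == 0 or len(non) == 0:
        raise ValueError(f"drug {drug!r}: users and non-users must both be present")
    rows = []
    for col in cols:
        contributor = col.split("|", 1)[1]
        u = values.loc[users, col].to_numpy()
        v = values.loc[non, col].to_numpy()
        if np.all(u == u[0]) and np.all(v == v[0]) and u[0] == v[0]:
            rows.append({"pathway": pathway, "contributor": contributor,
                         "n_users": len(u), "n_nonusers": len(v),
                         "p": 1.0, "direction": "none"})
            continue
        _, p = rank_sum_test(u, v)
        direction = "up" if np.median(u) > np.median(v) else "down"
        rows.append({"pathway": pathway, "contributor": contributor,
                     "n_users": len(u), "n_nonusers": len(v),
                     "p": p, "direction": direction})
    out = pd.DataFrame(rows)
    out["fdr"] = bh_adjust(out["p"])
    return out.sort_values(["direction", "fdr"]).reset_index(drop=True)


def feature_correlation(x, y) -> tuple[float, float]:
    """Spearman rank correlation between two feature vectors (rho, two-sided p)."""
    return spearman(x, y)


def group_contrast(
    feature: pd.Series,
    meta: SampleMetadata,
    drug: str,
    contrast: str,
    thresholds: dict | None = None,
    cohort: str | None = None,
) -> list[ContrastResult]:
    """Dose or subtype contrast on one feature.

    ``contrast='dose'``: users split at the per-drug threshold (high = dose
    >= threshold) and compared high vs low.  ``contrast='subtype'``: each
    subtype with at least 5 users compared against participants using no drug
    of the parent category.  Degenerate groupings are skipped with a logged
    reason.
    """
    if contrast not in ("dose", "subtype"):
        raise ValueError("contrast must be 'dose' or 'subtype'")
    thresholds = {**DOSE_THRESHOLDS, **(thresholds or {})}
    idx = meta.frame.index
    if cohort is not None:
        idx = idx[meta.frame["cohort"] == cohort]
    label = cohort if cohort is not None else "pooled"
    exposure = meta.drugs.loc[idx, drug]
    users = idx[exposure == 1]
    results: list[ContrastResult] = []
    if contrast == "dose":
        if drug not in thresholds:
            log.warning("drug %s has no dose threshold; dose contrast skipped", drug)
            return results
        doses = meta.dose.loc[users, drug].dropna()
        thr = thresholds[drug]
        high = doses.index[doses >= thr]
        low = doses.index[doses < thr]
        if len(high) == 0 or len(low) == 0:
            log.warning("drug %s: all users on one side of %.0f mg/day; "
                        "dose contrast skipped", drug, thr)
            return results
        u, v = feature.loc[high].to_numpy(), feature.loc[low].to_numpy()
        _, p = rank_sum_test(u, v)
        results.append(ContrastResult(
            label, str(feature.name), "high-vs-low-dose",
            f">= {thr:g} mg/day", f"< {thr:g} mg/day",
            len(high), len(low), float(p),
            "up" if np.median(u) > np.median(v) else "down",
        ))
        return results
    category_free = idx[exposure == 0]
    subtypes = meta.subtype.loc[users, drug].dropna()
    for sub, sub_users in subtypes.groupby(subtypes).groups.items():
        if len(sub_users) < MIN_SUBTYPE_USERS:
            log.warning("subtype %s of %s has %d users (< %d); skipped",
                        sub, drug, len(sub_users), MIN_SUBTYPE_USERS)
            continue
        u = feature.loc[sub_users].to_numpy()
        v = feature.loc[category_free].to_numpy()
        _, p = rank_sum_test(u, v)
        results.append(ContrastResult(
            label, str(feature.name), "subtype-vs-category-non-users",
            str(sub), f"no {drug}", len(sub_users), len(category_free), float(p),
            "up" if np.median(u) > np.median(v) else "down",
        ))
    if results:
        padj = bh_adjust([r.p for r in results])
        for r, q in zip(results, padj):
            r.fdr = float(q)
    return results
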