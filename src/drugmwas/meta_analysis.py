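"""Inverse-variance fixed-effect meta-analysis with heterogeneity gating.

Per-cohort coefficients beta_i with standard errors SE_i are combined with
weights w_i = 1/SE_i^2:

    beta_meta = sum(w_i beta_i) / sum(w_i)
    SE_meta   = (sum w_i)^(-1/2)
    z_meta    = beta_meta / SE_meta,   p_meta = 2 Phi(-|z_meta|)

Benjamini-Hochberg adjustment runs within a declared family (feature kind x
model mode by default).  Associations reaching FDR < 0.1 are tested for
cross-cohort heterogeneity with Cochran's Q = sum w_i (beta_i - beta_meta)^2,
referred to chi-square with k-1 degrees of freedom.  An association is called
significant when FDR < 0.05 AND the heterogeneity p-value exceeds 0.05;
FDR < 0.05 with het_p <= 0.05 is labelled heterogeneous instead.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from ._stats import bh_adjust

FDR_SIGNIFICANT = 0.05
FDR_HET_TRIGGER = 0.10
HET_P_GATE = 0.05

STATUSES = ("significant", "heterogeneous", "not-significant", "not-combined")


@dataclass
class MetaAssociation:
    drug: str
    feature: str
    mode: str
    k: int
    beta_meta: float
    se_meta: float
    z_meta: float
    p_meta: float
    fdr: float | None = None
    q: float | None = None
    het_p: float | None = None
    status: str = "not-significant"


def inverse_variance_meta(assocs: pd.DataFrame) -> MetaAssociation:
    """Fixed-effect combination of one (drug, feature, mode)'s cohort rows.

    Rows with SE <= 0 are dropped (flagged upstream as degenerate).  With
    fewer than two usable cohorts the association is emitted uncombined.
    """
    drug = assocs["drug"].iloc[0]
    feature = assocs["feature"].iloc[0]
    mode = assocs["mode"].iloc[0]
    usable = assocs[assocs["se"] > 0]
    k = len(usable)
    if k < 2:
        return MetaAssociation(drug, feature, mode, k,
                               np.nan, np.nan, np.nan, np.nan,
                               status="not-combined")
    w = 1.0 / usable["se"].to_numpy() ** 2
    b = usable["beta"].to_numpy()
    beta_meta = float((w * b).sum() / w.sum())
    se_meta = float(w.sum() ** -0.5)
    z = beta_meta / se_meta
    p = float(2 * stats.norm.sf(abs(z)))
    return MetaAssociation(drug, feature, mode, k, beta_meta, se_meta, float(z), p)


def cochran_q(assocs: pd.DataFrame, meta: MetaAssociation) -> tuple[float, float]:
    """Cochran's Q and its chi-square(k-1) upper-tail p-value."""
    usable = assocs[assocs["se"] > 0]
    if len(usable) < 2:
        raise ValueError("Cochran's Q requires at least two cohorts")
    w = 1.0 / usable["se"].to_numpy() ** 2
    b = usable["beta"].to_numpy()
    q = float((w * (b - meta.beta_meta) ** 2).sum())
    het_p = float(stats.chi2.sf(q, len(usable) - 1))
    return q, het_p


def meta_analyze(
    cohort_table: pd.DataFrame,
    family: tuple[str, ...] = ("mode",),
    fdr_significant: float = FDR_SIGNIFICANT,
    fdr_het_trigger: float = FDR_HET_TRIGGER,
    het_p_gate: float = HET_P_GATE,
) -> pd.DataFrame:
    """Meta-analyse a long cohort-association table and apply the gate.

    ``family`` names the grouping columns that define each BH adjustment
    family (the feature-kind split is handled by the caller running taxa and
    pathways separately; within a kind, each mode forms one family by
    default).  Degenerate cohort fits (flagged) never enter the combination.
    Returns one row per (drug, feature, mode) with per-cohort beta/SE kept in
    wide columns.
    """
    tab = cohort_table[~cohort_table["flags"].str.contains("degenerate", na=False)]
    rows = []
    for (drug, feature, mode), grp in tab.groupby(["drug", "feature", "mode"], sort=False):
        m = inverse_variance_meta(grp)
        row = {"drug": drug, "feature": feature, "mode": mode, "k": m.k,
               "beta_meta": m.beta_meta, "se_meta": m.se_meta,
               "z_meta": m.z_meta, "p_meta": m.p_meta, "status": m.status}
        for _, r in grp.iterrows():
            row[f"beta_{r['cohort']}"] = r["beta"]
            row[f"se_{r['cohort']}"] = r["se"]
        row["_grp"] = grp
        rows.append(row)
    out = pd.DataFrame(rows)
    if out.empty:
        return out
    combined = out["status"] != "not-combined"
    out["fdr"] = np.nan
    if family:
        fam_groups = list(out[combined].groupby(list(family)).groups.values())
    else:
        fam_groups = [out.index[combined]]
    for fam_idx in fam_groups:
        out.loc[fam_idx, "fdr"] = bh_adjust(out.loc[fam_idx, "p_meta"])
    out["q"] = np.nan
    out["het_p"] = np.nan
    for i in out.index[combined]:
        if out.at[i, "fdr"] < fdr_het_trigger:
            m = MetaAssociation(out.at[i, "drug"], out.at[i, "feature"],
                                out.at[i, "mode"], int(out.at[i, "k"]),
                                out.at[i, "beta_meta"], out.at[i, "se_meta"],
                                out.at[i, "z_meta"], out.at[i, "p_meta"])
            q, het_p = cochran_q(out.at[i, "_grp"], m)
            out.at[i, "q"] = q
            out.at[i, "het_p"] = het_p
    sig = combined & (out["fdr"] < fdr_significant)
    out.loc[combined, "status"] = "not-significant"
    out.loc[sig & (out["het_p"] > het_p_gate), "status"] = "significant"
    out.loc[sig & (out["het_p"] <= het_p_gate), "status"] = "heterogeneous"
    return out.drop(columns=["_grp"])


def significance_gate(meta_table: pd.DataFrame,
                      fdr_significant: float = FDR_SIGNIFICANT,
                      het_p_gate: float = HET_P_GATE) -> pd.DataFrame:
    """(Re)annotate status on an already meta-analysed table.

    Heterogeneity is only consulted where it was evaluated (FDR below the
    trigger); FDR >= 0.05 rows are not-significant regardless.
    """
    out = meta_table.copy()
    combined = out["status"] != "not-combined"
    sig = combined & (out["fdr"] < fdr_significant)
    out.loc[combined, "status"] = "not-significant"
    out.loc[sig & (out["het_p"] > het_p_gate), "status"] = "significant"
    out.loc[sig & (out["het_p"] <= het_p_gate), "status"] = "heterogeneous"
    return out
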