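"""Per-cohort multivariable linear models for drug-feature associations.

For every cohort and drug category with enough users, an ordinary
least-squares model relates each (transformed) microbial feature to the drug
exposure indicator, adjusting for age, sex, BMI, sequencing depth and disease
labels (IBS yes/no in the population and IBS cohorts; CD/UC/IBDU dummies in
the IBD cohort, CD as reference).  Two modes are provided:

* ``single`` — one model per drug: feature ~ drug + covariates;
* ``multi``  — one model per cohort containing *all* eligible drug
  indicators simultaneously; each drug's coefficient is extracted from that
  joint fit.  This is the polypharmacy-adjusted analysis.

All features sharing a design are solved in one vectorised least-squares
call; coefficient standard errors come from the unscaled covariance
sigma^2 (X'X)^-1 with residual degrees of freedom n - rank(X).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .feature_engineering import FeatureMatrix
from .io_profiles import SampleMetadata

log = logging.getLogger(__name__)

MIN_USERS_PER_COHORT = 5
MODES = ("single", "multi")

#: sequencing depth enters the design scaled to millions of reads
DEPTH_SCALE = 1e6


@dataclass
class CohortAssociation:
    cohort: str
    drug: str
    feature: str
    mode: str
    beta: float
    se: float
    t: float
    p: float
    n: int
    n_users: int
    covariates: tuple
    flags: str = ""


def _covariate_design(meta: SampleMetadata, idx) -> pd.DataFrame:
    """Host covariates for one cohort: age, sex, BMI, depth, disease dummies."""
    frame = meta.frame.loc[idx]
    x = pd.DataFrame(index=frame.index)
    x["age"] = frame["age"].astype(float)
    x["sex_female"] = (frame["sex"] == "female").astype(float)
    x["bmi"] = frame["bmi"].astype(float)
    x["seq_depth_m"] = frame["seq_depth"].astype(float) / DEPTH_SCALE
    subtypes = frame.get("ibd_subtype")
    if subtypes is not None and (subtypes.fillna("none") != "none").any():
        # IBD cohort: CD is the reference level
        x["disease_UC"] = (subtypes == "UC").astype(float)
        x["disease_IBDU"] = (subtypes == "IBDU").astype(float)
    elif "ibs_status" in frame.columns:
        x["ibs_yes"] = (frame["ibs_status"] == "yes").astype(float)
    return x


def eligible_drugs(meta: SampleMetadata, cohort: str,
                   min_users: int = MIN_USERS_PER_COHORT) -> list[str]:
    """Drugs with at least ``min_users`` users in the cohort."""
    idx = meta.frame.index[meta.frame["cohort"] == cohort]
    counts = meta.drugs.loc[idx].sum(axis=0)
    return [d for d in meta.drugs.columns if counts[d] >= min_users]


def _complete_rows(meta: SampleMetadata, cohort: str) -> pd.Index:
    idx = meta.frame.index[meta.frame["cohort"] == cohort]
    covars = meta.frame.loc[idx, ["age", "bmi", "seq_depth"]]
    complete = idx[covars.notna().all(axis=1)]
    dropped = len(idx) - len(complete)
    if dropped:
        log.warning("cohort %s: %d samples dropped from model fitting "
                    "(missing age/BMI/depth)", cohort, dropped)
    return complete


def _solve(x: pd.DataFrame, y: np.ndarray, drug_cols: list[str],
           droppable: list[str]) -> tuple[pd.DataFrame, np.ndarray, int, str]:
    """Full-rank OLS solve after the drop-and-flag collinearity policy.

    ``droppable`` lists drug columns that may be removed (fewest users first)
    to restore full rank.  Returns the possibly reduced design, coefficient
    matrix, rank and a flag string.
    """
    flags = ""
    xm = x.to_numpy(dtype=float)
    rank = np.linalg.matrix_rank(xm)
    order = list(droppable)
    while rank < xm.shape[1] and order:
        victim = order.pop(0)
        x = x.drop(columns=[victim])
        xm = x.to_numpy(dtype=float)
        rank = np.linalg.matrix_rank(xm)
        flags = "collinear-dropped"
        log.warning("dropped collinear covariate %s", victim)
    if rank < xm.shape[1]:
        flags = (flags + ";" if flags else "") + "rank-deficient"
    beta, _, rank, _ = np.linalg.lstsq(xm, y, rcond=None)
    return x, beta, int(rank), flags


def _assemble(x: pd.DataFrame, beta: np.ndarray, y: np.ndarray, rank: int,
              col: str) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, int]:
    """Per-feature beta/SE/t/p for one design column, vectorised over features."""
    xm = x.to_numpy(dtype=float)
    n = xm.shape[0]
    dof = n - rank
    resid = y - xm @ beta
    sigma2 = (resid ** 2).sum(axis=0) / dof
    xtx_inv = np.linalg.pinv(xm.T @ xm)
    j = x.columns.get_loc(col)
    se = np.sqrt(np.maximum(sigma2 * xtx_inv[j, j], 0.0))
    b = beta[j]
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, b / se, 0.0)
    p = 2 * stats.t.sf(np.abs(t), dof)
    return b, se, t, p, dof


def fit_feature_model(
    y,
    meta: SampleMetadata,
    drug: str,
    mode: str = "single",
    cohort: str | None = None,
) -> CohortAssociation:
    """Fit one cohort's model for one feature and return the drug's row.

    ``y`` is the transformed feature vector indexed by sample.  With
    ``mode='multi'`` all other eligible drugs in the cohort enter as
    covariates and the requested drug's coefficient is extracted.
    """
    if cohort is None:
        cohorts = meta.frame["cohort"].unique()
        if len(cohorts) != 1:
            raise ValueError("metadata spans multiple cohorts; pass cohort=")
        cohort = cohorts[0]
    if not isinstance(y, pd.Series):
        cidx = meta.frame.index[meta.frame["cohort"] == cohort]
        y = pd.Series(np.asarray(y, dtype=float), index=cidx)
    feature = y.name if y.name is not None else "feature"
    table = _fit_cohort(
        pd.DataFrame({feature: y}), meta, cohort, mode,
        drugs=[drug],
    )
    rows = table[table["drug"] == drug] if not table.empty else table
    if rows.empty:
        raise ValueError(f"drug {drug!r} could not be fitted in cohort {cohort!r}")
    r = rows.iloc[0]
    return CohortAssociation(
        cohort=r["cohort"], drug=r["drug"], feature=r["feature"], mode=r["mode"],
        beta=r["beta"], se=r["se"], t=r["t"], p=r["p"], n=int(r["n"]),
        n_users=int(r["n_users"]), covariates=tuple(r["covariates"].split(",")),
        flags=r["flags"],
    )


def _fit_cohort(features: pd.DataFrame, meta: SampleMetadata, cohort: str,
                mode: str, drugs: list[str] | None = None,
                min_users: int = MIN_USERS_PER_COHORT) -> pd.DataFrame:
    if mode not in MODES:
        raise ValueError(f"mode must be one of {MODES}")
    idx = _complete_rows(meta, cohort)
    idx = idx.intersection(features.index)
    covars = _covariate_design(meta, idx)
    elig = eligible_drugs(meta, cohort, min_users)
    test_drugs = drugs if drugs is not None else elig
    yall = features.loc[idx]
    y = yall.to_numpy(dtype=float)
    degenerate = yall.std(axis=0).to_numpy() == 0
    rows = []
    user_counts = meta.drugs.loc[idx].sum(axis=0)

    def emit(drug, x, beta, rank, flags, n_users):
        b, se, t, p, dof = _assemble(x, beta, y, rank, drug)
        covariate_names = ",".join(c for c in x.columns if c not in ("const", drug))
        for f_i, feat in enumerate(yall.columns):
            fl = flags
            if degenerate[f_i]:
                fl = (fl + ";" if fl else "") + "degenerate-constant-y"
            rows.append(
                {"cohort": cohort, "drug": drug, "feature": feat, "mode": mode,
                 "beta": float(b[f_i]), "se": float(se[f_i]), "t": float(t[f_i]),
                 "p": float(p[f_i]), "n": len(idx), "n_users": int(n_users),
                 "covariates": covariate_names, "flags": fl}
            )

    if mode == "single":
        for drug in test_drugs:
            dvec = meta.drugs.loc[idx, drug].astype(float)
            nu = int(dvec.sum())
            if nu < 1 or nu == len(idx):
                log.warning("cohort %s drug %s: no users or no non-users; skipped",
                            cohort, drug)
                continue
            x = pd.concat(
                [pd.Series(1.0, index=idx, name="const"), dvec.rename(drug), covars],
                axis=1,
            )
            if len(idx) < x.shape[1] + 2:
                log.warning("cohort %s drug %s: too few samples for the design; skipped",
                            cohort, drug)
                continue
            x, beta, rank, flags = _solve(x, y, [drug], droppable=[])
            emit(drug, x, beta, flags=flags, rank=rank, n_users=nu)
    else:
        include = sorted(set(elig) | {d for d in test_drugs if d in meta.drugs.columns})
        include = [d for d in include
                   if 0 < user_counts[d] < len(idx)]
        dmat = meta.drugs.loc[idx, include].astype(float)
        x = pd.concat([pd.Series(1.0, index=idx, name="const"), covars, dmat], axis=1)
        if len(idx) < x.shape[1] + 2:
            raise ValueError(
                f"cohort {cohort!r}: n={len(idx)} too small for the multi-drug design "
                f"({x.shape[1]} columns)"
            )
        droppable = sorted(include, key=lambda d: user_counts[d])
        x, beta, rank, flags = _solve(x, y, include, droppable=droppable)
        for drug in test_drugs:
            if drug not in x.columns:
                log.warning("cohort %s drug %s: absent from multi-drug design; skipped",
                            cohort, drug)
                continue
            emit(drug, x, beta, flags=flags, rank=rank,
                 n_users=int(user_counts[drug]))
    return pd.DataFrame(rows)


def run_cohort_associations(
    features: FeatureMatrix,
    meta: SampleMetadata,
    mode: str = "single",
    min_users: int = MIN_USERS_PER_COHORT,
) -> pd.DataFrame:
    """Fit every (cohort, eligible drug, feature) association.

    Drugs are fitted wherever they have at least ``min_users`` users in the
    cohort; the ``meta_eligible`` column marks drugs fitted in at least two
    cohorts (single-cohort drugs are fitted but never meta-combined).
    Constant-feature fits are flagged degenerate and excluded from
    meta-analysis downstream.
    """
    tables = []
    cohorts = list(meta.frame["cohort"].unique())
    fitted_in = {}
    for cohort in cohorts:
        elig = eligible_drugs(meta, cohort, min_users)
        for d in elig:
            fitted_in.setdefault(d, set()).add(cohort)
        tables.append(_fit_cohort(features.data, meta, cohort, mode,
                                  min_users=min_users))
    out = pd.concat(tables, ignore_index=True)
    out["meta_eligible"] = out["drug"].map(
        lambda d: len(fitted_in.get(d, ())) >= 2
    ) & ~out["flags"].str.contains("degenerate")
    return out
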