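"""Community-level statistics: diversity, dissimilarity and PERMANOVA.

Shannon index and Bray-Curtis dissimilarities are computed on taxonomic
end-point compositions.  PERMANOVA partitions the Gower-centred inner-product
form of a distance matrix against a one-term design (categorical grouping or
a single numeric regressor such as the number of drugs used) and assesses the
pseudo-F by whole-row label permutation; the permutation p-value always
includes the observed statistic, so it can never be exactly zero.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from ._stats import bh_adjust, rank_sum_test, spearman
from .io_profiles import SampleMetadata

DEFAULT_N_PERM = 10_000


@dataclass
class PermanovaResult:
    grouping: str
    r2: float
    pseudo_f: float
    p: float
    n_permutations: int


def shannon_index(abund) -> float:
    """Shannon diversity H = -sum p_i ln p_i (nats) over the nonzero entries,
    after renormalising the vector to sum 1."""
    p = np.asarray(abund, dtype=float)
    if np.any(p < 0):
        raise ValueError("abundances must be non-negative")
    total = p.sum()
    if total == 0:
        raise ValueError("all-zero abundance vector")
    p = p[p > 0] / total
    return float(-(p * np.log(p)).sum())


def shannon_per_sample(data: pd.DataFrame) -> pd.Series:
    """Shannon index for each row of a samples x features table."""
    return pd.Series(
        [shannon_index(row) for row in data.to_numpy()], index=data.index, name="shannon"
    )


def bray_curtis(x, y) -> float:
    """Bray-Curtis dissimilarity sum|x-y| / sum(x+y)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("vectors must have equal length")
    denom = float((x + y).sum())
    if denom == 0:
        raise ValueError("Bray-Curtis undefined for two all-zero vectors")
    return float(np.abs(x - y).sum() / denom)


def bray_curtis_matrix(data: pd.DataFrame) -> pd.DataFrame:
    """Pairwise Bray-Curtis dissimilarities between the rows of ``data``."""
    if (data.sum(axis=1) == 0).any():
        bad = data.sum(axis=1).idxmin()
        raise ValueError(f"sample {bad!r} is all-zero; dissimilarity undefined")
    dm = squareform(pdist(data.to_numpy(dtype=float), metric="braycurtis"))
    return pd.DataFrame(dm, index=data.index, columns=data.index)


def _gower_center(dist: np.ndarray) -> np.ndarray:
    a = -0.5 * dist ** 2
    return a - a.mean(axis=0, keepdims=True) - a.mean(axis=1, keepdims=True) + a.mean()


def _design_hat(grouping: pd.Series) -> tuple[np.ndarray, int]:
    """Centered hat matrix and model df for a one-term design."""
    if grouping.dtype.kind in "if":
        x = grouping.to_numpy(dtype=float)[:, None]
        x = x - x.mean(axis=0)
    else:
        x = pd.get_dummies(grouping, drop_first=True).to_numpy(dtype=float)
        x = x - x.mean(axis=0)
    q, r = np.linalg.qr(x)
    rank = int(np.sum(np.abs(np.diag(r)) > 1e-10 * max(1.0, np.abs(np.diag(r)).max())))
    q = q[:, :rank]
    return q @ q.T, rank


def permanova(
    dist: pd.DataFrame,
    grouping: pd.Series,
    n_perm: int = DEFAULT_N_PERM,
    seed: int | None = None,
) -> PermanovaResult:
    """One-term PERMANOVA on a symmetric dissimilarity matrix.

    ``grouping`` may be a factor (dummy-coded) or numeric (single regressor).
    The p-value is ``(1 + #{F_perm >= F_obs}) / (1 + n_perm)``.
    """
    d = dist.to_numpy(dtype=float)
    if d.shape[0] != d.shape[1] or not np.allclose(d, d.T, atol=1e-10):
        raise ValueError("distance matrix must be square and symmetric")
    if not np.allclose(np.diag(d), 0, atol=1e-10):
        raise ValueError("distance matrix must have a zero diagonal")
    grouping = grouping.loc[dist.index]
    if grouping.nunique() < 2:
        raise ValueError("grouping is constant; PERMANOVA undefined")
    n = d.shape[0]
    g = _gower_center(d)
    hat, df_model = _design_hat(grouping)
    ss_total = float(np.trace(g))

    def _ss_model(gm: np.ndarray) -> float:
        return float(np.sum(hat * gm))  # trace(H G) for symmetric G

    def _f_from_ss(ss_model: float) -> float:
        ss_resid = ss_total - ss_model
        if ss_resid <= 1e-12 * max(1.0, abs(ss_total)):
            return float("inf")  # perfect separation
        return (ss_model / df_model) / (ss_resid / (n - df_model - 1))

    # ss_total is permutation-invariant, so F >= F_obs iff SS_model >= SS_model_obs;
    # comparing on SS_model avoids a numerically degenerate division
    ss_obs = _ss_model(g)
    f_obs = _f_from_ss(ss_obs)
    tie_tol = 1e-10 * max(1.0, abs(ss_total))
    if math.factorial(n) <= n_perm:
        # small samples: exhaustive enumeration over all relabelings
        count = 0
        total = 0
        for perm in itertools.permutations(range(n)):
            if _ss_model(g[np.ix_(perm, perm)]) >= ss_obs - tie_tol:
                count += 1
            total += 1
        p = count / total  # identity permutation included
        n_perm = total
    else:
        rng = np.random.default_rng(seed)
        count = 0
        for _ in range(n_perm):
            perm = rng.permutation(n)
            if _ss_model(g[np.ix_(perm, perm)]) >= ss_obs - tie_tol:
                count += 1
        p = (1 + count) / (1 + n_perm)
    ss_model = ss_obs
    r2 = ss_model / ss_total if ss_total > 0 else np.nan
    return PermanovaResult(str(grouping.name), float(r2), float(f_obs), float(p), n_perm)


def richness_drug_associations(
    h: pd.Series,
    meta: SampleMetadata,
    min_users: int = 1,
) -> pd.DataFrame:
    """Per-cohort tests of diversity against each drug and the drug count.

    For each drug: two-sided two-sample rank test of Shannon H between users
    and non-users.  For the polypharmacy burden: Spearman correlation of H
    with the number of drugs used, plus the OLS slope with its 95% CI.
    BH adjustment is applied within each cohort (drug tests only).
    """
    rows = []
    for cohort, idx in meta.frame.groupby("cohort").groups.items():
        hc = h.loc[idx]
        drugs = meta.drugs.loc[idx]
        cohort_rows = []
        for drug in drugs.columns:
            users = hc[drugs[drug] == 1]
            non = hc[drugs[drug] == 0]
            if len(users) < min_users or len(non) < 1 or len(users) < 1:
                continue
            stat, p = rank_sum_test(users, non)
            cohort_rows.append(
                {"cohort": cohort, "variable": drug, "test": "rank-sum",
                 "statistic": stat, "p": p, "n_users": int(len(users))}
            )
        if cohort_rows:
            padj = bh_adjust([r["p"] for r in cohort_rows])
            for r, q in zip(cohort_rows, padj):
                r["fdr"] = float(q)
        rows.extend(cohort_rows)
        counts = drugs.sum(axis=1).astype(float)
        if counts.nunique() > 1 and hc.nunique() > 1:
            rho, p_rho = spearman(counts, hc)
            x = np.column_stack([np.ones(len(counts)), counts.to_numpy()])
            beta, *_ = np.linalg.lstsq(x, hc.to_numpy(), rcond=None)
            resid = hc.to_numpy() - x @ beta
            dof = len(counts) - 2
            sigma2 = float(resid @ resid) / dof
            cov = sigma2 * np.linalg.inv(x.T @ x)
            se = float(np.sqrt(cov[1, 1]))
            from scipy import stats as _st
            tcrit = _st.t.ppf(0.975, dof)
            rows.append(
                {"cohort": cohort, "variable": "n_drugs", "test": "spearman",
                 "statistic": float(rho), "p": float(p_rho), "n_users": int(len(counts)),
                 "slope": float(beta[1]), "slope_lo": float(beta[1] - tcrit * se),
                 "slope_hi": float(beta[1] + tcrit * se)}
            )
    return pd.DataFrame(rows)
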