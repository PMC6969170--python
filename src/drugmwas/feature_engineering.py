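"""Taxonomic end-points, prevalence/abundance filters and transforms.

The unit of taxonomic analysis is the *end-point*: the lowest observed,
non-redundant clade of each branch of the taxonomy implied by the lineage
labels.  A clade is redundant when a descendant clade is itself observed in
the table; only the observed leaves are kept.  End-points are then filtered
per cohort (prevalence > 10% and mean abundance >= 0.01% required in every
cohort) and variance-stabilised with the arcsine-square-root transform.
Pathways are converted to within-sample relative abundance, filtered on
prevalence and natural-log transformed with zeros kept at zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_profiles import ProfileTable

RANK_PREFIXES = ("k__", "p__", "c__", "o__", "f__", "g__", "s__", "t__")

DEFAULT_MIN_PREVALENCE = 0.10
DEFAULT_MIN_MEAN_ABUND = 1e-4  # 0.01% as a proportion

TRANSFORMS = ("raw-proportion", "arcsine-sqrt", "log-kept-zeros", "relative-abundance")


@dataclass
class FeatureMatrix:
    """Samples x features matrix carrying its transform tag and provenance."""

    data: pd.DataFrame
    transform: str
    provenance: list = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.transform not in TRANSFORMS:
            raise ValueError(f"unknown transform tag {self.transform!r}")
        vals = self.data.to_numpy()
        if self.transform == "arcsine-sqrt" and (vals.min() < 0 or vals.max() > np.pi / 2 + 1e-9):
            raise ValueError("arcsine-sqrt values must lie in [0, pi/2]")
        if self.transform == "raw-proportion" and (vals.min() < 0 or vals.max() > 1 + 1e-9):
            raise ValueError("proportions must lie in [0, 1]")


def _validate_lineages(labels) -> None:
    for lab in labels:
        for part in lab.split("|"):
            if not part.startswith(RANK_PREFIXES):
                raise ValueError(f"lineage label {lab!r} lacks a rank prefix on {part!r}")


def extract_endpoints(taxa: ProfileTable, tol: float = 1e-8) -> tuple[ProfileTable, pd.DataFrame]:
    """Keep only observed taxonomy leaves; drop redundant internal clades.

    A clade is internal (redundant) when another observed label extends it.
    Internal clades whose abundance exceeds the sum of their observed children
    by more than ``tol`` in at least one sample are flagged in the report as
    carrying unclassified residual mass, but are dropped all the same.  A
    child exceeding its parent by more than ``tol`` produces a warning row.
    """
    labels = list(taxa.data.columns)
    _validate_lineages(labels)
    label_set = set(labels)
    prefixes = {}
    for lab in labels:
        parts = lab.split("|")
        for depth in range(1, len(parts)):
            prefixes.setdefault("|".join(parts[:depth]), []).append(lab)
    leaves = [lab for lab in labels if lab not in prefixes]
    report_rows = []
    for internal, descendants in prefixes.items():
        if internal not in label_set:
            continue
        children = [
            d for d in descendants
            if d.count("|") > internal.count("|") and d.startswith(internal + "|")
        ]
        # residual check against the *observed* direct subtree mass
        child_depth = internal.count("|") + 1
        direct = [d for d in children if d.count("|") == child_depth]
        if direct:
            residual = taxa.data[internal] - taxa.data[direct].sum(axis=1)
            worst = float(residual.max())
            if worst > tol:
                report_rows.append(
                    {"feature": internal, "issue": "unclassified-residual", "value": worst}
                )
            if float(residual.min()) < -tol:
                report_rows.append(
                    {"feature": internal, "issue": "children-exceed-parent",
                     "value": float(residual.min())}
                )
    endpoints = ProfileTable(taxa.data[leaves], "taxa")
    report = pd.DataFrame(report_rows, columns=["feature", "issue", "value"])
    return endpoints, report


def filter_taxa(
    endpoints: ProfileTable,
    cohorts: pd.Series,
    min_prevalence: float = DEFAULT_MIN_PREVALENCE,
    min_mean_abund: float = DEFAULT_MIN_MEAN_ABUND,
) -> tuple[ProfileTable, pd.DataFrame]:
    """Per-cohort prevalence/abundance filter, conjoined across cohorts.

    A taxon is kept iff in EVERY cohort it is present (>0) in strictly more
    than ``min_prevalence`` of that cohort's samples AND its mean proportion
    is at least ``min_mean_abund``.  The report lists each removed taxon with
    the first failing cohort and criterion.
    """
    cohorts = cohorts.loc[endpoints.data.index]
    keep = []
    removed = []
    groups = {c: g for c, g in endpoints.data.groupby(cohorts)}
    for cohort, g in groups.items():
        if len(g) == 0:
            raise ValueError(f"cohort {cohort!r} has no samples")
    for taxon in endpoints.data.columns:
        verdict = None
        for cohort, g in groups.items():
            col = g[taxon]
            prev = float((col > 0).mean())
            if prev <= min_prevalence:
                verdict = {"feature": taxon, "decision": "removed",
                           "failing_cohort": cohort, "failing_criterion": "prevalence",
                           "value": prev}
                break
            mean = float(col.mean())
            if mean < min_mean_abund:
                verdict = {"feature": taxon, "decision": "removed",
                           "failing_cohort": cohort, "failing_criterion": "mean-abundance",
                           "value": mean}
                break
        if verdict is None:
            keep.append(taxon)
        else:
            removed.append(verdict)
    if not keep:
        raise ValueError("no taxa survive the per-cohort filters")
    report = pd.DataFrame(removed,
                          columns=["feature", "decision", "failing_cohort",
                                   "failing_criterion", "value"])
    return ProfileTable(endpoints.data[keep], "taxa"), report


def transform_taxa(filtered) -> FeatureMatrix:
    """Arcsine-square-root transform: p -> arcsin(sqrt(p)), elementwise."""
    data = filtered.data if hasattr(filtered, "data") else filtered
    vals = data.to_numpy(dtype=float)
    if vals.min() < 0 or vals.max() > 1 + 1e-12:
        raise ValueError("arcsine-sqrt transform requires proportions in [0, 1]")
    out = np.arcsin(np.sqrt(np.clip(vals, 0.0, 1.0)))
    return FeatureMatrix(
        pd.DataFrame(out, index=data.index, columns=data.columns),
        "arcsine-sqrt",
        ["transform_taxa"],
    )


def prepare_pathways(
    pathways: ProfileTable,
    cohorts: pd.Series,
    min_prevalence: float = DEFAULT_MIN_PREVALENCE,
    *,
    log_base: str = "e",
    pseudocount: float | None = None,
) -> tuple[FeatureMatrix, pd.DataFrame]:
    """Relative abundance -> per-cohort prevalence filter -> log, zeros kept.

    Each sample's pathway vector is divided by its total; pathways whose
    prevalence is <= ``min_prevalence`` in any cohort are dropped; strictly
    positive entries are natural-log transformed (``log_base='10'`` switches
    to log10; a pseudocount, if given, is added everywhere before logging so
    no zeros remain).  Zeros stay exactly zero in the default configuration.
    """
    cohorts = cohorts.loc[pathways.data.index]
    totals = pathways.data.sum(axis=1)
    if (totals == 0).any():
        bad = totals[totals == 0].index[0]
        raise ValueError(f"sample {bad!r} has an all-zero pathway vector")
    rel = pathways.data.div(totals, axis=0)
    removed = []
    keep = []
    groups = {c: g for c, g in rel.groupby(cohorts)}
    for pwy in rel.columns:
        verdict = None
        for cohort, g in groups.items():
            prev = float((g[pwy] > 0).mean())
            if prev <= min_prevalence:
                verdict = {"feature": pwy, "decision": "removed",
                           "failing_cohort": cohort, "failing_criterion": "prevalence",
                           "value": prev}
                break
        if verdict is None:
            keep.append(pwy)
        else:
            removed.append(verdict)
    if not keep:
        raise ValueError("no pathways survive the prevalence filter")
    kept = rel[keep]
    log = np.log10 if log_base == "10" else np.log
    vals = kept.to_numpy(dtype=float)
    if pseudocount is not None:
        out = log(vals + pseudocount)
        tag = "relative-abundance"
    else:
        out = np.where(vals > 0, log(np.where(vals > 0, vals, 1.0)), 0.0)
        tag = "log-kept-zeros"
    report = pd.DataFrame(removed,
                          columns=["feature", "decision", "failing_cohort",
                                   "failing_criterion", "value"])
    return (
        FeatureMatrix(pd.DataFrame(out, index=kept.index, columns=kept.columns),
                      tag, ["prepare_pathways"]),
        report,
    )
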