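"""Reading, writing and screening of metagenomic profile tables and metadata.

Three profile-table dialects are supported, all plain TSV with features as
rows and samples as columns (a sample-major flag covers the transposed
layout):

* taxonomic relative abundances with pipe-delimited lineage labels
  (``k__Bacteria|p__Firmicutes|...``), values in percent 0-100 as emitted by
  MetaPhlAn-style profilers;
* pathway abundances (reads-per-kilobase), optionally carrying
  species-stratified rows (``PWY-xxx|g__Genus.s__species``) interleaved with
  the community totals, HUMAnN-style;
* antibiotic-resistance marker quantifications (normalized read counts,
  ShortBRED-style) plus a marker-to-gene map.

Sample metadata travels in a single TSV with drug exposure, dose and subtype
columns identified by the ``drug__`` / ``dose__`` / ``subtype__`` prefixes.

This module also applies the sample exclusion rules used before any analysis
(stoma/pouch/short-bowel patients; sequencing depth below 10 million reads)
and produces the per-cohort drug-usage summary.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._stats import round_half_away

PROFILE_KINDS = ("taxa", "pathway", "stratified", "ar_marker")

DEFAULT_MIN_DEPTH = 10_000_000

_META_COLUMNS = [
    "cohort",
    "age",
    "sex",
    "bmi",
    "seq_depth",
    "ibs_status",
    "ibd_subtype",
    "stoma_pouch",
]


@dataclass
class ProfileTable:
    """Samples x features abundance matrix with a feature-kind tag.

    ``data`` holds samples as rows and features as columns (the in-memory
    orientation; files are feature-major).  All values are non-negative and
    missing cells are zero-filled at read time.
    """

    data: pd.DataFrame
    kind: str

    def __post_init__(self) -> None:
        if self.kind not in PROFILE_KINDS:
            raise ValueError(f"unknown profile kind {self.kind!r}; expected one of {PROFILE_KINDS}")
        if self.data.shape[1] == 0 or self.data.shape[0] == 0:
            raise ValueError("empty profile table")
        if self.data.columns.duplicated().any():
            dup = self.data.columns[self.data.columns.duplicated()][0]
            raise ValueError(f"duplicate feature label: {dup!r}")
        if self.data.index.duplicated().any():
            dup = self.data.index[self.data.index.duplicated()][0]
            raise ValueError(f"duplicate sample id: {dup!r}")
        vals = self.data.to_numpy()
        if np.any(vals < 0):
            i, j = np.argwhere(vals < 0)[0]
            raise ValueError(
                f"negative abundance at sample {self.data.index[i]!r}, "
                f"feature {self.data.columns[j]!r}"
            )
        if self.kind == "taxa":
            kingdom = [c for c in self.data.columns if "|" not in c]
            if kingdom:
                totals = self.data[kingdom].sum(axis=1)
                if (totals > 100 + 1e-6).any():
                    bad = totals.idxmax()
                    raise ValueError(
                        f"kingdom-level abundances of sample {bad!r} sum to "
                        f"{totals.max():.6f} > 100"
                    )

    @property
    def sample_ids(self) -> list:
        return list(self.data.index)

    @property
    def feature_ids(self) -> list:
        return list(self.data.columns)


@dataclass
class SampleMetadata:
    """Per-sample covariates, disease labels and drug exposures.

    ``frame`` carries cohort, age (years), sex ('female'/'male'), BMI (kg/m²),
    sequencing depth (reads), IBS status ('yes'/'no' where applicable), IBD
    subtype ('CD'/'UC'/'IBDU'/'none') and the stoma/pouch flag.  ``drugs`` is
    the binary exposure matrix (samples x drug categories); ``dose`` holds
    mg/day where known (NaN otherwise); ``subtype`` the drug subtype label.
    """

    frame: pd.DataFrame
    drugs: pd.DataFrame
    dose: pd.DataFrame = field(default=None)
    subtype: pd.DataFrame = field(default=None)

    def __post_init__(self) -> None:
        if self.dose is None:
            self.dose = pd.DataFrame(index=self.frame.index, columns=self.drugs.columns, dtype=float)
        if self.subtype is None:
            self.subtype = pd.DataFrame(index=self.frame.index, columns=self.drugs.columns, dtype=object)
        if not self.frame.index.equals(self.drugs.index):
            raise ValueError("metadata frame and drug matrix must share sample ids")
        vals = self.drugs.to_numpy()
        if not np.isin(vals, (0, 1)).all():
            raise ValueError("drug exposures must be binary 0/1")
        if (self.dose.to_numpy(dtype=float, na_value=0.0) < 0).any():
            raise ValueError("doses must be non-negative")
        for col, lo in (("age", 0.0), ("bmi", 0.0)):
            bad = self.frame[col].dropna() <= lo
            if bad.any():
                raise ValueError(f"{col} must be > {lo}")
        if (self.frame["seq_depth"] < 0).any():
            raise ValueError("seq_depth must be >= 0")

    @property
    def sample_ids(self) -> list:
        return list(self.frame.index)

    @property
    def cohorts(self) -> pd.Series:
        return self.frame["cohort"]

    def subset(self, sample_ids) -> "SampleMetadata":
        return SampleMetadata(
            self.frame.loc[sample_ids].copy(),
            self.drugs.loc[sample_ids].copy(),
            self.dose.loc[sample_ids].copy(),
            self.subtype.loc[sample_ids].copy(),
        )


@dataclass
class DrugUsageSummary:
    """Per-cohort drug usage counts, mirroring a published cohort table."""

    per_drug: pd.DataFrame  # cohort, drug, n_users, percent
    per_cohort: pd.DataFrame  # cohort, n_samples, median_drugs, mean_drugs, n_combinations
    n_combinations_total: int


def _read_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", index_col=0)


def read_profile_table(path, kind: str, *, split_stratified: bool = False,
                       sample_major: bool = False):
    """Read a feature-major TSV profile table.

    With ``kind='pathway'`` and ``split_stratified=True``, rows whose label
    carries a ``|`` contributor suffix are separated out and the function
    returns ``(community_table, stratified_table)``.
    """
    raw = _read_tsv(path)
    if raw.shape[0] == 0 or raw.shape[1] == 0:
        raise ValueError(f"empty profile table: {path}")
    frame = raw if sample_major else raw.T
    frame = frame.fillna(0.0).astype(float)
    if split_stratified:
        if kind != "pathway":
            raise ValueError("split_stratified only applies to pathway tables")
        strat_cols = [c for c in frame.columns if "|" in c]
        plain_cols = [c for c in frame.columns if "|" not in c]
        if not plain_cols:
            raise ValueError("no unstratified pathway rows found")
        community = ProfileTable(frame[plain_cols], "pathway")
        stratified = (
            ProfileTable(frame[strat_cols], "stratified") if strat_cols else None
        )
        return community, stratified
    return ProfileTable(frame, kind)


def write_profile_table(table: ProfileTable, path, *, header_comment: str | None = None) -> None:
    """Write feature-major TSV (features as rows, samples as columns)."""
    with open(path, "w") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        table.data.T.to_csv(fh, sep="\t", index_label="feature")


def read_metadata(path) -> SampleMetadata:
    """Read the single-TSV metadata dialect (prefixed drug/dose/subtype columns)."""
    raw = pd.read_csv(path, sep="\t", comment="#", index_col=0)
    raw.index.name = None
    drug_cols = [c for c in raw.columns if c.startswith("drug__")]
    dose_cols = [c for c in raw.columns if c.startswith("dose__")]
    subtype_cols = [c for c in raw.columns if c.startswith("subtype__")]
    drugs = raw[drug_cols].rename(columns=lambda c: c[len("drug__"):]).fillna(0).astype(int)
    dose = raw[dose_cols].rename(columns=lambda c: c[len("dose__"):]).astype(float)
    subtype = raw[subtype_cols].rename(columns=lambda c: c[len("subtype__"):])
    dose = dose.reindex(columns=drugs.columns)
    subtype = subtype.reindex(columns=drugs.columns)
    frame = raw[[c for c in _META_COLUMNS if c in raw.columns]].copy()
    if "stoma_pouch" in frame:
        frame["stoma_pouch"] = frame["stoma_pouch"].astype(bool)
    return SampleMetadata(frame, drugs, dose, subtype)


def write_metadata(meta: SampleMetadata, path, *, header_comment: str | None = None) -> None:
    out = meta.frame.copy()
    for col in meta.drugs.columns:
        out[f"drug__{col}"] = meta.drugs[col]
    for col in meta.dose.columns:
        if meta.dose[col].notna().any():
            out[f"dose__{col}"] = meta.dose[col]
    for col in meta.subtype.columns:
        if meta.subtype[col].notna().any():
            out[f"subtype__{col}"] = meta.subtype[col]
    with open(path, "w") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        out.to_csv(fh, sep="\t", index_label="sample_id")


def taxa_to_proportions(table: ProfileTable) -> ProfileTable:
    """Convert a percent-scale (0-100) taxa table to proportions (0-1).

    This is the single conversion point: downstream transforms assume
    proportions.
    """
    if table.kind != "taxa":
        raise ValueError("proportion conversion applies to taxa tables")
    if (table.data.to_numpy() > 100 + 1e-6).any():
        raise ValueError("taxa values exceed 100; not a percent-scale table")
    return ProfileTable(table.data / 100.0, "taxa")


def apply_sample_exclusions(
    profiles: ProfileTable,
    meta: SampleMetadata,
    min_depth: float = DEFAULT_MIN_DEPTH,
) -> tuple[ProfileTable, SampleMetadata, pd.DataFrame]:
    """Remove stoma/pouch patients and low-depth samples.

    Returns the screened profile table and metadata (surviving sample order
    preserved) plus a report with one row per removal and its reason.
    """
    prof_ids = set(profiles.sample_ids)
    meta_ids = set(meta.sample_ids)
    if prof_ids != meta_ids:
        only_p = sorted(prof_ids - meta_ids)
        only_m = sorted(meta_ids - prof_ids)
        raise ValueError(
            f"sample mismatch between profiles and metadata: "
            f"profiles-only={only_p}, metadata-only={only_m}"
        )
    reasons = []
    for sid in profiles.sample_ids:
        row = meta.frame.loc[sid]
        if bool(row.get("stoma_pouch", False)):
            reasons.append({"sample_id": sid, "reason": "stoma/pouch/short-bowel"})
        elif row["seq_depth"] < min_depth:
            reasons.append(
                {"sample_id": sid, "reason": f"sequencing depth {row['seq_depth']:.0f} < {min_depth:.0f}"}
            )
    report = pd.DataFrame(reasons, columns=["sample_id", "reason"])
    removed = set(report["sample_id"])
    keep = [s for s in profiles.sample_ids if s not in removed]
    if not keep:
        raise ValueError("all samples excluded")
    return ProfileTable(profiles.data.loc[keep], profiles.kind), meta.subset(keep), report


def summarize_drug_usage(meta: SampleMetadata) -> DrugUsageSummary:
    """Per-cohort user counts and integer percentages (round half away from zero),
    plus per-participant drug counts and the number of distinct drug combinations."""
    per_drug_rows = []
    per_cohort_rows = []
    for cohort, grp in meta.drugs.groupby(meta.cohorts):
        n = len(grp)
        if n == 0:
            raise ValueError(f"cohort {cohort!r} has no samples")
        counts = grp.sum(axis=0)
        pct = round_half_away(100.0 * counts / n)
        for drug in meta.drugs.columns:
            per_drug_rows.append(
                {"cohort": cohort, "drug": drug, "n_users": int(counts[drug]),
                 "percent": int(pct[meta.drugs.columns.get_loc(drug)])}
            )
        per_sample = grp.sum(axis=1)
        combos = grp.apply(lambda r: tuple(r[r == 1].index), axis=1)
        per_cohort_rows.append(
            {"cohort": cohort, "n_samples": n,
             "median_drugs": float(per_sample.median()),
             "mean_drugs": float(per_sample.mean()),
             "n_combinations": int(combos[per_sample > 0].nunique())}
        )
    combos_all = meta.drugs.apply(lambda r: tuple(r[r == 1].index), axis=1)
    n_total = int(combos_all[meta.drugs.sum(axis=1) > 0].nunique())
    return DrugUsageSummary(
        pd.DataFrame(per_drug_rows),
        pd.DataFrame(per_cohort_rows),
        n_total,
    )


def write_usage_summary(summary: DrugUsageSummary, path) -> None:
    """Wide per-drug usage TSV mirroring the published cohort-table layout."""
    wide = summary.per_drug.pivot(index="drug", columns="cohort")
    cohorts = summary.per_cohort["cohort"]
    cols = {}
    for cohort in cohorts:
        cols[cohort] = (
            wide[("n_users", cohort)].astype(int).astype(str)
            + " ("
            + wide[("percent", cohort)].astype(int).astype(str)
            + "%)"
        )
    pd.DataFrame(cols).to_csv(path, sep="\t", index_label="drug")
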