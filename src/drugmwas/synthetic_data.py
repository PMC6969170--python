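"""Multi-cohort synthetic metagenomics generator with a known truth table.

The generator emulates the statistical structure the analysis assumes, so
every pipeline stage is testable without access to restricted cohort data:

* three cohorts of unequal size with cohort-specific disease labelling
  (population-style, IBS case-control, IBD subtypes);
* binary drug exposures with configurable per-cohort prevalences; correlated
  drug pairs are produced by thresholding a bivariate Gaussian copula whose
  latent correlation is solved numerically to hit the target rank
  correlation of the binary indicators;
* compositional, zero-inflated log-normal taxa with pipe-delimited lineage
  labels (internal clades are exact sums of their children, so end-point
  extraction removes precisely the internal rows);
* pathways as non-negative linear mixtures of species contributions, emitted
  both as community totals and as per-species stratified rows (community
  total = sum of stratified rows + an unclassified noise remainder, exactly);
* antibiotic-resistance markers whose genes track a driver species with a
  configurable Spearman coupling;
* effects injected for drug users on the *transformed* analysis scale
  (arcsine-sqrt for taxa, log for pathways), sized in units of the feature's
  transformed-scale standard deviation, so the association model's estimand
  equals the configured effect.

Same seed, same config => identical outputs.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .io_profiles import ProfileTable, SampleMetadata
from . import reference

# ---------------------------------------------------------------- configuration


@dataclass
class CohortSpec:
    name: str
    n: int
    disease_scheme: str  # 'population' | 'ibs-case-control' | 'ibd'
    ibs_prevalence: float = 0.10
    stoma_prevalence: float = 0.0


@dataclass
class DrugSpec:
    name: str
    prevalence: dict  # cohort name -> fraction of users
    doses: tuple = ()  # discrete mg/day values drawn for users
    dose_probs: tuple = ()
    subtypes: tuple = ()
    subtype_probs: tuple = ()


@dataclass
class ARGeneSpec:
    gene_id: str
    gene_name: str
    n_markers: int = 2
    driver_species: int | None = None  # species index the gene tracks
    coupling: float = 0.7  # target Spearman with the driver
    prevalence: float = 1.0  # fraction of samples where the gene is detected


@dataclass
class EffectSpec:
    drug: str
    feature: str  # species lineage label or pathway id
    effect_sd: float  # shift in units of the feature's transformed-scale SD


@dataclass
class GeneratorConfig:
    seed: int
    cohorts: list
    drugs: list
    drug_correlations: dict = field(default_factory=dict)  # "a|b" -> target rho
    n_taxa: int = 150
    n_prevalent_taxa: int = 40  # first species are never zero-inflated
    taxa_log_mean: float = 0.0
    taxa_log_mean_sd: float = 1.8
    taxa_log_sd_range: tuple = (0.5, 1.5)
    max_zero_inflation: float = 0.85
    n_pathways: int = 60
    contributors_per_pathway: tuple = (2, 6)
    pathway_noise_scale: float = 0.10
    ar_genes: list = field(default_factory=list)
    effects: list = field(default_factory=list)

    def hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class SyntheticDataset:
    taxa: ProfileTable
    pathways: ProfileTable
    stratified: ProfileTable
    ar_markers: ProfileTable
    marker_map: pd.DataFrame
    meta: SampleMetadata
    truth: pd.DataFrame
    config: GeneratorConfig


# ------------------------------------------------------------------ drug matrix


def _phi_from_latent(rho: float, za: float, zb: float, pa: float, pb: float) -> float:
    """Phi coefficient of the two thresholded indicators given latent rho."""
    cov = [[1.0, rho], [rho, 1.0]]
    p11 = stats.multivariate_normal.cdf([-za, -zb], mean=[0.0, 0.0], cov=cov)
    return (p11 - pa * pb) / np.sqrt(pa * (1 - pa) * pb * (1 - pb))


def solve_latent_correlation(target: float, pa: float, pb: float) -> float:
    """Latent Gaussian correlation hitting a target binary rank correlation.

    For binary indicators the Spearman correlation equals the phi
    coefficient.  Raises if the target exceeds the Fréchet upper bound for
    the given prevalences.
    """
    if target == 0.0:
        return 0.0
    za = stats.norm.ppf(1 - pa)
    zb = stats.norm.ppf(1 - pb)
    denom = np.sqrt(pa * (1 - pa) * pb * (1 - pb))
    phi_max = (min(pa, pb) - pa * pb) / denom
    phi_min = (max(pa + pb - 1, 0.0) - pa * pb) / denom
    if not (phi_min - 1e-9 <= target <= phi_max + 1e-9):
        raise ValueError(
            f"target correlation {target} outside the Fréchet bounds "
            f"[{phi_min:.3f}, {phi_max:.3f}] for prevalences ({pa}, {pb})"
        )
    return float(optimize.brentq(
        lambda r: _phi_from_latent(r, za, zb, pa, pb) - target, -0.999, 0.999,
        xtol=1e-6,
    ))


def generate_drug_matrix(
    config: GeneratorConfig, cohort: CohortSpec, rng: np.random.Generator
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Binary exposures plus doses and subtypes for one cohort."""
    names = [d.name for d in config.drugs]
    k = len(names)
    latent_r = np.eye(k)
    for pair, target in config.drug_correlations.items():
        a, b = pair.split("|")
        if a not in names or b not in names:
            raise ValueError(f"correlation pair {pair!r} references unknown drugs")
        pa = config.drugs[names.index(a)].prevalence.get(cohort.name, 0.0)
        pb = config.drugs[names.index(b)].prevalence.get(cohort.name, 0.0)
        if pa <= 0 or pb <= 0:
            continue
        rho = solve_latent_correlation(target, pa, pb)
        i, j = names.index(a), names.index(b)
        latent_r[i, j] = latent_r[j, i] = rho
    eigvals = np.linalg.eigvalsh(latent_r)
    if eigvals.min() < -1e-8:
        raise ValueError("latent drug correlation matrix is not positive semidefinite")
    z = rng.multivariate_normal(np.zeros(k), latent_r, size=cohort.n,
                                method="cholesky" if eigvals.min() > 1e-10 else "svd")
    ids = [f"{cohort.name}_{i:04d}" for i in range(cohort.n)]
    drugs = pd.DataFrame(0, index=ids, columns=names, dtype=int)
    dose = pd.DataFrame(np.nan, index=ids, columns=names, dtype=float)
    subtype = pd.DataFrame(np.nan, index=ids, columns=names, dtype=object)
    for j, spec in enumerate(config.drugs):
        prev = spec.prevalence.get(cohort.name, 0.0)
        if prev <= 0:
            continue
        users = z[:, j] > stats.norm.ppf(1 - prev)
        drugs.iloc[users, j] = 1
        n_users = int(users.sum())
        if spec.doses and n_users:
            probs = spec.dose_probs or [1 / len(spec.doses)] * len(spec.doses)
            dose.iloc[users, j] = rng.choice(spec.doses, size=n_users, p=probs)
        if spec.subtypes and n_users:
            probs = spec.subtype_probs or [1 / len(spec.subtypes)] * len(spec.subtypes)
            subtype.iloc[users, j] = rng.choice(spec.subtypes, size=n_users, p=probs)
    return drugs, dose, subtype


# ------------------------------------------------------------------- covariates


def _generate_covariates(cohort: CohortSpec, ids, rng: np.random.Generator) -> pd.DataFrame:
    n = cohort.n
    frame = pd.DataFrame(index=ids)
    frame["cohort"] = cohort.name
    frame["age"] = np.clip(rng.normal(45.0, 14.0, n), 18.0, 95.0)
    frame["sex"] = np.where(rng.random(n) < 0.6, "female", "male")
    frame["bmi"] = np.clip(rng.normal(25.0, 4.5, n), 15.0, 55.0)
    frame["seq_depth"] = np.exp(rng.normal(np.log(2.2e7), 0.35, n)).round()
    if cohort.disease_scheme == "ibd":
        frame["ibs_status"] = "no"
        frame["ibd_subtype"] = rng.choice(["CD", "UC", "IBDU"], size=n,
                                          p=[0.60, 0.35, 0.05])
    else:
        prev = cohort.ibs_prevalence if cohort.disease_scheme == "population" else 0.55
        frame["ibs_status"] = np.where(rng.random(n) < prev, "yes", "no")
        frame["ibd_subtype"] = "none"
    frame["stoma_pouch"] = rng.random(n) < cohort.stoma_prevalence
    return frame


# ------------------------------------------------------------------- taxonomy


def taxonomy_template(n_taxa: int) -> list[str]:
    """Deterministic lineage labels: one archaeal species, bacterial rest.

    Species are grouped four-to-a-genus and genera five-to-a-phylum, so the
    emitted table exercises end-point extraction at three internal levels.
    """
    labels = ["k__Archaea|p__Euryarchaeota|g__Methanobrevibacter|s__Methanobrevibacter_smithii"]
    named = [
        ("Firmicutes", "Streptococcus", "Streptococcus_parasanguinis"),
        ("Firmicutes", "Streptococcus", "Streptococcus_salivarius"),
        ("Firmicutes", "Streptococcus", "Streptococcus_mutans"),
        ("Actinobacteria", "Bifidobacterium", "Bifidobacterium_dentium"),
        ("Actinobacteria", "Bifidobacterium", "Bifidobacterium_longum"),
        ("Firmicutes", "Eubacterium", "Eubacterium_ramulus"),
        ("Proteobacteria", "Escherichia", "Escherichia_coli"),
        ("Bacteroidetes", "Alistipes", "Alistipes_putredinis"),
        ("Bacteroidetes", "Bacteroides", "Bacteroides_vulgatus"),
        ("Firmicutes", "Veillonella", "Veillonella_parvula"),
    ]
    for phylum, genus, species in named[: max(0, n_taxa - 1)]:
        labels.append(f"k__Bacteria|p__{phylum}|g__{genus}|s__{species}")
    i = len(labels)
    while len(labels) < n_taxa:
        idx = len(labels)
        genus = f"G{idx // 4:03d}"
        phylum = f"P{idx // 20:02d}"
        labels.append(f"k__Bacteria|p__{phylum}|g__{genus}|s__S{idx:03d}")
    return labels[:n_taxa]


def _close_with_internals(species_pct: pd.DataFrame) -> pd.DataFrame:
    """Add internal clade rows as exact sums of their children."""
    out = {}
    for lab in species_pct.columns:
        out[lab] = species_pct[lab]
    internals = {}
    for lab in species_pct.columns:
        parts = lab.split("|")
        for depth in range(1, len(parts)):
            anc = "|".join(parts[:depth])
            internals.setdefault(anc, []).append(lab)
    for anc, children in internals.items():
        out[anc] = species_pct[children].sum(axis=1)
    ordered = sorted(out, key=lambda l: (l.count("|"), l))
    return pd.DataFrame({k: out[k] for k in ordered})


# ------------------------------------------------------------------- profiles


def generate_profiles(
    config: GeneratorConfig,
    exposures: pd.DataFrame,
    covariates: pd.DataFrame,
    rng: np.random.Generator,
) -> tuple[ProfileTable, ProfileTable, ProfileTable, ProfileTable, pd.DataFrame, pd.DataFrame]:
    """Taxa, pathway (community + stratified) and AR-marker tables plus truth.

    ``exposures`` and ``covariates`` cover all cohorts (rows = samples).
    Returns ``(taxa, pathways, stratified, ar_markers, marker_map, truth)``.
    """
    ids = list(exposures.index)
    n = len(ids)
    n_taxa = config.n_taxa
    species = taxonomy_template(n_taxa)

    # species parameter draws (template stream: independent of sample count)
    mu = rng.normal(config.taxa_log_mean, config.taxa_log_mean_sd, n_taxa)
    sig = rng.uniform(*config.taxa_log_sd_range, n_taxa)
    zi = rng.uniform(0.0, config.max_zero_inflation, n_taxa)
    zi[: config.n_prevalent_taxa] = 0.0

    present = rng.random((n, n_taxa)) >= zi[None, :]
    x = np.where(present, np.exp(rng.normal(mu[None, :], sig[None, :], (n, n_taxa))), 0.0)
    # guarantee a nonzero vector everywhere (prevalent block is never empty)
    p = x / x.sum(axis=1, keepdims=True)

    # ---- effect injection on the arcsine-sqrt scale
    truth_rows = []
    t_all = np.arcsin(np.sqrt(p))
    sd_t = t_all.std(axis=0, ddof=1)
    species_index = {s: i for i, s in enumerate(species)}
    for eff in config.effects:
        if eff.feature not in species_index:
            continue  # pathway effects handled below
        j = species_index[eff.feature]
        delta = float(eff.effect_sd * sd_t[j])
        users = exposures[eff.drug].to_numpy(dtype=bool)
        t_new = np.clip(np.arcsin(np.sqrt(p[users, j])) + delta, 0.0, np.pi / 2)
        p_new = np.sin(t_new) ** 2
        old = p[users, j].copy()
        scale = (1.0 - p_new) / np.where(1.0 - old > 0, 1.0 - old, 1.0)
        p[users, :] *= scale[:, None]
        p[users, j] = p_new
        truth_rows.append({"drug": eff.drug, "feature": eff.feature, "kind": "taxa",
                           "effect_sd": eff.effect_sd, "effect_abs": delta,
                           "scale": "arcsine-sqrt"})

    species_pct = pd.DataFrame(100.0 * p, index=ids, columns=species)
    taxa = ProfileTable(_close_with_internals(species_pct), "taxa")

    # ---- pathways as mixtures of species contributions
    lo, hi = config.contributors_per_pathway
    pwy_ids = [f"PWY-{1000 + i}" for i in range(config.n_pathways)]
    strat_cols = {}
    noise_mat = {}
    contrib = {}
    for pw in pwy_ids:
        k = int(rng.integers(lo, hi + 1))
        members = rng.choice(n_taxa, size=min(k, n_taxa), replace=False)
        weights = np.exp(rng.normal(0.0, 1.0, len(members)))
        contrib[pw] = list(zip(members, weights))
        for m, w in zip(members, weights):
            strat_cols[f"{pw}|g__{species[m].split('|')[2][3:]}.s__{species[m].split('|')[3][3:]}"] = (
                1000.0 * w * p[:, m]
            )
        noise = np.where(rng.random(n) < 0.7,
                         config.pathway_noise_scale * 1000.0 * np.exp(rng.normal(0, 1, n)) / n_taxa,
                         0.0)
        noise_mat[pw] = noise
    strat = pd.DataFrame(strat_cols, index=ids)

    # pathway effects: multiply a user's contributor rows and noise by exp(delta)
    pwy_totals = {pw: sum(strat[c] for c in strat.columns if c.split("|", 1)[0] == pw)
                  + noise_mat[pw] for pw in pwy_ids}
    for eff in config.effects:
        if eff.feature not in pwy_ids:
            continue
        rel = pd.DataFrame(pwy_totals)
        rel = rel.div(rel.sum(axis=1), axis=0)
        logv = np.log(rel[eff.feature].where(rel[eff.feature] > 0, 1.0))
        delta = float(eff.effect_sd * logv.std(ddof=1))
        users = exposures[eff.drug].to_numpy(dtype=bool)
        factor = np.exp(delta)
        for c in strat.columns:
            if c.split("|", 1)[0] == eff.feature:
                strat.loc[users, c] *= factor
        noise_mat[eff.feature] = np.where(users, noise_mat[eff.feature] * factor,
                                          noise_mat[eff.feature])
        truth_rows.append({"drug": eff.drug, "feature": eff.feature, "kind": "pathway",
                           "effect_sd": eff.effect_sd, "effect_abs": delta,
                           "scale": "log-kept-zeros"})

    community = pd.DataFrame(
        {pw: sum(strat[c] for c in strat.columns if c.split("|", 1)[0] == pw) + noise_mat[pw]
         for pw in pwy_ids},
        index=ids,
    )
    # unclassified remainder emitted as its own contributor row
    for pw in pwy_ids:
        strat[f"{pw}|unclassified"] = noise_mat[pw]
    pathways = ProfileTable(community, "pathway")
    stratified = ProfileTable(strat, "stratified")

    # ---- AR markers
    marker_cols = {}
    map_rows = []
    log_p = np.log(np.where(p > 0, p, np.nan))
    for spec in config.ar_genes:
        if spec.driver_species is not None:
            drv = log_p[:, spec.driver_species]
            s_p = np.nanstd(drv, ddof=1)
            rho_latent = 2 * np.sin(np.pi * spec.coupling / 6)
            sigma = s_p * np.sqrt(1.0 / rho_latent ** 2 - 1.0)
            base = np.where(np.isnan(drv), 0.0,
                            np.exp(drv + rng.normal(0.0, sigma, n)))
        else:
            detected = rng.random(n) < spec.prevalence
            base = np.where(detected, np.exp(rng.normal(0.0, 1.0, n)), 0.0)
        for m in range(spec.n_markers):
            marker_id = f"{spec.gene_name}_m{m}"
            marker_cols[marker_id] = base * np.exp(rng.normal(0.0, 0.2, n))
            map_rows.append({"marker_id": marker_id, "gene_id": spec.gene_id,
                             "gene_name": spec.gene_name})
    marker_map = pd.DataFrame(map_rows, columns=["marker_id", "gene_id", "gene_name"])
    ar = ProfileTable(pd.DataFrame(marker_cols, index=ids), "ar_marker")

    truth = pd.DataFrame(truth_rows,
                         columns=["drug", "feature", "kind", "effect_sd",
                                  "effect_abs", "scale"])
    # mark injected features that default filters would remove as unevaluable
    evaluable = []
    for _, row in truth.iterrows():
        if row["kind"] == "taxa":
            j = species_index[row["feature"]]
            col = p[:, j]
            ok = True
            for cohort in covariates["cohort"].unique():
                mask = (covariates["cohort"] == cohort).to_numpy()
                if (col[mask] > 0).mean() <= 0.10 or col[mask].mean() < 1e-4:
                    ok = False
            evaluable.append(ok)
        else:
            evaluable.append(True)
    truth["evaluable"] = evaluable
    return taxa, pathways, stratified, ar, marker_map, truth


def generate(config: GeneratorConfig) -> SyntheticDataset:
    """Run the full generator: drugs, covariates, profiles, truth."""
    root = np.random.SeedSequence(config.seed)
    cohort_seeds = root.spawn(len(config.cohorts))
    profile_seed = root.spawn(1)[0]
    drug_frames, dose_frames, subtype_frames, cov_frames = [], [], [], []
    for cohort, seq in zip(config.cohorts, cohort_seeds):
        rng = np.random.default_rng(seq)
        d, dose, sub = generate_drug_matrix(config, cohort, rng)
        cov = _generate_covariates(cohort, d.index, rng)
        drug_frames.append(d)
        dose_frames.append(dose)
        subtype_frames.append(sub)
        cov_frames.append(cov)
    drugs = pd.concat(drug_frames)
    covariates = pd.concat(cov_frames)
    meta = SampleMetadata(covariates, drugs, pd.concat(dose_frames),
                          pd.concat(subtype_frames))
    rng = np.random.default_rng(profile_seed)
    taxa, pathways, stratified, ar, marker_map, truth = generate_profiles(
        config, drugs, covariates, rng
    )
    return SyntheticDataset(taxa, pathways, stratified, ar, marker_map, meta,
                            truth, config)


# ---------------------------------------------------------------------- truth IO


def write_truth(truth: pd.DataFrame, path, config: GeneratorConfig) -> None:
    """Write the truth table with the generator seed and config hash embedded."""
    with open(path, "w") as fh:
        fh.write(f"# seed: {config.seed}\n")
        fh.write(f"# config_hash: {config.hash()}\n")
        truth.to_csv(fh, sep="\t", index=False)


def read_truth(path, config: GeneratorConfig | None = None) -> pd.DataFrame:
    """Read a truth table; verify the config hash when a config is supplied."""
    stored = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            key, _, val = line[1:].strip().partition(":")
            stored[key.strip()] = val.strip()
    if config is not None and stored.get("config_hash") != config.hash():
        raise ValueError(
            f"truth table config hash {stored.get('config_hash')!r} does not match "
            f"the supplied config ({config.hash()!r})"
        )
    return pd.read_csv(path, sep="\t", comment="#")


# ------------------------------------------------------------------------ presets


_DOSE_SETS = {
    "PPI": ((20.0, 40.0, 80.0), (0.5, 0.35, 0.15)),
    "metformin": ((500.0, 1000.0, 2000.0), (0.35, 0.45, 0.2)),
}
_SUBTYPE_SETS = {
    "PPI": (("omeprazole", "esomeprazole", "pantoprazole"), (0.5, 0.25, 0.25)),
    "SSRI antidepressant": (("paroxetine", "citalopram", "sertraline"),
                            (0.4, 0.35, 0.25)),
}

_DEFAULT_AR_GENES = [
    ARGeneSpec("ARO:3004033", "tetA", 2, driver_species=1, coupling=0.7),
    ARGeneSpec("ARO:3004032", "tetB", 2, driver_species=1, coupling=0.6),
    ARGeneSpec("ARO:3000616", "Mel", 3, driver_species=1, coupling=0.7),
    ARGeneSpec("ARO:3000216", "TolC", 2, prevalence=0.8),
    ARGeneSpec("ARO:3003549", "mdtP", 2, prevalence=0.6),
    ARGeneSpec("ARO:3000264", "emrE", 1, prevalence=0.5),
    ARGeneSpec("ARO:9000001", "synthG7", 2, prevalence=0.3),
    ARGeneSpec("ARO:9000002", "synthG8", 1, prevalence=0.05),  # below the 10% rule
]


def _study_cohorts(sizes=(600, 250, 150)) -> list:
    return [
        CohortSpec("population", sizes[0], "population"),
        CohortSpec("IBD", sizes[1], "ibd"),
        CohortSpec("IBS", sizes[2], "ibs-case-control"),
    ]


def null_preset(seed: int, sizes=(600, 250, 150), n_taxa: int = 500,
                n_drugs: int = 5) -> GeneratorConfig:
    """No injected effects: every downstream hit is a false positive."""
    drugs = [
        DrugSpec(f"drug_{i}", {"population": 0.15, "IBD": 0.15, "IBS": 0.15})
        for i in range(n_drugs)
    ]
    return GeneratorConfig(seed=seed, cohorts=_study_cohorts(sizes), drugs=drugs,
                           n_taxa=n_taxa, n_prevalent_taxa=max(20, n_taxa // 10),
                           n_pathways=20, ar_genes=list(_DEFAULT_AR_GENES))


def effects_preset(seed: int, sizes=(600, 250, 150), n_taxa: int = 150,
                   effect_sd: float = 0.5, n_effects: int = 20,
                   driver_effect_sd: float = 1.0) -> GeneratorConfig:
    """Twenty injected taxon effects of 0.5 transformed-scale SDs, plus one
    strong PPI effect on the AR-driver species.

    The standard effects are spread over five drug categories and target
    prevalent species (so the default filters keep them).  The extra driver
    effect emulates the hallmark oral-bacteria enrichment in acid-suppressed
    guts — by design the strongest association — which propagates, via the
    gene-species coupling, into the resistome of PPI users.
    """
    drug_names = ["PPI", "metformin", "laxatives", "antibiotics merged",
                  "SSRI antidepressant"]
    drugs = []
    for name in drug_names:
        spec = DrugSpec(name, {"population": 0.20, "IBD": 0.25, "IBS": 0.20})
        if name in _DOSE_SETS:
            spec.doses, spec.dose_probs = _DOSE_SETS[name]
        if name in _SUBTYPE_SETS:
            spec.subtypes, spec.subtype_probs = _SUBTYPE_SETS[name]
        drugs.append(spec)
    template = taxonomy_template(n_taxa)
    # index 1 is the AR-driver species; standard targets start at index 2 and
    # stay within the prevalent block so the default filters keep them
    effects = [EffectSpec("PPI", template[1], driver_effect_sd)]
    for i in range(n_effects):
        effects.append(
            EffectSpec(drug_names[i % len(drug_names)], template[2 + (i % 30)],
                       effect_sd if i % 2 == 0 else -effect_sd)
        )
    return GeneratorConfig(seed=seed, cohorts=_study_cohorts(sizes), drugs=drugs,
                           n_taxa=n_taxa, n_prevalent_taxa=40, n_pathways=40,
                           ar_genes=list(_DEFAULT_AR_GENES), effects=effects)


def confounded_preset(seed: int, sizes=(600, 250, 150), n_taxa: int = 100,
                      effect_sd: float = 0.5, correlation: float = 0.7) -> GeneratorConfig:
    """A causal drug plus a correlated null drug for the deconfounding check."""
    template = taxonomy_template(n_taxa)
    drugs = [
        DrugSpec("causal_drug", {"population": 0.20, "IBD": 0.20, "IBS": 0.20}),
        DrugSpec("null_drug", {"population": 0.20, "IBD": 0.20, "IBS": 0.20}),
        DrugSpec("bystander", {"population": 0.15, "IBD": 0.15, "IBS": 0.15}),
    ]
    effects = [EffectSpec("causal_drug", template[i], effect_sd) for i in (1, 2, 3)]
    return GeneratorConfig(
        seed=seed, cohorts=_study_cohorts(sizes), drugs=drugs,
        drug_correlations={"causal_drug|null_drug": correlation},
        n_taxa=n_taxa, n_prevalent_taxa=30, n_pathways=20,
        ar_genes=list(_DEFAULT_AR_GENES), effects=effects,
    )


def reference_preset(seed: int, n_taxa: int = 200, n_pathways: int = 80) -> GeneratorConfig:
    """Published-cohort preset: analysed sizes (1124, 454, 305), published
    per-cohort drug prevalences, and the strongly correlated inhaler pair."""
    cohorts = [
        CohortSpec("population", reference.COHORT_SIZES["population"], "population"),
        CohortSpec("IBD", reference.COHORT_SIZES["IBD"], "ibd"),
        CohortSpec("IBS", reference.COHORT_SIZES["IBS"], "ibs-case-control"),
    ]
    drugs = []
    for drug in reference.usage_table()["drug"].unique():
        prev = {c: reference.prevalence(c, drug) for c in reference.COHORTS}
        spec = DrugSpec(drug, prev)
        if drug in _DOSE_SETS:
            spec.doses, spec.dose_probs = _DOSE_SETS[drug]
        if drug in _SUBTYPE_SETS:
            spec.subtypes, spec.subtype_probs = _SUBTYPE_SETS[drug]
        drugs.append(spec)
    correlations = {"steroid inhaler|beta sympathomimetic inhaler": 0.78}
    template = taxonomy_template(n_taxa)
    effects = [
        EffectSpec("PPI", template[1], 0.5),    # S. parasanguinis up in PPI users
        EffectSpec("PPI", template[4], 0.5),    # B. dentium up in PPI users
        EffectSpec("oral steroid", template[0], 0.5),  # M. smithii up
    ]
    return GeneratorConfig(seed=seed, cohorts=cohorts, drugs=drugs,
                           drug_correlations=correlations, n_taxa=n_taxa,
                           n_prevalent_taxa=40, n_pathways=n_pathways,
                           ar_genes=list(_DEFAULT_AR_GENES), effects=effects)
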