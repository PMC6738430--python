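"""Synthetic multi-cohort methylation + phenotype generator with known ground truth.

Emulates the data structure of a large stratified leukocyte-telomere-length
(LTL) EWAS: 16 cohort x sex x ethnicity strata, age-correlated LTL,
white-blood-cell composition that confounds both the methylome and LTL,
family/twin clustering in the family-based cohorts, and a set of planted
causal CpGs whose methylation levels are predominantly *negatively*
correlated with LTL.  Every downstream stage of the pipeline (deconvolution,
trait adjustment, per-stratum EWAS, meta-analysis, enrichment, SMR, network
modules) can be exercised against the returned :class:`TruthRecord`.

The methylation model is a convex mixture of cell-type reference profiles
plus per-CpG Gaussian noise, clipped to [0, 1]; baseline probe means are
drawn from a bimodal distribution so the marginal beta-value distribution
has the familiar two-humped shape of Illumina array data.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

ISLAND_RELATIONS = ("Island", "N_Shore", "S_Shore", "N_Shelf", "S_Shelf", "OpenSea")
SMOKING_LEVELS = ("never", "former", "current")
AUTOSOMES = tuple(f"chr{i}" for i in range(1, 23))


@dataclass(frozen=True)
class StratumSpec:
    """Design of one cohort x sex x ethnicity x batch stratum."""

    cohort_name: str
    sex: str                      # "male" | "female"
    ethnicity: str                # "European" | "African"
    batch: str
    n: int
    age_range: tuple[float, float]
    ltl_mean: float               # kb (Southern-blot-like) or T/S ratio (qPCR-like)
    ltl_sd: float
    target_age_ltl_corr: float
    family_fraction: float = 0.0  # fraction of samples in twin/sib pairs

    def __post_init__(self) -> None:
        if self.n < 4:
            raise ValueError(f"stratum {self.cohort_name}: n must be >= 4, got {self.n}")
        lo, hi = self.age_range
        if not lo < hi:
            raise ValueError(f"stratum {self.cohort_name}: age_range min must be < max")
        if not abs(self.target_age_ltl_corr) < 1:
            raise ValueError("|target_age_ltl_corr| must be < 1")
        if not 0.0 <= self.family_fraction <= 1.0:
            raise ValueError("family_fraction must be in [0, 1]")

    @property
    def stratum_id(self) -> str:
        return f"{self.cohort_name}_{self.ethnicity}_{self.sex}_{self.batch}"

    @property
    def group(self) -> str:
        """Meta-analysis group label, e.g. ``EuropeanFemale``."""
        return f"{self.ethnicity}{self.sex.capitalize()}"


# 16-stratum design mirroring the published study layout: cohort, sex,
# ethnicity, n, age range (years), mean LTL and range-derived sd
# (kb for Southern-blot cohorts, T/S ratio for the qPCR birth cohorts),
# and the reported age-LTL correlation.  sd is (range width)/5.
_STUDY_ROWS = [
    # cohort, sex, ethnicity, n, (age lo, hi), ltl mean, (ltl lo, hi), age-ltl r, fam frac
    ("FHS", "female", "European", 442, (33, 81), 7.07, (5.51, 8.70), -0.29, 0.6),
    ("FHS", "male", "European", 432, (36, 82), 6.92, (5.59, 8.52), -0.34, 0.6),
    ("JHS", "female", "African", 1034, (23, 92), 7.22, (4.93, 10.03), -0.39, 0.0),
    ("JHS", "male", "African", 603, (22, 93), 7.06, (5.12, 9.24), -0.45, 0.0),
    ("WHI", "female", "African", 342, (50, 80), 7.12, (5.57, 9.06), -0.24, 0.0),
    ("WHI", "female", "European", 476, (51, 80), 6.77, (5.24, 8.49), -0.27, 0.0),
    ("BHS", "female", "African", 156, (30, 54), 7.34, (5.35, 9.22), -0.08, 0.0),
    ("BHS", "male", "African", 94, (33, 49), 7.21, (5.60, 9.47), -0.17, 0.0),
    ("BHS", "female", "European", 315, (29, 55), 6.82, (5.02, 9.17), -0.08, 0.0),
    ("BHS", "male", "European", 266, (28, 52), 6.75, (5.27, 8.54), -0.18, 0.0),
    ("LBC1921", "female", "European", 242, (78, 80), 3.99, (3.00, 4.72), -0.29, 0.0),
    ("LBC1921", "male", "European", 161, (78, 81), 4.26, (3.46, 5.31), -0.29, 0.0),
    ("LBC1936", "female", "European", 448, (68, 71), 4.05, (2.69, 6.00), 0.01, 0.0),
    ("LBC1936", "male", "European", 458, (68, 71), 4.33, (2.99, 7.12), 0.17, 0.0),
    ("LSADT", "female", "European", 172, (73, 90), 5.79, (3.94, 7.38), -0.25, 1.0),
    ("LSADT", "male", "European", 72, (74, 87), 5.60, (4.53, 6.78), -0.17, 1.0),
]

#: Cohorts entering the consensus co-methylation network analysis.
CONSENSUS_COHORTS = ("FHS", "JHS", "WHI")


def study_specs() -> list[StratumSpec]:
    """The 16 strata of the full study design ("table2" profile)."""
    specs = []
    for cohort, sex, eth, n, ages, mean, (lo, hi), r, fam in _STUDY_ROWS:
        specs.append(
            StratumSpec(
                cohort_name=cohort, sex=sex, ethnicity=eth, batch="b1", n=n,
                age_range=ages, ltl_mean=mean, ltl_sd=(hi - lo) / 5.0,
                target_age_ltl_corr=r, family_fraction=fam,
            )
        )
    return specs


def mini_specs(n_per_stratum: int = 50) -> list[StratumSpec]:
    """The same 16-stratum structure scaled down for fast runs."""
    out = []
    for s in study_specs():
        out.append(
            StratumSpec(
                cohort_name=s.cohort_name, sex=s.sex, ethnicity=s.ethnicity,
                batch=s.batch, n=n_per_stratum, age_range=s.age_range,
                ltl_mean=s.ltl_mean, ltl_sd=s.ltl_sd,
                target_age_ltl_corr=s.target_age_ltl_corr,
                family_fraction=s.family_fraction,
            )
        )
    return out


@dataclass
class TruthRecord:
    """Ground truth planted by :func:`generate_cohorts`.

    ``causal_cpg_effects`` are LTL units per unit of beta value;
    ``celltype_effects`` are LTL units per unit cell proportion.
    ``reference`` and ``cell_proportions`` expose the signatures and true
    mixing weights so closed-loop deconvolution tests are possible.
    """

    causal_cpg_effects: dict[str, float]
    negative_fraction: float
    celltype_effects: np.ndarray
    planted_module_blocks: list[tuple[frozenset, str]]
    smr_truth: dict[str, tuple[float, float]] = field(default_factory=dict)
    reference: pd.DataFrame | None = None
    cell_proportions: pd.DataFrame | None = None
    clipped_fraction: float = 0.0


def _bimodal_baseline(rng: np.random.Generator, n: int) -> np.ndarray:
    """Per-probe baseline methylation means, bimodal in (0.05, 0.95)."""
    comp = rng.choice(3, size=n, p=(0.4, 0.4, 0.2))
    mu = np.empty(n)
    mu[comp == 0] = rng.beta(3, 8, size=(comp == 0).sum())
    mu[comp == 1] = rng.beta(8, 3, size=(comp == 1).sum())
    mu[comp == 2] = rng.beta(2, 2, size=(comp == 2).sum())
    return 0.05 + 0.9 * mu


def _signature_matrix(
    rng: np.random.Generator,
    n_probes: int,
    n_celltypes: int,
    discriminating_fraction: float = 0.25,
    delta_sd: float = 0.2,
) -> tuple[np.ndarray, np.ndarray]:
    """Probe x cell-type reference profiles in [0.05, 0.95].

    Returns the matrix and the indices of the cell-type-discriminating
    probes (the rest are identical across cell types).
    """
    mu = _bimodal_baseline(rng, n_probes)
    ref = np.tile(mu[:, None], (1, n_celltypes))
    n_disc = max(int(discriminating_fraction * n_probes), min(n_probes, 10))
    disc = rng.choice(n_probes, size=n_disc, replace=False)
    ref[disc] += rng.normal(0.0, delta_sd, size=(n_disc, n_celltypes))
    return np.clip(ref, 0.05, 0.95), disc


def generate_reference_signatures(
    n_celltypes: int, n_probes: int, seed: int
) -> pd.DataFrame:
    """Standalone cell-type reference signatures (probe x cell type).

    Columns are distinguishable (pairwise correlation < 0.95 on the
    discriminating probes); deterministic given the seed.
    """
    if n_celltypes < 2:
        raise ValueError("n_celltypes must be >= 2 (deconvolution is degenerate)")
    rng = np.random.default_rng(seed)
    ref, _ = _signature_matrix(rng, n_probes, n_celltypes)
    probes = [f"cg{i:08d}" for i in range(n_probes)]
    cols = [f"celltype_{c}" for c in range(n_celltypes)]
    return pd.DataFrame(ref, index=probes, columns=cols)


def _parse_block_driver(driver: str) -> tuple[str, int | None]:
    if driver == "latent":
        return "latent", None
    if driver.startswith("celltype:"):
        return "celltype", int(driver.split(":", 1)[1])
    raise ValueError(f"unknown module-block driver {driver!r}")


def generate_cohorts(
    specs: list[StratumSpec],
    n_probes: int,
    n_causal: int,
    seed: int,
    *,
    n_celltypes: int = 3,
    causal_effect_size: float = 0.05,
    negative_fraction: float = 0.88,
    beta_noise_sd: float = 0.03,
    cell_var_frac: float = 0.10,
    family_var_frac: float = 0.25,
    celltype_effect_scale: float = 1.5,
    dirichlet_concentration: float = 10.0,
    module_blocks: list[tuple[int, float, str]] | None = None,
    smoking_effects: tuple[float, float] = (0.0, 0.0),
    missing_rate: float = 0.0,
    chrx_fraction: float = 0.02,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, TruthRecord]:
    """Generate (beta matrix, phenotypes, probe annotation, truth record).

    The beta matrix is probes x samples.  LTL is assembled per stratum from
    an age slope calibrated to the stratum's target age-LTL correlation,
    cell-proportion effects (the confounder the full adjustment removes),
    planted causal-CpG effects with ``negative_fraction`` of negative signs,
    a family random intercept for paired samples, and residual noise scaled
    so the stratum LTL variance matches its spec.

    ``module_blocks`` plants co-methylated CpG blocks: each entry is
    ``(block_size, within_block_corr, driver)`` with driver ``"latent"`` or
    ``"celltype:<j>"`` (block driven by cell type *j*'s proportion, which
    recreates the blood-cell-confounded modules seen in real data).
    """
    if n_causal > n_probes:
        raise ValueError("n_causal must be <= n_probes")
    if not specs:
        raise ValueError("at least one stratum spec required")
    rng = np.random.default_rng(seed)

    probe_ids = np.array([f"cg{i:08d}" for i in range(n_probes)])
    ref, disc_idx = _signature_matrix(rng, n_probes, n_celltypes)
    celltype_names = [f"celltype_{c}" for c in range(n_celltypes)]

    # planted causal effects on LTL.  ``causal_effect_size`` is LTL units
    # per *standard deviation* of methylation; the per-CpG coefficient
    # (LTL units per beta unit) divides by the model sd so every causal
    # CpG contributes a comparable LTL variance.  The model sd combines
    # Dirichlet mixing variance across cell types with the probe noise.
    # causal CpGs are drawn from the non-discriminating probes so their LTL
    # effect is a pathway distinct from cell composition (which confounds
    # through the discriminating probes and is removed by full adjustment)
    nondisc = np.setdiff1d(np.arange(n_probes), disc_idx)
    pool = nondisc if nondisc.size >= n_causal else np.arange(n_probes)
    causal_idx = rng.choice(pool, size=n_causal, replace=False)
    signs = np.where(rng.random(n_causal) < negative_fraction, -1.0, 1.0)
    var_mix = ((ref**2).mean(axis=1) - ref.mean(axis=1) ** 2) / (
        n_celltypes * dirichlet_concentration + 1.0
    )
    sd_model = np.sqrt(var_mix + beta_noise_sd**2)
    effects = signs * causal_effect_size / np.maximum(sd_model[causal_idx], 1e-3)
    causal_effects = dict(zip(probe_ids[causal_idx], effects))

    # co-methylation blocks occupy probes not used as causal CpGs
    module_blocks = module_blocks or []
    free = np.setdiff1d(np.arange(n_probes), causal_idx)
    rng.shuffle(free)
    block_members: list[tuple[np.ndarray, str, float]] = []
    cursor = 0
    for size, corr, driver in module_blocks:
        if cursor + size > free.size:
            raise ValueError("not enough free probes for the requested module blocks")
        block_members.append((free[cursor : cursor + size], driver, corr))
        cursor += size

    # direction of cell-type effects on LTL, in LTL units per proportion
    c_dir = rng.normal(size=n_celltypes)
    c_dir = c_dir / np.linalg.norm(c_dir)
    celltype_effects = celltype_effect_scale * c_dir

    sample_rows = []
    beta_cols = []
    prop_rows = []
    clipped = 0
    fam_counter = 0
    latent_factors: dict[str, list[np.ndarray]] = {d: [] for _, d, _ in block_members}

    for spec in specs:
        n = spec.n
        sid = spec.stratum_id
        # twin/sib pairs share family id, age and a family intercept
        n_paired = 2 * int(spec.family_fraction * n / 2)
        family_id = np.array([None] * n, dtype=object)
        fam_intercept = np.zeros(n)
        ages = rng.uniform(*spec.age_range, size=n)
        for p in range(n_paired // 2):
            i, j = 2 * p, 2 * p + 1
            fam_counter += 1
            family_id[i] = family_id[j] = f"fam{fam_counter:05d}"
            ages[j] = ages[i]
            g = rng.normal(0.0, np.sqrt(family_var_frac) * spec.ltl_sd)
            fam_intercept[i] = fam_intercept[j] = g

        props = rng.dirichlet(np.full(n_celltypes, dirichlet_concentration), size=n)
        noise = rng.normal(0.0, beta_noise_sd, size=(n_probes, n))
        raw = ref @ props.T + noise

        block_factor = {}
        for members, driver, corr in block_members:
            kind, j = _parse_block_driver(driver)
            if kind == "latent":
                f = rng.standard_normal(n)
            else:
                pj = props[:, j]
                f = (pj - pj.mean()) / max(pj.std(), 1e-12)
            block_factor[(driver, corr, members[0])] = f
            mu_b = rng.uniform(0.3, 0.7, size=members.size)
            eps = rng.standard_normal((members.size, n))
            scale = 0.12
            raw[members] = mu_b[:, None] + scale * (
                np.sqrt(corr) * f[None, :] + np.sqrt(1 - corr) * eps
            )

        beta = np.clip(raw, 0.0, 1.0)
        clipped += int((raw != beta).sum())

        smoking = rng.choice(SMOKING_LEVELS, size=n, p=(0.55, 0.25, 0.20))
        smoke_add = np.where(
            smoking == "former", smoking_effects[0],
            np.where(smoking == "current", smoking_effects[1], 0.0),
        )

        cell_comp = props @ celltype_effects
        causal_comp = (beta[causal_idx].T - ref[causal_idx].mean(axis=1)) @ effects
        other = cell_comp + causal_comp + fam_intercept + smoke_add
        other = other - other.mean()

        r = spec.target_age_ltl_corr
        sd_age = ages.std()
        b_age = r * spec.ltl_sd / sd_age if sd_age > 0 else 0.0
        v_other = other.var()
        resid_var = max(
            spec.ltl_sd**2 * (1 - r**2) - v_other, 0.05 * spec.ltl_sd**2
        )
        ltl = (
            spec.ltl_mean
            + b_age * (ages - ages.mean())
            + other
            + rng.normal(0.0, np.sqrt(resid_var), size=n)
        )
        ltl = np.maximum(ltl, 0.05 * spec.ltl_mean)  # LTL is a positive length/ratio

        ids = [f"{sid}_s{k:04d}" for k in range(n)]
        sample_rows.append(
            pd.DataFrame(
                {
                    "sample_id": ids,
                    "ltl": ltl,
                    "age": ages,
                    "sex": spec.sex,
                    "ethnicity": spec.ethnicity,
                    "cohort": spec.cohort_name,
                    "batch": spec.batch,
                    "family_id": family_id,
                    "smoking": smoking,
                    "stratum_id": sid,
                }
            )
        )
        beta_cols.append(pd.DataFrame(beta, index=probe_ids, columns=ids))
        prop_rows.append(pd.DataFrame(props, index=ids, columns=celltype_names))

    pheno = pd.concat(sample_rows, ignore_index=True)
    beta = pd.concat(beta_cols, axis=1)
    cell_props = pd.concat(prop_rows)
    clipped_fraction = clipped / beta.size
    if clipped_fraction > 0:
        logger.info("clipped %.4f%% of beta entries to [0, 1]", 100 * clipped_fraction)

    if missing_rate > 0:
        mask = rng.random(beta.shape) < missing_rate
        beta = beta.mask(mask)

    annot = _make_annotation(rng, probe_ids, chrx_fraction)

    n_neg = int((effects < 0).sum())
    truth = TruthRecord(
        causal_cpg_effects=causal_effects,
        negative_fraction=n_neg / n_causal if n_causal else 0.0,
        celltype_effects=celltype_effects,
        planted_module_blocks=[
            (frozenset(probe_ids[m]), d) for m, d, _ in block_members
        ],
        reference=pd.DataFrame(ref, index=probe_ids, columns=celltype_names),
        cell_proportions=cell_props,
        clipped_fraction=clipped_fraction,
    )
    return beta, pheno, annot, truth


def _make_annotation(
    rng: np.random.Generator, probe_ids: np.ndarray, chrx_fraction: float
) -> pd.DataFrame:
    """BED-like probe annotation over hg19-length chromosomes."""
    from .position_enrich import load_genome_table

    genome = load_genome_table()
    n = probe_ids.size
    chroms = np.array(AUTOSOMES)[rng.integers(0, len(AUTOSOMES), size=n)].astype(object)
    n_x = int(chrx_fraction * n)
    if n_x:
        chroms[rng.choice(n, size=n_x, replace=False)] = "chrX"
    pos = np.array(
        [rng.integers(0, genome.lengths[c]) for c in chroms], dtype=np.int64
    )
    return pd.DataFrame(
        {
            "cpg_id": probe_ids,
            "chrom": chroms,
            "pos": pos,
            "gene": [f"GENE{i // 5}" for i in range(n)],
            "island_relation": rng.choice(ISLAND_RELATIONS, size=n),
        }
    )


def generate_smr_dataset(
    n_snps: int,
    n_samples: int,
    truth: TruthRecord,
    seed: int,
    *,
    resid_sd: float = 1.0,
    snp_effect: float | None = None,
) -> pd.DataFrame:
    """Simulate per-CpG instrument SNPs and paired GWAS/mQTL summary stats.

    Each causal chain is SNP -> CpG -> LTL: a biallelic genotype drives the
    CpG's (linear-scale) methylation with the SNP->CpG effect, and LTL
    responds to methylation with the CpG->LTL effect from the truth record
    (zero for non-causal CpGs).  Effects and standard errors come from
    per-SNP least-squares fits, so GWAS effect ~= (SNP->CpG) x (CpG->LTL)
    within simulation error.  Updates ``truth.smr_truth`` in place.
    """
    if n_samples < 10:
        raise ValueError("n_samples must be >= 10")
    rng = np.random.default_rng(seed)
    if truth.reference is None:
        raise ValueError("truth record lacks the probe list (reference is None)")
    pool = list(truth.causal_cpg_effects)
    extra = [p for p in truth.reference.index if p not in truth.causal_cpg_effects]
    cpgs = (pool + extra)[:n_snps]
    if len(cpgs) < n_snps:
        raise ValueError("not enough probes for the requested number of SNPs")

    rows = []
    truth.smr_truth = {}
    alleles = np.array(["A", "C", "G", "T"])
    for k, cpg in enumerate(cpgs):
        b_zx = rng.uniform(0.3, 0.6) if snp_effect is None else snp_effect
        b_xy = truth.causal_cpg_effects.get(cpg, 0.0)
        maf = rng.uniform(0.1, 0.5)
        g = rng.binomial(2, maf, size=n_samples).astype(float)
        m = b_zx * g + rng.normal(0.0, resid_sd, size=n_samples)
        y = b_xy * m + rng.normal(0.0, resid_sd, size=n_samples)
        ea, oa = rng.choice(alleles, size=2, replace=False)
        b_m, se_m = _ols_slope(g, m)
        b_g, se_g = _ols_slope(g, y)
        rows.append(
            {
                "cpg": cpg, "snp": f"rs{k:06d}",
                "effect_allele": ea, "other_allele": oa,
                "b_gwas": b_g, "se_gwas": se_g,
                "b_mqtl": b_m, "se_mqtl": se_m,
                "n": n_samples,
            }
        )
        truth.smr_truth[cpg] = (b_zx, b_xy)
    return pd.DataFrame(rows)


def _ols_slope(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Simple-regression slope and its standard error."""
    x = x - x.mean()
    sxx = (x**2).sum()
    if sxx == 0:
        return np.nan, np.nan
    b = (x * y).sum() / sxx
    resid = y - y.mean() - b * x
    s2 = (resid**2).sum() / (x.size - 2)
    return float(b), float(np.sqrt(s2 / sxx))
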