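"""Consensus co-methylation network modules across cohorts.

Follows the weighted-correlation-network recipe: per cohort, an unsigned
adjacency ``a_ij = |bicor(x_i, x_j)|^beta`` (soft power beta, default 6) is
turned into a topological overlap matrix

    TOM_ij = (sum_u a_iu a_uj + a_ij) / (min(k_i, k_j) + 1 - a_ij),

cohort TOMs are scaled so a chosen quantile (default 0.95) matches the
first cohort's, and the consensus is a componentwise quantile across
cohorts (default 0 = minimum).  Modules come from average-linkage
hierarchical clustering of 1 - TOM with a static height cut, a minimum
module size (smaller clusters become "grey"), and iterative merging of
modules whose eigengenes are closer than the merge threshold (default
0.15) in 1 - correlation.  Module eigengenes are the first principal
component of the standardized module matrix, sign-aligned with mean
methylation.  Module-trait relationships reuse the EWAS bicor -> Z
transform combined across strata with the weighted-Stouffer rule.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .ewas import bicor, bicor_matrix, r_to_pz
from .meta import stouffer_meta

logger = logging.getLogger(__name__)

GREY = "grey"


@dataclass(frozen=True)
class NetworkConfig:
    n_subsample: int = 30_000
    soft_power: float = 6.0
    consensus_quantile: float = 0.0
    tom_scaling_quantile: float = 0.95
    min_module_size: int = 30
    merge_threshold: float = 0.15
    cut_height: float = 0.99       # fraction of the dendrogram height range
    seed: int = 0

    def __post_init__(self):
        if not 0 < self.merge_threshold < 1:
            raise ValueError("merge_threshold must be in (0, 1)")
        if not 0 <= self.consensus_quantile <= 1:
            raise ValueError("consensus_quantile must be in [0, 1]")


@dataclass
class ModuleSet:
    assignment: pd.Series                       # cpg -> module label
    eigengenes: dict[str, pd.DataFrame] = field(default_factory=dict)
    module_trait_meta: pd.DataFrame | None = None


def _tom_from_adjacency(A: np.ndarray) -> np.ndarray:
    """Topological overlap from an adjacency with unit diagonal."""
    A0 = A.copy()
    np.fill_diagonal(A0, 0.0)
    L = A0 @ A0
    k = A0.sum(axis=1)
    kmin = np.minimum.outer(k, k)
    with np.errstate(divide="ignore", invalid="ignore"):
        tom = (L + A0) / (kmin + 1.0 - A0)
    tom = np.where(np.isfinite(tom), tom, 0.0)
    np.fill_diagonal(tom, 1.0)
    return np.clip(tom, 0.0, 1.0)


def subsample_probes(
    probe_ids: pd.Index, config: NetworkConfig
) -> pd.Index:
    """Seeded random probe subsample (all probes if fewer than requested)."""
    if config.n_subsample >= len(probe_ids):
        return probe_ids
    rng = np.random.default_rng(config.seed)
    pick = np.sort(rng.choice(len(probe_ids), size=config.n_subsample, replace=False))
    return probe_ids[pick]


def consensus_tom(
    beta_by_cohort: list[pd.DataFrame],
    config: NetworkConfig,
    return_cohort_toms: bool = False,
):
    """Consensus topological-overlap matrix over cohorts sharing probes.

    Returns (TOM, probe index of its rows), plus the list of per-cohort
    scaled TOMs when ``return_cohort_toms`` is set.  With a single cohort
    the plain TOM is returned with a warning.
    """
    if not beta_by_cohort:
        raise ValueError("no cohorts supplied")
    probes = beta_by_cohort[0].index
    for b in beta_by_cohort[1:]:
        if not probes.equals(b.index):
            probes = probes.intersection(b.index)
    probes = subsample_probes(probes, config)
    if len(beta_by_cohort) < 2:
        logger.warning("single cohort: plain (non-consensus) TOM")

    toms = []
    ref_q = None
    for beta in beta_by_cohort:
        if beta.shape[1] < 20:
            raise ValueError("each cohort needs at least 20 samples")
        X = beta.loc[probes].to_numpy(dtype=float)
        C = bicor_matrix(X)
        C = np.nan_to_num(C, nan=0.0)
        A = np.abs(C) ** config.soft_power
        np.fill_diagonal(A, 1.0)
        tom = _tom_from_adjacency(A)
        off = tom[np.triu_indices_from(tom, k=1)]
        q = np.quantile(off, config.tom_scaling_quantile)
        if ref_q is None:
            ref_q = q
        elif q > 0:
            tom = np.clip(tom * (ref_q / q), 0.0, 1.0)
        toms.append(tom)
    consensus = np.quantile(np.stack(toms), config.consensus_quantile, axis=0)
    np.fill_diagonal(consensus, 1.0)
    if return_cohort_toms:
        return consensus, probes, toms
    return consensus, probes


def module_eigengene(beta_module: pd.DataFrame) -> pd.Series:
    """First principal component of a sample x CpG module matrix.

    Columns are standardized first; the unit-norm sample-score vector is
    sign-aligned so it correlates positively with the module's mean
    methylation.
    """
    if beta_module.shape[1] < 2 or beta_module.shape[0] < 3:
        raise ValueError("need >= 2 CpGs and >= 3 samples")
    X = beta_module.to_numpy(dtype=float)
    sd = X.std(axis=0)
    if (sd == 0).all():
        raise ValueError("module is constant across samples")
    keep = sd > 0
    Xs = (X[:, keep] - X[:, keep].mean(axis=0)) / sd[keep]
    U, S, _ = np.linalg.svd(Xs, full_matrices=False)
    e = U[:, 0]
    mean_meth = X.mean(axis=1)
    if np.corrcoef(e, mean_meth)[0, 1] < 0:
        e = -e
    return pd.Series(e, index=beta_module.index, name="eigengene")


def _merge_modules(
    labels: np.ndarray, beta: pd.DataFrame, threshold: float
) -> np.ndarray:
    """Iteratively merge the closest module pair (eigengene 1-corr < threshold)."""
    labels = labels.copy()
    while True:
        mods = [m for m in np.unique(labels) if m != GREY]
        if len(mods) < 2:
            return labels
        eg = {
            m: module_eigengene(beta.loc[labels == m].T).to_numpy() for m in mods
        }
        best, best_d = None, np.inf
        for i in range(len(mods)):
            for j in range(i + 1, len(mods)):
                d = 1.0 - np.corrcoef(eg[mods[i]], eg[mods[j]])[0, 1]
                if d < best_d:
                    best, best_d = (mods[i], mods[j]), d
        if best_d >= threshold:
            return labels
        a, b = best
        logger.info("merging modules %s and %s (eigengene dissim %.3f)", a, b, best_d)
        labels[labels == b] = a


def detect_modules(
    tom: np.ndarray,
    config: NetworkConfig,
    beta: pd.DataFrame | None = None,
    probe_ids: pd.Index | None = None,
) -> pd.Series:
    """Module assignment from a TOM: average-linkage clustering of 1 - TOM,
    static cut, size gate, then eigengene merging.

    ``beta`` (probes x samples, rows covering the TOM probes) is needed for
    the eigengene-merge step; without it, merging is skipped with a
    warning.  Returns cpg -> module label ("grey" = unassigned).
    """
    n = tom.shape[0]
    if probe_ids is None:
        probe_ids = beta.index[:n] if beta is not None else pd.RangeIndex(n)
    dissim = 1.0 - tom
    np.fill_diagonal(dissim, 0.0)
    dissim = (dissim + dissim.T) / 2.0
    Z = hierarchy.linkage(squareform(dissim, checks=False), method="average")
    heights = Z[:, 2]
    cut = heights.min() + config.cut_height * (heights.max() - heights.min())
    raw = hierarchy.fcluster(Z, t=cut, criterion="distance")

    labels = np.full(n, GREY, dtype=object)
    next_id = 1
    for c in np.unique(raw):
        members = raw == c
        if members.sum() >= config.min_module_size:
            labels[members] = f"module_{next_id}"
            next_id += 1
    if (labels == GREY).all():
        logger.warning("all probes unassigned (grey)")
        return pd.Series(labels, index=probe_ids, name="module")

    if beta is not None:
        sub = beta.loc[probe_ids]
        labels = _merge_modules(labels, sub.set_axis(range(n)), config.merge_threshold)
        # relabel in size order for stable naming after merges
        mods = [m for m in pd.unique(labels) if m != GREY]
        sizes = {m: (labels == m).sum() for m in mods}
        remap = {
            m: f"module_{i+1}"
            for i, m in enumerate(sorted(mods, key=lambda m: -sizes[m]))
        }
        labels = np.array([remap.get(m, GREY) for m in labels], dtype=object)
    else:
        logger.warning("no methylation data supplied; eigengene merging skipped")
    return pd.Series(labels, index=probe_ids, name="module")


def cohort_eigengenes(
    assignment: pd.Series, beta_by_cohort: dict[str, pd.DataFrame]
) -> dict[str, pd.DataFrame]:
    """Per-cohort sample x module eigengene matrices."""
    out = {}
    for cohort, beta in beta_by_cohort.items():
        cols = {}
        for m in sorted(set(assignment) - {GREY}):
            cpgs = assignment.index[assignment == m]
            cols[m] = module_eigengene(beta.loc[cpgs].T)
        out[cohort] = pd.DataFrame(cols, index=beta.columns)
    return out


def module_trait_meta(
    assignment: pd.Series,
    beta_by_stratum: dict[str, pd.DataFrame],
    traits_by_stratum: dict[str, pd.DataFrame],
) -> pd.DataFrame:
    """Module x trait meta-Z table across strata.

    Per stratum, each module eigengene is correlated (bicor) with each
    trait column, transformed to a signed Z, and combined across strata
    with sqrt(n) Stouffer weights.  A stratum missing a trait column simply
    does not contribute to that cell; an all-missing cell is NaN.  Returns
    a table indexed by module with a two-level column index
    (trait, {"z", "p"}).
    """
    modules = sorted(set(assignment) - {GREY})
    traits = []
    for t in traits_by_stratum.values():
        traits += [c for c in t.columns if c not in traits]
    zs: dict[tuple[str, str], tuple[list, list]] = {
        (m, t): ([], []) for m in modules for t in traits
    }
    for sid, beta in beta_by_stratum.items():
        tdf = traits_by_stratum.get(sid)
        if tdf is None:
            continue
        samples = beta.columns.intersection(tdf.index)
        for m in modules:
            cpgs = assignment.index[assignment == m]
            eg = module_eigengene(beta.loc[cpgs, samples].T)
            for t in traits:
                if t not in tdf.columns:
                    logger.warning("stratum %s lacks trait %s", sid, t)
                    continue
                y = tdf.loc[samples, t].to_numpy(dtype=float)
                r = bicor(eg.to_numpy(), y)
                if not np.isfinite(r):
                    continue
                _, z = r_to_pz(np.array([r]), np.array([len(samples)]))
                zs[(m, t)][0].append(float(z[0]))
                zs[(m, t)][1].append(len(samples))
    cols = pd.MultiIndex.from_product([traits, ["z", "p"]])
    out = pd.DataFrame(index=modules, columns=cols, dtype=float)
    for (m, t), (zlist, nlist) in zs.items():
        if not zlist:
            continue
        z, p = stouffer_meta(np.array(zlist), np.array(nlist))
        out.loc[m, (t, "z")] = z
        out.loc[m, (t, "p")] = p
    return out
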