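"""Per-stratum epigenome-wide robust correlation against adjusted LTL.

The association statistic is the biweight midcorrelation (bicor): each
vector is centered on its median, deviations are weighted with Tukey
biweights ``(1 - u^2)^2`` where ``u = deviation / (9 * MAD)`` (weights zero
for |u| >= 1), and the correlation is the normalized cross-product of the
weighted deviations.  When a vector's MAD is zero the biweight is undefined
and that vector falls back to ordinary mean-centering (Pearson behaviour),
with the fallback logged.

p-values use the Student-t transform of the correlation,
``t = r * sqrt((n - 2) / (1 - r^2))`` on n-2 degrees of freedom, and the
signed Z equivalent is ``sign(r) * Phi^{-1}(1 - p/2)``, capped at |Z| = 40
(beyond double-precision tail resolution).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

#: Cap on |Z| so downstream meta-analysis arithmetic stays finite.
Z_CAP = 40.0

MIN_PAIRS = 4


@dataclass(frozen=True)
class ProbeFilter:
    """Probe retention rules, applied (as set intersections) before any statistics."""

    autosomes_only: bool = False
    shared_platform_probes: frozenset | None = None
    exclude_snp_probes: frozenset | None = None
    exclude_multimap_probes: frozenset | None = None


def _biweight_vector(x: np.ndarray) -> np.ndarray | None:
    """Weighted, normalized deviations for one vector; None if zero variance."""
    med = np.median(x)
    mad = np.median(np.abs(x - med))
    if mad == 0:
        logger.debug("MAD = 0; Pearson fallback for one vector")
        d = x - x.mean()
    else:
        u = (x - med) / (9.0 * mad)
        inside = np.abs(u) < 1.0
        uc = np.where(inside, u, 1.0)  # avoid overflow outside the support
        w = (1.0 - uc**2) ** 2 * inside
        d = (x - med) * w
    nrm = np.sqrt((d**2).sum())
    if nrm == 0:
        return None
    return d / nrm


def bicor(x, y) -> float:
    """Biweight midcorrelation of two vectors; NaN when undefined.

    Undefined when fewer than 4 complete pairs remain or either vector has
    zero variance.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D vectors of equal length")
    ok = np.isfinite(x) & np.isfinite(y)
    if ok.sum() < MIN_PAIRS:
        return float("nan")
    a = _biweight_vector(x[ok])
    b = _biweight_vector(y[ok])
    if a is None or b is None:
        return float("nan")
    return float(np.clip(a @ b, -1.0, 1.0))


def _biweight_rows(X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Row-wise weighted normalized deviations for a (probes x samples) matrix.

    Returns the prepared matrix and a boolean mask of zero-variance rows
    (their prepared rows are zero so dot products give 0; callers mark them
    undefined).
    """
    med = np.median(X, axis=1, keepdims=True)
    absdev = np.abs(X - med)
    mad = np.median(absdev, axis=1, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        u = (X - med) / (9.0 * mad)
    inside = np.abs(u) < 1.0
    uc = np.where(inside, u, 1.0)
    w = (1.0 - uc**2) ** 2 * inside
    D = (X - med) * w
    fallback = mad[:, 0] == 0
    if fallback.any():
        logger.debug("MAD = 0 for %d probes; Pearson fallback", int(fallback.sum()))
        Xf = X[fallback]
        D[fallback] = Xf - Xf.mean(axis=1, keepdims=True)
    nrm = np.sqrt((D**2).sum(axis=1, keepdims=True))
    zero_var = nrm[:, 0] == 0
    nrm[zero_var] = 1.0
    return D / nrm, zero_var


def bicor_matrix(X: np.ndarray) -> np.ndarray:
    """All pairwise biweight midcorrelations between rows of X.

    Valid because each vector's biweights depend only on that vector, so
    bicor(x_i, x_j) is the dot product of the two prepared rows.
    """
    D, zero_var = _biweight_rows(np.asarray(X, dtype=float))
    C = np.clip(D @ D.T, -1.0, 1.0)
    C[zero_var, :] = np.nan
    C[:, zero_var] = np.nan
    np.fill_diagonal(C, 1.0)
    C[np.ix_(zero_var, zero_var)] = np.nan
    return C


def r_to_pz(r: np.ndarray, n: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Two-sided p and signed Z from correlation(s) and complete-pair count(s).

    |r| = 1 maps to p = 0 and Z = +/-Z_CAP; undefined inputs propagate NaN.
    """
    r = np.asarray(r, dtype=float)
    n = np.asarray(n, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt((n - 2) / (1.0 - r**2))
    df = np.maximum(n - 2, 1)
    p = 2.0 * stats.t.sf(np.abs(t), df)
    p = np.where(np.abs(r) >= 1.0, 0.0, p)
    with np.errstate(divide="ignore"):
        z = np.sign(r) * stats.norm.isf(p / 2.0)
    z = np.clip(z, -Z_CAP, Z_CAP)
    bad = ~np.isfinite(r) | (n < MIN_PAIRS)
    p = np.where(bad, np.nan, p)
    z = np.where(bad, np.nan, z)
    # r exactly 0 gives t = 0 -> p = 1, z = 0 by construction
    return p, z


def apply_probe_filter(
    annotation: pd.DataFrame, probe_filter: ProbeFilter
) -> pd.Index:
    """Retained probe ids after intersecting all requested filters.

    Unknown ids in exclusion lists are warned about and ignored; removal
    counts per filter are logged.
    """
    probes = pd.Index(annotation["cpg_id"])
    keep = pd.Series(True, index=probes)
    if probe_filter.autosomes_only:
        auto = annotation.set_index("cpg_id")["chrom"].isin(
            [f"chr{i}" for i in range(1, 23)]
        )
        logger.info("autosomes_only removed %d probes", int((~auto).sum()))
        keep &= auto
    if probe_filter.shared_platform_probes is not None:
        shared = probes.isin(probe_filter.shared_platform_probes)
        logger.info("shared-platform filter removed %d probes", int((~shared).sum()))
        keep &= pd.Series(shared, index=probes)
    for name, excl in (
        ("exclude_snp_probes", probe_filter.exclude_snp_probes),
        ("exclude_multimap_probes", probe_filter.exclude_multimap_probes),
    ):
        if excl is None:
            continue
        unknown = set(excl) - set(probes)
        if unknown:
            logger.warning(
                "%s: %d ids not in annotation, ignored", name, len(unknown)
            )
        hit = probes.isin(excl)
        logger.info("%s removed %d probes", name, int(hit.sum()))
        keep &= pd.Series(~hit, index=probes)
    return probes[keep.to_numpy()]


def stratum_ewas(
    beta: pd.DataFrame,
    trait: pd.DataFrame,
    probe_filter: ProbeFilter | None = None,
    annotation: pd.DataFrame | None = None,
    *,
    logit_transform: bool = False,
) -> pd.DataFrame:
    """Epigenome-wide bicor of every retained CpG against the adjusted trait.

    ``beta`` is probes x samples; ``trait`` has columns ``sample_id`` and
    ``residual_ltl`` (and optionally ``stratum_id``).  Missing beta values
    are handled pairwise-complete per CpG.  Returns a table with columns
    ``cpg, r, n, p, z`` (attrs carry the stratum id).  Betas are analyzed
    untransformed by default; ``logit_transform`` switches to M-values.
    """
    if probe_filter is not None:
        if annotation is None:
            raise ValueError("probe_filter requires an annotation table")
        retained = apply_probe_filter(annotation, probe_filter)
        retained = retained.intersection(beta.index)
        if len(retained) == 0:
            raise ValueError("all probes were filtered out")
        beta = beta.loc[beta.index.intersection(retained)]

    missing_samples = set(trait["sample_id"]) - set(beta.columns)
    if missing_samples:
        raise ValueError(
            f"{len(missing_samples)} trait samples absent from beta matrix"
        )
    y = trait.set_index("sample_id")["residual_ltl"]
    X = beta[y.index].to_numpy(dtype=float)
    if logit_transform:
        eps = 1e-6
        X = np.log2(np.clip(X, eps, 1 - eps) / (1 - np.clip(X, eps, 1 - eps)))
    yv = y.to_numpy(dtype=float)

    if np.isnan(X).any() or np.isnan(yv).any():
        r = np.array([bicor(row, yv) for row in X])
        n = (np.isfinite(X) & np.isfinite(yv)[None, :]).sum(axis=1)
    else:
        D, zero_var = _biweight_rows(X)
        b = _biweight_vector(yv)
        if b is None:
            raise ValueError("adjusted trait has zero variance")
        r = np.clip(D @ b, -1.0, 1.0)
        r[zero_var] = np.nan
        n = np.full(X.shape[0], yv.size)
    p, z = r_to_pz(r, n)
    out = pd.DataFrame({"cpg": beta.index, "r": r, "n": n, "p": p, "z": z})
    if "stratum_id" in trait.columns and len(trait):
        out.attrs["stratum_id"] = str(trait["stratum_id"].iloc[0])
    return out
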