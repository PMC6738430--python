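"""Sample-size-weighted Stouffer combination of per-stratum EWAS Z scores.

Z scores from the 16 strata are combined as

    Z_meta = sum_i Z_i * w_i / sqrt(sum_i w_i^2),    w_i = sqrt(n_i)

so Z_meta is standard normal under the null, and
``p_meta = 2 * (1 - Phi(|Z_meta|))``.  Strata with undefined Z for a CpG
are dropped for that CpG (never imputed) and the total n reduced
accordingly.  Group metas (European/African x male/female) and the global
meta over all strata follow the same rule; the combination is associative:
combining the four group meta-Zs with sqrt(group n) weights equals
combining all strata directly.

Genome-wide significance uses the fixed threshold P < 1e-7, the 5%
family-wise error level for 450K methylation arrays.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

GENOME_WIDE_P = 1e-7

GROUPS = ("EuropeanMale", "AfricanMale", "EuropeanFemale", "AfricanFemale")
GLOBAL = "Global"


def stouffer_meta(z_by_stratum, n_by_stratum) -> tuple[float, float]:
    """Weighted-Z combination of per-stratum Z scores.

    Non-finite Z entries are excluded (with a warning); the corresponding
    n does not contribute to the denominator.
    """
    z = np.asarray(z_by_stratum, dtype=float)
    n = np.asarray(n_by_stratum, dtype=float)
    if z.shape != n.shape or z.ndim != 1 or z.size == 0:
        raise ValueError("z and n must be equal-length non-empty vectors")
    if (n[np.isfinite(z)] < 4).any():
        raise ValueError("all contributing strata must have n >= 4")
    ok = np.isfinite(z)
    if not ok.all():
        logger.warning("excluding %d strata with undefined Z", int((~ok).sum()))
    if not ok.any():
        raise ValueError("no stratum contributed a finite Z")
    w = np.sqrt(n[ok])
    z_meta = float((z[ok] * w).sum() / np.sqrt((w**2).sum()))
    p_meta = float(2.0 * stats.norm.sf(abs(z_meta)))
    return z_meta, p_meta


def _combine_frame(results: list[pd.DataFrame]) -> pd.DataFrame:
    """Vectorized per-CpG Stouffer combination over a list of stratum tables."""
    cpgs = results[0]["cpg"]
    Z = np.column_stack([r.set_index("cpg").loc[cpgs, "z"].to_numpy() for r in results])
    N = np.column_stack(
        [r.set_index("cpg").loc[cpgs, "n"].to_numpy(dtype=float) for r in results]
    )
    ok = np.isfinite(Z)
    N_eff = np.where(ok, N, 0.0)
    Zv = np.where(ok, Z, 0.0)
    denom = np.sqrt(N_eff.sum(axis=1))
    with np.errstate(divide="ignore", invalid="ignore"):
        z_meta = (Zv * np.sqrt(N_eff)).sum(axis=1) / denom
    z_meta = np.where(denom > 0, z_meta, np.nan)
    p_meta = 2.0 * stats.norm.sf(np.abs(z_meta))
    return pd.DataFrame(
        {
            "cpg": cpgs.to_numpy(),
            "z": z_meta,
            "p": p_meta,
            "n": N_eff.sum(axis=1).astype(int),
            "n_strata": ok.sum(axis=1),
            "direction": np.sign(z_meta),
        }
    )


def run_meta(
    stratum_results: list[pd.DataFrame],
    grouping: dict[str, str],
) -> dict[str, pd.DataFrame]:
    """Group-specific and global meta-analyses from per-stratum EWAS tables.

    ``stratum_results`` are outputs of :func:`telemeth.ewas.stratum_ewas`
    (attrs carry the stratum id); ``grouping`` maps stratum id -> group
    label.  Returns one combined table per non-empty group plus "Global".
    """
    by_id = {}
    for r in stratum_results:
        sid = r.attrs.get("stratum_id")
        if sid is None:
            raise ValueError("stratum result lacks a stratum_id (attrs)")
        by_id[sid] = r
    missing = set(by_id) - set(grouping)
    if missing:
        raise ValueError(f"grouping does not cover strata: {sorted(missing)}")

    out: dict[str, pd.DataFrame] = {}
    for group in GROUPS:
        members = [by_id[s] for s in by_id if grouping[s] == group]
        if not members:
            logger.warning("group %s has no strata; omitted", group)
            continue
        out[group] = _combine_frame(members)
    out[GLOBAL] = _combine_frame(list(by_id.values()))
    return out


def significance_calls(
    meta: pd.DataFrame, threshold: float = GENOME_WIDE_P
) -> pd.DataFrame:
    """Per-CpG genome-wide significance flags and direction of association."""
    sig = meta["p"] < threshold
    return pd.DataFrame(
        {
            "cpg": meta["cpg"],
            "significant": sig.fillna(False),
            "direction": np.sign(meta["z"]),
        }
    )


def group_concordance(meta_a: pd.DataFrame, meta_b: pd.DataFrame) -> float:
    """Pearson correlation of two groups' meta-Z vectors over shared CpGs."""
    merged = meta_a.merge(meta_b, on="cpg", suffixes=("_a", "_b")).dropna(
        subset=["z_a", "z_b"]
    )
    if len(merged) < 3:
        raise ValueError("need at least 3 shared CpGs")
    return float(np.corrcoef(merged["z_a"], merged["z_b"])[0, 1])
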