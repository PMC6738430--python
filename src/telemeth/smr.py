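"""Summary-data Mendelian randomization: causal effect of methylation on LTL.

For a CpG with instrument SNP, the causal-effect estimate is the ratio of
the SNP's GWAS effect on LTL to its mQTL effect on the CpG,

    b_smr = b_gwas / b_mqtl,

with the approximate test statistic

    T = z_gwas^2 * z_mqtl^2 / (z_gwas^2 + z_mqtl^2),   z = b / se,

referred to a chi-squared distribution with 1 df, and the delta-method
standard error se_smr^2 ~= b_smr^2 (se_gwas^2/b_gwas^2 + se_mqtl^2/b_mqtl^2).
A weak instrument (|z_mqtl| below the threshold, default 3) flags the
ratio as uninterpretable; b_mqtl = 0 leaves it undefined.  The HEIDI
heterogeneity test needs LD among multiple instruments and is out of
scope; the result schema reserves an empty ``heidi_p`` column.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

WEAK_Z_DEFAULT = 3.0

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


@dataclass(frozen=True)
class SummaryStatPair:
    """One CpG's instrument SNP with paired GWAS and mQTL effect/SE."""

    cpg: str
    snp: str
    b_gwas: float
    se_gwas: float
    b_mqtl: float
    se_mqtl: float

    def __post_init__(self):
        if not (self.se_gwas > 0 and self.se_mqtl > 0):
            raise ValueError("standard errors must be positive")
        if not (self.cpg and self.snp):
            raise ValueError("cpg and snp ids must be non-empty")


@dataclass(frozen=True)
class SMRResult:
    cpg: str
    snp: str
    b_smr: float          # NaN when undefined (b_mqtl = 0)
    se_smr: float
    p_smr: float
    weak_instrument: bool
    heidi_p: float = float("nan")   # reserved; HEIDI needs LD information


def smr_effect(
    pair: SummaryStatPair, weak_z_threshold: float = WEAK_Z_DEFAULT
) -> SMRResult:
    """Ratio estimate, delta-method SE and chi-squared(1) p for one pair."""
    z_g = pair.b_gwas / pair.se_gwas
    z_m = pair.b_mqtl / pair.se_mqtl
    if pair.b_mqtl == 0:
        return SMRResult(pair.cpg, pair.snp, float("nan"), float("nan"), 1.0, True)
    b = pair.b_gwas / pair.b_mqtl
    se = _delta_se(pair, b)
    denom = z_g**2 + z_m**2
    if denom == 0:
        T, p = 0.0, 1.0
    else:
        T = z_g**2 * z_m**2 / denom
        p = float(stats.chi2.sf(T, df=1))
    weak = abs(z_m) < weak_z_threshold
    return SMRResult(pair.cpg, pair.snp, float(b), float(se), p, bool(weak))


def _delta_se(pair: SummaryStatPair, b: float) -> float:
    rel_g = (pair.se_gwas / pair.b_gwas) ** 2 if pair.b_gwas != 0 else np.inf
    rel_m = (pair.se_mqtl / pair.b_mqtl) ** 2
    return float(abs(b) * np.sqrt(rel_g + rel_m)) if np.isfinite(rel_g) else float(
        pair.se_gwas / abs(pair.b_mqtl)
    )


def smr_batch(
    pairs: pd.DataFrame,
    results_filter: set | None = None,
    weak_z_threshold: float = WEAK_Z_DEFAULT,
) -> pd.DataFrame:
    """SMR over a table of (cpg, snp, b_gwas, se_gwas, b_mqtl, se_mqtl) rows.

    ``results_filter`` restricts to a CpG set (e.g. the genome-wide
    significant CpGs); one instrument SNP per CpG is assumed, and duplicate
    (cpg, snp) rows are an error.  Weak-instrument counts are logged.
    """
    if pairs.duplicated(subset=["cpg", "snp"]).any():
        raise ValueError("duplicate (cpg, snp) rows in summary-statistic pairs")
    if results_filter is not None:
        pairs = pairs[pairs["cpg"].isin(results_filter)]
    rows = []
    for rec in pairs.itertuples(index=False):
        pair = SummaryStatPair(
            cpg=rec.cpg, snp=rec.snp,
            b_gwas=float(rec.b_gwas), se_gwas=float(rec.se_gwas),
            b_mqtl=float(rec.b_mqtl), se_mqtl=float(rec.se_mqtl),
        )
        res = smr_effect(pair, weak_z_threshold)
        rows.append(res.__dict__)
    out = pd.DataFrame(
        rows,
        columns=["cpg", "snp", "b_smr", "se_smr", "p_smr", "weak_instrument",
                 "heidi_p"],
    )
    if len(out):
        logger.info(
            "SMR: %d pairs, %d weak instruments", len(out),
            int(out["weak_instrument"].sum()),
        )
    return out


def harmonize_alleles(
    gwas: pd.DataFrame, mqtl: pd.DataFrame
) -> pd.DataFrame:
    """Join GWAS and mQTL summary tables on SNP with allele harmonization.

    Inputs carry columns ``snp, effect_allele, other_allele, b, se`` (mQTL
    additionally ``cpg``).  Matching effect alleles are kept as-is; swapped
    alleles flip the mQTL effect sign; strand flips (A<->T, C<->G) are
    resolved by complementing before comparison; anything else is dropped
    with a logged count.  Returns the paired table consumed by
    :func:`smr_batch`.
    """
    merged = mqtl.merge(gwas, on="snp", suffixes=("_mqtl", "_gwas"))
    rows, dropped = [], 0
    for rec in merged.itertuples(index=False):
        ea_g, oa_g = rec.effect_allele_gwas.upper(), rec.other_allele_gwas.upper()
        ea_m, oa_m = rec.effect_allele_mqtl.upper(), rec.other_allele_mqtl.upper()
        sign = None
        for flip in (False, True):
            a, o = (ea_g, oa_g)
            if flip:
                a, o = _COMPLEMENT.get(a, "?"), _COMPLEMENT.get(o, "?")
            if (a, o) == (ea_m, oa_m):
                sign = 1.0
                break
            if (a, o) == (oa_m, ea_m):
                sign = -1.0
                break
        if sign is None:
            dropped += 1
            continue
        rows.append(
            {
                "cpg": rec.cpg, "snp": rec.snp,
                "b_gwas": rec.b_gwas, "se_gwas": rec.se_gwas,
                "b_mqtl": sign * rec.b_mqtl, "se_mqtl": rec.se_mqtl,
            }
        )
    if dropped:
        logger.warning("allele harmonization dropped %d SNPs", dropped)
    return pd.DataFrame(rows, columns=["cpg", "snp", "b_gwas", "se_gwas",
                                       "b_mqtl", "se_mqtl"])
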