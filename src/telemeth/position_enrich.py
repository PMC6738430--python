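"""Positional and set-overlap enrichment of LTL-associated CpGs.

Two analyses: (1) subtelomeric classification — a CpG is subtelomeric when
it lies in the first or last 5% of its chromosome's length — followed by a
2x2 chi-squared test comparing the proportion of *positive* LTL-DNAm
correlations between subtelomeric and non-subtelomeric CpGs; (2) exact
hypergeometric upper-tail test of the overlap between the significant CpG
set and a cis-mQTL catalogue against the analyzed probe background.

The head/tail definition is a deliberate simplification (inter-CpG
correlation may differ near chromosome ends, the dichotomy is crude, and
bulk LTL is not chromosome-specific); see docs/methods.md.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib import resources
from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class GenomeTable:
    """Chromosome lengths (bp) and the subtelomere fraction per end."""

    lengths: dict[str, int] = field(default_factory=dict)
    subtelomere_fraction: float = 0.05

    def __post_init__(self):
        if not 0 < self.subtelomere_fraction < 0.5:
            raise ValueError("subtelomere_fraction must be in (0, 0.5)")
        if any(l <= 0 for l in self.lengths.values()):
            raise ValueError("chromosome lengths must be positive")


def load_genome_table(
    path=None, subtelomere_fraction: float = 0.05
) -> GenomeTable:
    """Load a two-column (chrom, length) table; defaults to bundled hg19."""
    if path is None:
        src = resources.files("telemeth.data") / "hg19.chrom.sizes.tsv"
        with resources.as_file(src) as p:
            df = pd.read_csv(p, sep="\t", header=None, names=["chrom", "length"])
    else:
        df = pd.read_csv(path, sep="\t", header=None, names=["chrom", "length"])
    return GenomeTable(
        lengths=dict(zip(df["chrom"], df["length"].astype(int))),
        subtelomere_fraction=subtelomere_fraction,
    )


def classify_subtelomeric(
    annot: pd.DataFrame, genome: GenomeTable
) -> pd.Series:
    """Boolean flag per CpG: within the head or tail fraction of its chromosome.

    Boundary convention: subtelomeric iff ``pos < f*L`` or ``pos >= (1-f)*L``
    (0-based, half-open).  Every annotated CpG receives a flag.
    """
    unknown = sorted(set(annot["chrom"]) - set(genome.lengths))
    if unknown:
        raise ValueError(f"chromosomes missing from genome table: {unknown}")
    L = annot["chrom"].map(genome.lengths).to_numpy(dtype=float)
    pos = annot["pos"].to_numpy(dtype=float)
    f = genome.subtelomere_fraction
    flags = (pos < f * L) | (pos >= (1.0 - f) * L)
    return pd.Series(flags, index=annot.index, name="subtelomeric")


class ProportionTestResult(NamedTuple):
    prop_subtel: float
    prop_nonsubtel: float
    chi2: float
    p: float


def positive_proportion_test(
    flags, signs, continuity_correction: bool = False
) -> ProportionTestResult:
    """2x2 chi-squared test: positive-correlation proportion, subtelomeric
    vs non-subtelomeric CpGs.

    ``flags`` are subtelomeric indicators, ``signs`` the direction of each
    CpG's meta-Z (positive counted when sign > 0).  Pearson chi-squared
    without continuity correction by default.
    """
    flags = np.asarray(flags, dtype=bool)
    pos = np.asarray(signs, dtype=float) > 0
    if flags.all() or (~flags).all():
        raise ValueError("need at least one CpG in each positional class")
    table = np.array(
        [
            [(flags & pos).sum(), (flags & ~pos).sum()],
            [(~flags & pos).sum(), (~flags & ~pos).sum()],
        ]
    )
    prop_sub = table[0, 0] / table[0].sum()
    prop_non = table[1, 0] / table[1].sum()
    if table[:, 0].sum() == 0 or table[:, 1].sum() == 0 or prop_sub == prop_non:
        # degenerate margins or exact homogeneity: no evidence of difference
        return ProportionTestResult(float(prop_sub), float(prop_non), 0.0, 1.0)
    chi2, p, _, _ = stats.chi2_contingency(table, correction=continuity_correction)
    return ProportionTestResult(float(prop_sub), float(prop_non), float(chi2), float(p))


class OverlapResult(NamedTuple):
    k: int          # selected CpGs found in the catalogue
    n: int          # selected CpGs
    K: int          # catalogue CpGs within the background
    N: int          # background CpGs
    p_upper: float  # P(X >= k), exact hypergeometric tail


def hypergeom_overlap(selected, catalogue, background) -> OverlapResult:
    """Exact upper-tail hypergeometric overlap test.

    ``selected`` must be a subset of ``background``; the catalogue is
    intersected with the background before testing.  The upper tail
    includes the observed count (P(X >= k)).
    """
    selected, catalogue, background = set(selected), set(catalogue), set(background)
    if not selected <= background:
        raise ValueError(
            f"{len(selected - background)} selected CpGs are not in the background"
        )
    K_set = catalogue & background
    k = len(selected & K_set)
    n, K, N = len(selected), len(K_set), len(background)
    if K == 0:
        p = 1.0 if k == 0 else 0.0
    else:
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
    return OverlapResult(k, n, K, N, p)
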