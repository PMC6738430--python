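"""Reference-based white-blood-cell deconvolution from methylation.

Each sample's methylation profile over the reference probes is projected
onto the cell-type signature matrix by non-negative least squares, and the
coefficients are normalized to sum to one.  This is the constrained-
projection estimator in routine use for blood methylation data; the cell
identities are opaque labels carried through from the reference file.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy.optimize import nnls

logger = logging.getLogger(__name__)

MIN_SHARED_PROBES = 10


def estimate_cell_proportions(
    beta: pd.DataFrame, reference: pd.DataFrame
) -> pd.DataFrame:
    """Per-sample cell-type proportions (rows: sample_id; columns: cell types).

    ``beta`` is probes x samples, ``reference`` probes x cell types; the
    reference probes must be a subset of the beta probes (at least
    MIN_SHARED_PROBES shared).  Proportions are non-negative and sum to 1.
    """
    if reference.shape[1] < 2:
        raise ValueError("need at least 2 reference cell types")
    shared = reference.index.intersection(beta.index)
    if len(shared) < MIN_SHARED_PROBES:
        raise ValueError(
            f"only {len(shared)} probes shared between beta matrix and "
            f"reference (need >= {MIN_SHARED_PROBES})"
        )
    R = reference.loc[shared].to_numpy(dtype=float)
    if np.linalg.matrix_rank(R) < R.shape[1]:
        corr = np.corrcoef(R.T)
        pairs = [
            f"{reference.columns[i]}~{reference.columns[j]}"
            for i in range(R.shape[1])
            for j in range(i + 1, R.shape[1])
            if abs(corr[i, j]) > 0.999
        ]
        raise ValueError(f"rank-deficient reference; collinear columns: {pairs}")

    B = beta.loc[shared].to_numpy(dtype=float)
    props = np.empty((beta.shape[1], R.shape[1]))
    total_obj = 0.0
    for s in range(B.shape[1]):
        b = B[:, s]
        ok = np.isfinite(b)
        w, rnorm = nnls(R[ok], b[ok])
        total_obj += rnorm**2
        tot = w.sum()
        props[s] = w / tot if tot > 0 else np.full(R.shape[1], 1.0 / R.shape[1])
    logger.info(
        "deconvolved %d samples on %d probes; total squared residual %.4g",
        B.shape[1], len(shared), total_obj,
    )
    return pd.DataFrame(props, index=beta.columns, columns=reference.columns)


def attach_proportions(pheno: pd.DataFrame, comp: pd.DataFrame) -> pd.DataFrame:
    """Append cell-proportion columns to the phenotype table by sample id.

    ``comp`` is indexed by sample_id (the output of
    :func:`estimate_cell_proportions`).  Every phenotype sample must have
    exactly one proportion row.
    """
    if comp.index.has_duplicates:
        dups = comp.index[comp.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate sample ids in cell composition: {dups}")
    missing = [s for s in pheno["sample_id"] if s not in comp.index]
    if missing:
        raise ValueError(f"samples without cell composition: {missing}")
    merged = pheno.merge(
        comp, left_on="sample_id", right_index=True, how="left", validate="m:1"
    )
    assert len(merged) == len(pheno)
    return merged
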