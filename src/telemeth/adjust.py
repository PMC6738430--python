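"""Stratified LTL adjustment: OLS residuals, or conditional residuals from a
family random-intercept mixed model.

Two adjustment sets mirror the study design: "partial" regresses LTL on age
alone within each stratum (sex, ethnicity and cohort are handled by the
stratification itself), and "full" additionally removes DNAm-estimated
white-blood-cell proportions.  Cohorts with family/twin structure use a
linear mixed model with a per-family random intercept fitted by REML; the
returned residuals are *conditional* (LTL minus fixed-effect predictions
minus predicted family intercepts), which removes family clustering from
the trait.  A degenerate REML fit (boundary variance ~ 0 or convergence
failure) falls back to OLS with a logged note.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


class SingularDesignError(ValueError):
    """Raised when the within-stratum design matrix is rank deficient."""


@dataclass(frozen=True)
class AdjustmentSpec:
    mode: str                                  # "partial" | "full"
    covariates: tuple[str, ...] = ("age",)
    use_family_random_effect: bool = False
    extra_covariates: tuple[str, ...] = ()

    def __post_init__(self):
        if self.mode not in ("partial", "full"):
            raise ValueError("mode must be 'partial' or 'full'")


def partial_spec(use_family_random_effect: bool = False) -> AdjustmentSpec:
    return AdjustmentSpec(mode="partial", covariates=("age",),
                          use_family_random_effect=use_family_random_effect)


def full_spec(
    cell_columns: tuple[str, ...], use_family_random_effect: bool = False
) -> AdjustmentSpec:
    return AdjustmentSpec(
        mode="full", covariates=("age", *cell_columns),
        use_family_random_effect=use_family_random_effect,
    )


def _design(df: pd.DataFrame, columns: list[str]) -> tuple[np.ndarray, list[str]]:
    """Intercept + covariate design; constant covariates dropped with a warning."""
    kept = []
    for c in columns:
        v = df[c].to_numpy(dtype=float)
        if np.nanstd(v) == 0:
            logger.warning("covariate %r is constant in this stratum; dropped", c)
            continue
        kept.append(c)
    X = np.column_stack(
        [np.ones(len(df))] + [df[c].to_numpy(dtype=float) for c in kept]
    )
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # identify collinear columns by leave-one-out rank probing
        bad = [
            kept[j]
            for j in range(len(kept))
            if np.linalg.matrix_rank(np.delete(X, j + 1, axis=1)) == rank
        ]
        raise SingularDesignError(
            f"singular design; collinear columns: {bad or kept}"
        )
    return X, kept


def _smoking_dummies(df: pd.DataFrame) -> pd.DataFrame:
    """'never' is the reference level; two indicator columns."""
    out = df.copy()
    out["smoking_former"] = (df["smoking"] == "former").astype(float)
    out["smoking_current"] = (df["smoking"] == "current").astype(float)
    return out


def _mixed_model_residuals(
    y: np.ndarray, X: np.ndarray, families: pd.Series
) -> np.ndarray | None:
    """Conditional residuals from a family random-intercept model (REML).

    Returns None when the fit fails or the family variance collapses to the
    boundary, letting the caller fall back to OLS.  Samples without a family
    label are treated as singleton groups.
    """
    from statsmodels.regression.mixed_linear_model import MixedLM

    groups = families.astype(object).where(families.notna(), None)
    groups = np.array(
        [g if g is not None else f"_singleton{i}" for i, g in enumerate(groups)]
    )
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = MixedLM(y, X, groups=groups).fit(reml=True)
    except Exception as exc:  # pragma: no cover - numerical edge cases
        logger.warning("mixed model failed (%s); falling back to OLS", exc)
        return None
    var_fam = float(np.asarray(fit.cov_re).ravel()[0])
    if not np.isfinite(var_fam) or var_fam < 1e-10 * max(float(fit.scale), 1e-300):
        logger.info("family variance at boundary; falling back to OLS")
        return None
    fixed = X @ np.asarray(fit.fe_params)
    blup = fit.random_effects
    u = np.array(
        [float(np.asarray(blup[g]).ravel()[0]) if g in blup else 0.0 for g in groups]
    )
    return y - fixed - u


def _ols_residuals(y: np.ndarray, X: np.ndarray) -> np.ndarray:
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    return y - X @ beta


def adjust_ltl(
    pheno: pd.DataFrame,
    cellprops: pd.DataFrame | None,
    spec: AdjustmentSpec,
) -> pd.DataFrame:
    """Per-stratum adjusted-LTL residuals.

    ``cellprops`` (sample_id-indexed proportions) is required for the full
    adjustment and merged onto the phenotype table.  Strata too small for
    the design are skipped with a warning.  Returns columns
    ``sample_id, residual_ltl, stratum_id, n_used``.
    """
    df = pheno.copy()
    if cellprops is not None:
        from .celltypes import attach_proportions

        df = attach_proportions(df, cellprops)
    covariates = list(spec.covariates)
    if spec.extra_covariates:
        if any(c.startswith("smoking_") for c in spec.extra_covariates):
            df = _smoking_dummies(df)
        covariates += list(spec.extra_covariates)
    absent = [c for c in covariates if c not in df.columns]
    if absent:
        raise ValueError(f"covariate columns not found: {absent}")

    out = []
    for sid, sub in df.groupby("stratum_id", sort=False):
        if len(sub) < len(covariates) + 2:
            logger.warning("stratum %s too small (n=%d); skipped", sid, len(sub))
            continue
        X, kept = _design(sub, covariates)
        y = sub["ltl"].to_numpy(dtype=float)
        resid = None
        if spec.use_family_random_effect and sub["family_id"].notna().any():
            resid = _mixed_model_residuals(y, X, sub["family_id"])
        if resid is None:
            resid = _ols_residuals(y, X)
        out.append(
            pd.DataFrame(
                {
                    "sample_id": sub["sample_id"].to_numpy(),
                    "residual_ltl": resid,
                    "stratum_id": sid,
                    "n_used": len(sub),
                }
            )
        )
    if not out:
        raise ValueError("no stratum was large enough to adjust")
    return pd.concat(out, ignore_index=True)


def sensitivity_covariates(
    pheno: pd.DataFrame,
    cellprops: pd.DataFrame | None,
    spec: AdjustmentSpec,
) -> pd.DataFrame:
    """Smoking-sensitivity variant: the same adjustment with former/current
    smoking indicators appended to the design (never = reference)."""
    aug = AdjustmentSpec(
        mode=spec.mode,
        covariates=spec.covariates,
        use_family_random_effect=spec.use_family_random_effect,
        extra_covariates=("smoking_former", "smoking_current"),
    )
    return adjust_ltl(pheno, cellprops, aug)
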