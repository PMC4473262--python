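"""Quality filtering, transformation, covariate adjustment and
probe-to-gene collapsing.

Adjustment is per-feature complete-case OLS on intercept + age + sex;
missing entries stay missing. Probe collapsing keeps, per gene, the probe
with the strongest absolute correlation to any metabolite (ties broken
lexicographically on probe id for determinism). The downstream
significance threshold must still be derived from the full probe-level
test count; see :mod:`crossomics.network`.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .exceptions import AlignmentError, CrossOmicsError, DomainError
from .matrix import OmicsMatrix
from .stats import covariate_design


def filter_missing(metabolome: OmicsMatrix, max_missing: float = 0.5) -> OmicsMatrix:
    """Retain features whose missing fraction is <= ``max_missing``
    (strictly-greater fractions are excluded). Idempotent."""
    if metabolome.scale_tag not in ("raw", "log"):
        raise DomainError("filter_missing expects raw or log scale")
    frac = metabolome.missing_fraction()
    keep = frac.index[frac <= max_missing]
    if len(keep) == 0:
        warnings.warn("missingness filter removed every feature")
    return OmicsMatrix(metabolome.values[list(keep)].copy(), scale_tag=metabolome.scale_tag)


def log_and_adjust(matrix: OmicsMatrix, covariates: pd.DataFrame) -> OmicsMatrix:
    """Natural-log transform followed by per-feature OLS residualization on
    intercept + age + sex (complete cases per feature)."""
    if matrix.scale_tag == "raw":
        logged = matrix.log()
    elif matrix.scale_tag == "log":
        logged = matrix
    else:
        raise DomainError("log_and_adjust expects raw or log scale")
    return adjust_covariates(logged, covariates)


def adjust_covariates(matrix: OmicsMatrix, covariates: pd.DataFrame) -> OmicsMatrix:
    """Residualize each feature on intercept + age + sex."""
    if not matrix.values.index.equals(covariates.index):
        raise AlignmentError("covariate rows do not match matrix samples")
    X_full = covariate_design(covariates)
    vals = matrix.values.to_numpy(dtype=float)
    out = np.full_like(vals, np.nan)
    for j in range(vals.shape[1]):
        y = vals[:, j]
        obs = ~np.isnan(y)
        if obs.sum() <= X_full.shape[1]:
            continue  # too few observations to adjust; left missing
        X = X_full[obs]
        beta, *_ = np.linalg.lstsq(X, y[obs], rcond=None)
        out[obs, j] = y[obs] - X @ beta
    return OmicsMatrix(
        pd.DataFrame(out, index=matrix.values.index, columns=matrix.values.columns),
        scale_tag="residual",
    )


def collapse_probes(
    expr: OmicsMatrix, probe_map: pd.Series | dict, corr: pd.DataFrame
) -> OmicsMatrix:
    """One representative probe per gene, chosen as the probe maximizing
    ``max over metabolites of |rho|`` in the supplied probe-level
    correlation table; feature ids become gene ids.
    """
    probe_map = pd.Series(probe_map)
    probes = list(expr.feature_ids)
    missing = set(probes) - set(probe_map.index)
    if missing:
        raise CrossOmicsError(f"probes missing from probe map: {sorted(missing)[:5]}")
    strength = corr.assign(abs_rho=corr["rho"].abs()).groupby("transcript")["abs_rho"].max()
    absent = set(probes) - set(strength.index)
    if absent:
        raise CrossOmicsError(f"probes absent from correlation table: {sorted(absent)[:5]}")

    chosen: dict[str, str] = {}
    for probe in sorted(probes):  # lexicographic order makes ties deterministic
        gene = probe_map[probe]
        if gene not in chosen or strength[probe] > strength[chosen[gene]] + 1e-12:
            chosen[gene] = probe
    genes = sorted(chosen)
    collapsed = expr.values[[chosen[g] for g in genes]].copy()
    collapsed.columns = genes
    return OmicsMatrix(collapsed, scale_tag=expr.scale_tag)


def apply_blacklist(matrix: OmicsMatrix, blacklist) -> OmicsMatrix:
    """Drop features by id (stand-in for gonosomal-probe / QC-flag filters)."""
    drop = set(blacklist)
    keep = [f for f in matrix.feature_ids if f not in drop]
    return matrix.subset_features(keep)
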