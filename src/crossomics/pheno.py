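"""Clinical-trait association and projection onto the networks.

Each trait is regressed on one explanatory variable at a time (feature or
category aggZ-score) with age and sex as covariates. Node scores are
``-log10(p) * sign(beta1)``. The feature-level Bonferroni denominator is
the number of explanatory variables tested per trait.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .exceptions import CrossOmicsError
from .stats import covariate_design, ols_fit, spearman

P_FLOOR = 1e-300  # keeps -log10 finite when p underflows


def bonferroni_cutoff(alpha: float, n_tests: int) -> float:
    """Per-test significance cutoff at family-wise level ``alpha``."""
    if n_tests <= 0:
        raise CrossOmicsError("n_tests must be positive")
    return alpha / n_tests


def association_score(p: float, beta: float) -> float:
    """Signed association strength: -log10(p) x sign(beta)."""
    return float(-np.log10(max(p, P_FLOOR)) * np.sign(beta))


def trait_associations(
    traits: pd.DataFrame,
    targets: pd.DataFrame,
    covariates: pd.DataFrame,
    alpha: float = 0.05,
    n_tests: int | None = None,
) -> pd.DataFrame:
    """Per-target OLS of each trait on target + age + sex.

    ``targets`` is a samples x variables frame (features or category
    aggZ-scores). ``n_tests`` sets the Bonferroni denominator; it defaults
    to the number of target columns. Constant predictors are skipped with
    a flag. Returns columns trait, target, beta, p, score, significant,
    skipped.
    """
    if not traits.index.equals(targets.index) or not traits.index.equals(covariates.index):
        raise CrossOmicsError("traits, targets and covariates must share sample order")
    m = n_tests if n_tests is not None else targets.shape[1]
    cutoff = bonferroni_cutoff(alpha, m)

    rows = []
    tvals = targets.to_numpy(dtype=float)
    for trait in traits.columns:
        y_all = traits[trait].to_numpy(dtype=float)
        for j, target in enumerate(targets.columns):
            x = tvals[:, j]
            obs = ~(np.isnan(x) | np.isnan(y_all))
            if obs.sum() <= 4 or np.nanvar(x[obs]) == 0:
                rows.append({"trait": trait, "target": target, "beta": np.nan, "p": np.nan,
                             "score": np.nan, "significant": False, "skipped": True})
                continue
            X = covariate_design(covariates.loc[covariates.index[obs]], extra=x[obs])
            fit = ols_fit(y_all[obs], X)
            beta, p = float(fit["beta"][1]), float(fit["p"][1])
            rows.append({"trait": trait, "target": target, "beta": beta, "p": p,
                         "score": association_score(p, beta),
                         "significant": p <= cutoff, "skipped": False})
    out = pd.DataFrame(rows)
    out.attrs["bonferroni_cutoff"] = cutoff
    out.attrs["n_tests"] = m
    out.attrs["alpha"] = alpha
    return out


def project_and_compare(
    assoc_a: pd.DataFrame,
    assoc_b: pd.DataFrame,
    graph,
) -> tuple[object, float]:
    """Write per-trait scores as node attributes and return the Spearman
    correlation of node scores between the two traits over shared nodes.

    ``graph`` is a networkx graph whose node ids appear in the ``target``
    column of the association tables (a bipartite network's graph or a PIN).
    """
    scores_a = assoc_a.set_index("target")["score"]
    scores_b = assoc_b.set_index("target")["score"]
    name_a = assoc_a["trait"].iloc[0] if len(assoc_a) else "a"
    name_b = assoc_b["trait"].iloc[0] if len(assoc_b) else "b"

    shared = [
        n
        for n in graph.nodes
        if n in scores_a.index and n in scores_b.index
        and np.isfinite(scores_a[n]) and np.isfinite(scores_b[n])
    ]
    if len(shared) < 3:
        raise CrossOmicsError("fewer than 3 shared scored nodes")
    for n in shared:
        graph.nodes[n][f"score_{name_a}"] = float(scores_a[n])
        graph.nodes[n][f"score_{name_b}"] = float(scores_b[n])
    rho, _, _ = spearman(scores_a[shared].to_numpy(), scores_b[shared].to_numpy())
    return graph, rho
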