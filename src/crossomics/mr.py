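"""Bidirectional causal testing of network edges with the Wald ratio.

Both stage regressions (exposure on SNP, outcome on SNP) adjust for age
and sex. Inference is by individual-level bootstrap: percentile confidence
intervals and a two-sided bootstrap p-value floored at ``1/n_boot``.
Q-values across all tested (edge, direction) pairs use Benjamini-Hochberg.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import CrossOmicsError, UndefinedRatioError
from .stats import bh_qvalues, covariate_design, ols_fit

NEAR_ZERO = 1e-8


# ---------------------------------------------------------------------------
# Instrument filtering
# ---------------------------------------------------------------------------

@dataclass
class InstrumentSet:
    """Candidate SNP-trait associations with validity and LD screens applied."""

    table: pd.DataFrame  # snp, trait, beta, se, p, q, retained, reason
    r2: pd.DataFrame  # pairwise genotype r^2 over retained SNPs
    fdr: float
    r2_max: float

    @property
    def retained(self) -> pd.DataFrame:
        return self.table[self.table["retained"]]

    def instruments_for(self, trait: str) -> list[str]:
        sub = self.retained
        return list(sub.loc[sub["trait"] == trait, "snp"])


def _genotype_r2(genotypes: pd.DataFrame) -> pd.DataFrame:
    g = genotypes.to_numpy(dtype=float)
    with np.errstate(invalid="ignore"):
        r = np.corrcoef(g, rowvar=False)
    return pd.DataFrame(r**2, index=genotypes.columns, columns=genotypes.columns)


def filter_instruments(
    genotypes: pd.DataFrame,
    features: pd.DataFrame,
    covariates: pd.DataFrame,
    candidates: pd.DataFrame,
    fdr: float = 0.05,
    r2_max: float = 0.8,
) -> InstrumentSet:
    """Validity screen (per-candidate OLS of trait on genotype + age + sex,
    BH over the candidate set) followed by greedy LD pruning that drops the
    weaker-association member of any pair with genotype r^2 >= ``r2_max``.

    ``features`` holds the trait values (metabolite or transcript levels,
    already on the analysis scale) as columns; ``candidates`` has columns
    ``snp`` and ``trait``. Monomorphic SNPs are excluded with a warning.
    """
    rows = []
    for cand in candidates.itertuples():
        snp, trait = cand.snp, cand.trait
        if snp not in genotypes.columns:
            raise CrossOmicsError(f"unknown SNP {snp}")
        if trait not in features.columns:
            raise CrossOmicsError(f"unknown trait {trait}")
        g = genotypes[snp].to_numpy(dtype=float)
        y = features[trait].to_numpy(dtype=float)
        obs = ~(np.isnan(g) | np.isnan(y))
        if np.nanvar(g[obs]) == 0:
            warnings.warn(f"monomorphic SNP {snp} excluded")
            rows.append(
                {"snp": snp, "trait": trait, "beta": np.nan, "se": np.nan, "p": np.nan,
                 "retained": False, "reason": "monomorphic"}
            )
            continue
        X = covariate_design(covariates.loc[genotypes.index[obs]], extra=g[obs])
        fit = ols_fit(y[obs], X)
        rows.append(
            {"snp": snp, "trait": trait, "beta": fit["beta"][1], "se": fit["se"][1],
             "p": fit["p"][1], "retained": True, "reason": ""}
        )
    table = pd.DataFrame(rows)

    testable = table["p"].notna()
    q = np.full(len(table), np.nan)
    if testable.any():
        q[testable.to_numpy()] = bh_qvalues(table.loc[testable, "p"].to_numpy())
    table["q"] = q
    fail = testable & (table["q"] > fdr)
    table.loc[fail, "retained"] = False
    table.loc[fail, "reason"] = "validity-fdr"

    # greedy LD pruning over the retained set
    retained_snps = list(dict.fromkeys(table.loc[table["retained"], "snp"]))
    r2 = _genotype_r2(genotypes[retained_snps]) if retained_snps else pd.DataFrame()
    best_p = table[table["retained"]].groupby("snp")["p"].min()
    dropped: set[str] = set()
    for i, a in enumerate(retained_snps):
        for b in retained_snps[i + 1 :]:
            if a in dropped or b in dropped:
                continue
            if r2.loc[a, b] >= r2_max:
                weaker = a if best_p[a] > best_p[b] else b
                dropped.add(weaker)
    mask = table["snp"].isin(dropped) & table["retained"]
    table.loc[mask, "retained"] = False
    table.loc[mask, "reason"] = "ld-pruned"
    kept = [s for s in retained_snps if s not in dropped]
    return InstrumentSet(table=table, r2=r2.loc[kept, kept] if kept else r2, fdr=fdr, r2_max=r2_max)


# ---------------------------------------------------------------------------
# Wald ratio
# ---------------------------------------------------------------------------

def wald_ratio(beta_snp_outcome: float, beta_snp_exposure: float) -> float:
    """Causal effect estimate: ratio of SNP->outcome to SNP->exposure."""
    if beta_snp_exposure == 0:
        raise UndefinedRatioError("zero SNP->exposure effect")
    return beta_snp_outcome / beta_snp_exposure


# ---------------------------------------------------------------------------
# Bootstrap inference
# ---------------------------------------------------------------------------

@dataclass
class CausalResult:
    metabolite_id: str
    transcript_id: str
    direction: str  # 'Met->mRNA' or 'mRNA->Met'
    beta_causal: float
    ci_low: float
    ci_high: float
    p_boot: float
    n_boot: int
    unstable: bool = False
    q: float | None = None


def _stage_beta(y: np.ndarray, g: np.ndarray, age: np.ndarray, sex: np.ndarray) -> float:
    obs = ~np.isnan(y)
    X = np.column_stack([np.ones(obs.sum()), g[obs], age[obs], sex[obs]])
    beta, *_ = np.linalg.lstsq(X, y[obs], rcond=None)
    return float(beta[1])


def bootstrap_causal_test(
    genotype: np.ndarray,
    exposure: np.ndarray,
    outcome: np.ndarray,
    covariates: pd.DataFrame,
    metabolite_id: str,
    transcript_id: str,
    direction: str,
    n_boot: int = 10_000,
    seed: int = 0,
) -> CausalResult:
    """Wald-ratio estimate with individual-resampling bootstrap.

    Each replicate resamples individuals with replacement, recomputes both
    stage regressions (with age/sex adjustment) and the ratio. 95% CI by
    the percentile method; two-sided p = 2 * min(frac <= 0, frac >= 0),
    floored at ``1/n_boot``. If more than 5% of replicates have a near-zero
    exposure effect the result is flagged unstable.
    """
    g = np.asarray(genotype, dtype=float)
    x = np.asarray(exposure, dtype=float)
    y = np.asarray(outcome, dtype=float)
    age = covariates["age"].to_numpy(dtype=float)
    sex = covariates["sex"].to_numpy(dtype=float)
    n = len(g)

    b_exp = _stage_beta(x, g, age, sex)
    b_out = _stage_beta(y, g, age, sex)
    estimate = wald_ratio(b_out, b_exp)

    rng = np.random.default_rng(seed)
    ratios = np.empty(n_boot)
    n_near_zero = 0
    for i in range(n_boot):
        idx = rng.integers(0, n, n)
        be = _stage_beta(x[idx], g[idx], age[idx], sex[idx])
        bo = _stage_beta(y[idx], g[idx], age[idx], sex[idx])
        if abs(be) < NEAR_ZERO:
            n_near_zero += 1
            ratios[i] = np.nan
        else:
            ratios[i] = bo / be
    valid = ratios[~np.isnan(ratios)]
    unstable = n_near_zero > 0.05 * n_boot
    if unstable:
        warnings.warn(
            f"unstable Wald ratio for {metabolite_id}-{transcript_id} ({direction}): "
            f"{n_near_zero}/{n_boot} near-zero exposure effects"
        )
    if len(valid) == 0:
        ci_low = ci_high = np.nan
        p = 1.0
    else:
        ci_low, ci_high = np.percentile(valid, [2.5, 97.5])
        p = 2.0 * min(np.mean(valid <= 0), np.mean(valid >= 0))
        p = float(min(1.0, max(p, 1.0 / n_boot)))
    return CausalResult(
        metabolite_id=metabolite_id,
        transcript_id=transcript_id,
        direction=direction,
        beta_causal=estimate,
        ci_low=float(ci_low),
        ci_high=float(ci_high),
        p_boot=p,
        n_boot=n_boot,
        unstable=unstable,
    )


def add_qvalues(results: list[CausalResult]) -> list[CausalResult]:
    """BH q-values across all tested (edge, direction) pairs, in place."""
    if not results:
        return results
    q = bh_qvalues([r.p_boot for r in results])
    for r, qi in zip(results, q):
        r.q = float(qi)
    return results


def results_table(results: list[CausalResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "metabolite": r.metabolite_id,
                "transcript": r.transcript_id,
                "direction": r.direction,
                "beta": r.beta_causal,
                "ci_low": r.ci_low,
                "ci_high": r.ci_high,
                "p": r.p_boot,
                "q": r.q,
                "unstable": r.unstable,
            }
            for r in results
        ]
    )


def run_mr(
    edges: pd.DataFrame,
    instruments: InstrumentSet,
    genotypes: pd.DataFrame,
    metabolome: pd.DataFrame,
    transcriptome: pd.DataFrame,
    covariates: pd.DataFrame,
    n_boot: int = 10_000,
    seed: int = 0,
) -> list[CausalResult]:
    """Test every edge in both directions where a valid instrument exists
    for the direction's exposure, then attach BH q-values.
    """
    results: list[CausalResult] = []
    counter = 0
    for row in edges.itertuples():
        met, trans = row.metabolite, row.transcript
        for direction, exposure_trait in (("Met->mRNA", met), ("mRNA->Met", trans)):
            for snp in instruments.instruments_for(exposure_trait):
                exposure = (metabolome if exposure_trait == met else transcriptome)[exposure_trait]
                outcome = (transcriptome if exposure_trait == met else metabolome)[
                    trans if exposure_trait == met else met
                ]
                results.append(
                    bootstrap_causal_test(
                        genotypes[snp].to_numpy(),
                        exposure.to_numpy(dtype=float),
                        outcome.to_numpy(dtype=float),
                        covariates,
                        metabolite_id=met,
                        transcript_id=trans,
                        direction=direction,
                        n_boot=n_boot,
                        seed=seed + counter,
                    )
                )
                counter += 1
    return add_qvalues(results)
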