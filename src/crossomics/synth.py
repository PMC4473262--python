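"""Synthetic cohort, toy metabolic model and motif-hit generators.

The generators plant the statistical structure that downstream stages
assume: latent-factor correlation blocks between metabolites and
transcripts, SNP -> exposure -> outcome causal chains, MCAR metabolite
missingness, antagonistic HDL-like / TG-like traits, linear reaction
chains with currency metabolites and compartment duplicates, and motif
enrichments inside designated gene sets.

Rank correlations are planted through a shared Gaussian latent factor and
survive the exponentiation used to produce positive concentrations, since
Spearman correlation is invariant under strictly monotone transforms. To
hit a target Spearman ``rho_s`` the factor loading is chosen such that the
latent Pearson correlation equals ``2 sin(pi * rho_s / 6)`` (the inverse of
the bivariate-normal rank-correlation identity).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .exceptions import ConfigurationError
from .matrix import OmicsMatrix
from .metnet import MetabolicModel, Metabolite, Reaction


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CausalChain:
    """Planted SNP -> exposure -> outcome chain."""

    snp: str
    exposure: str
    outcome: str
    beta_gx: float
    beta_xy: float


@dataclass
class SynthConfig:
    """Knobs of the synthetic cohort.

    Defaults mirror the emulated study population: 712 samples, age
    68.82 +/- 4.31 years truncated to [55, 85], roughly balanced sexes.
    """

    n_samples: int = 712
    n_metabolites: int = 40
    n_transcripts: int = 120
    n_modules: int = 4
    module_rho: float | Sequence[float] = 0.5
    module_n_metabolites: int = 2
    module_n_transcripts: int = 5
    missing_rate_range: tuple[float, float] = (0.0, 0.6)
    age_mean: float = 68.82
    age_sd: float = 4.31
    age_range: tuple[float, float] = (55.0, 85.0)
    age_beta: float = 0.0
    sex_beta: float = 0.0
    n_snps: int = 10
    causal_chains: list[CausalChain] = field(default_factory=list)
    trait_spec: dict[str, list[tuple[str, float]]] | None = None
    trait_noise_sd: float = 0.7
    n_motifs: int = 40
    motif_p_in: float = 0.9
    motif_p_out: float = 0.1
    n_chains: int = 3
    chain_length: int = 5
    seed: int = 0

    # -- derived namings -----------------------------------------------------
    def metabolite_ids(self) -> list[str]:
        return [f"M{i:04d}" for i in range(self.n_metabolites)]

    def transcript_ids(self) -> list[str]:
        return [f"G{i:05d}" for i in range(self.n_transcripts)]

    def snp_ids(self) -> list[str]:
        return [f"rs{i:04d}" for i in range(self.n_snps)]

    def module_rhos(self) -> list[float]:
        if isinstance(self.module_rho, (int, float)):
            return [float(self.module_rho)] * self.n_modules
        rhos = [float(r) for r in self.module_rho]
        if len(rhos) != self.n_modules:
            raise ConfigurationError("module_rho list length must equal n_modules")
        return rhos

    def validate(self) -> None:
        if self.n_samples <= 0:
            raise ConfigurationError("n_samples must be positive")
        for name in ("n_metabolites", "n_transcripts", "n_modules", "n_snps"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0")
        for rho in self.module_rhos():
            if not abs(rho) < 1:
                raise ConfigurationError("|module_rho| must be < 1")
        lo, hi = self.missing_rate_range
        if not (0 <= lo <= hi <= 1):
            raise ConfigurationError("missing_rate_range must satisfy 0 <= lo <= hi <= 1")
        needed_mets = self.n_modules * self.module_n_metabolites
        needed_trans = self.n_modules * self.module_n_transcripts
        if needed_mets > self.n_metabolites or needed_trans > self.n_transcripts:
            raise ConfigurationError("planted modules exceed feature counts")
        features = set(self.metabolite_ids()) | set(self.transcript_ids())
        snps = set(self.snp_ids())
        for chain in self.causal_chains:
            if chain.snp not in snps:
                raise ConfigurationError(f"chain references unknown SNP {chain.snp}")
            if chain.exposure not in features or chain.outcome not in features:
                raise ConfigurationError("chain references unknown feature")


# ---------------------------------------------------------------------------
# Cohort
# ---------------------------------------------------------------------------

@dataclass
class SyntheticTruth:
    """Planted structure of a cohort, for downstream power/recovery tests."""

    edges: list[tuple[str, str, float]]
    causal: list[CausalChain]
    categories: dict[str, set[str]]  # category id -> member feature ids
    category_kinds: dict[str, str]  # category id -> 'GO' | 'MP'
    couplings: list[tuple[str, str]]  # planted (GO, MP) couplings


@dataclass
class SyntheticCohort:
    metabolome: OmicsMatrix
    transcriptome: OmicsMatrix
    covariates: pd.DataFrame  # columns age, sex
    genotypes: pd.DataFrame  # samples x SNPs, additive 0/1/2
    traits: pd.DataFrame  # columns HDL, LDL, TG
    truth: SyntheticTruth


def _planted_loading(rho: float) -> float:
    """Factor loading such that pairwise latent Pearson = 2 sin(pi rho / 6)."""
    pearson = 2.0 * math.sin(math.pi * abs(rho) / 6.0)
    return math.sqrt(pearson)


def _module_layout(config: SynthConfig):
    """Assign metabolites/transcripts to planted modules (front slices)."""
    mets = config.metabolite_ids()
    trans = config.transcript_ids()
    layout = []
    for i in range(config.n_modules):
        m0 = i * config.module_n_metabolites
        t0 = i * config.module_n_transcripts
        layout.append(
            (
                mets[m0 : m0 + config.module_n_metabolites],
                trans[t0 : t0 + config.module_n_transcripts],
            )
        )
    return layout


def generate_cohort(config: SynthConfig) -> SyntheticCohort:
    """Generate a cohort with the planted structure described in ``config``.

    Deterministic given ``config.seed``: the same config yields bit-identical
    output on repeated calls.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_samples
    met_ids = config.metabolite_ids()
    trans_ids = config.transcript_ids()

    # covariates: truncated-normal age, balanced 0/1 sex
    a, b = (
        (config.age_range[0] - config.age_mean) / config.age_sd,
        (config.age_range[1] - config.age_mean) / config.age_sd,
    )
    age = sps.truncnorm.rvs(a, b, loc=config.age_mean, scale=config.age_sd, size=n, random_state=rng)
    sex = rng.integers(0, 2, size=n).astype(float)
    covariates = pd.DataFrame({"age": age, "sex": sex}, index=_sample_ids(n))

    # latent signals: one shared Gaussian factor per module
    factors = rng.standard_normal((config.n_modules, n))
    met_sig = rng.standard_normal((n, config.n_metabolites))
    trans_sig = rng.standard_normal((n, config.n_transcripts))
    met_index = {m: j for j, m in enumerate(met_ids)}
    trans_index = {t: j for j, t in enumerate(trans_ids)}

    truth_edges: list[tuple[str, str, float]] = []
    categories: dict[str, set[str]] = {}
    category_kinds: dict[str, str] = {}
    couplings: list[tuple[str, str]] = []
    rhos = config.module_rhos()
    for i, (mod_mets, mod_trans) in enumerate(_module_layout(config)):
        rho = rhos[i]
        loading = _planted_loading(rho)
        resid = math.sqrt(max(0.0, 1.0 - loading**2))
        for m in mod_mets:
            met_sig[:, met_index[m]] = loading * factors[i] + resid * rng.standard_normal(n)
        sign = 1.0 if rho >= 0 else -1.0
        for t in mod_trans:
            trans_sig[:, trans_index[t]] = sign * loading * factors[i] + resid * rng.standard_normal(n)
        truth_edges.extend((m, t, rho) for m in mod_mets for t in mod_trans)
        go_id, mp_id = f"GO:mod{i}", f"MP:mod{i}"
        categories[go_id] = set(mod_trans)
        categories[mp_id] = set(mod_mets)
        category_kinds[go_id] = "GO"
        category_kinds[mp_id] = "MP"
        couplings.append((go_id, mp_id))

    # genotypes
    mafs = rng.uniform(0.1, 0.5, size=config.n_snps)
    geno = rng.binomial(2, mafs, size=(n, config.n_snps)).astype(float)
    genotypes = pd.DataFrame(geno, index=covariates.index, columns=config.snp_ids())

    # planted causal chains override the involved feature signals
    def _signal_col(fid: str) -> np.ndarray:
        if fid in met_index:
            return met_sig[:, met_index[fid]]
        return trans_sig[:, trans_index[fid]]

    def _set_signal(fid: str, values: np.ndarray) -> None:
        if fid in met_index:
            met_sig[:, met_index[fid]] = values
        else:
            trans_sig[:, trans_index[fid]] = values

    for chain in config.causal_chains:
        g = genotypes[chain.snp].to_numpy()
        exposure = chain.beta_gx * g + rng.standard_normal(n)
        outcome = chain.beta_xy * exposure + rng.standard_normal(n)
        _set_signal(chain.exposure, exposure)
        _set_signal(chain.outcome, outcome)

    # age/sex effects, added on the (log) signal scale
    effect = config.age_beta * age + config.sex_beta * sex
    met_log = met_sig + effect[:, None]
    trans_vals = trans_sig + effect[:, None]

    # metabolite concentrations: positive via exponentiation of a shifted
    # log signal (per-feature location only, so planted slopes are preserved
    # on the log scale)
    met_mu = rng.uniform(1.0, 4.0, size=config.n_metabolites)
    met_vals = np.exp(met_log + met_mu[None, :])

    # MCAR missingness at per-feature rates from missing_rate_range; the
    # first feature is forced above 0.5 whenever the range allows, so the
    # missingness filter is always exercised
    lo, hi = config.missing_rate_range
    rates = rng.uniform(lo, hi, size=config.n_metabolites)
    if hi > 0.5 and config.n_metabolites:
        rates[0] = 0.5 + 0.5 * (hi - 0.5)
    miss = rng.random((n, config.n_metabolites)) < rates[None, :]
    met_vals = np.where(miss, np.nan, met_vals)

    metabolome = OmicsMatrix(
        pd.DataFrame(met_vals, index=covariates.index, columns=met_ids), scale_tag="raw"
    )
    transcriptome = OmicsMatrix(
        pd.DataFrame(trans_vals + 8.0, index=covariates.index, columns=trans_ids),
        scale_tag="log",
    )

    traits = _generate_traits(config, rng, covariates.index, met_sig, trans_sig, met_index, trans_index)

    truth = SyntheticTruth(
        edges=truth_edges,
        causal=list(config.causal_chains),
        categories=categories,
        category_kinds=category_kinds,
        couplings=couplings,
    )
    return SyntheticCohort(metabolome, transcriptome, covariates, genotypes, traits, truth)


def _sample_ids(n: int) -> pd.Index:
    return pd.Index([f"S{i:04d}" for i in range(n)], name="sample")


def _default_trait_spec(config: SynthConfig) -> dict[str, list[tuple[str, float]]]:
    """HDL-like and TG-like traits load with opposite signs on all planted
    module metabolites; LDL is pure noise.
    """
    loaded = [m for mod_mets, _ in _module_layout(config) for m in mod_mets]
    return {
        "HDL": [(m, -1.0) for m in loaded],
        "LDL": [],
        "TG": [(m, 1.0) for m in loaded],
    }


_TRAIT_BASE = {"HDL": (55.80, 13.95), "LDL": (140.60, 35.97), "TG": (132.64, 75.70)}


def _generate_traits(config, rng, index, met_sig, trans_sig, met_index, trans_index):
    spec = config.trait_spec if config.trait_spec is not None else _default_trait_spec(config)
    out = {}
    for trait in ("HDL", "LDL", "TG"):
        loadings = spec.get(trait, [])
        score = np.zeros(len(index))
        for fid, w in loadings:
            col = met_sig[:, met_index[fid]] if fid in met_index else trans_sig[:, trans_index[fid]]
            score = score + w * col
        if loadings:
            score = score / np.std(score)
        mean, sd = _TRAIT_BASE[trait]
        noise = config.trait_noise_sd * rng.standard_normal(len(index))
        signal_w = math.sqrt(1.0 / (1.0 + config.trait_noise_sd**2))
        out[trait] = mean + sd * signal_w * (score + noise)
    return pd.DataFrame(out, index=index)


# ---------------------------------------------------------------------------
# Toy metabolic model
# ---------------------------------------------------------------------------

@dataclass
class ToyModel:
    """Raw compartmentalized model plus its ground truth."""

    model: MetabolicModel
    truth_model: MetabolicModel  # what prepare_model should produce
    truth_distances: dict[tuple[str, str], float]  # (metabolite, gene) -> d


CURRENCY_IDS = ("h2o", "atp")


def generate_toy_model(config: SynthConfig) -> ToyModel:
    """Linear reaction chains with one gene per reaction, currency
    metabolites attached everywhere, and a duplicated compartment copy of
    one chain metabolite (bridged by a pure transport reaction).

    Chain ``c``: ``cpd{c}x0 -(rx{c}x1 : gene{c}x1)-> cpd{c}x1 -> ...`` so
    that by construction ``d(cpd{c}x0, gene{c}x{k}) = k - 1``.
    """
    config.validate()
    L = config.chain_length
    metabolites: dict[str, Metabolite] = {}
    reactions: dict[str, Reaction] = {}
    gene_assoc: dict[str, set[str]] = {}
    t_metabolites: dict[str, Metabolite] = {}
    t_reactions: dict[str, Reaction] = {}
    t_gene_assoc: dict[str, set[str]] = {}
    truth_distances: dict[tuple[str, str], float] = {}

    for cur in CURRENCY_IDS:
        metabolites[f"{cur}_c"] = Metabolite(id=f"{cur}_c", compartment="c", refs={})

    for c in range(config.n_chains):
        subsystem = f"subsystem{c}"
        for k in range(L + 1):
            base = f"cpd{c}x{k}"
            metabolites[f"{base}_c"] = Metabolite(
                id=f"{base}_c", compartment="c", refs={"KEGG": f"K{c:02d}{k:02d}"}
            )
            t_metabolites[base] = Metabolite(id=base, compartment=None, refs={"KEGG": f"K{c:02d}{k:02d}"})
        for k in range(1, L + 1):
            rid = f"rx{c}x{k}"
            gene = f"gene{c}x{k}"
            mets = {f"cpd{c}x{k-1}_c", f"cpd{c}x{k}_c"} | {f"{cur}_c" for cur in CURRENCY_IDS}
            reactions[rid] = Reaction(id=rid, mets=mets, subsystem=subsystem)
            gene_assoc[rid] = {gene}
            t_reactions[rid] = Reaction(
                id=rid, mets={f"cpd{c}x{k-1}", f"cpd{c}x{k}"}, subsystem=subsystem
            )
            t_gene_assoc[rid] = {gene}
            truth_distances[(f"cpd{c}x0", gene)] = float(k - 1)

    # duplicated compartment copy of chain-0 metabolite 1, plus a pure
    # transport reaction that must collapse to a (dropped) self-loop
    dup = "cpd0x1"
    metabolites[f"{dup}_m"] = Metabolite(id=f"{dup}_m", compartment="m", refs={"KEGG": "K0001"})
    reactions["tr0"] = Reaction(id="tr0", mets={f"{dup}_c", f"{dup}_m"}, subsystem="transport")
    gene_assoc["tr0"] = {"geneTR"}

    model = MetabolicModel(
        metabolites=metabolites,
        reactions=reactions,
        gene_assoc=gene_assoc,
        currency=set(CURRENCY_IDS),
    )
    truth_model = MetabolicModel(
        metabolites=t_metabolites, reactions=t_reactions, gene_assoc=t_gene_assoc, currency=set()
    )
    return ToyModel(model=model, truth_model=truth_model, truth_distances=truth_distances)


# ---------------------------------------------------------------------------
# Motif hits
# ---------------------------------------------------------------------------

@dataclass
class MotifHits:
    """Gene x motif occurrence counts plus the planted-motif key."""

    table: pd.DataFrame  # genes x motifs, non-negative integers
    planted: dict[str, int]  # motif id -> index of the enriched gene set


def generate_motif_hits(config: SynthConfig, gene_sets: list[set[str]]) -> MotifHits:
    """Occurrence counts where motif ``i`` (for each supplied gene set) hits
    set members with probability ``motif_p_in`` and the rest of the universe
    with ``motif_p_out``; remaining motifs hit uniformly at ``motif_p_out``.
    """
    config.validate()
    universe = config.transcript_ids()
    if not universe:
        raise ConfigurationError("empty gene universe")
    known = set(universe)
    for gs in gene_sets:
        if not set(gs) <= known:
            raise ConfigurationError("gene set references genes outside the universe")
    if len(gene_sets) > config.n_motifs:
        raise ConfigurationError("more gene sets than motifs to plant")

    rng = np.random.default_rng(config.seed + 1)
    motifs = [f"MA{i:04d}" for i in range(config.n_motifs)]
    counts = np.zeros((len(universe), config.n_motifs), dtype=int)
    planted: dict[str, int] = {}
    gene_pos = {g: i for i, g in enumerate(universe)}
    for j, motif in enumerate(motifs):
        p = np.full(len(universe), config.motif_p_out)
        if j < len(gene_sets):
            for g in gene_sets[j]:
                p[gene_pos[g]] = config.motif_p_in
            planted[motif] = j
        hit = rng.random(len(universe)) < p
        counts[:, j] = hit * (1 + rng.poisson(1.0, size=len(universe)))
    table = pd.DataFrame(counts, index=pd.Index(universe, name="gene"), columns=motifs)
    return MotifHits(table=table, planted=planted)
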