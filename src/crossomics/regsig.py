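"""Regulatory-signature analysis over a precomputed motif-hit table.

Gene sets are derived from the network neighborhoods of metabolites
(degree >= 3) and from subpathway/superpathway unions of those
neighborhoods. The default enrichment backend is a one-sided
hypergeometric test on genes with at least one motif occurrence in the set
versus the remaining gene universe; an external scanner's results table
can be substituted since downstream steps only consume (set, motif, p).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .exceptions import CrossOmicsError
from .network import BipartiteNetwork

DEFAULT_P_CUT = 1e-7

SET_LEVELS = ("metabolite", "subpathway", "superpathway")


# ---------------------------------------------------------------------------
# Gene-set construction
# ---------------------------------------------------------------------------

def build_gene_sets(
    network: BipartiteNetwork,
    metabolite_annotations: pd.DataFrame | None = None,
    min_degree: int = 3,
) -> dict[str, dict[str, set[str]]]:
    """Gene sets per level.

    - ``metabolite``: transcript neighbors of each metabolite with network
      degree >= ``min_degree``.
    - ``subpathway`` / ``superpathway``: union of the neighbor sets of all
      member metabolites (requires ``metabolite_annotations`` with columns
      ``metabolite``, ``subpathway``, ``superpathway``).
    """
    sets: dict[str, dict[str, set[str]]] = {level: {} for level in SET_LEVELS}
    neighbor = {m: network.neighbors(m) for m in network.metabolites}
    for m, genes in neighbor.items():
        if len(genes) >= min_degree:
            sets["metabolite"][m] = set(genes)
    if metabolite_annotations is not None:
        for level in ("subpathway", "superpathway"):
            for label, group in metabolite_annotations.groupby(level):
                union: set[str] = set()
                for m in group["metabolite"]:
                    union |= neighbor.get(m, set())
                if union:
                    sets[level][label] = union
    return sets


# ---------------------------------------------------------------------------
# Enrichment backend
# ---------------------------------------------------------------------------

@dataclass
class EnrichmentResult:
    set_id: str
    motif_id: str
    p: float
    frac_with_hit: float
    significant: bool


def motif_enrichment(
    gene_set: set[str],
    background: set[str],
    hits: pd.DataFrame,
    p_cut: float = DEFAULT_P_CUT,
    set_id: str = "",
) -> list[EnrichmentResult]:
    """One-sided hypergeometric over-representation of each motif in
    ``gene_set`` against ``background`` (disjoint from the set).

    A gene "has" a motif if its occurrence count is >= 1.
    """
    if not gene_set:
        raise CrossOmicsError("empty gene set")
    if gene_set & background:
        raise CrossOmicsError("gene set and background overlap")
    set_genes = sorted(g for g in gene_set if g in hits.index)
    bg_genes = sorted(g for g in background if g in hits.index)
    n_set, n_bg = len(set_genes), len(bg_genes)
    N = n_set + n_bg
    results = []
    set_hits = (hits.loc[set_genes] >= 1).sum(axis=0)
    bg_hits = (hits.loc[bg_genes] >= 1).sum(axis=0)
    for motif in hits.columns:
        k = int(set_hits[motif])
        K = k + int(bg_hits[motif])
        p = float(sps.hypergeom.sf(k - 1, N, K, n_set))
        results.append(
            EnrichmentResult(
                set_id=set_id,
                motif_id=motif,
                p=p,
                frac_with_hit=k / n_set if n_set else np.nan,
                significant=p <= p_cut,
            )
        )
    return results


def enrich_all(
    sets_by_level: dict[str, dict[str, set[str]]],
    hits: pd.DataFrame,
    universe: set[str],
    p_cut: float = DEFAULT_P_CUT,
) -> dict[str, pd.DataFrame]:
    """Run the enrichment backend for every set at every level; the
    background of each set is the remaining gene universe."""
    out = {}
    for level, sets in sets_by_level.items():
        rows = []
        for set_id, genes in sets.items():
            for res in motif_enrichment(genes, universe - genes, hits, p_cut, set_id=set_id):
                rows.append(
                    {"set_id": res.set_id, "motif": res.motif_id, "p": res.p,
                     "frac_with_hit": res.frac_with_hit, "significant": res.significant}
                )
        out[level] = pd.DataFrame(rows, columns=["set_id", "motif", "p", "frac_with_hit", "significant"])
    return out


# ---------------------------------------------------------------------------
# Shared-TFBS matrices and triads
# ---------------------------------------------------------------------------

def shared_matrices(enrichments: dict[str, pd.DataFrame]) -> dict[str, pd.DataFrame]:
    """Per level, symmetric matrix of pairwise shared significant motifs;
    the diagonal holds each set's significant-motif count."""
    out = {}
    for level, table in enrichments.items():
        sig = table[table["significant"]]
        motif_sets = {s: set(g["motif"]) for s, g in sig.groupby("set_id")}
        ids = sorted(motif_sets)
        mat = pd.DataFrame(0, index=ids, columns=ids, dtype=int)
        for a in ids:
            for b in ids:
                mat.loc[a, b] = len(motif_sets[a] & motif_sets[b])
        out[level] = mat
    return out


@dataclass
class Triad:
    metabolite: str
    tf_gene: str
    motif: str
    p: float


def find_triads(
    network: BipartiteNetwork,
    tf_gene_map: dict[str, str],
    hits: pd.DataFrame,
    universe: set[str],
    p_cut: float = DEFAULT_P_CUT,
    min_degree: int = 3,
) -> list[Triad]:
    """Metabolite / transcription-factor / target-gene triads.

    A triad (M, t) requires (i) the TF's transcript to be a network
    neighbor of metabolite M and (ii) the TF's motif to be significantly
    enriched in M's *other* neighbor genes, with the TF gene excluded from
    the test set (and from the background). Motifs without a TF-gene
    mapping cannot form triads.
    """
    triads = []
    for m in sorted(network.metabolites):
        neighbors = network.neighbors(m)
        if len(neighbors) < min_degree:
            continue
        for motif, tf_gene in sorted(tf_gene_map.items()):
            if tf_gene not in neighbors:
                continue
            test_set = neighbors - {tf_gene}
            if not test_set:
                continue
            background = universe - test_set - {tf_gene}
            results = motif_enrichment(test_set, background, hits[[motif]], p_cut, set_id=m)
            if results and results[0].significant:
                triads.append(Triad(metabolite=m, tf_gene=tf_gene, motif=motif, p=results[0].p))
    return triads
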