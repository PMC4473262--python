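"""Functional-category aggregation (aggZ-scores) and the pathway
interaction network (PIN).

For each (GO, MP) category pair, membership is edge-constrained: only
transcripts of the GO term with at least one network edge into the MP
term's metabolites (and vice versa) contribute to the pair's aggregated
z-scores. The per-sample aggZ-score of a member set is the arithmetic mean
of the members' z-score-normalized profiles.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .exceptions import CrossOmicsError
from .matrix import OmicsMatrix
from .network import BipartiteNetwork
from .stats import spearman

GO_ROOT_TERMS = ("biological_process", "molecular_function", "cellular_component")


# ---------------------------------------------------------------------------
# Category map
# ---------------------------------------------------------------------------

@dataclass
class CategoryMap:
    """Functional categories: GO-slim-like gene terms and metabolic
    (sub)pathway metabolite terms."""

    members: dict[str, set[str]]
    kinds: dict[str, str]  # category id -> 'GO' | 'MP'

    def __post_init__(self) -> None:
        if set(self.members) != set(self.kinds):
            raise ValueError("members and kinds must cover the same categories")

    def of_kind(self, kind: str) -> list[str]:
        return sorted(c for c, k in self.kinds.items() if k == kind)

    def filtered(
        self,
        metabolite_universe,
        transcript_universe,
        min_mp_metabolites: int = 2,
        go_roots=GO_ROOT_TERMS,
    ) -> "CategoryMap":
        """Apply the category filters: MP terms need >= 2 metabolite members
        in the universe; GO root terms and terms without any annotated
        transcript are removed."""
        mets = set(metabolite_universe)
        trans = set(transcript_universe)
        roots = set(go_roots)
        members: dict[str, set[str]] = {}
        kinds: dict[str, str] = {}
        for cat, mem in self.members.items():
            kind = self.kinds[cat]
            if kind == "MP":
                kept = mem & mets
                if len(kept) < min_mp_metabolites:
                    continue
            else:
                if cat in roots:
                    continue
                kept = mem & trans
                if not kept:
                    continue
            members[cat] = kept
            kinds[cat] = kind
        return CategoryMap(members=members, kinds=kinds)


# ---------------------------------------------------------------------------
# Edge-constrained membership
# ---------------------------------------------------------------------------

@dataclass
class PairMembers:
    go: str
    mp: str
    transcripts: set[str]
    metabolites: set[str]

    @property
    def testable(self) -> bool:
        return bool(self.transcripts) and bool(self.metabolites)


def build_category_sets(
    categories: CategoryMap, network: BipartiteNetwork
) -> list[PairMembers]:
    """Edge-constrained member sets for every (GO, MP) combination."""
    adjacency = {n: set(network.graph.neighbors(n)) for n in network.graph.nodes}
    pairs = []
    for go in categories.of_kind("GO"):
        go_members = categories.members[go]
        for mp in categories.of_kind("MP"):
            mp_members = categories.members[mp]
            transcripts = {
                t for t in go_members if adjacency.get(t, set()) & mp_members
            }
            metabolites = {
                m for m in mp_members if adjacency.get(m, set()) & go_members
            }
            pairs.append(PairMembers(go=go, mp=mp, transcripts=transcripts, metabolites=metabolites))
    return pairs


# ---------------------------------------------------------------------------
# aggZ-scores
# ---------------------------------------------------------------------------

def aggz_scores(z_matrix: OmicsMatrix, member_set) -> np.ndarray:
    """Per-sample arithmetic mean of the members' z-scores; samples with
    missing members use the mean over observed members."""
    members = sorted(member_set)
    if not members:
        raise CrossOmicsError("empty member set")
    if z_matrix.scale_tag != "zscore":
        raise CrossOmicsError("aggz_scores expects a zscore-scale matrix")
    sub = z_matrix.values[members].to_numpy(dtype=float)
    observed = ~np.isnan(sub)
    counts = observed.sum(axis=1)
    sums = np.where(observed, sub, 0.0).sum(axis=1)
    return np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)


# ---------------------------------------------------------------------------
# PIN construction
# ---------------------------------------------------------------------------

@dataclass
class PinResult:
    pairs: pd.DataFrame  # go, mp, rho, p, n_members_go, n_members_mp, tested, skipped
    full: nx.Graph
    viz: nx.Graph
    alpha: float
    viz_p: float
    n_tests: int
    p_cutoff: float
    scores: dict = field(default_factory=dict, repr=False)  # (go, mp) -> (go aggZ, mp aggZ)


def build_pin(
    pair_members: list[PairMembers],
    met_z: OmicsMatrix,
    trans_z: OmicsMatrix,
    alpha: float = 0.01,
    viz_p: float = 1e-11,
    n_tests: int | None = None,
) -> PinResult:
    """Spearman correlation of the GO-side and MP-side aggZ vectors per
    testable pair, Bonferroni-thresholded PIN plus a sparser viz network.

    The Bonferroni denominator defaults to the number of testable pairs and
    is recorded in the result metadata.
    """
    rows = []
    scores = {}
    for pair in pair_members:
        if not pair.testable:
            rows.append({"go": pair.go, "mp": pair.mp, "rho": np.nan, "p": np.nan,
                         "n_go": 0, "n_mp": 0, "tested": False, "skipped": "untestable"})
            continue
        go_score = aggz_scores(trans_z, pair.transcripts)
        mp_score = aggz_scores(met_z, pair.metabolites)
        rho, p, n = spearman(go_score, mp_score)
        if not np.isfinite(rho):
            rows.append({"go": pair.go, "mp": pair.mp, "rho": np.nan, "p": np.nan,
                         "n_go": len(pair.transcripts), "n_mp": len(pair.metabolites),
                         "tested": False, "skipped": "degenerate"})
            continue
        scores[(pair.go, pair.mp)] = (go_score, mp_score)
        rows.append({"go": pair.go, "mp": pair.mp, "rho": rho, "p": p,
                     "n_go": len(pair.transcripts), "n_mp": len(pair.metabolites),
                     "tested": True, "skipped": ""})
    pairs = pd.DataFrame(rows)

    tested = pairs[pairs["tested"]]
    m = n_tests if n_tests is not None else len(tested)
    p_cutoff = alpha / m if m else 0.0

    def graph_at(threshold: float) -> nx.Graph:
        g = nx.Graph()
        for row in tested.itertuples():
            if row.p <= threshold:
                g.add_node(row.go, kind="GO")
                g.add_node(row.mp, kind="MP")
                g.add_edge(row.go, row.mp, rho=float(row.rho), p=float(row.p))
        return g

    return PinResult(
        pairs=pairs,
        full=graph_at(p_cutoff),
        viz=graph_at(min(p_cutoff, viz_p)),
        alpha=alpha,
        viz_p=viz_p,
        n_tests=m,
        p_cutoff=p_cutoff,
        scores=scores,
    )
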