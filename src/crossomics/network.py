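"""Pairwise metabolite-transcript Spearman correlation, FDR thresholding,
network construction, replication and marker-list overlap.

Correlations are computed per pair on pairwise-complete samples (the
transcriptome is required to be complete; metabolite missingness drives the
per-pair sample counts). Significance is controlled by Benjamini-Hochberg,
optionally over the full pre-collapse probe-level test family.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats as sps

from .exceptions import AlignmentError, CrossOmicsError
from .matrix import OmicsMatrix
from .stats import bh_cutoff, bh_reject, spearman, spearman_pvalue

MIN_SAMPLES = 10  # pairs with fewer complete samples are flagged, not thresholded


# ---------------------------------------------------------------------------
# Correlation table
# ---------------------------------------------------------------------------

def cross_correlate(metabolome: OmicsMatrix, transcriptome: OmicsMatrix) -> pd.DataFrame:
    """Spearman correlation for every metabolite x transcript pair.

    Returns a long-format table with columns ``metabolite``, ``transcript``,
    ``rho``, ``p``, ``n_used`` and ``low_n``.
    """
    if not metabolome.values.index.equals(transcriptome.values.index):
        raise AlignmentError("matrices must share sample order")
    if metabolome.n_samples == 0:
        raise CrossOmicsError("no shared samples")
    tvals = transcriptome.values.to_numpy(dtype=float)
    if np.isnan(tvals).any():
        raise CrossOmicsError("transcriptome must be complete")

    mvals = metabolome.values.to_numpy(dtype=float)
    met_ids = metabolome.feature_ids
    trans_ids = transcriptome.feature_ids
    frames = []
    for j, met in enumerate(met_ids):
        y = mvals[:, j]
        obs = ~np.isnan(y)
        n = int(obs.sum())
        if n < 3:
            rho = np.full(len(trans_ids), np.nan)
            p = np.full(len(trans_ids), np.nan)
        else:
            ry = sps.rankdata(y[obs])
            rt = sps.rankdata(tvals[obs], axis=0)
            ry = ry - ry.mean()
            rt = rt - rt.mean(axis=0)
            denom = np.sqrt((ry @ ry) * np.sum(rt * rt, axis=0))
            with np.errstate(divide="ignore", invalid="ignore"):
                rho = np.where(denom > 0, ry @ rt / denom, np.nan)
            rho = np.clip(rho, -1.0, 1.0)
            p = np.array([spearman_pvalue(r, n) if np.isfinite(r) else np.nan for r in rho])
        frames.append(
            pd.DataFrame(
                {
                    "metabolite": met,
                    "transcript": trans_ids,
                    "rho": rho,
                    "p": p,
                    "n_used": n,
                    "low_n": n < MIN_SAMPLES,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# Network
# ---------------------------------------------------------------------------

@dataclass
class BipartiteNetwork:
    """Significance-thresholded bipartite metabolite-transcript network."""

    graph: nx.Graph
    fdr: float
    p_cutoff: float
    rho_cutoff: float
    n_tests: int

    @property
    def metabolites(self) -> set[str]:
        return {n for n, d in self.graph.nodes(data=True) if d.get("type") == "metabolite"}

    @property
    def transcripts(self) -> set[str]:
        return {n for n, d in self.graph.nodes(data=True) if d.get("type") == "transcript"}

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def edges_table(self) -> pd.DataFrame:
        rows = []
        for u, v, d in self.graph.edges(data=True):
            met, trans = (u, v) if self.graph.nodes[u]["type"] == "metabolite" else (v, u)
            rows.append({"metabolite": met, "transcript": trans, "rho": d["rho"], "p": d["p"]})
        return pd.DataFrame(rows, columns=["metabolite", "transcript", "rho", "p"])

    def neighbors(self, node: str) -> set[str]:
        return set(self.graph.neighbors(node))

    def to_graphml(self, path) -> None:
        nx.write_graphml(self.graph, path)


def connectivity(n_edges: int, n_metabolites: int, n_transcripts: int) -> float:
    """Realized edge fraction over all possible metabolite-transcript pairs."""
    possible = n_metabolites * n_transcripts
    if possible == 0:
        raise CrossOmicsError("no possible pairs")
    return n_edges / possible


def density_curve(corr: pd.DataFrame, step: float = 0.005) -> pd.DataFrame:
    """Edge fraction as a function of an absolute-correlation cutoff grid."""
    abs_rho = corr["rho"].abs().to_numpy()
    abs_rho = abs_rho[np.isfinite(abs_rho)]
    top = float(abs_rho.max()) if len(abs_rho) else 0.0
    grid = np.arange(0.0, top + step, step)
    dens = [(abs_rho >= c).mean() if len(abs_rho) else 0.0 for c in grid]
    return pd.DataFrame({"cutoff": grid, "density": dens})


def threshold_and_build(
    corr: pd.DataFrame,
    fdr: float = 0.01,
    probe_level_m: int | None = None,
    grid_step: float = 0.005,
) -> tuple[BipartiteNetwork, pd.DataFrame]:
    """BH thresholding of a correlation table and bipartite network
    construction, plus the density diagnostic curve.

    ``probe_level_m`` supplies the pre-collapse transcript (probe) count so
    the BH family is ``probe_level_m x n_metabolites`` even when ``corr``
    itself is probe-collapsed.
    """
    if not 0 < fdr < 1:
        raise CrossOmicsError("fdr must be in (0, 1)")
    tested = corr[~corr["low_n"] & corr["p"].notna()]
    n_mets = corr["metabolite"].nunique()
    m_total = probe_level_m * n_mets if probe_level_m is not None else len(tested)
    if m_total < len(tested):
        raise CrossOmicsError("probe-level family smaller than tested pair count")
    p_cutoff = bh_cutoff(tested["p"].to_numpy(), fdr, m_total)
    edges = tested[tested["p"] <= p_cutoff] if p_cutoff > 0 else tested.iloc[0:0]

    graph = nx.Graph()
    for row in edges.itertuples():
        graph.add_node(row.metabolite, type="metabolite")
        graph.add_node(row.transcript, type="transcript")
        graph.add_edge(row.metabolite, row.transcript, rho=float(row.rho), p=float(row.p))
    rho_cutoff = float(edges["rho"].abs().min()) if len(edges) else np.nan
    net = BipartiteNetwork(
        graph=graph, fdr=fdr, p_cutoff=p_cutoff, rho_cutoff=rho_cutoff, n_tests=m_total
    )
    return net, density_curve(corr, step=grid_step)


# ---------------------------------------------------------------------------
# Replication
# ---------------------------------------------------------------------------

@dataclass
class ReplicationSummary:
    n_edges: int
    n_testable: int
    n_nominal: int
    n_fdr: int
    nominal_alpha: float = 0.05
    fdr_level: float = 0.05
    table: pd.DataFrame = field(default_factory=pd.DataFrame, repr=False)

    @property
    def frac_nominal(self) -> float:
        return self.n_nominal / self.n_testable if self.n_testable else np.nan

    @property
    def frac_fdr(self) -> float:
        return self.n_fdr / self.n_testable if self.n_testable else np.nan


def replicate_edges(
    network: BipartiteNetwork,
    metabolome2: OmicsMatrix,
    transcriptome2: OmicsMatrix,
    metabolite_map: dict[str, str] | None = None,
    transcript_map: dict[str, str] | None = None,
    nominal_alpha: float = 0.05,
    fdr_level: float = 0.05,
) -> ReplicationSummary:
    """Re-test every mappable network edge in a second cohort.

    Maps list comparable features between the cohorts (identity by
    default); the FDR correction is applied over the tested-edge set.
    """
    met_map = metabolite_map if metabolite_map is not None else {
        m: m for m in network.metabolites if m in metabolome2.values.columns
    }
    trans_map = transcript_map if transcript_map is not None else {
        t: t for t in network.transcripts if t in transcriptome2.values.columns
    }
    if not met_map or not trans_map:
        raise CrossOmicsError("empty feature overlap between cohorts")

    rows = []
    edges = network.edges_table()
    for row in edges.itertuples():
        if row.metabolite not in met_map or row.transcript not in trans_map:
            continue
        x = metabolome2.values[met_map[row.metabolite]]
        y = transcriptome2.values[trans_map[row.transcript]]
        rho, p, n = spearman(x, y)
        rows.append(
            {
                "metabolite": row.metabolite,
                "transcript": row.transcript,
                "rho_discovery": row.rho,
                "rho_replication": rho,
                "p": p,
                "n_used": n,
            }
        )
    table = pd.DataFrame(rows)
    tested = table[table["p"].notna()]
    n_nominal = int((tested["p"] < nominal_alpha).sum())
    n_fdr = int(bh_reject(tested["p"].to_numpy(), fdr_level).sum()) if len(tested) else 0
    return ReplicationSummary(
        n_edges=len(edges),
        n_testable=len(tested),
        n_nominal=n_nominal,
        n_fdr=n_fdr,
        nominal_alpha=nominal_alpha,
        fdr_level=fdr_level,
        table=table,
    )


# ---------------------------------------------------------------------------
# Marker overlap
# ---------------------------------------------------------------------------

def marker_overlap(network_genes, marker_lists: dict[str, set]) -> pd.DataFrame:
    """Percentage of network genes contained in each marker list, plus the
    ``unassigned`` remainder (genes in no list). A gene present in several
    lists is counted once per label, matching per-source summaries.
    """
    genes = set(network_genes)
    n = len(genes)
    rows = []
    assigned: set = set()
    for label, members in marker_lists.items():
        hit = genes & set(members)
        assigned |= hit
        rows.append({"label": label, "n_genes": len(hit), "percent": 100.0 * len(hit) / n if n else 0.0})
    rows.append(
        {
            "label": "unassigned",
            "n_genes": n - len(assigned),
            "percent": 100.0 * (n - len(assigned)) / n if n else 0.0,
        }
    )
    return pd.DataFrame(rows)
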