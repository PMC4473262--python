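"""Metabolic reconstruction handling and metabolite-enzyme reaction-step
distances.

The model is reduced before distance computation: compartment copies of a
species are merged into a single node, duplicated reactions are collapsed,
currency metabolites are removed, and all reaction directionality is
ignored. Distances are computed on the undirected bipartite
metabolite-reaction incidence graph; a distance of zero means the
metabolite is a direct participant of a reaction catalyzed by the gene.
"""

from __future__ import annotations

import re
import warnings
import xml.etree.ElementTree as ET
from dataclasses import dataclass, field, replace

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats as sps

DEFAULT_COMPARTMENT_REGEX = r"(_[a-z]\b|\[[a-z]\])$"


@dataclass
class Metabolite:
    id: str
    compartment: str | None = None
    refs: dict = field(default_factory=dict)  # e.g. {'KEGG': ..., 'HMDB': ...}


@dataclass
class Reaction:
    id: str
    mets: set[str]
    subsystem: str | None = None


@dataclass
class MetabolicModel:
    metabolites: dict[str, Metabolite]
    reactions: dict[str, Reaction]
    gene_assoc: dict[str, set[str]]  # reaction id -> gene ids
    currency: set[str] = field(default_factory=set)
    prepared: bool = False

    def __post_init__(self) -> None:
        for rid, rxn in self.reactions.items():
            if not rxn.mets:
                raise ValueError(f"reaction {rid} has no participants")
        for rid in self.gene_assoc:
            if rid not in self.reactions:
                raise ValueError(f"gene association references unknown reaction {rid}")

    def genes(self) -> set[str]:
        return set().union(*self.gene_assoc.values()) if self.gene_assoc else set()

    def gene_reactions(self) -> dict[str, set[str]]:
        """Gene id -> set of reaction ids it catalyzes."""
        idx: dict[str, set[str]] = {}
        for rid, genes in self.gene_assoc.items():
            for g in genes:
                idx.setdefault(g, set()).add(rid)
        return idx


# ---------------------------------------------------------------------------
# Model preparation
# ---------------------------------------------------------------------------

def prepare_model(
    model: MetabolicModel, compartment_regex: str = DEFAULT_COMPARTMENT_REGEX
) -> MetabolicModel:
    """Merge compartment copies, collapse duplicate reactions, drop pure
    transport self-loops and remove currency metabolites.

    Idempotent: preparing a prepared model returns an equivalent model.
    """
    pat = re.compile(compartment_regex)

    def base(mid: str) -> str:
        return pat.sub("", mid)

    # merge species across compartments
    merged_mets: dict[str, Metabolite] = {}
    for met in model.metabolites.values():
        b = base(met.id)
        if b in merged_mets:
            merged_mets[b].refs.update(met.refs)
        else:
            merged_mets[b] = Metabolite(id=b, compartment=None, refs=dict(met.refs))

    # remap reactions; a multi-participant reaction collapsing to a single
    # node (pure transport) becomes a self-loop and is dropped
    remapped: dict[str, Reaction] = {}
    remapped_genes: dict[str, set[str]] = {}
    for rid, rxn in model.reactions.items():
        mets = {base(m) for m in rxn.mets}
        if len(mets) < 2 and len(rxn.mets) > 1:
            continue
        remapped[rid] = Reaction(id=rid, mets=mets, subsystem=rxn.subsystem)
        remapped_genes[rid] = set(model.gene_assoc.get(rid, set()))

    # collapse duplicate reactions (identical participant sets after merge)
    by_mets: dict[frozenset, str] = {}
    reactions: dict[str, Reaction] = {}
    gene_assoc: dict[str, set[str]] = {}
    for rid in sorted(remapped):
        rxn = remapped[rid]
        key = frozenset(rxn.mets)
        if key in by_mets:
            keep = by_mets[key]
            gene_assoc[keep] |= remapped_genes[rid]
        else:
            by_mets[key] = rid
            reactions[rid] = rxn
            gene_assoc[rid] = set(remapped_genes[rid])

    # remove currency metabolites and their incidences
    currency = {base(c) for c in model.currency}
    missing = currency - set(merged_mets)
    if missing:
        warnings.warn(f"currency ids absent from model: {sorted(missing)}")
    for c in currency:
        merged_mets.pop(c, None)
    for rid in list(reactions):
        kept = reactions[rid].mets - currency
        if not kept:
            del reactions[rid]
            del gene_assoc[rid]
        else:
            reactions[rid] = replace(reactions[rid], mets=kept)

    return MetabolicModel(
        metabolites=merged_mets,
        reactions=reactions,
        gene_assoc={rid: g for rid, g in gene_assoc.items() if g},
        currency=set(),
        prepared=True,
    )


# ---------------------------------------------------------------------------
# Distances
# ---------------------------------------------------------------------------

def incidence_graph(model: MetabolicModel) -> nx.Graph:
    """Undirected bipartite metabolite-reaction graph."""
    g = nx.Graph()
    for mid in model.metabolites:
        g.add_node(("M", mid))
    for rid, rxn in model.reactions.items():
        g.add_node(("R", rid))
        for m in rxn.mets:
            if m in model.metabolites:
                g.add_edge(("M", m), ("R", rid))
    return g


def resolve_metabolites(model: MetabolicModel, ids) -> dict[str, str | None]:
    """Map queried ids to model metabolites by internal id or exact
    KEGG/HMDB reference match (no fuzzy matching)."""
    ref_index: dict[str, str] = {}
    for mid, met in model.metabolites.items():
        for ref in met.refs.values():
            ref_index.setdefault(str(ref), mid)
    out: dict[str, str | None] = {}
    for q in ids:
        if q in model.metabolites:
            out[q] = q
        else:
            out[q] = ref_index.get(q)
    return out


def pairwise_distances(model: MetabolicModel, metabolite_ids, gene_ids) -> pd.DataFrame:
    """Reaction-step distances for all requested (metabolite, gene) pairs.

    Returns a DataFrame with columns ``metabolite``, ``gene``, ``d``,
    ``status`` and ``subsystems``. ``d`` is ``NaN`` with status ``NM`` when
    either endpoint is unmapped, ``inf`` with status ``Inf`` when both map
    but are disconnected, and otherwise the minimal number of reaction steps
    (0 = direct reactant). ``subsystems`` lists the subsystem labels of the
    gene's reactions that attain the minimal distance.
    """
    if not model.prepared:
        warnings.warn("computing distances on an unprepared model")
    graph = incidence_graph(model)
    gene_rxns = model.gene_reactions()
    met_map = resolve_metabolites(model, metabolite_ids)

    records = []
    for met in metabolite_ids:
        internal = met_map[met]
        hops = None
        if internal is not None:
            hops = nx.single_source_shortest_path_length(graph, ("M", internal))
        for gene in gene_ids:
            rxns = gene_rxns.get(gene)
            if internal is None or not rxns:
                records.append((met, gene, np.nan, "NM", ()))
                continue
            best = None
            for rid in rxns:
                h = hops.get(("R", rid))
                if h is not None and (best is None or h < best):
                    best = h
            if best is None:
                records.append((met, gene, np.inf, "Inf", ()))
            else:
                d = (best - 1) // 2  # hop count -> reaction steps
                subs = tuple(
                    sorted(
                        {
                            model.reactions[rid].subsystem
                            for rid in rxns
                            if hops.get(("R", rid)) == best
                            and model.reactions[rid].subsystem is not None
                        }
                    )
                )
                records.append((met, gene, float(d), "ok", subs))
    return pd.DataFrame(records, columns=["metabolite", "gene", "d", "status", "subsystems"])


# ---------------------------------------------------------------------------
# Enrichment
# ---------------------------------------------------------------------------

def distance_enrichment(
    distances: pd.DataFrame,
    significant,
    max_subsystem_distance: int = 2,
) -> dict:
    """Over-representation of significant pairs at each finite distance and
    within each cumulative band, via one-tailed Fisher's exact tests, plus
    subsystem frequency tables among significant pairs at short distances.

    Parameters
    ----------
    distances
        Output of :func:`pairwise_distances`.
    significant
        Iterable of (metabolite, gene) pairs flagged significant.
    """
    sig_pairs = set(map(tuple, significant))
    finite = distances[distances["status"] == "ok"].copy()
    finite["significant"] = [
        (m, g) in sig_pairs for m, g in zip(finite["metabolite"], finite["gene"])
    ]
    n_sig = int(finite["significant"].sum())
    n_tot = len(finite)

    def fisher(in_band: pd.Series) -> tuple[float, bool]:
        a = int((in_band & finite["significant"]).sum())
        b = n_sig - a
        c = int(in_band.sum()) - a
        d = n_tot - a - b - c
        if in_band.sum() == 0:
            return 1.0, True  # empty band, flagged
        p = sps.fisher_exact([[a, b], [c, d]], alternative="greater")[1]
        return float(p), False

    per_distance = []
    cumulative = []
    for d in sorted(finite["d"].unique()):
        p, empty = fisher(finite["d"] == d)
        per_distance.append({"d": d, "p": p, "empty": empty})
        p, empty = fisher(finite["d"] <= d)
        cumulative.append({"d": d, "p": p, "empty": empty})

    subsystem_freq = {}
    for d in range(max_subsystem_distance + 1):
        rows = finite[(finite["d"] == d) & finite["significant"]]
        counts: dict[str, int] = {}
        for subs in rows["subsystems"]:
            for s in subs:
                counts[s] = counts.get(s, 0) + 1
        subsystem_freq[d] = pd.Series(counts, dtype=int).sort_values(ascending=False)

    return {
        "per_distance": pd.DataFrame(per_distance),
        "cumulative": pd.DataFrame(cumulative),
        "subsystem_freq": subsystem_freq,
        "n_significant": n_sig,
        "n_finite": n_tot,
    }


# ---------------------------------------------------------------------------
# Serialization: JSON dialect and SBML subset
# ---------------------------------------------------------------------------

def model_to_dict(model: MetabolicModel) -> dict:
    return {
        "metabolites": [
            {"id": m.id, "compartment": m.compartment, "refs": m.refs}
            for m in model.metabolites.values()
        ],
        "reactions": [
            {
                "id": r.id,
                "mets": sorted(r.mets),
                "genes": sorted(model.gene_assoc.get(r.id, set())),
                "subsystem": r.subsystem,
            }
            for r in model.reactions.values()
        ],
        "currency": sorted(model.currency),
        "prepared": model.prepared,
    }


def model_from_dict(payload: dict) -> MetabolicModel:
    metabolites = {
        m["id"]: Metabolite(id=m["id"], compartment=m.get("compartment"), refs=m.get("refs", {}))
        for m in payload["metabolites"]
    }
    reactions = {}
    gene_assoc = {}
    for r in payload["reactions"]:
        reactions[r["id"]] = Reaction(id=r["id"], mets=set(r["mets"]), subsystem=r.get("subsystem"))
        if r.get("genes"):
            gene_assoc[r["id"]] = set(r["genes"])
    return MetabolicModel(
        metabolites=metabolites,
        reactions=reactions,
        gene_assoc=gene_assoc,
        currency=set(payload.get("currency", [])),
        prepared=bool(payload.get("prepared", False)),
    )


_SBML_NS = "http://www.sbml.org/sbml/level3/version1/core"


def read_sbml(path) -> MetabolicModel:
    """Minimal SBML Level-3-subset reader: species ids/compartments,
    reaction participant sets, and COBRA-style ``GENE_ASSOCIATION`` /
    ``SUBSYSTEM`` notes. Boolean gene logic is flattened to the gene set.
    """
    tree = ET.parse(path)
    root = tree.getroot()

    def findall(el, tag):
        return el.findall(f"{{{_SBML_NS}}}{tag}") + el.findall(tag)

    model_el = findall(root, "model")[0]
    metabolites: dict[str, Metabolite] = {}
    for lst in findall(model_el, "listOfSpecies"):
        for sp in findall(lst, "species"):
            sid = sp.get("id")
            metabolites[sid] = Metabolite(id=sid, compartment=sp.get("compartment"), refs={})
    reactions: dict[str, Reaction] = {}
    gene_assoc: dict[str, set[str]] = {}
    for lst in findall(model_el, "listOfReactions"):
        for rxn in findall(lst, "reaction"):
            rid = rxn.get("id")
            mets: set[str] = set()
            for side in ("listOfReactants", "listOfProducts"):
                for part in findall(rxn, side):
                    for ref in findall(part, "speciesReference"):
                        mets.add(ref.get("species"))
            subsystem = None
            genes: set[str] = set()
            for notes in findall(rxn, "notes"):
                for text in notes.itertext():
                    text = text.strip()
                    if text.startswith("GENE_ASSOCIATION:"):
                        raw = text.split(":", 1)[1]
                        tokens = re.split(r"[()\s]+", raw)
                        genes |= {t for t in tokens if t and t.lower() not in ("and", "or")}
                    elif text.startswith("SUBSYSTEM:"):
                        subsystem = text.split(":", 1)[1].strip() or None
            reactions[rid] = Reaction(id=rid, mets=mets, subsystem=subsystem)
            if genes:
                gene_assoc[rid] = genes
    return MetabolicModel(metabolites=metabolites, reactions=reactions, gene_assoc=gene_assoc)


def write_sbml(model: MetabolicModel, path) -> None:
    """Companion writer for :func:`read_sbml` (round-trip tested)."""
    ET.register_namespace("", _SBML_NS)
    root = ET.Element(f"{{{_SBML_NS}}}sbml", {"level": "3", "version": "1"})
    model_el = ET.SubElement(root, f"{{{_SBML_NS}}}model", {"id": "model"})
    sp_list = ET.SubElement(model_el, f"{{{_SBML_NS}}}listOfSpecies")
    for met in model.metabolites.values():
        attrs = {"id": met.id}
        if met.compartment:
            attrs["compartment"] = met.compartment
        ET.SubElement(sp_list, f"{{{_SBML_NS}}}species", attrs)
    rx_list = ET.SubElement(model_el, f"{{{_SBML_NS}}}listOfReactions")
    for rxn in model.reactions.values():
        rx = ET.SubElement(rx_list, f"{{{_SBML_NS}}}reaction", {"id": rxn.id})
        notes = ET.SubElement(rx, f"{{{_SBML_NS}}}notes")
        genes = sorted(model.gene_assoc.get(rxn.id, set()))
        if genes:
            ET.SubElement(notes, "p").text = "GENE_ASSOCIATION: " + " or ".join(genes)
        if rxn.subsystem:
            ET.SubElement(notes, "p").text = f"SUBSYSTEM: {rxn.subsystem}"
        reactants = ET.SubElement(rx, f"{{{_SBML_NS}}}listOfReactants")
        for m in sorted(rxn.mets):
            ET.SubElement(reactants, f"{{{_SBML_NS}}}speciesReference", {"species": m})
    ET.ElementTree(root).write(path, xml_declaration=True, encoding="unicode")
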