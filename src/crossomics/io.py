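"""Plain-text readers/writers: TSV matrices (empty cell = missing),
covariate/trait/genotype tables, GMT-like annotations, motif-hit tables,
model JSON, and truth sidecars.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from .matrix import OmicsMatrix
from .metnet import MetabolicModel, model_from_dict, model_to_dict
from .pin import CategoryMap
from .synth import CausalChain, SyntheticCohort, SyntheticTruth


# -- matrices ---------------------------------------------------------------

def write_matrix(matrix: OmicsMatrix, path) -> None:
    matrix.values.to_csv(path, sep="\t", index_label="sample", na_rep="")


def read_matrix(path, scale_tag: str = "raw") -> OmicsMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return OmicsMatrix(df, scale_tag=scale_tag)


def write_table(df: pd.DataFrame, path, index: bool = True) -> None:
    df.to_csv(path, sep="\t", index=index, index_label="sample" if index else None)


def read_table(path, index_col=0) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=index_col)


# -- cohort -----------------------------------------------------------------

def write_cohort(cohort: SyntheticCohort, outdir) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_matrix(cohort.metabolome, outdir / "metabolome.tsv")
    write_matrix(cohort.transcriptome, outdir / "transcriptome.tsv")
    write_table(cohort.covariates, outdir / "covariates.tsv")
    write_table(cohort.genotypes, outdir / "genotypes.tsv")
    write_table(cohort.traits, outdir / "traits.tsv")
    truth = {
        "edges": [list(e) for e in cohort.truth.edges],
        "causal": [vars(c) for c in cohort.truth.causal],
        "categories": {k: sorted(v) for k, v in cohort.truth.categories.items()},
        "category_kinds": cohort.truth.category_kinds,
        "couplings": [list(c) for c in cohort.truth.couplings],
    }
    (outdir / "truth.json").write_text(json.dumps(truth, indent=1))


def read_truth(path) -> SyntheticTruth:
    payload = json.loads(Path(path).read_text())
    return SyntheticTruth(
        edges=[tuple(e) for e in payload["edges"]],
        causal=[CausalChain(**c) for c in payload["causal"]],
        categories={k: set(v) for k, v in payload["categories"].items()},
        category_kinds=payload["category_kinds"],
        couplings=[tuple(c) for c in payload["couplings"]],
    )


# -- model ------------------------------------------------------------------

def write_model_json(model: MetabolicModel, path) -> None:
    Path(path).write_text(json.dumps(model_to_dict(model), indent=1))


def read_model_json(path) -> MetabolicModel:
    return model_from_dict(json.loads(Path(path).read_text()))


def read_currency_list(path) -> set[str]:
    return {line.strip() for line in Path(path).read_text().splitlines() if line.strip()}


# -- annotations ------------------------------------------------------------

def write_gmt(categories: CategoryMap, path) -> None:
    """GMT-like format: category <tab> kind <tab> member1 <tab> member2 ..."""
    lines = []
    for cat in sorted(categories.members):
        members = "\t".join(sorted(categories.members[cat]))
        lines.append(f"{cat}\t{categories.kinds[cat]}\t{members}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_gmt(path) -> CategoryMap:
    members: dict[str, set[str]] = {}
    kinds: dict[str, str] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        parts = line.split("\t")
        cat, kind, mem = parts[0], parts[1], parts[2:]
        members[cat] = {m for m in mem if m}
        kinds[cat] = kind
    return CategoryMap(members=members, kinds=kinds)


# -- motif hits -------------------------------------------------------------

def write_motif_hits(table: pd.DataFrame, path) -> None:
    """Long TSV: gene, motif, count (zero counts omitted)."""
    long = table.stack().rename("count").reset_index()
    long.columns = ["gene", "motif", "count"]
    long = long[long["count"] > 0]
    long.to_csv(path, sep="\t", index=False)


def read_motif_hits(path, genes=None, motifs=None) -> pd.DataFrame:
    long = pd.read_csv(path, sep="\t")
    wide = long.pivot_table(index="gene", columns="motif", values="count", fill_value=0)
    if genes is not None:
        wide = wide.reindex(list(genes), fill_value=0)
    if motifs is not None:
        wide = wide.reindex(columns=list(motifs), fill_value=0)
    return wide.astype(int)
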