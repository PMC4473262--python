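import networkx as nx
import numpy as np
import pytest
from scipy.special import comb

from crossomics import metnet, synth
from crossomics.metnet import MetabolicModel, Metabolite, Reaction


def make_model(reactions, currency=(), compartments=None):
    """Build a model from {rid: (met_ids, genes, subsystem)}."""
    mets = {}
    rxns = {}
    gene_assoc = {}
    for rid, (met_ids, genes, subsystem) in reactions.items():
        for m in met_ids:
            comp = (compartments or {}).get(m)
            mets.setdefault(m, Metabolite(id=m, compartment=comp, refs={}))
        rxns[rid] = Reaction(id=rid, mets=set(met_ids), subsystem=subsystem)
        if genes:
            gene_assoc[rid] = set(genes)
    return MetabolicModel(metabolites=mets, reactions=rxns, gene_assoc=gene_assoc,
                          currency=set(currency))


def brute_force_distance(model, met, gene):
    """BFS oracle over the bipartite incidence graph."""
    g = nx.Graph()
    for rid, rxn in model.reactions.items():
        for m in rxn.mets:
            if m in model.metabolites:
                g.add_edge(("M", m), ("R", rid))
    if met not in model.metabolites:
        return None
    rxns = [rid for rid, genes in model.gene_assoc.items() if gene in genes]
    if not rxns:
        return None
    best = np.inf
    for rid in rxns:
        node = ("R", rid)
        if ("M", met) in g and node in g:
            try:
                hops = nx.shortest_path_length(g, ("M", met), node)
                best = min(best, (hops - 1) // 2)
            except nx.NetworkXNoPath:
                pass
        elif met in model.reactions[rid].mets:
            best = min(best, 0)
    return best


class TestPrepareModel:
    def test_compartment_merge_drops_transport_self_loop(self):
        model = make_model(
            {
                "r1": (["a_c", "b_c"], ["g1"], "s"),
                "tr": (["a_c", "a_m"], ["gT"], "transport"),
                "r2": (["a_m", "d_m"], ["g2"], "s"),
            }
        )
        prep = metnet.prepare_model(model)
        assert set(prep.metabolites) == {"a", "b", "d"}
        assert "tr" not in prep.reactions
        assert prep.reactions["r1"].mets == {"a", "b"}
        assert prep.reactions["r2"].mets == {"a", "d"}

    def test_duplicate_reactions_collapse_and_union_genes(self):
        model = make_model(
            {
                "r1": (["a_c", "b_c"], ["g1"], "s"),
                "r2": (["a_m", "b_m"], ["g2"], "s"),
            }
        )
        prep = metnet.prepare_model(model)
        assert len(prep.reactions) == 1
        (rid,) = prep.reactions
        assert prep.gene_assoc[rid] == {"g1", "g2"}

    def test_currency_removal_disconnects_chains(self):
        model = make_model(
            {
                "r1": (["a_c", "b_c", "atp_c"], ["g1"], "s1"),
                "r9": (["x_c", "y_c", "atp_c"], ["g9"], "s2"),
            },
            currency=["atp"],
        )
        prep = metnet.prepare_model(model)
        dist = metnet.pairwise_distances(prep, ["a"], ["g9"])
        assert dist["status"].iloc[0] == "Inf"
        assert np.isinf(dist["d"].iloc[0])

    def test_missing_currency_warns_only(self):
        model = make_model({"r1": (["a_c", "b_c"], ["g1"], "s")}, currency=["nothere"])
        with pytest.warns(UserWarning):
            prep = metnet.prepare_model(model)
        assert set(prep.metabolites) == {"a", "b"}

    def test_toy_model_round_trip(self, small_config):
        toy = synth.generate_toy_model(small_config)
        prep = metnet.prepare_model(toy.model)
        truth = toy.truth_model
        assert set(prep.metabolites) == set(truth.metabolites)
        truth_sets = {frozenset(r.mets) for r in truth.reactions.values()}
        prep_sets = {frozenset(r.mets) for r in prep.reactions.values()}
        assert prep_sets == truth_sets
        assert {frozenset(g) for g in prep.gene_assoc.values()} == {
            frozenset(g) for g in truth.gene_assoc.values()
        }

    def test_idempotent(self, small_config):
        toy = synth.generate_toy_model(small_config)
        once = metnet.prepare_model(toy.model)
        twice = metnet.prepare_model(once)
        assert set(twice.metabolites) == set(once.metabolites)
        assert {frozenset(r.mets) for r in twice.reactions.values()} == {
            frozenset(r.mets) for r in once.reactions.values()
        }


class TestDistances:
    def test_direct_reactant_is_zero(self):
        # fatty-acid-activation style: metabolite participates in the
        # gene's own reaction
        model = make_model({"r1": (["fa", "facoa"], ["acsl"], "lipid")})
        model.prepared = True
        dist = metnet.pairwise_distances(model, ["fa"], ["acsl"])
        assert dist["d"].iloc[0] == 0

    def test_carnitine_shuttle_two_steps(self):
        # activation -> carnitine attachment -> translocation: the
        # translocase gene sits two reaction steps from the fatty acid
        model = make_model(
            {
                "activation": (["fa", "facoa"], ["acsl"], "lipid"),
                "attach": (["facoa", "facarn"], ["cpt1a"], "transport"),
                "translocate": (["facarn", "facarn_i"], ["slc25a20"], "transport"),
            }
        )
        model.prepared = True
        dist = metnet.pairwise_distances(model, ["fa"], ["acsl", "cpt1a", "slc25a20"])
        lookup = dist.set_index("gene")["d"]
        assert lookup["acsl"] == 0
        assert lookup["cpt1a"] == 1
        assert lookup["slc25a20"] == 2

    def test_min_over_catalyzed_reactions(self):
        # gene catalyzes reactions at chain distances 1 and 4 -> d = 1
        chain = {}
        for k in range(1, 6):
            chain[f"r{k}"] = ([f"m{k-1}", f"m{k}"], [f"g{k}"], "s")
        chain["r2"] = (["m1", "m2"], ["gBoth"], "s")
        chain["r5"] = (["m4", "m5"], ["gBoth"], "s")
        model = make_model(chain)
        model.prepared = True
        dist = metnet.pairwise_distances(model, ["m0"], ["gBoth"])
        assert dist["d"].iloc[0] == 1

    def test_unmapped_is_nm(self):
        model = make_model({"r1": (["a", "b"], ["g1"], "s")})
        model.prepared = True
        dist = metnet.pairwise_distances(model, ["a", "zz"], ["g1", "gz"])
        lookup = dist.set_index(["metabolite", "gene"])
        assert lookup.loc[("zz", "g1"), "status"] == "NM"
        assert lookup.loc[("a", "gz"), "status"] == "NM"
        assert lookup.loc[("a", "g1"), "status"] == "ok"

    def test_external_ref_mapping(self):
        model = make_model({"r1": (["a", "b"], ["g1"], "s")})
        model.metabolites["a"].refs["KEGG"] = "C00123"
        model.prepared = True
        dist = metnet.pairwise_distances(model, ["C00123"], ["g1"])
        assert dist["d"].iloc[0] == 0

    def test_matches_brute_force_on_random_models(self, rng):
        for trial in range(8):
            n_mets = int(rng.integers(5, 25))
            n_rxns = int(rng.integers(4, 30))
            reactions = {}
            for r in range(n_rxns):
                size = int(rng.integers(2, 4))
                mets = rng.choice(n_mets, size=size, replace=False)
                reactions[f"r{r}"] = (
                    [f"m{m}" for m in mets],
                    [f"g{rng.integers(0, 10)}"],
                    "s",
                )
            model = make_model(reactions)
            model.prepared = True
            met_ids = [f"m{i}" for i in range(n_mets)]
            gene_ids = [f"g{i}" for i in range(10)]
            dist = metnet.pairwise_distances(model, met_ids, gene_ids)
            for row in dist.itertuples():
                expect = brute_force_distance(model, row.metabolite, row.gene)
                if expect is None:
                    assert row.status == "NM"
                elif np.isinf(expect):
                    assert row.status == "Inf"
                else:
                    assert row.d == expect, (trial, row.metabolite, row.gene)

    def test_toy_truth_distances(self, small_config):
        toy = synth.generate_toy_model(small_config)
        prep = metnet.prepare_model(toy.model)
        mets = sorted({m for m, _ in toy.truth_distances})
        genes = sorted({g for _, g in toy.truth_distances})
        dist = metnet.pairwise_distances(prep, mets, genes).set_index(["metabolite", "gene"])
        for (m, g), d in toy.truth_distances.items():
            assert dist.loc[(m, g), "d"] == d


class TestDistanceEnrichment:
    @staticmethod
    def _distances(rows):
        import pandas as pd

        return pd.DataFrame(rows, columns=["metabolite", "gene", "d", "status", "subsystems"])

    def test_fisher_hand_table(self):
        # band membership gives the 2x2 table [[4,1],[1,4]]
        rows = []
        for i in range(5):
            rows.append((f"m{i}", "gA", 0.0, "ok", ("s",)))  # in band
        for i in range(5):
            rows.append((f"m{i}", "gB", 3.0, "ok", ("s",)))  # out of band
        sig = [(f"m{i}", "gA") for i in range(4)] + [("m0", "gB")]
        report = metnet.distance_enrichment(self._distances(rows), sig)
        p0 = report["per_distance"].set_index("d").loc[0.0, "p"]
        assert p0 == pytest.approx(0.1032, abs=5e-5)
        # exact enumeration oracle
        expect = sum(
            comb(5, k, exact=True) * comb(5, 5 - k, exact=True) for k in (4, 5)
        ) / comb(10, 5, exact=True)
        assert p0 == pytest.approx(expect, rel=1e-10)

    def test_all_significant_gives_one(self):
        rows = [(f"m{i}", "g", float(i % 3), "ok", ()) for i in range(9)]
        sig = [(f"m{i}", "g") for i in range(9)]
        report = metnet.distance_enrichment(self._distances(rows), sig)
        assert (report["per_distance"]["p"] == 1.0).all()
        assert (report["cumulative"]["p"] == 1.0).all()

    def test_cumulative_at_max_distance_is_one(self):
        rows = [(f"m{i}", "g", float(i % 4), "ok", ()) for i in range(20)]
        sig = [(f"m{i}", "g") for i in range(0, 20, 3)]
        report = metnet.distance_enrichment(self._distances(rows), sig)
        assert report["cumulative"]["p"].iloc[-1] == pytest.approx(1.0)

    def test_planted_short_distance_enrichment(self, rng):
        rows = []
        sig = []
        for i in range(250):
            d = float(rng.integers(0, 6))
            rows.append((f"m{i}", "g", d, "ok", ()))
            if d <= 1 and rng.random() < 0.8:
                sig.append((f"m{i}", "g"))
            elif rng.random() < 0.05:
                sig.append((f"m{i}", "g"))
        report = metnet.distance_enrichment(self._distances(rows), sig)
        p_cum1 = report["cumulative"].set_index("d").loc[1.0, "p"]
        assert p_cum1 < 0.01

    def test_subsystem_frequencies(self):
        rows = [
            ("m1", "g1", 0.0, "ok", ("transport",)),
            ("m2", "g2", 0.0, "ok", ("transport", "lipid")),
            ("m3", "g3", 1.0, "ok", ("energy",)),
        ]
        sig = [("m1", "g1"), ("m2", "g2"), ("m3", "g3")]
        report = metnet.distance_enrichment(self._distances(rows), sig)
        assert report["subsystem_freq"][0]["transport"] == 2
        assert report["subsystem_freq"][0]["lipid"] == 1
        assert report["subsystem_freq"][1]["energy"] == 1


class TestSerialization:
    def test_json_round_trip(self, small_config, tmp_path):
        from crossomics import io

        toy = synth.generate_toy_model(small_config)
        path = tmp_path / "model.json"
        io.write_model_json(toy.model, path)
        back = io.read_model_json(path)
        assert set(back.metabolites) == set(toy.model.metabolites)
        assert {frozenset(r.mets) for r in back.reactions.values()} == {
            frozenset(r.mets) for r in toy.model.reactions.values()
        }
        assert back.currency == toy.model.currency

    def test_sbml_round_trip(self, small_config, tmp_path):
        toy = synth.generate_toy_model(small_config)
        path = tmp_path / "model.xml"
        metnet.write_sbml(toy.model, path)
        back = metnet.read_sbml(path)
        assert set(back.metabolites) == set(toy.model.metabolites)
        assert {frozenset(r.mets) for r in back.reactions.values()} == {
            frozenset(r.mets) for r in toy.model.reactions.values()
        }
        for rid, genes in toy.model.gene_assoc.items():
            assert back.gene_assoc[rid] == genes
        subsystems = {r.subsystem for r in back.reactions.values()}
        assert "subsystem0" in subsystems
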