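import json

import networkx as nx
import numpy as np
import pytest

from oracles import merge_naive
from survnet.ppi_graph import load_edge_list
from survnet.reporting import (
    PipelineConfig,
    export_network,
    merge_modules,
    modules_table,
    run_pipeline,
    subnetworks_table,
)
from survnet.search import SearchConfig, Subnetwork
from survnet.simulate import generate_dataset

from survnet.datasets import HCC_TOP5_SUBNETWORKS


def make_subnet(seed, genes, edges=(), rank=None, p=0.01):
    return Subnetwork(
        seed=seed,
        genes=tuple(genes),
        edges=frozenset(frozenset(e) for e in edges),
        p_multivariate=p,
        p_adjusted=p * 2,
        per_gene_univariate_p={},
        fit=None,
        rank=rank,
    )


class TestMergeModules:
    def test_shared_gene_merges(self):
        mods = merge_modules([{"A", "B", "C"}, {"C", "D"}])
        assert len(mods) == 1
        assert mods[0].genes == frozenset("ABCD")

    def test_disjoint_stay_separate(self):
        mods = merge_modules([{"A", "B"}, {"C", "D"}])
        assert len(mods) == 2

    def test_published_hcc_sets_form_two_modules(self):
        mods = merge_modules(HCC_TOP5_SUBNETWORKS)
        assert len(mods) == 2
        by_members = {m.members: m for m in mods}
        assert (1, 2, 4) in by_members  # chemokine/ECM branch shares FBLN2
        assert (3, 5) in by_members  # CAV1 cell-death branch

    @pytest.mark.parametrize("trial", range(20))
    def test_matches_union_find_oracle(self, trial):
        rng = np.random.default_rng(trial)
        n_sets = int(rng.integers(1, 12))
        sets = [
            set(rng.choice(30, size=rng.integers(1, 6), replace=False).tolist())
            for _ in range(n_sets)
        ]
        ours = sorted(m.genes for m in merge_modules(sets))
        theirs = sorted(frozenset(map(str, s)) for s in merge_naive(sets))
        assert [set(map(int, g)) for g in ours] == [set(map(int, g)) for g in theirs]

    def test_jaccard_threshold_is_stricter(self):
        sets = [{"A", "B", "C", "D"}, {"D", "E", "F", "G"}]
        assert len(merge_modules(sets)) == 1
        assert len(merge_modules(sets, jaccard_threshold=0.5)) == 2

    def test_accepts_subnetwork_objects(self):
        subs = [
            make_subnet("A", ["A", "B"], rank=1),
            make_subnet("B", ["B", "C"], rank=2),
        ]
        mods = merge_modules(subs)
        assert mods[0].members == (1, 2)


class TestExportNetwork:
    def test_sif_single_edge(self, tmp_path):
        s = make_subnet("A", ["A", "B"], edges=[("A", "B")], rank=1)
        out = export_network([s], tmp_path / "net.sif", format="sif")
        assert out.read_text() == "A\tpp\tB\n"

    def test_graphml_round_trip(self, tmp_path):
        s = make_subnet("A", ["A", "B", "C"], edges=[("A", "B"), ("B", "C")], rank=1)
        path = export_network([s], tmp_path / "net.graphml", format="graphml")
        g = nx.read_graphml(path)
        assert {frozenset(e) for e in g.edges()} == {
            frozenset({"A", "B"}), frozenset({"B", "C"})
        }

    def test_multi_membership_labels(self, tmp_path):
        s1 = make_subnet("A", ["A", "B"], edges=[("A", "B")], rank=1)
        s2 = make_subnet("B", ["B", "C"], edges=[("B", "C")], rank=2)
        path = export_network([s1, s2], tmp_path / "net.graphml", format="graphml")
        g = nx.read_graphml(path)
        assert g.nodes["B"]["subnetworks"] == "rank1,rank2"

    def test_unknown_format(self, tmp_path):
        with pytest.raises(ValueError):
            export_network([make_subnet("A", ["A"])], tmp_path / "x", format="dot")

    def test_empty_errors(self, tmp_path):
        with pytest.raises(ValueError):
            export_network([], tmp_path / "x.sif")


@pytest.fixture(scope="module")
def synthetic_inputs(tmp_path_factory):
    """A small synthetic cohort written to disk as pipeline inputs."""
    root = tmp_path_factory.mktemp("cohort")
    ds = generate_dataset(
        n_nodes=60, module_size=4, n_samples=80, effect_size=0.9, random_seed=13
    )
    with open(root / "network.tsv", "w") as fh:
        fh.write("#gene_a\tgene_b\n")
        for a, b in sorted(map(sorted, ds.network.edges())):
            fh.write(f"{a}\t{b}\n")
    ds.expression.to_csv(root / "expression.tsv", sep="\t")
    ds.survival.to_frame().to_csv(root / "survival.tsv", sep="\t")
    with open(root / "sets.gmt", "w") as fh:
        genes = sorted(ds.network.nodes)
        fh.write("planted\tplanted module\t" + "\t".join(sorted(ds.planted_genes)) + "\n")
        fh.write("random\trandom set\t" + "\t".join(genes[:10]) + "\n")
    return root, ds


class TestRunPipeline:
    def test_outputs_and_schema(self, synthetic_inputs, tmp_path):
        root, ds = synthetic_inputs
        cfg = PipelineConfig(
            edge_list=str(root / "network.tsv"),
            expression=str(root / "expression.tsv"),
            survival=str(root / "survival.tsv"),
            gmt=str(root / "sets.gmt"),
            outdir=str(tmp_path / "out"),
            search=SearchConfig(alpha_adjusted=0.05),
        )
        summary = run_pipeline(cfg)
        out = tmp_path / "out"
        for name in (
            "subnetworks.tsv",
            "univariate.tsv",
            "modules.tsv",
            "enrichment.tsv",
            "run_log.json",
        ):
            assert (out / name).exists(), name
        header = (out / "subnetworks.tsv").read_text().splitlines()[0].split("\t")
        assert header == [
            "rank", "seed", "genes", "n_genes", "n_edges",
            "p_multivariate", "p_adjusted", "univariate_p",
        ]
        log = json.loads((out / "run_log.json").read_text())
        assert log["summary"]["n_subnetworks"] == summary["n_subnetworks"]

    def test_rerun_byte_identical(self, synthetic_inputs, tmp_path):
        root, _ = synthetic_inputs
        texts = []
        for tag in ("a", "b"):
            cfg = PipelineConfig(
                edge_list=str(root / "network.tsv"),
                expression=str(root / "expression.tsv"),
                survival=str(root / "survival.tsv"),
                outdir=str(tmp_path / tag),
                search=SearchConfig(alpha_adjusted=0.05, random_seed=1),
            )
            run_pipeline(cfg)
            texts.append((tmp_path / tag / "subnetworks.tsv").read_bytes())
        assert texts[0] == texts[1]

    def test_missing_input_named(self, synthetic_inputs, tmp_path):
        root, _ = synthetic_inputs
        cfg = PipelineConfig(
            edge_list=str(root / "nope.tsv"),
            expression=str(root / "expression.tsv"),
            survival=str(root / "survival.tsv"),
            outdir=str(tmp_path / "out"),
        )
        with pytest.raises(FileNotFoundError, match="nope.tsv"):
            run_pipeline(cfg)

    def test_stage_name_in_errors(self, synthetic_inputs, tmp_path):
        root, _ = synthetic_inputs
        bad = tmp_path / "bad_survival.tsv"
        bad.write_text("sample_id\ttime_months\tevent\nS1\t-4\t1\n")
        cfg = PipelineConfig(
            edge_list=str(root / "network.tsv"),
            expression=str(root / "expression.tsv"),
            survival=str(bad),
            outdir=str(tmp_path / "out"),
        )
        with pytest.raises(RuntimeError, match="stage 'load'"):
            run_pipeline(cfg)


class TestTables:
    def test_subnetworks_table_roundtrips_ranks(self):
        subs = [make_subnet("A", ["A", "B"], edges=[("A", "B")], rank=1)]
        table = subnetworks_table(subs)
        assert table.loc[0, "rank"] == 1
        assert table.loc[0, "genes"] == "A,B"
        assert table.loc[0, "n_edges"] == 1

    def test_modules_table(self):
        mods = merge_modules([{"A", "B"}, {"B", "C"}, {"X"}])
        table = modules_table(mods)
        assert list(table["module"]) == [1, 2]
        assert set(table.loc[0, "genes"].split(",")) == {"A", "B", "C"}
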