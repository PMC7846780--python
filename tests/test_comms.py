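import itertools
import logging

import numpy as np
import pandas as pd
import pytest

import cardiocomm as cc
from cardiocomm.comms import (
    build_network,
    expression_fractions,
    receptor_expression_bubble,
    screen_source_ligands,
)


def fractions_frame(table: dict) -> pd.DataFrame:
    """{gene: {type: fraction}} -> long-format fraction table."""
    rows = [
        {"gene": g, "cell_type": t, "fraction": f}
        for g, per_type in table.items()
        for t, f in per_type.items()
    ]
    return pd.DataFrame(rows)


TYPES = ["CM", "FB", "MP", "NP", "EC"]


@pytest.fixture
def toy_fractions():
    rng = np.random.default_rng(3)
    genes = [f"L{i}" for i in range(4)] + [f"R{i}" for i in range(4)]
    return fractions_frame(
        {g: {t: float(rng.uniform()) for t in TYPES} for g in genes}
    )


@pytest.fixture
def toy_pairs():
    return cc.LRPairTable(
        pd.DataFrame(
            [(f"L{i}", f"R{j}") for i in range(4) for j in range(4) if (i + j) % 2 == 0],
            columns=["ligand", "receptor"],
        )
    )


class TestExpressionFractions:
    def test_simple_fraction(self):
        df = pd.DataFrame({"c1": [0.0], "c2": [2.0], "c3": [5.0]}, index=["g"])
        annot = cc.CellAnnotation(
            pd.DataFrame(
                {"condition": ["1dpIR"] * 3, "cell_type": ["FB"] * 3},
                index=["c1", "c2", "c3"],
            )
        )
        frac = expression_fractions(df, annot, presence_count=1)
        assert frac.iloc[0]["fraction"] == pytest.approx(2 / 3)

    def test_all_zero_gene_has_zero_fraction_everywhere(self):
        df = pd.DataFrame(
            np.vstack([np.zeros(4), np.ones(4)]),
            index=["dead", "alive"],
            columns=["c1", "c2", "c3", "c4"],
        )
        annot = cc.CellAnnotation(
            pd.DataFrame(
                {"condition": ["1dpIR"] * 4, "cell_type": ["CM", "CM", "FB", "FB"]},
                index=df.columns,
            )
        )
        frac = expression_fractions(df, annot).set_index(["gene", "cell_type"])
        assert (frac.loc["dead"]["fraction"] == 0).all()
        assert (frac.loc["alive"]["fraction"] == 1).all()

    def test_missing_cell_type_rejected(self):
        df = pd.DataFrame({"c1": [1.0]}, index=["g"])
        annot = cc.CellAnnotation(pd.DataFrame({"condition": ["1dpIR"]}, index=["c1"]))
        with pytest.raises(cc.ContractError):
            expression_fractions(df, annot)

    def test_planted_detection_probabilities_recovered(self):
        """Empirical expressing fractions must sit inside a binomial CI
        of the per-type detection probability implied by the programs."""
        sim = cc.default_config(seed=5)
        matrix, annot, truth = cc.simulate_dataset(sim)
        frac = expression_fractions(matrix.values, annot, presence_count=1).set_index(
            ["gene", "cell_type"]
        )
        # receptor RecFB1 planted at mean 8 in FB: detection prob is
        # 1 - P(NB(r=4, mu=8*lib/total) = 0), averaged over library sizes
        fb_cells = annot.table.index[annot.table.cell_type == "FB"]
        f = float(frac.loc[("RecFB1", "FB"), "fraction"])
        n = len(fb_cells)
        assert f > 0.8  # mean ~8 molecules: nearly always detected
        se = np.sqrt(f * (1 - f) / n)
        # and absent types never express it
        assert float(frac.loc[("RecFB1", "CM"), "fraction"]) < 0.05


class TestBuildNetwork:
    def test_no_gene_reaches_tau_gives_empty_network(self, toy_pairs):
        frac = fractions_frame({g: {t: 0.05 for t in TYPES} for g in ["L0", "R0"]})
        net = build_network(frac, toy_pairs, tau=0.2)
        assert net.n_edges == 0 and net.total_couples == 0

    def test_single_autocrine_loop(self):
        pairs = cc.LRPairTable(pd.DataFrame([("L", "R")], columns=["ligand", "receptor"]))
        frac = fractions_frame({"L": {"CM": 0.5, "FB": 0.1}, "R": {"CM": 0.9, "FB": 0.1}})
        net = build_network(frac, pairs, tau=0.2)
        assert net.edges == {("CM", "CM"): {("L", "R")}}
        assert net.couple_counts()["n_couples"].tolist() == [1]

    def test_matches_exhaustive_enumeration(self, toy_fractions, toy_pairs):
        tau = 0.4
        net = build_network(toy_fractions, toy_pairs, tau=tau)
        lut = toy_fractions.pivot(index="gene", columns="cell_type", values="fraction")
        expected = {}
        for (lig, rec), (s, t) in itertools.product(
            toy_pairs.as_tuples(), itertools.product(TYPES, TYPES)
        ):
            if lut.at[lig, s] >= tau and lut.at[rec, t] >= tau:
                expected.setdefault((s, t), set()).add((lig, rec))
        assert net.edges == expected

    def test_monotone_in_tau(self, toy_fractions, toy_pairs):
        taus = [0.1, 0.3, 0.5, 0.7, 0.9]
        nets = [build_network(toy_fractions, toy_pairs, tau=t) for t in taus]
        for lo, hi in zip(nets, nets[1:]):
            for edge, couples in hi.edges.items():
                assert couples <= lo.edges.get(edge, set())

    def test_total_couples_identity(self, toy_fractions, toy_pairs):
        tau = 0.35
        net = build_network(toy_fractions, toy_pairs, tau=tau)
        lut = toy_fractions.pivot(index="gene", columns="cell_type", values="fraction")
        expected_total = sum(
            int((lut.loc[lig] >= tau).sum()) * int((lut.loc[rec] >= tau).sum())
            for lig, rec in toy_pairs.as_tuples()
        )
        assert net.total_couples == expected_total

    def test_absent_pair_gene_skipped_with_log(self, toy_fractions, caplog):
        pairs = cc.LRPairTable(
            pd.DataFrame([("Ghost", "R0")], columns=["ligand", "receptor"])
        )
        with caplog.at_level(logging.INFO, logger="cardiocomm.comms"):
            net = build_network(toy_fractions, pairs, tau=0.2)
        assert net.n_edges == 0
        assert "skipped" in caplog.text

    def test_noiseless_fractions_recover_planted_network(self):
        """With 0/1 fractions derived from the planted programs, the
        recovered network is exactly the planted edge set."""
        sim = cc.default_config(seed=0)
        genes = {p.ligand for p in sim.planted_lr} | {p.receptor for p in sim.planted_lr}
        prog = {t.name: t.program for t in sim.cell_types}
        table = {
            g: {t: 1.0 if prog[t][sim.gene_index(g)] > 0 else 0.0 for t in prog}
            for g in genes
        }
        net = build_network(fractions_frame(table), sim.lr_table(), tau=0.2)
        planted = {}
        for p in sim.planted_lr:
            for s in prog:
                for t in prog:
                    if table[p.ligand][s] and table[p.receptor][t]:
                        planted.setdefault((s, t), set()).add((p.ligand, p.receptor))
        assert net.edges == planted


@pytest.fixture
def screen_inputs():
    """Hand-built funnel scenario: four up-regulated ligands, one decoy,
    one ECM ligand, one enriched elsewhere."""
    fractions = fractions_frame(
        {
            "LigA": {"CM": 0.6, "FB": 0.1, "MP": 0.0},
            "LigB": {"CM": 0.5, "FB": 0.2, "MP": 0.1},
            "LigEcm": {"CM": 0.8, "FB": 0.3, "MP": 0.0},
            "LigShared": {"CM": 0.3, "FB": 0.9, "MP": 0.1},  # 3x fraction in FB
            "LigDecoy": {"CM": 0.7, "FB": 0.0, "MP": 0.0},
            "RecA": {"CM": 0.0, "FB": 0.9, "MP": 0.1},
            "RecB": {"CM": 0.1, "FB": 0.1, "MP": 0.8},
            "RecC": {"CM": 0.4, "FB": 0.4, "MP": 0.4},
        }
    )
    pairs = cc.LRPairTable(
        pd.DataFrame(
            [
                ("LigA", "RecA"),
                ("LigB", "RecB"),
                ("LigB", "RecC"),
                ("LigEcm", "RecC"),
                ("LigShared", "RecA"),
                ("LigDecoy", "RecA"),
                ("LigMissing", "RecA"),
            ],
            columns=["ligand", "receptor"],
        )
    )
    fold = pd.DataFrame(
        {
            "gene": ["LigA", "LigB", "LigEcm", "LigShared", "LigDecoy"],
            "fold_change": [5.0, 3.5, 4.0, 6.0, 1.2],
        }
    )
    net = build_network(fractions, pairs, tau=0.2)
    cfg = cc.RunConfig(seed=0, ecm_genes=("LigEcm",))
    return net, fold, fractions, cfg


class TestLigandScreen:
    def test_funnel_stages(self, screen_inputs, caplog):
        net, fold, fractions, cfg = screen_inputs
        with caplog.at_level(logging.INFO, logger="cardiocomm.comms"):
            res = screen_source_ligands(net, fold, fractions, cfg, source_type="CM")
        # stage 1-2: decoy fails the 3-fold cut, LigMissing absent from matrix
        assert res.ligands_after_fold == ["LigA", "LigB", "LigEcm", "LigShared"]
        assert set(res.combinations) == {
            ("LigA", "RecA"), ("LigB", "RecB"), ("LigB", "RecC"),
            ("LigEcm", "RecC"), ("LigShared", "RecA"),
        }
        # stage 3 exclusions with reasons
        rec = res.records.set_index("ligand")
        assert rec.loc["LigEcm", "exclusion_reason"] == "ECM"
        assert "enriched elsewhere" in rec.loc["LigShared", "exclusion_reason"]
        assert res.ligands_final == ["LigA", "LigB"]
        # funnel counts never increase along the stages
        assert res.n_final <= res.n_unique_ligands <= res.n_combinations

    def test_infinite_threshold_empties_the_screen(self, screen_inputs):
        net, fold, fractions, cfg = screen_inputs
        cfg_inf = cc.RunConfig(seed=0, fold_threshold=float("inf"))
        res = screen_source_ligands(net, fold, fractions, cfg_inf, source_type="CM")
        assert res.n_combinations == 0 and res.n_unique_ligands == 0 and res.n_final == 0

    def test_missing_fold_change_dropped_with_reason(self, screen_inputs):
        net, fold, fractions, cfg = screen_inputs
        res = screen_source_ligands(
            net, fold[fold.gene != "LigA"], fractions, cfg, source_type="CM"
        )
        rec = res.records.set_index("ligand")
        assert rec.loc["LigA", "exclusion_reason"] == "no fold-change entry"
        assert "LigA" not in res.ligands_after_fold

    def test_unknown_source_type_rejected(self, screen_inputs):
        net, fold, fractions, cfg = screen_inputs
        with pytest.raises(cc.ContractError):
            screen_source_ligands(net, fold, fractions, cfg, source_type="NP")


class TestReceptorBubble:
    def test_projection_of_fraction_table(self, screen_inputs):
        net, fold, fractions, cfg = screen_inputs
        pairs = cc.LRPairTable(
            pd.DataFrame([("LigA", "RecA")], columns=["ligand", "receptor"])
        )
        bubble = receptor_expression_bubble(fractions, ["LigA"], pairs)
        lut = fractions.pivot(index="gene", columns="cell_type", values="fraction")
        assert len(bubble) == 3  # one row per cell type
        for _, row in bubble.iterrows():
            assert row["fraction"] == lut.at[row["receptor"], row["cell_type"]]

    def test_ligand_without_receptor_yields_no_rows(self, screen_inputs, caplog):
        _, _, fractions, _ = screen_inputs
        pairs = cc.LRPairTable(
            pd.DataFrame([("Other", "RecA")], columns=["ligand", "receptor"])
        )
        with caplog.at_level(logging.INFO, logger="cardiocomm.comms"):
            bubble = receptor_expression_bubble(fractions, ["LigA"], pairs)
        assert bubble.empty
        assert "no receptor" in caplog.text
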