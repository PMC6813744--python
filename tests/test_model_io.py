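import json

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import linprog

from toxpipe import model_io
from toxpipe.model_io import (
    GeneSetCollection,
    ModelIOError,
    parse_gpr,
    read_expression_study,
    read_gmt,
    read_metabolic_model,
    read_orthologs,
    read_tf_targets,
    write_expression_study,
    write_gmt,
    write_metabolic_model,
    write_orthologs,
    write_tf_targets,
)


class TestExpressionStudy:
    def test_round_trip(self, tiny_expression, tmp_path):
        m, d = tmp_path / "m.tsv", tmp_path / "d.tsv"
        write_expression_study(tiny_expression, m, d)
        back = read_expression_study(m, d)
        pd.testing.assert_frame_equal(back.values, tiny_expression.values)
        assert back.values.shape == (3, 4)
        assert list(back.metadata.columns) == list(tiny_expression.metadata.columns)

    def test_sample_missing_from_metadata_is_named(self, tiny_expression, tmp_path):
        m, d = tmp_path / "m.tsv", tmp_path / "d.tsv"
        write_expression_study(tiny_expression, m, d)
        meta = pd.read_csv(d, sep="\t")
        meta.loc[meta.sample_id == "t2", "sample_id"] = "s9"
        meta.to_csv(d, sep="\t", index=False)
        with pytest.raises(ModelIOError, match="t2"):
            read_expression_study(m, d)

    def test_non_numeric_cell_rejected(self, tiny_expression, tmp_path):
        m, d = tmp_path / "m.tsv", tmp_path / "d.tsv"
        write_expression_study(tiny_expression, m, d)
        text = m.read_text().replace("5.0", "oops")
        m.write_text(text)
        with pytest.raises(ModelIOError, match="non-numeric"):
            read_expression_study(m, d)

    def test_duplicate_gene_ids_rejected(self, tiny_expression, tmp_path):
        m, d = tmp_path / "m.tsv", tmp_path / "d.tsv"
        write_expression_study(tiny_expression, m, d)
        lines = m.read_text().splitlines()
        lines.append(lines[1])  # repeat first gene row
        m.write_text("\n".join(lines) + "\n")
        with pytest.raises(ModelIOError, match="duplicate gene"):
            read_expression_study(m, d)


class TestGMT:
    def test_line_parsing_and_round_trip(self, tmp_path):
        p = tmp_path / "x.gmt"
        p.write_text("P1\tdesc\tg1\tg2\nP2\tother\tg3\tg4\tg5\n")
        coll = read_gmt(p)
        assert coll.sets["P1"] == ["g1", "g2"]
        assert len(coll.sets["P2"]) == 3
        q = tmp_path / "y.gmt"
        write_gmt(coll, q)
        assert read_gmt(q).sets == coll.sets

    def test_duplicate_set_id_rejected(self, tmp_path):
        p = tmp_path / "x.gmt"
        p.write_text("P1\td\tg1\tg2\nP1\td\tg3\n")
        with pytest.raises(ModelIOError, match="duplicate set ID"):
            read_gmt(p)

    @pytest.mark.parametrize("line", ["P1\tonly_two_fields", "P1\tdesc\t"])
    def test_short_or_empty_lines_rejected(self, tmp_path, line):
        p = tmp_path / "x.gmt"
        p.write_text(line + "\n")
        with pytest.raises(ModelIOError):
            read_gmt(p)

    def test_empty_set_rejected_at_construction(self):
        with pytest.raises(ModelIOError, match="empty"):
            GeneSetCollection(sets={"P1": []})


class TestTFAndOrthologTables:
    def test_tf_round_trip_dedup(self, tmp_path):
        p = tmp_path / "tf.tsv"
        df = pd.DataFrame(
            {"tf": ["T1", "T1", "T1"], "target": ["g1", "g2", "g1"],
             "mode": ["activation", "repression", "activation"]})
        write_tf_targets(df, p)
        back = read_tf_targets(p)
        assert len(back) == 2  # duplicate (tf, target) dropped
        assert set(back["target"]) == {"g1", "g2"}

    def test_ortholog_one_to_many_preserved(self, tmp_path):
        p = tmp_path / "o.tsv"
        df = pd.DataFrame({"human_gene": ["h1", "h1", "h2", "h2"],
                           "rat_gene": ["r1", "r2", "r3", "r3"]})
        write_orthologs(df, p)
        back = read_orthologs(p)
        assert len(back) == 3  # exact duplicate dropped, 1-to-many kept
        assert set(back[back.human_gene == "h1"]["rat_gene"]) == {"r1", "r2"}


class TestGPRParsing:
    @pytest.mark.parametrize("rule,genes", [
        ("g1", {"g1"}),
        ("g1 and g2", {"g1", "g2"}),
        ("g1 AND (g2 OR g3)", {"g1", "g2", "g3"}),
        ("(g1 or g2) and (g3 or g4)", {"g1", "g2", "g3", "g4"}),
    ])
    def test_valid_rules(self, rule, genes):
        tree = parse_gpr(rule)
        assert tree.genes() == genes

    @pytest.mark.parametrize("rule", [
        "g1 AND (g2 OR", "and g1", "g1 or", "(g1", "g1 g2", "g1 )("])
    def test_malformed_rules_rejected(self, rule):
        with pytest.raises(ModelIOError):
            parse_gpr(rule)

    def test_empty_rule_is_none(self):
        assert parse_gpr("") is None
        assert parse_gpr("   ") is None


class TestMetabolicModel:
    def _toy_doc(self):
        return {
            "metabolites": [
                {"id": "A", "name": "A", "exchangeable": False},
                {"id": "B", "name": "B", "exchangeable": True},
            ],
            "reactions": [
                {"id": "EX_A", "name": "up", "lb": -10, "ub": 0, "gpr": "",
                 "stoich": {"A": -1}},
                {"id": "R1", "name": "conv", "lb": 0, "ub": 1000,
                 "gpr": "g1 and g2", "stoich": {"A": -1, "B": 1}},
                {"id": "EX_B", "name": "out", "lb": 0, "ub": 1000, "gpr": "",
                 "stoich": {"B": -1}},
            ],
        }

    def test_load_flags_exchanges(self, tmp_path):
        p = tmp_path / "m.json"
        p.write_text(json.dumps(self._toy_doc()))
        model = read_metabolic_model(p)
        assert set(model.exchange_reactions) == {"EX_A", "EX_B"}
        assert model.reaction("R1").gpr_tree is not None

    def test_round_trip(self, tmp_path):
        p, q = tmp_path / "m.json", tmp_path / "m2.json"
        p.write_text(json.dumps(self._toy_doc()))
        model = read_metabolic_model(p)
        write_metabolic_model(model, q)
        back = read_metabolic_model(q)
        assert np.array_equal(back.stoichiometric_matrix(),
                              model.stoichiometric_matrix())
        assert [r.id for r in back.reactions] == [r.id for r in model.reactions]

    def test_unparseable_gpr_names_reaction(self, tmp_path):
        doc = self._toy_doc()
        doc["reactions"][1]["gpr"] = "g1 AND (g2 OR"
        p = tmp_path / "m.json"
        p.write_text(json.dumps(doc))
        with pytest.raises(ModelIOError, match="R1"):
            read_metabolic_model(p)

    def test_bounds_violation_rejected(self, tmp_path):
        doc = self._toy_doc()
        doc["reactions"][1]["lb"] = 5
        doc["reactions"][1]["ub"] = -5
        p = tmp_path / "m.json"
        p.write_text(json.dumps(doc))
        with pytest.raises(ModelIOError, match="lb"):
            read_metabolic_model(p)

    def test_mass_balance_has_nonzero_feasible_flux(self, tmp_path):
        """S v = 0 admits a nonzero flux (uptake -> convert -> secrete)."""
        p = tmp_path / "m.json"
        p.write_text(json.dumps(self._toy_doc()))
        model = read_metabolic_model(p)
        S = model.stoichiometric_matrix()
        lb, ub = model.bounds()
        j = [r.id for r in model.reactions].index("EX_B")
        c = np.zeros(len(model.reactions))
        c[j] = -1.0
        res = linprog(c, A_eq=S, b_eq=np.zeros(S.shape[0]),
                      bounds=list(zip(lb, ub)), method="highs")
        assert res.success
        v = res.x
        assert np.allclose(S @ v, 0, atol=1e-9)
        assert np.abs(v).max() > 1e-6


class TestConfig:
    def test_defaults_carry_pipeline_thresholds(self):
        cfg = model_io.load_config()
        assert cfg["deg"]["pfp_cutoff"] == 0.05
        assert cfg["prep"]["fc_cutoff"] == 0.6
        assert cfg["timbr"]["call_cutoff"] == 0.1
        assert cfg["overlap"]["frequency_threshold"] == 0.05
        assert cfg["enrich"]["min_hits"] == 3

    def test_unknown_key_rejected(self, tmp_path):
        p = tmp_path / "c.yaml"
        p.write_text("deg:\n  n_permutatoins: 10\n")
        with pytest.raises(ModelIOError, match="n_permutatoins"):
            model_io.load_config(p)

    def test_override_merges(self, tmp_path):
        p = tmp_path / "c.yaml"
        p.write_text("seed: 42\ndeg:\n  n_permutations: 17\n")
        cfg = model_io.load_config(p)
        assert cfg["seed"] == 42
        assert cfg["deg"]["n_permutations"] == 17
        assert cfg["deg"]["pfp_cutoff"] == 0.05
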