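from itertools import chain, combinations

import numpy as np
import pandas as pd
import pytest

from conftest import ast_kos, eval_module_ast, random_module_ast, render_module_ast
from fbmeta.kegg_modules import (
    And,
    Complex,
    DefinitionParseError,
    Leaf,
    NITROGENASE_KOS,
    Optional_,
    Or,
    Wildcard,
    evaluate,
    expression_kos,
    nitrogenase_screen,
    parse_definition,
    required_kos,
    screen_modules,
    serialize,
)
from fbmeta.synthetic_data import load_default_modules


def subsets(items):
    items = sorted(items)
    return chain.from_iterable(combinations(items, r) for r in range(len(items) + 1))


class TestParse:
    def test_two_step_chain(self):
        assert parse_definition("K00001 K00002") == And((Leaf("K00001"), Leaf("K00002")))

    def test_nitrogenase_complex(self):
        # matches the packaged nitrogen-fixation definition's core complex
        expr = parse_definition("K02588+K02586+K02591")
        assert expr == Complex((Leaf("K02588"), Leaf("K02586"), Leaf("K02591")))
        packaged = {m.module_id: m.definition for m in load_default_modules()}
        assert packaged["M00175"].startswith("K02588+K02586+K02591")

    def test_mixed_operators(self):
        expr = parse_definition("(K00001,K00002) K00003 -K00004")
        assert expr == And(
            (
                Or((Leaf("K00001"), Leaf("K00002"))),
                Leaf("K00003"),
                Optional_(Leaf("K00004")),
            )
        )

    def test_optional_inside_complex(self):
        expr = parse_definition("K00001+K00002-K00003")
        assert expr == Complex(
            (Leaf("K00001"), Leaf("K00002"), Optional_(Leaf("K00003")))
        )

    def test_wildcard(self):
        assert parse_definition("K00001 --") == And((Leaf("K00001"), Wildcard()))

    def test_plus_binds_tighter_than_comma(self):
        expr = parse_definition("K00001+K00002,K00003")
        assert expr == Or((Complex((Leaf("K00001"), Leaf("K00002"))), Leaf("K00003")))

    def test_comma_binds_tighter_than_space_in_group(self):
        expr = parse_definition("K00001,K00002 K00003")
        assert expr == And((Or((Leaf("K00001"), Leaf("K00002"))), Leaf("K00003")))

    def test_unbalanced_parentheses(self):
        with pytest.raises(DefinitionParseError, match="position"):
            parse_definition("(K00001 K00002")
        with pytest.raises(DefinitionParseError):
            parse_definition("K00001)")

    def test_illegal_token_with_position(self):
        with pytest.raises(DefinitionParseError, match="position 7"):
            parse_definition("K00001 M00002")

    def test_parse_serialize_parse_fixed_point_random(self):
        rng = np.random.default_rng(9)
        for _ in range(300):
            ast, _pool = random_module_ast(rng)
            definition = render_module_ast(ast)
            expr = parse_definition(definition)
            canonical = serialize(expr)
            assert parse_definition(canonical) == expr
            assert serialize(parse_definition(canonical)) == canonical

    def test_packaged_modules_all_parse(self):
        for record in load_default_modules():
            expr = parse_definition(record.definition)
            assert parse_definition(serialize(expr)) == expr


class TestEvaluate:
    def test_all_leaves_present(self):
        res = evaluate(parse_definition("K00001 K00002"), {"K00001", "K00002"})
        assert res.complete and res.satisfied_fraction == 1.0 and res.missing_kos == ()

    def test_nitrogenase_empty_presence(self):
        res = evaluate(parse_definition("K02588+K02586+K02591"), set())
        assert not res.complete
        assert res.satisfied_fraction == 0.0
        assert set(res.missing_kos) == set(NITROGENASE_KOS)

    def test_or_alternative_suffices(self):
        expr = parse_definition("(K00001,K00002) K00003")
        # oracle: full truth table over all 2^3 subsets
        for subset in subsets({"K00001", "K00002", "K00003"}):
            present = set(subset)
            expected = ("K00001" in present or "K00002" in present) and "K00003" in present
            assert evaluate(expr, present).complete == expected

    def test_optional_never_blocks(self):
        expr = parse_definition("K00001 -K00002")
        res = evaluate(expr, {"K00001"})
        assert res.complete and res.satisfied_fraction == 1.0

    def test_fraction_excludes_optional_steps(self):
        expr = parse_definition("K00001 K00002 -K00003")
        res = evaluate(expr, {"K00001"})
        assert res.satisfied_fraction == pytest.approx(0.5)

    def test_wildcard_semantics_flag(self):
        expr = parse_definition("K00001 --")
        assert evaluate(expr, {"K00001"}, wildcard_satisfied=True).complete
        res = evaluate(expr, {"K00001"}, wildcard_satisfied=False)
        assert not res.complete and not res.feasible

    def test_missing_kos_minimal_and_lexicographic(self):
        expr = parse_definition("(K00011+K00012,K00003) (K00004,K00005)")
        res = evaluate(expr, set())
        # cheapest: single-KO branch K00003; tie K00004/K00005 -> lexicographic
        assert res.missing_kos == ("K00003", "K00004")

    def test_complete_iff_fraction_one(self):
        rng = np.random.default_rng(17)
        for _ in range(200):
            ast, pool = random_module_ast(rng)
            expr = parse_definition(render_module_ast(ast))
            present = {k for k in pool if rng.random() < 0.5}
            res = evaluate(expr, present)
            assert res.complete == (res.satisfied_fraction == 1.0)
            assert res.complete == (res.missing_kos == ())

    def test_monotone_in_presence(self):
        rng = np.random.default_rng(23)
        for _ in range(200):
            ast, pool = random_module_ast(rng)
            expr = parse_definition(render_module_ast(ast))
            present = {k for k in pool if rng.random() < 0.4}
            extra = present | {k for k in pool if rng.random() < 0.4}
            lo = evaluate(expr, present)
            hi = evaluate(expr, extra)
            assert hi.satisfied_fraction >= lo.satisfied_fraction
            if lo.complete:
                assert hi.complete

    def test_completion_with_missing_kos_completes(self):
        rng = np.random.default_rng(31)
        for _ in range(200):
            ast, pool = random_module_ast(rng)
            expr = parse_definition(render_module_ast(ast))
            present = {k for k in pool if rng.random() < 0.3}
            res = evaluate(expr, present)
            if res.feasible:
                assert evaluate(expr, present | set(res.missing_kos)).complete

    def test_required_kos_satisfy(self):
        expr = parse_definition("(K00001,K00002+K00003) K00004")
        kos = required_kos(expr)
        assert evaluate(expr, kos).complete
        assert kos == {"K00001", "K00004"}

    def test_expression_kos(self):
        expr = parse_definition("(K00001,K00002) -K00003 --")
        assert expression_kos(expr) == {"K00001", "K00002", "K00003"}


class TestScreenModules:
    def test_planted_family_complete(self, small_bundle, small_tpm):
        mg, _ = small_tpm
        table = screen_modules(
            load_default_modules(),
            mg,
            small_bundle.annotations(),
            small_bundle.lineages(),
            groups=small_bundle.truth.labels,
        )
        rotten = table[table.group == "rotten"]
        burk = rotten[(rotten.scope == "Burkholderiaceae") & (rotten.module_id == "M00530")]
        assert bool(burk.complete.iloc[0])
        community = rotten[(rotten.scope == "community") & (rotten.module_id == "M00530")]
        assert bool(community.complete.iloc[0])

    def test_split_module_community_only(self, small_bundle, small_tpm):
        # denitrification KOs are planted across two families
        mg, _ = small_tpm
        table = screen_modules(
            load_default_modules(),
            mg,
            small_bundle.annotations(),
            small_bundle.lineages(),
            groups=small_bundle.truth.labels,
        )
        rotten = table[(table.group == "rotten") & (table.module_id == "M00529")]
        assert bool(rotten[rotten.scope == "community"].complete.iloc[0])
        per_family = rotten[rotten.scope != "community"]
        assert len(per_family) > 0 and not per_family.complete.any()

    def test_rare_family_not_screened(self, small_bundle, small_tpm):
        mg, _ = small_tpm
        table = screen_modules(
            load_default_modules(),
            mg,
            small_bundle.annotations(),
            small_bundle.lineages(),
            groups=small_bundle.truth.labels,
            min_family_share=0.999,  # nothing can exceed this
        )
        assert set(table.scope) == {"community"}

    def test_restricted_to_bacterial_genes(self, small_bundle, small_tpm):
        mg, _ = small_tpm
        lineages = small_bundle.lineages()
        annotations = small_bundle.annotations()
        table = screen_modules(
            load_default_modules(), mg, annotations, lineages, per_family=True
        )
        scopes = set(table.scope) - {"community"}
        for scope in scopes:
            # every screened family must be bacterial
            assert any(
                lin.family == scope and lin.superkingdom == "Bacteria"
                for lin in lineages.values()
            )


class TestNitrogenaseScreen:
    def test_blacklisted_by_default(self, small_bundle, small_tpm):
        mg, mt = small_tpm
        table = nitrogenase_screen(
            small_bundle.annotations(), {"metagenome": mg, "metatranscriptome": mt}
        )
        assert set(table.ko) == set(NITROGENASE_KOS)
        assert not table.present.any()

    def test_direct_lookup_single_layer(self):
        tpm = pd.DataFrame(
            [[5.0, 0.0], [0.0, 3.0]], index=["s1", "s2"], columns=["g1", "g2"]
        )
        table = nitrogenase_screen({"g1": "K02586"}, {"metagenome": tpm})
        by = table.set_index(["sample", "ko"]).present
        assert bool(by[("s1", "K02586")])
        assert not bool(by[("s2", "K02586")])
        assert not bool(by[("s1", "K02588")])
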