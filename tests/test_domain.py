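import json

import numpy as np
import pytest
from hypothesis import given, strategies as st

from bcfkit.chemdata import CompoundRecord, DataError, Dataset, parse_structure
from bcfkit.classify import make_result
from bcfkit.domain import (
    ApplicabilityDomain,
    DescriptorScaling,
    FragmentRule,
    NeighborHit,
    PatternError,
    check_ranges,
    compute_descriptors,
    count_fragment,
    domain_verdict,
    find_neighbors,
    learn_ranges,
    load_rules,
    match_rule,
    render_result_sheet,
    result_sheet_json,
    screen_rules,
    similarity_index,
)

# ---------------------------------------------------------------------------
# Brute-force oracles, independent of the SMARTS matcher
# ---------------------------------------------------------------------------


def chlorine_atom_count(structure):
    """Oracle for "[Cl]": scan atoms for atomic number 17."""
    return sum(1 for a in structure.mol.GetAtoms() if a.GetAtomicNum() == 17)


def oxygen_aromatic_bond_count(structure):
    """Oracle for "O[a]": enumerate O-aromatic bonds, count unique atom pairs."""
    pairs = set()
    for bond in structure.mol.GetBonds():
        a, b = bond.GetBeginAtom(), bond.GetEndAtom()
        for o, ar in ((a, b), (b, a)):
            if o.GetAtomicNum() == 8 and ar.GetIsAromatic():
                pairs.add(frozenset((o.GetIdx(), ar.GetIdx())))
    return len(pairs)


def halogen_on_aromatic_count(structure):
    """Oracle for "[Cl,Br]a": Cl/Br atoms bonded to an aromatic atom."""
    pairs = set()
    for bond in structure.mol.GetBonds():
        a, b = bond.GetBeginAtom(), bond.GetEndAtom()
        for hal, ar in ((a, b), (b, a)):
            if hal.GetAtomicNum() in (17, 35) and ar.GetIsAromatic():
                pairs.add(frozenset((hal.GetIdx(), ar.GetIdx())))
    return len(pairs)


class TestCountFragment:
    def test_matches_hand_verified_fixture_counts(self, parsed_fixtures):
        for name, (structure, expected) in parsed_fixtures.items():
            for smarts, count in expected.items():
                assert count_fragment(structure, smarts) == count, (name, smarts)

    def test_matches_brute_force_oracles_on_all_fixtures(self, parsed_fixtures):
        oracles = {
            "[Cl]": chlorine_atom_count,
            "O[a]": oxygen_aromatic_bond_count,
            "[Cl,Br]a": halogen_on_aromatic_count,
        }
        for name, (structure, _) in parsed_fixtures.items():
            for smarts, oracle in oracles.items():
                assert count_fragment(structure, smarts) == oracle(structure), (
                    name,
                    smarts,
                )

    def test_hexachlorobenzene_chlorines(self, parsed_fixtures):
        structure, _ = parsed_fixtures["hexachlorobenzene"]
        assert count_fragment(structure, "[Cl]") == 6

    def test_trichlorophenol_single_aromatic_oxygen(self, parsed_fixtures):
        structure, _ = parsed_fixtures["246-trichlorophenol"]
        assert count_fragment(structure, "O[a]") == 1

    def test_symmetric_pattern_counts_atom_sets_not_embeddings(self):
        # C-C in ethane: one bond, even though two embeddings exist
        assert count_fragment(parse_structure("CC"), "CC") == 1

    def test_invalid_smarts_fails_at_load(self):
        with pytest.raises(PatternError):
            count_fragment(parse_structure("CC"), "[Qq")


class TestMatchRule:
    def test_chlorine_count_rule(self, parsed_fixtures):
        rule_a = FragmentRule(rule_id="A", smarts_list=["[Cl]"], min_counts=[6])
        assert match_rule(parsed_fixtures["hexachlorobenzene"][0], rule_a)
        assert not match_rule(parsed_fixtures["pentachlorophenol"][0], rule_a)

    def test_conjunctive_rule_with_per_pattern_minima(self, parsed_fixtures):
        rule_e = FragmentRule(
            rule_id="E",
            smarts_list=["O[a]", "[Cl,Br]a"],
            min_counts=[1, 3],
            conjunctive=True,
        )
        assert match_rule(parsed_fixtures["pentachlorophenol"][0], rule_e)
        assert match_rule(parsed_fixtures["246-trichlorophenol"][0], rule_e)
        assert not match_rule(parsed_fixtures["hexachlorobenzene"][0], rule_e)
        assert not match_rule(parsed_fixtures["dodecanol"][0], rule_e)

    def test_rule_validation(self):
        with pytest.raises(PatternError):
            FragmentRule(rule_id="bad", smarts_list=["[Cl]"], min_counts=[0])
        with pytest.raises(PatternError):
            FragmentRule(rule_id="bad", smarts_list=["[[["])
        with pytest.raises(PatternError):
            FragmentRule(rule_id="bad", smarts_list=[])


class TestScreenRules:
    def test_expected_rules_fire_on_fixtures(self, parsed_fixtures):
        rules = load_rules()
        expected = {
            "benzene": [],
            "hexachlorobenzene": ["A"],
            "pentachlorophenol": ["E"],
            "246-trichloroanisole": ["E"],
            "246-trichlorophenol": ["E"],
            "carbon-disulfide": [],
            "octamethylcyclotetrasiloxane": ["J"],
            "dodecanol": [],
        }
        for name, (structure, _) in parsed_fixtures.items():
            assert screen_rules(structure, rules) == expected[name], name

    def test_multiple_rules_report_in_file_order(self, parsed_fixtures):
        rules = [
            FragmentRule(rule_id="first", smarts_list=["[Cl]"]),
            FragmentRule(rule_id="second", smarts_list=["O[a]"]),
        ]
        triggered = screen_rules(parsed_fixtures["pentachlorophenol"][0], rules)
        assert triggered == ["first", "second"]

    def test_rules_load_from_custom_json(self, tmp_path):
        path = tmp_path / "rules.json"
        path.write_text(
            json.dumps(
                [{"rule_id": "X", "smarts_list": ["[Br]"], "min_counts": [2]}]
            )
        )
        rules = load_rules(path)
        assert rules[0].rule_id == "X"
        assert rules[0].min_count == 2


# ---------------------------------------------------------------------------
# Descriptor ranges
# ---------------------------------------------------------------------------


def _rec(rid, **desc):
    return CompoundRecord(id=rid, smiles="C", descriptors=desc)


class TestRanges:
    def test_componentwise_min_max(self):
        ds = Dataset(records=[_rec("a", x=1.0, y=5.0), _rec("b", x=2.0, y=-1.0),
                              _rec("c", x=3.0, y=0.0)])
        ranges = learn_ranges(ds, ["x", "y"])
        assert ranges == {"x": (1.0, 3.0), "y": (-1.0, 5.0)}

    def test_single_record_degenerate_range(self):
        ds = Dataset(records=[_rec("a", x=2.0)])
        assert learn_ranges(ds, ["x"]) == {"x": (2.0, 2.0)}

    def test_missing_descriptor_names_record(self):
        ds = Dataset(records=[_rec("a", x=1.0), CompoundRecord(id="b", smiles="C")])
        with pytest.raises(DataError, match="b"):
            learn_ranges(ds, ["x"])

    def test_boundary_value_inside_closed_interval(self):
        ranges = {"x": (1.0, 3.0)}
        assert check_ranges(_rec("q", x=1.0), ranges) == []
        assert check_ranges(_rec("q", x=3.0), ranges) == []
        assert check_ranges(_rec("q", x=3.0 + 1e-9), ranges) == ["x"]

    def test_multiple_excursions_all_named(self):
        ranges = {"x": (0.0, 1.0), "y": (0.0, 1.0), "z": (0.0, 1.0)}
        flagged = check_ranges(_rec("q", x=5.0, y=0.5, z=-2.0), ranges)
        assert flagged == ["x", "z"]


# ---------------------------------------------------------------------------
# Similarity and neighbors
# ---------------------------------------------------------------------------


def _reference(n=10, seed=0, d=3):
    rng = np.random.default_rng(seed)
    recs = []
    for i in range(n):
        vec = {f"d{j}": float(rng.uniform(0, 1)) for j in range(d)}
        recs.append(
            CompoundRecord(
                id=f"ref-{i}",
                smiles="C",
                exp_logbcf=[float(rng.normal(2, 1))],
                predicted_logbcf=float(rng.normal(2, 1)),
                descriptors=vec,
            )
        )
    return Dataset(records=recs)


class TestSimilarity:
    def test_identical_vectors_score_exactly_one(self):
        ref = _reference()
        scaling = DescriptorScaling.fit(ref, ["d0", "d1", "d2"])
        v = ref[0].descriptors
        assert similarity_index(v, v, scaling) == 1.0

    def test_opposite_corners_of_unit_hypercube_score_zero(self):
        ds = Dataset(records=[_rec("lo", x=0.0, y=0.0), _rec("hi", x=1.0, y=1.0)])
        scaling = DescriptorScaling.fit(ds, ["x", "y"])
        sim = similarity_index(ds[0].descriptors, ds[1].descriptors, scaling)
        assert sim == pytest.approx(0.0, abs=1e-12)
        assert sim <= 0.5

    def test_bounds_symmetry_and_self_similarity_on_seeded_vectors(self):
        ref = _reference(n=30, seed=42, d=4)
        names = ["d0", "d1", "d2", "d3"]
        scaling = DescriptorScaling.fit(ref, names)
        rng = np.random.default_rng(7)
        for _ in range(100):
            a = {n: float(rng.uniform(-0.5, 1.5)) for n in names}
            b = {n: float(rng.uniform(-0.5, 1.5)) for n in names}
            sab = similarity_index(a, b, scaling)
            assert 0.0 <= sab <= 1.0
            assert sab == pytest.approx(similarity_index(b, a, scaling))
            assert similarity_index(a, a, scaling) == 1.0

    def test_name_mismatch_is_data_error(self):
        ref = _reference()
        scaling = DescriptorScaling.fit(ref, ["d0", "d1", "d2"])
        with pytest.raises(DataError):
            similarity_index({"d0": 0.1}, ref[0].descriptors, scaling)


class TestFindNeighbors:
    def test_top_k_sorted_by_similarity(self):
        ref = _reference(n=10)
        scaling = DescriptorScaling.fit(ref, ["d0", "d1", "d2"])
        hits, short = find_neighbors(ref[0], ref, scaling, k=6)
        assert len(hits) == 6 and not short
        sims = [h.similarity for h in hits]
        assert sims == sorted(sims, reverse=True)
        assert hits[0].neighbor_id == "ref-0" and hits[0].similarity == 1.0

    def test_short_reference_returns_all_with_flag(self):
        ref = _reference(n=4)
        scaling = DescriptorScaling.fit(ref, ["d0", "d1", "d2"])
        hits, short = find_neighbors(ref[1], ref, scaling, k=6)
        assert len(hits) == 4 and short

    def test_abs_error_consistent_with_exp_and_predicted(self):
        hit = NeighborHit("x", 0.9, exp_logbcf=2.0, predicted_logbcf=3.5)
        assert hit.abs_error == pytest.approx(1.5, abs=1e-9)

    def test_far_compound_never_enters_top_k(self):
        ref = _reference(n=10, seed=3)
        names = ["d0", "d1", "d2"]
        scaling = DescriptorScaling.fit(ref, names)
        query = ref[2]
        base_ids = {h.neighbor_id for h in find_neighbors(query, ref, scaling, k=6)[0]}
        far = CompoundRecord(
            id="far", smiles="C", exp_logbcf=[0.0], predicted_logbcf=0.0,
            descriptors={n: 1e6 for n in names},
        )
        extended = Dataset(records=ref.records + [far])
        new_ids = {h.neighbor_id for h in find_neighbors(query, extended, scaling, k=6)[0]}
        assert new_ids == base_ids

    def test_reference_without_predictions_rejected(self):
        ref = _reference(n=3)
        ref.records[1].predicted_logbcf = None
        scaling = DescriptorScaling.fit(ref, ["d0", "d1", "d2"])
        with pytest.raises(DataError):
            find_neighbors(ref[0], ref, scaling, k=2)


# ---------------------------------------------------------------------------
# Verdict and reporting
# ---------------------------------------------------------------------------


def _hits(sims, errors):
    return [
        NeighborHit(f"n{i}", s, exp_logbcf=2.0, predicted_logbcf=2.0 + e)
        for i, (s, e) in enumerate(zip(sims, errors))
    ]


class TestDomainVerdict:
    def test_clean_compound_in_domain(self):
        report = domain_verdict([], [], _hits([0.9, 0.8], [0.1, 0.2]))
        assert report.verdict == "in_domain"
        assert report.reasons == []

    def test_low_similarity_is_warning(self):
        report = domain_verdict([], [], _hits([0.45, 0.4], [0.1, 0.1]))
        assert report.verdict == "warning"
        assert any("low similarity" in r for r in report.reasons)

    def test_out_of_range_descriptor_dominates(self):
        report = domain_verdict(["mol_weight"], [], _hits([0.9], [0.1]))
        assert report.verdict == "out_of_domain"
        assert report.reasons  # out_of_domain implies reasons non-empty

    def test_triggered_rule_is_warning(self):
        report = domain_verdict([], ["A"], _hits([0.9], [0.1]))
        assert report.verdict == "warning"
        assert any("rule A" in r for r in report.reasons)

    def test_large_neighbor_errors_warn(self):
        report = domain_verdict([], [], _hits([0.9, 0.9], [1.5, 1.2]))
        assert report.verdict == "warning"
        assert any("neighborhood" in r for r in report.reasons)

    @given(st.lists(st.sampled_from(["A", "E", "J"]), max_size=3, unique=True))
    def test_adding_rules_never_moves_toward_in_domain(self, rules):
        order = {"in_domain": 0, "warning": 1, "out_of_domain": 2}
        base = domain_verdict([], rules, _hits([0.9], [0.1]))
        more = domain_verdict([], rules + ["Z"], _hits([0.9], [0.1]))
        assert order[more.verdict] >= order[base.verdict]


class TestApplicabilityDomainEstimator:
    def test_end_to_end_on_structures(self, parsed_fixtures):
        # reference: plain organic compounds with computed descriptors
        rng = np.random.default_rng(0)
        smiles_pool = ["CCO", "CCCCCC", "c1ccccc1", "Cc1ccccc1", "CCCCCCCC",
                       "CCOCC", "c1ccc2ccccc2c1", "CCCCO", "CC(C)CC", "CCCCCCCCCC"]
        recs = []
        for i, smi in enumerate(smiles_pool):
            recs.append(
                CompoundRecord(
                    id=f"train-{i}", smiles=smi,
                    exp_logbcf=[float(rng.normal(2, 0.5))],
                    predicted_logbcf=float(rng.normal(2, 0.5)),
                    structure=parse_structure(smi),
                )
            )
        ad = ApplicabilityDomain().fit(Dataset(records=recs, split_label="training"))

        benzene = CompoundRecord(
            id="q-benzene", smiles="c1ccccc1", structure=parse_structure("c1ccccc1")
        )
        assert ad.assess(benzene).verdict == "in_domain"

        # carbon disulfide: no carbon-chain analogue in the reference
        cs2 = CompoundRecord(id="q-cs2", smiles="S=C=S", structure=parse_structure("S=C=S"))
        assert ad.assess(cs2).verdict == "out_of_domain"

        hexa = CompoundRecord(
            id="q-hcb",
            smiles="Clc1c(Cl)c(Cl)c(Cl)c(Cl)c1Cl",
            structure=parse_structure("Clc1c(Cl)c(Cl)c(Cl)c(Cl)c1Cl"),
        )
        report = ad.assess(hexa)
        assert "A" in report.triggered_rules
        assert report.verdict == "out_of_domain"  # halogen count far out of range

    def test_result_sheet_contents(self):
        ref = _reference(n=10)
        ad = ApplicabilityDomain(descriptor_names=["d0", "d1", "d2"]).fit(ref)
        report = ad.assess(ref[0])
        result = make_result(3.0, domain_verdict=report.verdict)
        sheet = render_result_sheet(ref[0], result, report)
        assert "in domain" in sheet
        assert sheet.count("ref-") >= 6  # six neighbor rows
        assert "3.31" in sheet
        payload = json.loads(result_sheet_json(ref[0], result, report))
        assert payload["bcf_class"] == "B"
        assert len(payload["domain"]["neighbors"]) == 6

    def test_short_reference_noted_on_sheet(self):
        ref = _reference(n=4)
        ad = ApplicabilityDomain(descriptor_names=["d0", "d1", "d2"]).fit(ref)
        report = ad.assess(ref[0])
        sheet = render_result_sheet(ref[0], make_result(2.0), report)
        assert "fewer than requested" in sheet


def test_compute_descriptors_returns_eight_values(parsed_fixtures):
    structure, _ = parsed_fixtures["hexachlorobenzene"]
    desc = compute_descriptors(structure)
    assert len(desc) == 8
    assert desc["halogen_count"] == 6.0
    assert desc["aromatic_atoms"] == 6.0
    assert desc["heavy_atoms"] == 12.0
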