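import numpy as np
import pytest
from rdkit import Chem

from hmgrqsar.dataset import CompoundRecord
from hmgrqsar.errors import ConfigurationError, StructureError
from hmgrqsar.scaffolds import (
    DEFAULT_SMARTS,
    DiversitySummary,
    cyclic_flag,
    diversity_summary,
    diversity_table,
    functional_groups,
    group_by_scaffold,
    murcko_scaffold,
    render_scaffold_svg,
    scaffold_table,
)


def _rec(cid, smiles, pic50=7.0, cls="intermediate"):
    return CompoundRecord(cid, smiles, 10 ** (9 - pic50), pic50, cls)


# ---------------------------------------------------------------- extraction


def test_side_chain_pruning():
    assert murcko_scaffold("CCc1ccccc1") == "c1ccccc1"


def test_acyclic_molecules_have_empty_scaffold():
    for smi in ("CCCC", "CCO", "CC(=O)NC"):
        assert murcko_scaffold(smi) == ""
        assert not cyclic_flag(smi)


def test_published_cores_are_their_own_scaffolds(table4_smiles):
    """Re-extraction is a fixed point on every published core structure."""
    for smi in table4_smiles.values():
        scaf = murcko_scaffold(smi)
        assert scaf != ""
        assert murcko_scaffold(scaf) == scaf


def test_idempotence_on_synthetic_molecules(default_dataset):
    table, _ = default_dataset
    for smi in table["smiles"]:
        scaf = murcko_scaffold(smi)
        if scaf:
            assert murcko_scaffold(scaf) == scaf


def test_extraction_invariant_to_atom_order(rng, table4_smiles):
    for smi in table4_smiles.values():
        mol = Chem.MolFromSmiles("".join(smi.split()))
        order = [int(i) for i in rng.permutation(mol.GetNumAtoms())]
        shuffled = Chem.MolToSmiles(Chem.RenumberAtoms(mol, order), canonical=False)
        assert murcko_scaffold(shuffled) == murcko_scaffold(smi)


def test_unparseable_raises():
    with pytest.raises(StructureError):
        murcko_scaffold("((")
    with pytest.raises(StructureError):
        cyclic_flag("((")


def test_cyclic_flag_counting():
    mols = ["c1ccccc1", "C1CC1", "c1ccncc1", "C1CCCCC1C", "CCCC"]
    assert sum(cyclic_flag(s) for s in mols) == 4


# ---------------------------------------------------------------- diversity


def test_diversity_quotients_from_published_counts():
    """Quotients of the published class tallies, to six decimals."""
    active = DiversitySummary.from_counts("active", 211, 69, 210)
    assert round(active.ns_over_n, 6) == 0.327014
    assert round(active.ncsk_over_n, 6) == 0.995261
    assert round(active.ncsk_over_ns, 6) == 3.043478
    inter = DiversitySummary.from_counts("intermediate", 56, 32, 48)
    assert round(inter.ns_over_n, 6) == 0.571429
    assert round(inter.ncsk_over_ns, 6) == 1.5
    inact = DiversitySummary.from_counts("inactive", 43, 23, 41)
    assert round(inact.ns_over_n, 6) == 0.534884


def test_single_cyclic_molecule_all_ratios_one():
    s = diversity_summary([_rec("a", "c1ccccc1")], "active")
    assert s.ns_over_n == s.ncsk_over_n == s.ncsk_over_ns == 1.0


def test_diversity_summary_counts_ring_bearing_molecules():
    records = [
        _rec("a", "CCc1ccccc1"),
        _rec("b", "CCCCc1ccccc1"),   # same scaffold as a
        _rec("c", "C1CCNCC1"),
        _rec("d", "CCCC"),           # acyclic
        _rec("e", "CCO"),            # acyclic
    ]
    s = diversity_summary(records, "x")
    assert (s.n_molecules, s.n_scaffolds, s.n_cyclic) == (5, 2, 3)
    assert s.ns_over_n == pytest.approx(2 / 5, abs=1e-12)
    assert s.ncsk_over_ns == pytest.approx(3 / 2, abs=1e-12)


def test_empty_class_rejected():
    with pytest.raises(ConfigurationError):
        diversity_summary([], "active")


def test_diversity_matches_grouping(curated_records):
    """Ns from grouping equals Ns from the diversity summary."""
    for label in ("active", "intermediate", "inactive"):
        members = [r for r in curated_records if r.activity_class == label]
        groups, acyclic = group_by_scaffold(members)
        s = diversity_summary(members, label)
        assert len(groups) == s.n_scaffolds
        assert sum(g.count for g in groups) + len(acyclic) == s.n_molecules


# ---------------------------------------------------------------- grouping


def test_group_means_and_classes():
    records = [
        _rec("a", "CCc1ccccc1", 8.0),
        _rec("b", "CCCc1ccccc1", 8.2),
        _rec("c", "C1CCNCC1", 4.3),
        _rec("d", "CC(C)c1ccncc1", 6.0),
        _rec("e", "CCc1ccncc1", 8.0),
    ]
    groups, acyclic = group_by_scaffold(records)
    assert acyclic == []
    by_scaf = {g.scaffold_smiles: g for g in groups}
    benzene = by_scaf[murcko_scaffold("CCc1ccccc1")]
    assert benzene.mean_pic50 == pytest.approx(8.1)
    assert benzene.scaffold_class == "active"
    piperidine = by_scaf[murcko_scaffold("C1CCNCC1")]
    assert piperidine.scaffold_class == "inactive"
    pyridine = by_scaf[murcko_scaffold("CCc1ccncc1")]
    assert pyridine.mean_pic50 == pytest.approx(7.0)
    assert pyridine.scaffold_class == "intermediate"


def test_group_ordering_and_acyclic_bucket():
    records = (
        [_rec(f"b{i}", "CCc1ccccc1") for i in range(3)]
        + [_rec(f"p{i}", "CCc1ccncc1") for i in range(3)]
        + [_rec("x", "C1CC1"), _rec("acy", "CCCC")]
    )
    groups, acyclic = group_by_scaffold(records)
    assert acyclic == ["acy"]
    assert [g.count for g in groups] == [3, 3, 1]
    # tie on count broken by canonical scaffold SMILES
    assert groups[0].scaffold_smiles < groups[1].scaffold_smiles
    assert sum(g.count for g in groups) + len(acyclic) == len(records)
    frame = scaffold_table(groups)
    assert list(frame["count"]) == [3, 3, 1]


def test_group_invariants_on_synthetic(curated_records):
    groups, acyclic = group_by_scaffold(curated_records)
    assert sum(g.count for g in groups) + len(acyclic) == len(curated_records)
    by_id = {r.compound_id: r for r in curated_records}
    for g in groups:
        assert g.count == len(g.member_ids) >= 1
        member_pic50 = [by_id[m].pic50 for m in g.member_ids]
        assert min(member_pic50) - 1e-12 <= g.mean_pic50 <= max(member_pic50) + 1e-12
        assert murcko_scaffold(g.scaffold_smiles) == g.scaffold_smiles


# ---------------------------------------------------------------- SMARTS


def test_benzene_profile():
    prof = functional_groups("c1ccccc1")
    flags = prof.flags()
    assert flags["aromatic_ring"]
    assert not flags["amide"] and not flags["hydroxyl"]
    assert not flags["nitrogen_heterocycle"]


def test_anilide_core_has_amide_and_aromatics(table4_smiles):
    prof = functional_groups(table4_smiles[5])
    flags = prof.flags()
    assert flags["amide"] and flags["aromatic_ring"]
    assert flags["nitrogen_heterocycle"]  # pyrrole nitrogen is in-ring


def test_phenol_hydroxyl_not_ether():
    flags = functional_groups("Oc1ccccc1").flags()
    assert flags["hydroxyl"] and not flags["ether"]
    flags2 = functional_groups("COc1ccccc1").flags()
    assert flags2["ether"] and not flags2["hydroxyl"]


def test_invalid_user_smarts_named():
    with pytest.raises(ConfigurationError, match="mypattern"):
        functional_groups("c1ccccc1", {"mypattern": "[[["})


def test_svg_rendering(tmp_path):
    out = tmp_path / "scaffold.svg"
    render_scaffold_svg("c1ccccc1", out)
    text = out.read_text()
    assert text.lstrip().startswith("<?xml") and "<svg" in text


def test_diversity_table_covers_classes(curated_records):
    frame = diversity_table(curated_records)
    assert set(frame["class_label"]) <= {"active", "intermediate", "inactive"}
    assert (frame["n_scaffolds"] <= frame["n_molecules"]).all()
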