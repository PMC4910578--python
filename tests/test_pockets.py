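"""Contact detection, 10-class classification, transfer and occlusion."""

import numpy as np
import pytest

from plgicmap import (
    build_site_atlas,
    classify_site,
    ligand_contacts,
    occlusion_score,
    plant_ligand,
    transfer_site,
)
from plgicmap.matching import positional_correspondence, structural_correspondence
from plgicmap.pockets import INTERFACE_CLASSES, TransferError
from plgicmap.structure import Atom, LigandInstance
from plgicmap.synthetic import FIXTURE_CONTACT_CUTOFF, PLANTABLE_CLASSES
from tests.conftest import random_rotation


def _make_lig(positions, het="LIG", element="C"):
    return LigandInstance(
        het_name=het, chain_id="A", number=999,
        atoms=[Atom(name=f"X{i}", element=element, position=np.asarray(p, float),
                    is_hetero=True) for i, p in enumerate(np.atleast_2d(positions))])


def brute_force_contacts(s, lig, cutoff):
    """Independent double-loop oracle."""
    out = {}
    for chain in s.chains:
        hits = [r.key for r in chain.residues
                if any(np.linalg.norm(a.position - q) <= cutoff
                       for a in r.atoms for q in lig.coords())]
        if hits:
            out[chain.id] = hits
    return out


def test_far_ligand_has_empty_contact_set(pentamer):
    s, _ = pentamer
    lig = _make_lig([[500.0, 500.0, 500.0]])
    cs = ligand_contacts(s, lig, 6.5)
    assert cs.contacts == {}


def test_displaced_planted_ligand_empty(pentamer):
    s, gt = pentamer
    s2, _ = plant_ligand(s, gt, 9)
    lig = s2.ligands[-1]
    for a in lig.atoms:
        r = np.array([a.position[0], a.position[1], 0.0])
        a.position = a.position + 20.0 * r / np.linalg.norm(r)
    cs = ligand_contacts(s2, lig, FIXTURE_CONTACT_CUTOFF)
    assert cs.contacts == {}


def test_interface_ligand_contacts_two_chains_and_matches_brute_force(pentamer):
    s, gt = pentamer
    s2, expected = plant_ligand(s, gt, 7)
    lig = s2.ligands[-1]
    cs = ligand_contacts(s2, lig, FIXTURE_CONTACT_CUTOFF)
    assert sorted(cs.contacts) == ["A", "B"]
    assert cs.contacts == brute_force_contacts(s2, lig, FIXTURE_CONTACT_CUTOFF)
    assert cs.contacts == expected.contacts


def test_contacts_invariant_under_rigid_transform(pentamer, rng):
    s, gt = pentamer
    s2, _ = plant_ligand(s, gt, 8)
    cs = ligand_contacts(s2, s2.ligands[-1], FIXTURE_CONTACT_CUTOFF)
    moved = s2.transformed(random_rotation(rng), rng.normal(size=3) * 30)
    cs2 = ligand_contacts(moved, moved.ligands[-1], FIXTURE_CONTACT_CUTOFF)
    assert cs.contacts == cs2.contacts


def test_contact_monotonicity_in_cutoff(pentamer):
    s, gt = pentamer
    s2, _ = plant_ligand(s, gt, 5)
    lig = s2.ligands[-1]
    small = ligand_contacts(s2, lig, 5.0)
    large = ligand_contacts(s2, lig, 7.5)
    small_keys = {k for ks in small.contacts.values() for k in ks}
    large_keys = {k for ks in large.contacts.values() for k in ks}
    assert small_keys <= large_keys


def test_zero_cutoff_rejected(pentamer):
    s, gt = pentamer
    s2, _ = plant_ligand(s, gt, 5)
    with pytest.raises(ValueError):
        ligand_contacts(s2, s2.ligands[-1], 0.0)


# ---------------------------------------------------------------------------
# classification


@pytest.mark.parametrize("site_class", PLANTABLE_CLASSES)
def test_planted_class_recovered(pentamer, anchor_maps, pore, fixture_config,
                                 site_class):
    s, gt = pentamer
    s2, _ = plant_ligand(s, gt, site_class)
    cs = ligand_contacts(s2, s2.ligands[-1], FIXTURE_CONTACT_CUTOFF)
    cls = classify_site(cs, s2, anchor_maps, pore, fixture_config)
    assert cls.site_class == site_class
    assert cls.interface == (site_class in INTERFACE_CLASSES)
    if cls.interface:
        assert cls.principal_chain == "A"
        assert cls.complementary_chain == "B"
    else:
        assert cls.principal_chain == "" and cls.complementary_chain == ""


def test_single_chain_contacts_never_interface_class(pentamer, anchor_maps, pore,
                                                     fixture_config):
    s, gt = pentamer
    for site_class in (5, 6, 8, 9, 10):
        s2, _ = plant_ligand(s, gt, site_class)
        cs = ligand_contacts(s2, s2.ligands[-1], FIXTURE_CONTACT_CUTOFF)
        assert len(cs.contacts) == 1
        cls = classify_site(cs, s2, anchor_maps, pore, fixture_config)
        assert cls.site_class not in INTERFACE_CLASSES


def test_pore_axis_ligand_flagged_not_classified(pentamer, anchor_maps, pore,
                                                 fixture_config):
    s, gt = pentamer
    origin, axis = pore
    # inside the pore cylinder at TMD heights, close enough to touch M2
    m2_pos = s.residue(("A", gt.anchors["M2"][10], "")).calpha.position
    rel = m2_pos - origin
    radial = rel - np.dot(rel, axis) * axis
    base_pt = origin + np.dot(rel, axis) * axis + 5.5 * radial / np.linalg.norm(radial)
    blocker = _make_lig([base_pt + i * axis for i in range(3)])
    s2 = s.copy()
    s2.ligands.append(blocker)
    cs = ligand_contacts(s2, blocker, FIXTURE_CONTACT_CUTOFF)
    cls = classify_site(cs, s2, anchor_maps, pore, fixture_config)
    assert cls.pore_facing
    assert cls.site_class == "unclassified"


def test_empty_contacts_unclassified(pentamer, anchor_maps, pore, fixture_config):
    s, _ = pentamer
    lig = _make_lig([[400.0, 0.0, 0.0]])
    s2 = s.copy()
    s2.ligands.append(lig)
    cs = ligand_contacts(s2, lig, FIXTURE_CONTACT_CUTOFF)
    cls = classify_site(cs, s2, anchor_maps, pore, fixture_config)
    assert cls.site_class == "unclassified"


# ---------------------------------------------------------------------------
# occlusion


def test_occlusion_empty_space_zero(pentamer):
    s, _ = pentamer
    assert occlusion_score(np.array([[300.0, 0.0, 0.0]]), s) == 0.0


def test_occlusion_full_overlap_one(pentamer):
    s, _ = pentamer
    pts = s.chains[0].calpha_coords()[:5]
    assert occlusion_score(pts, s, clash_distance=0.5) == 1.0


@pytest.mark.parametrize("k", [0, 1, 3, 5])
def test_partial_overlap_fraction_exact(pentamer, k):
    s, _ = pentamer
    n = 5
    on_protein = s.chains[0].calpha_coords()[:k]
    in_space = np.array([[300.0 + 10 * i, 0.0, 0.0]
                         for i in range(n - k)]).reshape(-1, 3)
    pts = np.vstack([on_protein.reshape(-1, 3), in_space])
    assert occlusion_score(pts, s, clash_distance=0.5) == pytest.approx(k / n)


# ---------------------------------------------------------------------------
# transfer


def test_identity_transfer_plausible(pentamer, fixture_config):
    s, gt = pentamer
    s2, _ = plant_ligand(s, gt, 1)
    cs = ligand_contacts(s2, s2.ligands[-1], FIXTURE_CONTACT_CUTOFF)
    corrs = [positional_correspondence(s2, c, s, c) for c in cs.contacts]
    ts = transfer_site(cs, corrs, s2, s, fixture_config)
    assert ts.unmapped_count == 0
    mapped = {k for ks in ts.mapped.values() for k in ks}
    assert mapped == {k for ks in cs.contacts.values() for k in ks}
    assert ts.occlusion <= fixture_config.occlusion_threshold
    assert ts.verdict == "plausible"


def test_vestibule_transfer_onto_occluded_variant_rejected(
        pentamer, occluded_pentamer, fixture_config):
    s, gt = pentamer
    occ, _ = occluded_pentamer
    s2, _ = plant_ligand(s, gt, 4)
    cs = ligand_contacts(s2, s2.ligands[-1], FIXTURE_CONTACT_CUTOFF)
    corrs = [structural_correspondence(s2, c, occ, c) for c in cs.contacts]
    ts = transfer_site(cs, corrs, s2, occ, fixture_config)
    assert ts.verdict == "occluded"
    assert ts.occlusion > fixture_config.occlusion_threshold


def test_transfer_with_too_few_mappable_residues_errors(pentamer, fixture_config):
    from plgicmap.alignment import Correspondence

    s, gt = pentamer
    s2, _ = plant_ligand(s, gt, 9)
    cs = ligand_contacts(s2, s2.ligands[-1], FIXTURE_CONTACT_CUTOFF)
    empty = Correspondence(source=(s2.label, "A"), target=(s.label, "A"), pairs=[])
    with pytest.raises(TransferError):
        transfer_site(cs, [empty], s2, s, fixture_config)


# ---------------------------------------------------------------------------
# atlas


def test_atlas_over_three_planted_classes(pentamer, anchor_maps, pore,
                                          fixture_config):
    s, gt = pentamer
    planted = s
    for cls in (1, 7, 9):
        planted, _ = plant_ligand(planted, gt, cls)
    df = build_site_atlas([planted], {planted.label: anchor_maps},
                          {planted.label: pore}, fixture_config)
    assert len(df) == 3
    assert set(df["site_class"]) == {1, 7, 9}
    assert not df["error"].any()


def test_atlas_empty_input(fixture_config):
    df = build_site_atlas([], {}, {}, fixture_config)
    assert df.empty


def test_atlas_merges_multi_copy_ligands(pentamer, anchor_maps, pore,
                                         fixture_config):
    s, gt = pentamer
    planted, _ = plant_ligand(s, gt, 8)
    # second copy of the same het in (almost) the same pocket
    twin = planted.copy()
    lig2 = LigandInstance(
        het_name="LIG", chain_id="A", number=950,
        atoms=[Atom(name=a.name, element=a.element,
                    position=a.position + [0.3, 0.0, 0.0], is_hetero=True)
               for a in planted.ligands[-1].atoms])
    twin.ligands.append(lig2)
    df = build_site_atlas([twin], {twin.label: anchor_maps},
                          {twin.label: pore}, fixture_config)
    assert len(df) == 1  # merged into a single occurrence
    assert df.iloc[0]["site_class"] == 8
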