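"""Kabsch fitting, RMSD bookkeeping and domain-motion decomposition."""

import numpy as np
import pytest
from scipy.optimize import minimize
from scipy.spatial.transform import Rotation

from plgicmap import (
    domain_motion,
    kabsch_fit,
    pairwise_rmsd,
    perturb_state,
    pore_axis,
    superpose_subset,
)
from plgicmap.anchors import domain_keys
from plgicmap.matching import positional_correspondence
from plgicmap.superpose import FitError, rmsd_between
from tests.conftest import random_rotation


def brute_force_min_rmsd(p: np.ndarray, q: np.ndarray) -> float:
    """Numeric minimization over rotation space: the independent oracle."""
    pc = p - p.mean(axis=0)
    qc = q - q.mean(axis=0)

    def objective(rotvec):
        r = Rotation.from_rotvec(rotvec).as_matrix()
        return np.sqrt(np.mean(np.sum((pc @ r.T - qc) ** 2, axis=1)))

    best = np.inf
    for x0 in ([0.1, 0.0, 0.0], [2.0, 0.5, -1.0], [-1.0, 2.0, 2.0], [0.0, -2.5, 0.5]):
        res = minimize(objective, x0, method="Nelder-Mead",
                       options={"xatol": 1e-10, "fatol": 1e-14, "maxiter": 5000})
        best = min(best, res.fun)
    return float(best)


def test_identical_points_fit_to_identity():
    p = np.random.default_rng(0).normal(size=(10, 3))
    fit = kabsch_fit(p, p)
    assert fit.rmsd == pytest.approx(0.0, abs=1e-12)
    np.testing.assert_allclose(fit.rotation, np.eye(3), atol=1e-12)


def test_pure_translation_recovered():
    p = np.random.default_rng(1).normal(size=(8, 3))
    fit = kabsch_fit(p, p + [5.0, 0.0, 0.0])
    assert fit.rmsd == pytest.approx(0.0, abs=1e-12)
    np.testing.assert_allclose(fit.rotation, np.eye(3), atol=1e-10)
    np.testing.assert_allclose(fit.translation, [5.0, 0.0, 0.0], atol=1e-10)


@pytest.mark.parametrize("seed", [0, 1, 2])
def test_kabsch_matches_brute_force_optimizer(seed):
    rng = np.random.default_rng(seed)
    p = rng.normal(size=(10, 3)) * 5
    q = rng.normal(size=(10, 3)) * 5
    fit = kabsch_fit(p, q)
    assert abs(fit.rmsd - brute_force_min_rmsd(p, q)) < 1e-6


def test_no_reflection_even_for_mirrored_cloud():
    rng = np.random.default_rng(3)
    p = rng.normal(size=(10, 3))
    q = p * [-1.0, 1.0, 1.0]  # mirror image
    fit = kabsch_fit(p, q)
    assert np.linalg.det(fit.rotation) == pytest.approx(1.0, abs=1e-9)


def test_degenerate_collinear_points_rejected():
    p = np.array([[float(i), 0.0, 0.0] for i in range(5)])
    with pytest.raises(FitError):
        kabsch_fit(p, p + 1.0)


def test_weighted_fit_prefers_heavy_points():
    p = np.array([[0.0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1]])
    q = p.copy()
    q[3] = [3.0, 3.0, 3.0]  # outlier
    w = np.array([1.0, 1.0, 1.0, 1e-9])
    fit = kabsch_fit(p, q, weights=w)
    assert fit.rmsd < 1e-3


def test_rmsd_invariant_under_rigid_transform(pentamer, rng):
    s, _ = pentamer
    other = s.copy()
    corr = positional_correspondence(s, "A", other, "A")
    base = superpose_subset(s, other, corr).rmsd
    moved = other.transformed(random_rotation(rng), rng.normal(size=3) * 15)
    corr2 = positional_correspondence(s, "A", moved, "A")
    assert superpose_subset(s, moved, corr2).rmsd == pytest.approx(base, abs=1e-9)


def test_three_rigid_copies_all_pairwise_zero(pentamer, rng):
    s, _ = pentamer
    copies = [s] + [s.transformed(random_rotation(rng), rng.normal(size=3) * 10)
                    for _ in range(2)]
    for i, a in enumerate(copies):
        for b in copies[i + 1:]:
            corr = positional_correspondence(a, "A", b, "A")
            assert superpose_subset(a, b, corr).rmsd < 1e-6


def test_subset_restriction_and_labels(pentamer, anchor_maps):
    s, gt = pentamer
    twisted = perturb_state(s, gt, twist=10.0)
    corrs = [positional_correspondence(s, c, twisted, c) for c in s.chain_ids]
    tmd = domain_keys(s, anchor_maps, "TMD")
    fit = superpose_subset(s, twisted, corrs, tmd, "TMD")
    assert fit.subset_label == "TMD"
    assert fit.rmsd < 1e-9  # the TMD did not move
    ecd = domain_keys(s, anchor_maps, "ECD")
    assert superpose_subset(s, twisted, corrs, ecd, "ECD").rmsd < 1e-9  # rigid ECD


def test_empty_subset_errors(pentamer):
    s, _ = pentamer
    corr = positional_correspondence(s, "A", s, "A")
    with pytest.raises(FitError):
        superpose_subset(s, s, corr, subset_keys_a={("Z", 1, "")})


def test_domain_rmsd_never_exceeds_subunit_rmsd(pentamer, anchor_maps):
    s, gt = pentamer
    state = perturb_state(s, gt, twist=8.0, noise_sd=0.2, seed=5)
    corr = positional_correspondence(s, "A", state, "A")
    whole = superpose_subset(s, state, corr).rmsd
    keys_a = {r.key for r in s.chain("A").residues}
    for dom in ("ECD", "TMD"):
        sub = domain_keys(s, anchor_maps, dom) & keys_a
        assert superpose_subset(s, state, corr, sub).rmsd <= whole + 1e-9


# ---------------------------------------------------------------------------
# pairwise matrices


def test_duplicate_structures_give_zero_offdiagonal(pentamer):
    s, _ = pentamer
    copies = [s.copy() for _ in range(3)]
    for i, c in enumerate(copies):
        c.label = f"copy{i}"
    m = pairwise_rmsd(copies, positional_correspondence)
    assert np.allclose(m.values, 0.0, atol=1e-9)
    assert np.allclose(m.values, m.values.T)


def test_two_state_ensemble_separates(pentamer):
    s, gt = pentamer
    states = [perturb_state(s, gt, twist=tw, noise_sd=0.15, seed=i, label=f"st{i}")
              for i, tw in enumerate([0.0, 0.0, 25.0, 25.0])]
    m = pairwise_rmsd(states, positional_correspondence, pentamer_mode=True)
    within = [m.values[0, 1], m.values[2, 3]]
    between = [m.values[i, j] for i in (0, 1) for j in (2, 3)]
    assert max(within) < min(between)


def test_pentamer_cyclic_minimum_not_above_fixed_order(pentamer, rng):
    s, gt = pentamer
    other = perturb_state(s, gt, twist=12.0, noise_sd=0.1, seed=7, label="o")
    m = pairwise_rmsd([s, other], positional_correspondence, pentamer_mode=True)
    corrs = [positional_correspondence(s, c, other, c) for c in s.chain_ids]
    fixed = superpose_subset(s, other, corrs).rmsd
    assert m.values[0, 1] <= fixed + 1e-9


def test_rotated_chain_order_recovered_by_cyclic_assignment(pentamer):
    # relabel chains by one step around the ring: cyclic minimization
    # must still find the zero-RMSD assignment
    s, _ = pentamer
    shifted = s.copy()
    ids = [c.id for c in shifted.chains]
    for c, new in zip(shifted.chains, ids[1:] + ids[:1]):
        old = c.id
        c.id = new
        for r in c.residues:
            r.chain_id = new
    shifted.chains.sort(key=lambda c: c.id)
    shifted.label = "shifted"
    m = pairwise_rmsd([s, shifted], positional_correspondence, pentamer_mode=True)
    assert m.values[0, 1] < 1e-6


def test_unmatchable_pair_flagged_missing(pentamer, homologs):
    s, _ = pentamer
    _, sb, _, _ = homologs  # single chain, shorter by the loop-E deletion
    m = pairwise_rmsd([s, sb], positional_correspondence)
    assert np.isnan(m.values[0, 1])


# ---------------------------------------------------------------------------
# domain motion


def test_identical_conformations_zero_motion(pentamer, anchor_maps, pore):
    s, _ = pentamer
    corr = positional_correspondence(s, "A", s, "A")
    keys_a = {r.key for r in s.chain("A").residues}
    ecd = domain_keys(s, anchor_maps, "ECD") & keys_a
    tmd = domain_keys(s, anchor_maps, "TMD") & keys_a
    dm = domain_motion(s, s, corr, ecd, tmd, pore[1])
    assert dm.twist == 0.0 and dm.tilt == 0.0
    assert dm.degenerate


@pytest.mark.parametrize("twist", [5.0, 10.0])
def test_planted_twist_recovered(pentamer, anchor_maps, pore, twist):
    s, gt = pentamer
    state = perturb_state(s, gt, twist=twist)
    corrs = [positional_correspondence(s, c, state, c) for c in s.chain_ids]
    ecd = domain_keys(s, anchor_maps, "ECD")
    tmd = domain_keys(s, anchor_maps, "TMD")
    dm = domain_motion(s, state, corrs, ecd, tmd, pore[1])
    assert dm.twist == pytest.approx(twist, abs=0.5)
    assert dm.tilt == pytest.approx(0.0, abs=0.5)


def test_domain_residuals_below_whole_subunit_rmsd(pentamer, anchor_maps, pore):
    s, gt = pentamer
    state = perturb_state(s, gt, twist=10.0, tilt=3.0, noise_sd=0.1, seed=2)
    corrs = [positional_correspondence(s, c, state, c) for c in s.chain_ids]
    ecd = domain_keys(s, anchor_maps, "ECD")
    tmd = domain_keys(s, anchor_maps, "TMD")
    dm = domain_motion(s, state, corrs, ecd, tmd, pore[1])
    whole = superpose_subset(s, state, corrs).rmsd
    assert dm.residual_rmsd_ecd < whole
    assert dm.residual_rmsd_tmd < whole


def test_pore_axis_points_extracellular(pentamer, pore):
    origin, axis = pore
    # construction: pore along +z, ECD above the TMD
    assert abs(axis[2]) > 0.99
    assert axis[2] > 0
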