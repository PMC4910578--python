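"""Least-squares rigid superposition and RMSD bookkeeping.

Everything here is Cα-driven: a :func:`kabsch_fit` over matched Cα pairs,
domain/subunit/pentamer RMSD matrices, and a swing-twist decomposition of
the residual extracellular-domain rotation measured in the trans-membrane
frame (the "twist and tilt" of the two domains relative to one another).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.transform import Rotation

from .structure import Structure

__all__ = [
    "Superposition",
    "RMSDMatrix",
    "DomainMotion",
    "kabsch_fit",
    "apply_fit",
    "superpose_subset",
    "pairwise_rmsd",
    "domain_motion",
    "pore_axis",
]


class FitError(ValueError):
    """Degenerate geometry: too few points or all collinear."""


@dataclass
class Superposition:
    """Rigid map ``x -> R x + t`` minimizing RMSD of the moving set onto the fixed set."""

    rotation: np.ndarray  # (3, 3), proper
    translation: np.ndarray  # (3,)
    rmsd: float
    n_pairs: int
    subset_label: str = "custom"

    def transform(self, points: np.ndarray) -> np.ndarray:
        return points @ self.rotation.T + self.translation


@dataclass
class RMSDMatrix:
    labels: list[str]
    values: np.ndarray  # symmetric, Angstrom; NaN = unmatchable pair
    subset_label: str = "custom"
    mode: str = "structural"

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)

    def entry(self, a: str, b: str) -> float:
        return float(self.values[self.labels.index(a), self.labels.index(b)])


@dataclass
class DomainMotion:
    twist: float  # degrees about the pore axis
    tilt: float  # degrees of axis deviation
    residual_rmsd_ecd: float
    residual_rmsd_tmd: float
    degenerate: bool = False


def kabsch_fit(
    p: np.ndarray, q: np.ndarray, weights: np.ndarray | None = None,
    subset_label: str = "custom",
) -> Superposition:
    """Optimal proper rotation + translation of point set ``p`` onto ``q``.

    Standard Kabsch solution via SVD of the weighted covariance, with the
    reflection branch removed by sign-flipping the smallest singular
    direction.
    """
    p = np.asarray(p, float)
    q = np.asarray(q, float)
    if p.shape != q.shape or p.ndim != 2 or p.shape[1] != 3:
        raise FitError(f"point sets must both be (n, 3); got {p.shape} and {q.shape}")
    n = p.shape[0]
    if n < 3:
        raise FitError(f"need at least 3 point pairs, got {n}")
    if weights is None:
        w = np.full(n, 1.0 / n)
    else:
        w = np.asarray(weights, float)
        if w.shape != (n,) or np.any(w < 0) or w.sum() <= 0:
            raise FitError("weights must be non-negative with positive sum")
        w = w / w.sum()

    cp = w @ p
    cq = w @ q
    pc = p - cp
    qc = q - cq
    h = (pc * w[:, None]).T @ qc
    u, s, vt = np.linalg.svd(h)
    if s[1] < 1e-12:  # rank < 2: collinear or coincident points
        raise FitError("degenerate geometry: points are (nearly) collinear")
    d = np.sign(np.linalg.det(vt.T @ u.T))
    diag = np.diag([1.0, 1.0, d])
    rot = vt.T @ diag @ u.T
    trans = cq - rot @ cp
    delta = pc @ rot.T - qc
    rmsd = float(np.sqrt(np.sum(w * np.sum(delta**2, axis=1))))
    return Superposition(rotation=rot, translation=trans, rmsd=rmsd,
                         n_pairs=n, subset_label=subset_label)


def apply_fit(fit: Superposition, s: Structure) -> Structure:
    """Rigid-transform a whole structure by a fitted superposition."""
    return s.transformed(fit.rotation, fit.translation)


def rmsd_between(p: np.ndarray, q: np.ndarray) -> float:
    """Plain coordinate RMSD with no fitting."""
    p = np.asarray(p, float)
    q = np.asarray(q, float)
    return float(np.sqrt(np.mean(np.sum((p - q) ** 2, axis=1))))


# ---------------------------------------------------------------------------
# correspondence-driven superposition


def _corr_coords(a: Structure, b: Structure, corr, subset_keys_a=None):
    """Cα coordinate pairs of a correspondence, optionally restricted to
    source-side residue keys in ``subset_keys_a``."""
    pa, pb = [], []
    for ka, kb in corr.pairs:
        if subset_keys_a is not None and ka not in subset_keys_a:
            continue
        ra = a.residue(ka)
        rb = b.residue(kb)
        if ra is None or rb is None:
            continue
        ca, cb = ra.calpha, rb.calpha
        if ca is None or cb is None:
            continue
        pa.append(ca.position)
        pb.append(cb.position)
    return np.array(pa), np.array(pb)


def superpose_subset(
    a: Structure,
    b: Structure,
    corrs,
    subset_keys_a=None,
    subset_label: str = "custom",
) -> Superposition:
    """Kabsch fit of ``a`` onto ``b`` over matched Cα pairs.

    ``corrs`` is a single Correspondence or an iterable of them (one per
    chain pair); ``subset_keys_a`` optionally restricts to a set of
    source-side residue keys (a domain definition).
    """
    if not isinstance(corrs, (list, tuple)):
        corrs = [corrs]
    all_a, all_b = [], []
    for corr in corrs:
        pa, pb = _corr_coords(a, b, corr, subset_keys_a)
        if len(pa):
            all_a.append(pa)
            all_b.append(pb)
    if not all_a:
        raise FitError(f"empty subset restriction ({subset_label})")
    pa = np.vstack(all_a)
    pb = np.vstack(all_b)
    if len(pa) < 3:
        raise FitError(f"subset {subset_label!r} covers only {len(pa)} pairs (<3)")
    return kabsch_fit(pa, pb, subset_label=subset_label)


def pairwise_rmsd(
    structures: list[Structure],
    corr_provider,
    subset_label: str = "subunit",
    subset_keys=None,
    pentamer_mode: bool = False,
) -> RMSDMatrix:
    """Symmetric matrix of superposition RMSDs over a structure ensemble.

    ``corr_provider(a, chain_a, b, chain_b)`` must return a Correspondence.
    In ``pentamer_mode`` all chains are matched and each pair's RMSD is the
    minimum over the five cyclic chain-order assignments (mirror
    assignments are never tried); otherwise the first chain of each
    structure is compared.  ``subset_keys(structure) -> set of residue
    keys`` optionally restricts to a domain; chain ids in the returned keys
    are ignored for non-first chains in pentamer mode (the restriction is
    resolved per matched chain pair).
    """
    n = len(structures)
    if n < 2:
        raise ValueError("need at least two structures")
    vals = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            a, b = structures[i], structures[j]
            try:
                if pentamer_mode:
                    r = _pentamer_rmsd(a, b, corr_provider, subset_keys)
                else:
                    corr = corr_provider(a, a.chains[0].id, b, b.chains[0].id)
                    keys = subset_keys(a) if subset_keys else None
                    r = superpose_subset(a, b, corr, keys, subset_label).rmsd
            except (FitError, ValueError):
                r = np.nan
            vals[i, j] = vals[j, i] = r
    return RMSDMatrix(
        labels=[s.label for s in structures],
        values=vals,
        subset_label="pentamer" if pentamer_mode else subset_label,
    )


def _pentamer_rmsd(a: Structure, b: Structure, corr_provider, subset_keys) -> float:
    ids_a = a.chain_ids
    ids_b = b.chain_ids
    if len(ids_a) != len(ids_b):
        raise FitError("pentamer mode needs equal chain counts")
    m = len(ids_a)
    best = np.inf
    for shift in range(m):  # cyclic assignments only, no reflections
        corrs = []
        for k, ca in enumerate(ids_a):
            cb = ids_b[(k + shift) % m]
            corrs.append(corr_provider(a, ca, b, cb))
        keys = subset_keys(a) if subset_keys else None
        try:
            r = superpose_subset(a, b, corrs, keys, "pentamer").rmsd
        except FitError:
            continue
        best = min(best, r)
    if not np.isfinite(best):
        raise FitError("no cyclic assignment could be fitted")
    return best


# ---------------------------------------------------------------------------
# pore axis and domain motion


def pore_axis(s: Structure, m2_keys) -> tuple[np.ndarray, np.ndarray]:
    """(origin, unit axis) of the channel pore.

    Principal axis of the pooled M2-helix Cα cloud, oriented so that the
    extracellular side (the centroid of everything that is not M2) is on
    the positive side.
    """
    pts = []
    for key in m2_keys:
        r = s.residue(key)
        if r is not None and r.calpha is not None:
            pts.append(r.calpha.position)
    pts = np.array(pts)
    if len(pts) < 3:
        raise FitError("too few M2 Cα atoms to define a pore axis")
    center = pts.mean(axis=0)
    cov = np.cov((pts - center).T)
    w, v = np.linalg.eigh(cov)
    axis = v[:, np.argmax(w)]
    other = [r.calpha.position for c in s.chains for r in c.residues
             if r.calpha is not None and r.key not in set(m2_keys)]
    if other:
        up = np.mean(other, axis=0) - center
        if np.dot(axis, up) < 0:
            axis = -axis
    return center, axis / np.linalg.norm(axis)


def domain_motion(
    a: Structure,
    b: Structure,
    corr,
    ecd_keys_a,
    tmd_keys_a,
    axis: np.ndarray,
) -> DomainMotion:
    """Rigid-body decomposition of the inter-domain motion between two states.

    The trans-membrane domains are superposed first; the residual rotation
    that still maps the extracellular domain of ``a`` onto that of ``b`` is
    then expressed in that frame and split (swing-twist decomposition)
    into a *twist* about the reference pore axis and a *tilt* of the axis.
    """
    tmd_fit = superpose_subset(a, b, corr, tmd_keys_a, "TMD")
    a_in_b = apply_fit(tmd_fit, a)
    ecd_fit = superpose_subset(a_in_b, b, corr, ecd_keys_a, "ECD")

    axis = np.asarray(axis, float)
    axis = axis / np.linalg.norm(axis)
    rot = Rotation.from_matrix(ecd_fit.rotation)
    angle = np.degrees(rot.magnitude())
    if angle < 0.1:
        return DomainMotion(0.0, 0.0, ecd_fit.rmsd, tmd_fit.rmsd, degenerate=True)

    # swing-twist: project the quaternion onto the twist axis
    x, y, z, w = rot.as_quat()
    v = np.array([x, y, z])
    proj = np.dot(v, axis) * axis
    twist_quat = np.array([proj[0], proj[1], proj[2], w])
    norm = np.linalg.norm(twist_quat)
    if norm < 1e-12:
        twist_deg = 0.0
    else:
        twist_rot = Rotation.from_quat(twist_quat / norm)
        twist_deg = np.degrees(twist_rot.magnitude())
    swing = rot * Rotation.from_quat(twist_quat / norm).inv() if norm >= 1e-12 else rot
    tilt_deg = np.degrees(swing.magnitude())
    return DomainMotion(
        twist=float(twist_deg),
        tilt=float(tilt_deg),
        residual_rmsd_ecd=ecd_fit.rmsd,
        residual_rmsd_tmd=tmd_fit.rmsd,
    )
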