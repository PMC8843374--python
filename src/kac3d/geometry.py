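"""Rigid-body and internal-coordinate geometry primitives.

The Kabsch solver is the workhorse of every superposition in the
package: it returns the proper rotation (det = +1, reflections
forbidden) and translation minimizing Cα RMSD over the paired points.
"""

from __future__ import annotations

import numpy as np


class DegenerateGeometryError(ValueError):
    """Point sets too small or collinear for a unique rotation."""


def kabsch_superpose(P: np.ndarray, Q: np.ndarray):
    """Optimal proper rotation/translation mapping points Q onto points P.

    Returns ``(R, t, rmsd)`` with ``R @ q + t ≈ p`` for paired rows.
    Requires at least 3 non-collinear pairs.
    """
    P = np.asarray(P, dtype=float)
    Q = np.asarray(Q, dtype=float)
    if P.shape != Q.shape or P.ndim != 2 or P.shape[1] != 3:
        raise ValueError("paired coordinate sets must both have shape (n, 3)")
    n = P.shape[0]
    if n < 3:
        raise DegenerateGeometryError(f"need >= 3 point pairs, got {n}")
    cp = P.mean(axis=0)
    cq = Q.mean(axis=0)
    Pc = P - cp
    Qc = Q - cq
    H = Qc.T @ Pc
    U, S, Vt = np.linalg.svd(H)
    scale = max(S[0], 1.0)
    if S[1] / scale < 1e-9 and np.linalg.norm(Pc) > 1e-9:
        raise DegenerateGeometryError("collinear points: rotation not unique")
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = cp - R @ cq
    msd = (np.sum(Pc * Pc) + np.sum(Qc * Qc) - 2.0 * (S[0] + S[1] + d * S[2])) / n
    rmsd = float(np.sqrt(max(msd, 0.0)))
    return R, t, rmsd


def batched_fragment_rmsd(A: np.ndarray, B: np.ndarray):
    """Optimal-superposition RMSD for many fragment pairs at once.

    A, B: arrays of shape (m, L, 3) holding m paired fragments.
    Returns ``(rmsd, R, t)`` with shapes (m,), (m, 3, 3), (m, 3) such
    that ``R[k] @ b + t[k]`` superposes fragment B[k] onto A[k].
    """
    A = np.asarray(A, dtype=float)
    B = np.asarray(B, dtype=float)
    m, L, _ = A.shape
    ca = A.mean(axis=1, keepdims=True)
    cb = B.mean(axis=1, keepdims=True)
    Ac = A - ca
    Bc = B - cb
    H = np.einsum("mli,mlj->mij", Bc, Ac)
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(U) * np.linalg.det(Vt))
    D = np.repeat(np.eye(3)[None], m, axis=0)
    D[:, 2, 2] = d
    # R = V @ D @ U^T with V = Vt^T
    R = np.einsum("mij,mjk,mlk->mil", Vt.transpose(0, 2, 1), D, U)
    t = ca[:, 0, :] - np.einsum("mij,mj->mi", R, cb[:, 0, :])
    traceS = S[:, 0] + S[:, 1] + d * S[:, 2]
    msd = (np.sum(Ac * Ac, axis=(1, 2)) + np.sum(Bc * Bc, axis=(1, 2)) - 2.0 * traceS) / L
    return np.sqrt(np.clip(msd, 0.0, None)), R, t


def rotation_angle_deg(R1: np.ndarray, R2: np.ndarray) -> float:
    """Angle (degrees) of the relative rotation R1⁻¹R2."""
    tr = float(np.trace(R1.T @ R2))
    cosang = np.clip((tr - 1.0) / 2.0, -1.0, 1.0)
    return float(np.degrees(np.arccos(cosang)))


def dihedral(p0, p1, p2, p3) -> float:
    """Torsion angle in degrees for four points (IUPAC sign convention)."""
    b0 = np.asarray(p0) - np.asarray(p1)
    b1 = np.asarray(p2) - np.asarray(p1)
    b2 = np.asarray(p3) - np.asarray(p2)
    b1n = b1 / np.linalg.norm(b1)
    v = b0 - np.dot(b0, b1n) * b1n
    w = b2 - np.dot(b2, b1n) * b1n
    x = np.dot(v, w)
    y = np.dot(np.cross(b1n, v), w)
    return float(np.degrees(np.arctan2(y, x)))


def place_atom(a, b, c, bond_length: float, bond_angle_deg: float, torsion_deg: float):
    """Place atom D given three predecessors A-B-C, the C-D bond length,
    the B-C-D angle and the A-B-C-D torsion (natural extension reference
    frame construction)."""
    a, b, c = (np.asarray(x, dtype=float) for x in (a, b, c))
    bc = c - b
    bc /= np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    ang = np.radians(bond_angle_deg)
    tor = np.radians(torsion_deg)
    d_local = bond_length * np.array(
        [-np.cos(ang), np.sin(ang) * np.cos(tor), np.sin(ang) * np.sin(tor)]
    )
    rot = np.column_stack([bc, m, n])
    return c + rot @ d_local


def rotation_about_axis(axis: np.ndarray, point: np.ndarray, angle_deg: float):
    """Rotation by ``angle_deg`` about the line through ``point`` with
    direction ``axis``; returns (R, t) acting as x -> R x + t."""
    axis = np.asarray(axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    point = np.asarray(point, dtype=float)
    th = np.radians(angle_deg)
    K = np.array(
        [[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]], [-axis[1], axis[0], 0]]
    )
    R = np.eye(3) + np.sin(th) * K + (1 - np.cos(th)) * (K @ K)
    t = point - R @ point
    return R, t
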