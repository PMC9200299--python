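"""Inter-residue and side-chain geometry labels.

Nine geometries are computed per record: the pairwise C-beta distance d, the
inter-residue dihedrals omega (CA_i-CB_i-CB_j-CA_j) and theta
(N_i-CA_i-CB_i-CB_j), the planar angle phi (CA_i-CB_i-CB_j), and up to five
side-chain dihedrals chi_1..chi_5 per residue.  Masking rules:

* glycine has no C-beta, so omega/theta/phi are masked on any pair involving
  a glycine; the distance row survives with CA as the C-beta surrogate;
* chi angles are masked for glycine and alanine (no C-gamma) and proline
  (non-rotameric), and wherever a constitutive atom is absent;
* masked entries carry NaN — downstream code must consult the masks.

Dihedral sign follows the IUPAC convention (clockwise positive when viewed
along the p2->p3 axis); dihedrals live in [-180, 180), planar angles in
[0, 180], everything in degrees.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .antibody_io import FvRecord
from .constants import CHI_ATOMS, MAX_CHI, NO_CB, NO_CHI


def _wrap_deg(a):
    """Map angles into [-180, 180)."""
    return (np.asarray(a) + 180.0) % 360.0 - 180.0


def dihedral(p1, p2, p3, p4):
    """Torsion angle in degrees in [-180, 180); broadcasts over leading axes.

    Raises for degenerate scalar input (collinear central atoms); vectorized
    callers mask those entries instead.
    """
    p1, p2, p3, p4 = (np.asarray(p, dtype=float) for p in (p1, p2, p3, p4))
    b1, b2, b3 = p2 - p1, p3 - p2, p4 - p3
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    m1 = np.cross(n1, b2 / np.linalg.norm(b2, axis=-1, keepdims=True))
    x = (n1 * n2).sum(axis=-1)
    y = (m1 * n2).sum(axis=-1)
    if p1.ndim == 1:
        if np.linalg.norm(n1) < 1e-9 or np.linalg.norm(n2) < 1e-9:
            raise ValueError("degenerate dihedral: collinear points")
    ang = np.degrees(np.arctan2(y, x))
    return _wrap_deg(ang)


def planar_angle(p1, p2, p3):
    """Angle p1-p2-p3 in degrees in [0, 180]; broadcasts over leading axes."""
    p1, p2, p3 = (np.asarray(p, dtype=float) for p in (p1, p2, p3))
    v1, v2 = p1 - p2, p3 - p2
    n1 = np.linalg.norm(v1, axis=-1)
    n2 = np.linalg.norm(v2, axis=-1)
    if p1.ndim == 1 and (n1 < 1e-9 or n2 < 1e-9):
        raise ValueError("degenerate planar angle: zero-length arm")
    cosv = (v1 * v2).sum(axis=-1) / (n1 * n2)
    return np.degrees(np.arccos(np.clip(cosv, -1.0, 1.0)))


@dataclass
class GeometryLabels:
    """The 9 label geometries of one record, with validity masks.

    pair_mask stacks the validity of (d, omega, theta, phi) along the last
    axis; chi_mask marks defined chi angles.  Masked entries of the value
    arrays are NaN.
    """

    d: np.ndarray          # (L, L) Angstroms
    omega: np.ndarray      # (L, L) degrees [-180, 180)
    theta: np.ndarray      # (L, L) degrees [-180, 180)
    phi: np.ndarray        # (L, L) degrees [0, 180]
    chi: np.ndarray        # (L, 5) degrees [-180, 180)
    pair_mask: np.ndarray  # (L, L, 4) bool
    chi_mask: np.ndarray   # (L, 5) bool


def _virtual_cb(record: FvRecord) -> tuple[np.ndarray, np.ndarray]:
    """C-beta coordinates with CA substituted for glycine (distance only)."""
    cb, cb_ok = record.coords("CB")
    ca, ca_ok = record.coords("CA")
    out = cb.copy()
    ok = cb_ok.copy()
    for i in range(record.L):
        if record.res3(i) in NO_CB:
            out[i] = ca[i]
            ok[i] = ca_ok[i]
    return out, ok


def compute_pairwise_geometry(record: FvRecord) -> GeometryLabels:
    """d/omega/theta/phi maps with masks (chi arrays left empty/masked)."""
    L = record.L
    n, n_ok = record.coords("N")
    ca, ca_ok = record.coords("CA")
    cb, cb_ok = record.coords("CB")
    cbv, cbv_ok = _virtual_cb(record)
    gly = np.array([record.res3(i) in NO_CB for i in range(L)])

    with np.errstate(invalid="ignore", divide="ignore"):
        d = np.linalg.norm(cbv[:, None, :] - cbv[None, :, :], axis=-1)
        omega = dihedral(ca[:, None, :], cb[:, None, :],
                         np.broadcast_to(cb[None, :, :], (L, L, 3)),
                         np.broadcast_to(ca[None, :, :], (L, L, 3)))
        theta = dihedral(n[:, None, :], ca[:, None, :], cb[:, None, :],
                         np.broadcast_to(cb[None, :, :], (L, L, 3)))
        phi = planar_angle(ca[:, None, :], cb[:, None, :],
                           np.broadcast_to(cb[None, :, :], (L, L, 3)))

    eye = np.eye(L, dtype=bool)
    m_d = cbv_ok[:, None] & cbv_ok[None, :]
    dihedral_ok = ~gly[:, None] & ~gly[None, :] & ~eye
    m_omega = dihedral_ok & (ca_ok & cb_ok)[:, None] & (ca_ok & cb_ok)[None, :]
    m_theta = dihedral_ok & (n_ok & ca_ok & cb_ok)[:, None] & cb_ok[None, :]
    m_phi = dihedral_ok & (ca_ok & cb_ok)[:, None] & cb_ok[None, :]

    for arr, m in ((d, m_d), (omega, m_omega), (theta, m_theta), (phi, m_phi)):
        arr[~m] = np.nan
    np.fill_diagonal(d, np.where(np.diag(m_d), 0.0, np.nan))

    chi = np.full((L, MAX_CHI), np.nan)
    chi_mask = np.zeros((L, MAX_CHI), dtype=bool)
    return GeometryLabels(d=d, omega=omega, theta=theta, phi=phi, chi=chi,
                          pair_mask=np.stack([m_d, m_omega, m_theta, m_phi], axis=-1),
                          chi_mask=chi_mask)


def compute_chi_angles(record: FvRecord) -> tuple[np.ndarray, np.ndarray]:
    """(L, 5) chi table and mask; undefined or incomplete chi angles are NaN."""
    L = record.L
    chi = np.full((L, MAX_CHI), np.nan)
    mask = np.zeros((L, MAX_CHI), dtype=bool)
    for i in range(L):
        res3 = record.res3(i)
        if res3 in NO_CHI:
            continue
        for k, quad in enumerate(CHI_ATOMS[res3]):
            if all(record.has_atom(i, a) for a in quad):
                pts = [record.atoms[i][a] for a in quad]
                chi[i, k] = dihedral(*pts)
                mask[i, k] = True
    return chi, mask


def compute_geometry(record: FvRecord) -> GeometryLabels:
    """All nine geometries of a record."""
    geom = compute_pairwise_geometry(record)
    geom.chi, geom.chi_mask = compute_chi_angles(record)
    return geom
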