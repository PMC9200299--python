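"""Distribution-to-energy conversion, decoy scoring/ranking, CDR-H3 RMSD,
and Rosetta spline-constraint emission.

Predicted distributions become negative-log-probability tables (with a small
probability floor so empty bins stay finite) knotted at bin centers; cubic
splines — periodic for dihedral outputs, natural for distance and the planar
angle — give a continuous energy.  A structure's score is the sum of the
energy of every valid pairwise term at its measured geometry plus every valid
chi term, optionally restricted to terms touching the CDR-H3 loop.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.interpolate import CubicSpline

from .antibody_io import FvRecord, region_masks
from .constants import CHI_ATOMS, NO_CB
from .discretize import ALL_OUTPUTS, PAIR_OUTPUTS, output_bins
from .geometry import GeometryLabels, compute_geometry
from .network import PredictionSet

BACKBONE_FIT_ATOMS = ("N", "CA", "C")
H3_BACKBONE_ATOMS = ("N", "CA", "C", "O")


class EnergyModel:
    """Per-output -log p tables with continuous spline interpolation.

    Tables: pairwise outputs (L, L, 36), chi outputs (L, 36).  The energy at
    a bin center equals -log(max(p, floor)) exactly; between knots a cubic
    spline interpolates (cyclically for dihedral kinds), which can overshoot
    below the minimum table energy by a small amount (bounded in tests).
    """

    def __init__(self, tables: dict[str, np.ndarray], floor: float = 1e-4):
        self.tables = tables
        self.floor = floor
        self.bins = output_bins()
        self._splines: dict[str, CubicSpline] = {}

    def _spline(self, name: str) -> CubicSpline:
        if name not in self._splines:
            spec = self.bins[name]
            x = spec.centers
            y = self.tables[name]
            if spec.wrap:
                x = np.append(x, x[0] + 360.0)
                y = np.concatenate([y, y[..., :1]], axis=-1)
                self._splines[name] = CubicSpline(x, y, axis=-1, bc_type="periodic")
            else:
                self._splines[name] = CubicSpline(x, y, axis=-1, bc_type="natural")
        return self._splines[name]

    def energy(self, name: str, values: np.ndarray, index) -> np.ndarray:
        """Continuous energies for entries `index` of output `name`.

        `values` are the measured geometry values; `index` is a tuple of
        integer arrays selecting table entries ((i, j) for pairwise outputs,
        (i,) for chi outputs).  Out-of-domain values clamp to the boundary
        knots for non-periodic kinds and wrap for periodic kinds.
        """
        spec = self.bins[name]
        sp = self._spline(name)
        x = sp.x
        v = np.asarray(values, dtype=float)
        if spec.wrap:
            v = (v - x[0]) % 360.0 + x[0]
        v = np.clip(v, x[0], x[-1])
        seg = np.clip(np.searchsorted(x, v, side="right") - 1, 0, len(x) - 2)
        t = v - x[seg]
        # sp.c has shape (4, n_seg, L, L) or (4, n_seg, L)
        coef = sp.c[(slice(None), seg) + tuple(index)]
        return ((coef[0] * t + coef[1]) * t + coef[2]) * t + coef[3]


def to_energies(pred: PredictionSet, floor: float = 1e-4) -> EnergyModel:
    """-log p tables from (ensemble-averaged) predicted distributions."""
    tables = {}
    for name in ALL_OUTPUTS:
        if name in PAIR_OUTPUTS and pred.p_d is None:
            continue
        tables[name] = -np.log(np.maximum(pred.output(name), floor))
    return EnergyModel(tables, floor=floor)


# ---------------------------------------------------------------------------
# scoring

def _scope_masks(record: FvRecord, scope: str):
    L = record.L
    if scope == "all":
        return np.ones((L, L), dtype=bool), np.ones(L, dtype=bool)
    if scope == "h3_only":
        h3 = region_masks(record)["CDR-H3"]
        return h3[:, None] | h3[None, :], h3
    raise ValueError(f"unknown scope {scope!r}")


def score_structure(E: EnergyModel, decoy: FvRecord, scope: str = "all",
                    geom: GeometryLabels | None = None) -> float:
    """Sum of spline energies at the decoy's measured geometries.

    Pairwise terms are skipped wherever the decoy's own validity mask is
    false (missing atoms, glycine rules); `scope='h3_only'` keeps only pair
    terms touching the CDR-H3 loop and chi terms of H3 residues.
    """
    some = next(iter(E.tables.values()))
    if some.shape[0] != decoy.L:
        raise ValueError("energy model length does not match the decoy")
    geom = geom or compute_geometry(decoy)
    pair_scope, res_scope = _scope_masks(decoy, scope)
    total = 0.0
    values = {"d": geom.d, "omega": geom.omega, "theta": geom.theta,
              "phi": geom.phi}
    for ki, name in enumerate(PAIR_OUTPUTS):
        if name not in E.tables:
            continue
        mask = geom.pair_mask[..., ki] & pair_scope
        if name == "d":
            mask = mask & ~np.eye(decoy.L, dtype=bool)  # self-distance carries no signal
        idx = np.nonzero(mask)
        if idx[0].size:
            total += float(E.energy(name, values[name][idx], idx).sum())
    for k in range(5):
        name = f"chi{k + 1}"
        if name not in E.tables:
            continue
        mask = geom.chi_mask[:, k] & res_scope
        idx = np.nonzero(mask)
        if idx[0].size:
            total += float(E.energy(name, geom.chi[idx[0], k], idx).sum())
    return total


# ---------------------------------------------------------------------------
# RMSD

def _kabsch(mobile: np.ndarray, ref: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Rotation + centroids superposing mobile onto ref (least-squares)."""
    mc, rc = mobile.mean(0), ref.mean(0)
    H = (mobile - mc).T @ (ref - rc)
    U, _, Vt = np.linalg.svd(H)
    D = np.diag([1.0, 1.0, np.sign(np.linalg.det(U @ Vt))])
    return U @ D @ Vt, mc, rc


def framework_superpose(decoy: FvRecord, native: FvRecord
                        ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Kabsch fit of the decoy onto the native over framework backbone atoms."""
    fr = region_masks(native)["FR"]
    mob, ref = [], []
    for i in np.nonzero(fr)[0]:
        for a in BACKBONE_FIT_ATOMS:
            if decoy.has_atom(i, a) and native.has_atom(i, a):
                mob.append(decoy.atoms[i][a])
                ref.append(native.atoms[i][a])
    if len(mob) < 3:
        raise ValueError("fewer than 3 shared framework backbone atoms")
    return _kabsch(np.array(mob), np.array(ref))


def cdr_h3_rmsd(decoy: FvRecord, native: FvRecord) -> float:
    """Backbone heavy-atom RMSD of the CDR-H3 loop after framework alignment.

    The decoy is superposed on the native over framework N/CA/C atoms
    (no refit on the loop); the RMSD runs over H3 N/CA/C/O atoms present in
    both structures.
    """
    if [n for n in decoy.numbering] != [n for n in native.numbering]:
        raise ValueError("decoy and native numbering differ")
    R, mc, rc = framework_superpose(decoy, native)
    h3 = np.nonzero(region_masks(native)["CDR-H3"])[0]
    mob, ref = [], []
    n_expected = 0
    for i in h3:
        for a in H3_BACKBONE_ATOMS:
            n_expected += 1
            if decoy.has_atom(i, a) and native.has_atom(i, a):
                mob.append(decoy.atoms[i][a])
                ref.append(native.atoms[i][a])
    if not mob:
        raise ValueError("no shared CDR-H3 backbone atoms")
    if len(mob) < n_expected:
        warnings.warn("CDR-H3 RMSD computed over a partial atom set")
    mob = (np.array(mob) - mc) @ R + rc
    diff = mob - np.array(ref)
    return float(np.sqrt((diff ** 2).sum(axis=1).mean()))


@dataclass
class DecoyResult:
    """Scores and RMSDs of a ranked decoy set."""

    names: list[str]
    scores: np.ndarray
    rmsds: np.ndarray
    order: np.ndarray       # indices sorted by ascending score (stable)
    top1_rmsd: float
    top5_rmsd: float


def rank_decoys(E: EnergyModel, decoys: list[FvRecord], native: FvRecord,
                scope: str = "all") -> DecoyResult:
    """Score decoys, sort ascending (ties keep input order), report the
    native-RMSD of the best and the minimum RMSD among the 5 best."""
    if not decoys:
        raise ValueError("need at least one decoy")
    scores = np.array([score_structure(E, d, scope=scope) for d in decoys])
    rmsds = np.array([cdr_h3_rmsd(d, native) for d in decoys])
    order = np.argsort(scores, kind="stable")
    top1 = float(rmsds[order[0]])
    top5 = float(rmsds[order[:5]].min()) if len(decoys) >= 5 else top1
    return DecoyResult(names=[d.name for d in decoys], scores=scores,
                       rmsds=rmsds, order=order, top1_rmsd=top1,
                       top5_rmsd=top5)


# ---------------------------------------------------------------------------
# Rosetta constraints

ROSETTA_FLAGS_NOTE = (
    "# Apply with ConstraintSetMover + PackRotamersMover, ref2015 score\n"
    "# function, all constraint weights 1.0, and extended rotamer sampling\n"
    "# flags -ex1 -ex2.\n")


def _spline_line(kind: str, atoms: list[tuple[str, int]], tag: str,
                 x_vals: np.ndarray, y_vals: np.ndarray) -> str:
    atom_str = " ".join(f"{a} {r}" for a, r in atoms)
    xs = " ".join(f"{v:.6f}" for v in x_vals)
    ys = " ".join(f"{v:.6f}" for v in y_vals)
    return f"{kind} {atom_str} SPLINE {tag} NONE 0.0 1.0 0.5 x_axis {xs} y_axis {ys}"


def write_rosetta_constraints(E: EnergyModel, record: FvRecord,
                              geom: GeometryLabels | None = None) -> str:
    """Constraint-file text: one SPLINE line per valid term.

    Pose numbering is 1-based over the concatenated heavy-then-light chains.
    Distance x-axes are in Angstroms, angle/dihedral x-axes in radians
    (Rosetta's units); y-axes are the -log p energies at the bin centers.
    Glycine uses CA as the distance atom and contributes no omega/theta/phi
    or chi lines.  d and omega are symmetric and written once per pair
    (i < j); theta and phi are direction-dependent and written for both
    orderings.
    """
    geom = geom or compute_geometry(record)
    bins = E.bins
    lines = [ROSETTA_FLAGS_NOTE.rstrip()]
    L = record.L

    def dist_atom(i):
        return "CA" if record.res3(i) in NO_CB else "CB"

    centers = {name: bins[name].centers for name in ALL_OUTPUTS}
    rad = {name: np.radians(centers[name]) for name in ALL_OUTPUTS if name != "d"}

    for i in range(L):
        for j in range(L):
            if i < j and geom.pair_mask[i, j, 0] and "d" in E.tables:
                lines.append(_spline_line(
                    "AtomPair", [(dist_atom(i), i + 1), (dist_atom(j), j + 1)],
                    f"d_{i + 1}_{j + 1}", centers["d"], E.tables["d"][i, j]))
            if i < j and geom.pair_mask[i, j, 1] and "omega" in E.tables:
                lines.append(_spline_line(
                    "Dihedral", [("CA", i + 1), ("CB", i + 1), ("CB", j + 1),
                                 ("CA", j + 1)],
                    f"omega_{i + 1}_{j + 1}", rad["omega"],
                    E.tables["omega"][i, j]))
            if i != j and geom.pair_mask[i, j, 2] and "theta" in E.tables:
                lines.append(_spline_line(
                    "Dihedral", [("N", i + 1), ("CA", i + 1), ("CB", i + 1),
                                 ("CB", j + 1)],
                    f"theta_{i + 1}_{j + 1}", rad["theta"],
                    E.tables["theta"][i, j]))
            if i != j and geom.pair_mask[i, j, 3] and "phi" in E.tables:
                lines.append(_spline_line(
                    "Angle", [("CA", i + 1), ("CB", i + 1), ("CB", j + 1)],
                    f"phi_{i + 1}_{j + 1}", rad["phi"], E.tables["phi"][i, j]))
    for i in range(L):
        res3 = record.res3(i)
        for k in range(5):
            name = f"chi{k + 1}"
            if geom.chi_mask[i, k] and name in E.tables:
                quad = CHI_ATOMS[res3][k]
                lines.append(_spline_line(
                    "Dihedral", [(a, i + 1) for a in quad],
                    f"{name}_{i + 1}", rad[name], E.tables[name][i]))
    return "\n".join(lines) + "\n"


def parse_rosetta_constraints(text: str) -> list[dict]:
    """Parse constraint lines emitted by :func:`write_rosetta_constraints`
    (round-trip checks); returns one dict per SPLINE line."""
    out = []
    for line in text.splitlines():
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        kind = parts[0]
        xi = parts.index("x_axis")
        yi = parts.index("y_axis")
        si = parts.index("SPLINE")
        atoms = [(parts[i], int(parts[i + 1])) for i in range(1, si, 2)]
        out.append({
            "kind": kind, "atoms": atoms, "tag": parts[si + 1],
            "x": np.array([float(v) for v in parts[xi + 1:yi]]),
            "y": np.array([float(v) for v in parts[yi + 1:]]),
        })
    return out
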