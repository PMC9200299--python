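"""Desk-scale synthetic antibody-like fixtures.

Generates Fv-like records — two chains with sampled sequences, full heavy-atom
coordinates built from ideal internal coordinates (NeRF), Chothia-style
numbering containing a CDR-H3-like segment, optional missing atoms — plus
dihedral-perturbed decoy ensembles.  Because chains are built from internal
coordinates, torsion extraction and rebuilding are exact inverses: the chi
values drawn by the generator are recovered bit-near-exactly by
``geometry.compute_chi_angles``, which is the closure property all
parameter-recovery tests rest on.

These are geometric idealizations, not physically relaxed antibodies:
frameworks are extended strands, the H3-like segment has varied torsions, and
no packing, clash relief or crystal artifacts are emulated.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import constants as C
from .antibody_io import FvRecord
from .geometry import dihedral

# residue-type weights loosely following antibody variable-domain composition
DEFAULT_COMPOSITION = {
    "A": 0.06, "C": 0.01, "D": 0.05, "E": 0.04, "F": 0.04, "G": 0.09,
    "H": 0.02, "I": 0.03, "K": 0.05, "L": 0.07, "M": 0.02, "N": 0.04,
    "P": 0.04, "Q": 0.05, "R": 0.04, "S": 0.12, "T": 0.08, "V": 0.07,
    "W": 0.03, "Y": 0.05,
}


@dataclass
class SyntheticSpec:
    """Generation parameters; the seed fully determines the output."""

    heavy_len: int = 35
    light_len: int = 25
    h3_len: int = 7
    seed: int = 0
    composition: dict[str, float] | None = None
    missing_atom_rate: float = 0.0
    decoy_noise: float = 25.0  # degrees

    def __post_init__(self):
        if self.heavy_len < 5 or self.light_len < 5:
            raise ValueError("chain lengths must be >= 5")
        if not 0 < self.h3_len <= self.heavy_len - 10:
            raise ValueError("h3_len must fit inside the heavy chain")


# ---------------------------------------------------------------------------
# internal-coordinate (NeRF) placement

def nerf(a, b, c, bond: float, angle_deg: float, torsion_deg: float) -> np.ndarray:
    """Place a new atom at `bond` from c, angle new-c-b, torsion new-c-b-a.

    The torsion satisfies ``dihedral(a, b, c, new) == torsion_deg``.
    """
    ang = np.radians(angle_deg)
    tau = np.radians(torsion_deg)
    bc = c - b
    bc /= np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d = np.array([-bond * np.cos(ang),
                  bond * np.sin(ang) * np.cos(tau),
                  -bond * np.sin(ang) * np.sin(tau)])
    return c + d[0] * bc + d[1] * m + d[2] * n


def _build_chain(seq: str, phi: np.ndarray, psi: np.ndarray, omega: np.ndarray,
                 chi: np.ndarray) -> list[dict[str, np.ndarray]]:
    """Build one chain's heavy atoms from torsions with ideal covalent geometry.

    phi[0] and omega[0] are unused (no preceding residue); psi of the last
    residue only orients its carbonyl oxygen.
    """
    n_res = len(seq)
    residues: list[dict[str, np.ndarray]] = []
    for i in range(n_res):
        res3 = C.ONE_TO_THREE[seq[i]]
        amap: dict[str, np.ndarray] = {}
        if i == 0:
            amap["N"] = np.zeros(3)
            amap["CA"] = np.array([C.BOND_N_CA, 0.0, 0.0])
            ang = np.radians(C.ANGLE_N_CA_C)
            amap["C"] = amap["CA"] + C.BOND_CA_C * np.array(
                [-np.cos(ang), np.sin(ang), 0.0])
        else:
            prev = residues[-1]
            amap["N"] = nerf(prev["N"], prev["CA"], prev["C"],
                             C.BOND_C_N, C.ANGLE_CA_C_N, psi[i - 1])
            amap["CA"] = nerf(prev["CA"], prev["C"], amap["N"],
                              C.BOND_N_CA, C.ANGLE_C_N_CA, omega[i])
            amap["C"] = nerf(prev["C"], amap["N"], amap["CA"],
                             C.BOND_CA_C, C.ANGLE_N_CA_C, phi[i])
        # carbonyl oxygen opposite the next amide nitrogen
        amap["O"] = nerf(amap["N"], amap["CA"], amap["C"],
                         C.BOND_C_O, C.ANGLE_CA_C_O, psi[i] + 180.0)
        if res3 != "GLY":
            amap["CB"] = nerf(amap["C"], amap["N"], amap["CA"],
                              C.BOND_CA_CB, C.ANGLE_N_CA_CB, C.DIHEDRAL_N_C_CA_CB)
        for aname, (p1, p2, p3), bond, angle, torsion in C.SIDECHAIN_TOPOLOGY[res3]:
            if isinstance(torsion, tuple):
                k = torsion[1]
                tau = chi[i, k - 1]
                if torsion[0] == "chi+":
                    tau = (tau + torsion[2] + 180.0) % 360.0 - 180.0
            else:
                tau = torsion
            amap[aname] = nerf(amap[p3], amap[p2], amap[p1], bond, angle, tau)
        residues.append(amap)
    return residues


def extract_backbone_torsions(residues: list[dict[str, np.ndarray]]
                              ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(phi, psi, omega) per residue from chain coordinates (NaN where undefined)."""
    n = len(residues)
    phi = np.full(n, np.nan)
    psi = np.full(n, np.nan)
    omega = np.full(n, np.nan)
    for i, r in enumerate(residues):
        if i > 0:
            p = residues[i - 1]
            phi[i] = dihedral(p["C"], r["N"], r["CA"], r["C"])
            omega[i] = dihedral(p["CA"], p["C"], r["N"], r["CA"])
        if i < n - 1:
            nxt = residues[i + 1]
            psi[i] = dihedral(r["N"], r["CA"], r["C"], nxt["N"])
        else:
            # recover the oxygen-orienting pseudo-psi of the last residue
            psi[i] = dihedral(r["N"], r["CA"], r["C"], r["O"]) % 360.0 - 180.0
    return phi, psi, omega


# ---------------------------------------------------------------------------
# record generation

def _sample_sequence(rng: np.random.Generator, n: int, composition) -> str:
    aas = sorted(composition)
    p = np.array([composition[a] for a in aas], dtype=float)
    p /= p.sum()
    return "".join(rng.choice(aas, size=n, p=p))


def _sample_chi(rng: np.random.Generator, seq: str) -> np.ndarray:
    """Chi draws from the canonical wells {-60, 60, 180} plus small noise."""
    chi = np.full((len(seq), C.MAX_CHI), np.nan)
    wells = np.array([-60.0, 60.0, 180.0])
    for i, aa in enumerate(seq):
        res3 = C.ONE_TO_THREE[aa]
        for k in range(C.N_CHI.get(res3, 0)):
            chi[i, k] = (rng.choice(wells) + rng.normal(0.0, 8.0)
                         + 180.0) % 360.0 - 180.0
    return chi


def _heavy_numbering(heavy_len: int, h3_len: int) -> list[tuple[str, int, str]]:
    """Chothia-style heavy numbering with the H3-like segment at 95-102."""
    post = min(4, heavy_len - h3_len - 1)
    pre = heavy_len - h3_len - post
    numbering = [("H", i + 1, "") for i in range(pre)]
    h3_numbers: list[tuple[int, str]] = []
    for j in range(h3_len):
        if j < 6:
            h3_numbers.append((95 + j, ""))
        elif j >= h3_len - 2:
            h3_numbers.append((101 + (j - (h3_len - 2)), ""))
        else:  # insertion codes at Chothia 100
            h3_numbers.append((100, chr(ord("A") + j - 6)))
    # ensure position 100 itself precedes its insertions when h3_len >= 7
    if h3_len >= 7:
        h3_numbers[5] = (100, "")
        ordered = sorted(h3_numbers, key=lambda t: (t[0], t[1]))
        h3_numbers = ordered
    numbering += [("H", n, ic) for n, ic in h3_numbers]
    numbering += [("H", 103 + i, "") for i in range(post)]
    return numbering


def _framework_phi_psi(rng: np.random.Generator, n: int):
    states = np.array([[-139.0, 135.0], [-119.0, 113.0], [-75.0, 145.0]])
    picks = states[rng.integers(0, len(states), size=n)]
    return picks[:, 0] + rng.normal(0, 5, n), picks[:, 1] + rng.normal(0, 5, n)


def make_fv(spec: SyntheticSpec) -> FvRecord:
    """Generate one Fv-like record with full coordinates and ground truth.

    The returned record's ``meta`` holds the generator draws: per-chain
    backbone torsions, the chi table, and the H3 index range.
    """
    rng = np.random.default_rng(spec.seed)
    comp = spec.composition or DEFAULT_COMPOSITION
    heavy = _sample_sequence(rng, spec.heavy_len, comp)
    light = _sample_sequence(rng, spec.light_len, comp)

    numbering = _heavy_numbering(spec.heavy_len, spec.h3_len)
    numbering += [("L", i + 1, "") for i in range(spec.light_len)]
    post = min(4, spec.heavy_len - spec.h3_len - 1)
    h3_start = spec.heavy_len - spec.h3_len - post
    h3_idx = list(range(h3_start, h3_start + spec.h3_len))

    torsions = {}
    residues_all: list[dict[str, np.ndarray]] = []
    chi_all = []
    for chain, seq in (("H", heavy), ("L", light)):
        n = len(seq)
        phi, psi = _framework_phi_psi(rng, n)
        if chain == "H":  # varied torsions in the H3-like loop
            for i in h3_idx:
                phi[i] = rng.uniform(-150.0, -45.0)
                psi[i] = rng.uniform(-70.0, 160.0)
        omega = np.full(n, C.OMEGA_TRANS)
        chi = _sample_chi(rng, seq)
        residues = _build_chain(seq, phi, psi, omega, chi)
        if chain == "L":  # keep the chains spatially separated
            shift = np.array([0.0, 14.0, 6.0])
            residues = [{k: v + shift for k, v in r.items()} for r in residues]
        torsions[chain] = {"phi": phi, "psi": psi, "omega": omega}
        residues_all.extend(residues)
        chi_all.append(chi)
    chi_table = np.concatenate(chi_all, axis=0)

    if spec.missing_atom_rate > 0:
        for amap in residues_all:
            for aname in list(amap):
                if aname in ("N", "CA", "C"):
                    continue
                if rng.random() < spec.missing_atom_rate:
                    del amap[aname]

    return FvRecord(
        name=f"synth{spec.seed}", heavy_seq=heavy, light_seq=light,
        numbering=numbering, atoms=residues_all, resolution=None,
        meta={"chi": chi_table, "torsions": torsions, "h3_idx": h3_idx,
              "spec_seed": spec.seed})


def build_isolated_residue(res3: str, chi: np.ndarray | None = None
                           ) -> dict[str, np.ndarray]:
    """Single residue with ideal geometry (used for SASA reference maxima)."""
    one = C.THREE_TO_ONE[res3]
    n_chi = C.N_CHI[res3]
    table = np.full((1, C.MAX_CHI), np.nan)
    if n_chi:
        vals = np.full(n_chi, 180.0) if chi is None else np.asarray(chi, dtype=float)
        table[0, :n_chi] = vals
    residues = _build_chain(one, np.array([np.nan]), np.array([135.0]),
                            np.array([np.nan]), table)
    return residues[0]


# ---------------------------------------------------------------------------
# decoys

def _kabsch_apply(mobile: np.ndarray, ref: np.ndarray, coords: np.ndarray
                  ) -> np.ndarray:
    """Superpose `mobile` onto `ref` (both (n,3)) and apply to `coords`."""
    mc, rc = mobile.mean(0), ref.mean(0)
    H = (mobile - mc).T @ (ref - rc)
    U, _, Vt = np.linalg.svd(H)
    sign = np.sign(np.linalg.det(U @ Vt))
    D = np.diag([1.0, 1.0, sign])
    R = U @ D @ Vt
    return (coords - mc) @ R + rc


def _rebuild_sidechain(res3: str, amap: dict[str, np.ndarray],
                       chi_row: np.ndarray) -> None:
    """Re-place CB and the side chain of one residue (in amap, in place)
    from its backbone N/CA/C at the given chi values."""
    if res3 == "GLY":
        return
    amap["CB"] = nerf(amap["C"], amap["N"], amap["CA"],
                      C.BOND_CA_CB, C.ANGLE_N_CA_CB, C.DIHEDRAL_N_C_CA_CB)
    for aname, (p1, p2, p3), bond, angle, torsion in C.SIDECHAIN_TOPOLOGY[res3]:
        if isinstance(torsion, tuple):
            tau = chi_row[torsion[1] - 1]
            if torsion[0] == "chi+":
                tau = (tau + torsion[2] + 180.0) % 360.0 - 180.0
        else:
            tau = torsion
        amap[aname] = nerf(amap[p3], amap[p2], amap[p1], bond, angle, tau)


def make_decoys(native: FvRecord, n: int, noise_deg: float, seed: int,
                region: str = "h3_only") -> tuple[list[FvRecord], np.ndarray]:
    """Dihedral-perturbed decoy ensemble plus true CDR-H3 RMSDs.

    Decoy 0 is always the unperturbed native.  Backbone phi/psi are
    perturbed by Gaussian noise of scale `noise_deg` — restricted to the
    H3-like segment when region='h3_only' — and all side-chain chi angles
    are perturbed regardless of region.  With region='h3_only' the loop is
    rebuilt in place, anchored at its N-terminal side (the far end leaves a
    chain break, as in loop-sampling decoys) so framework atoms stay
    bit-identical to the native; with region='all' whole chains are rebuilt
    and superposed back onto the native backbone.
    """
    from .geometry import compute_chi_angles
    from .scoring import cdr_h3_rmsd  # local import: scoring is downstream

    if n < 1:
        raise ValueError("need at least one decoy")
    if native.atoms is None:
        raise ValueError("native record has no coordinates")
    rng = np.random.default_rng(seed)
    hlen = native.heavy_len
    chains = {"H": list(range(hlen)), "L": list(range(hlen, native.L))}
    h3_idx = sorted(native.meta.get("h3_idx", []))
    if not h3_idx:
        from .antibody_io import region_masks
        h3_idx = sorted(np.nonzero(region_masks(native)["CDR-H3"])[0])
    chi_native, chi_mask = compute_chi_angles(native)

    def copy_atoms():
        return [{k: v.copy() for k, v in a.items()} for a in native.atoms]

    decoys: list[FvRecord] = [FvRecord(
        name=f"{native.name}_decoy0", heavy_seq=native.heavy_seq,
        light_seq=native.light_seq, numbering=list(native.numbering),
        atoms=copy_atoms(), meta={"h3_idx": h3_idx})]

    for di in range(1, n):
        chi = chi_native.copy()
        noise = rng.normal(0, noise_deg, chi.shape)
        chi = np.where(chi_mask, (chi + noise + 180.0) % 360.0 - 180.0, chi)

        if region == "h3_only":
            new_atoms = copy_atoms()
            seg = h3_idx
            prev = new_atoms[seg[0] - 1]
            residues = [native.atoms[i] for i in range(hlen)]
            phi, psi, omega = extract_backbone_torsions(residues)
            for i in seg:
                res3 = native.res3(i)
                amap: dict[str, np.ndarray] = {}
                prev_psi = (psi[i - 1] + (rng.normal(0, noise_deg)
                                          if i - 1 in seg else 0.0))
                amap["N"] = nerf(prev["N"], prev["CA"], prev["C"],
                                 C.BOND_C_N, C.ANGLE_CA_C_N, prev_psi)
                amap["CA"] = nerf(prev["CA"], prev["C"], amap["N"],
                                  C.BOND_N_CA, C.ANGLE_C_N_CA, omega[i])
                amap["C"] = nerf(prev["C"], amap["N"], amap["CA"],
                                 C.BOND_CA_C, C.ANGLE_N_CA_C,
                                 phi[i] + rng.normal(0, noise_deg))
                amap["O"] = nerf(amap["N"], amap["CA"], amap["C"],
                                 C.BOND_C_O, C.ANGLE_CA_C_O,
                                 psi[i] + 180.0)
                _rebuild_sidechain(res3, amap, chi[i])
                new_atoms[i] = amap
                prev = amap
            # side-chain perturbation everywhere else, on the native backbone
            for i in range(native.L):
                if i not in seg:
                    _rebuild_sidechain(native.res3(i), new_atoms[i], chi[i])
        elif region == "all":
            new_atoms = [None] * native.L
            for chain, idx in chains.items():
                seq = "".join(native.sequence[i] for i in idx)
                residues = [native.atoms[i] for i in idx]
                phi, psi, omega = extract_backbone_torsions(residues)
                phi = phi + rng.normal(0, noise_deg, len(idx))
                psi = psi + rng.normal(0, noise_deg, len(idx))
                rebuilt = _build_chain(seq, np.nan_to_num(phi, nan=-120.0),
                                       psi, np.nan_to_num(omega, nan=180.0),
                                       chi[idx])
                mob = np.array([r[a] for r in rebuilt for a in ("N", "CA", "C")])
                ref = np.array([r[a] for r in residues for a in ("N", "CA", "C")])
                all_xyz = np.concatenate([np.stack(list(r.values()))
                                          for r in rebuilt])
                fitted = _kabsch_apply(mob, ref, all_xyz)
                pos = 0
                for local, r in enumerate(rebuilt):
                    fixed = {}
                    for aname in r:
                        fixed[aname] = fitted[pos]
                        pos += 1
                    new_atoms[idx[local]] = fixed
        else:
            raise ValueError(f"unknown region {region!r}")

        # respect the native's missing atoms
        for i in range(native.L):
            new_atoms[i] = {a: v for a, v in new_atoms[i].items()
                            if a in native.atoms[i]}
        decoys.append(FvRecord(
            name=f"{native.name}_decoy{di}", heavy_seq=native.heavy_seq,
            light_seq=native.light_seq, numbering=list(native.numbering),
            atoms=new_atoms, meta={"h3_idx": h3_idx}))

    rmsds = np.array([cdr_h3_rmsd(d, native) for d in decoys])
    return decoys, rmsds


# ---------------------------------------------------------------------------
# datasets

def make_dataset(n_records: int, spec_template: SyntheticSpec | None = None,
                 seed: int = 0, duplicate_fraction: float = 0.0
                 ) -> list[FvRecord]:
    """Varied synthetic records with ids and resolutions for filtering tests.

    Resolutions are drawn uniformly in [1.5, 3.5] A so a 3 A cutoff has work
    to do; `duplicate_fraction` of the records reuse a previous record's
    sequences (fresh id/resolution), exercising identity filtering.
    """
    if n_records < 1:
        raise ValueError("n_records must be >= 1")
    base = spec_template or SyntheticSpec()
    rng = np.random.default_rng(seed)
    records: list[FvRecord] = []
    for i in range(n_records):
        sub = int(rng.integers(0, 2 ** 31 - 1))
        if records and rng.random() < duplicate_fraction:
            src = records[int(rng.integers(0, len(records)))]
            rec = make_fv(SyntheticSpec(
                heavy_len=base.heavy_len, light_len=base.light_len,
                h3_len=base.h3_len, seed=src.meta["spec_seed"],
                composition=base.composition,
                missing_atom_rate=base.missing_atom_rate))
        else:
            rec = make_fv(SyntheticSpec(
                heavy_len=base.heavy_len, light_len=base.light_len,
                h3_len=base.h3_len, seed=sub, composition=base.composition,
                missing_atom_rate=base.missing_atom_rate))
        rec.name = f"fv{i:03d}"
        rec.resolution = float(np.round(rng.uniform(1.5, 3.5), 2))
        records.append(rec)
    return records
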