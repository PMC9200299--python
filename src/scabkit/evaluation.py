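"""Evaluation statistics: relative side-chain SASA, SASA-stratified side-chain
RMSD, cosine dihedral error, framework-aligned C-beta deviation, and
attention-anchor identification.

SASA uses the Shrake-Rupley algorithm (Bio.PDB, probe 1.4 A, 100 sphere
points per atom).  "Relative" side-chain SASA divides a residue's side-chain
heavy-atom SASA by a per-residue-type reference maximum; the default
reference is computed once from isolated ideal-geometry residues (so an
unoccluded residue scores ~1 by construction), with the Tien et al. 2013
theoretical column available as the alternative normalization used for real
structures.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from Bio.PDB.SASA import ShrakeRupley
from Bio.PDB.StructureBuilder import StructureBuilder

from .antibody_io import FvRecord
from .constants import (AA3, BACKBONE_ATOMS, TIEN_THEORETICAL_MAX_SASA,
                        atom_element, heavy_atoms)
from .geometry import dihedral  # noqa: F401  (re-exported convenience)
from .scoring import framework_superpose

_SASA_PROBE = 1.4
_SASA_POINTS = 100


def _as_biopdb(residue_atoms: list[dict[str, np.ndarray]],
               res_names: list[str]):
    """Build a Bio.PDB structure from per-residue atom maps."""
    sb = StructureBuilder()
    sb.init_structure("s")
    sb.init_model(0)
    sb.init_chain("A")
    sb.init_seg("    ")
    for i, (amap, res3) in enumerate(zip(residue_atoms, res_names)):
        sb.init_residue(res3, " ", i + 1, " ")
        for aname, xyz in amap.items():
            sb.init_atom(aname, np.asarray(xyz, dtype=float), 0.0, 1.0, " ",
                         aname, element=atom_element(aname))
    return sb.get_structure()


def _sidechain_atom_names(res3: str) -> list[str]:
    return [a for a in heavy_atoms(res3) if a not in BACKBONE_ATOMS]


def _sc_sasa(residue_atoms, res_names) -> np.ndarray:
    """Side-chain heavy-atom SASA per residue (A^2)."""
    structure = _as_biopdb(residue_atoms, res_names)
    ShrakeRupley(probe_radius=_SASA_PROBE, n_points=_SASA_POINTS).compute(
        structure, level="A")
    out = np.zeros(len(res_names))
    for i, residue in enumerate(structure[0]["A"]):
        sc = set(_sidechain_atom_names(res_names[i]))
        out[i] = sum(a.sasa for a in residue if a.get_name() in sc)
    return out


@lru_cache(maxsize=1)
def ideal_reference_sc_sasa() -> dict[str, float]:
    """Side-chain SASA of each isolated ideal-geometry residue (the default
    normalization reference)."""
    from .synthetic import build_isolated_residue
    ref = {}
    for res3 in AA3:
        amap = build_isolated_residue(res3)
        val = _sc_sasa([amap], [res3])[0]
        ref[res3] = float(val) if val > 0 else np.nan
    return ref


def relative_sc_sasa(record: FvRecord, reference: str = "ideal"
                     ) -> tuple[np.ndarray, np.ndarray]:
    """Per-residue relative side-chain SASA plus a 'partial' flag.

    The flag marks residues with missing side-chain atoms (their value is a
    lower bound).  Glycine has no side-chain heavy atoms and scores 0 with
    the flag set.  ``reference='tien'`` divides by the Tien et al.
    theoretical per-residue maxima instead of the ideal-residue reference.
    """
    if record.atoms is None:
        raise ValueError("record carries no coordinates")
    res_names = [record.res3(i) for i in range(record.L)]
    raw = _sc_sasa(record.atoms, res_names)
    if reference == "ideal":
        ref = ideal_reference_sc_sasa()
    elif reference == "tien":
        ref = TIEN_THEORETICAL_MAX_SASA
    else:
        raise ValueError(f"unknown reference {reference!r}")
    values = np.zeros(record.L)
    partial = np.zeros(record.L, dtype=bool)
    for i, res3 in enumerate(res_names):
        expected = _sidechain_atom_names(res3)
        missing = [a for a in expected if not record.has_atom(i, a)]
        partial[i] = bool(missing) or not expected
        denom = ref.get(res3, np.nan)
        values[i] = raw[i] / denom if np.isfinite(denom) and denom > 0 else 0.0
    return values, partial


# ---------------------------------------------------------------------------
# structural error measures

def _aligned_atoms(pred: FvRecord, native: FvRecord):
    R, mc, rc = framework_superpose(pred, native)

    def fit(x):
        return (np.asarray(x) - mc) @ R + rc
    return fit


def sasa_stratified_error(pred: FvRecord, native: FvRecord,
                          bin_edges: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Mean per-residue side-chain RMSD within relative-SC-SASA bins.

    SASA bins are computed on the native; the prediction is framework-aligned
    globally first.  Returns (per-bin mean, per-bin count); empty bins carry
    NaN, not zero.
    """
    fit = _aligned_atoms(pred, native)
    rel, _ = relative_sc_sasa(native)
    per_res = np.full(native.L, np.nan)
    for i in range(native.L):
        names = [a for a in _sidechain_atom_names(native.res3(i))
                 if pred.has_atom(i, a) and native.has_atom(i, a)]
        if not names:
            continue
        d = fit([pred.atoms[i][a] for a in names]) - np.array(
            [native.atoms[i][a] for a in names])
        per_res[i] = np.sqrt((d ** 2).sum(axis=1).mean())
    edges = np.asarray(bin_edges, dtype=float)
    means = np.full(len(edges) - 1, np.nan)
    counts = np.zeros(len(edges) - 1, dtype=int)
    which = np.searchsorted(edges, rel, side="right") - 1
    in_range = (rel >= edges[0]) & (rel < edges[-1])
    for b in range(len(edges) - 1):
        sel = (which == b) & in_range & np.isfinite(per_res)
        counts[b] = sel.sum()
        if counts[b]:
            means[b] = per_res[sel].mean()
    return means, counts


def dihedral_cosine_error(pred_chi: np.ndarray, native_chi: np.ndarray,
                          mask: np.ndarray, reduce: str = "residue"
                          ) -> np.ndarray:
    """Cosine distance 1 - cos(chi_pred - chi_native) per valid dihedral.

    chi_5 is omitted (sparsely observed).  ``reduce='residue'`` averages
    chi_1..chi_4 per residue (NaN when a residue has no valid chi);
    ``reduce='dihedral'`` averages per chi class over residues.
    """
    diff = np.radians(pred_chi[:, :4] - native_chi[:, :4])
    err = 1.0 - np.cos(diff)
    valid = mask[:, :4]
    err = np.where(valid, err, np.nan)
    if reduce not in ("residue", "dihedral"):
        raise ValueError(f"unknown reduce {reduce!r}")
    axis = 1 if reduce == "residue" else 0
    import warnings as _warnings
    with _warnings.catch_warnings():
        _warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN rows
        return np.nanmean(err, axis=axis)


def framework_cb_deviation(pred: FvRecord, native: FvRecord) -> np.ndarray:
    """Per-residue |C-beta_pred - C-beta_native| (A) after framework alignment.

    Uses CA for glycine.  Requires at least 3 shared framework residues
    (enforced by the Kabsch fit).  NaN where either structure lacks the atom.
    """
    fit = _aligned_atoms(pred, native)
    out = np.full(native.L, np.nan)
    for i in range(native.L):
        atom = "CA" if native.res3(i) == "GLY" else "CB"
        if pred.has_atom(i, atom) and native.has_atom(i, atom):
            out[i] = np.linalg.norm(fit(pred.atoms[i][atom])
                                    - native.atoms[i][atom])
    return out


# ---------------------------------------------------------------------------
# attention interpretation

@dataclass
class AttentionProfile:
    """Aggregated per-position attention with top-k anchor positions."""

    scores: np.ndarray    # raw aggregated attention received per position
    percent: np.ndarray   # normalized so the maximum position is 100
    anchors: np.ndarray   # top-k positions (ties resolved to lower index)


def attention_anchors(attn: np.ndarray, k: int = 8) -> AttentionProfile:
    """Identify anchor positions from a (heads, L, L) attention stack.

    A position's score is the mean attention it *receives*, averaged over
    heads and query positions (column mean); anchors are the k highest
    scoring positions, ties resolved toward the lower sequence index.
    """
    attn = np.asarray(attn)
    if attn.ndim != 3:
        raise ValueError("attention must be (heads, L, L)")
    L = attn.shape[-1]
    if k > L:
        raise ValueError(f"k={k} exceeds sequence length {L}")
    scores = attn.mean(axis=(0, 1))
    percent = 100.0 * scores / scores.max()
    order = np.argsort(-scores, kind="stable")
    return AttentionProfile(scores=scores, percent=percent,
                            anchors=order[:k])


# ---------------------------------------------------------------------------
# report

def evaluation_report(pred: FvRecord, native: FvRecord):
    """Per-residue evaluation table (pandas DataFrame): region, relative
    SC SASA, side-chain RMSD, cosine dihedral error, C-beta deviation."""
    import pandas as pd

    from .geometry import compute_chi_angles
    rel, partial = relative_sc_sasa(native)
    chi_p, mask_p = compute_chi_angles(pred)
    chi_n, mask_n = compute_chi_angles(native)
    cos_err = dihedral_cosine_error(chi_p, chi_n, mask_p & mask_n)
    cb_dev = framework_cb_deviation(pred, native)
    fit = _aligned_atoms(pred, native)
    sc_rmsd = np.full(native.L, np.nan)
    for i in range(native.L):
        names = [a for a in _sidechain_atom_names(native.res3(i))
                 if pred.has_atom(i, a) and native.has_atom(i, a)]
        if names:
            d = fit([pred.atoms[i][a] for a in names]) - np.array(
                [native.atoms[i][a] for a in names])
            sc_rmsd[i] = np.sqrt((d ** 2).sum(axis=1).mean())
    region = native.region
    return pd.DataFrame({
        "chain": [n[0] for n in native.numbering],
        "number": [n[1] for n in native.numbering],
        "icode": [n[2] for n in native.numbering],
        "region": region,
        "rel_sasa": rel,
        "sasa_partial": partial,
        "sc_rmsd": sc_rmsd,
        "cosine_error": cos_err,
        "cb_dev": cb_dev,
    })
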