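"""Bin systems for the nine network outputs.

All outputs use 36 bins: distance covers [0, 18] Angstroms in 0.5 A steps;
uniform dihedrals cover [-180, 180) in 10 degree steps; the planar angle
covers [0, 180] in 5 degree steps.  chi_1 uses 36 non-uniform bins — 30 fine
bins of 6 degrees clustered around the rotameric wells at -60, 60 and 180
degrees (each well sits at a fine-bin *center*) and 6 coarse bins of 30
degrees covering the barriers between wells.

Placing the wells at fine-bin centers forces all edges to lie at 3 mod 6
degrees, so the chi_1 bin system is laid out on the wrapped domain
[-177, 183): the 180-degree cluster straddles the +/-180 cut with the bin
(177, 183) centered exactly at 180.  Bins are half-open [lo, hi); distances
at or beyond 18 A clip into the last bin; wrapped kinds normalize the value
into the domain first (so -180 and +180 land in the same bin).
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

from .geometry import GeometryLabels

N_BINS = 36
KINDS = ("distance", "dihedral_uniform", "planar", "chi1_nonuniform")


@dataclass(frozen=True)
class BinSpec:
    kind: str
    edges: np.ndarray  # 37 strictly increasing boundaries
    wrap: bool

    @property
    def n_bins(self) -> int:
        return len(self.edges) - 1

    @property
    def widths(self) -> np.ndarray:
        return np.diff(self.edges)

    @property
    def centers(self) -> np.ndarray:
        return 0.5 * (self.edges[:-1] + self.edges[1:])


def _chi1_edges() -> np.ndarray:
    """Edge list on [-177, 183]: fine(6 deg) / coarse(30 deg) segments."""
    segments = [(-177, -153, 6), (-153, -93, 30), (-93, -33, 6),
                (-33, 27, 30), (27, 87, 6), (87, 147, 30), (147, 183, 6)]
    edges = [-177.0]
    for lo, hi, w in segments:
        edges.extend(np.arange(lo + w, hi + w / 2, w))
    return np.asarray(edges, dtype=float)


def make_bins(kind: str) -> BinSpec:
    """Build the bin system for one output kind."""
    if kind == "distance":
        return BinSpec(kind, np.linspace(0.0, 18.0, N_BINS + 1), wrap=False)
    if kind == "dihedral_uniform":
        return BinSpec(kind, np.linspace(-180.0, 180.0, N_BINS + 1), wrap=True)
    if kind == "planar":
        return BinSpec(kind, np.linspace(0.0, 180.0, N_BINS + 1), wrap=False)
    if kind == "chi1_nonuniform":
        return BinSpec(kind, _chi1_edges(), wrap=True)
    raise ValueError(f"unknown bin kind: {kind!r}")


def bin_value(spec: BinSpec, v) -> np.ndarray | int:
    """Map continuous value(s) to bin indices 0..35.

    NaN (the mask sentinel) raises — callers must mask first.  Out-of-range
    distances clip into the edge bins; the planar upper bound 180 maps to the
    last bin; wrapped kinds are normalized into the spec's domain.
    """
    arr = np.asarray(v, dtype=float)
    if np.isnan(arr).any():
        raise ValueError("bin_value received the masked sentinel (NaN)")
    lo = spec.edges[0]
    if spec.wrap:
        arr = (arr - lo) % 360.0 + lo
    idx = np.searchsorted(spec.edges, arr, side="right") - 1
    idx = np.clip(idx, 0, spec.n_bins - 1)
    return idx if idx.ndim else int(idx)


def bin_center(spec: BinSpec, index) -> np.ndarray | float:
    """Arithmetic midpoint of a bin (the wrap cut never splits a bin)."""
    idx = np.asarray(index)
    if (idx < 0).any() or (idx >= spec.n_bins).any():
        raise IndexError("bin index out of range")
    c = spec.centers[idx]
    return c if c.ndim else float(c)


OUTPUT_KINDS = {
    "d": "distance", "omega": "dihedral_uniform", "theta": "dihedral_uniform",
    "phi": "planar",
    "chi1": "chi1_nonuniform", "chi2": "dihedral_uniform",
    "chi3": "dihedral_uniform", "chi4": "dihedral_uniform",
    "chi5": "dihedral_uniform",
}
PAIR_OUTPUTS = ("d", "omega", "theta", "phi")
CHI_OUTPUTS = ("chi1", "chi2", "chi3", "chi4", "chi5")
ALL_OUTPUTS = PAIR_OUTPUTS + CHI_OUTPUTS


def output_bins() -> dict[str, BinSpec]:
    """One BinSpec per network output."""
    return {name: make_bins(kind) for name, kind in OUTPUT_KINDS.items()}


def export_edges_json() -> str:
    """Bin edges of all four kinds as JSON (single source of truth for docs
    and the constraint writer)."""
    return json.dumps({kind: list(make_bins(kind).edges) for kind in KINDS},
                      indent=2)


@dataclass
class LabelTensors:
    """Integer class labels aligned with GeometryLabels; -1 = ignore."""

    d: np.ndarray      # (L, L)
    omega: np.ndarray
    theta: np.ndarray
    phi: np.ndarray
    chi: np.ndarray    # (L, 5)

    def output(self, name: str) -> np.ndarray:
        """Label array for a named output ('d', ..., 'chi5')."""
        if name in PAIR_OUTPUTS:
            return getattr(self, name)
        if name in CHI_OUTPUTS:
            return self.chi[:, int(name[3]) - 1]
        raise KeyError(name)


def discretize_labels(geom: GeometryLabels) -> LabelTensors:
    """Bin all geometry labels; masked entries get the ignore label -1."""
    specs = output_bins()

    def binned(values, mask, spec):
        out = np.full(values.shape, -1, dtype=np.int64)
        if mask.any():
            out[mask] = bin_value(spec, values[mask])
        return out

    chi = np.stack([binned(geom.chi[:, k], geom.chi_mask[:, k],
                           specs[f"chi{k + 1}"])
                    for k in range(geom.chi.shape[1])], axis=1)
    return LabelTensors(
        d=binned(geom.d, geom.pair_mask[..., 0], specs["d"]),
        omega=binned(geom.omega, geom.pair_mask[..., 1], specs["omega"]),
        theta=binned(geom.theta, geom.pair_mask[..., 2], specs["theta"]),
        phi=binned(geom.phi, geom.pair_mask[..., 3], specs["phi"]),
        chi=chi,
    )
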