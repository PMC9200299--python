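"""Energy models, decoy scoring/ranking, CDR-H3 RMSD, and the Rosetta
constraint writer."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from scabkit.antibody_io import FvRecord
from scabkit.discretize import ALL_OUTPUTS, N_BINS, PAIR_OUTPUTS, output_bins
from scabkit.geometry import compute_geometry
from scabkit.network import PredictionSet
from scabkit.scoring import (EnergyModel, cdr_h3_rmsd,
                             parse_rosetta_constraints, rank_decoys,
                             score_structure, to_energies,
                             write_rosetta_constraints)
from scabkit.synthetic import SyntheticSpec, make_decoys, make_fv


def uniform_prediction(L):
    uni = np.full((L, L, N_BINS), 1.0 / N_BINS)
    return PredictionSet(p_d=uni.copy(), p_omega=uni.copy(),
                         p_theta=uni.copy(), p_phi=uni.copy(),
                         p_chi=np.full((5, L, N_BINS), 1.0 / N_BINS),
                         attention=np.full((1, L, L), 1.0 / L))


def native_delta_prediction(record, sharpness=1.0):
    """Distributions concentrated on the native's bins (uniform where
    masked)."""
    from scabkit.discretize import discretize_labels
    labels = discretize_labels(compute_geometry(record))
    L = record.L

    def expand(lab):
        p = np.full(lab.shape + (N_BINS,), (1.0 - sharpness) / N_BINS)
        ok = lab >= 0
        p[ok, lab[ok]] += sharpness
        p[~ok] = 1.0 / N_BINS
        return p

    return PredictionSet(
        p_d=expand(labels.d), p_omega=expand(labels.omega),
        p_theta=expand(labels.theta), p_phi=expand(labels.phi),
        p_chi=np.stack([expand(labels.chi[:, k]) for k in range(5)]),
        attention=np.full((1, L, L), 1.0 / L))


class TestEnergyModel:
    def test_uniform_distribution_flat_at_ln36(self, small_record):
        E = to_energies(uniform_prediction(small_record.L))
        for name in ALL_OUTPUTS:
            spec = output_bins()[name]
            idx = ((np.zeros(5, int), np.zeros(5, int)) if name in PAIR_OUTPUTS
                   else (np.zeros(5, int),))
            vals = np.linspace(spec.edges[0] + 0.01, spec.edges[-1] - 0.01, 5)
            e = E.energy(name, vals, idx)
            assert np.allclose(e, np.log(36), atol=1e-9), name

    def test_energy_at_knots_equals_table(self, small_record):
        rng = np.random.default_rng(0)
        L = small_record.L
        p = rng.dirichlet(np.ones(N_BINS), size=(L, L))
        pred = uniform_prediction(L)
        pred.p_omega = p
        E = to_energies(pred)
        spec = output_bins()["omega"]
        ii = np.full(36, 2)
        jj = np.full(36, 5)
        e = E.energy("omega", spec.centers, (ii, jj))
        assert np.allclose(e, -np.log(np.maximum(p[2, 5], 1e-4)), atol=1e-9)

    def test_delta_distribution_minimum_at_bin_center(self):
        table = {"d": np.zeros((1, 1, N_BINS))}
        p = np.full((1, 1, N_BINS), 1e-4)
        p[0, 0, 10] = 1.0
        E = EnergyModel({"d": -np.log(np.maximum(p, 1e-4))})
        spec = output_bins()["d"]
        grid = np.linspace(0.3, 17.7, 500)
        e = E.energy("d", grid, (np.zeros(500, int), np.zeros(500, int)))
        assert abs(grid[np.argmin(e)] - spec.centers[10]) < 0.1

    def test_periodic_spline_continuous_across_wrap(self, rng):
        p = rng.dirichlet(np.ones(N_BINS), size=(1,))
        E = EnergyModel({"chi2": -np.log(np.maximum(p, 1e-4))})
        lo = E.energy("chi2", np.array([-179.999]), (np.zeros(1, int),))
        hi = E.energy("chi2", np.array([179.999]), (np.zeros(1, int),))
        assert abs(lo[0] - hi[0]) < 1e-3

    def test_spline_overshoot_bounded(self, rng):
        for _ in range(20):
            p = rng.dirichlet(np.full(N_BINS, 0.3), size=(1,))
            E = EnergyModel({"chi2": -np.log(np.maximum(p, 1e-4))})
            grid = np.linspace(-180, 180, 2000)
            e = E.energy("chi2", grid, (np.zeros(grid.size, int),))
            floor = (-np.log(np.maximum(p, 1e-4))).min()
            assert e.min() > floor - 2.0  # documented overshoot tolerance


class TestScoreStructure:
    def test_uniform_energies_score_counts_terms(self, small_record):
        E = to_energies(uniform_prediction(small_record.L))
        geom = compute_geometry(small_record)
        L = small_record.L
        off_diag = ~np.eye(L, dtype=bool)
        n_terms = (int((geom.pair_mask[..., 0] & off_diag).sum())
                   + int(geom.pair_mask[..., 1:].sum())
                   + int(geom.chi_mask.sum()))
        score = score_structure(E, small_record, scope="all")
        assert score == pytest.approx(n_terms * np.log(36), rel=1e-9)

    def test_uniform_energies_identical_for_all_decoys(self, small_record):
        E = to_energies(uniform_prediction(small_record.L))
        decoys, _ = make_decoys(small_record, 3, 30.0, seed=1)
        scores = [score_structure(E, d) for d in decoys]
        assert np.allclose(scores, scores[0], rtol=1e-9)

    def test_native_delta_energies_make_native_minimal(self, small_record):
        E = to_energies(native_delta_prediction(small_record))
        decoys, _ = make_decoys(small_record, 6, 30.0, seed=2, region="all")
        scores = [score_structure(E, d) for d in decoys]
        assert np.argmin(scores) == 0

    def test_scope_all_dominates_h3_only(self, small_record):
        E = to_energies(uniform_prediction(small_record.L))
        assert score_structure(E, small_record, "all") >= \
            score_structure(E, small_record, "h3_only")

    def test_two_residue_hand_fixture(self):
        rec = make_fv(SyntheticSpec(heavy_len=16, light_len=8, h3_len=5,
                                    seed=7))
        E = to_energies(uniform_prediction(rec.L))
        # by-hand count for the h3 scope
        geom = compute_geometry(rec)
        from scabkit.antibody_io import region_masks
        h3 = region_masks(rec)["CDR-H3"]
        pair_scope = h3[:, None] | h3[None, :]
        off_diag = ~np.eye(rec.L, dtype=bool)
        n = (int((geom.pair_mask[..., 0] & pair_scope & off_diag).sum())
             + int((geom.pair_mask[..., 1:]
                    & pair_scope[..., None]).sum())
             + int(geom.chi_mask[h3].sum()))
        assert score_structure(E, rec, "h3_only") == pytest.approx(
            n * np.log(36), rel=1e-9)

    def test_length_mismatch_rejected(self, small_record, fv_record):
        E = to_energies(uniform_prediction(small_record.L))
        with pytest.raises(ValueError, match="length"):
            score_structure(E, fv_record)


class TestCdrH3Rmsd:
    def test_native_vs_itself_is_zero(self, small_record):
        assert cdr_h3_rmsd(small_record, small_record) == pytest.approx(0.0)

    def test_rigid_transform_invariance(self, small_record):
        R = Rotation.from_euler("xyz", [30, -60, 100], degrees=True).as_matrix()
        t = np.array([5.0, -3.0, 8.0])
        moved = FvRecord(
            name="m", heavy_seq=small_record.heavy_seq,
            light_seq=small_record.light_seq,
            numbering=list(small_record.numbering),
            atoms=[{a: v @ R.T + t for a, v in amap.items()}
                   for amap in small_record.atoms])
        assert cdr_h3_rmsd(moved, small_record) == pytest.approx(0.0, abs=1e-9)

    def test_single_displaced_atom_closed_form(self, small_record):
        from scabkit.antibody_io import region_masks
        h3 = np.nonzero(region_masks(small_record)["CDR-H3"])[0]
        moved = FvRecord(
            name="m", heavy_seq=small_record.heavy_seq,
            light_seq=small_record.light_seq,
            numbering=list(small_record.numbering),
            atoms=[{a: v.copy() for a, v in amap.items()}
                   for amap in small_record.atoms])
        moved.atoms[h3[2]]["O"] += np.array([0.0, 0.0, 1.0])
        n = 4 * len(h3)  # N, CA, C, O per H3 residue
        assert cdr_h3_rmsd(moved, small_record) == pytest.approx(
            np.sqrt(1.0 / n), abs=1e-9)

    def test_partial_atoms_warn(self, small_record):
        moved = FvRecord(
            name="m", heavy_seq=small_record.heavy_seq,
            light_seq=small_record.light_seq,
            numbering=list(small_record.numbering),
            atoms=[{a: v.copy() for a, v in amap.items()}
                   for amap in small_record.atoms])
        from scabkit.antibody_io import region_masks
        h3 = np.nonzero(region_masks(small_record)["CDR-H3"])[0]
        del moved.atoms[h3[0]]["O"]
        with pytest.warns(UserWarning, match="partial"):
            cdr_h3_rmsd(moved, small_record)


class TestRankDecoys:
    def test_tied_scores_keep_input_order(self, small_record):
        E = to_energies(uniform_prediction(small_record.L))
        decoys, rmsds = make_decoys(small_record, 6, 25.0, seed=3)
        res = rank_decoys(E, decoys, small_record)
        assert res.order[0] == 0
        assert res.top1_rmsd == pytest.approx(rmsds[0])

    def test_native_delta_puts_native_first(self, small_record):
        E = to_energies(native_delta_prediction(small_record))
        decoys, _ = make_decoys(small_record, 8, 25.0, seed=3, region="all")
        res = rank_decoys(E, decoys, small_record)
        assert res.top1_rmsd == pytest.approx(0.0, abs=1e-9)
        assert res.top5_rmsd <= res.top1_rmsd + 1e-12

    def test_manual_ranking_of_six(self, small_record, monkeypatch):
        E = to_energies(uniform_prediction(small_record.L))
        decoys, _ = make_decoys(small_record, 6, 25.0, seed=4)
        fake_scores = iter([3.0, 1.0, 2.0, 5.0, 0.5, 4.0])
        monkeypatch.setattr("scabkit.scoring.score_structure",
                            lambda *a, **k: next(fake_scores))
        res = rank_decoys(E, decoys, small_record)
        assert res.order.tolist() == [4, 1, 2, 0, 5, 3]
        assert res.top1_rmsd == pytest.approx(res.rmsds[4])
        assert res.top5_rmsd == pytest.approx(res.rmsds[[4, 1, 2, 0, 5]].min())

    def test_empty_decoy_list_rejected(self, small_record):
        E = to_energies(uniform_prediction(small_record.L))
        with pytest.raises(ValueError):
            rank_decoys(E, [], small_record)

    def test_monotone_ranking_sanity(self, small_record):
        """Median score of noisier ensembles never decreases under a
        native-delta energy model."""
        E = to_energies(native_delta_prediction(small_record))
        medians = []
        for noise in (5.0, 20.0, 45.0):
            scores = []
            for seed in range(3):
                decoys, _ = make_decoys(small_record, 5, noise, seed=seed,
                                        region="all")
                scores += [score_structure(E, d) for d in decoys[1:]]
            medians.append(np.median(scores))
        assert medians[0] <= medians[1] <= medians[2]


@pytest.fixture(scope="module")
def five_residue_record():
    from scabkit.synthetic import _build_chain
    heavy, light = "GAS", "RD"
    chi = np.full((5, 5), np.nan)
    chi[2, 0] = -60.0           # SER chi1
    chi[3, :5] = (-60, 170, 60, 180, 0)   # ARG
    chi[4, :2] = (60, 120)      # ASP
    resH = _build_chain(heavy, np.array([np.nan, -120, -120]),
                        np.array([135.0, 135, 135]),
                        np.array([np.nan, 180, 180]), chi[:3])
    resL = _build_chain(light, np.array([np.nan, -120]),
                        np.array([135.0, 135]),
                        np.array([np.nan, 180]), chi[3:])
    shift = np.array([0.0, 12.0, 0.0])
    resL = [{k: v + shift for k, v in r.items()} for r in resL]
    return FvRecord(name="tiny", heavy_seq=heavy, light_seq=light,
                    numbering=[("H", 1, ""), ("H", 2, ""), ("H", 3, ""),
                               ("L", 1, ""), ("L", 2, "")],
                    atoms=resH + resL)


class TestConstraintWriter:
    def test_line_count_matches_valid_terms(self, five_residue_record):
        rec = five_residue_record
        E = to_energies(uniform_prediction(rec.L))
        geom = compute_geometry(rec)
        text = write_rosetta_constraints(E, rec, geom)
        cons = parse_rosetta_constraints(text)
        L = rec.L
        iu = np.triu_indices(L, k=1)
        expect = (int((geom.pair_mask[..., 0][iu]).sum())       # d, i<j
                  + int((geom.pair_mask[..., 1][iu]).sum())     # omega, i<j
                  + int(geom.pair_mask[..., 2].sum())           # theta, both
                  + int(geom.pair_mask[..., 3].sum())           # phi, both
                  + int(geom.chi_mask.sum()))
        assert len(cons) == expect

    def test_glycine_contributes_no_orientation_lines(self, five_residue_record):
        rec = five_residue_record
        E = to_energies(uniform_prediction(rec.L))
        cons = parse_rosetta_constraints(write_rosetta_constraints(E, rec))
        # residue 1 (pose numbering) is glycine
        for c in cons:
            if c["kind"] in ("Dihedral", "Angle"):
                assert 1 not in [r for _, r in c["atoms"]]
        # but distance lines include it via CA
        d_lines = [c for c in cons if c["kind"] == "AtomPair"]
        gly_pairs = [c for c in d_lines if c["atoms"][0] == ("CA", 1)]
        assert gly_pairs

    def test_round_trip_energies_exact(self, five_residue_record, rng):
        rec = five_residue_record
        pred = uniform_prediction(rec.L)
        pred.p_d = rng.dirichlet(np.ones(N_BINS), size=(rec.L, rec.L))
        pred.p_d = 0.5 * (pred.p_d + pred.p_d.transpose(1, 0, 2))
        E = to_energies(pred)
        cons = parse_rosetta_constraints(write_rosetta_constraints(E, rec))
        for c in cons:
            if c["kind"] != "AtomPair":
                continue
            (a1, r1), (a2, r2) = c["atoms"]
            expect = E.tables["d"][r1 - 1, r2 - 1]
            assert np.abs(c["y"] - expect).max() < 1e-6

    def test_dihedral_axes_in_radians(self, five_residue_record):
        rec = five_residue_record
        E = to_energies(uniform_prediction(rec.L))
        cons = parse_rosetta_constraints(write_rosetta_constraints(E, rec))
        for c in cons:
            if c["kind"] == "Dihedral":
                assert np.abs(c["x"]).max() < 2 * np.pi
            if c["kind"] == "AtomPair":
                assert c["x"].max() > 17.0  # Angstrom axis
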