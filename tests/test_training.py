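"""Losses, chi weighting, the training loop, entropy and dataset filtering."""

import copy
import warnings

import numpy as np
import pytest

from scabkit.discretize import LabelTensors, N_BINS
from scabkit.network import ModelConfig, PredictionSet
from scabkit.synthetic import SyntheticSpec, make_dataset, make_fv
from scabkit.training import (RunConfig, chi_class_weights,
                              filter_dataset, loss, positional_entropy,
                              sequence_identity, train, _prepare)

MICRO = ModelConfig(res1d_blocks=1, res2d_blocks=2, seq_channels=8,
                    attn_ff_dim=64, head_kernel=1)
MICRO_RUN = RunConfig(epochs=200, lr=1e-2, phase1_epochs=100, rotamer_lr=3e-3,
                      trunk_lr=1e-4, clip_norm=1.0, seed=5, n_models=1,
                      split=1.0)


def _onehot_prediction(labels: LabelTensors, L: int) -> PredictionSet:
    """Probabilities that are exactly one-hot on the labels (uniform where
    masked)."""
    def expand(lab):
        p = np.full(lab.shape + (N_BINS,), 1.0 / N_BINS)
        ok = lab >= 0
        p[ok] = 0.0
        p[ok, lab[ok]] = 1.0
        return p

    return PredictionSet(
        p_d=expand(labels.d), p_omega=expand(labels.omega),
        p_theta=expand(labels.theta), p_phi=expand(labels.phi),
        p_chi=np.stack([expand(labels.chi[:, k]) for k in range(5)]),
        attention=np.full((1, L, L), 1.0 / L))


def _labels_with_counts(counts):
    """LabelTensors whose chi columns have the given numbers of valid rows."""
    n = max(counts)
    chi = np.full((n, 5), -1, dtype=np.int64)
    for k, c in enumerate(counts):
        chi[:c, k] = 0
    z = np.full((1, 1), -1, dtype=np.int64)
    return LabelTensors(d=z, omega=z, theta=z, phi=z, chi=chi)


class TestLoss:
    def test_one_hot_correct_prediction_has_zero_loss(self, small_record):
        encs, labels = _prepare([small_record])
        pred = _onehot_prediction(labels[0], small_record.L)
        lb = loss(pred, labels[0])
        assert lb.total == pytest.approx(0.0, abs=1e-12)

    def test_uniform_prediction_gives_ln36_per_output(self, small_record):
        _, labels = _prepare([small_record])
        L = small_record.L
        uni = np.full((L, L, N_BINS), 1.0 / N_BINS)
        pred = PredictionSet(p_d=uni, p_omega=uni, p_theta=uni, p_phi=uni,
                             p_chi=np.full((5, L, N_BINS), 1.0 / N_BINS),
                             attention=np.full((1, L, L), 1.0 / L))
        lb = loss(pred, labels[0])
        for name, ce in lb.per_output.items():
            assert ce == pytest.approx(np.log(36), abs=1e-9), name
        assert lb.pairwise_total == pytest.approx(4 * np.log(36), abs=1e-9)

    def test_masked_entries_provably_excluded(self, small_record):
        _, labels = _prepare([small_record])
        lab = labels[0]
        pred = _onehot_prediction(lab, small_record.L)
        base = loss(pred, lab).total
        # perturb probabilities only where the label is masked
        pred2 = copy.deepcopy(pred)
        masked = lab.omega < 0
        pred2.p_omega[masked] = np.roll(pred2.p_omega[masked], 5, axis=-1)
        assert loss(pred2, lab).total == base

    def test_flipping_unmasked_label_changes_loss(self, small_record):
        _, labels = _prepare([small_record])
        lab = labels[0]
        pred = _onehot_prediction(lab, small_record.L)
        lab2 = copy.deepcopy(lab)
        i, j = np.argwhere(lab2.omega >= 0)[0]
        lab2.omega[i, j] = (lab2.omega[i, j] + 1) % 36
        assert loss(pred, lab2).total > loss(pred, lab).total

    def test_weighted_rotamer_total(self):
        lab = _labels_with_counts([100, 0, 0, 0, 20])
        w = chi_class_weights([lab])
        pred = PredictionSet(
            p_d=None, p_omega=None, p_theta=None, p_phi=None,
            p_chi=np.full((5, 100, N_BINS), 1.0 / N_BINS),
            attention=np.full((1, 100, 100), 0.01))
        lb = loss(pred, lab, w)
        # chi1 weight 1, chi5 weight 5, heads 2-4 excluded
        assert lb.rotamer_total == pytest.approx(6 * np.log(36), abs=1e-9)


class TestChiWeights:
    def test_engineered_five_to_one_ratio(self):
        w = chi_class_weights([_labels_with_counts([100, 0, 0, 0, 20])])
        assert w.w[0] == 1.0
        assert w.w[4] == pytest.approx(5.0)

    def test_serine_only_excludes_later_heads(self):
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")
            w = chi_class_weights([_labels_with_counts([50, 0, 0, 0, 0])])
        assert w.w[0] == 1.0
        assert all(np.isnan(w.w[1:]))
        assert any("excluded" in str(c.message) for c in caught)

    def test_equal_counts_give_unit_weights(self):
        rec = make_fv(SyntheticSpec(heavy_len=16, light_len=8, h3_len=5,
                                    seed=2, composition={"R": 1.0}))
        _, labels = _prepare([rec])
        w = chi_class_weights(labels)
        assert np.allclose(w.w, 1.0)

    def test_duplication_invariance(self, small_record):
        _, labels = _prepare([small_record])
        w1 = chi_class_weights(labels)
        w2 = chi_class_weights(labels * 3)
        assert np.allclose(w1.w, w2.w, equal_nan=True)

    def test_empty_dataset_rejected(self):
        with pytest.raises(ValueError):
            chi_class_weights([])


@pytest.fixture(scope="module")
def micro_records():
    return [make_fv(SyntheticSpec(heavy_len=16, light_len=8, h3_len=5,
                                  seed=s)) for s in (7, 8)]


@pytest.fixture(scope="module")
def micro_result(micro_records):
    return train(micro_records, MICRO, MICRO_RUN)


class TestTrainLoop:
    def test_overfits_two_records(self, micro_result):
        assert micro_result.curves[0][-1]["train"] < 0.2

    def test_seeded_rerun_reproduces_loss_curve(self, micro_records):
        from dataclasses import replace
        short = replace(MICRO_RUN, epochs=6)
        a = train(micro_records, MICRO, short)
        b = train(micro_records, MICRO, short)
        assert [c["train"] for c in a.curves[0]] \
            == [c["train"] for c in b.curves[0]]

    def test_control_variant_trains_on_rotamer_losses_only(self, micro_records):
        cfg = ModelConfig(res1d_blocks=1, seq_channels=8, attn_ff_dim=64,
                          variant="control")
        res = train(micro_records, cfg,
                    RunConfig(epochs=5, lr=1e-3, seed=1, n_models=1, split=1.0))
        assert np.isfinite([c["train"] for c in res.curves[0]]).all()
        assert res.models[0].predict(
            _prepare(micro_records)[0][0]).p_d is None

    def test_validation_split_runs_and_logs(self, micro_records):
        recs = micro_records * 3  # 6 records so a 5/1 split exists
        res = train(recs, MICRO,
                    RunConfig(epochs=2, lr=1e-3, seed=1, n_models=2,
                              split=0.8))
        for curve in res.curves:
            assert np.isfinite([c["val"] for c in curve]).all()

    def test_empty_validation_split_rejected(self, micro_records):
        with pytest.raises(ValueError, match="split"):
            train(micro_records, MICRO,
                  RunConfig(epochs=1, split=0.99, n_models=1))

    def test_empty_dataset_rejected(self):
        with pytest.raises(ValueError):
            train([], MICRO, MICRO_RUN)


class TestPositionalEntropy:
    def test_uniform_twenty_residues(self):
        from scabkit.constants import AA1
        seqs = [{("H", 1, ""): aa} for aa in AA1]
        ent = positional_entropy(seqs)
        assert ent[("H", 1, "")] == pytest.approx(np.log2(20), abs=1e-9)

    def test_invariant_position_is_zero(self):
        ent = positional_entropy([{("H", 1, ""): "A"}] * 10)
        assert ent[("H", 1, "")] == 0.0

    def test_half_and_half_is_one_bit(self):
        seqs = [{("H", 5, ""): "A"}] * 5 + [{("H", 5, ""): "G"}] * 5
        assert positional_entropy(seqs)[("H", 5, "")] == pytest.approx(1.0)

    def test_absent_positions_skipped_and_order_invariant(self):
        seqs = [{("H", 1, ""): "A", ("H", 2, ""): "G"}, {("H", 1, ""): "C"}]
        ent = positional_entropy(seqs)
        assert ent[("H", 2, "")] == 0.0
        assert ent == positional_entropy(seqs[::-1])


class TestFilterDataset:
    def _recs(self):
        return make_dataset(12, SyntheticSpec(heavy_len=16, light_len=8,
                                              h3_len=5), seed=4,
                            duplicate_fraction=0.5)

    def test_resolution_cutoff_strict(self):
        recs = self._recs()
        kept = filter_dataset(recs, max_resolution=3.0)
        assert all(r.resolution <= 3.0 for r in kept)
        assert any(r.resolution > 3.0 for r in recs)

    def test_identity_clustering_keeps_first(self):
        recs = self._recs()
        kept = filter_dataset(recs, max_resolution=10.0, identity_cutoff=0.99)
        seqs = [r.sequence for r in kept]
        assert len(set(seqs)) == len(seqs)
        # first occurrence of each duplicated sequence is the one kept
        first_by_seq = {}
        for r in recs:
            first_by_seq.setdefault(r.sequence, r.name)
        assert all(first_by_seq[r.sequence] == r.name for r in kept)

    def test_exclusion_ids_removed(self):
        recs = self._recs()
        kept = filter_dataset(recs, max_resolution=10.0,
                              exclusion_ids=(recs[0].name, recs[3].name))
        names = {r.name for r in kept}
        assert recs[0].name not in names and recs[3].name not in names

    def test_identity_of_identical_records_is_one(self, small_record):
        assert sequence_identity(small_record, small_record) == 1.0
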