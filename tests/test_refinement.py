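"""Discrepancy ranking and tail selection with discard-and-replace."""

import numpy as np
import pytest

import countreg as cr
from countreg.refine import DiscrepancyRecord
from countreg.synthetic import UNIDENTIFIABLE

from conftest import dummy_dataset


class StubModel:
    """Predicts from a lookup table — isolates ranking from the network."""

    def __init__(self, table):
        self.table = table

    def predict(self, images, batch_size=128):
        return np.array([self.table[im.id] for im in images], dtype=float)


def _records(residuals, flags=None, prefix="r"):
    """Records with noisy label 10 and prediction 10 + residual."""
    flags = flags or [False] * len(residuals)
    recs = []
    for i, (res, flag) in enumerate(zip(residuals, flags)):
        im = cr.LabelledImage(
            pixels=np.zeros((1, 1)), label=10, true_label=20,
            id=f"{prefix}-{i:04d}", noisy=True, unidentifiable=flag,
        )
        recs.append(DiscrepancyRecord(id=im.id, noisy_label=10, predicted_count=10 + res, image=im))
    return sorted(recs, key=lambda r: (-r.residual, r.id))


def _brute_force_select(records, k_over, k_under):
    """Independent enumeration: sort, walk tails, skip unidentifiable."""
    ordered = sorted(records, key=lambda r: (-r.residual, r.id))
    chosen = []
    for rec in ordered:
        if len(chosen) >= k_over:
            break
        if not rec.image.unidentifiable:
            chosen.append(rec.id)
    n_over = len(chosen)
    for rec in reversed(ordered):
        if len(chosen) - n_over >= k_under:
            break
        if not rec.image.unidentifiable and rec.id not in chosen:
            chosen.append(rec.id)
    return sorted(chosen)


class TestRankDiscrepancies:
    def test_sorted_descending_with_id_tiebreak(self):
        ds = dummy_dataset([5, 5, 5, 5], prefix="p")
        model = StubModel({im.id: 5.0 for im in ds})
        records = cr.rank_discrepancies(model, ds)
        assert [r.residual for r in records] == [0.0] * 4
        assert [r.id for r in records] == sorted(ds.ids)

    def test_sort_contract(self):
        ds = dummy_dataset([10, 10, 10, 10], prefix="q")
        preds = {ds.ids[0]: 15.0, ds.ids[1]: 12.0, ds.ids[2]: 9.0, ds.ids[3]: 3.0}
        records = cr.rank_discrepancies(StubModel(preds), ds)
        assert [r.residual for r in records] == [5.0, 2.0, -1.0, -7.0]

    def test_matches_brute_force_sort(self):
        rng = np.random.default_rng(0)
        ds = dummy_dataset(rng.integers(0, 40, size=1000), prefix="big")
        preds = {im.id: float(rng.normal(im.label, 5)) for im in ds}
        records = cr.rank_discrepancies(StubModel(preds), ds)
        expected = sorted(
            ((preds[i] - l, i) for i, l in zip(ds.ids, ds.labels)),
            key=lambda t: (-t[0], t[1]),
        )
        assert [r.id for r in records] == [i for _, i in expected]

    def test_empty_pool_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            cr.rank_discrepancies(StubModel({}), dummy_dataset([]))


class TestSelectRefinementSet:
    def test_worked_example_selects_extremes(self):
        records = _records([5, 2, -1, -7])
        config = cr.RefinementConfig(k_over=1, k_under=1)
        selected, report = cr.select_refinement_set(records, config)
        assert sorted(im.id for im in selected) == sorted([records[0].id, records[-1].id])
        assert all(im.label == 20 and not im.noisy for im in selected)
        assert len(report) == 2

    def test_unidentifiable_top_replaced_by_next_in_tail(self):
        records = _records([5, 2, -1, -7], flags=[True, False, False, False])
        config = cr.RefinementConfig(k_over=1, k_under=0)
        selected, report = cr.select_refinement_set(records, config)
        assert [im.id for im in selected] == [records[1].id]  # the +2 image
        assert report[0]["replaced_flag"] is True

    def test_archive_scale_selection_with_35_replacements(self):
        rng = np.random.default_rng(3)
        residuals = rng.normal(0, 10, size=10_200)
        order = np.argsort(-residuals)
        flags = np.zeros(10_200, dtype=bool)
        flags[order[:20]] = True  # 20 among the worst over-estimates
        flags[order[-15:]] = True  # 15 among the worst under-estimates
        records = _records(residuals, flags=list(flags), prefix="pool")
        config = cr.RefinementConfig(k_over=50, k_under=50)
        selected, report = cr.select_refinement_set(records, config)
        assert len(selected) == 100
        assert len(report) == 100
        assert sum(r["replaced_flag"] for r in report) == 35

    def test_exhausted_tail_reports_shortfall(self):
        records = _records([3, 2, 1], flags=[True, True, False])
        with pytest.raises(ValueError, match="over tail exhausted.*shortfall 1"):
            cr.select_refinement_set(records, cr.RefinementConfig(k_over=2, k_under=0))

    def test_quota_covering_pool_selects_everything_once(self):
        records = _records([4, 1, -2, -6])
        selected, _ = cr.select_refinement_set(records, cr.RefinementConfig(k_over=3, k_under=3))
        assert sorted(im.id for im in selected) == sorted(r.id for r in records)
        assert len(selected) == 4

    @pytest.mark.parametrize("trial", range(50))
    def test_equals_brute_force_enumeration(self, trial):
        rng = np.random.default_rng(trial)
        n = int(rng.integers(4, 30))
        residuals = rng.integers(-8, 8, size=n).astype(float)  # ties likely
        flags = list(rng.random(n) < 0.15)
        records = _records(residuals, flags=flags, prefix=f"t{trial}")
        k_over, k_under = int(rng.integers(0, 5)), int(rng.integers(0, 5))
        config = cr.RefinementConfig(k_over=k_over, k_under=k_under)
        try:
            selected, _ = cr.select_refinement_set(records, config)
        except ValueError:
            return
        assert sorted(im.id for im in selected) == _brute_force_select(
            records, k_over, k_under
        )


class TestRefine:
    def test_id_collision_rejected(self):
        s1 = dummy_dataset([1, 2], prefix="a")
        s2 = dummy_dataset([3, 4], prefix="a")
        with pytest.raises(ValueError, match="share image ids"):
            cr.refine(cr.build_regressor("micro"), s1, s2, cr.RefinementConfig())

    def test_zero_epoch_refine_is_identity(self):
        s1 = dummy_dataset([1] * 6, prefix="a")
        s2 = dummy_dataset([2] * 4, prefix="b")
        model = cr.build_regressor("micro", seed=0)
        ref = model.state_dict()
        config = cr.RefinementConfig(
            finetune_phase=cr.PhaseSpec(epochs=0, section_lrs=(1e-3,) * 3)
        )
        out, history = cr.refine(model, s1, s2, config)
        assert history == []
        assert all(np.array_equal(v, out.state_dict()[k]) for k, v in ref.items())

    def test_merged_split_arithmetic(self):
        merged = dummy_dataset(range(887))
        train, val = cr.train_val_split(merged, 0.8, seed=0)
        assert len(train) == 709 and len(val) == 178
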