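"""Neighbor-ring accuracy, cross-validation, flexibility, and consistency."""

import numpy as np
import pytest

from stripefit import evaluation as ev
from stripefit import labeling as lab
from stripefit import model as model_mod
from stripefit import synthetic as syn
from stripefit.errors import StripefitError
from stripefit.model import FittedModel, ModelSpec, PredictionField

from conftest import make_path_atlas


def field_from_p(atlas, p):
    p = np.asarray(p, float)
    pc = np.clip(p, 1e-12, 1 - 1e-12)
    return PredictionField(nucleus_ids=atlas.nucleus_ids.copy(),
                           eta=np.log(pc / (1 - pc)), p=p)


class TestAccuracyReport:
    def test_perfect_field_scores_100_0_0(self, path_atlas):
        labels = lab.assign_stripes(path_atlas,
                                    lab.binarize(path_atlas.values("eve"), 0.5),
                                    min_size=1)
        fld = field_from_p(path_atlas, path_atlas.values("eve"))
        rep = ev.accuracy_report(fld, labels, {1})
        assert rep.pct_in_stripe == 100.0
        assert rep.pct_ring1 == 0.0 and rep.pct_ring2 == 0.0
        assert (rep.n_stripe, rep.n_ring1, rep.n_ring2) == (2, 2, 2)

    def test_field_spilling_into_ring1_scores_100_100_0(self, path_atlas):
        labels = lab.assign_stripes(path_atlas,
                                    lab.binarize(path_atlas.values("eve"), 0.5),
                                    min_size=1)
        # ON on nuclei 4..7 = stripe {5,6} plus its full ring 1 {4,7}
        p = np.isin(path_atlas.nucleus_ids, [4, 5, 6, 7]).astype(float)
        rep = ev.accuracy_report(field_from_p(path_atlas, p), labels, {1})
        assert (rep.pct_in_stripe, rep.pct_ring1, rep.pct_ring2) == (100.0, 100.0, 0.0)

    def test_empty_ring_reports_none_not_zero(self):
        # ON block at the end of the path: ring 2 of stripe 1 is empty
        a = make_path_atlas(n=4, on_ids=(1, 2, 3))
        labels = lab.assign_stripes(a, lab.binarize(a.values("eve"), 0.5), min_size=1)
        assert labels.ring1[1] == {4} and labels.ring2[1] == set()
        rep = ev.accuracy_report(field_from_p(a, a.values("eve")), labels, {1})
        assert rep.pct_ring2 is None and rep.n_ring2 == 0

    def test_threshold_is_strict(self, path_atlas):
        labels = lab.assign_stripes(path_atlas,
                                    lab.binarize(path_atlas.values("eve"), 0.5),
                                    min_size=1)
        rep = ev.accuracy_report(field_from_p(path_atlas, np.full(10, 0.5)), labels, {1})
        assert rep.pct_in_stripe == 0.0

    def test_mismatched_atlas_is_an_error(self, path_atlas, small_atlas, truth_model):
        fld = model_mod.predict(truth_model, small_atlas)
        labels = lab.assign_stripes(path_atlas,
                                    lab.binarize(path_atlas.values("eve"), 0.5),
                                    min_size=1)
        with pytest.raises(StripefitError, match="share an atlas"):
            ev.accuracy_report(fld, labels, {1})

    def test_truth_model_scores_high_in_stripe_low_outside(self, small_atlas,
                                                           small_labels, truth_model):
        fld = model_mod.predict(truth_model, small_atlas)
        rep = ev.accuracy_report(fld, small_labels, small_labels.stripes)
        assert rep.pct_in_stripe > 80.0
        assert rep.pct_ring1 < 20.0
        assert rep.pct_ring2 <= rep.pct_ring1


class TestCrossValidate:
    def test_deterministic_for_fixed_seed(self, noisy_training_set, noisy_atlas):
        spec = syn.recovery_truth().spec
        a = ev.cross_validate(noisy_training_set, spec, noisy_atlas, reps=5, n=60, seed=3)
        b = ev.cross_validate(noisy_training_set, spec, noisy_atlas, reps=5, n=60, seed=3)
        assert np.array_equal(a.p, b.p)

    def test_single_rep_full_sample_equals_plain_fit(self, noisy_training_set, noisy_atlas):
        spec = syn.recovery_truth().spec
        cv = ev.cross_validate(noisy_training_set, spec, noisy_atlas,
                               reps=1, n=len(noisy_training_set.y), seed=0)
        fm = model_mod.fit(noisy_training_set, spec)
        assert np.allclose(cv.p, model_mod.predict(fm, noisy_atlas).p, atol=1e-12)

    def test_oversized_subsample_is_an_error(self, noisy_training_set, noisy_atlas):
        spec = syn.recovery_truth().spec
        with pytest.raises(StripefitError, match="exceeds"):
            ev.cross_validate(noisy_training_set, spec, noisy_atlas,
                              n=len(noisy_training_set.y) + 1)

    def test_degenerate_subsamples_are_redrawn(self, noisy_training_set, noisy_atlas, caplog):
        """Tiny subsamples frequently land in a single class; the average must
        still come from exactly `reps` two-class fits."""
        spec = model_mod.ModelSpec(regulators=(syn.recovery_truth().spec.regulators[0],))
        import logging
        with caplog.at_level(logging.INFO, logger="stripefit.evaluation"):
            fld = ev.cross_validate(noisy_training_set, spec, noisy_atlas,
                                    reps=30, n=2, seed=0)
        assert np.all((fld.p >= 0) & (fld.p <= 1))
        assert any("redrew" in r.message for r in caplog.records)

    def test_probabilities_average_of_replicates(self, noisy_training_set, noisy_atlas):
        spec = syn.recovery_truth().spec
        ps = []
        for r in range(3):
            sub = lab.restrict_random(noisy_training_set, 80, seed=5 + r)
            fm = model_mod.fit(sub, spec)
            ps.append(model_mod.predict(fm, noisy_atlas).p)
        cv = ev.cross_validate(noisy_training_set, spec, noisy_atlas, reps=3, n=80, seed=5)
        assert np.allclose(cv.p, np.mean(ps, axis=0), atol=1e-12)


class TestRibbon:
    def test_matches_brute_force_band_filter(self, small_atlas, truth_model):
        fld = model_mod.predict(truth_model, small_atlas)
        rib = ev.extract_ribbon(fld, small_atlas, halfwidth=10.0)
        z_mid = 0.5 * (small_atlas.z.min() + small_atlas.z.max())
        mask = np.abs(small_atlas.z - z_mid) <= 10.0
        assert set(rib.nucleus_ids.tolist()) == set(small_atlas.nucleus_ids[mask].tolist())
        assert np.all(np.diff(rib.x) >= 0)
        lookup = dict(zip(fld.nucleus_ids.tolist(), fld.p))
        assert np.allclose(rib.p, [lookup[i] for i in rib.nucleus_ids])

    def test_ribbon_spans_most_of_the_ap_axis(self, small_atlas, truth_model):
        fld = model_mod.predict(truth_model, small_atlas)
        rib = ev.extract_ribbon(fld, small_atlas, halfwidth=15.0)
        extent = small_atlas.x.max() - small_atlas.x.min()
        assert (rib.x.max() - rib.x.min()) > 0.9 * extent

    def test_empty_band_is_an_error(self, small_atlas, truth_model):
        fld = model_mod.predict(truth_model, small_atlas)
        with pytest.raises(StripefitError, match="midline"):
            ev.extract_ribbon(fld, small_atlas, halfwidth=1e-6)


class TestFlexibility:
    def test_true_target_scores_best(self, small_atlas, truth_model):
        """With a seven-stripe decoy channel, the regulators encode only the
        truth stripe; fitting them to arbitrary decoy stripes scores worse."""
        # decoy stripes placed posterior of the truth stripe so components
        # stay disconnected from it
        pat = syn.PatternDef("s3", "mRNA", "stripes",
                             params={"centers": [0.55, 0.7, 0.85]})
        a = small_atlas.with_channel(syn.generate_pattern(small_atlas, pat))
        decoy = np.maximum(a.values("eve"), a.values("s3"))
        a = a.with_channel(type(a.channels[0])("decoy", "mRNA", 1, decoy))
        labels = lab.label_target(a, "decoy")
        truth_stripe = labels.stripes[np.argmin(
            [abs(a.ap_fraction[labels.stripe_id == s].mean() - 0.33)
             for s in labels.stripes])]
        regs = list(truth_model.spec.regulators)
        others = [s for s in labels.stripes if s != truth_stripe][:3]
        res = ev.flexibility_test(a, labels, regs,
                                  [{truth_stripe}] + [{s} for s in others],
                                  quadratic=truth_model.spec.quadratic)
        per_row = {t: r["score"] / max(r["model"].n_train, 1) for t, r in res.items()}
        best = max(per_row, key=per_row.get)
        assert best == frozenset({truth_stripe})
        truth_rep = res[frozenset({truth_stripe})]["report"]
        assert truth_rep.pct_in_stripe > 80.0


class TestConsistencySuite:
    def test_variants_agree_on_well_specified_truth(self, small_atlas, small_labels, truth_model):
        rep = ev.consistency_suite(small_atlas, small_labels, truth_model.spec,
                                   small_labels.stripes, cv_reps=20, cv_n=50)
        assert not rep.errors
        assert {"full", "dv_band", "ap_band", "cross_validation", "max"} <= set(rep.variants)
        scores = [v.pct_in_stripe for v in rep.variants.values()]
        assert all(s is not None and s > 75.0 for s in scores)
        assert max(scores) - min(scores) <= 10.0

    def test_drop_stripe_variants_present_for_multi_stripe_target(self, small_atlas):
        pat = syn.PatternDef("s7", "mRNA", "stripes", params={"n_stripes": 7})
        a = small_atlas.with_channel(syn.generate_pattern(small_atlas, pat))
        labels = lab.label_target(a, "s7")
        spec = model_mod.ModelSpec(regulators=(("Hb", "protein"), ("kni", "mRNA")))
        rep = ev.consistency_suite(a, labels, spec, {3, 4}, cv_reps=5, cv_n=40)
        present = set(rep.variants) | set(rep.errors)
        assert {"drop_stripe_3", "drop_stripe_4"} <= present

    def test_as_dict_round_trips_variant_names(self, small_atlas, small_labels, truth_model):
        rep = ev.consistency_suite(small_atlas, small_labels, truth_model.spec,
                                   small_labels.stripes, cv_reps=2, cv_n=40)
        d = rep.as_dict()
        assert set(d) == set(rep.variants) | set(rep.errors)
        assert all("pct_in_stripe" in v or "error" in v for v in d.values())
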