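"""Accuracy, consistency, flexibility and cross-validation of fitted models.

The canonical accuracy surface is the neighbor-ring metric: the percentage of
nuclei with predicted probability above 0.5 inside the target stripes (true
positives), among their immediate OFF neighbors (ring 1), and among OFF
nuclei two steps away (ring 2).  A good model scores high in the stripe and
drops off sharply across the rings.  Percentages always use the fixed
category sizes as denominators so reports are comparable across models.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from . import labeling as lab
from . import model as model_mod
from .atlas import ExpressionAtlas
from .errors import DegenerateResponseError, StripefitError
from .labeling import StripeLabels, TrainingSet

logger = logging.getLogger(__name__)

P_THRESHOLD = 0.5


@dataclass
class AccuracyReport:
    """Percent of nuclei called ON (p > 0.5) per border category."""

    pct_in_stripe: float | None
    pct_ring1: float | None
    pct_ring2: float | None
    n_stripe: int
    n_ring1: int
    n_ring2: int
    p_threshold: float = P_THRESHOLD
    target_stripes: frozenset = frozenset()

    def as_dict(self) -> dict:
        return {"pct_in_stripe": self.pct_in_stripe, "pct_ring1": self.pct_ring1,
                "pct_ring2": self.pct_ring2, "n_stripe": self.n_stripe,
                "n_ring1": self.n_ring1, "n_ring2": self.n_ring2}


def accuracy_report(field_: model_mod.PredictionField, labels: StripeLabels,
                    target_stripes, p_threshold: float = P_THRESHOLD) -> AccuracyReport:
    """Neighbor-ring accuracy of a prediction field against stripe labels.

    Empty categories report None (undefined), never 0.
    """
    if len(field_.p) != len(labels.nucleus_ids) or not np.array_equal(
            field_.nucleus_ids, labels.nucleus_ids):
        raise StripefitError("prediction field and labels do not share an atlas")
    target_stripes = sorted(int(s) for s in target_stripes)
    on_call = field_.p > p_threshold

    stripe_mask = np.isin(labels.stripe_id, target_stripes)
    r1, r2 = labels.rings_for(target_stripes)
    r1_mask = np.isin(labels.nucleus_ids, sorted(r1))
    r2_mask = np.isin(labels.nucleus_ids, sorted(r2))

    def pct(mask):
        n = int(mask.sum())
        return (100.0 * float(on_call[mask].mean()) if n else None), n

    ps, ns = pct(stripe_mask)
    p1, n1 = pct(r1_mask)
    p2, n2 = pct(r2_mask)
    return AccuracyReport(ps, p1, p2, ns, n1, n2, p_threshold,
                          frozenset(target_stripes))


def cross_validate(ts: TrainingSet, spec: model_mod.ModelSpec, atlas: ExpressionAtlas,
                   reps: int = 100, n: int = 50, seed: int = 0,
                   options: model_mod.FitOptions | None = None) -> model_mod.PredictionField:
    """Average of ``reps`` whole-embryo predictions, each trained on a random
    subsample of ``n`` rows.  Replicate r is seeded seed+r; subsamples that
    contain a single class are redrawn (with a logged count) so exactly
    ``reps`` replicates contribute.
    """
    if n > len(ts.y):
        raise StripefitError(f"subsample size {n} exceeds the {len(ts.y)} training rows")
    acc = np.zeros(atlas.n_nuclei)
    redraws = 0
    for r in range(reps):
        sub_seed = seed + r
        for attempt in range(1000):
            sub = lab.restrict_random(ts, n, seed=sub_seed + 100_000 * attempt)
            if 0 < sub.y.sum() < len(sub.y):
                break
            redraws += 1
        else:  # pragma: no cover - would need pathological class imbalance
            raise DegenerateResponseError("could not draw a two-class subsample")
        fm = model_mod.fit(sub, spec, options)
        acc += model_mod.predict(fm, atlas).p
    if redraws:
        logger.info("cross-validation redrew %d degenerate subsample(s)", redraws)
    p = acc / reps
    pc = np.clip(p, 1e-300, 1.0 - 1e-16)
    eta = np.log(pc / (1.0 - pc))
    return model_mod.PredictionField(nucleus_ids=atlas.nucleus_ids.copy(), eta=eta, p=p)


def flexibility_test(atlas: ExpressionAtlas, labels: StripeLabels, regulators,
                     targets, quadratic=(), options=None) -> dict:
    """Fit the same regulator set to each target stripe-set in turn.

    A non-flexible (i.e. well-behaved) model should fit only the target whose
    expression the regulators actually encode; arbitrary stripes should score
    poorly.  Returns {target: {"report": AccuracyReport, "score": ll}}.
    """
    spec = model_mod.ModelSpec(regulators=tuple(regulators), quadratic=tuple(quadratic))
    out = {}
    for target in targets:
        target = frozenset(int(s) for s in target)
        ts = lab.build_training_set(atlas, labels, target, regulators)
        fm = model_mod.fit(ts, spec, options)
        fld = model_mod.predict(fm, atlas)
        out[target] = {"report": accuracy_report(fld, labels, target),
                       "score": fm.log_likelihood, "model": fm}
    return out


@dataclass
class RibbonProfile:
    """Probabilities for nuclei in a thin band around the lateral midline,
    ordered along the anteroposterior axis."""

    nucleus_ids: np.ndarray
    x: np.ndarray
    p: np.ndarray
    band_halfwidth: float = 10.0


def extract_ribbon(field_: model_mod.PredictionField, atlas: ExpressionAtlas,
                   halfwidth: float = 10.0) -> RibbonProfile:
    """Nuclei within ``halfwidth`` μm of the lateral midline plane, sorted by x."""
    z_mid = 0.5 * (atlas.z.min() + atlas.z.max())
    mask = np.abs(atlas.z - z_mid) <= halfwidth
    if not mask.any():
        raise StripefitError(f"no nuclei within {halfwidth} μm of the midline")
    order = np.argsort(atlas.x[mask], kind="stable")
    return RibbonProfile(nucleus_ids=atlas.nucleus_ids[mask][order],
                         x=atlas.x[mask][order], p=field_.p[mask][order],
                         band_halfwidth=halfwidth)


@dataclass
class ConsistencyReport:
    """Whole-embryo accuracy of one model refit on several training subsets."""

    variants: dict = field(default_factory=dict)   # name -> AccuracyReport
    errors: dict = field(default_factory=dict)     # name -> error message

    def as_dict(self) -> dict:
        d = {k: v.as_dict() for k, v in self.variants.items()}
        d.update({k: {"error": v} for k, v in self.errors.items()})
        return d


def consistency_suite(atlas: ExpressionAtlas, labels: StripeLabels,
                      spec: model_mod.ModelSpec, target_stripes, seed: int = 0,
                      cv_reps: int = 100, cv_n: int = 50,
                      max_ridge: float = 0.0, options=None) -> ConsistencyReport:
    """Refit on restricted training subsets and report whole-embryo accuracy.

    Variants: full fit, DV band (20 μm either side of the lateral midline),
    AP band (target stripes + ring-1 only), cross-validation average,
    drop-stripe variants for multi-stripe targets, and a "max" fit using
    every candidate regulator on the same rows.  Per-variant errors are
    recorded and the suite continues.
    """
    target_stripes = frozenset(int(s) for s in target_stripes)
    regulators = list(spec.regulators)
    ts = lab.build_training_set(atlas, labels, target_stripes, regulators)
    report = ConsistencyReport()

    def run(name, builder):
        try:
            fld = builder()
            report.variants[name] = accuracy_report(fld, labels, target_stripes)
        except StripefitError as exc:
            logger.warning("consistency variant %r failed: %s", name, exc)
            report.errors[name] = str(exc)

    def fit_predict(train):
        return model_mod.predict(model_mod.fit(train, spec, options), atlas)

    run("full", lambda: fit_predict(ts))
    run("dv_band", lambda: fit_predict(lab.restrict_dv_band(ts, atlas, 20.0)))
    run("ap_band", lambda: fit_predict(lab.restrict_ap_band(ts, labels)))
    run("cross_validation", lambda: cross_validate(ts, spec, atlas, reps=cv_reps,
                                                   n=cv_n, seed=seed, options=options))
    if len(target_stripes) > 1:
        for s in sorted(target_stripes):
            run(f"drop_stripe_{s}", lambda s=s: fit_predict(lab.drop_stripe(ts, labels, s)))

    def max_fit():
        cands = atlas.candidate_regulators()
        ts_max = lab.build_training_set(atlas, labels, target_stripes, cands)
        spec_max = model_mod.ModelSpec(regulators=tuple(cands), quadratic=spec.quadratic)
        opts = model_mod.FitOptions(ridge=max_ridge) if max_ridge else options
        return model_mod.predict(model_mod.fit(ts_max, spec_max, opts), atlas)

    run("max", max_fit)
    return report
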