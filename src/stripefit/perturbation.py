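"""In-silico regulatory perturbations.

A perturbation edits regulator concentration fields — never coordinates,
neighbors, or (unless a scenario explicitly retrains) model coefficients —
and the trained model then predicts the target's expression on the edited
atlas.  Null mutants and binding-site deletions are "set the concentration to
zero"; misexpression adds a scaled copy of another gene's spatial pattern;
indirect effects are always explicit edits declared by a scenario, never
inferred automatically.

Edits are applied in order on raw values; negative intermediate values are
clamped to zero at the end (concentrations are non-negative).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from . import model as model_mod
from .atlas import ExpressionAtlas, GeneChannel
from .errors import StripefitError
from .labeling import TrainingSet

#: Anteroposterior fraction splitting "anterior" from "posterior" regions.
AP_SPLIT = 0.5
#: Anteroposterior fraction beyond which lies the posterior stripe-7 region.
POSTERIOR_TAIL = 0.8

#: Damping prefactor for the attenuated-dual-regulation transform.
DAMP_PREFACTOR = 0.5

NAMED_TRANSFORMS = {
    "damp": lambda x, pref=None: (DAMP_PREFACTOR if pref is None else pref) * (1.0 - np.exp(-2.0 * x)),
}


def region_mask(atlas: ExpressionAtlas, region, ap_split: float = AP_SPLIT) -> np.ndarray:
    """Boolean nucleus mask for a named region or a callable predicate."""
    if callable(region):
        return np.asarray(region(atlas), dtype=bool)
    s = atlas.ap_fraction
    if region == "anterior":
        return s < ap_split
    if region == "posterior":
        return s >= ap_split
    if region == "posterior_stripe7":
        return s > POSTERIOR_TAIL
    if region == "all":
        return np.ones(atlas.n_nuclei, dtype=bool)
    raise StripefitError(f"unknown region {region!r}")


# ------------------------------------------------------------------- edits

@dataclass(frozen=True)
class SetZero:
    gene: str

    def __call__(self, atlas, values):
        return np.zeros_like(values)


@dataclass(frozen=True)
class ScaleRegion:
    gene: str
    region: object
    factor: float

    def __call__(self, atlas, values):
        out = values.copy()
        m = region_mask(atlas, self.region)
        out[m] = out[m] * self.factor
        return out


@dataclass(frozen=True)
class SetFloorRegion:
    """Raise values in a region to at least ``level``."""

    gene: str
    region: object
    level: float

    def __call__(self, atlas, values):
        out = values.copy()
        m = region_mask(atlas, self.region)
        out[m] = np.maximum(out[m], self.level)
        return out


@dataclass(frozen=True)
class AddUniform:
    gene: str
    amount: float

    def __call__(self, atlas, values):
        return values + self.amount


@dataclass(frozen=True)
class AddScaledPattern:
    """Add another gene's pattern, normalized to peak 1 then scaled to ``peak``."""

    gene: str
    source_gene: str
    peak: float

    def __call__(self, atlas, values):
        src = atlas.values(self.source_gene)
        mx = src.max()
        if mx <= 0:
            raise StripefitError(f"source pattern {self.source_gene!r} is identically zero")
        return values + self.peak * (src / mx)


@dataclass(frozen=True)
class Transform:
    gene: str
    func: str
    prefactor: float | None = None

    def __call__(self, atlas, values):
        try:
            f = NAMED_TRANSFORMS[self.func]
        except KeyError:
            raise StripefitError(f"unknown transform {self.func!r}; known: {sorted(NAMED_TRANSFORMS)}")
        return f(values, self.prefactor)


@dataclass
class PerturbationSpec:
    """An ordered list of channel edits plus model-side adjustments."""

    edits: list = field(default_factory=list)
    intercept_shift: float = 0.0
    retrain: bool = False
    name: str = "custom"

    def to_dict(self) -> dict:
        return {"name": self.name, "intercept_shift": self.intercept_shift,
                "retrain": self.retrain,
                "edits": [f"{type(e).__name__}{e.__dict__}" for e in self.edits]}


# ------------------------------------------------------------------- engine

def apply(atlas: ExpressionAtlas, spec: PerturbationSpec) -> ExpressionAtlas:
    """New atlas with the spec's edits applied; the input atlas is untouched.

    An edit targets every channel (any kind, any cohort) whose gene name
    matches case-insensitively, since mRNA and protein channels describe the
    same concentration field.  Values are clamped at >= 0 after all edits.
    """
    edited = {}
    touched = set()
    for e in spec.edits:
        matches = [ch for ch in atlas.channels if ch.gene.casefold() == e.gene.casefold()]
        if not matches:
            raise StripefitError(f"perturbation references unknown gene {e.gene!r}")
        for ch in matches:
            vals = edited.get(ch.key, ch.values.copy())
            edited[ch.key] = e(atlas, vals)
            touched.add(ch.key)
    channels = []
    for ch in atlas.channels:
        if ch.key in touched:
            channels.append(GeneChannel(ch.gene, ch.kind, ch.cohort,
                                        np.clip(edited[ch.key], 0.0, None)))
        else:
            channels.append(ch)
    return replace(atlas, channels=channels)


def predict_under(model: model_mod.FittedModel, atlas: ExpressionAtlas,
                  spec: PerturbationSpec, ts_template: TrainingSet | None = None,
                  cohort: int | None = None) -> model_mod.PredictionField:
    """Predict the target on the perturbed atlas.

    With ``retrain=False`` (the default, and the paper-style direct
    prediction) the original coefficients are applied to the edited channels.
    With ``retrain=True`` the model is refitted on the edited concentrations
    of the original training rows first.  ``intercept_shift`` is added to
    beta0 before prediction.
    """
    edited = apply(atlas, spec)
    m = model
    if spec.retrain:
        if ts_template is None:
            raise StripefitError("retrain=True requires the training-set template")
        regs = [(g, k) for g, k in ts_template.regulator_names]
        X = np.column_stack([edited.values(g, kind=k)[edited.index_of(ts_template.nucleus_ids)]
                             for g, k in regs])
        ts = replace(ts_template, X=X)
        m = model_mod.fit(ts, model.spec)
    if spec.intercept_shift:
        m = m.with_intercept_shift(spec.intercept_shift)
    return model_mod.predict(m, edited, cohort=cohort)


# ---------------------------------------------------------------- scenarios

def scenario(name: str, **params) -> PerturbationSpec:
    """Library of documented perturbation experiments.

    Null mutants / binding-site deletions set a regulator to zero.  The
    kni-shift scenario adds a small uniform amount (default 0.1, ~10% of the
    maximum) to kni and retrains; the reporter-intercept scenario raises
    beta0 (default +4.5).  The zygotic-hb scenarios combine regional scaling
    with optional residual posterior protein or a damping transform.
    Misexpression adds the ventral sna pattern at 0.2 per transgene copy.
    """
    p = dict(params)

    def make(edits=(), **kw):
        return PerturbationSpec(edits=list(edits), name=name, **kw)

    if name in ("gt_null", "kr_null", "bcd_null", "hb_null", "kni_null"):
        default_gene = {"gt_null": "Gt", "kr_null": "Kr", "bcd_null": "Bcd",
                        "hb_null": "Hb", "kni_null": "kni"}[name]
        return make([SetZero(p.get("gene", default_gene))])
    if name == "kni_shift":
        return make([AddUniform(p.get("gene", "kni"), p.get("amount", 0.1))], retrain=True)
    if name == "reporter_intercept":
        return make(intercept_shift=p.get("delta", 4.5))
    if name == "kni_indirect_hb":
        f = p.get("factor", 0.5)
        return make([AddScaledPattern(p.get("hb_gene", "Hb"), p.get("kni_gene", "kni"), f),
                     SetZero(p.get("kni_gene", "kni"))])
    if name == "hb_zygotic":
        g = p.get("gene", "Hb")
        return make([SetZero_region(g, "posterior"),
                     ScaleRegion(g, "anterior", p.get("anterior_factor", 0.2))])
    if name == "hb_residual":
        g = p.get("gene", "Hb")
        return make([SetZero_region(g, "posterior"),
                     ScaleRegion(g, "anterior", p.get("anterior_factor", 0.2)),
                     SetFloorRegion(g, "posterior_stripe7", p.get("level", 0.15))])
    if name == "hb_damped":
        return make([Transform(p.get("gene", "Hb"), "damp", p.get("prefactor"))])
    if name == "misexpress":
        gene = p["gene"]
        copies = p.get("copies", 1)
        per_copy = p.get("per_copy", 0.2)
        return make([AddScaledPattern(gene, p.get("source", "sna"), per_copy * copies)])
    if name == "misexpress_with_kr_indirect":
        copies = p.get("copies", 1)
        per_copy = p.get("per_copy", 0.2)
        # Kr rises in proportion (50%) to the added Hb, which is itself a
        # scaled copy of the sna pattern, so the indirect edit reuses sna.
        return make([AddScaledPattern(p.get("gene", "Hb"), p.get("source", "sna"), per_copy * copies),
                     AddScaledPattern(p.get("kr_gene", "Kr"), p.get("source", "sna"),
                                      p.get("kr_factor", 0.5) * per_copy * copies)])
    raise StripefitError(f"unknown scenario {name!r}")


def SetZero_region(gene: str, region) -> ScaleRegion:
    """Zero a gene inside a region only (scale by 0)."""
    return ScaleRegion(gene, region, 0.0)
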