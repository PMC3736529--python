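"""Synthetic blastoderm atlases with known regulatory ground truth.

Nuclei are placed quasi-uniformly on an ellipsoid surface whose semi-axes
default to (202, 77, 77.5) μm, matching a ~404 μm anteroposterior extent.
Smooth graded transcription-factor fields (anterior exponential gradients,
sigmoidal ramps, gap-gene-like domains, terminal and ventral patterns, and a
seven-stripe pattern) are laid over the surface as functions of the
anteroposterior fraction (and dorsoventral position for the ventral shape).
A target gene is generated from a known logistic regulatory input function of
those fields, optionally with Bernoulli sampling noise, so that every
downstream stage — labeling, fitting, discovery, perturbation, evaluation —
can be tested against a known truth.

Patterns are static fields per cohort; there is no reaction–diffusion or
gap-gene dynamics here.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import networkx as nx
import numpy as np
from scipy.spatial import cKDTree

from . import model as model_mod
from .atlas import MRNA, PROTEIN, ExpressionAtlas, GeneChannel
from .errors import GenerationError, ValidationError

#: Shapes understood by :func:`generate_pattern`.
SHAPES = ("anterior_exponential", "sigmoid", "gaussian_domain", "two_domain",
          "terminal", "ventral", "stripes")


@dataclass(frozen=True)
class PatternDef:
    """A named smooth expression field.

    Positions and widths are anteroposterior fractions in [0, 1]; amplitudes
    are unitless relative expression.  The peak of every generated pattern is
    within 1% of ``amplitude``.
    """

    gene: str
    kind: str = MRNA
    shape: str = "gaussian_domain"
    amplitude: float = 1.0
    params: dict = field(default_factory=dict)
    cohort: int | None = None  # None: emit for every cohort

    def __post_init__(self):
        if self.shape not in SHAPES:
            raise ValidationError(f"unknown pattern shape {self.shape!r}; known: {SHAPES}")


@dataclass
class SyntheticSpec:
    """Everything needed to generate one synthetic atlas."""

    n_nuclei: int = 6078
    semi_axes: tuple = (202.0, 77.0, 77.5)
    seed: int = 0
    patterns: list = field(default_factory=list)
    truth_model: model_mod.FittedModel | None = None
    target_gene: str = "eve"
    noise: str = "none"  # "none" | "bernoulli"
    n_cohorts: int = 1
    jitter: float = 0.2          # fraction of mean nucleus spacing
    n_neighbors: int = 6
    min_spacing: float | None = None  # μm; generation error if violated

    def __post_init__(self):
        if self.n_nuclei < 10:
            raise ValidationError("n_nuclei must be at least 10")
        if any(a <= 0 for a in self.semi_axes):
            raise ValidationError("semi-axes must be positive")
        if self.noise not in ("none", "bernoulli"):
            raise ValidationError(f"unknown noise kind {self.noise!r}")
        if self.noise == "bernoulli" and self.truth_model is None:
            raise ValidationError("bernoulli noise requires a truth model")


# ------------------------------------------------------------------ geometry

def _fibonacci_ellipsoid(n: int, axes, rng, jitter: float):
    """Quasi-uniform points on the ellipsoid surface, seeded jitter included.

    A Fibonacci lattice on the unit sphere is scaled onto the ellipsoid; the
    polar coordinate is mapped to x so the anteroposterior axis spans almost
    the full 2a extent.  Jitter perturbs each unit-sphere point and reprojects
    it, so every nucleus stays exactly on the surface.
    """
    i = np.arange(n)
    u0 = 1.0 - 2.0 * (i + 0.5) / n                 # polar -> anteroposterior
    r = np.sqrt(np.clip(1.0 - u0 ** 2, 0.0, None))
    golden = np.pi * (3.0 - np.sqrt(5.0))
    phi = golden * i
    u = np.column_stack([u0, r * np.cos(phi), r * np.sin(phi)])
    if jitter > 0:
        # angular scale of the mean spacing on the unit sphere
        ang = np.sqrt(4.0 * np.pi / n)
        u = u + rng.normal(scale=jitter * ang / np.sqrt(3.0), size=u.shape)
        u /= np.linalg.norm(u, axis=1, keepdims=True)
    return u * np.asarray(axes, float)


def _neighbor_graph(points: np.ndarray, k: int):
    """Symmetrized k-nearest-neighbor lists (indices, not ids)."""
    tree = cKDTree(points)
    _, idx = tree.query(points, k=k + 1)
    nbrs = [set() for _ in range(len(points))]
    for i, row in enumerate(idx):
        for j in row[1:]:
            nbrs[i].add(int(j))
            nbrs[int(j)].add(i)
    return [np.array(sorted(s), dtype=int) for s in nbrs]


def generate_atlas(spec: SyntheticSpec) -> ExpressionAtlas:
    """Geometry + patterns + (optionally) the truth-model target channel."""
    rng = np.random.default_rng(spec.seed)
    pts = _fibonacci_ellipsoid(spec.n_nuclei, spec.semi_axes, rng, spec.jitter)
    tree = cKDTree(pts)
    d, _ = tree.query(pts, k=2)
    if spec.min_spacing is not None and float(d[:, 1].min()) < spec.min_spacing:
        raise GenerationError(
            f"{spec.n_nuclei} nuclei violate the minimum spacing of {spec.min_spacing} μm "
            f"(closest pair {d[:, 1].min():.3g} μm); reduce n_nuclei or the spacing")
    neighbors_idx = _neighbor_graph(pts, spec.n_neighbors)
    g = nx.Graph((i, int(j)) for i, nbs in enumerate(neighbors_idx) for j in nbs)
    g.add_nodes_from(range(spec.n_nuclei))
    if not nx.is_connected(g):
        raise GenerationError("neighbor graph is disconnected; increase n_neighbors")

    ids = np.arange(1, spec.n_nuclei + 1)
    atlas = ExpressionAtlas(
        nucleus_ids=ids,
        x=pts[:, 0], y=pts[:, 1], z=pts[:, 2],
        neighbors=[ids[nb] for nb in neighbors_idx],
        channels=[],
    )
    for cohort in range(1, spec.n_cohorts + 1):
        for pat in spec.patterns:
            if pat.cohort is not None and pat.cohort != cohort:
                continue
            atlas = atlas.with_channel(generate_pattern(atlas, pat, cohort=cohort))
        if spec.truth_model is not None:
            atlas = atlas.with_channel(generate_target(
                atlas, spec.truth_model, noise=spec.noise,
                seed=np.random.default_rng((spec.seed, cohort)).integers(2 ** 31),
                gene=spec.target_gene, cohort=cohort))
    atlas.validate()
    return atlas


# ------------------------------------------------------------------ patterns

def _dv_position(atlas: ExpressionAtlas) -> np.ndarray:
    """Dorsoventral position scaled to [-1, 1]; -1 is the ventralmost (min z)."""
    lo, hi = atlas.z.min(), atlas.z.max()
    return 2.0 * (atlas.z - lo) / (hi - lo) - 1.0


def pattern_values(atlas: ExpressionAtlas, pattern: PatternDef) -> np.ndarray:
    s = atlas.ap_fraction
    A = pattern.amplitude
    p = pattern.params

    def gauss(center, width):
        return np.exp(-0.5 * ((s - center) / width) ** 2)

    if pattern.shape == "anterior_exponential":
        return A * np.exp(-s / p.get("decay", 0.25))
    if pattern.shape == "sigmoid":
        return A / (1.0 + np.exp((s - p.get("midpoint", 0.5)) / p.get("width", 0.05)))
    if pattern.shape == "gaussian_domain":
        return A * gauss(p.get("center", 0.5), p.get("width", 0.08))
    if pattern.shape == "two_domain":
        c1, w1 = p.get("center1", 0.2), p.get("width1", 0.06)
        c2, w2 = p.get("center2", 0.6), p.get("width2", 0.05)
        return A * np.maximum(gauss(c1, w1), gauss(c2, w2))
    if pattern.shape == "terminal":
        w = p.get("width", 0.08)
        return A * np.maximum(np.exp(-s / w), np.exp(-(1.0 - s) / w))
    if pattern.shape == "ventral":
        dv = _dv_position(atlas)
        width = p.get("width", 0.4)
        return A * np.exp(-0.5 * ((dv + 1.0) / width) ** 2)
    if pattern.shape == "stripes":
        n = p.get("n_stripes", 7)
        width = p.get("width", 0.02)
        centers = p.get("centers", np.linspace(0.15, 0.85, n))
        return A * np.max([gauss(c, width) for c in centers], axis=0)
    raise ValidationError(f"unknown pattern shape {pattern.shape!r}")


def generate_pattern(atlas: ExpressionAtlas, pattern: PatternDef, cohort: int = 1) -> GeneChannel:
    """Deterministic smooth field of the named shape as a GeneChannel."""
    vals = pattern_values(atlas, pattern)
    return GeneChannel(pattern.gene, pattern.kind, cohort, vals)


def generate_target(atlas: ExpressionAtlas, truth_model: model_mod.FittedModel,
                    noise: str = "none", seed: int = 0, gene: str = "eve",
                    cohort: int | None = None) -> GeneChannel:
    """Target channel drawn from the truth model's probability field.

    ``noise="none"`` stores p_i itself; ``noise="bernoulli"`` stores seeded
    0/1 draws with success probability p_i.
    """
    use_cohort = cohort if cohort in atlas.cohorts else None
    fld = model_mod.predict(truth_model, atlas, cohort=use_cohort)
    if noise == "none":
        vals = fld.p
    elif noise == "bernoulli":
        rng = np.random.default_rng(seed)
        vals = rng.binomial(1, fld.p).astype(float)
    else:
        raise ValidationError(f"unknown noise kind {noise!r}")
    return GeneChannel(gene, MRNA, cohort or 1, vals)


# ----------------------------------------------------- reference truth setup

def stripe2_like_patterns() -> list:
    """Regulator fields emulating the stripe-2 situation.

    One broad activator ramp (hb-like), one anterior exponential gradient used
    as a dual regulator (bcd-like), one two-domain repressor (gt-like), one
    central repressor domain (kr-like), plus a posterior domain (kni-like), a
    terminal pattern (tll-like) and a ventral pattern (sna-like) as decoys for
    discovery runs.
    """
    return [
        PatternDef("Hb", PROTEIN, "sigmoid", 1.0, {"midpoint": 0.55, "width": 0.04}),
        PatternDef("Bcd", PROTEIN, "anterior_exponential", 1.0, {"decay": 0.25}),
        PatternDef("Gt", PROTEIN, "two_domain", 1.0,
                   {"center1": 0.16, "width1": 0.08, "center2": 0.60, "width2": 0.05}),
        PatternDef("Kr", PROTEIN, "gaussian_domain", 1.0, {"center": 0.48, "width": 0.06}),
        PatternDef("kni", MRNA, "gaussian_domain", 1.0, {"center": 0.72, "width": 0.07}),
        PatternDef("tll", MRNA, "terminal", 1.0, {"width": 0.06}),
        PatternDef("sna", MRNA, "ventral", 1.0, {"width": 0.4}),
    ]


def stripe2_like_truth() -> model_mod.FittedModel:
    """The frozen ground-truth regulatory input function for the fixture.

    Calibrated once from the analytic one-dimensional profile so that exactly
    one sharp stripe forms near anteroposterior fraction 0.33 (ON region
    roughly 0.28–0.39 at the 0.2 threshold), with the dual regulator's
    activator→repressor crossover at concentration 0.25.
    """
    spec = model_mod.ModelSpec(
        regulators=(("Hb", PROTEIN), ("Bcd", PROTEIN), ("Gt", PROTEIN), ("Kr", PROTEIN)),
        quadratic=(("Bcd", PROTEIN),),
    )
    return model_mod.FittedModel(
        spec=spec, beta0=-5.0,
        beta=np.array([10.0, 20.0, -24.0, -24.0]),
        beta_quad=np.array([-40.0]),
    )


def recovery_truth() -> model_mod.FittedModel:
    """Five-parameter quadratic truth used for Wald-interval recovery runs.

    Three regulators (activator, dual, repressor) plus intercept and one
    quadratic term; effect sizes moderate enough that Bernoulli draws stay
    informative (no separation).
    """
    spec = model_mod.ModelSpec(
        regulators=(("Hb", PROTEIN), ("Bcd", PROTEIN), ("Gt", PROTEIN)),
        quadratic=(("Bcd", PROTEIN),),
    )
    return model_mod.FittedModel(
        spec=spec, beta0=-3.0,
        beta=np.array([4.0, 8.0, -6.0]),
        beta_quad=np.array([-12.0]),
    )


def default_spec(n_nuclei: int = 6078, seed: int = 0, noise: str = "none",
                 **kwargs) -> SyntheticSpec:
    """The standard stripe-2-like synthetic embryo."""
    return SyntheticSpec(n_nuclei=n_nuclei, seed=seed, noise=noise,
                         patterns=stripe2_like_patterns(),
                         truth_model=stripe2_like_truth(), **kwargs)
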