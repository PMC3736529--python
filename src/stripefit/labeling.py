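"""Discretize the target gene and build stripe-aware training sets.

The target channel is thresholded (default 0.2, roughly 20% of maximal
expression) into ON/OFF calls.  ON nuclei are grouped into stripes as
connected components of the neighbor graph restricted to ON nuclei, numbered
anterior to posterior.  Around each stripe two rings of OFF nuclei are
recorded: ring 1 (immediately adjacent) and ring 2 (two steps away) — these
are the categories of the border-accuracy metric.

A training set for a target stripe (or set of stripes) contains the ON nuclei
of those stripes as positive rows and, as negative rows, every OFF nucleus
except the nuclei of other stripes and their immediate (ring-1) neighbors.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import networkx as nx
import numpy as np

from .atlas import ExpressionAtlas
from .errors import StripefitError, ValidationError

DEFAULT_THRESHOLD = 0.2

#: Components smaller than this are reported but not numbered as stripes, so
#: that tiny speckle cannot shift stripe indices.
MIN_STRIPE_SIZE = 5


def binarize(values: np.ndarray, threshold: float = DEFAULT_THRESHOLD) -> np.ndarray:
    """ON/OFF call per nucleus: strictly above the threshold is ON."""
    values = np.asarray(values, dtype=float)
    if not np.all(np.isfinite(values)):
        raise ValidationError("cannot binarize non-finite expression values")
    return values > threshold


@dataclass
class StripeLabels:
    """Per-nucleus ON flag, stripe membership, and neighbor rings."""

    nucleus_ids: np.ndarray
    on_flag: np.ndarray                  # bool per nucleus
    stripe_id: np.ndarray                # int per nucleus; 0 = none
    ring1: dict = field(default_factory=dict)   # stripe -> set of nucleus ids
    ring2: dict = field(default_factory=dict)
    threshold: float = DEFAULT_THRESHOLD
    small_components: list = field(default_factory=list)  # lists of nucleus ids

    @property
    def stripes(self) -> list:
        return sorted(int(s) for s in np.unique(self.stripe_id) if s > 0)

    def stripe_nuclei(self, stripe: int) -> np.ndarray:
        return self.nucleus_ids[self.stripe_id == stripe]

    @property
    def stripe_sizes(self) -> dict:
        return {s: int(np.sum(self.stripe_id == s)) for s in self.stripes}

    def rings_for(self, target_stripes) -> tuple:
        """(ring1, ring2) id-sets pooled over the target stripes."""
        r1 = set().union(*(self.ring1[s] for s in target_stripes)) if target_stripes else set()
        r2 = set().union(*(self.ring2[s] for s in target_stripes)) if target_stripes else set()
        return r1, r2 - r1

    def to_frame(self):
        import pandas as pd
        ring = np.zeros(len(self.nucleus_ids), dtype=int)
        r1, r2 = self.rings_for(self.stripes)
        ring[np.isin(self.nucleus_ids, sorted(r1))] = 1
        ring[np.isin(self.nucleus_ids, sorted(r2))] = 2
        return pd.DataFrame({"nucleus_id": self.nucleus_ids, "on_flag": self.on_flag,
                             "stripe_id": self.stripe_id, "ring": ring})


def assign_stripes(atlas: ExpressionAtlas, on_flags: np.ndarray,
                   threshold: float = DEFAULT_THRESHOLD,
                   min_size: int = MIN_STRIPE_SIZE) -> StripeLabels:
    """Group ON nuclei into stripes via the atlas's neighbor graph.

    Stripes are connected components of the ON-induced subgraph, ordered by
    increasing mean anteroposterior (x) coordinate.  Zero ON nuclei yield
    empty labels, not an error.
    """
    on_flags = np.asarray(on_flags, dtype=bool)
    if len(on_flags) != atlas.n_nuclei:
        raise ValidationError("on_flags length does not match the atlas")
    ids = atlas.nucleus_ids
    on_ids = set(int(i) for i in ids[on_flags])

    g = nx.Graph()
    g.add_nodes_from(int(i) for i in ids)
    for nid, nbs in zip(ids, atlas.neighbors):
        for m in nbs:
            g.add_edge(int(nid), int(m))

    sub = g.subgraph(on_ids)
    comps = [set(c) for c in nx.connected_components(sub)]
    big = [c for c in comps if len(c) >= min_size]
    small = [sorted(c) for c in comps if len(c) < min_size]

    xmap = dict(zip((int(i) for i in ids), atlas.x))
    big.sort(key=lambda c: np.mean([xmap[n] for n in c]))

    stripe_id = np.zeros(atlas.n_nuclei, dtype=int)
    idx = {int(i): j for j, i in enumerate(ids)}
    ring1, ring2 = {}, {}
    off_ids = {int(i) for i in ids} - on_ids
    for s, comp in enumerate(big, start=1):
        for n in comp:
            stripe_id[idx[n]] = s
        r1 = {m for n in comp for m in g.neighbors(n)} & off_ids
        r2 = ({m for n in r1 for m in g.neighbors(n)} & off_ids) - r1
        ring1[s] = r1
        ring2[s] = r2
    return StripeLabels(nucleus_ids=ids.copy(), on_flag=on_flags.copy(),
                        stripe_id=stripe_id, ring1=ring1, ring2=ring2,
                        threshold=threshold, small_components=small)


def label_target(atlas: ExpressionAtlas, gene: str = "eve",
                 threshold: float = DEFAULT_THRESHOLD, **kwargs) -> StripeLabels:
    """Binarize a target channel and assign stripes in one step."""
    return assign_stripes(atlas, binarize(atlas.values(gene), threshold),
                          threshold=threshold, **kwargs)


@dataclass
class TrainingSet:
    """Design rows for one enhancer's classification problem."""

    nucleus_ids: np.ndarray
    X: np.ndarray                       # nuclei x regulator concentrations
    y: np.ndarray                       # 1 = target ON
    regulator_names: list               # [(gene, kind), ...] matching X columns
    target_stripes: frozenset

    @property
    def n_on(self) -> int:
        return int(self.y.sum())

    @property
    def n_off(self) -> int:
        return int(len(self.y) - self.y.sum())


def build_training_set(atlas: ExpressionAtlas, labels: StripeLabels,
                       target_stripes, regulators) -> TrainingSet:
    """Positive rows: nuclei of the target stripes.  Negative rows: all OFF
    nuclei except other stripes' ring-1 neighbors (other stripes' own nuclei
    are ON and excluded already; ON nuclei in sub-threshold-size components
    are excluded from training altogether)."""
    target_stripes = frozenset(int(s) for s in target_stripes)
    missing = target_stripes - set(labels.stripes)
    if missing:
        raise StripefitError(f"target stripe(s) {sorted(missing)} not present; have {labels.stripes}")

    ids = atlas.nucleus_ids
    on_rows = np.isin(labels.stripe_id, sorted(target_stripes))
    if not on_rows.any():
        raise StripefitError("empty ON set for the requested target stripes")

    others = [s for s in labels.stripes if s not in target_stripes]
    excluded = set()
    for s in others:
        excluded |= labels.ring1[s]
    off_rows = ~labels.on_flag & ~np.isin(ids, sorted(excluded))

    rows = on_rows | off_rows
    regulators = [r if isinstance(r, tuple) else (r, None) for r in regulators]
    X = np.column_stack([atlas.values(g, kind=k)[rows] for g, k in regulators])
    names = []
    for g, k in regulators:
        ch = atlas.get_channel(g, kind=k)
        names.append((ch.gene, ch.kind))
    return TrainingSet(nucleus_ids=ids[rows].copy(), X=X,
                       y=on_rows[rows].astype(float),
                       regulator_names=names, target_stripes=target_stripes)


# ------------------------------------------------------------- restrictions

def _subset(ts: TrainingSet, mask: np.ndarray) -> TrainingSet:
    return replace(ts, nucleus_ids=ts.nucleus_ids[mask], X=ts.X[mask], y=ts.y[mask])


def restrict_dv_band(ts: TrainingSet, atlas: ExpressionAtlas, halfwidth: float = 20.0) -> TrainingSet:
    """Keep rows within ``halfwidth`` μm of the lateral midline plane.

    The midline is operationalized as z = (min z + max z) / 2; the
    dorsoventral axis runs along z in the lateral view.
    """
    z_mid = 0.5 * (atlas.z.min() + atlas.z.max())
    z = atlas.z[atlas.index_of(ts.nucleus_ids)]
    return _subset(ts, np.abs(z - z_mid) <= halfwidth)


def restrict_ap_band(ts: TrainingSet, labels: StripeLabels) -> TrainingSet:
    """Keep only the target stripes and their immediate (ring-1) neighbors."""
    r1, _ = labels.rings_for(sorted(ts.target_stripes))
    keep_ids = set(int(i) for s in ts.target_stripes for i in labels.stripe_nuclei(s)) | r1
    return _subset(ts, np.isin(ts.nucleus_ids, sorted(keep_ids)))


def restrict_random(ts: TrainingSet, n: int, seed: int) -> TrainingSet:
    """Seeded uniform subsample of n rows (without replacement)."""
    if n > len(ts.y):
        raise StripefitError(f"cannot sample {n} of {len(ts.y)} rows")
    rng = np.random.default_rng(seed)
    mask = np.zeros(len(ts.y), dtype=bool)
    mask[rng.choice(len(ts.y), size=n, replace=False)] = True
    return _subset(ts, mask)


def drop_stripe(ts: TrainingSet, labels: StripeLabels, stripe: int) -> TrainingSet:
    """Remove one target stripe's ON nuclei (consistency check for multi-stripe fits)."""
    if stripe not in ts.target_stripes:
        raise StripefitError(f"stripe {stripe} is not a target of this training set")
    drop_ids = set(int(i) for i in labels.stripe_nuclei(stripe))
    return _subset(ts, ~np.isin(ts.nucleus_ids, sorted(drop_ids)))


def restrict(ts: TrainingSet, rule: str, *, atlas=None, labels=None, **params) -> TrainingSet:
    """Dispatch a named restriction rule (dv_band, ap_band, random_n, drop_stripe)."""
    if rule == "dv_band":
        return restrict_dv_band(ts, atlas, params.get("halfwidth", 20.0))
    if rule == "ap_band":
        return restrict_ap_band(ts, labels)
    if rule == "random_n":
        return restrict_random(ts, params["n"], params["seed"])
    if rule == "drop_stripe":
        return drop_stripe(ts, labels, params["stripe"])
    raise StripefitError(f"unknown restriction rule {rule!r}")
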