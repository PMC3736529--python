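"""Per-nucleus expression atlas data model and Virtual-Embryo-style VPC I/O.

The atlas holds, for every nucleus of a blastoderm embryo, its 3-D coordinates
(μm), the identities of its spatial neighbors, and one expression channel per
(gene, kind, cohort) triple.  Expression values are relative measurements
normalized so that the maximum of a gene over all cohorts is about 1 (values a
little above 1 are legal and preserved; no clipping happens anywhere in I/O).

The on-disk dialect is a plain comma-separated file with one header row:
``nucleus_id,x,y,z,neighbors`` followed by one column per channel.  Channel
columns are named ``<gene>__<cohort>``; the neighbor list is a
semicolon-delimited string of nucleus ids.  Protein channels are recognized by
gene name (capitalized, e.g. ``Hb``) against a configurable set; everything
else is mRNA.  Real-release header aliases are handled through a
:class:`ColumnMap`.
"""

from __future__ import annotations

import difflib
import logging
import re
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import yaml

from .errors import FormatError, LookupChannelError, ValidationError

logger = logging.getLogger(__name__)

#: Gene products for which the atlas carries protein measurements; models
#: prefer these channels over the corresponding mRNA.
PROTEIN_GENES = ("Bcd", "Hb", "Kr", "Gt")

#: Pair-rule genes excluded from the candidate-regulator set because their
#: striped patterns parallel the target's own.
PAIR_RULE_EXCLUDED = ("ftz", "odd", "h", "prd")

MRNA = "mRNA"
PROTEIN = "protein"


@dataclass(frozen=True)
class ColumnMap:
    """Mapping from atlas roles to file column names.

    ``channel_pattern`` must expose named groups ``gene`` and ``cohort``.
    """

    id_col: str = "nucleus_id"
    x_col: str = "x"
    y_col: str = "y"
    z_col: str = "z"
    neighbors_col: str = "neighbors"
    channel_pattern: str = r"^(?P<gene>.+)__(?P<cohort>\d+)$"
    protein_genes: tuple = PROTEIN_GENES

    @classmethod
    def from_yaml(cls, path) -> "ColumnMap":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise FormatError(f"unknown column-map keys: {sorted(unknown)}")
        if "protein_genes" in data:
            data["protein_genes"] = tuple(data["protein_genes"])
        return cls(**data)

    def channel_column(self, gene: str, cohort: int) -> str:
        return f"{gene}__{cohort}"


@dataclass
class GeneChannel:
    """One gene's expression values for one cohort.

    values are non-negative relative expression, aligned with the atlas's
    nucleus order.
    """

    gene: str
    kind: str  # MRNA or PROTEIN
    cohort: int
    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.kind not in (MRNA, PROTEIN):
            raise ValidationError(f"channel kind must be {MRNA!r} or {PROTEIN!r}, got {self.kind!r}")
        if not np.all(np.isfinite(self.values)):
            raise ValidationError(f"channel {self.gene} cohort {self.cohort} has non-finite values")
        if np.any(self.values < 0):
            raise ValidationError(f"channel {self.gene} cohort {self.cohort} has negative values")

    @property
    def key(self):
        return (self.gene, self.kind, self.cohort)


@dataclass
class ExpressionAtlas:
    """Coordinates, neighbor graph and expression channels for one embryo."""

    nucleus_ids: np.ndarray
    x: np.ndarray
    y: np.ndarray
    z: np.ndarray
    neighbors: list  # per nucleus, array of neighbor nucleus ids
    channels: list = field(default_factory=list)

    def __post_init__(self):
        self.nucleus_ids = np.asarray(self.nucleus_ids, dtype=int)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        self.z = np.asarray(self.z, dtype=float)
        self.neighbors = [np.asarray(nb, dtype=int) for nb in self.neighbors]

    # ------------------------------------------------------------------ basic
    @property
    def n_nuclei(self) -> int:
        return len(self.nucleus_ids)

    @property
    def cohorts(self) -> list:
        return sorted({ch.cohort for ch in self.channels})

    @property
    def ap_fraction(self) -> np.ndarray:
        """Anteroposterior position as a fraction of the x-extent (0=anterior)."""
        lo, hi = self.x.min(), self.x.max()
        return (self.x - lo) / (hi - lo)

    def index_of(self, nucleus_ids) -> np.ndarray:
        """Positions of the given nucleus ids in atlas order."""
        order = {nid: i for i, nid in enumerate(self.nucleus_ids)}
        return np.array([order[n] for n in np.atleast_1d(nucleus_ids)], dtype=int)

    def validate(self) -> None:
        """Check structural invariants; raise ValidationError on violation."""
        ids = self.nucleus_ids
        if len(np.unique(ids)) != len(ids):
            raise ValidationError("nucleus ids are not unique")
        if not (len(self.x) == len(self.y) == len(self.z) == len(ids) == len(self.neighbors)):
            raise ValidationError("coordinate/neighbor arrays are not aligned with nucleus ids")
        known = set(ids.tolist())
        nb_sets = {}
        for nid, nbs in zip(ids, self.neighbors):
            for m in nbs:
                if int(m) not in known:
                    raise ValidationError(f"nucleus {nid} lists unknown neighbor {m}")
            nb_sets[int(nid)] = set(int(m) for m in nbs)
        for i, nbs in nb_sets.items():
            for j in nbs:
                if i not in nb_sets[j]:
                    raise ValidationError(f"asymmetric neighbor relation: {i} lists {j} but not vice versa")
        for ch in self.channels:
            if len(ch.values) != self.n_nuclei:
                raise ValidationError(
                    f"channel {ch.gene} cohort {ch.cohort}: {len(ch.values)} values for {self.n_nuclei} nuclei")

    # --------------------------------------------------------------- channels
    def _matches(self, gene: str, kind=None, cohort=None):
        g = gene.casefold()
        return [ch for ch in self.channels
                if ch.gene.casefold() == g
                and (kind is None or ch.kind == kind)
                and (cohort is None or ch.cohort == cohort)]

    def has_channel(self, gene: str, kind=None, cohort=None) -> bool:
        return bool(self._matches(gene, kind, cohort))

    def get_channel(self, gene: str, kind: str | None = None, cohort: int | None = None) -> GeneChannel:
        """Return the channel for ``gene``.

        When ``kind`` is not given, protein is preferred for the gene products
        that have protein measurements (Bcd, Hb, Kr, Gt) and mRNA otherwise;
        if the preferred kind is absent the other is returned with a warning.
        A single-cohort atlas does not require ``cohort``.
        """
        matches = self._matches(gene, kind, cohort)
        if not matches:
            if kind is not None or cohort is not None:
                loose = self._matches(gene)
                if loose:
                    raise LookupChannelError(
                        f"gene {gene!r} present but not with kind={kind} cohort={cohort}; "
                        f"available: {[ch.key for ch in loose]}")
            names = sorted({ch.gene for ch in self.channels})
            near = difflib.get_close_matches(gene, names, n=5, cutoff=0.5)
            raise LookupChannelError(f"unknown gene {gene!r}; close matches: {near}")
        if kind is None:
            prefer = PROTEIN if gene.casefold() in {p.casefold() for p in PROTEIN_GENES} else MRNA
            preferred = [ch for ch in matches if ch.kind == prefer]
            if not preferred:
                logger.warning("channel %s: preferred kind %s absent, falling back to %s",
                               gene, prefer, matches[0].kind)
                preferred = matches
            matches = preferred
        cohorts = sorted({ch.cohort for ch in matches})
        if len(cohorts) > 1:
            raise LookupChannelError(
                f"gene {gene!r} present in cohorts {cohorts}; pass cohort= or select_cohort() first")
        return matches[0]

    def values(self, gene: str, kind: str | None = None, cohort: int | None = None) -> np.ndarray:
        return self.get_channel(gene, kind, cohort).values

    def select_cohort(self, cohort: int) -> "ExpressionAtlas":
        """Atlas restricted to one cohort's channels; geometry unchanged."""
        if cohort not in self.cohorts:
            raise LookupChannelError(f"cohort {cohort} absent; available cohorts: {self.cohorts}")
        kept = [ch for ch in self.channels if ch.cohort == cohort]
        return replace(self, channels=list(kept))

    def candidate_regulators(self, target: str = "eve", exclude=PAIR_RULE_EXCLUDED) -> list:
        """(gene, kind) pairs eligible as regulators of ``target``.

        Protein is used in place of mRNA for the gene products with protein
        measurements; the target itself and the excluded pair-rule genes are
        dropped.  On the real release this yields 38 entries (34 mRNA + 4
        protein); on synthetic atlases the size follows the channel content.
        """
        dropped = {g.casefold() for g in exclude} | {target.casefold()}
        by_gene = {}
        for ch in self.channels:
            g = ch.gene.casefold()
            if g in dropped:
                continue
            cur = by_gene.get(g)
            if cur is None or (ch.kind == PROTEIN and cur[1] == MRNA):
                by_gene[g] = (ch.gene, ch.kind)
        return sorted(by_gene.values())

    def with_channel(self, channel: GeneChannel, overwrite: bool = False) -> "ExpressionAtlas":
        """New atlas with ``channel`` added (or replaced when ``overwrite``)."""
        chans = [ch for ch in self.channels if not (overwrite and ch.key == channel.key)]
        if any(ch.key == channel.key for ch in chans):
            raise ValidationError(f"channel {channel.key} already present")
        return replace(self, channels=chans + [channel])


# ---------------------------------------------------------------------- I/O

def read_atlas(path, column_map: ColumnMap | None = None) -> ExpressionAtlas:
    """Read a VPC-dialect CSV file into an :class:`ExpressionAtlas`.

    Gene names are reported verbatim from the header.  Raises
    :class:`FormatError` when coordinate columns are missing and
    :class:`ValidationError` (naming the offending pair) when the neighbor
    relation is asymmetric.
    """
    cmap = column_map or ColumnMap()
    # the neighbors column must stay textual: a file with any empty neighbor
    # list would otherwise be inferred as float ("2" -> "2.0")
    df = pd.read_csv(path, dtype={cmap.neighbors_col: str})
    required = [cmap.id_col, cmap.x_col, cmap.y_col, cmap.z_col, cmap.neighbors_col]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required columns {missing}")

    neighbors = []
    for raw in df[cmap.neighbors_col].astype(str):
        raw = raw.strip()
        neighbors.append([int(t) for t in raw.split(";") if t] if raw and raw != "nan" else [])

    pattern = re.compile(cmap.channel_pattern)
    protein = {g.casefold() for g in cmap.protein_genes}
    channels = []
    for col in df.columns:
        if col in required:
            continue
        m = pattern.match(col)
        if m is None:
            logger.warning("column %r does not match the channel pattern; ignored", col)
            continue
        gene = m.group("gene")
        kind = PROTEIN if gene.casefold() in protein else MRNA
        channels.append(GeneChannel(gene, kind, int(m.group("cohort")), df[col].to_numpy(float)))

    atlas = ExpressionAtlas(
        nucleus_ids=df[cmap.id_col].to_numpy(int),
        x=df[cmap.x_col].to_numpy(float),
        y=df[cmap.y_col].to_numpy(float),
        z=df[cmap.z_col].to_numpy(float),
        neighbors=neighbors,
        channels=channels,
    )
    atlas.validate()
    return atlas


def write_atlas(atlas: ExpressionAtlas, path, column_map: ColumnMap | None = None):
    """Write the atlas in the VPC dialect; values round-trip within 1e-9."""
    if not atlas.channels:
        raise ValidationError("refusing to write an atlas with no expression channels")
    atlas.validate()
    cmap = column_map or ColumnMap()
    cols = {
        cmap.id_col: atlas.nucleus_ids,
        cmap.x_col: atlas.x,
        cmap.y_col: atlas.y,
        cmap.z_col: atlas.z,
        cmap.neighbors_col: [";".join(str(int(m)) for m in nb) for nb in atlas.neighbors],
    }
    for ch in atlas.channels:
        cols[cmap.channel_column(ch.gene, ch.cohort)] = ch.values
    pd.DataFrame(cols).to_csv(path, index=False, float_format="%.12g")
    return path
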