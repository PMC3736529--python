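"""Exhaustive regulator discovery by scoring all k-regulator models.

Every combination of k (default 4) candidate regulators is fitted on the same
training rows and scored by its maximized log-likelihood (AIC is stored
alongside, since quadratic mode mixes parameter counts).  The scores are
summarized as a pairwise-best matrix: entry (a, b) holds the best score among
all combinations containing both a and b, so regulators that are consistently
informative show up as high-value bands.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np

from . import model as model_mod
from .errors import StripefitError
from .labeling import TrainingSet

logger = logging.getLogger(__name__)


def enumerate_combinations(regulators, k: int = 4):
    """All k-subsets of the candidate list, each exactly once.

    Candidates are sorted internally so the order (and all downstream scores)
    is invariant to the input ordering.
    """
    regs = sorted(regulators)
    if k > len(regs):
        raise StripefitError(f"cannot choose {k} of {len(regs)} candidates")
    return itertools.combinations(regs, k)


@dataclass
class DiscoveryResult:
    """Scores for every regulator combination plus pairwise-best summaries."""

    candidates: list                     # sorted (gene, kind) pairs
    records: list                        # dicts: combination, score, aic, ...
    mode: str                            # "linear" | "quadratic"
    dual_set: frozenset = frozenset()

    def ranked(self) -> list:
        return sorted(self.records, key=lambda r: -r["score"])

    @property
    def best(self) -> dict:
        return self.ranked()[0]

    def rank_of(self, combination) -> int:
        """1-based rank of a combination (ties broken by score order)."""
        key = frozenset(combination)
        for i, rec in enumerate(self.ranked(), start=1):
            if frozenset(rec["combination"]) == key:
                return i
        raise StripefitError(f"combination {sorted(key)} was not scored")

    def pairwise_best_matrix(self) -> np.ndarray:
        """Symmetric matrix of best scores over combinations containing each pair.

        The diagonal holds the best score among combinations containing the
        single regulator.  Entries for pairs never co-occurring (possible only
        for k < 2) are -inf.
        """
        n = len(self.candidates)
        pos = {c: i for i, c in enumerate(self.candidates)}
        m = np.full((n, n), -np.inf)
        for rec in self.records:
            s = rec["score"]
            idxs = [pos[c] for c in rec["combination"]]
            for i in idxs:
                if s > m[i, i]:
                    m[i, i] = s
            for i, j in itertools.combinations(idxs, 2):
                if s > m[i, j]:
                    m[i, j] = m[j, i] = s
        return m

    def matrix_frame(self):
        import pandas as pd
        names = [g for g, _ in self.candidates]
        return pd.DataFrame(self.pairwise_best_matrix(), index=names, columns=names)

    def ranked_frame(self):
        import pandas as pd
        rows = [{"rank": i, "combination": "+".join(g for g, _ in sorted(r["combination"])),
                 "score": r["score"], "aic": r["aic"], "n_parameters": r["n_parameters"],
                 "converged": r["converged"], "separation": r["separation"]}
                for i, r in enumerate(self.ranked(), start=1)]
        return pd.DataFrame(rows)


def score_all(ts: TrainingSet, candidates=None, k: int = 4, mode: str = "linear",
              dual_set=(), options: model_mod.FitOptions | None = None) -> DiscoveryResult:
    """Fit and score every k-combination of candidates on the same rows.

    ``ts`` must carry concentration columns for every candidate.  In
    quadratic mode each combination gets a squared term for every member of
    ``dual_set`` it contains.  A fit that fails numerically is recorded with
    score -inf and the failure reason rather than aborting the sweep;
    quasi-separation is not failure and keeps its achieved likelihood.
    """
    if mode not in ("linear", "quadratic"):
        raise StripefitError(f"unknown discovery mode {mode!r}")
    cands = sorted(candidates if candidates is not None else ts.regulator_names)
    dual = frozenset(d if isinstance(d, tuple) else (d, None) for d in dual_set)
    dual_genes = {g.casefold() for g, _ in dual}
    if mode == "quadratic" and not dual_genes <= {g.casefold() for g, _ in cands}:
        raise StripefitError("dual_set must be a subset of the candidates")

    records = []
    for comb in enumerate_combinations(cands, k):
        quad = tuple(c for c in comb if mode == "quadratic" and c[0].casefold() in dual_genes)
        spec = model_mod.ModelSpec(regulators=comb, quadratic=quad)
        rec = {"combination": comb, "n_parameters": spec.n_parameters,
               "converged": False, "separation": False, "reason": None}
        try:
            fm = model_mod.fit(ts, spec, options)
            if fm.converged:
                rec.update(score=fm.log_likelihood, converged=True,
                           separation=fm.separation_flag)
            else:
                rec.update(score=-np.inf, reason="did not converge",
                           separation=fm.separation_flag)
        except StripefitError as exc:  # pragma: no cover - defensive
            rec.update(score=-np.inf, reason=str(exc))
        rec["aic"] = 2 * spec.n_parameters - 2 * rec["score"]
        records.append(rec)
    return DiscoveryResult(candidates=cands, records=records, mode=mode, dual_set=dual)
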