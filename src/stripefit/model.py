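"""Linear and quadratic logistic regulatory-input functions.

A regulatory input function maps the transcription-factor concentrations in a
nucleus to the probability that the target enhancer is ON there.  For nucleus
i with regulator concentrations x_1i..x_ki the linear predictor is

    eta_i = beta0 + beta_1 x_1i + ... + beta_k x_ki  [+ beta_q x_qi^2 ...]

and p_i = 1 / (1 + exp(-eta_i)).  A quadratic term for a regulator lets its
marginal effect on eta change sign with concentration ("dual regulation"):
with beta_q > 0 > beta_qq the factor activates below the crossover
x* = -beta_q / (2 beta_qq) and represses above it.

Fitting maximizes the Bernoulli log-likelihood by Newton iteration (IRLS)
with step-halving.  Quasi-complete separation — fitted probabilities
numerically at 0 or 1 — is a *desirable* outcome for a sharp classifier here
and is reported via a flag, never raised as an error.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import scipy.linalg
from scipy.special import expit

from .errors import DegenerateResponseError, LookupChannelError, ValidationError

logger = logging.getLogger(__name__)


def _as_reg(r):
    """Normalize a regulator reference to (gene, kind-or-None)."""
    if isinstance(r, str):
        return (r, None)
    g, k = r
    return (g, k)


@dataclass(frozen=True)
class ModelSpec:
    """Which regulators enter the model, and which get a quadratic term."""

    regulators: tuple
    quadratic: tuple = ()
    include_intercept: bool = True

    def __post_init__(self):
        regs = tuple(_as_reg(r) for r in self.regulators)
        quad = tuple(_as_reg(r) for r in self.quadratic)
        object.__setattr__(self, "regulators", regs)
        object.__setattr__(self, "quadratic", quad)
        genes = [g.casefold() for g, _ in regs]
        if len(set(genes)) != len(genes):
            raise ValidationError(f"duplicate regulators in {regs}")
        reg_genes = set(genes)
        for g, _ in quad:
            if g.casefold() not in reg_genes:
                raise ValidationError(f"quadratic regulator {g!r} is not among the linear regulators")

    @property
    def n_parameters(self) -> int:
        return int(self.include_intercept) + len(self.regulators) + len(self.quadratic)

    @property
    def column_names(self) -> list:
        names = ["(intercept)"] if self.include_intercept else []
        names += [g for g, _ in self.regulators]
        names += [f"{g}^2" for g, _ in self.quadratic]
        return names


@dataclass
class FitOptions:
    tol: float = 1e-8           # relative log-likelihood change
    max_iter: int = 100
    ridge: float = 0.0          # optional L2 penalty (all-38 stress test only)
    separation_eps: float = 1e-8


@dataclass
class FittedModel:
    """Coefficients and fit metadata of a logistic regulatory input function."""

    spec: ModelSpec
    beta0: float
    beta: np.ndarray            # one per linear regulator, in spec order
    beta_quad: np.ndarray       # one per quadratic regulator, in spec order
    log_likelihood: float = np.nan
    converged: bool = True
    separation_flag: bool = False
    n_train: int = 0
    n_iter: int = 0
    covariance: np.ndarray | None = None  # inverse observed information

    @property
    def coefficients(self) -> np.ndarray:
        """Full coefficient vector in design-column order."""
        parts = ([self.beta0] if self.spec.include_intercept else [])
        return np.concatenate([parts, np.atleast_1d(self.beta), np.atleast_1d(self.beta_quad)])

    def standard_errors(self) -> np.ndarray:
        if self.covariance is None:
            raise ValidationError("no covariance stored for this model")
        return np.sqrt(np.diag(self.covariance))

    def with_intercept_shift(self, delta: float) -> "FittedModel":
        return replace(self, beta0=self.beta0 + float(delta))

    # ----------------------------------------------------------- persistence
    def to_dict(self) -> dict:
        return {
            "regulators": [list(r) for r in self.spec.regulators],
            "quadratic": [list(r) for r in self.spec.quadratic],
            "include_intercept": self.spec.include_intercept,
            "beta0": float(self.beta0),
            "beta": np.asarray(self.beta, float).tolist(),
            "beta_quad": np.asarray(self.beta_quad, float).tolist(),
            "log_likelihood": float(self.log_likelihood),
            "converged": bool(self.converged),
            "separation_flag": bool(self.separation_flag),
            "n_train": int(self.n_train),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "FittedModel":
        spec = ModelSpec(tuple(tuple(r) for r in d["regulators"]),
                         tuple(tuple(r) for r in d.get("quadratic", [])),
                         d.get("include_intercept", True))
        return cls(spec=spec, beta0=d["beta0"], beta=np.asarray(d["beta"], float),
                   beta_quad=np.asarray(d.get("beta_quad", []), float),
                   log_likelihood=d.get("log_likelihood", np.nan),
                   converged=d.get("converged", True),
                   separation_flag=d.get("separation_flag", False),
                   n_train=d.get("n_train", 0))

    def save(self, path):
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)
        return path

    @classmethod
    def load(cls, path) -> "FittedModel":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


@dataclass
class PredictionField:
    """Per-nucleus linear predictor and ON-probability for a whole atlas."""

    nucleus_ids: np.ndarray
    eta: np.ndarray
    p: np.ndarray
    model: FittedModel | None = None
    cohort: int | None = None

    def to_frame(self):
        import pandas as pd
        return pd.DataFrame({"nucleus_id": self.nucleus_ids, "eta": self.eta, "p": self.p})


# ------------------------------------------------------------------- design

def _regulator_matrix(source, spec: ModelSpec) -> tuple:
    """(values matrix n x k in spec order, squared-column matrix) for a source.

    The source is either a TrainingSet (uses its stored concentrations) or an
    ExpressionAtlas (uses whole-embryo channels via the preference rule).
    """
    cols = []
    if hasattr(source, "regulator_names"):  # TrainingSet
        names = [(_as_reg(r)[0].casefold()) for r in source.regulator_names]
        for g, k in spec.regulators:
            try:
                j = names.index(g.casefold())
            except ValueError:
                raise LookupChannelError(f"regulator {g!r} not in training set {source.regulator_names}")
            cols.append(np.asarray(source.X[:, j], float))
    else:  # ExpressionAtlas
        for g, k in spec.regulators:
            cols.append(source.values(g, kind=k))
    X = np.column_stack(cols) if cols else np.empty((len(source.y) if hasattr(source, "y") else source.n_nuclei, 0))
    quad_cols = []
    genes = [g.casefold() for g, _ in spec.regulators]
    for g, _ in spec.quadratic:
        quad_cols.append(X[:, genes.index(g.casefold())] ** 2)
    Q = np.column_stack(quad_cols) if quad_cols else np.empty((X.shape[0], 0))
    return X, Q


def build_design(source, spec: ModelSpec) -> np.ndarray:
    """Design matrix: [1, x_1..x_k, x_q^2 ...] aligned to the source's rows."""
    X, Q = _regulator_matrix(source, spec)
    blocks = []
    if spec.include_intercept:
        blocks.append(np.ones((X.shape[0], 1)))
    blocks += [X, Q]
    return np.hstack(blocks)


# --------------------------------------------------------------------- fit

def _loglik(eta: np.ndarray, y: np.ndarray) -> float:
    # sum y*eta - log(1 + e^eta), numerically stable
    return float(np.sum(y * eta - np.logaddexp(0.0, eta)))


def fit_design(D: np.ndarray, y: np.ndarray, options: FitOptions | None = None,
               column_names=None):
    """Newton/IRLS maximum-likelihood logistic fit on an explicit design.

    Returns (coef, log_likelihood, converged, separation_flag, n_iter, cov).
    Rank-deficient designs get the offending columns zeroed out with a
    warning naming them.
    """
    opt = options or FitOptions()
    D = np.asarray(D, float)
    y = np.asarray(y, float)
    if y.min() == y.max():
        raise DegenerateResponseError(
            f"response is constant ({int(y[0])} for all {len(y)} rows); cannot fit")

    n, k = D.shape
    keep = np.arange(k)
    # rank check via pivoted QR; drop trailing pivots beyond numerical rank
    _, R, piv = scipy.linalg.qr(D, mode="economic", pivoting=True)
    diag = np.abs(np.diag(R))
    tol = diag.max() * max(n, k) * np.finfo(float).eps if diag.size else 0.0
    rank = int(np.sum(diag > tol))
    if rank < k:
        dropped = sorted(piv[rank:])
        names = [column_names[j] if column_names else str(j) for j in dropped]
        warnings.warn(f"design is rank-deficient; dropping collinear column(s) {names}",
                      RuntimeWarning, stacklevel=2)
        keep = np.array(sorted(piv[:rank]))
        D = D[:, keep]

    beta = np.zeros(D.shape[1])
    eta = D @ beta
    ll = _loglik(eta, y)
    converged = False
    it = 0
    for it in range(1, opt.max_iter + 1):
        p = expit(eta)
        w = p * (1.0 - p)
        H = D.T @ (D * w[:, None])
        if opt.ridge > 0:
            H = H + opt.ridge * np.eye(D.shape[1])
        g = D.T @ (y - p)
        if opt.ridge > 0:
            g = g - opt.ridge * beta
        try:
            # quasi-separation drives the Hessian toward singularity; the
            # conditioning warning would fire every iteration, and separation
            # is reported through the separation flag instead
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", scipy.linalg.LinAlgWarning)
                step = scipy.linalg.solve(H, g, assume_a="pos")
        except scipy.linalg.LinAlgError:
            step = scipy.linalg.lstsq(H, g)[0]
        # step-halving: never let the (penalized) log-likelihood decrease
        scale = 1.0
        for _ in range(40):
            cand = beta + scale * step
            eta_c = D @ cand
            ll_c = _loglik(eta_c, y)
            if opt.ridge > 0:
                ll_c -= 0.5 * opt.ridge * float(cand @ cand)
            if ll_c >= ll - 1e-14:
                break
            scale *= 0.5
        else:
            converged = True  # no uphill step exists: at a maximum
            break
        beta, eta = cand, eta_c
        if abs(ll_c - ll) <= opt.tol * (abs(ll) + 1e-12):
            ll = ll_c
            converged = True
            break
        ll = ll_c

    p = expit(eta)
    separation = bool(np.any(p < opt.separation_eps) or np.any(p > 1 - opt.separation_eps))
    if separation:
        logger.info("fitted probabilities numerically 0 or 1 occurred (quasi-separation); "
                    "max |beta| = %.3g", float(np.max(np.abs(beta))))
    w = np.clip(p * (1.0 - p), 1e-300, None)
    H = D.T @ (D * w[:, None])
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", scipy.linalg.LinAlgWarning)
            cov_k = scipy.linalg.inv(H)
    except scipy.linalg.LinAlgError:
        cov_k = scipy.linalg.pinv(H)

    coef = np.zeros(k)
    coef[keep] = beta
    cov = np.full((k, k), np.nan)
    cov[np.ix_(keep, keep)] = cov_k
    ll_unpen = _loglik(D @ beta, y)
    return coef, ll_unpen, converged, separation, it, cov


def fit(ts, spec: ModelSpec, options: FitOptions | None = None) -> FittedModel:
    """Fit the regulatory input function on a training set."""
    D = build_design(ts, spec)
    coef, ll, converged, separation, n_iter, cov = fit_design(
        D, ts.y, options, column_names=spec.column_names)
    off = 1 if spec.include_intercept else 0
    k = len(spec.regulators)
    return FittedModel(
        spec=spec,
        beta0=float(coef[0]) if spec.include_intercept else 0.0,
        beta=coef[off:off + k].copy(),
        beta_quad=coef[off + k:].copy(),
        log_likelihood=ll,
        converged=converged,
        separation_flag=separation,
        n_train=len(ts.y),
        n_iter=n_iter,
        covariance=cov,
    )


# ----------------------------------------------------------------- predict

def predict(model: FittedModel, atlas, cohort: int | None = None) -> PredictionField:
    """Probability field over every nucleus of the atlas.

    Applies the trained coefficients to the requested cohort's channels,
    including nuclei never seen during training.
    """
    a = atlas.select_cohort(cohort) if cohort is not None else atlas
    D = build_design(a, model.spec)
    eta = D @ model.coefficients
    p = expit(eta)
    return PredictionField(nucleus_ids=a.nucleus_ids.copy(), eta=eta, p=p,
                           model=model, cohort=cohort)


def dual_crossover(model: FittedModel, regulator: str) -> float:
    """Concentration x* = -beta_q / (2 beta_qq) where d(eta)/dx_q flips sign.

    With beta_q > 0 > beta_qq the regulator activates below x* and represses
    above it.
    """
    g = _as_reg(regulator)[0].casefold()
    quad_genes = [q.casefold() for q, _ in model.spec.quadratic]
    if g not in quad_genes:
        raise LookupChannelError(f"regulator {regulator!r} has no quadratic term in this model")
    bq2 = float(np.atleast_1d(model.beta_quad)[quad_genes.index(g)])
    if bq2 == 0.0:
        raise ValidationError(f"quadratic coefficient for {regulator!r} is zero; crossover undefined")
    lin_genes = [r.casefold() for r, _ in model.spec.regulators]
    bq = float(np.atleast_1d(model.beta)[lin_genes.index(g)])
    return -bq / (2.0 * bq2)
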