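"""Pluggable variable-selection backends.

Three backends satisfy the same contract (a score table per molecular
level):

* ``ssvi`` — coordinate-ascent variational inference for a spike-and-slab
  linear regression, run separately on the standardized level-1 design and
  on the mask-aggregated level-2 design; emits posterior inclusion
  probabilities (PIPs).
* ``minsnp`` — univariate ordinary least squares per SNP; a gene's score is
  the smallest p-value among its member SNPs.
* ``exact`` (helper, K <= 12) — exact Bayesian model averaging by subset
  enumeration under the matching slab prior; the test oracle for ``ssvi``.

Third-party backends register by name via :func:`register_backend`.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import Callable, Optional

import numpy as np
from scipy import stats
from scipy.special import expit, logsumexp

from .errors import UsageError, ValidationError
from .io import AnnotationMask, GenotypeDataset, ScoreTable, SelectionResult
from .preprocess import build_group_features, standardize_columns

# p-values from numerically perfect fits underflow to 0; clamp so that
# score tables keep p in (0, 1]
_P_FLOOR = 1e-300


@dataclass
class BackendConfig:
    """Hyperparameters shared by the selection backends.

    ``pi`` defaults to min(0.1, 10/K) at fit time when left as None;
    ``sigma_beta_sq`` (slab variance, in units of the residual variance) is
    derived from the heritability proxy ``h2`` as h2 / ((1 - h2) * pi * K)
    when not given explicitly.
    """

    pi: Optional[float] = None
    sigma_beta_sq: Optional[float] = None
    h2: float = 0.5
    tol: float = 1e-4
    max_iterations: int = 500
    seed: int = 0
    sigma2: Optional[float] = None  # fix residual variance instead of updating

    def __post_init__(self) -> None:
        if self.pi is not None and not 0.0 < self.pi < 1.0:
            raise UsageError(f"pi must lie in (0, 1), got {self.pi}")
        if self.sigma_beta_sq is not None and self.sigma_beta_sq <= 0:
            raise UsageError("sigma_beta_sq must be positive")
        if not 0.0 < self.h2 < 1.0:
            raise UsageError(f"h2 must lie in (0, 1), got {self.h2}")
        if self.tol <= 0:
            raise UsageError("tol must be positive")

    def resolve(self, K: int) -> tuple[float, float]:
        """Effective (pi, sigma_beta_sq) for a K-column design."""
        pi = self.pi if self.pi is not None else min(0.1, 10.0 / K)
        sa = (
            self.sigma_beta_sq
            if self.sigma_beta_sq is not None
            else self.h2 / ((1.0 - self.h2) * pi * K)
        )
        return pi, sa

    def to_dict(self) -> dict:
        return {
            "pi": self.pi,
            "sigma_beta_sq": self.sigma_beta_sq,
            "h2": self.h2,
            "tol": self.tol,
            "max_iterations": self.max_iterations,
            "seed": self.seed,
            "sigma2": self.sigma2,
        }


@dataclass
class VIFit:
    """Raw output of :func:`fit_spike_slab_vi`."""

    alpha: np.ndarray  # PIP per column
    mu: np.ndarray  # posterior slab mean per column
    s2: np.ndarray  # posterior slab variance per column
    sigma2: float
    converged: bool
    n_iterations: int


def fit_spike_slab_vi(
    y: np.ndarray, Z: np.ndarray, config: BackendConfig
) -> VIFit:
    """Coordinate-ascent variational spike-and-slab regression.

    Model: y = Z beta + eps, eps ~ N(0, sigma2 I), and independently
    beta_k ~ pi * N(0, sigma2 * sigma_beta_sq) + (1 - pi) * delta_0.
    The variational family factorizes per coordinate; each coordinate update
    (alpha_k, mu_k, s2_k) is closed-form, as is the residual-variance update.
    Iterates until max_k |delta alpha_k| < tol or ``max_iterations``.

    Initialization is the symmetric point alpha_k = pi, mu_k = 0 for all k,
    so the fit is deterministic and exchangeable columns start exchangeably.
    """
    y = np.asarray(y, dtype=float)
    Z = np.asarray(Z, dtype=float)
    if Z.ndim != 2 or y.ndim != 1 or Z.shape[0] != y.shape[0]:
        raise ValidationError(f"shape mismatch: y {y.shape}, Z {Z.shape}")
    if not (np.isfinite(y).all() and np.isfinite(Z).all()):
        raise ValidationError("non-finite values in y or Z")
    n, K = Z.shape
    if K < 1:
        raise ValidationError("Z must have at least one column")

    pi, sa = config.resolve(K)
    log_odds_prior = np.log(pi) - np.log1p(-pi)

    d = np.einsum("nk,nk->k", Z, Z)  # column squared norms
    Zty = Z.T @ y
    yty = float(y @ y)

    alpha = np.full(K, pi)
    mu = np.zeros(K)
    s2 = np.zeros(K)
    update_sigma2 = config.sigma2 is None
    sigma2 = config.sigma2 if config.sigma2 is not None else max(yty / n, 1e-12)
    Zr = Z @ (alpha * mu)

    converged = False
    it = 0
    for it in range(1, config.max_iterations + 1):
        alpha_old = alpha.copy()
        for k in range(K):
            beta_k = alpha[k] * mu[k]
            s2[k] = sigma2 / (d[k] + 1.0 / sa)
            r_k = Zty[k] - Z[:, k] @ Zr + d[k] * beta_k
            mu[k] = s2[k] * r_k / sigma2
            logit = (
                log_odds_prior
                + 0.5 * np.log(s2[k] / (sigma2 * sa))
                + 0.5 * mu[k] ** 2 / s2[k]
            )
            alpha[k] = expit(logit)
            Zr += Z[:, k] * (alpha[k] * mu[k] - beta_k)
        if update_sigma2:
            b = alpha * mu
            ssr = yty - 2.0 * (b @ Zty) + Zr @ Zr
            var_b = alpha * (s2 + mu**2) - b**2
            sigma2 = (
                ssr + d @ var_b + (alpha * (s2 + mu**2)).sum() / sa
            ) / (n + alpha.sum())
            sigma2 = max(sigma2, 1e-12)
        if np.max(np.abs(alpha - alpha_old)) < config.tol:
            converged = True
            break
    if not converged:
        warnings.warn(
            f"spike-and-slab VI did not converge in {config.max_iterations} "
            "iterations",
            RuntimeWarning,
            stacklevel=2,
        )
    return VIFit(
        alpha=alpha, mu=mu, s2=s2, sigma2=float(sigma2),
        converged=converged, n_iterations=it,
    )


def exact_pip_enumeration(
    y: np.ndarray, Z: np.ndarray, config: BackendConfig
) -> np.ndarray:
    """Exact PIPs by enumerating all 2^K sparsity patterns (K <= 12).

    Each subset S gets prior weight pi^|S| (1-pi)^(K-|S|) times the marginal
    likelihood of y under beta_S ~ N(0, sigma2 * sigma_beta_sq * I). With
    ``config.sigma2`` unset the residual variance is integrated out under
    Jeffreys' prior (matching the VI backend, which estimates sigma2);
    otherwise it is held fixed. PIP_k is the total normalized weight of the
    subsets containing k.
    """
    y = np.asarray(y, dtype=float)
    Z = np.asarray(Z, dtype=float)
    n, K = Z.shape
    if K > 12:
        raise UsageError(f"exact enumeration supports K <= 12, got K={K}")
    pi, sa = config.resolve(K)
    log_pi, log_1mpi = np.log(pi), np.log1p(-pi)
    G = Z.T @ Z
    Zty = Z.T @ y
    yty = float(y @ y)

    log_w = np.empty(2**K)
    members = np.zeros((2**K, K), dtype=bool)
    for m, S in enumerate(itertools.product((False, True), repeat=K)):
        idx = np.array(S, dtype=bool)
        members[m] = idx
        k = int(idx.sum())
        lw = k * log_pi + (K - k) * log_1mpi
        if k == 0:
            quad = yty
            logdet = 0.0
        else:
            A = G[np.ix_(idx, idx)] + np.eye(k) / sa
            sign, logdetA = np.linalg.slogdet(A)
            logdet = k * np.log(sa) + logdetA  # log det(I + sa Z_S Z_S')
            b = Zty[idx]
            quad = yty - float(b @ np.linalg.solve(A, b))
        if config.sigma2 is None:
            lw += -0.5 * logdet - 0.5 * n * np.log(quad)
        else:
            lw += -0.5 * logdet - 0.5 * quad / config.sigma2
        log_w[m] = lw
    log_w -= logsumexp(log_w)
    w = np.exp(log_w)
    return w @ members


# ---------------------------------------------------------------------------
# Backend registry and the two-level fits
# ---------------------------------------------------------------------------

BackendFn = Callable[[GenotypeDataset, AnnotationMask, BackendConfig], SelectionResult]

_BACKENDS: dict[str, BackendFn] = {}


def register_backend(name: str, fn: BackendFn) -> None:
    _BACKENDS[name] = fn


def get_backend(name: str) -> BackendFn:
    try:
        return _BACKENDS[name]
    except KeyError:
        raise UsageError(
            f"unknown backend {name!r}; registered: {sorted(_BACKENDS)}"
        ) from None


def list_backends() -> list[str]:
    return sorted(_BACKENDS)


def fit_two_level(
    data: GenotypeDataset, mask: AnnotationMask, config: BackendConfig
) -> SelectionResult:
    """Spike-and-slab VI on both molecular levels.

    Level 1 fits the standardized genotype columns; level 2 fits the
    mask-aggregated group features from
    :func:`grnkit.preprocess.build_group_features`. Both tables carry PIPs.
    """
    if data.y is None:
        raise UsageError("dataset has no phenotype")
    if np.isnan(data.X).any():
        raise UsageError("X has missing entries; preprocess before fitting")
    if data.variable_ids != mask.row_ids:
        raise ValidationError("variable ids do not match mask row ids")
    y = data.y - data.y.mean()
    Xs = standardize_columns(data.X)
    fit1 = fit_spike_slab_vi(y, Xs, config)
    H, group_ids, _ = build_group_features(data, mask)
    fit2 = fit_spike_slab_vi(y, H, config)
    level1 = ScoreTable(
        ids=list(data.variable_ids),
        scores=[float(a) for a in np.clip(fit1.alpha, 0.0, 1.0)],
        level=1,
        score_kind="pip",
    )
    level2 = ScoreTable(
        ids=group_ids,
        scores=[float(a) for a in np.clip(fit2.alpha, 0.0, 1.0)],
        level=2,
        score_kind="pip",
    )
    pi1, sa1 = config.resolve(data.J)
    pi2, sa2 = config.resolve(mask.G)
    return SelectionResult(
        level1=level1,
        level2=level2,
        backend="ssvi",
        converged=fit1.converged and fit2.converged,
        n_iterations=fit1.n_iterations + fit2.n_iterations,
        seed=config.seed,
        notes={
            "config": config.to_dict(),
            "effective_level1": {"pi": pi1, "sigma_beta_sq": sa1},
            "effective_level2": {"pi": pi2, "sigma_beta_sq": sa2},
            "sigma2_level1": fit1.sigma2,
            "sigma2_level2": fit2.sigma2,
        },
    )


def univariate_pvalue(x: np.ndarray, y: np.ndarray) -> tuple[float, bool]:
    """Two-sided slope p-value of y ~ intercept + x; (p, degenerate_flag)."""
    if np.ptp(x) == 0.0:
        return 1.0, True
    res = stats.linregress(x, y)
    p = float(res.pvalue)
    if not np.isfinite(p) or p <= 0.0:
        p = _P_FLOOR
    return p, False


def minsnp_backend(
    data: GenotypeDataset,
    mask: AnnotationMask,
    config: Optional[BackendConfig] = None,
    sidak: bool = False,
) -> SelectionResult:
    """Univariate regression per SNP; gene score = min member SNP p-value.

    ``sidak=True`` applies a Sidak correction 1 - (1-p)^m to each gene's
    minimum over its m member SNPs (off by default: the raw minimum is the
    procedure as practiced).
    """
    if data.y is None:
        raise UsageError("dataset has no phenotype")
    if np.isnan(data.X).any():
        raise UsageError("X has missing entries; preprocess before fitting")
    if data.N < 3:
        raise UsageError(f"minSNP needs n >= 3 samples, got {data.N}")
    if data.variable_ids != mask.row_ids:
        raise ValidationError("variable ids do not match mask row ids")

    pvals = np.empty(data.J)
    degenerate: list[str] = []
    for j in range(data.J):
        p, flag = univariate_pvalue(data.X[:, j], data.y)
        pvals[j] = p
        if flag:
            degenerate.append(data.variable_ids[j])

    gene_ids: list[str] = []
    gene_p: list[float] = []
    empty_genes: list[str] = []
    for g, gid in enumerate(mask.col_ids):
        member = mask.values[:, g] == 1
        if not member.any():
            empty_genes.append(gid)
            continue
        p = float(pvals[member].min())
        if sidak:
            m = int(member.sum())
            p = float(min(1.0, 1.0 - (1.0 - p) ** m))
            p = max(p, _P_FLOOR)
        gene_ids.append(gid)
        gene_p.append(p)

    level1 = ScoreTable(
        ids=list(data.variable_ids),
        scores=[float(p) for p in pvals],
        level=1,
        score_kind="pvalue",
    )
    level2 = ScoreTable(ids=gene_ids, scores=gene_p, level=2, score_kind="pvalue")
    return SelectionResult(
        level1=level1,
        level2=level2,
        backend="minsnp",
        converged=True,
        n_iterations=1,
        seed=config.seed if config is not None else 0,
        notes={
            "degenerate_fits": degenerate,
            "genes_without_snps": empty_genes,
            "sidak": sidak,
        },
    )


def threshold_scores(table: ScoreTable, cutoff: float) -> list[str]:
    """Ids passing the significance cutoff, preserving table order.

    PIPs: significant iff score >= cutoff (median probability model is
    inclusive). P-values: significant iff score <= cutoff.
    """
    if table.score_kind == "pip":
        if not 0.0 <= cutoff <= 1.0:
            raise UsageError(f"pip cutoff must lie in [0, 1], got {cutoff}")
        return [i for i, s in zip(table.ids, table.scores) if s >= cutoff]
    if not 0.0 < cutoff <= 1.0:
        raise UsageError(f"p-value cutoff must lie in (0, 1], got {cutoff}")
    return [i for i, s in zip(table.ids, table.scores) if s <= cutoff]


def _ssvi_entry(
    data: GenotypeDataset, mask: AnnotationMask, config: BackendConfig
) -> SelectionResult:
    return fit_two_level(data, mask, config)


def _minsnp_entry(
    data: GenotypeDataset, mask: AnnotationMask, config: BackendConfig
) -> SelectionResult:
    return minsnp_backend(data, mask, config)


register_backend("ssvi", _ssvi_entry)
register_backend("minsnp", _minsnp_entry)
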