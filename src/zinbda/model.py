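"""Exact probability computations for the zero-inflated NB hierarchical model.

The count-generating process for feature j in sample i is a zero-inflated
negative binomial: with probability pi_j the observation is a structural
("non-biological") zero, otherwise it is NB with mean

    log(eta_ij) = x_i beta_j + z_i u_j + log(depth_i)

where x is the diet design row (intercept + dummy coding, reference level
omitted), z the cage one-hot row, and depth the sample's total count. The NB
is parameterized by mean mu and dispersion phi with Var = mu + mu^2/phi
(Poisson in the limit phi -> infinity).

The structural-zero indicator is never represented explicitly: the
likelihood marginalizes it, giving for each cell

    y = 0:  log( pi + (1 - pi) * NB(0 | eta, phi) )
    y > 0:  log(1 - pi) + log NB(y | eta, phi)

Priors (matching the fitted model): pi_j ~ Beta(1.5, 1.5),
phi_j^{-1} ~ half-Cauchy(0, 3), every beta ~ Normal(0, sd 5), every cage
effect ~ Normal(0, sd 2). Normal scales are standard deviations. The
half-Cauchy prior is placed on 1/phi; evaluating it as a density in phi
includes the change-of-variables Jacobian |d(1/phi)/dphi| = phi^{-2}.

All functions here are pure; sampling lives in :mod:`zinbda.inference`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import gammaln

from .exceptions import ConfigurationError, ValidationError
from .table_io import CountTable, SampleMetadata

__all__ = [
    "DesignMatrices",
    "ZINBParams",
    "PriorConfig",
    "build_design",
    "nb_log_pmf",
    "zinb_log_likelihood",
    "log_prior",
    "log_posterior",
]


@dataclass
class DesignMatrices:
    """Fixed-effect (diet) and random-effect (cage) design matrices.

    ``x`` is samples x covariates: a leading intercept column plus one dummy
    per non-reference diet level, levels in sorted order. ``z`` is the
    samples x cages one-hot matrix (or None when cages are not modelled).
    """

    x: np.ndarray
    covariate_names: list[str]
    reference_level: str
    z: np.ndarray | None = None
    cage_names: list[str] = field(default_factory=list)

    def __post_init__(self):
        self.x = np.asarray(self.x, dtype=float)
        if self.x.ndim != 2 or self.x.shape[1] != len(self.covariate_names):
            raise ValidationError("x shape inconsistent with covariate names")
        if self.x.shape[0] and not np.all(self.x[:, 0] == 1.0):
            raise ValidationError("first column of x must be the intercept")
        if self.z is not None:
            self.z = np.asarray(self.z, dtype=float)
            if self.z.shape != (self.x.shape[0], len(self.cage_names)):
                raise ValidationError("z shape inconsistent with cage names")
            if self.z.shape[0] and not np.allclose(self.z.sum(axis=1), 1.0):
                raise ValidationError("each z row must sum to 1 (one cage per sample)")

    @property
    def n_samples(self) -> int:
        return self.x.shape[0]

    @property
    def n_covariates(self) -> int:
        return self.x.shape[1]

    @property
    def n_cages(self) -> int:
        return 0 if self.z is None else self.z.shape[1]


@dataclass
class ZINBParams:
    """One parameter state: beta/u are covariate(cage) x feature matrices."""

    beta: np.ndarray  # (n_covariates, n_features)
    u: np.ndarray | None  # (n_cages, n_features) or None
    pi: np.ndarray  # (n_features,)
    phi: np.ndarray  # (n_features,)

    def __post_init__(self):
        self.beta = np.atleast_2d(np.asarray(self.beta, dtype=float))
        self.pi = np.atleast_1d(np.asarray(self.pi, dtype=float))
        self.phi = np.atleast_1d(np.asarray(self.phi, dtype=float))
        if self.u is not None:
            self.u = np.atleast_2d(np.asarray(self.u, dtype=float))
        d = self.beta.shape[1]
        if self.pi.shape != (d,) or self.phi.shape != (d,):
            raise ValidationError("pi/phi length must equal the number of features")
        if self.u is not None and self.u.shape[1] != d:
            raise ValidationError("u width must equal the number of features")

    def in_support(self) -> bool:
        ok = np.all((self.pi >= 0) & (self.pi <= 1)) and np.all(self.phi > 0)
        finite = np.all(np.isfinite(self.beta)) and np.all(np.isfinite(self.pi)) \
            and np.all(np.isfinite(self.phi))
        if self.u is not None:
            finite = finite and np.all(np.isfinite(self.u))
        return bool(ok and finite)


@dataclass
class PriorConfig:
    """Prior hyperparameters of the fitted model.

    Defaults match the model as fitted: Beta(1.5, 1.5) on each pi_j,
    half-Cauchy(scale 3) on each 1/phi_j, Normal(0, sd 5) on every
    regression coefficient (intercept included) and Normal(0, sd 2) on every
    cage effect.
    """

    pi_alpha: float = 1.5
    pi_beta: float = 1.5
    inv_phi_scale: float = 3.0
    beta_sd: float = 5.0
    u_sd: float = 2.0

    def __post_init__(self):
        for name in ("pi_alpha", "pi_beta", "inv_phi_scale", "beta_sd", "u_sd"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"prior parameter {name} must be positive")


def build_design(metadata: SampleMetadata, reference_level: str,
                 include_cage: bool = True) -> DesignMatrices:
    """Dummy-code diet (reference level omitted) and one-hot-code cage.

    Column order is deterministic: intercept, then non-reference diet levels
    sorted; cage columns sorted by label.
    """
    diets = metadata.diet.astype(str)
    levels = sorted(diets.unique())
    if len(metadata) and reference_level not in levels:
        raise ConfigurationError(
            f"reference level {reference_level!r} not among diet levels {levels}"
        )
    others = [lv for lv in levels if lv != reference_level]
    n = len(metadata)
    x = np.ones((n, 1 + len(others)))
    for k, lv in enumerate(others, start=1):
        x[:, k] = (diets == lv).to_numpy(dtype=float)
    names = ["intercept"] + [f"diet[{lv}]" for lv in others]
    z = None
    cage_names: list[str] = []
    if include_cage:
        cages = metadata.cage.astype(str)
        cage_names = sorted(cages.unique())
        z = np.zeros((n, len(cage_names)))
        for c, lab in enumerate(cage_names):
            z[:, c] = (cages == lab).to_numpy(dtype=float)
    return DesignMatrices(x=x, covariate_names=names, reference_level=reference_level,
                          z=z, cage_names=cage_names)


def nb_log_pmf(y, mean, dispersion):
    """Log pmf of the mean/dispersion negative binomial.

    log Gamma(y+phi)/(Gamma(phi) y!) + phi log(phi/(phi+mu)) + y log(mu/(phi+mu)),
    finite for every y >= 0, mu > 0, phi > 0. Broadcasts over array inputs.
    """
    y = np.asarray(y, dtype=float)
    mu = np.asarray(mean, dtype=float)
    phi = np.asarray(dispersion, dtype=float)
    if not (np.all(np.isfinite(y)) and np.all(np.isfinite(mu)) and np.all(np.isfinite(phi))):
        raise ValidationError("nb_log_pmf requires finite inputs")
    if np.any(y < 0) or np.any(mu <= 0) or np.any(phi <= 0):
        raise ValidationError("nb_log_pmf requires y >= 0, mean > 0, dispersion > 0")
    return (gammaln(y + phi) - gammaln(phi) - gammaln(y + 1.0)
            + phi * (np.log(phi) - np.log(phi + mu))
            + y * (np.log(mu) - np.log(phi + mu)))


def _cell_log_likelihood(y, log_eta, pi, phi):
    """Marginalized ZINB log density per cell; vectorized over (samples, features).

    ``log_eta`` is the linear predictor including the log-depth offset; pi and
    phi broadcast along the feature axis.
    """
    y = np.asarray(y, dtype=float)
    mu = np.exp(log_eta)
    nb = (gammaln(y + phi) - gammaln(phi) - gammaln(y + 1.0)
          + phi * (np.log(phi) - np.log(phi + mu))
          + y * (log_eta - np.log(phi + mu)))
    with np.errstate(divide="ignore"):
        log_pi = np.log(pi)
        log1m_pi = np.log1p(-pi)
    zero = np.logaddexp(log_pi, log1m_pi + nb)  # valid where y == 0
    return np.where(y == 0, zero, log1m_pi + nb)


def zinb_log_likelihood(table: CountTable, params: ZINBParams,
                        design: DesignMatrices, depths=None) -> float:
    """Log likelihood of a count table under the marginalized ZINB model.

    The structural-zero indicator is summed out analytically cell by cell
    (log-sum-exp of the two mixture branches), so no discrete latent state is
    ever instantiated.
    """
    depths = np.asarray(table.depths if depths is None else depths, dtype=float)
    if np.any(depths <= 0):
        raise ValidationError("sample depths must be positive (offset is log depth)")
    if design.n_samples != table.n_samples:
        raise ValidationError("design and table disagree on the number of samples")
    if params.beta.shape != (design.n_covariates, table.n_features):
        raise ValidationError("beta shape inconsistent with design/table")
    log_eta = design.x @ params.beta + np.log(depths)[:, None]
    if design.z is not None and params.u is not None:
        log_eta = log_eta + design.z @ params.u
    y = table.counts.T  # samples x features
    cells = _cell_log_likelihood(y, log_eta, params.pi[None, :], params.phi[None, :])
    return float(cells.sum())


def log_prior(params: ZINBParams, priors: PriorConfig | None = None) -> float:
    """Joint log prior density; -inf (not an exception) outside the support.

    The half-Cauchy prior on 1/phi is evaluated in phi with the Jacobian
    phi^{-2}.
    """
    priors = priors or PriorConfig()
    if not params.in_support():
        return -np.inf
    lp = stats.beta.logpdf(params.pi, priors.pi_alpha, priors.pi_beta).sum()
    lp += (stats.halfcauchy.logpdf(1.0 / params.phi, scale=priors.inv_phi_scale)
           - 2.0 * np.log(params.phi)).sum()
    lp += stats.norm.logpdf(params.beta, scale=priors.beta_sd).sum()
    if params.u is not None:
        lp += stats.norm.logpdf(params.u, scale=priors.u_sd).sum()
    return float(lp)


def log_posterior(table: CountTable, params: ZINBParams, design: DesignMatrices,
                  priors: PriorConfig | None = None, depths=None) -> float:
    """Unnormalized log posterior: likelihood + prior; -inf propagates."""
    lp = log_prior(params, priors)
    if not np.isfinite(lp):
        return -np.inf
    return lp + zinb_log_likelihood(table, params, design, depths=depths)
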