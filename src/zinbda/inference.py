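"""Posterior sampling, convergence diagnostics and CLR effect summaries.

The model's likelihood factorizes over features (each feature has its own
coefficients, cage effects, dropout probability and dispersion), so the
sampler updates all features simultaneously with vectorized scalar
Metropolis-within-Gibbs moves on the unconstrained scale: raw coefficients,
logit(pi) and log(1/phi). Step sizes adapt per parameter per feature during
warmup (Robbins-Monro toward 0.44 acceptance, the scalar-update optimum) and
are frozen afterwards.

Compositional coordinates: fitted coefficients describe change in count
relative to sequencing depth, which is only interpretable up to a per-sample
compositional constant. Additive log-ratio (ALR) coordinates remove it by
subtracting the reference feature's coefficient per draw (the reference's
ALR coordinate is identically zero); centred log-ratio (CLR) coordinates
then subtract the across-feature mean, so CLR effects sum to zero over
features within each covariate and draw.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import arviz as az
import numpy as np
import pandas as pd
from scipy.special import gammaln

from .exceptions import ConfigurationError, InitializationError, ValidationError
from .model import PriorConfig, build_design
from .table_io import CountTable, SampleMetadata

logger = logging.getLogger(__name__)

__all__ = [
    "MCMCConfig",
    "PosteriorDraws",
    "DifferentialAbundanceResult",
    "fit_zinb",
    "rhat",
    "ess",
    "beta_to_alr",
    "alr_to_clr",
    "clr_draws",
    "summarize",
]


@dataclass
class MCMCConfig:
    """Sampler settings; defaults are conventional, none are stated by the model."""

    n_chains: int = 4
    n_warmup: int = 1000
    n_draws: int = 1000
    seed: int = 0
    init_step: float = 0.5
    target_accept: float = 0.44
    rhat_max: float = 1.05
    ess_min: float = 100.0

    def __post_init__(self):
        if self.n_chains < 2:
            raise ConfigurationError("need at least 2 chains for split-chain diagnostics")
        if self.n_draws < 1 or self.n_warmup < 0:
            raise ConfigurationError("n_draws must be >= 1 and n_warmup >= 0")
        if self.init_step <= 0:
            raise ConfigurationError("init_step must be positive")


@dataclass
class PosteriorDraws:
    """Stacked posterior draws over chains x draws, plus labels and diagnostics."""

    beta: np.ndarray  # (chains, draws, n_covariates, n_features)
    u: np.ndarray | None  # (chains, draws, n_cages, n_features)
    pi: np.ndarray  # (chains, draws, n_features)
    phi: np.ndarray  # (chains, draws, n_features)
    feature_ids: list[str]
    covariate_names: list[str]
    cage_names: list[str] = field(default_factory=list)
    reference_level: str | None = None
    diagnostics: pd.DataFrame | None = None

    @property
    def n_chains(self) -> int:
        return self.pi.shape[0]

    @property
    def n_draws(self) -> int:
        return self.pi.shape[1]

    def extract(self, parameter: str, feature: str, name: str | None = None) -> np.ndarray:
        """Return the (chains, draws) trace of one scalar parameter."""
        j = self.feature_ids.index(feature)
        if parameter == "beta":
            return self.beta[:, :, self.covariate_names.index(name), j]
        if parameter == "u":
            return self.u[:, :, self.cage_names.index(name), j]
        if parameter in ("pi", "phi"):
            return getattr(self, parameter)[:, :, j]
        raise ConfigurationError(f"unknown parameter {parameter!r}")


@dataclass
class DifferentialAbundanceResult:
    """CLR-scale posterior summaries per feature x covariate.

    ``frame`` columns: feature_id, covariate, clr_mean, clr_sd, lo, hi —
    sorted by covariate then descending CLR mean for reporting.
    """

    frame: pd.DataFrame
    level: float
    reference_feature: str

    def for_covariate(self, covariate: str) -> pd.DataFrame:
        sub = self.frame[self.frame["covariate"] == covariate]
        if sub.empty:
            raise ConfigurationError(f"unknown covariate {covariate!r}; "
                                     f"have {sorted(self.frame['covariate'].unique())}")
        return sub.set_index("feature_id")


# ---------------------------------------------------------------------------
# sampler internals
# ---------------------------------------------------------------------------

_LOGIT_CLIP = (0.02, 0.98)


def _log_sigmoid(t):
    return -np.logaddexp(0.0, -t)


class _FeatureState:
    """Vectorized-over-features sampler state with cached NB cell densities."""

    def __init__(self, Y, X, Z, offset, priors, fix_pi, fix_phi):
        self.Y = Y.astype(float)  # (n, D)
        self.X = X
        self.Z = Z
        self.offset = offset  # (n,)
        self.priors = priors
        self.fix_pi = fix_pi
        self.fix_phi = fix_phi
        self.is_zero = self.Y == 0
        self.gl_y1 = gammaln(self.Y + 1.0)
        self.n, self.D = self.Y.shape

    def set_state(self, B, U, t_pi, s):
        self.B = B  # (P, D)
        self.U = U  # (C, D) or None
        self.t_pi = t_pi  # (D,) or None (pi fixed)
        self.s = s  # (D,) log(1/phi), or None (phi fixed)
        self.L = self.X @ B + self.offset[:, None]
        if self.Z is not None and U is not None:
            self.L += self.Z @ U
        self._set_pi()
        self._set_phi()
        self.nb = self._nb(self.L, self.phi, self.gl_yphi, self.gl_phi, self.philog)
        self.ll = self._ll(self.nb, self.log_pi, self.log1m_pi)

    def _set_pi(self):
        if self.t_pi is None:
            pi = np.full(self.D, self.fix_pi)
            with np.errstate(divide="ignore"):
                self.log_pi = np.log(pi)
                self.log1m_pi = np.log1p(-pi)
        else:
            self.log_pi = _log_sigmoid(self.t_pi)
            self.log1m_pi = _log_sigmoid(-self.t_pi)
        self.pi = np.exp(self.log_pi)

    def _set_phi(self):
        self.phi = (np.full(self.D, self.fix_phi) if self.s is None
                    else np.exp(-self.s))
        self.gl_phi = gammaln(self.phi)
        self.philog = self.phi * np.log(self.phi)
        self.gl_yphi = gammaln(self.Y + self.phi[None, :])

    def _nb(self, L, phi, gl_yphi, gl_phi, philog):
        with np.errstate(over="ignore", invalid="ignore"):
            mu = np.exp(L)
            lpm = np.log(phi[None, :] + mu)
            nb = (gl_yphi - gl_phi[None, :] - self.gl_y1
                  + philog[None, :] - (self.Y + phi[None, :]) * lpm + self.Y * L)
        # overflowing proposals give nan/-inf cells -> -inf feature ll -> reject
        return np.where(np.isfinite(nb), nb, -np.inf)

    def _ll(self, nb, log_pi, log1m_pi):
        with np.errstate(invalid="ignore"):
            zero = np.logaddexp(log_pi[None, :], log1m_pi[None, :] + nb)
            cells = np.where(self.is_zero, zero, log1m_pi[None, :] + nb)
        return cells.sum(axis=0)

    # --- priors on the unconstrained scale (constants dropped) ---

    def _coef_prior(self, b, sd):
        return -0.5 * b * b / (sd * sd)

    def _pi_prior(self, t):
        a, bb = self.priors.pi_alpha, self.priors.pi_beta
        return a * _log_sigmoid(t) + bb * _log_sigmoid(-t)

    def _phi_prior(self, s):
        g = self.priors.inv_phi_scale
        return s - np.log1p(np.exp(2.0 * s) / (g * g))

    # --- block updates; each returns per-feature acceptance probabilities ---

    def update_coef(self, which, k, step, rng):
        mat, col, sd = ((self.B, self.X[:, k], self.priors.beta_sd) if which == "beta"
                        else (self.U, self.Z[:, k], self.priors.u_sd))
        delta = step * rng.standard_normal(self.D)
        Lp = self.L + col[:, None] * delta[None, :]
        nb_p = self._nb(Lp, self.phi, self.gl_yphi, self.gl_phi, self.philog)
        ll_p = self._ll(nb_p, self.log_pi, self.log1m_pi)
        cur = mat[k]
        dlp = (ll_p - self.ll
               + self._coef_prior(cur + delta, sd) - self._coef_prior(cur, sd))
        acc_p = np.exp(np.minimum(0.0, dlp))
        acc = np.log(rng.random(self.D)) < dlp
        if acc.any():
            mat[k, acc] = cur[acc] + delta[acc]
            self.L[:, acc] = Lp[:, acc]
            self.nb[:, acc] = nb_p[:, acc]
            self.ll[acc] = ll_p[acc]
        return acc_p

    def update_shift(self, k, members, step, rng):
        """Translation move along the beta_k / nested-cage ridge.

        When the samples with x_ik = 1 are exactly the samples of a set of
        cages (cages nested in a diet, or all cages for the intercept), adding
        delta to beta_k while subtracting it from those cages' effects leaves
        the linear predictor — hence the likelihood — unchanged, so the move
        is accepted on the prior ratio alone. Scalar updates mix very slowly
        along this prior-identified ridge; this move fixes that.
        """
        delta = step * rng.standard_normal(self.D)
        bk = self.B[k]
        um = self.U[members]  # (m, D)
        dlp = (self._coef_prior(bk + delta, self.priors.beta_sd)
               - self._coef_prior(bk, self.priors.beta_sd)
               + (self._coef_prior(um - delta[None, :], self.priors.u_sd)
                  - self._coef_prior(um, self.priors.u_sd)).sum(axis=0))
        acc_p = np.exp(np.minimum(0.0, dlp))
        acc = np.log(rng.random(self.D)) < dlp
        if acc.any():
            self.B[k, acc] = bk[acc] + delta[acc]
            self.U[np.ix_(members, acc)] -= delta[acc]
        return acc_p

    def update_pi(self, step, rng):
        delta = step * rng.standard_normal(self.D)
        t_p = self.t_pi + delta
        log_pi_p = _log_sigmoid(t_p)
        log1m_p = _log_sigmoid(-t_p)
        ll_p = self._ll(self.nb, log_pi_p, log1m_p)
        dlp = ll_p - self.ll + self._pi_prior(t_p) - self._pi_prior(self.t_pi)
        acc_p = np.exp(np.minimum(0.0, dlp))
        acc = np.log(rng.random(self.D)) < dlp
        if acc.any():
            self.t_pi[acc] = t_p[acc]
            self.log_pi[acc] = log_pi_p[acc]
            self.log1m_pi[acc] = log1m_p[acc]
            self.ll[acc] = ll_p[acc]
            self.pi = np.exp(self.log_pi)
        return acc_p

    def update_phi(self, step, rng):
        delta = step * rng.standard_normal(self.D)
        s_p = self.s + delta
        phi_p = np.exp(-s_p)
        gl_phi_p = gammaln(phi_p)
        philog_p = phi_p * np.log(phi_p)
        gl_yphi_p = gammaln(self.Y + phi_p[None, :])
        nb_p = self._nb(self.L, phi_p, gl_yphi_p, gl_phi_p, philog_p)
        ll_p = self._ll(nb_p, self.log_pi, self.log1m_pi)
        dlp = ll_p - self.ll + self._phi_prior(s_p) - self._phi_prior(self.s)
        acc_p = np.exp(np.minimum(0.0, dlp))
        acc = np.log(rng.random(self.D)) < dlp
        if acc.any():
            self.s[acc] = s_p[acc]
            self.phi[acc] = phi_p[acc]
            self.gl_phi[acc] = gl_phi_p[acc]
            self.philog[acc] = philog_p[acc]
            self.gl_yphi[:, acc] = gl_yphi_p[:, acc]
            self.nb[:, acc] = nb_p[:, acc]
            self.ll[acc] = ll_p[acc]
        return acc_p


def _initial_state(Y, X, Z, offset, rng, fix_pi, fix_phi, jitter=0.0):
    n, D = Y.shape
    P = X.shape[1]
    if n:
        T = np.log(Y + 0.5) - offset[:, None]  # log relative abundance targets
        A = X.T @ X + np.eye(P)  # ridge keeps the solve well-posed
        B = np.linalg.solve(A, X.T @ T)
        zero_frac = (Y == 0).mean(axis=0)
    else:
        B = np.zeros((P, D))
        zero_frac = np.full(D, 0.5)
    U = np.zeros((Z.shape[1], D)) if Z is not None else None
    if fix_pi is None:
        p0 = np.clip(zero_frac, *_LOGIT_CLIP)
        t_pi = np.log(p0) - np.log1p(-p0)
    else:
        t_pi = None
    s = np.zeros(D) if fix_phi is None else None
    if jitter:
        B = B + rng.normal(0.0, jitter, B.shape)
        if U is not None:
            U = U + rng.normal(0.0, jitter, U.shape)
        if t_pi is not None:
            t_pi = t_pi + rng.normal(0.0, jitter, D)
        if s is not None:
            s = s + rng.normal(0.0, jitter, D)
    return B, U, t_pi, s


def _run_chain(Y, X, Z, offset, priors, config, seed_seq, fix_pi, fix_phi):
    rng = np.random.default_rng(seed_seq)
    state = _FeatureState(Y, X, Z, offset, priors, fix_pi, fix_phi)
    for attempt in range(6):
        B, U, t_pi, s = _initial_state(Y, X, Z, offset, rng, fix_pi, fix_phi,
                                       jitter=0.0 if attempt == 0 else 0.1 * attempt)
        state.set_state(B, U, t_pi, s)
        if np.all(np.isfinite(state.ll)):
            break
    else:
        raise InitializationError("non-finite posterior at initialization after 5 retries")

    blocks = [("beta", k) for k in range(X.shape[1])]
    if Z is not None:
        blocks += [("u", c) for c in range(Z.shape[1])]
        # translation moves where a covariate's support is a union of cages
        for k in range(X.shape[1]):
            in_k = X[:, k] == 1.0
            members = np.array([bool(np.all(in_k[Z[:, c] == 1.0])) and Z[:, c].any()
                                for c in range(Z.shape[1])])
            if members.any() and np.array_equal(in_k, (Z @ members) > 0):
                blocks.append(("shift", k, members))
    if fix_pi is None:
        blocks.append(("pi", 0))
    if fix_phi is None:
        blocks.append(("phi", 0))
    D = Y.shape[1]
    log_step = np.full((len(blocks), D), np.log(config.init_step))

    P = X.shape[1]
    out_beta = np.empty((config.n_draws, P, D))
    out_u = np.empty((config.n_draws, Z.shape[1], D)) if Z is not None else None
    out_pi = np.empty((config.n_draws, D))
    out_phi = np.empty((config.n_draws, D))

    total = config.n_warmup + config.n_draws
    for it in range(total):
        for b, block in enumerate(blocks):
            kind, k = block[0], block[1]
            step = np.exp(log_step[b])
            if kind == "beta" or kind == "u":
                acc_p = state.update_coef(kind, k, step, rng)
            elif kind == "shift":
                acc_p = state.update_shift(k, block[2], step, rng)
            elif kind == "pi":
                acc_p = state.update_pi(step, rng)
            else:
                acc_p = state.update_phi(step, rng)
            if it < config.n_warmup:
                rate = (it + 1.0) ** -0.6
                log_step[b] += rate * (acc_p - config.target_accept)
        if it >= config.n_warmup:
            d = it - config.n_warmup
            out_beta[d] = state.B
            if out_u is not None:
                out_u[d] = state.U
            out_pi[d] = state.pi
            out_phi[d] = state.phi
    return out_beta, out_u, out_pi, out_phi


def fit_zinb(table: CountTable, metadata: SampleMetadata,
             priors: PriorConfig | None = None, mcmc: MCMCConfig | None = None, *,
             reference_level: str | None = None, include_cage: bool = True,
             fix_pi: float | None = None, fix_phi: float | None = None,
             depths=None) -> PosteriorDraws:
    """Sample the ZINB posterior for every feature of a (filtered) table.

    The structural-zero indicator is marginalized, never sampled. Sampling is
    on the unconstrained scale (raw coefficients, logit pi, log 1/phi).
    ``fix_pi`` / ``fix_phi`` pin those parameters instead of sampling them
    (``fix_pi=0`` turns zero-inflation off); ``depths`` overrides the offset,
    which defaults to the table's column totals. Split-R-hat and effective
    sample size are computed for every scalar parameter and attached; missing
    the configured thresholds warns but does not fail.
    """
    priors = priors or PriorConfig()
    mcmc = mcmc or MCMCConfig()
    if metadata.sample_ids != table.sample_ids:
        raise ValidationError("metadata is not aligned with the table "
                              "(use table_io.read_metadata)")
    if reference_level is None:
        levels = sorted(metadata.diet.astype(str).unique())
        reference_level = levels[0] if levels else ""
    design = build_design(metadata, reference_level, include_cage=include_cage)
    depths = np.asarray(table.depths if depths is None else depths, dtype=float)
    if depths.shape != (table.n_samples,):
        raise ValidationError("depths must have one entry per sample")
    if np.any(depths <= 0):
        raise ValidationError("depths must be positive")
    if fix_pi is not None and not 0.0 <= fix_pi <= 1.0:
        raise ConfigurationError("fix_pi must lie in [0, 1]")
    if fix_phi is not None and fix_phi <= 0:
        raise ConfigurationError("fix_phi must be positive")

    Y = table.counts.T.astype(float)
    X = design.x
    Z = design.z if (include_cage and design.n_cages > 0) else None
    offset = np.log(depths)
    seeds = np.random.SeedSequence(mcmc.seed).spawn(mcmc.n_chains)
    chains = [_run_chain(Y, X, Z, offset, priors, mcmc, s, fix_pi, fix_phi)
              for s in seeds]
    beta = np.stack([c[0] for c in chains])
    u = np.stack([c[1] for c in chains]) if Z is not None else None
    pi = np.stack([c[2] for c in chains])
    phi = np.stack([c[3] for c in chains])
    draws = PosteriorDraws(
        beta=beta, u=u, pi=pi, phi=phi,
        feature_ids=list(table.feature_ids),
        covariate_names=list(design.covariate_names),
        cage_names=list(design.cage_names) if Z is not None else [],
        reference_level=reference_level,
    )
    draws.diagnostics = _diagnostics_table(draws, fix_pi, fix_phi)
    worst_rhat = draws.diagnostics["rhat"].max()
    worst_ess = draws.diagnostics["ess"].min()
    if (np.isfinite(worst_rhat) and worst_rhat > mcmc.rhat_max) or \
       (np.isfinite(worst_ess) and worst_ess < mcmc.ess_min):
        warnings.warn(
            f"convergence diagnostics outside thresholds: max R-hat "
            f"{worst_rhat:.3f} (limit {mcmc.rhat_max}), min ESS {worst_ess:.0f} "
            f"(limit {mcmc.ess_min:.0f})", stacklevel=2)
    return draws


def _diagnostics_table(draws: PosteriorDraws, fix_pi, fix_phi) -> pd.DataFrame:
    rows = []
    for k, name in enumerate(draws.covariate_names):
        for j, fid in enumerate(draws.feature_ids):
            x = draws.beta[:, :, k, j]
            rows.append(("beta", name, fid, rhat(x), ess(x)))
    scalars = []
    if fix_pi is None:
        scalars.append("pi")
    if fix_phi is None:
        scalars.append("phi")
    for p in scalars:
        arr = getattr(draws, p)
        for j, fid in enumerate(draws.feature_ids):
            x = arr[:, :, j]
            rows.append((p, "-", fid, rhat(x), ess(x)))
    return pd.DataFrame(rows, columns=["parameter", "name", "feature", "rhat", "ess"])


def rhat(samples) -> float:
    """Rank-normalized split-R-hat of one scalar parameter's (chains, draws) trace.

    Zero-variance (constant) chains yield NaN, the undefined marker.
    """
    x = np.asarray(samples, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2:
        raise ValidationError("rhat needs a (chains >= 2, draws) array")
    if np.ptp(x) == 0:
        return float("nan")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return float(az.rhat(x))


def ess(samples) -> float:
    """Rank-normalized bulk effective sample size of a (chains, draws) trace."""
    x = np.asarray(samples, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2:
        raise ValidationError("ess needs a (chains >= 2, draws) array")
    if np.ptp(x) == 0:
        return float("nan")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return float(az.ess(x))


# ---------------------------------------------------------------------------
# compositional coordinates
# ---------------------------------------------------------------------------

def _reference_index(feature_ids, reference_feature) -> int:
    try:
        return list(feature_ids).index(reference_feature)
    except ValueError:
        raise ConfigurationError(
            f"reference feature {reference_feature!r} not in the table") from None


def beta_to_alr(beta, feature_ids, reference_feature):
    """Raw per-feature coefficients -> ALR coordinates (reference column dropped).

    Subtracting the reference feature's coefficient per draw cancels any
    per-sample compositional constant absorbed by the depth offset; the
    reference's own ALR coordinate is identically zero and is omitted.
    Operates on the trailing (feature) axis of an arbitrary-rank array.
    """
    idx = _reference_index(feature_ids, reference_feature)
    beta = np.asarray(beta, dtype=float)
    alr = beta - beta[..., idx:idx + 1]
    return np.delete(alr, idx, axis=-1)


def alr_to_clr(beta_alr, feature_ids, reference_feature):
    """ALR coordinates (reference implicit zero) -> CLR coordinates.

    Re-inserts the reference's zero at its table position and subtracts the
    across-feature mean (the zero included): clr_j = alr_j - mean_k(alr_k).
    Output columns follow ``feature_ids`` order and sum to zero.
    """
    idx = _reference_index(feature_ids, reference_feature)
    alr = np.asarray(beta_alr, dtype=float)
    if alr.shape[-1] != len(feature_ids) - 1:
        raise ValidationError(
            f"expected {len(feature_ids) - 1} ALR coordinates, got {alr.shape[-1]}")
    full = np.insert(alr, idx, 0.0, axis=-1)
    return full - full.mean(axis=-1, keepdims=True)


def clr_draws(draws: PosteriorDraws, reference_feature: str | None = None) -> np.ndarray:
    """Per-draw CLR coefficients (chains, draws, covariates, features)."""
    ref = reference_feature if reference_feature is not None else draws.feature_ids[0]
    alr = beta_to_alr(draws.beta, draws.feature_ids, ref)
    return alr_to_clr(alr, draws.feature_ids, ref)


def summarize(draws: PosteriorDraws, level: float = 0.95,
              reference_feature: str | None = None) -> DifferentialAbundanceResult:
    """CLR posterior mean, sd and central credible interval per feature x covariate."""
    if not 0.0 < level < 1.0:
        raise ConfigurationError("credible level must lie strictly between 0 and 1")
    ref = reference_feature if reference_feature is not None else draws.feature_ids[0]
    clr = clr_draws(draws, ref)  # (chains, draws, P, D)
    flat = clr.reshape(-1, clr.shape[2], clr.shape[3])
    lo_q, hi_q = (1.0 - level) / 2.0, 1.0 - (1.0 - level) / 2.0
    mean = flat.mean(axis=0)
    sd = flat.std(axis=0, ddof=1) if flat.shape[0] > 1 else np.zeros_like(mean)
    lo = np.quantile(flat, lo_q, axis=0)
    hi = np.quantile(flat, hi_q, axis=0)
    rows = []
    for k, cov in enumerate(draws.covariate_names):
        for j, fid in enumerate(draws.feature_ids):
            rows.append((fid, cov, mean[k, j], sd[k, j], lo[k, j], hi[k, j]))
    frame = pd.DataFrame(rows, columns=["feature_id", "covariate", "clr_mean",
                                        "clr_sd", "lo", "hi"])
    frame = frame.sort_values(["covariate", "clr_mean"],
                              ascending=[True, False]).reset_index(drop=True)
    return DifferentialAbundanceResult(frame=frame, level=level, reference_feature=ref)
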