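"""Synthetic data with the generative structure the ZINB model assumes.

The generator emulates a caged-mouse shotgun-metagenomics experiment: cages
are nested within diet groups, every sample in a cage shares that cage's
per-feature random effect, sequencing depth varies lognormally across
samples, diet acts as a per-feature log-linear fixed effect on relative
abundance, counts are negative binomial around depth * relative abundance,
and each feature has a structural-zero (dropout) probability applied
independently per observation.

Defaults: 4 diet groups (low fat / high fat, each with and without dietary
sphingolipid), two cages per diet, 5 mice per cage, nominal depth 1e6 reads
(lognormal sd 0.3 on the log scale), baseline log relative abundance
Normal(log(1/n_features), 1) so column totals track nominal depth, diet
effects Normal(0, 1) on the natural-log scale, cage effects Normal(0, 0.5),
dropout probabilities Beta(1.5, 1.5), NB dispersions LogNormal(log 5, 0.5).
The effect scale is kept moderate on purpose: much larger diet effects let a
single feature dominate a small composition, and the observed-depth offset
then tracks that feature's dropout rather than sequencing effort.

The cage-effect sd deliberately differs from the fitting prior's scale 2:
a weakly informative prior is wider than realistic cage-to-cage variation,
and with two cages per diet the diet coefficient is only prior-identified
against the cage effects, so simulating cage noise at the prior scale would
swamp any realistic diet signal (see docs/methods.md).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import NamedTuple

import numpy as np
import pandas as pd

from .exceptions import ConfigurationError, ValidationError
from .table_io import CountTable, SampleMetadata

__all__ = [
    "SimulationConfig",
    "SimulationTruth",
    "AnnotationTruth",
    "generate_truth",
    "simulate_count_table",
    "simulate_genome_annotations",
]

DEFAULT_DIETS = ("LFD", "LFD_noSG", "HFD", "HFD_noSG")


@dataclass
class SimulationConfig:
    """Hyperparameters of the generative model; all laws on the natural-log scale."""

    n_features: int = 30
    n_cages: int = 8
    samples_per_cage: int = 5
    diet_levels: tuple[str, ...] = DEFAULT_DIETS
    cage_to_diet: dict[str, str] | None = None
    depth_log_mean: float = math.log(1e6)
    depth_log_sd: float = 0.3
    intercept_mean: float | None = None  # default log(1/n_features)
    intercept_sd: float = 1.0
    beta_sd: float = 1.0
    u_sd: float = 0.5
    pi_alpha: float = 1.5
    pi_beta: float = 1.5
    phi_log_mean: float = math.log(5.0)
    phi_log_sd: float = 0.5
    seed: int = 0

    def __post_init__(self):
        if min(self.n_features, self.n_cages, self.samples_per_cage) < 1:
            raise ConfigurationError("n_features, n_cages, samples_per_cage must be >= 1")
        if not self.diet_levels:
            raise ConfigurationError("at least one diet level required")
        if len(set(self.diet_levels)) != len(self.diet_levels):
            raise ConfigurationError("duplicate diet levels")
        for name in ("depth_log_sd", "intercept_sd", "pi_alpha", "pi_beta", "phi_log_sd"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be positive")
        for name in ("beta_sd", "u_sd"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be non-negative")
        if self.intercept_mean is None:
            self.intercept_mean = math.log(1.0 / self.n_features)
        if self.cage_to_diet is None:
            # cages split evenly over diets, in order: C1.. -> diet blocks
            self.cage_to_diet = {
                self.cage_ids[c]: self.diet_levels[(c * len(self.diet_levels)) // self.n_cages]
                for c in range(self.n_cages)
            }
        else:
            if set(self.cage_to_diet) != set(self.cage_ids):
                raise ConfigurationError("cage_to_diet must map exactly the cage ids "
                                         f"{self.cage_ids}")
            bad = {d for d in self.cage_to_diet.values() if d not in self.diet_levels}
            if bad:
                raise ConfigurationError(f"cage_to_diet uses unknown diets: {sorted(bad)}")

    @property
    def cage_ids(self) -> list[str]:
        return [f"C{c + 1}" for c in range(self.n_cages)]

    @property
    def sample_ids(self) -> list[str]:
        n = self.n_cages * self.samples_per_cage
        width = len(str(n))
        return [f"S{i + 1:0{width}d}" for i in range(n)]

    @property
    def n_samples(self) -> int:
        return self.n_cages * self.samples_per_cage

    @property
    def reference_level(self) -> str:
        return self.diet_levels[0]

    @property
    def effect_names(self) -> list[str]:
        """Diet covariates carrying a true effect (reference level omitted)."""
        return [lv for lv in self.diet_levels if lv != self.reference_level]

    def metadata(self) -> SampleMetadata:
        rows = []
        i = 0
        for cage in self.cage_ids:
            for _ in range(self.samples_per_cage):
                rows.append((self.sample_ids[i], self.cage_to_diet[cage], cage))
                i += 1
        return SampleMetadata(pd.DataFrame(rows, columns=["sample_id", "diet", "cage"]))

    def to_dict(self) -> dict:
        d = asdict(self)
        d["diet_levels"] = list(self.diet_levels)
        return d


@dataclass
class SimulationTruth:
    """Ground-truth parameters behind one simulated dataset.

    ``beta_true`` rows follow ``config.effect_names`` (the reference diet's
    effect is identically zero and not stored); the per-feature baseline is
    ``intercept_true``. All effects are on the natural-log (ALR-interpretable)
    scale.
    """

    intercept_true: np.ndarray  # (n_features,)
    beta_true: np.ndarray  # (n_diets - 1, n_features)
    u_true: np.ndarray  # (n_cages, n_features)
    pi_true: np.ndarray  # (n_features,)
    phi_true: np.ndarray  # (n_features,)
    depths: np.ndarray  # (n_samples,)

    def validate(self, config: SimulationConfig) -> None:
        d = config.n_features
        expect = {
            "intercept_true": (d,),
            "beta_true": (len(config.diet_levels) - 1, d),
            "u_true": (config.n_cages, d),
            "pi_true": (d,),
            "phi_true": (d,),
            "depths": (config.n_samples,),
        }
        for name, shape in expect.items():
            if np.asarray(getattr(self, name)).shape != shape:
                raise ValidationError(f"truth field {name} has shape "
                                      f"{np.asarray(getattr(self, name)).shape}, expected {shape}")
        if np.any((self.pi_true < 0) | (self.pi_true > 1)):
            raise ValidationError("pi_true must lie in [0, 1]")
        if np.any(self.phi_true <= 0):
            raise ValidationError("phi_true must be positive")

    def to_dict(self) -> dict:
        return {k: np.asarray(v).tolist() for k, v in asdict(self).items()}


class AnnotationTruth(NamedTuple):
    """Annotations plus the generator's record of which genomes are complete."""

    annotations: dict[str, set[str]]
    pathway_definitions: dict[str, set[str]]
    complete_genomes: dict[str, set[str]]  # pathway id -> genome ids with completeness 1


def _rngs(config: SimulationConfig, n: int) -> list[np.random.Generator]:
    return [np.random.default_rng(s) for s in np.random.SeedSequence(config.seed).spawn(n)]


def generate_truth(config: SimulationConfig) -> SimulationTruth:
    """Draw ground-truth parameters from the configured laws (seeded)."""
    rng = _rngs(config, 2)[0]
    d = config.n_features
    depths = rng.lognormal(config.depth_log_mean, config.depth_log_sd, config.n_samples)
    intercept = rng.normal(config.intercept_mean, config.intercept_sd, d)
    n_eff = len(config.diet_levels) - 1
    beta = (rng.normal(0.0, config.beta_sd, (n_eff, d)) if config.beta_sd > 0
            else np.zeros((n_eff, d)))
    u = (rng.normal(0.0, config.u_sd, (config.n_cages, d)) if config.u_sd > 0
         else np.zeros((config.n_cages, d)))
    pi = rng.beta(config.pi_alpha, config.pi_beta, d)
    phi = rng.lognormal(config.phi_log_mean, config.phi_log_sd, d)
    truth = SimulationTruth(intercept_true=intercept, beta_true=beta, u_true=u,
                            pi_true=pi, phi_true=phi, depths=depths)
    truth.validate(config)
    return truth


def expected_counts(truth: SimulationTruth, config: SimulationConfig) -> np.ndarray:
    """NB mean matrix eta (features x samples) implied by the truth."""
    meta = config.metadata()
    effect_idx = {lv: k for k, lv in enumerate(config.effect_names)}
    cage_idx = {c: k for k, c in enumerate(config.cage_ids)}
    log_eta = np.empty((config.n_features, config.n_samples))
    for i in range(config.n_samples):
        diet = meta.diet.iloc[i]
        cage = meta.cage.iloc[i]
        lp = truth.intercept_true + truth.u_true[cage_idx[cage]]
        if diet in effect_idx:
            lp = lp + truth.beta_true[effect_idx[diet]]
        log_eta[:, i] = lp + np.log(truth.depths[i])
    return np.exp(log_eta)


def simulate_count_table(truth: SimulationTruth,
                         config: SimulationConfig) -> tuple[CountTable, SampleMetadata]:
    """Draw a ZINB count table: NB(eta, phi) masked by per-observation dropout.

    For each cell an independent Bernoulli(pi_j) indicator decides whether the
    observation is a structural zero; otherwise the NB count is kept.
    """
    truth.validate(config)
    rng = _rngs(config, 2)[1]
    eta = expected_counts(truth, config)  # features x samples
    phi = truth.phi_true[:, None]
    p = phi / (phi + eta)
    counts = rng.negative_binomial(phi, p).astype(np.int64)
    dropout = rng.random(counts.shape) < truth.pi_true[:, None]
    counts[dropout] = 0
    feature_ids = [f"G{j + 1:04d}" for j in range(config.n_features)]
    table = CountTable(counts, feature_ids, config.sample_ids)
    return table, config.metadata()


def simulate_genome_annotations(truth: SimulationTruth, config: SimulationConfig,
                                n_pathways: int = 5, reactions_per_pathway: int = 4,
                                complete_fraction: float = 0.5,
                                planted_effect: int | None = None) -> AnnotationTruth:
    """Generate genome -> reaction annotations with known pathway completeness.

    For each pathway exactly ``floor(complete_fraction * n_genomes)`` genomes
    carry all of its reactions; every other genome is missing at least one
    (it gets a seeded random proper subset). If ``planted_effect`` is given,
    the first pathway's complete genomes are the genomes with the largest
    true effect for that diet covariate (row index into ``beta_true``), so
    completeness of that pathway is positively associated with the effect —
    the planted signal used to validate the completeness/effect correlation.
    """
    if not 0.0 <= complete_fraction <= 1.0:
        raise ConfigurationError("complete_fraction must lie in [0, 1]")
    if reactions_per_pathway < 1:
        raise ConfigurationError("reactions_per_pathway must be >= 1")
    if n_pathways < 1:
        raise ConfigurationError("n_pathways must be >= 1")
    if planted_effect is not None and not 0 <= planted_effect < truth.beta_true.shape[0]:
        raise ConfigurationError("planted_effect is not a valid effect row index")
    rng = np.random.default_rng(np.random.SeedSequence(config.seed).spawn(3)[2])
    genomes = [f"G{j + 1:04d}" for j in range(config.n_features)]
    n_complete = int(math.floor(complete_fraction * len(genomes)))
    pathway_defs: dict[str, set[str]] = {}
    annotations: dict[str, set[str]] = {g: set() for g in genomes}
    complete: dict[str, set[str]] = {}
    for p in range(n_pathways):
        pid = f"PWY{p + 1:03d}"
        reactions = [f"RXN{p + 1:03d}_{r + 1}" for r in range(reactions_per_pathway)]
        pathway_defs[pid] = set(reactions)
        if p == 0 and planted_effect is not None:
            order = np.argsort(truth.beta_true[planted_effect])[::-1]
        else:
            order = rng.permutation(len(genomes))
        chosen = {genomes[j] for j in order[:n_complete]}
        complete[pid] = chosen
        for g in genomes:
            if g in chosen:
                annotations[g].update(reactions)
            elif reactions_per_pathway > 1:
                # proper subset: keep a random number (possibly zero) of reactions
                k = int(rng.integers(0, reactions_per_pathway))
                keep = rng.choice(reactions_per_pathway, size=k, replace=False)
                annotations[g].update(reactions[r] for r in keep)
            # reactions_per_pathway == 1: incomplete genome carries nothing
    return AnnotationTruth(annotations, pathway_defs, complete)
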