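"""Genome pathway completeness and its relation to differential abundance.

Completeness of a pathway in a genome is the fraction of the pathway's
reactions annotated in that genome (a proportion in [0, 1]; "complete" means
exactly 1). Completeness columns are rank-correlated (Spearman) against the
CLR posterior-mean effects of a chosen covariate, and the correlation is
validated model-free through the per-sample log ratio of summed counts of
complete vs incomplete genomes, compared between diet groups by one-way
ANOVA with Fisher's least-significant-difference post hoc tests.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import ConfigurationError, DegeneratePartitionError, ValidationError
from .inference import DifferentialAbundanceResult
from .table_io import CountTable

logger = logging.getLogger(__name__)

__all__ = [
    "CompletenessMatrix",
    "LogRatioSeries",
    "compute_completeness",
    "spearman",
    "correlate_completeness_with_beta",
    "complete_incomplete_log_ratio",
    "compare_groups_lsd",
]

#: Largest n for which the Spearman p-value is computed by exhaustive
#: permutation enumeration (n! permutations); beyond this the t
#: approximation is used.
EXACT_PERMUTATION_MAX_N = 9


@dataclass
class CompletenessMatrix:
    """Genome x pathway proportions in [0, 1] plus pathway reaction counts."""

    frame: pd.DataFrame  # index: genome ids, columns: pathway ids
    reaction_counts: pd.Series  # per pathway

    def __post_init__(self):
        vals = self.frame.to_numpy()
        if vals.size and (np.nanmin(vals) < 0 or np.nanmax(vals) > 1):
            raise ValidationError("completeness values must lie in [0, 1]")

    def complete_genomes(self, pathway: str) -> set[str]:
        col = self.frame[pathway]
        return set(col.index[col == 1.0])

    def incomplete_genomes(self, pathway: str) -> set[str]:
        col = self.frame[pathway]
        return set(col.index[col < 1.0])


@dataclass
class LogRatioSeries:
    """Per-sample log ratio of summed complete vs incomplete genome counts."""

    values: pd.Series  # indexed by sample id
    pathway: str
    complete_set: set[str]
    incomplete_set: set[str]
    pseudocount: float
    base: float  # natural log when math.e


def compute_completeness(annotations, pathway_definitions,
                         genomes=None) -> CompletenessMatrix:
    """Score each genome's completeness of each pathway.

    completeness(g, p) = |reactions of p annotated in g| / |reactions of p|.
    ``genomes`` fixes the row universe (e.g. a count table's features);
    genomes without annotations score 0 everywhere.
    """
    for p, rs in pathway_definitions.items():
        if not rs:
            raise ValidationError(f"pathway {p!r} has no reactions")
    if genomes is None:
        genomes = list(annotations)
    pathways = list(pathway_definitions)
    mat = np.zeros((len(genomes), len(pathways)))
    for i, g in enumerate(genomes):
        have = annotations.get(g, set())
        for k, p in enumerate(pathways):
            rs = pathway_definitions[p]
            mat[i, k] = len(have & rs) / len(rs)
    frame = pd.DataFrame(mat, index=list(genomes), columns=pathways)
    counts = pd.Series({p: len(rs) for p, rs in pathway_definitions.items()})
    return CompletenessMatrix(frame=frame, reaction_counts=counts)


def _rank_correlation(rx: np.ndarray, ry: np.ndarray) -> float:
    """Pearson correlation of average ranks (the tie-corrected Spearman rho)."""
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    denom = math.sqrt((rx * rx).sum() * (ry * ry).sum())
    return float((rx * ry).sum() / denom)


def spearman(x, y, p_method: str = "auto") -> tuple[float, float]:
    """Tie-corrected Spearman rank correlation with a two-sided p-value.

    rho is the Pearson correlation of average (midrank) ranks. The p-value is
    computed by exhaustive permutation enumeration when ``n <= 9`` (exact even
    under ties), and by the usual t approximation otherwise; ``p_method`` can
    force ``"exact"`` or ``"approx"``. A constant input yields (nan, nan).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValidationError("x and y must be equal-length 1-D vectors")
    n = x.size
    if n < 3:
        raise ValidationError("need at least 3 observations")
    if p_method not in ("auto", "exact", "approx"):
        raise ConfigurationError(f"unknown p_method {p_method!r}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return (float("nan"), float("nan"))
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    rho = _rank_correlation(rx, ry)
    exact = p_method == "exact" or (p_method == "auto" and n <= EXACT_PERMUTATION_MAX_N)
    if exact:
        if n > EXACT_PERMUTATION_MAX_N:
            raise ConfigurationError(
                f"exact permutation p limited to n <= {EXACT_PERMUTATION_MAX_N}")
        perms = np.array(list(itertools.permutations(range(n))))
        ry_perm = ry[perms]  # (n!, n)
        rxc = rx - rx.mean()
        ryc = ry_perm - ry_perm.mean(axis=1, keepdims=True)
        den = np.sqrt((rxc * rxc).sum() * (ryc * ryc).sum(axis=1))
        rho_perm = ryc @ rxc / den
        p = float(np.mean(np.abs(rho_perm) >= abs(rho) - 1e-12))
    else:
        # t approximation with n-2 degrees of freedom
        if abs(rho) >= 1.0:
            p = 0.0
        else:
            t = rho * math.sqrt((n - 2) / (1.0 - rho * rho))
            p = float(2.0 * stats.t.sf(abs(t), df=n - 2))
    return rho, p


def correlate_completeness_with_beta(completeness: CompletenessMatrix,
                                     result: DifferentialAbundanceResult,
                                     covariate: str,
                                     p_method: str = "auto") -> pd.DataFrame:
    """Spearman-correlate each pathway's completeness with CLR effect means.

    Returns one row per pathway (rho, p, n shared genomes), ranked by |rho|;
    pathways sharing fewer than 3 genomes with the result are skipped with a
    warning, and constant completeness yields the NaN undefined marker.
    """
    effects = result.for_covariate(covariate)["clr_mean"]
    rows = []
    for pathway in completeness.frame.columns:
        col = completeness.frame[pathway]
        shared = [g for g in col.index if g in effects.index]
        if len(shared) < 3:
            logger.warning("pathway %s shares only %d genomes with the results; skipped",
                           pathway, len(shared))
            continue
        rho, p = spearman(col.loc[shared].to_numpy(),
                          effects.loc[shared].to_numpy(), p_method=p_method)
        rows.append((pathway, rho, p, len(shared)))
    frame = pd.DataFrame(rows, columns=["pathway", "rho", "p", "n"])
    order = frame["rho"].abs().sort_values(ascending=False, na_position="last").index
    return frame.loc[order].reset_index(drop=True)


def complete_incomplete_log_ratio(table: CountTable, completeness: CompletenessMatrix,
                                  pathway: str, pseudocount: float = 1.0,
                                  base: float = math.e) -> LogRatioSeries:
    """Per-sample log ratio of summed counts: complete vs incomplete genomes.

    value_i = log_base( (sum of counts of genomes with completeness 1 + pc)
                        / (sum of counts of genomes with completeness < 1 + pc) ).
    The pseudocount is added to each SUM, not each count. Raw counts are used
    deliberately (model-free validation); the per-sample depth cancels in the
    ratio, so raw and relative abundance give the same value.
    """
    if pathway not in completeness.frame.columns:
        raise ConfigurationError(f"pathway {pathway!r} not in the completeness matrix")
    if pseudocount < 0:
        raise ConfigurationError("pseudocount must be >= 0")
    if base <= 0 or base == 1.0:
        raise ConfigurationError("log base must be positive and != 1")
    in_table = set(table.feature_ids)
    complete = completeness.complete_genomes(pathway) & in_table
    incomplete = completeness.incomplete_genomes(pathway) & in_table
    if not complete or not incomplete:
        raise DegeneratePartitionError(
            f"pathway {pathway!r}: complete/incomplete partition is degenerate "
            f"({len(complete)} complete, {len(incomplete)} incomplete genomes in the table)")
    idx = {f: i for i, f in enumerate(table.feature_ids)}
    num = table.counts[[idx[g] for g in sorted(complete)], :].sum(axis=0)
    den = table.counts[[idx[g] for g in sorted(incomplete)], :].sum(axis=0)
    with np.errstate(divide="ignore"):
        vals = (np.log(num + pseudocount) - np.log(den + pseudocount)) / math.log(base)
    series = pd.Series(vals, index=table.sample_ids, name=f"logratio[{pathway}]")
    return LogRatioSeries(values=series, pathway=pathway, complete_set=complete,
                          incomplete_set=incomplete, pseudocount=pseudocount, base=base)


def compare_groups_lsd(values, groups) -> tuple[float, pd.DataFrame]:
    """One-way ANOVA F plus Fisher LSD pairwise p-values.

    Fisher's least significant difference: after the omnibus ANOVA, each pair
    of group means is compared with a t statistic using the pooled ANOVA error
    variance (MSE) on N - k degrees of freedom, unadjusted for multiplicity.
    Returns (F, frame) where the frame has one row per group pair with the
    mean difference, t, and p. If every observation is identical the MSE is
    zero and F is the NaN undefined marker (all pairwise p NaN).
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    if values.shape != groups.shape or values.ndim != 1:
        raise ValidationError("values and groups must be equal-length 1-D vectors")
    labels = sorted(pd.unique(groups).tolist())
    if len(labels) < 2:
        raise ValidationError("need at least 2 groups")
    by = {g: values[groups == g] for g in labels}
    small = [g for g, v in by.items() if v.size < 2]
    if small:
        raise ValidationError(f"groups with fewer than 2 observations: {small}")
    n_total = values.size
    k = len(labels)
    grand = values.mean()
    ss_between = sum(v.size * (v.mean() - grand) ** 2 for v in by.values())
    ss_within = sum(((v - v.mean()) ** 2).sum() for v in by.values())
    df_b, df_w = k - 1, n_total - k
    mse = ss_within / df_w
    if mse == 0.0:
        f_stat = float("nan")
    else:
        f_stat = (ss_between / df_b) / mse
    rows = []
    for a, b in itertools.combinations(labels, 2):
        diff = by[a].mean() - by[b].mean()
        if mse == 0.0:
            t = p = float("nan")
        else:
            se = math.sqrt(mse * (1.0 / by[a].size + 1.0 / by[b].size))
            t = diff / se
            p = float(2.0 * stats.t.sf(abs(t), df=df_w))
        rows.append((a, b, diff, t, p))
    frame = pd.DataFrame(rows, columns=["group_a", "group_b", "mean_diff", "t", "p"])
    return f_stat, frame
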