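"""Reading, writing and filtering of feature tables, metadata and annotations.

Canonical in-memory orientation is features x samples (rows are genomes or
other features, columns are samples), the convention of BIOM-style tables.
Sequencing depths are always recomputed as column sums of the table, never
trusted from a side file.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .exceptions import EmptyTableError, FormatError, ValidationError

logger = logging.getLogger(__name__)

__all__ = [
    "CountTable",
    "SampleMetadata",
    "read_count_table",
    "write_count_table",
    "filter_samples_by_depth",
    "read_metadata",
    "write_metadata",
    "read_annotations",
    "read_pathway_definitions",
    "write_posterior_draws",
    "read_posterior_draws",
]

#: Column layout of the long-format posterior-draw TSV.
DRAW_COLUMNS = ["chain", "draw", "parameter", "feature", "covariate_or_cage", "value"]


@dataclass
class CountTable:
    """A features x samples table of non-negative integer counts.

    ``depths`` (per-sample sequencing depth, the offset of the model) is the
    column-sum vector and is recomputed on construction.
    """

    counts: np.ndarray
    feature_ids: list[str]
    sample_ids: list[str]
    depths: np.ndarray = field(init=False)

    def __post_init__(self):
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2:
            raise ValidationError("counts must be a 2-D matrix")
        if self.counts.shape != (len(self.feature_ids), len(self.sample_ids)):
            raise ValidationError(
                f"counts shape {self.counts.shape} does not match "
                f"{len(self.feature_ids)} features x {len(self.sample_ids)} samples"
            )
        if np.any(self.counts < 0):
            raise ValidationError("counts must be non-negative")
        if len(set(self.feature_ids)) != len(self.feature_ids):
            raise ValidationError("duplicate feature ids")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValidationError("duplicate sample ids")
        self.depths = self.counts.sum(axis=0).astype(np.int64)

    @property
    def n_features(self) -> int:
        return len(self.feature_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.feature_ids, columns=self.sample_ids)


@dataclass
class SampleMetadata:
    """Per-sample diet group and cage id, aligned with a table's samples."""

    frame: pd.DataFrame  # columns: sample_id, diet, cage

    def __post_init__(self):
        required = ["sample_id", "diet", "cage"]
        missing = [c for c in required if c not in self.frame.columns]
        if missing:
            raise ValidationError(f"metadata missing columns: {missing}")
        if self.frame[required].isna().any().any():
            raise ValidationError("metadata contains missing values")
        if self.frame["sample_id"].duplicated().any():
            raise ValidationError("duplicate sample ids in metadata")
        self.frame = self.frame[required].reset_index(drop=True)

    @property
    def sample_ids(self) -> list[str]:
        return self.frame["sample_id"].tolist()

    @property
    def diet(self) -> pd.Series:
        return self.frame["diet"]

    @property
    def cage(self) -> pd.Series:
        return self.frame["cage"]

    def __len__(self) -> int:
        return len(self.frame)


def read_count_table(path, orientation: str = "features-by-samples") -> CountTable:
    """Read a TSV count table into canonical features x samples orientation.

    Parameters
    ----------
    path
        TSV file; first cell is a corner label, first column holds row ids.
    orientation
        ``"features-by-samples"`` (rows are features) or
        ``"samples-by-features"`` (rows are samples; the table is transposed).
        Never guessed.
    """
    if orientation not in ("features-by-samples", "samples-by-features"):
        raise FormatError(f"unknown orientation {orientation!r}")
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    if df.index.duplicated().any() or df.columns.duplicated().any():
        raise FormatError(f"{path}: duplicate row or column ids")
    if orientation == "samples-by-features":
        df = df.T
    values = np.empty(df.shape, dtype=np.int64)
    for j, col in enumerate(df.columns):
        for i, row in enumerate(df.index):
            cell = df.iat[i, j]
            try:
                x = float(cell)
            except (TypeError, ValueError):
                raise FormatError(
                    f"{path}: non-numeric count {cell!r} at row {row!r}, column {col!r}"
                ) from None
            if not x.is_integer() or x < 0:
                raise FormatError(
                    f"{path}: count {cell!r} at row {row!r}, column {col!r} "
                    "is not a non-negative integer"
                )
            values[i, j] = int(x)
    return CountTable(values, [str(i) for i in df.index], [str(c) for c in df.columns])


def write_count_table(table: CountTable, path) -> None:
    """Write a count table as TSV, features as rows, corner cell 'feature_id'."""
    df = table.to_frame()
    df.index.name = "feature_id"
    df.to_csv(path, sep="\t")


def filter_samples_by_depth(table: CountTable, min_depth: int) -> CountTable:
    """Drop samples whose total count (column sum) is below ``min_depth``.

    The feature set is unchanged. Removed sample ids are logged. Raises
    :class:`EmptyTableError` if no sample survives.
    """
    if min_depth < 0:
        raise ValidationError("min_depth must be >= 0")
    keep = table.depths >= min_depth
    removed = [s for s, k in zip(table.sample_ids, keep) if not k]
    if removed:
        logger.info("depth filter (min_depth=%d) removed %d samples: %s",
                    min_depth, len(removed), ", ".join(removed))
    if not keep.any():
        raise EmptyTableError(
            f"depth filter at min_depth={min_depth} removed all {table.n_samples} samples"
        )
    return CountTable(
        table.counts[:, keep],
        list(table.feature_ids),
        [s for s, k in zip(table.sample_ids, keep) if k],
    )


def read_metadata(path, table: CountTable) -> SampleMetadata:
    """Read sample metadata and align its rows with the table's sample order.

    Metadata rows for samples absent from the table are dropped with a
    warning; table samples absent from the metadata raise an error listing
    the offending ids.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"sample_id", "diet", "cage"}
    if not required.issubset(df.columns):
        raise FormatError(
            f"{path}: metadata must have columns sample_id, diet, cage; got {list(df.columns)}"
        )
    have = set(df["sample_id"])
    missing = [s for s in table.sample_ids if s not in have]
    if missing:
        raise ValidationError(
            f"table samples absent from metadata: {', '.join(missing)}"
        )
    extra = sorted(have - set(table.sample_ids))
    if extra:
        logger.warning("metadata rows for %d samples not in the table dropped: %s",
                       len(extra), ", ".join(extra))
    df = df.set_index("sample_id").loc[table.sample_ids].reset_index()
    return SampleMetadata(df)


def write_metadata(metadata: SampleMetadata, path) -> None:
    metadata.frame.to_csv(path, sep="\t", index=False)


def _read_two_column_tsv(path, col_a: str, col_b: str) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str)
    if list(df.columns[:2]) != [col_a, col_b]:
        raise FormatError(
            f"{path}: expected columns ({col_a}, {col_b}); got {list(df.columns)}"
        )
    if df[[col_a, col_b]].isna().any().any():
        raise FormatError(f"{path}: missing values")
    return df


def read_annotations(path) -> dict[str, set[str]]:
    """Read a (genome_id, reaction_id) TSV into a genome -> reaction-set map.

    Duplicate rows are deduplicated (set semantics).
    """
    df = _read_two_column_tsv(path, "genome_id", "reaction_id")
    out: dict[str, set[str]] = {}
    for g, r in zip(df["genome_id"], df["reaction_id"]):
        out.setdefault(g, set()).add(r)
    return out


def read_pathway_definitions(path) -> dict[str, set[str]]:
    """Read a (pathway_id, reaction_id) TSV into a pathway -> reaction-set map.

    A pathway with an empty reaction id is rejected: completeness is a
    proportion of a pathway's reactions and needs at least one.
    """
    df = _read_two_column_tsv(path, "pathway_id", "reaction_id")
    out: dict[str, set[str]] = {}
    for p, r in zip(df["pathway_id"], df["reaction_id"]):
        if r == "":
            raise FormatError(f"{path}: pathway {p!r} has an empty reaction")
        out.setdefault(p, set()).add(r)
    for p, rs in out.items():
        if not rs:
            raise FormatError(f"{path}: pathway {p!r} has no reactions")
    return out


def write_annotations(annotations: Mapping[str, Iterable[str]], path) -> None:
    rows = [(g, r) for g, rs in annotations.items() for r in sorted(rs)]
    pd.DataFrame(rows, columns=["genome_id", "reaction_id"]).to_csv(path, sep="\t", index=False)


def write_pathway_definitions(pathways: Mapping[str, Iterable[str]], path) -> None:
    rows = [(p, r) for p, rs in pathways.items() for r in sorted(rs)]
    pd.DataFrame(rows, columns=["pathway_id", "reaction_id"]).to_csv(path, sep="\t", index=False)


def write_posterior_draws(draws, path) -> None:
    """Serialize posterior draws to long-format TSV.

    Columns are (chain, draw, parameter, feature, covariate_or_cage, value);
    for the per-feature scalars pi and phi the covariate_or_cage field is
    '-'. Values are written with 12 significant digits.
    """
    frames = []
    n_chains, n_draws = draws.pi.shape[:2]
    chain_idx = np.repeat(np.arange(n_chains), n_draws)
    draw_idx = np.tile(np.arange(n_draws), n_chains)
    for p, names in (("beta", draws.covariate_names), ("u", draws.cage_names)):
        arr = getattr(draws, p)  # (chains, draws, K, D)
        if arr is None:
            continue
        for k, kname in enumerate(names):
            for j, fid in enumerate(draws.feature_ids):
                frames.append(pd.DataFrame({
                    "chain": chain_idx, "draw": draw_idx, "parameter": p,
                    "feature": fid, "covariate_or_cage": kname,
                    "value": arr[:, :, k, j].reshape(-1),
                }))
    for p in ("pi", "phi"):
        arr = getattr(draws, p)  # (chains, draws, D)
        for j, fid in enumerate(draws.feature_ids):
            frames.append(pd.DataFrame({
                "chain": chain_idx, "draw": draw_idx, "parameter": p,
                "feature": fid, "covariate_or_cage": "-",
                "value": arr[:, :, j].reshape(-1),
            }))
    long = pd.concat(frames, ignore_index=True)
    long.to_csv(path, sep="\t", index=False, float_format="%.12g")


def read_posterior_draws(path):
    """Read long-format posterior draws written by :func:`write_posterior_draws`."""
    from .inference import PosteriorDraws  # deferred: avoid import cycle

    df = pd.read_csv(path, sep="\t", dtype={"parameter": str, "feature": str,
                                            "covariate_or_cage": str})
    if list(df.columns) != DRAW_COLUMNS:
        raise FormatError(
            f"{path}: expected columns {DRAW_COLUMNS}; got {list(df.columns)}"
        )
    n_chains = int(df["chain"].max()) + 1
    n_draws = int(df["draw"].max()) + 1

    def stack(param: str):
        sub = df[df["parameter"] == param]
        if sub.empty:
            return None, []
        names = list(dict.fromkeys(sub["covariate_or_cage"]))
        feats = list(dict.fromkeys(sub["feature"]))
        arr = np.empty((n_chains, n_draws, len(names), len(feats)))
        for (k, j), grp in sub.groupby(
                [sub["covariate_or_cage"].map(names.index),
                 sub["feature"].map(feats.index)], sort=False):
            grp = grp.sort_values(["chain", "draw"])
            arr[:, :, k, j] = grp["value"].to_numpy().reshape(n_chains, n_draws)
        return arr, (names, feats)

    beta, (cov_names, feature_ids) = stack("beta")
    u, u_meta = stack("u")
    cage_names = u_meta[0] if u is not None else []
    pi, _ = stack("pi")
    phi, _ = stack("phi")
    return PosteriorDraws(
        beta=beta, u=u, pi=pi[:, :, 0, :], phi=phi[:, :, 0, :],
        feature_ids=feature_ids, covariate_names=cov_names,
        cage_names=cage_names, reference_level=None,
    )
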