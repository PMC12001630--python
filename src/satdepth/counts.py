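"""Count-matrix I/O and seeded depth downsampling.

A :class:`CountMatrix` holds integer gene-by-sample expression counts, the
in-memory twin of a STAR ``ReadsPerGene.out.tab`` collection or a plain TSV
matrix.  Downsampling a sample to a lower sequencing depth is modelled at the
count level: drawing reads without replacement from a mapped library induces a
multivariate hypergeometric distribution on per-gene counts, so
``without_replacement`` thinning of the count vector is distributionally
equivalent to subsampling the reads themselves (e.g. with seqtk) and
re-counting.  A ``with_replacement`` (multinomial) mode is provided for
bootstrap-style resampling.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Literal, Sequence

import numpy as np
import pandas as pd

from ._errors import DepthError, FormatError

__all__ = [
    "CountMatrix",
    "DownsampleSpec",
    "ReplicateGrid",
    "STAR_SUMMARY_PREFIX",
    "read_counts",
    "read_star_genecounts",
    "combine_star_genecounts",
    "write_counts",
    "downsample_sample",
    "downsample_matrix",
    "coupled_downsample_column",
]

#: Leading summary rows of a STAR GeneCounts file (not genes).
STAR_SUMMARY_PREFIX = "N_"

#: Column order of the 4-column STAR GeneCounts dialect.
_STAR_COLUMNS = ("unstranded", "strand1", "strand2")


@dataclass
class CountMatrix:
    """Integer gene-by-sample count matrix.

    Parameters
    ----------
    gene_ids
        Ordered, unique gene identifiers (rows).
    sample_ids
        Ordered, unique sample identifiers (columns).
    counts
        Non-negative integer array of shape ``(n_genes, n_samples)``.
    meta
        Free-form metadata (e.g. STAR summary rows captured at read time).
    """

    gene_ids: list[str]
    sample_ids: list[str]
    counts: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.gene_ids = list(map(str, self.gene_ids))
        self.sample_ids = list(map(str, self.sample_ids))
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2:
            raise FormatError("counts must be a 2-D array")
        if self.counts.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise FormatError(
                f"counts shape {self.counts.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise FormatError("duplicate gene IDs")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise FormatError("duplicate sample IDs")
        if not np.issubdtype(self.counts.dtype, np.integer):
            rounded = np.rint(self.counts)
            if not np.allclose(self.counts, rounded, atol=0, rtol=0):
                raise FormatError("counts must be integers")
            self.counts = rounded.astype(np.int64)
        else:
            self.counts = self.counts.astype(np.int64)
        if (self.counts < 0).any():
            raise FormatError("negative counts")

    # -- container conveniences -------------------------------------------
    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def depths(self) -> np.ndarray:
        """Per-sample sequencing depth (column totals)."""
        return self.counts.sum(axis=0)

    def column(self, sample_id: str) -> np.ndarray:
        return self.counts[:, self.sample_ids.index(sample_id)]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.gene_ids, columns=self.sample_ids)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, **meta) -> "CountMatrix":
        return cls(
            gene_ids=list(frame.index.astype(str)),
            sample_ids=list(frame.columns.astype(str)),
            counts=frame.to_numpy(),
            meta=dict(meta),
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, CountMatrix):
            return NotImplemented
        return (
            self.gene_ids == other.gene_ids
            and self.sample_ids == other.sample_ids
            and np.array_equal(self.counts, other.counts)
        )


@dataclass(frozen=True)
class DownsampleSpec:
    """Target depth, seed and sampling mode for thinning one sample."""

    target_depth: int
    seed: int
    mode: Literal["without_replacement", "with_replacement"] = "without_replacement"

    def __post_init__(self) -> None:
        if self.target_depth < 0:
            raise DepthError("target_depth must be >= 0")
        if self.mode not in ("without_replacement", "with_replacement"):
            raise FormatError(f"unknown mode {self.mode!r}")


@dataclass(frozen=True)
class ReplicateGrid:
    """The (depth x seed) design of a downsampling experiment.

    The default grid mirrors a seven-depth, ten-seed design spanning
    0.5M-12M reads per sample.
    """

    depths: tuple[int, ...] = (
        500_000,
        1_000_000,
        2_000_000,
        5_000_000,
        7_500_000,
        10_000_000,
        12_000_000,
    )
    seeds: tuple[int, ...] = (127, 2, 5, 7, 9, 11, 12, 81, 21, 47)

    def __post_init__(self) -> None:
        object.__setattr__(self, "depths", tuple(int(d) for d in self.depths))
        object.__setattr__(self, "seeds", tuple(int(s) for s in self.seeds))
        if not self.depths or not self.seeds:
            raise FormatError("depths and seeds must be non-empty")
        if len(set(self.seeds)) != len(self.seeds):
            raise FormatError("seeds must be unique")
        if any(d <= 0 for d in self.depths):
            raise DepthError("depths must be positive")


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_counts(
    path: str | Path,
    dialect: Literal["matrix_tsv", "star_genecounts"] = "matrix_tsv",
    strand_column: str = "unstranded",
    sample_id: str | None = None,
) -> CountMatrix:
    """Read a count matrix from disk.

    ``matrix_tsv`` expects genes as rows, a header row of sample IDs, and the
    gene ID in the first column.  ``star_genecounts`` reads a single-sample
    STAR ``ReadsPerGene.out.tab`` file (columns: gene, unstranded, strand1,
    strand2); the leading ``N_*`` summary rows (unmapped, multimapping,
    noFeature, ambiguous) are excluded from the gene rows and reported in
    ``meta["star_summary"]``.
    """
    path = Path(path)
    if dialect == "matrix_tsv":
        frame = pd.read_csv(path, sep="\t", index_col=0)
        _check_count_frame(frame)
        return CountMatrix.from_frame(frame)
    if dialect == "star_genecounts":
        series, summary = read_star_genecounts(path, strand_column)
        name = sample_id or path.stem
        return CountMatrix(
            gene_ids=list(series.index),
            sample_ids=[name],
            counts=series.to_numpy()[:, None],
            meta={"star_summary": {name: summary}},
        )
    raise FormatError(f"unknown dialect {dialect!r}")


def read_star_genecounts(
    path: str | Path, strand_column: str = "unstranded"
) -> tuple[pd.Series, dict[str, int]]:
    """Read one STAR GeneCounts file into (gene counts, summary rows)."""
    if strand_column not in _STAR_COLUMNS:
        raise FormatError(
            f"strand_column must be one of {_STAR_COLUMNS}, got {strand_column!r}"
        )
    frame = pd.read_csv(
        path, sep="\t", header=None, names=("gene_id",) + _STAR_COLUMNS
    )
    is_summary = frame["gene_id"].str.startswith(STAR_SUMMARY_PREFIX)
    summary = dict(
        zip(frame.loc[is_summary, "gene_id"], frame.loc[is_summary, strand_column])
    )
    genes = frame.loc[~is_summary].set_index("gene_id")[strand_column]
    if genes.index.duplicated().any():
        raise FormatError("duplicate gene IDs in GeneCounts file")
    if (genes < 0).any():
        raise FormatError("negative counts in GeneCounts file")
    return genes.astype(np.int64), {k: int(v) for k, v in summary.items()}


def combine_star_genecounts(
    paths: Sequence[str | Path],
    sample_ids: Sequence[str] | None = None,
    strand_column: str = "unstranded",
) -> CountMatrix:
    """Assemble per-sample STAR GeneCounts files into one matrix.

    All files must agree on the gene universe; gene order follows the first
    file.
    """
    paths = [Path(p) for p in paths]
    ids = list(sample_ids) if sample_ids is not None else [p.stem for p in paths]
    columns, summaries = {}, {}
    for name, p in zip(ids, paths):
        series, summary = read_star_genecounts(p, strand_column)
        columns[name] = series
        summaries[name] = summary
    frame = pd.DataFrame(columns)
    if frame.isna().any().any():
        raise FormatError("GeneCounts files disagree on gene IDs")
    first = next(iter(columns.values()))
    frame = frame.loc[first.index]
    out = CountMatrix.from_frame(frame)
    out.meta["star_summary"] = summaries
    return out


def write_counts(matrix: CountMatrix, path: str | Path) -> None:
    """Write the matrix as TSV (genes as rows, header of sample IDs)."""
    frame = matrix.to_frame()
    frame.index.name = "gene_id"
    frame.to_csv(path, sep="\t")


def _check_count_frame(frame: pd.DataFrame) -> None:
    if frame.index.duplicated().any():
        raise FormatError("duplicate gene IDs")
    values = frame.to_numpy()
    if not np.issubdtype(values.dtype, np.number):
        raise FormatError("non-numeric counts")
    if (values < 0).any():
        raise FormatError("negative counts")
    if not np.allclose(values, np.rint(values), atol=0, rtol=0):
        raise FormatError("non-integer counts")


# ---------------------------------------------------------------------------
# Downsampling
# ---------------------------------------------------------------------------

def downsample_sample(counts_column: np.ndarray, spec: DownsampleSpec) -> np.ndarray:
    """Thin one sample's count vector to ``spec.target_depth`` total reads.

    ``without_replacement`` draws from the multivariate hypergeometric
    distribution (urn of reads labelled by gene); the output column sums to
    the target depth exactly.  ``with_replacement`` draws a multinomial with
    probabilities proportional to the counts.  Both are deterministic given
    ``spec.seed``.
    """
    column = np.asarray(counts_column, dtype=np.int64)
    if column.ndim != 1:
        raise FormatError("counts_column must be 1-D")
    if (column < 0).any():
        raise FormatError("negative counts")
    total = int(column.sum())
    rng = np.random.default_rng(np.random.SeedSequence(spec.seed))
    if spec.mode == "without_replacement":
        if spec.target_depth > total:
            raise DepthError(
                f"target depth {spec.target_depth} exceeds column total {total}"
            )
        if spec.target_depth == total:
            return column.copy()
        return rng.multivariate_hypergeometric(column, spec.target_depth).astype(
            np.int64
        )
    # with_replacement
    if total == 0:
        raise DepthError("cannot resample a zero-total column with replacement")
    return rng.multinomial(spec.target_depth, column / total).astype(np.int64)


def _substream_seed(grid_seed: int, depth: int, sample_index: int) -> int:
    """Deterministic per-(seed, depth, sample) substream seed.

    Hash-derived so that results do not depend on iteration order and remain
    stable across platforms and Python hash randomisation.
    """
    digest = hashlib.sha256(
        f"{grid_seed}:{depth}:{sample_index}".encode()
    ).digest()
    return int.from_bytes(digest[:4], "big")


def downsample_matrix(
    matrix: CountMatrix,
    grid: ReplicateGrid,
    mode: Literal["without_replacement", "with_replacement"] = "without_replacement",
    cap_at_total: bool = False,
) -> Iterator[tuple[int, int, CountMatrix]]:
    """Yield ``(depth, seed, thinned_matrix)`` for every grid cell.

    Each sample is thinned independently with a seed derived deterministically
    from ``(grid seed, depth, sample index)``.  Depths infeasible for a sample
    raise :class:`DepthError` unless ``cap_at_total`` is set, in which case the
    sample is capped at its own total (mirroring a dataset in which deeper
    downsampling "was not possible for all samples").
    """
    totals = matrix.depths()
    if mode == "without_replacement" and not cap_at_total:
        infeasible = [
            (sid, int(t))
            for sid, t in zip(matrix.sample_ids, totals)
            if t < max(grid.depths)
        ]
        if infeasible:
            raise DepthError(
                f"depth {max(grid.depths)} infeasible for samples {infeasible}; "
                "use cap_at_total=True to cap at the sample total"
            )
    for depth in grid.depths:
        for seed in grid.seeds:
            thinned = np.empty_like(matrix.counts)
            for j in range(matrix.n_samples):
                target = depth
                if cap_at_total and mode == "without_replacement":
                    target = min(depth, int(totals[j]))
                spec = DownsampleSpec(
                    target_depth=target,
                    seed=_substream_seed(seed, depth, j),
                    mode=mode,
                )
                thinned[:, j] = downsample_sample(matrix.counts[:, j], spec)
            yield depth, seed, CountMatrix(
                gene_ids=matrix.gene_ids,
                sample_ids=matrix.sample_ids,
                counts=thinned,
                meta={"depth": depth, "seed": seed},
            )


def coupled_downsample_column(
    counts_column: np.ndarray, depths: Sequence[int], seed: int
) -> dict[int, np.ndarray]:
    """Nested (coupled) thinnings of one column at several depths.

    A single random permutation of read slots is drawn; the thinning at depth
    ``d`` keeps the first ``d`` slots.  Consequently the thinned column at a
    smaller depth is element-wise <= the thinned column at any larger depth —
    the coupling used to verify detection-monotonicity properties.  Intended
    for modest totals (the read labels are materialised).
    """
    column = np.asarray(counts_column, dtype=np.int64)
    total = int(column.sum())
    if any(d > total for d in depths):
        raise DepthError("coupled depth exceeds column total")
    labels = np.repeat(np.arange(column.size), column)
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    order = rng.permutation(total)
    out: dict[int, np.ndarray] = {}
    for d in depths:
        kept = labels[order[:d]]
        out[int(d)] = np.bincount(kept, minlength=column.size).astype(np.int64)
    return out
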