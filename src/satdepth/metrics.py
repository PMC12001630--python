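"""Expressed-gene and informative-gene detection metrics.

Two gene-detection rules are used throughout the depth-saturation analysis:

* **expressed gene** — a gene to which at least one read mapped in a sample
  (liberal; many such genes appear in only a handful of individuals);
* **informative gene** — a gene with at least ten mapped reads in at least
  half of the samples (the conservative core set usable as population-level
  molecular phenotypes).

Both thresholds and the sample fraction are configurable; for 3' libraries no
length normalisation is applied (one read per transcript molecule).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal

import numpy as np
import pandas as pd

from ._errors import ParameterError
from .counts import CountMatrix

__all__ = [
    "MetricConfig",
    "expressed_genes_per_sample",
    "expressed_genes_union",
    "informative_genes",
    "prevalence_distribution",
    "detection_summary",
]


@dataclass(frozen=True)
class MetricConfig:
    """Thresholds of the detection rules.

    ``comparator`` selects whether a count must be ``>=`` (default) or
    strictly ``>`` the informative threshold; both conventions appear in
    common usage ("at least ten reads" vs "count > 10").  ``informative_min_
    sample_fraction`` is rounded up to a whole number of samples.
    """

    expressed_min_count: int = 1
    informative_min_count: int = 10
    informative_min_sample_fraction: float = 0.5
    comparator: Literal["ge", "gt"] = "ge"

    def __post_init__(self) -> None:
        if self.expressed_min_count < 1 or self.informative_min_count < 1:
            raise ParameterError("count thresholds must be positive")
        if not (0.0 < self.informative_min_sample_fraction <= 1.0):
            raise ParameterError("sample fraction must be in (0, 1]")
        if self.comparator not in ("ge", "gt"):
            raise ParameterError("comparator must be 'ge' or 'gt'")

    def min_samples(self, n_samples: int) -> int:
        return math.ceil(self.informative_min_sample_fraction * n_samples)


def _meets(counts: np.ndarray, threshold: int, comparator: str) -> np.ndarray:
    return counts >= threshold if comparator == "ge" else counts > threshold


def expressed_genes_per_sample(
    matrix: CountMatrix, config: MetricConfig = MetricConfig()
) -> dict[str, set[str]]:
    """Per-sample sets of expressed genes (count >= ``expressed_min_count``)."""
    genes = np.asarray(matrix.gene_ids, dtype=object)
    detected = matrix.counts >= config.expressed_min_count
    return {
        sid: set(genes[detected[:, j]])
        for j, sid in enumerate(matrix.sample_ids)
    }


def expressed_genes_union(
    matrix: CountMatrix, config: MetricConfig = MetricConfig()
) -> set[str]:
    """Dataset-level expressed set: genes expressed in at least one sample."""
    genes = np.asarray(matrix.gene_ids, dtype=object)
    any_detected = (matrix.counts >= config.expressed_min_count).any(axis=1)
    return set(genes[any_detected])


def informative_genes(
    matrix: CountMatrix, config: MetricConfig = MetricConfig()
) -> set[str]:
    """Genes with >= ``informative_min_count`` reads in >= half the samples.

    "Half" is ``ceil(informative_min_sample_fraction * n_samples)`` samples.
    """
    genes = np.asarray(matrix.gene_ids, dtype=object)
    meets = _meets(matrix.counts, config.informative_min_count, config.comparator)
    need = config.min_samples(matrix.n_samples)
    return set(genes[meets.sum(axis=1) >= need])


def prevalence_distribution(
    matrix: CountMatrix,
    rule: Literal["expressed", "informative"] = "expressed",
    config: MetricConfig = MetricConfig(),
) -> pd.Series:
    """Histogram of genes detected in exactly *k* individuals, k = 1..n.

    Under ``rule="informative"`` per-sample detection uses the informative
    count threshold (>= 10 reads in that sample); the histogram then shows in
    how many individuals each such gene clears the threshold.  The histogram
    sums to the number of genes detected in at least one sample.
    """
    if rule == "expressed":
        meets = matrix.counts >= config.expressed_min_count
    elif rule == "informative":
        meets = _meets(matrix.counts, config.informative_min_count, config.comparator)
    else:
        raise ParameterError(f"unknown rule {rule!r}")
    k = meets.sum(axis=1)
    n = matrix.n_samples
    values = np.bincount(k[k > 0], minlength=n + 1)[1 : n + 1]
    return pd.Series(values, index=pd.RangeIndex(1, n + 1, name="n_individuals"),
                     name="n_genes")


def detection_summary(
    matrix: CountMatrix, config: MetricConfig = MetricConfig()
) -> pd.DataFrame:
    """Per-sample table of expressed and informative-threshold gene counts.

    ``n_expressed`` counts genes with at least one read in the sample;
    ``n_ge_informative_count`` counts genes clearing the informative read
    threshold in that single sample (the per-sample dots accompanying the
    dataset-level star in detection plots).
    """
    expressed = (matrix.counts >= config.expressed_min_count).sum(axis=0)
    deep = _meets(matrix.counts, config.informative_min_count, config.comparator).sum(
        axis=0
    )
    return pd.DataFrame(
        {
            "sample_id": matrix.sample_ids,
            "n_expressed": expressed,
            "n_ge_informative_count": deep,
            "depth": matrix.depths(),
        }
    )
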