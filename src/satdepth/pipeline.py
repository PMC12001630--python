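"""Orchestration of the depth-saturation experiment.

``run_saturation`` takes a full-depth count matrix (and optionally condition
labels and a called VCF), defines the full-depth results as the truth sets,
thins the data to every (depth, seed) cell of the replicate grid, recomputes
each detection metric on the thinned data, benchmarks it against truth with
precision/recall/F, fits the asymptotic saturation curve per metric on the
raw detection counts, and derives the analytic plateau (saturation depth).

Variant saturation operates on the supplied full-depth VCF by binomially
thinning per-sample allele depths at ratio depth/full_depth and re-applying
the filter criteria — an explicit approximation of re-calling variants at
lower depth, flagged as such in the report.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from ._errors import ConfigError, FitError, ParameterError
from .benchmark import confusion, precision_recall_f, significance_stars, welch_t
from .counts import CountMatrix, ReplicateGrid, downsample_matrix, write_counts
from .de import deg_set, run_de
from .metrics import (
    MetricConfig,
    detection_summary,
    expressed_genes_union,
    informative_genes,
)
from .saturation import (
    DEFAULT_SLOPE_THRESHOLD,
    fit_asymptotic,
    plateau,
)
from .variants import (
    FilterThresholds,
    VariantRecord,
    filter_lenient,
    filter_stringent,
    is_snp,
    site_hard_filter,
    thin_variant_depths,
)

__all__ = [
    "ExperimentConfig",
    "SaturationReport",
    "run_saturation",
    "compare_groups",
]


@dataclass(frozen=True)
class ExperimentConfig:
    """Configuration of a saturation experiment."""

    grid: ReplicateGrid = ReplicateGrid()
    metric_config: MetricConfig = MetricConfig()
    de_alpha: float = 0.05
    slope_threshold: float = DEFAULT_SLOPE_THRESHOLD
    cap_at_total: bool = False
    include_variants: bool = True
    variant_thresholds: FilterThresholds = FilterThresholds()
    master_seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.de_alpha < 1.0):
            raise ConfigError("de_alpha must be in (0, 1)")
        if self.slope_threshold <= 0:
            raise ConfigError("slope_threshold must be positive")


@dataclass
class SaturationReport:
    """Per-cell metric rows, per-metric fits/plateaus, and provenance."""

    rows: pd.DataFrame
    fits: dict[str, dict]
    truth_sizes: dict[str, int]
    provenance: dict

    def to_json(self) -> str:
        payload = {
            "fits": self.fits,
            "truth_sizes": self.truth_sizes,
            "provenance": self.provenance,
        }
        return json.dumps(payload, indent=2, sort_keys=True)

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.rows.to_csv(outdir / "saturation_rows.tsv", sep="\t", index=False)
        (outdir / "saturation_fits.json").write_text(self.to_json() + "\n")


def _config_hash(config: ExperimentConfig) -> str:
    blob = json.dumps(
        dataclasses.asdict(config), sort_keys=True, default=str
    ).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def _variant_survivor_keys(
    records: Sequence[VariantRecord], thresholds: FilterThresholds
) -> dict[str, set]:
    """SNP/INDEL survivor keys under site + lenient and site + stringent filters."""
    passing = [r for r in records if site_hard_filter(r, thresholds)[0]]
    lenient, _ = filter_lenient(passing, thresholds)
    stringent = {r.key() for r, _a in filter_stringent(lenient, thresholds)}
    out: dict[str, set] = {}
    for kind, pred in (("snp", is_snp), ("indel", lambda r: not is_snp(r))):
        out[f"{kind}_lenient"] = {r.key() for r in lenient if pred(r)}
        out[f"{kind}_stringent"] = {
            r.key() for r in lenient if pred(r) and r.key() in stringent
        }
    return out


def run_saturation(
    matrix: CountMatrix,
    config: ExperimentConfig = ExperimentConfig(),
    labels: Sequence[str] | None = None,
    variant_records: Sequence[VariantRecord] | None = None,
    outdir: str | Path | None = None,
) -> SaturationReport:
    """Run the full downsampling experiment against full-depth truth.

    Metrics benchmarked per grid cell: the dataset-level expressed-gene set,
    the informative-gene set, the DEG set (when ``labels`` given) and variant
    survivor sets (when ``variant_records`` given).  Saturation curves are
    fitted on the raw detection counts pooled over replicate seeds.
    """
    truth: dict[str, set] = {
        "expressed": expressed_genes_union(matrix, config.metric_config),
        "informative": informative_genes(matrix, config.metric_config),
    }
    if labels is not None:
        if len(labels) != matrix.n_samples:
            raise ConfigError("labels length must match sample count")
        truth["deg"] = deg_set(run_de(matrix, labels, alpha=config.de_alpha))
    full_depths = matrix.depths()
    mean_full_depth = float(full_depths.mean())
    if variant_records is not None and config.include_variants:
        truth.update(
            _variant_survivor_keys(variant_records, config.variant_thresholds)
        )

    rows: list[dict] = []
    for depth, seed, thinned in downsample_matrix(
        matrix, config.grid, cap_at_total=config.cap_at_total
    ):
        cell_sets: dict[str, set] = {
            "expressed": expressed_genes_union(thinned, config.metric_config),
            "informative": informative_genes(thinned, config.metric_config),
        }
        if labels is not None:
            cell_sets["deg"] = deg_set(
                run_de(thinned, labels, alpha=config.de_alpha)
            )
        if variant_records is not None and config.include_variants:
            ratio = min(depth / mean_full_depth, 1.0)
            thinned_records = thin_variant_depths(
                variant_records, ratio, seed=(config.master_seed * 1_000_003 + seed) % (2**31)
            )
            cell_sets.update(
                _variant_survivor_keys(thinned_records, config.variant_thresholds)
            )
        for metric, observed in cell_sets.items():
            cc = confusion(observed, truth[metric])
            mr = precision_recall_f(cc)
            rows.append(
                {
                    "metric": metric,
                    "depth": depth,
                    "seed": seed,
                    "n_detected": len(observed),
                    "tp": cc.tp,
                    "fp": cc.fp,
                    "fn": cc.fn,
                    "precision": mr.precision,
                    "recall": mr.recall,
                    "f_score": mr.f_score,
                }
            )
    table = pd.DataFrame(rows)

    fits: dict[str, dict] = {}
    for metric, sub in table.groupby("metric"):
        entry: dict = {}
        try:
            fit = fit_asymptotic(sub["depth"].to_numpy(), sub["n_detected"].to_numpy())
            entry["fit"] = {
                "y0": fit.y0,
                "ymax": fit.ymax,
                "lrc": fit.lrc,
                "residual_sse": fit.residual_sse,
                "n_obs": fit.n_obs,
            }
            pl = plateau(
                fit,
                slope_threshold=config.slope_threshold,
                x_max_observed=float(sub["depth"].max()),
            )
            entry["plateau"] = {
                "x_plateau": pl.x_plateau,
                "y_at_plateau": pl.y_at_plateau,
                "slope_threshold": pl.slope_threshold,
                "extrapolated": pl.extrapolated,
            }
        except (FitError, ParameterError) as exc:
            entry["error"] = str(exc)
        fits[metric] = entry

    report = SaturationReport(
        rows=table,
        fits=fits,
        truth_sizes={k: len(v) for k, v in truth.items()},
        provenance={
            "config_hash": _config_hash(config),
            "depths": list(config.grid.depths),
            "seeds": list(config.grid.seeds),
            "master_seed": config.master_seed,
            "n_genes": matrix.n_genes,
            "n_samples": matrix.n_samples,
            "mean_full_depth": mean_full_depth,
            "variant_thinning": "binomial AD/DP thinning (approximation of re-calling)"
            if variant_records is not None
            else None,
        },
    )
    if outdir is not None:
        report.write(outdir)
    return report


def compare_groups(
    matrix_a: CountMatrix,
    matrix_b: CountMatrix,
    names: tuple[str, str] = ("group_a", "group_b"),
    metric_config: MetricConfig = MetricConfig(),
) -> pd.DataFrame:
    """Welch-test per-sample detection metrics between two datasets.

    One row per metric (n_expressed, n_ge_informative_count, depth) with group
    means, medians, the Welch t statistic, df, two-sided p, and significance
    stars — the comparison used to rank library-preparation kits.
    """
    summary_a = detection_summary(matrix_a, metric_config)
    summary_b = detection_summary(matrix_b, metric_config)
    rows = []
    for metric in ("n_expressed", "n_ge_informative_count", "depth"):
        x = summary_a[metric].to_numpy(dtype=float)
        y = summary_b[metric].to_numpy(dtype=float)
        t, df, p = welch_t(x, y)
        rows.append(
            {
                "metric": metric,
                f"mean_{names[0]}": float(np.mean(x)),
                f"mean_{names[1]}": float(np.mean(y)),
                f"median_{names[0]}": float(np.median(x)),
                f"median_{names[1]}": float(np.median(y)),
                "t": t,
                "df": df,
                "p_value": p,
                "stars": significance_stars(p),
            }
        )
    return pd.DataFrame(rows)
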