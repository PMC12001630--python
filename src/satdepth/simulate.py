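"""Synthetic data generators for every pipeline stage.

The generators emulate a 3' mRNA-Seq molecular-phenotyping study of whole
blood: negative-binomial gene counts over two conditions (morning vs night
sampling around an acute stressor) with a designated differentially-expressed
subset; saturation observations drawn from the asymptotic regression model;
and toy variant records with per-sample AD/DP fields and 3'-biased intragenic
positions.  All generators are pure functions of their seed, and ground truth
(the DE gene set, the generating curve parameters, the positional law) is
returned alongside the data for recovery tests.

Counts are drawn NB with variance mu + alpha*mu^2 (single dispersion alpha by
default).  Gene baseline means are log-uniform over a configurable range and
rescaled so that the expected column total equals the configured per-sample
depth; the wide log-range produces the long prevalence tail of real
blood transcriptomes (many genes seen in only a few individuals), which is
what makes detection thresholds and depth saturation informative.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from ._errors import ParameterError
from .counts import CountMatrix
from .saturation import AsymptoticFit, model_predict
from .variants import GeneModel, SampleCall, VariantRecord

__all__ = [
    "SimCountParams",
    "SimSaturationParams",
    "SimVariantParams",
    "simulate_counts",
    "simulate_saturation_observations",
    "simulate_variant_records",
    "simulate_gene_models",
    "write_sample_sheet",
    "read_sample_sheet",
]

CONDITIONS = ("morning", "night")


@dataclass(frozen=True)
class SimCountParams:
    """Parameters of the NB count generator.

    Defaults describe the reference study conditions: ~20,000 annotated genes
    over two conditions of 15 and 14 whole-blood samples, full sequencing
    depth well above the deepest 12M-read downsampling target, dispersion 0.1
    (typical bulk RNA-seq overdispersion), and a DE subset of 2,000 genes
    with |log fold change| 1 split evenly up/down.
    """

    n_genes: int = 20_000
    n_samples_per_condition: int = 15
    n_samples_second_condition: int | None = 14
    baseline_mean_log_range: tuple[float, float] = (np.log(0.01), np.log(10_000.0))
    dispersion: float = 0.1
    n_de_genes: int = 2_000
    lfc_magnitude: float = 1.0  # natural-log units
    fraction_up: float = 0.5
    depth_per_sample: int = 15_000_000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes <= 0 or self.n_samples_per_condition <= 0:
            raise ParameterError("dimensions must be positive")
        n2 = self.n_samples_second_condition
        if n2 is not None and n2 <= 0:
            raise ParameterError("dimensions must be positive")
        if self.n_de_genes < 0 or self.n_de_genes > self.n_genes:
            raise ParameterError("0 <= n_de_genes <= n_genes required")
        if self.dispersion <= 0:
            raise ParameterError("dispersion must be > 0")
        if self.depth_per_sample < 1:
            raise ParameterError("depth_per_sample must be >= 1")
        if not (0.0 <= self.fraction_up <= 1.0):
            raise ParameterError("fraction_up must be in [0, 1]")
        if self.lfc_magnitude <= 0:
            raise ParameterError("lfc_magnitude must be > 0")


@dataclass(frozen=True)
class SimSaturationParams:
    """Parameters of the saturation-observation generator.

    Defaults mimic an expressed-gene curve: ~500 genes detected with almost no
    reads, an asymptote near 23,000, and a rate constant giving a plateau in
    the 10^6-10^7 read range, observed on the seven-depth, ten-replicate
    design.
    """

    y0: float = 500.0
    ymax: float = 23_000.0
    lrc: float = -14.8
    depths: tuple[float, ...] = (
        500_000.0,
        1_000_000.0,
        2_000_000.0,
        5_000_000.0,
        7_500_000.0,
        10_000_000.0,
        12_000_000.0,
    )
    replicates_per_depth: int = 10
    noise_sd: float = 150.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.ymax <= self.y0:
            raise ParameterError("ymax must exceed y0")
        if any(d <= 0 for d in self.depths):
            raise ParameterError("depths must be strictly positive")
        if self.replicates_per_depth < 1:
            raise ParameterError("replicates_per_depth must be >= 1")
        if self.noise_sd < 0:
            raise ParameterError("noise_sd must be >= 0")


@dataclass(frozen=True)
class SimVariantParams:
    """Parameters of the toy variant-record generator.

    ``three_prime_bias_strength`` b draws intragenic relative positions with
    density proportional to r^b toward the 3' end (b = 0 is uniform).
    ``alt_fraction_distribution`` gives the Beta(a, b) law of per-variant alt
    allele fractions.  ``fail_site_fraction`` of records violate one randomly
    chosen site hard filter, exercising every filter branch.
    """

    n_variants: int = 1_000
    n_samples: int = 15
    three_prime_bias_strength: float = 4.0
    depth_distribution_mean: float = 20.0
    alt_fraction_distribution: tuple[float, float] = (2.0, 2.0)
    intragenic_fraction: float = 0.8
    fail_site_fraction: float = 0.1
    carrier_fraction: float = 0.3
    indel_fraction: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_variants < 1 or self.n_samples < 1:
            raise ParameterError("n_variants and n_samples must be >= 1")
        if self.three_prime_bias_strength < 0:
            raise ParameterError("bias strength must be >= 0")
        if self.depth_distribution_mean <= 0:
            raise ParameterError("depth mean must be > 0")
        if not (0.0 <= self.intragenic_fraction <= 1.0):
            raise ParameterError("intragenic_fraction must be in [0, 1]")


# ---------------------------------------------------------------------------
# Counts
# ---------------------------------------------------------------------------

def _nb_draw(rng: np.random.Generator, mu: np.ndarray, alpha: float) -> np.ndarray:
    """NB draw with variance mu + alpha mu^2 (size 1/alpha)."""
    size = 1.0 / alpha
    p = size / (size + mu)
    return rng.negative_binomial(size, p)


def simulate_counts(
    params: SimCountParams,
) -> tuple[CountMatrix, set[str], list[str]]:
    """Simulate a two-condition NB count matrix with known DE truth.

    Returns ``(matrix, truth, labels)`` where ``truth`` is the set of gene
    IDs carrying a condition effect and ``labels`` the per-sample condition
    labels.  The condition effect multiplies the second condition's mean by
    ``exp(+-lfc_magnitude)``; expected column totals equal
    ``depth_per_sample`` up to the (small) net effect of the DE subset.
    """
    rng = np.random.default_rng(np.random.SeedSequence([params.seed, 20_240_501]))
    n1 = params.n_samples_per_condition
    n2 = (
        params.n_samples_second_condition
        if params.n_samples_second_condition is not None
        else n1
    )
    gene_ids = [f"gene{i:05d}" for i in range(params.n_genes)]
    lo, hi = params.baseline_mean_log_range
    base = np.exp(rng.uniform(lo, hi, size=params.n_genes))
    base *= params.depth_per_sample / base.sum()

    de_idx = rng.choice(params.n_genes, size=params.n_de_genes, replace=False)
    n_up = int(round(params.fraction_up * params.n_de_genes))
    sign = np.zeros(params.n_genes)
    sign[de_idx[:n_up]] = +1.0
    sign[de_idx[n_up:]] = -1.0
    effect = np.exp(sign * params.lfc_magnitude)

    mu1 = np.repeat(base[:, None], n1, axis=1)
    mu2 = np.repeat((base * effect)[:, None], n2, axis=1)
    counts = np.concatenate(
        [
            _nb_draw(rng, mu1, params.dispersion),
            _nb_draw(rng, mu2, params.dispersion),
        ],
        axis=1,
    )
    sample_ids = [f"{CONDITIONS[0]}_{i+1:02d}" for i in range(n1)] + [
        f"{CONDITIONS[1]}_{i+1:02d}" for i in range(n2)
    ]
    labels = [CONDITIONS[0]] * n1 + [CONDITIONS[1]] * n2
    truth = {gene_ids[i] for i in de_idx}
    matrix = CountMatrix(
        gene_ids=gene_ids,
        sample_ids=sample_ids,
        counts=counts,
        meta={"baseline_means": base, "lfc_sign": sign, "params": params},
    )
    return matrix, truth, labels


# ---------------------------------------------------------------------------
# Saturation observations
# ---------------------------------------------------------------------------

def simulate_saturation_observations(params: SimSaturationParams) -> pd.DataFrame:
    """Draw (depth, replicate, y) observations from the asymptotic model.

    ``y = ymax + (y0 - ymax) exp(-exp(lrc) x) + Gaussian(0, noise_sd)``, with
    ``replicates_per_depth`` points per depth.
    """
    rng = np.random.default_rng(np.random.SeedSequence([params.seed, 777]))
    fit = AsymptoticFit(y0=params.y0, ymax=params.ymax, lrc=params.lrc)
    rows = []
    for depth in params.depths:
        mean = model_predict(fit, depth)
        for rep in range(params.replicates_per_depth):
            noise = rng.normal(0.0, params.noise_sd) if params.noise_sd > 0 else 0.0
            rows.append((float(depth), rep, mean + noise))
    return pd.DataFrame(rows, columns=["depth", "replicate", "y"])


# ---------------------------------------------------------------------------
# Variants
# ---------------------------------------------------------------------------

def simulate_gene_models(
    n_genes: int = 50,
    chrom: str = "chr1",
    gene_length: int = 2_000,
    spacing: int = 1_000,
    seed: int = 0,
) -> list[GeneModel]:
    """Evenly spaced gene fixtures with random strands."""
    rng = np.random.default_rng(np.random.SeedSequence([seed, 99]))
    genes = []
    pos = 1_000
    for i in range(n_genes):
        strand = "+" if rng.random() < 0.5 else "-"
        genes.append(
            GeneModel(
                gene_id=f"g{i:04d}",
                chrom=chrom,
                start=pos,
                end=pos + gene_length - 1,
                strand=strand,
            )
        )
        pos += gene_length + spacing
    return genes


def simulate_variant_records(
    params: SimVariantParams, genes: Sequence[GeneModel]
) -> list[VariantRecord]:
    """Toy called variants with AD/DP and 3'-biased intragenic positions.

    Intragenic relative positions r are drawn with density proportional to
    ``r**bias`` (inverse-CDF: ``U**(1/(bias+1))``) and mapped to genomic
    coordinates strand-aware, so the 3' pile-up of poly-A-proximal reads is
    reproduced.  Site INFO annotations are drawn in the passing range except
    for a ``fail_site_fraction`` of records, each violating one randomly
    chosen hard filter.  Per-sample depths are Poisson; carriers receive
    binomial alt reads at a Beta-distributed allele fraction.
    """
    if params.intragenic_fraction > 0 and not genes:
        raise ParameterError("intragenic_fraction > 0 requires gene models")
    rng = np.random.default_rng(np.random.SeedSequence([params.seed, 555]))
    genes = list(genes)
    chrom_max: dict[str, int] = {}
    for g in genes:
        chrom_max[g.chrom] = max(chrom_max.get(g.chrom, 0), g.end)
    chroms = sorted(chrom_max) or ["chr1"]
    a_beta, b_beta = params.alt_fraction_distribution

    records: list[VariantRecord] = []
    for i in range(params.n_variants):
        if genes and rng.random() < params.intragenic_fraction:
            gene = genes[rng.integers(len(genes))]
            u = rng.random()
            r = u ** (1.0 / (params.three_prime_bias_strength + 1.0))
            span = gene.end - gene.start
            if gene.strand == "+":
                pos = gene.start + int(round(r * span))
            else:
                pos = gene.end - int(round(r * span))
            chrom = gene.chrom
        else:  # intergenic: past the last gene on a random chromosome
            chrom = chroms[rng.integers(len(chroms))]
            limit = chrom_max.get(chrom, 0)
            pos = int(limit + 1 + rng.integers(100_000))

        ref, alt = (str(b) for b in rng.choice(list("ACGT"), size=2, replace=False))
        if rng.random() < params.indel_fraction:
            tail = "".join(rng.choice(list("ACGT"), size=int(rng.integers(1, 4))))
            if rng.random() < 0.5:
                alt = ref + tail  # insertion
            else:
                ref, alt = ref + tail, ref  # deletion
        info = {
            "QD": float(rng.uniform(20.5, 35.0)),
            "FS": float(rng.uniform(0.0, 15.0)),
            "MQRankSum": float(rng.uniform(-3.0, 3.0)),
            "ReadPosRankSum": float(rng.uniform(-3.0, 3.0)),
            "SOR": float(rng.uniform(0.2, 3.0)),
        }
        if rng.random() < params.fail_site_fraction:
            which = rng.integers(5)
            if which == 0:
                info["QD"] = float(rng.uniform(1.0, 19.0))
            elif which == 1:
                info["FS"] = float(rng.uniform(21.0, 60.0))
            elif which == 2:
                info["MQRankSum"] = float(rng.uniform(-20.0, -13.0))
            elif which == 3:
                info["ReadPosRankSum"] = float(rng.uniform(-15.0, -8.5))
            else:
                info["SOR"] = float(rng.uniform(5.5, 9.0))

        af = float(rng.beta(a_beta, b_beta))
        calls = []
        for _ in range(params.n_samples):
            dp = int(rng.poisson(params.depth_distribution_mean))
            if dp > 0 and rng.random() < params.carrier_fraction:
                ad_alt = int(rng.binomial(dp, af))
            else:
                ad_alt = 0
            calls.append(SampleCall(ad=[dp - ad_alt, ad_alt], dp=dp))
        records.append(
            VariantRecord(
                chrom=chrom,
                pos=pos,
                ref=ref,
                alts=[alt],
                site_info=info,
                per_sample=calls,
                id=f"var{i:05d}",
            )
        )
    records.sort(key=lambda r: (r.chrom, r.pos))
    return records


# ---------------------------------------------------------------------------
# Sample sheets
# ---------------------------------------------------------------------------

def write_sample_sheet(
    sample_ids: Sequence[str], labels: Sequence[str], path: str | Path
) -> None:
    pd.DataFrame({"sample_id": sample_ids, "condition": labels}).to_csv(
        path, sep="\t", index=False
    )


def read_sample_sheet(path: str | Path) -> pd.DataFrame:
    sheet = pd.read_csv(path, sep="\t")
    if not {"sample_id", "condition"} <= set(sheet.columns):
        raise ParameterError("sample sheet needs sample_id and condition columns")
    return sheet
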