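"""Post-calling variant filtering and 3' positional-bias analysis.

Consumes a jointly-called VCF (per-sample AD and DP FORMAT fields; site INFO
annotations QD, FS, MQRankSum, ReadPosRankSum, SOR when present) and applies,
in order:

1. **site hard filters** — threshold-based exclusion in lieu of recalibration
   (used when no reference panel of known polymorphic sites exists for the
   population): fail when QD < 20, FS > 20, MQRankSum < -12.5,
   ReadPosRankSum < -8, or SOR > 5; missing annotations never fail a site
   (GATK VariantFiltration convention) but are flagged;
2. **lenient depth criterion** — keep a record when total depth across
   samples DP_total >= 10 and total alternate allele depth ALT_AD_total > 0;
3. **stringent per-allele criterion** — an alt allele is supported in a
   sample when AD >= 2, or its allele ratio AR = AD/DP >= 0.1 with DP > 10;
   an allele survives when supported in at least one sample and the depth
   recalculated from allele depths (sum of AD over samples and alleles) is
   >= 5.

3' mRNA-Seq reads pile up at the poly-A-proximal end of transcripts, so
called intragenic variants cluster toward the annotated 3' gene end; the
strand-aware relative position (0 at 5', 1 at 3') and its histogram quantify
that bias.  Known-site overlap against a population-variant catalogue scores
call credibility.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np

from ._errors import FormatError, ParameterError

__all__ = [
    "VariantRecord",
    "SampleCall",
    "GeneModel",
    "FilterThresholds",
    "site_hard_filter",
    "filter_lenient",
    "filter_stringent",
    "classify_intragenic",
    "relative_position",
    "position_histogram",
    "known_site_overlap",
    "is_snp",
    "read_vcf",
    "write_vcf",
    "read_gene_models",
    "write_gff3",
    "thin_variant_depths",
]

_SITE_INFO_KEYS = ("QD", "FS", "MQRankSum", "ReadPosRankSum", "SOR")


@dataclass
class SampleCall:
    """Per-sample allele depths (ref first) and total depth."""

    ad: list[int] | None
    dp: int | None

    def alt_depths(self) -> list[int]:
        return [] if not self.ad else list(self.ad[1:])


@dataclass
class VariantRecord:
    chrom: str
    pos: int  # 1-based
    ref: str
    alts: list[str]
    site_info: dict[str, float] = field(default_factory=dict)
    per_sample: list[SampleCall] = field(default_factory=list)
    id: str = "."

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise FormatError("POS must be >= 1")
        for call in self.per_sample:
            if call.ad is not None and len(call.ad) != 1 + len(self.alts):
                raise FormatError(
                    f"AD length {len(call.ad)} != 1 + {len(self.alts)} alts "
                    f"at {self.chrom}:{self.pos}"
                )

    def key(self) -> tuple:
        """Allele-aware identity key (chrom, pos, ref, alts)."""
        return (self.chrom, self.pos, self.ref, tuple(self.alts))

    def dp_total(self) -> int:
        return sum(c.dp for c in self.per_sample if c.dp is not None)

    def alt_ad_total(self) -> int:
        return sum(sum(c.alt_depths()) for c in self.per_sample)

    def ad_sum_total(self) -> int:
        """Depth recalculated from allele depths (all samples, all alleles)."""
        return sum(sum(c.ad) for c in self.per_sample if c.ad is not None)


@dataclass(frozen=True)
class GeneModel:
    """A stranded gene interval (1-based inclusive coordinates)."""

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: Literal["+", "-"]

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise FormatError(f"gene {self.gene_id}: start > end")
        if self.strand not in ("+", "-"):
            raise FormatError(f"gene {self.gene_id}: strand must be + or -")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class FilterThresholds:
    """Hard-filter and depth-criterion thresholds."""

    qd_min: float = 20.0
    fs_max: float = 20.0
    mqranksum_min: float = -12.5
    readpos_min: float = -8.0
    sor_max: float = 5.0
    # lenient record-level criterion
    dp_total_min: int = 10
    alt_ad_total_min: int = 1
    # stringent per-allele criterion
    ad_min: int = 2
    ar_min: float = 0.1
    dp_min_for_ar: int = 10
    dp_total_recalc_min: int = 5
    recalc_strategy: Literal["ad_sum", "dp_sum"] = "ad_sum"


# ---------------------------------------------------------------------------
# Filters
# ---------------------------------------------------------------------------

def site_hard_filter(
    record: VariantRecord, thresholds: FilterThresholds = FilterThresholds()
) -> tuple[bool, list[str]]:
    """Evaluate the site-level hard filters.

    Returns ``(passed, labels)``; labels name the violated annotations, or
    ``["unannotated"]`` for a passing record carrying none of the filterable
    INFO keys.
    """
    info = record.site_info
    failed: list[str] = []
    checks = (
        ("QD", lambda v: v < thresholds.qd_min),
        ("FS", lambda v: v > thresholds.fs_max),
        ("MQRankSum", lambda v: v < thresholds.mqranksum_min),
        ("ReadPosRankSum", lambda v: v < thresholds.readpos_min),
        ("SOR", lambda v: v > thresholds.sor_max),
    )
    seen = 0
    for key, violates in checks:
        value = info.get(key)
        if value is None or (isinstance(value, float) and math.isnan(value)):
            continue
        seen += 1
        if violates(value):
            failed.append(key)
    if failed:
        return False, failed
    return True, ([] if seen else ["unannotated"])


def filter_lenient(
    records: Iterable[VariantRecord],
    thresholds: FilterThresholds = FilterThresholds(),
) -> tuple[list[VariantRecord], int]:
    """Record-level depth criterion: DP_total >= 10 and ALT_AD_total > 0.

    Records with neither AD nor DP in any sample are unevaluable; they are
    dropped and counted in the returned tally.
    """
    kept: list[VariantRecord] = []
    unevaluable = 0
    for record in records:
        has_fields = any(
            c.ad is not None or c.dp is not None for c in record.per_sample
        )
        if not has_fields:
            unevaluable += 1
            continue
        if (
            record.dp_total() >= thresholds.dp_total_min
            and record.alt_ad_total() >= thresholds.alt_ad_total_min
        ):
            kept.append(record)
    return kept, unevaluable


def _allele_supported(
    record: VariantRecord, allele_index: int, thresholds: FilterThresholds
) -> bool:
    """Alt allele supported in >= 1 sample: AD >= 2 or (AR >= 0.1 and DP > 10)."""
    for call in record.per_sample:
        if call.ad is None:
            continue
        ad_alt = call.ad[1 + allele_index]
        if ad_alt >= thresholds.ad_min:
            return True
        dp = call.dp
        if dp is not None and dp > thresholds.dp_min_for_ar and dp > 0:
            if ad_alt / dp >= thresholds.ar_min:
                return True
        # dp of 0 (or missing) with nonzero AD: AR undefined; AD branch only
    return False


def filter_stringent(
    records: Iterable[VariantRecord],
    thresholds: FilterThresholds = FilterThresholds(),
) -> list[tuple[VariantRecord, int]]:
    """Per-allele criterion; returns surviving (record, alt-allele index) pairs.

    An allele is retained when supported in at least one sample and the
    recalculated total depth clears ``dp_total_recalc_min``.  The recalculated
    depth is the sum of per-sample AD sums by default (``ad_sum``), or the sum
    of per-sample DP (``dp_sum``); it is evaluated per record.
    """
    survivors: list[tuple[VariantRecord, int]] = []
    for record in records:
        recalc = (
            record.ad_sum_total()
            if thresholds.recalc_strategy == "ad_sum"
            else record.dp_total()
        )
        if recalc < thresholds.dp_total_recalc_min:
            continue
        for a in range(len(record.alts)):
            if _allele_supported(record, a, thresholds):
                survivors.append((record, a))
    return survivors


# ---------------------------------------------------------------------------
# Positional analysis
# ---------------------------------------------------------------------------

def classify_intragenic(
    records: Sequence[VariantRecord], genes: Sequence[GeneModel]
) -> list[dict]:
    """Mark each record intragenic/intergenic and list overlapped gene IDs.

    A record is intragenic when its POS lies within [start, end] of at least
    one gene on the same chromosome (strand ignored for overlap); nested or
    overlapping genes all contribute their IDs.
    """
    by_chrom: dict[str, list[GeneModel]] = {}
    for gene in genes:
        by_chrom.setdefault(gene.chrom, []).append(gene)
    for chrom_genes in by_chrom.values():
        chrom_genes.sort(key=lambda g: g.start)
    starts = {c: np.array([g.start for g in gs]) for c, gs in by_chrom.items()}

    out = []
    for record in records:
        hits: list[str] = []
        chrom_genes = by_chrom.get(record.chrom, [])
        if chrom_genes:
            # genes starting at or before pos are overlap candidates
            idx = int(np.searchsorted(starts[record.chrom], record.pos, side="right"))
            for gene in chrom_genes[:idx]:
                if gene.end >= record.pos:
                    hits.append(gene.gene_id)
        out.append(
            {"record": record, "intragenic": bool(hits), "gene_ids": hits}
        )
    return out


def relative_position(record: VariantRecord, gene: GeneModel) -> float:
    """Strand-aware relative position within the gene body, 0 = 5', 1 = 3'.

    ``+`` strand: (pos - start)/(end - start); ``-`` strand:
    (end - pos)/(end - start).  A single-base gene returns 0.
    """
    if record.chrom != gene.chrom or not (gene.start <= record.pos <= gene.end):
        raise ParameterError(
            f"variant {record.chrom}:{record.pos} is outside gene {gene.gene_id}"
        )
    span = gene.end - gene.start
    if span == 0:
        return 0.0
    if gene.strand == "+":
        return (record.pos - gene.start) / span
    return (gene.end - record.pos) / span


def position_histogram(
    relative_positions: Sequence[float], n_bins: int = 20
) -> np.ndarray:
    """Counts per equal-width bin over [0, 1], 5' to 3'; last bin right-closed."""
    values = np.asarray(relative_positions, dtype=float)
    if values.size and ((values < 0).any() or (values > 1).any()):
        raise ParameterError("relative positions must lie in [0, 1]")
    counts, _ = np.histogram(values, bins=n_bins, range=(0.0, 1.0))
    return counts


def known_site_overlap(
    called: Iterable[tuple | VariantRecord],
    known: Iterable[tuple | VariantRecord],
    mode: Literal["allele", "position"] = "allele",
) -> dict:
    """Overlap of called variants with a known population-variant catalogue.

    Keys are ``(chrom, pos, ref, alt)`` in allele-aware mode (a multiallelic
    record matches if any of its alts matches) or ``(chrom, pos)`` in
    position mode.  Returns counts, the known fraction, and the partitioned
    key sets; ``n_known + n_novel == number of called variants``.
    """

    def norm_keys(item) -> list[tuple]:
        if isinstance(item, VariantRecord):
            if mode == "position":
                return [(item.chrom, item.pos)]
            return [(item.chrom, item.pos, item.ref, alt) for alt in item.alts]
        item = tuple(item)
        if mode == "position":
            return [item[:2]]
        if len(item) < 4:
            raise FormatError(f"known-site entry too short: {item!r}")
        return [item[:4]]

    known_keys: set[tuple] = set()
    for item in known:
        try:
            known_keys.update(norm_keys(item))
        except FormatError:
            continue  # malformed entries skipped
    called_list = list(called)
    known_hits, novel = [], []
    for item in called_list:
        keys = norm_keys(item)
        (known_hits if any(k in known_keys for k in keys) else novel).append(keys[0])
    n = len(called_list)
    return {
        "n_called": n,
        "n_known": len(known_hits),
        "n_novel": len(novel),
        "fraction_known": len(known_hits) / n if n else math.nan,
        "known_keys": set(known_hits),
        "novel_keys": set(novel),
    }


def is_snp(record: VariantRecord) -> bool:
    """SNP iff ref and every alt have length 1 (else INDEL/MNP)."""
    return len(record.ref) == 1 and all(len(a) == 1 for a in record.alts)


# ---------------------------------------------------------------------------
# I/O (VCF via pysam, gene models via gffutils)
# ---------------------------------------------------------------------------

def read_vcf(path: str | Path) -> list[VariantRecord]:
    """Read VCF records (v4.x, plain or bgzipped) into VariantRecords."""
    import pysam

    records: list[VariantRecord] = []
    with pysam.VariantFile(str(path)) as vcf:
        for rec in vcf:
            info = {}
            for key in _SITE_INFO_KEYS:
                if key in rec.info:
                    value = rec.info[key]
                    if isinstance(value, tuple):
                        value = value[0]
                    info[key] = float(value)
            calls = []
            for sample in rec.samples.values():
                ad = sample.get("AD")
                dp = sample.get("DP")
                ad = None if ad is None or all(v is None for v in ad) else [
                    int(v or 0) for v in ad
                ]
                calls.append(SampleCall(ad=ad, dp=None if dp is None else int(dp)))
            records.append(
                VariantRecord(
                    chrom=rec.chrom,
                    pos=rec.pos,
                    ref=rec.ref,
                    alts=list(rec.alts or []),
                    site_info=info,
                    per_sample=calls,
                    id=rec.id or ".",
                )
            )
    return records


def write_vcf(
    records: Sequence[VariantRecord],
    path: str | Path,
    sample_ids: Sequence[str] | None = None,
    contigs: Sequence[str] | None = None,
) -> None:
    """Write records as a minimal plain-text VCF v4.2 with GT:AD:DP."""
    if sample_ids is None:
        n = max((len(r.per_sample) for r in records), default=0)
        sample_ids = [f"sample{i+1}" for i in range(n)]
    if contigs is None:
        contigs = sorted({r.chrom for r in records})
    lines = ["##fileformat=VCFv4.2"]
    lines += [f"##contig=<ID={c}>" for c in contigs]
    lines += [
        '##INFO=<ID=QD,Number=1,Type=Float,Description="Variant call confidence normalized by depth">',
        '##INFO=<ID=FS,Number=1,Type=Float,Description="Phred-scaled strand bias Fisher test p-value">',
        '##INFO=<ID=MQRankSum,Number=1,Type=Float,Description="Mapping quality rank sum test">',
        '##INFO=<ID=ReadPosRankSum,Number=1,Type=Float,Description="Read position rank sum test">',
        '##INFO=<ID=SOR,Number=1,Type=Float,Description="Symmetric odds ratio of strand bias">',
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        '##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allele depths">',
        '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\t"
        + "FORMAT\t"
        + "\t".join(sample_ids),
    ]
    for r in records:
        info = ";".join(
            f"{k}={r.site_info[k]:g}" for k in _SITE_INFO_KEYS if k in r.site_info
        ) or "."
        fields = [
            r.chrom,
            str(r.pos),
            r.id,
            r.ref,
            ",".join(r.alts) if r.alts else ".",
            ".",
            ".",
            info,
            "GT:AD:DP",
        ]
        for call in r.per_sample:
            gt = "./." if call.ad is None else ("0/1" if sum(call.alt_depths()) else "0/0")
            ad = "." if call.ad is None else ",".join(map(str, call.ad))
            dp = "." if call.dp is None else str(call.dp)
            fields.append(f"{gt}:{ad}:{dp}")
        lines.append("\t".join(fields))
    Path(path).write_text("\n".join(lines) + "\n")


def read_gene_models(path: str | Path) -> list[GeneModel]:
    """Read gene features from GFF3/GTF into GeneModel intervals."""
    import gffutils

    db = gffutils.create_db(
        str(path),
        ":memory:",
        merge_strategy="create_unique",
        keep_order=True,
    )
    genes = []
    for feat in db.features_of_type("gene"):
        gene_id = (
            feat.attributes.get("ID", [None])[0]
            or feat.attributes.get("gene_id", [feat.id])[0]
        )
        strand = feat.strand if feat.strand in ("+", "-") else "+"
        genes.append(
            GeneModel(
                gene_id=str(gene_id),
                chrom=feat.seqid,
                start=feat.start,
                end=feat.end,
                strand=strand,
            )
        )
    return genes


def write_gff3(genes: Sequence[GeneModel], path: str | Path) -> None:
    lines = ["##gff-version 3"]
    for g in genes:
        lines.append(
            "\t".join(
                [
                    g.chrom,
                    "satdepth",
                    "gene",
                    str(g.start),
                    str(g.end),
                    ".",
                    g.strand,
                    ".",
                    f"ID={g.gene_id}",
                ]
            )
        )
    Path(path).write_text("\n".join(lines) + "\n")


def thin_variant_depths(
    records: Sequence[VariantRecord], ratio: float, seed: int
) -> list[VariantRecord]:
    """Binomially thin per-sample AD (and DP) at the given ratio.

    Approximates re-calling at a lower sequencing depth by keeping each
    supporting read independently with probability ``ratio``; DP is thinned
    as the sum of the thinned allele depths plus a thinned remainder
    (unassigned reads).  An approximation of full re-calling, not a
    replacement for it.
    """
    if not (0.0 <= ratio <= 1.0):
        raise ParameterError("ratio must be in [0, 1]")
    rng = np.random.default_rng(np.random.SeedSequence([seed]))
    out = []
    for r in records:
        calls = []
        for call in r.per_sample:
            if call.ad is None:
                calls.append(SampleCall(ad=None, dp=call.dp))
                continue
            ad = rng.binomial(np.asarray(call.ad, dtype=np.int64), ratio).tolist()
            if call.dp is None:
                dp = None
            else:
                rest = max(call.dp - sum(call.ad), 0)
                dp = int(sum(ad) + rng.binomial(rest, ratio))
            calls.append(SampleCall(ad=[int(v) for v in ad], dp=dp))
        out.append(
            VariantRecord(
                chrom=r.chrom,
                pos=r.pos,
                ref=r.ref,
                alts=list(r.alts),
                site_info=dict(r.site_info),
                per_sample=calls,
                id=r.id,
            )
        )
    return out
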