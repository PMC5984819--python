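"""Hard-filter predicates over annotated variant records.

These reimplement the deterministic site filters of a GATK-style RNA-seq
variant workflow as pure, testable functions: Fisher-strand (FS) and
quality-by-depth (QD) thresholds for SNPs, a looser FS threshold for indels,
and a positional SNP-cluster filter (>= `cluster_count` SNPs spanning at
most `cluster_window` bp).  Records are flagged, never removed; a record
with an empty flag set is PASS.

Threshold comparisons are strict inequalities exactly as conventionally
printed (FS > 30 fails, FS = 30 passes; QD < 2.0 fails, QD = 2.0 passes).
A record lacking an annotation is not flagged by that predicate: absent
evidence does not fail a site.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from varprov.model import INDEL, SNP, VariantRecord, key_str

FLAG_FS = "FS"
FLAG_QD = "QD"
FLAG_SNP_CLUSTER = "SnpCluster"


@dataclass(frozen=True)
class FilterConfig:
    """Hard-filter thresholds.

    snp_fs_max / snp_qd_min / indel_fs_max are the unitless GATK annotation
    cuts; cluster_window (bp) and cluster_count define the SNP-cluster
    filter; min_qual is the Phred cut used by the low-quality QC report
    (Q10: a 10% chance the call is wrong).
    """

    snp_fs_max: float = 30.0
    snp_qd_min: float = 2.0
    indel_fs_max: float = 200.0
    cluster_window: int = 35
    cluster_count: int = 3
    min_qual: float = 10.0

    def __post_init__(self) -> None:
        for name in ("snp_fs_max", "snp_qd_min", "indel_fs_max", "cluster_window", "min_qual"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.cluster_count < 2:
            raise ValueError("cluster_count must be >= 2")


def classify_variant(record: VariantRecord) -> str:
    """SNP iff both alleles are single bases; otherwise INDEL.

    The signed indel length is ``record.indel_length`` (positive insertion,
    negative deletion).  Equal alleles are rejected at record construction,
    but re-checked here for defence.
    """
    if record.ref == record.alt:
        raise ValueError(f"{record.chrom}:{record.pos}: ref equals alt, not a variant")
    return record.vclass


def _check_sorted(records: Sequence[VariantRecord]) -> None:
    for prev, cur in zip(records, records[1:]):
        if cur.chrom == prev.chrom and cur.pos < prev.pos:
            raise ValueError(
                f"records not sorted by (chrom, pos): {prev.chrom}:{prev.pos} "
                f"precedes {cur.chrom}:{cur.pos}"
            )


def snp_cluster_filter(
    records: Sequence[VariantRecord], window: int = 35, count: int = 3
) -> set[tuple[str, int, str, str]]:
    """Keys of SNPs lying in a positional cluster.

    A SNP is flagged when it belongs to a run of ``count`` consecutive SNPs
    on one chromosome whose positions span <= ``window`` - 1 bp, i.e.
    max(pos) - min(pos) + 1 <= window, evaluated sliding over every run of
    ``count`` consecutive SNPs.  Indels neither trigger nor receive the
    flag.  Records must be sorted by (chrom, pos).
    """
    _check_sorted(records)
    snp_idx = [i for i, r in enumerate(records) if r.vclass == SNP]
    if len(snp_idx) < count:
        return set()
    chroms = np.array([records[i].chrom for i in snp_idx])
    pos = np.array([records[i].pos for i in snp_idx], dtype=np.int64)
    n = len(snp_idx)
    # run of `count` consecutive SNPs starting at j clusters iff same chrom
    # and span <= window
    j = np.arange(n - count + 1)
    same_chrom = chroms[j] == chroms[j + count - 1]
    tight = (pos[j + count - 1] - pos[j] + 1) <= window
    starts = j[same_chrom & tight]
    flagged: set[int] = set()
    for s in starts:
        flagged.update(range(s, s + count))
    return {records[snp_idx[i]].key for i in flagged}


def apply_hard_filters(
    records: Sequence[VariantRecord], config: FilterConfig = FilterConfig()
) -> Sequence[VariantRecord]:
    """Set filter_flags on each record; returns the same sequence.

    SNPs: flagged FS when fs > snp_fs_max, QD when qd < snp_qd_min, and
    SnpCluster per :func:`snp_cluster_filter`.  Indels: flagged FS when
    fs > indel_fs_max.  Idempotent; records must be sorted by (chrom, pos).
    """
    _check_sorted(records)
    cluster_keys = snp_cluster_filter(records, config.cluster_window, config.cluster_count)
    for r in records:
        flags = set()
        if r.vclass == SNP:
            if r.fs is not None and r.fs > config.snp_fs_max:
                flags.add(FLAG_FS)
            if r.qd is not None and r.qd < config.snp_qd_min:
                flags.add(FLAG_QD)
            if r.key in cluster_keys:
                flags.add(FLAG_SNP_CLUSTER)
        else:
            if r.fs is not None and r.fs > config.indel_fs_max:
                flags.add(FLAG_FS)
        r.filter_flags = flags
    return records


def filter_summary(records: Sequence[VariantRecord], path: str | Path | None = None) -> pd.DataFrame:
    """Per-record filter table (variant key, class, flags, PASS); optionally
    written as TSV."""
    df = pd.DataFrame(
        {
            "variant": [key_str(r.key) for r in records],
            "vclass": [r.vclass for r in records],
            "flags": [";".join(sorted(r.filter_flags)) or "." for r in records],
            "pass": [r.is_pass for r in records],
        }
    )
    if path is not None:
        df.to_csv(path, sep="\t", index=False)
    return df


def pass_records(records: Sequence[VariantRecord]) -> list[VariantRecord]:
    return [r for r in records if r.is_pass]
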