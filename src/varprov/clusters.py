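"""Positional clustering of group-unique variants.

Standing heterogeneity between individuals of one cultivar shows up as a
dense cluster of variants inside a bounded genomic interval — sub-lines fix
different haplotypes over specific regions — whereas true de-novo mutations
are sparse and dispersed.  The scan formalises this as single-linkage
merging: consecutive same-chromosome variants at most ``max_gap`` bp apart
join one cluster, and clusters below ``min_cluster_size`` dissolve back
into the dispersed set.

Intervals are 1-based half-open [start, end); known heterogeneity regions
supplied as BED (0-based half-open) are converted on input.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import pandas as pd

from varprov.model import key_str

VariantKey = tuple[str, int, str, str]


@dataclass(frozen=True)
class ScanConfig:
    max_gap: int = 500_000  # bp between consecutive cluster members
    min_cluster_size: int = 5

    def __post_init__(self) -> None:
        if self.max_gap <= 0:
            raise ValueError("max_gap must be > 0")
        if self.min_cluster_size < 2:
            raise ValueError("min_cluster_size must be >= 2")


@dataclass
class HeterogeneityCluster:
    chrom: str
    start: int  # 1-based, inclusive
    end: int  # 1-based, exclusive
    members: list[VariantKey]

    @property
    def count(self) -> int:
        return len(self.members)

    @property
    def span(self) -> int:
        return self.end - self.start


def detect_clusters(
    keys: Sequence[VariantKey], config: ScanConfig = ScanConfig()
) -> tuple[list[HeterogeneityCluster], list[VariantKey]]:
    """Single-linkage positional clustering of variant keys.

    Returns (clusters, dispersed).  The union of cluster members and the
    dispersed list equals the input set; order of input does not affect the
    result.  Cluster intervals span min to max member position + 1.
    """
    clusters: list[HeterogeneityCluster] = []
    dispersed: list[VariantKey] = []
    ordered = sorted(keys, key=lambda k: (k[0], k[1], k[3], k[2]))
    run: list[VariantKey] = []

    def close_run() -> None:
        if len(run) >= config.min_cluster_size:
            clusters.append(
                HeterogeneityCluster(
                    chrom=run[0][0], start=run[0][1], end=run[-1][1] + 1, members=list(run)
                )
            )
        else:
            dispersed.extend(run)

    for key in ordered:
        if run and (key[0] != run[-1][0] or key[1] - run[-1][1] > config.max_gap):
            close_run()
            run = []
        run.append(key)
    if run:
        close_run()
    return clusters, dispersed


def intervals_overlap(
    chrom_a: str, start_a: int, end_a: int, chrom_b: str, start_b: int, end_b: int
) -> bool:
    """Half-open interval intersection; touching boundaries do not overlap."""
    return chrom_a == chrom_b and start_a < end_b and start_b < end_a


def annotate_overlap(
    clusters: Sequence[HeterogeneityCluster],
    known_regions: Sequence[tuple[str, int, int]],
) -> list[bool]:
    """Flag each cluster that intersects any known heterogeneity region.

    ``known_regions`` are (chrom, start, end) half-open 1-based intervals
    (use :func:`read_bed` for BED input).
    """
    return [
        any(
            intervals_overlap(c.chrom, c.start, c.end, chrom, start, end)
            for chrom, start, end in known_regions
        )
        for c in clusters
    ]


def read_bed(path: str | Path) -> list[tuple[str, int, int]]:
    """Read BED intervals, converting 0-based half-open to 1-based half-open."""
    regions: list[tuple[str, int, int]] = []
    for line_no, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip() or line.startswith(("#", "track", "browser")):
            continue
        fields = line.split("\t")
        if len(fields) < 3:
            raise ValueError(f"{path} line {line_no}: BED needs >= 3 columns")
        chrom, start, end = fields[0], int(fields[1]), int(fields[2])
        regions.append((chrom, start + 1, end + 1))
    return regions


def clusters_table(
    clusters: Sequence[HeterogeneityCluster],
    overlaps: Sequence[bool] | None = None,
    path: str | Path | None = None,
) -> pd.DataFrame:
    df = pd.DataFrame(
        {
            "chrom": [c.chrom for c in clusters],
            "start": [c.start for c in clusters],
            "end": [c.end for c in clusters],
            "n_variants": [c.count for c in clusters],
            "span_bp": [c.span for c in clusters],
        }
    )
    if overlaps is not None:
        df["overlaps_known_region"] = list(overlaps)
    if path is not None:
        df.to_csv(path, sep="\t", index=False)
    return df


def dispersed_table(dispersed: Sequence[VariantKey], path: str | Path | None = None) -> pd.DataFrame:
    df = pd.DataFrame({"variant": [key_str(k) for k in sorted(dispersed)]})
    if path is not None:
        df.to_csv(path, sep="\t", index=False)
    return df
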