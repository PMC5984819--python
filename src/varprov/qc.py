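"""Variant-call QC summaries that expose bioinformatic false positives.

Four diagnostics, each comparing an observed distribution against what true
inherited variation would look like in a replicated, selfed study design:

* depth histograms by zygosity — false positives pile up at 1-2 reads;
* the fraction of calls at Phred quality <= 10 (a 10% error chance);
* observed heterozygous fraction vs the closed-form selfing expectation
  100 x (1/2)^g after g generations of self-pollination;
* sibling concordance (Venn region counts) — calls private to a single
  replicate are suspect;
* indel size-class bookkeeping — an indel call set confined entirely to
  +-1-2 bp is the signature of an alignment artifact, not biology.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from varprov.model import DEPTH_UNKNOWN, GenotypeCall, INDEL, VariantRecord

DEPTH_BIN_TOP = 21  # final bin is "21+", closed at the top


@dataclass
class DepthHistogram:
    """Per-sample variant-call counts binned by read depth, split by zygosity.

    Bins are depths 1..20 plus a final 21+ bin.  A site contributes once per
    carrying sample (HET or HOM_ALT call); calls with unknown or zero depth
    are excluded (no reads informing a call means its depth was not
    observed).
    """

    het_counts: np.ndarray  # length 21
    hom_alt_counts: np.ndarray  # length 21

    @property
    def labels(self) -> list[str]:
        return [str(d) for d in range(1, DEPTH_BIN_TOP)] + [f"{DEPTH_BIN_TOP}+"]

    @property
    def total(self) -> int:
        return int(self.het_counts.sum() + self.hom_alt_counts.sum())

    def fraction_at_depth(self, depth: int) -> float:
        """Fraction of counted calls in one depth bin (depth >= 21 pools)."""
        i = min(depth, DEPTH_BIN_TOP) - 1
        if self.total == 0:
            return float("nan")
        return float(self.het_counts[i] + self.hom_alt_counts[i]) / self.total

    def to_frame(self, path: str | Path | None = None) -> pd.DataFrame:
        df = pd.DataFrame(
            {"depth": self.labels, "het": self.het_counts, "hom_alt": self.hom_alt_counts}
        )
        if path is not None:
            df.to_csv(path, sep="\t", index=False)
        return df


def _stacked(records: Sequence[VariantRecord]) -> tuple[np.ndarray, np.ndarray]:
    calls = np.vstack([r.calls for r in records]) if records else np.empty((0, 0), dtype=np.int8)
    depths = np.vstack([r.depths for r in records]) if records else np.empty((0, 0), dtype=np.int32)
    return calls, depths


def depth_histogram(
    records: Sequence[VariantRecord], sample_indices: Sequence[int] | None = None
) -> DepthHistogram:
    """Histogram of read depths for all carrying calls (HET / HOM_ALT)."""
    het = np.zeros(DEPTH_BIN_TOP, dtype=np.int64)
    hom = np.zeros(DEPTH_BIN_TOP, dtype=np.int64)
    if not records:
        return DepthHistogram(het, hom)
    calls, depths = _stacked(records)
    if sample_indices is not None:
        calls = calls[:, list(sample_indices)]
        depths = depths[:, list(sample_indices)]
    known = depths >= 1
    binned = np.minimum(depths, DEPTH_BIN_TOP)
    for zygosity, out in ((GenotypeCall.HET, het), (GenotypeCall.HOM_ALT, hom)):
        mask = known & (calls == zygosity)
        counts = np.bincount(binned[mask] - 1, minlength=DEPTH_BIN_TOP)
        out += counts[:DEPTH_BIN_TOP]
    return DepthHistogram(het, hom)


def low_quality_fraction(records: Sequence[VariantRecord], qual_cut: float = 10.0) -> float:
    """Fraction of variant records with QUAL <= qual_cut (inclusive).

    QUAL is Phred-scaled: Q10 means a 10% chance the call is wrong, Q20 a
    1% chance.  Records without a QUAL are excluded from the denominator.
    """
    quals = [r.qual for r in records if r.qual is not None]
    if not quals:
        return float("nan")
    return float(np.mean(np.asarray(quals) <= qual_cut))


def zygosity_fractions(
    records: Sequence[VariantRecord], sample_indices: Sequence[int] | None = None
) -> tuple[float, float]:
    """(het fraction, hom_alt fraction) over carrying calls.

    The denominator is all non-missing, non-HOM_REF per-sample calls: a
    "variant call" is a call of the alternate allele.
    """
    if not records:
        return (float("nan"), float("nan"))
    calls, _ = _stacked(records)
    if sample_indices is not None:
        calls = calls[:, list(sample_indices)]
    n_het = int(np.sum(calls == GenotypeCall.HET))
    n_hom = int(np.sum(calls == GenotypeCall.HOM_ALT))
    total = n_het + n_hom
    if total == 0:
        return (float("nan"), float("nan"))
    return (n_het / total, n_hom / total)


def expected_het_fraction(generations_selfed: int) -> float:
    """Expected percentage of variants still heterozygous after g selfings.

    A locus heterozygous in the T0 plant halves its heterozygosity each
    generation of self-pollination (no segregation distortion, no fitness
    effect): 100 x (1/2)^g.  g=8 gives 0.390625%, g=4 gives 6.25%.
    """
    g = int(generations_selfed)
    if g != generations_selfed or g < 0:
        raise ValueError("generations_selfed must be a non-negative integer")
    return 100.0 * 0.5**g


@dataclass
class VennCounts:
    """Counts of every non-empty membership pattern among k named sets."""

    set_names: list[str]
    region_counts: dict[tuple[str, ...], int]

    @property
    def union_size(self) -> int:
        return sum(self.region_counts.values())

    @property
    def all_shared(self) -> int:
        return self.region_counts.get(tuple(self.set_names), 0)

    def to_frame(self, path: str | Path | None = None) -> pd.DataFrame:
        rows = [
            {"members": "&".join(pattern), "count": count}
            for pattern, count in sorted(self.region_counts.items())
        ]
        df = pd.DataFrame(rows, columns=["members", "count"])
        if path is not None:
            df.to_csv(path, sep="\t", index=False)
        return df


def sibling_overlap(sets: Mapping[str, Iterable]) -> VennCounts:
    """Exact Venn region counts for the per-sample variant-key sets.

    For k sets there are up to 2^k - 1 non-empty membership patterns; the
    region counts partition the union.  The all-shared region measures
    replicate concordance — variation real in the plant should be called in
    every sibling.
    """
    named = {name: set(s) for name, s in sets.items()}
    if len(named) < 2:
        raise ValueError("sibling_overlap needs at least 2 sets")
    names = list(named)
    region_counts: dict[tuple[str, ...], int] = {}
    union = set().union(*named.values())
    for element in union:
        pattern = tuple(n for n in names if element in named[n])
        region_counts[pattern] = region_counts.get(pattern, 0) + 1
    return VennCounts(set_names=names, region_counts=region_counts)


@dataclass
class IndelClassTable:
    """Counts of indel calls keyed by (direction, |length| bp).

    ``all_short`` fires when every indel call in the input is a +-1 or
    +-2 bp event — real indel spectra have a long tail, so all mass at
    1-2 bp flags an alignment/pipeline artifact.
    """

    counts: dict[tuple[str, int], int]

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    @property
    def all_short(self) -> bool:
        return self.total > 0 and all(length <= 2 for _d, length in self.counts)

    def to_frame(self, path: str | Path | None = None) -> pd.DataFrame:
        rows = [
            {"direction": d, "length_bp": length, "count": c}
            for (d, length), c in sorted(self.counts.items())
        ]
        df = pd.DataFrame(rows, columns=["direction", "length_bp", "count"])
        if path is not None:
            df.to_csv(path, sep="\t", index=False)
        return df


def indel_class_table(records: Sequence[VariantRecord]) -> IndelClassTable:
    """Tabulate indel records by direction and unsigned length."""
    counts: dict[tuple[str, int], int] = {}
    for r in records:
        if r.vclass != INDEL:
            continue
        length = r.indel_length
        key = ("insertion" if length > 0 else "deletion", abs(length))
        counts[key] = counts.get(key, 0) + 1
    return IndelClassTable(counts=counts)


def qual_histogram(
    records: Sequence[VariantRecord], bin_width: float = 5.0, top: float = 100.0
) -> pd.DataFrame:
    """Binned QUAL distribution (records with known QUAL only)."""
    quals = np.asarray([r.qual for r in records if r.qual is not None])
    edges = np.arange(0.0, top + bin_width, bin_width)
    counts, _ = np.histogram(np.clip(quals, 0, top - 1e-9), bins=edges)
    return pd.DataFrame(
        {"qual_low": edges[:-1], "qual_high": edges[1:], "count": counts}
    )
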