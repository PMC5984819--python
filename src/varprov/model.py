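"""Core domain types and VCF / study-design I/O.

Conventions used throughout the package:

* Coordinates are 1-based as in VCF; every interval elsewhere in the
  package is half-open ``[start, end)`` in 1-based coordinates.
* Multi-allelic sites are split into one record per alternate allele at
  ingestion.  A genotype that references a different alternate allele than
  the split record's own becomes MISSING for that record.
* Genotype calls are stored as small integer codes (:class:`GenotypeCall`);
  per-record call/depth vectors are numpy arrays aligned to the sample list.
* An absent per-sample DP is stored as ``DEPTH_UNKNOWN`` (-1), never as 0:
  depth histograms bin observed depths only.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import IntEnum
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import pysam

DEPTH_UNKNOWN = -1

SNP = "SNP"
INDEL = "INDEL"


class GenotypeCall(IntEnum):
    """Diploid genotype category relative to the reference allele.

    After multi-allelic splitting every record carries a single alternate
    allele, so HET / HOM_ALT always refer to that allele.
    """

    MISSING = -1
    HOM_REF = 0
    HET = 1
    HOM_ALT = 2


class VcfParseError(ValueError):
    """Raised when a VCF cannot be parsed into the domain model."""


@dataclass(slots=True)
class VariantRecord:
    """One bi-allelic variant site with per-sample calls and depths.

    ``calls`` and ``depths`` are aligned to the sample list returned by
    :func:`read_vcf`; ``depths`` uses ``DEPTH_UNKNOWN`` (-1) where DP was
    absent.  ``qual``, ``fs`` and ``qd`` are ``None`` when the annotation is
    absent — absent evidence is distinct from a value of zero.
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    qual: float | None = None
    fs: float | None = None
    qd: float | None = None
    calls: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=np.int8))
    depths: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=np.int32))
    filter_flags: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"position must be >= 1, got {self.pos}")
        if self.ref == self.alt:
            raise ValueError(f"{self.chrom}:{self.pos} ref equals alt ({self.ref!r}): not a variant")
        if len(self.calls) != len(self.depths):
            raise ValueError("calls and depths must have equal length")

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref, self.alt)

    @property
    def vclass(self) -> str:
        return SNP if len(self.ref) == 1 and len(self.alt) == 1 else INDEL

    @property
    def indel_length(self) -> int:
        """Signed length: positive for insertions, negative for deletions."""
        return len(self.alt) - len(self.ref)

    @property
    def is_pass(self) -> bool:
        return not self.filter_flags


def records_equal(a: VariantRecord, b: VariantRecord, rel_tol: float = 1e-3) -> bool:
    """Domain-model equality with float tolerance for QUAL/FS/QD.

    Text round-tripping through VCF stores annotations at finite precision;
    the tolerance absorbs float32 storage in htslib.
    """

    def close(x: float | None, y: float | None) -> bool:
        if x is None or y is None:
            return x is None and y is None
        return abs(x - y) <= rel_tol * max(1.0, abs(x), abs(y))

    return (
        a.key == b.key
        and close(a.qual, b.qual)
        and close(a.fs, b.fs)
        and close(a.qd, b.qd)
        and np.array_equal(a.calls, b.calls)
        and np.array_equal(a.depths, b.depths)
        and a.filter_flags == b.filter_flags
    )


@dataclass(frozen=True)
class StudyDesign:
    """Maps each sample to its (group, family, replicate) cell.

    The default study layout is 4 groups x 9 samples, each group being 3
    families (independent plants) x 3 sibling seeds.
    """

    groups: tuple[str, ...]
    sample_map: dict[str, tuple[str, str, str]]

    def __post_init__(self) -> None:
        for sample, (group, _fam, _rep) in self.sample_map.items():
            if group not in self.groups:
                raise ValueError(f"sample {sample!r} maps to unknown group {group!r}")

    @property
    def samples(self) -> list[str]:
        return list(self.sample_map)

    def samples_in_group(self, group: str) -> list[str]:
        return [s for s, (g, _f, _r) in self.sample_map.items() if g == group]

    def group_of(self, sample: str) -> str:
        return self.sample_map[sample][0]

    def family_of(self, sample: str) -> tuple[str, str]:
        g, f, _ = self.sample_map[sample]
        return (g, f)

    def families(self) -> dict[tuple[str, str], list[str]]:
        """Samples per (group, family) cell, in design order."""
        fams: dict[tuple[str, str], list[str]] = {}
        for s, (g, f, _r) in self.sample_map.items():
            fams.setdefault((g, f), []).append(s)
        return fams

    def to_tsv(self, path: str | Path) -> Path:
        rows = [
            {"sample_id": s, "group": g, "family": f, "replicate": r}
            for s, (g, f, r) in self.sample_map.items()
        ]
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
        return Path(path)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "StudyDesign":
        df = pd.read_csv(path, sep="\t", dtype=str)
        required = {"sample_id", "group", "family", "replicate"}
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"design table {path} lacks columns: {sorted(missing)}")
        if df["sample_id"].duplicated().any():
            dupes = df.loc[df["sample_id"].duplicated(), "sample_id"].tolist()
            raise ValueError(f"duplicate sample ids in design table: {dupes}")
        sample_map = {
            row.sample_id: (row.group, row.family, row.replicate) for row in df.itertuples()
        }
        groups = tuple(dict.fromkeys(df["group"]))
        return cls(groups=groups, sample_map=sample_map)


def default_design(
    n_groups: int = 4, families_per_group: int = 3, siblings_per_family: int = 3
) -> StudyDesign:
    """The emulated study layout: three transgenic event series plus an
    untransformed control group, nine plants each (3 families x 3 siblings)."""
    groups = tuple(f"series_{i}" for i in range(1, n_groups)) + ("control",)
    sample_map: dict[str, tuple[str, str, str]] = {}
    for g in groups:
        for fam in range(1, families_per_group + 1):
            for sib in range(1, siblings_per_family + 1):
                sample_map[f"{g}_f{fam}_s{sib}"] = (g, f"f{fam}", f"s{sib}")
    return StudyDesign(groups=groups, sample_map=sample_map)


@dataclass
class GenotypeMatrix:
    """Rectangular variants x samples matrix of genotype codes and depths."""

    variants: list[tuple[str, int, str, str]]
    samples: list[str]
    calls: np.ndarray  # (V, S) int8 of GenotypeCall codes
    depths: np.ndarray  # (V, S) int32, DEPTH_UNKNOWN where absent

    def __post_init__(self) -> None:
        v, s = len(self.variants), len(self.samples)
        if self.calls.shape != (v, s) or self.depths.shape != (v, s):
            raise ValueError(
                f"matrix shape mismatch: {v} variants x {s} samples vs "
                f"calls {self.calls.shape}, depths {self.depths.shape}"
            )
        if len(set(self.variants)) != v:
            raise ValueError("variant keys are not unique")
        if len(set(self.samples)) != s:
            raise ValueError("sample ids are not unique")

    @property
    def shape(self) -> tuple[int, int]:
        return self.calls.shape

    def sample_index(self, samples: Iterable[str]) -> np.ndarray:
        lookup = {s: i for i, s in enumerate(self.samples)}
        return np.array([lookup[s] for s in samples], dtype=np.intp)


# ---------------------------------------------------------------------------
# VCF I/O (pysam-backed)

_GT_FROM_CODE = {
    int(GenotypeCall.HOM_REF): (0, 0),
    int(GenotypeCall.HET): (0, 1),
    int(GenotypeCall.HOM_ALT): (1, 1),
    int(GenotypeCall.MISSING): (None, None),
}


def _classify_gt(gt: tuple, alt_index: int, sample: str, where: str) -> int:
    """Map a pysam GT tuple to a GenotypeCall code for one split alt allele."""
    if gt is None or all(a is None for a in gt):
        return int(GenotypeCall.MISSING)
    if len(gt) != 2:
        raise VcfParseError(
            f"non-diploid genotype (ploidy {len(gt)}) for sample {sample!r} at {where}"
        )
    a, b = gt
    if a is None or b is None:
        return int(GenotypeCall.MISSING)
    alleles = {a, b}
    if not alleles <= {0, alt_index}:
        # references a different alternate allele than this split record's
        return int(GenotypeCall.MISSING)
    if alleles == {0}:
        return int(GenotypeCall.HOM_REF)
    if alleles == {alt_index}:
        return int(GenotypeCall.HOM_ALT)
    return int(GenotypeCall.HET)


def _scalar(value) -> float | None:
    """INFO fields declared Number=A arrive as tuples; collapse to a float."""
    if value is None:
        return None
    if isinstance(value, (tuple, list)):
        value = value[0] if value else None
        if value is None:
            return None
    return float(value)


def read_vcf(path: str | Path) -> tuple[list[VariantRecord], list[str]]:
    """Read a VCF into the domain model.

    Multi-allelic sites are split into one record per alternate allele;
    genotypes referencing another alternate become MISSING for that record.
    Phased separators are treated as unphased.  DP, FS and QD are optional;
    absent values are stored as unknown, not zero.

    Raises :class:`VcfParseError` naming the offending data line for
    malformed input, and listing the sample for non-diploid genotypes.
    """
    path = Path(path)
    records: list[VariantRecord] = []
    try:
        vcf = pysam.VariantFile(str(path))
    except (ValueError, OSError) as exc:
        raise VcfParseError(f"cannot parse VCF header of {path}: {exc}") from exc
    with vcf:
        samples = list(vcf.header.samples)
        line_no = len(str(vcf.header).rstrip("\n").split("\n"))
        rec_iter = iter(vcf)
        while True:
            line_no += 1
            try:
                rec = next(rec_iter)
            except StopIteration:
                break
            except Exception as exc:  # htslib raises various types
                raise VcfParseError(f"malformed VCF record at {path} line {line_no}: {exc}") from exc
            where = f"{rec.chrom}:{rec.pos} (line {line_no})"
            alts = rec.alts or ()
            fs = _scalar(rec.info.get("FS"))
            qd = _scalar(rec.info.get("QD"))
            flags = {f for f in rec.filter.keys() if f != "PASS"}
            n = len(samples)
            for alt_index, alt in enumerate(alts, start=1):
                calls = np.empty(n, dtype=np.int8)
                depths = np.full(n, DEPTH_UNKNOWN, dtype=np.int32)
                for i, sample in enumerate(samples):
                    data = rec.samples[sample]
                    calls[i] = _classify_gt(data.get("GT"), alt_index, sample, where)
                    dp = data.get("DP")
                    if dp is not None:
                        depths[i] = dp
                records.append(
                    VariantRecord(
                        chrom=rec.chrom,
                        pos=rec.pos,
                        ref=rec.ref,
                        alt=alt,
                        qual=rec.qual,
                        fs=fs,
                        qd=qd,
                        calls=calls,
                        depths=depths,
                        filter_flags=set(flags),
                    )
                )
    return records, samples


def write_vcf(
    records: Sequence[VariantRecord],
    samples: Sequence[str],
    path: str | Path,
    contig_length: int = 500_000_000,
) -> Path:
    """Write domain-model records as a plain-text VCF 4.2 file.

    FORMAT is GT:DP; FS and QD are carried in INFO; filter flags become
    FILTER entries (PASS when the flag set is empty).  ``read_vcf`` after
    ``write_vcf`` is the identity on the domain model (up to float storage
    precision in QUAL/FS/QD).
    """
    path = Path(path)
    header = pysam.VariantHeader()
    header.add_line('##fileformat=VCFv4.2')
    contigs = sorted({r.chrom for r in records})
    for contig in contigs:
        header.contigs.add(contig, length=contig_length)
    header.add_line('##INFO=<ID=FS,Number=1,Type=Float,Description="Fisher strand bias (Phred)">')
    header.add_line('##INFO=<ID=QD,Number=1,Type=Float,Description="Quality by depth">')
    flag_names = sorted({f for r in records for f in r.filter_flags})
    for name in flag_names:
        header.filters.add(name, None, None, f"Failed {name} hard filter")
    header.add_line('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    header.add_line('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">')
    for s in samples:
        header.add_sample(s)

    with pysam.VariantFile(str(path), mode="w", header=header) as out:
        for r in records:
            if len(r.calls) != len(samples):
                raise ValueError(f"record {r.key} has {len(r.calls)} calls for {len(samples)} samples")
            rec = out.new_record(
                contig=r.chrom, start=r.pos - 1, alleles=(r.ref, r.alt), qual=r.qual
            )
            if r.fs is not None:
                rec.info["FS"] = r.fs
            if r.qd is not None:
                rec.info["QD"] = r.qd
            if r.filter_flags:
                for f in sorted(r.filter_flags):
                    rec.filter.add(f)
            else:
                rec.filter.add("PASS")
            for i, s in enumerate(samples):
                rec.samples[s]["GT"] = _GT_FROM_CODE[int(r.calls[i])]
                if r.depths[i] != DEPTH_UNKNOWN:
                    rec.samples[s]["DP"] = int(r.depths[i])
            out.write(rec)
    return path


def build_matrix(records: Sequence[VariantRecord], design: StudyDesign,
                 samples: Sequence[str] | None = None) -> GenotypeMatrix:
    """Assemble the genotype matrix restricted to the design's samples.

    ``samples`` is the column order of the records' call vectors; when None
    it is taken to be the design's sample list (requiring exact agreement in
    length).  Variants are sorted by (chrom, pos, alt, ref); columns from
    samples absent from the design are dropped.
    """
    if samples is None:
        samples = design.samples
    sample_pos = {s: i for i, s in enumerate(samples)}
    missing = [s for s in design.samples if s not in sample_pos]
    if missing:
        raise ValueError(f"design samples absent from VCF: {missing}")
    cols = np.array([sample_pos[s] for s in design.samples], dtype=np.intp)

    if not records:
        v = 0
        return GenotypeMatrix(
            variants=[],
            samples=design.samples,
            calls=np.empty((v, len(cols)), dtype=np.int8),
            depths=np.empty((v, len(cols)), dtype=np.int32),
        )
    order = sorted(range(len(records)), key=lambda i: (
        records[i].chrom, records[i].pos, records[i].alt, records[i].ref))
    keys = [records[i].key for i in order]
    calls = np.vstack([records[i].calls for i in order])[:, cols]
    depths = np.vstack([records[i].depths for i in order])[:, cols]
    return GenotypeMatrix(variants=keys, samples=design.samples, calls=calls, depths=depths)


def key_str(key: tuple[str, int, str, str]) -> str:
    """Canonical text form of a variant key: chrom:pos:ref:alt."""
    return f"{key[0]}:{key[1]}:{key[2]}:{key[3]}"


def parse_key(text: str) -> tuple[str, int, str, str]:
    chrom, pos, ref, alt = text.split(":")
    return (chrom, int(pos), ref, alt)
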