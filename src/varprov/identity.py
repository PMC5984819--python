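"""Accession fingerprinting against a pre-ascertained SNP panel.

A dense set of group-unique homozygous variants may not be de-novo mutation
at all but the standing variation of a different genetic background.  To
diagnose this, the group's variant profile is intersected with a SNP-panel
matrix (pre-ascertained positions genotyped across a germplasm collection,
SoySNP50k-style) and scored for categorical genotype identity against every
accession.  A near-perfect top match identifies the true background; the
residual mismatches, when positionally clustered, point at heterogeneity
between individuals of the matched accession.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from varprov.model import GenotypeCall, VariantRecord, read_vcf

HETEROGENEITY_HINT = (
    "possible residual heterogeneity between individuals of the matched accession"
)

_TSV_CODE = {0: "0", 1: "1", 2: "2", -1: "NA"}
_CODE_TSV = {"0": 0, "1": 1, "2": 2, "NA": -1, ".": -1}


@dataclass
class SnpPanel:
    """Genotype matrix of pre-ascertained positions x accessions.

    Genotypes are GenotypeCall codes (0/1/2, -1 missing).  Positions are
    unique (chrom, pos, ref, alt) keys in matrix row order.
    """

    positions: list[tuple[str, int, str, str]]
    accessions: list[str]
    genotypes: np.ndarray  # (P, A) int8

    def __post_init__(self) -> None:
        p, a = len(self.positions), len(self.accessions)
        if self.genotypes.shape != (p, a):
            raise ValueError(
                f"panel shape mismatch: {p} positions x {a} accessions vs {self.genotypes.shape}"
            )
        site_keys = [(c, pos) for c, pos, _r, _a in self.positions]
        if len(set(site_keys)) != p:
            raise ValueError("panel position keys are not unique")
        self._site_index = {k: i for i, k in enumerate(site_keys)}

    def site_row(self, chrom: str, pos: int) -> int | None:
        return self._site_index.get((chrom, pos))

    def to_tsv(self, path: str | Path) -> Path:
        """TSV: chrom, pos, ref, alt, then one 0/1/2/NA column per accession."""
        df = pd.DataFrame(self.positions, columns=["chrom", "pos", "ref", "alt"])
        geno = pd.DataFrame(
            np.vectorize(_TSV_CODE.get)(self.genotypes), columns=self.accessions
        )
        pd.concat([df, geno], axis=1).to_csv(path, sep="\t", index=False)
        return Path(path)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "SnpPanel":
        df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
        meta_cols = ["chrom", "pos", "ref", "alt"]
        if df.columns[:4].tolist() != meta_cols:
            raise ValueError(f"panel TSV must start with columns {meta_cols}")
        accessions = df.columns[4:].tolist()
        positions = [
            (r.chrom, int(r.pos), r.ref, r.alt) for r in df[meta_cols].itertuples()
        ]
        coded = df[accessions].apply(lambda col: col.map(_CODE_TSV))
        if coded.isna().any().any():
            bad = sorted(set(df[accessions].to_numpy().ravel()) - set(_CODE_TSV))
            raise ValueError(f"panel TSV contains unrecognised genotype codes: {bad}")
        geno = coded.to_numpy(dtype=np.int8)
        return cls(positions=positions, accessions=accessions, genotypes=geno)

    @classmethod
    def from_vcf(cls, path: str | Path) -> "SnpPanel":
        """Panel as a multi-sample VCF with one sample column per accession."""
        records, accessions = read_vcf(path)
        positions = [r.key for r in records]
        geno = (
            np.vstack([r.calls for r in records])
            if records
            else np.empty((0, len(accessions)), dtype=np.int8)
        )
        return cls(positions=positions, accessions=accessions, genotypes=geno)


@dataclass
class QueryProfile:
    """A variant profile restricted to panel positions.

    ``rows`` are panel row indices; ``calls`` the query's genotype codes at
    those rows (already allele-remapped onto the panel's ref/alt
    orientation where needed).
    """

    rows: np.ndarray  # panel row indices, intp
    calls: np.ndarray  # int8 GenotypeCall codes
    keys: list[tuple[str, int, str, str]]

    def __len__(self) -> int:
        return len(self.rows)


@dataclass
class IdentityResult:
    accession: str
    n_compared: int
    n_match: int
    mismatch_positions: list[tuple[str, int]] = field(default_factory=list)

    @property
    def pct_identity(self) -> float:
        return 100.0 * self.n_match / self.n_compared if self.n_compared else float("nan")


def intersect_panel(
    query: Sequence[tuple[tuple[str, int, str, str], int | GenotypeCall]],
    panel: SnpPanel,
) -> QueryProfile:
    """Restrict a query profile to the panel's positions.

    ``query`` is a sequence of (variant key, genotype code) pairs.  At a
    shared (chrom, pos), allele orientation is reconciled: identical
    (ref, alt) pairs are kept as-is; a swapped pair (query alt = panel ref
    and vice versa) is remapped by flipping HOM_REF and HOM_ALT; any other
    allele disagreement drops the position with a warning.
    """
    rows: list[int] = []
    calls: list[int] = []
    keys: list[tuple[str, int, str, str]] = []
    for key, call in query:
        chrom, pos, ref, alt = key
        row = panel.site_row(chrom, pos)
        if row is None:
            continue
        p_ref, p_alt = panel.positions[row][2], panel.positions[row][3]
        code = int(call)
        if (ref, alt) == (p_ref, p_alt):
            pass
        elif (ref, alt) == (p_alt, p_ref):
            if code == GenotypeCall.HOM_REF:
                code = int(GenotypeCall.HOM_ALT)
            elif code == GenotypeCall.HOM_ALT:
                code = int(GenotypeCall.HOM_REF)
        else:
            warnings.warn(
                f"allele mismatch at {chrom}:{pos} (query {ref}>{alt}, "
                f"panel {p_ref}>{p_alt}); position dropped"
            )
            continue
        rows.append(row)
        calls.append(code)
        keys.append(key)
    return QueryProfile(
        rows=np.array(rows, dtype=np.intp),
        calls=np.array(calls, dtype=np.int8),
        keys=keys,
    )


def identity_scores(profile: QueryProfile, panel: SnpPanel) -> list[IdentityResult]:
    """Score the profile against every panel accession.

    Identity is categorical genotype equality (HOM_REF / HET / HOM_ALT); a
    position missing on either side is excluded from that accession's
    denominator.  Results are sorted by percent identity descending, ties
    broken by accession id ascending.
    """
    if len(profile) == 0:
        raise ValueError("empty profile: identity is undefined")
    sub = panel.genotypes[profile.rows, :]  # (P, A)
    q = profile.calls[:, None]
    comparable = (sub != GenotypeCall.MISSING) & (q != GenotypeCall.MISSING)
    match = comparable & (sub == q)
    n_comp = comparable.sum(axis=0)
    n_match = match.sum(axis=0)
    results = []
    for a, acc in enumerate(panel.accessions):
        mism = comparable[:, a] & ~match[:, a]
        positions = [
            (panel.positions[profile.rows[i]][0], panel.positions[profile.rows[i]][1])
            for i in np.flatnonzero(mism)
        ]
        results.append(
            IdentityResult(
                accession=acc,
                n_compared=int(n_comp[a]),
                n_match=int(n_match[a]),
                mismatch_positions=positions,
            )
        )
    results.sort(key=lambda r: (-(r.pct_identity if r.n_compared else -1.0), r.accession))
    return results


@dataclass
class MismatchInterval:
    """A run of clustered mismatch positions on one chromosome.

    ``start``/``end`` are a 1-based half-open interval; ``note`` carries the
    interpretation hint (clustered mismatches against an otherwise
    near-perfect match suggest residual heterogeneity within the matched
    accession, not de-novo mutation).
    """

    chrom: str
    start: int
    end: int
    positions: list[int]
    note: str = HETEROGENEITY_HINT

    @property
    def count(self) -> int:
        return len(self.positions)


def mismatch_intervals(result: IdentityResult, max_gap: int = 1_000_000) -> list[MismatchInterval]:
    """Merge a result's mismatch positions into clustered intervals.

    Consecutive mismatches on one chromosome at most ``max_gap`` bp apart
    join one interval; the interval spans min to max member position + 1.
    """
    by_chrom: dict[str, list[int]] = {}
    for chrom, pos in result.mismatch_positions:
        by_chrom.setdefault(chrom, []).append(pos)
    intervals: list[MismatchInterval] = []
    for chrom in sorted(by_chrom):
        positions = sorted(by_chrom[chrom])
        run = [positions[0]]
        for p in positions[1:]:
            if p - run[-1] <= max_gap:
                run.append(p)
            else:
                intervals.append(MismatchInterval(chrom, run[0], run[-1] + 1, run))
                run = [p]
        intervals.append(MismatchInterval(chrom, run[0], run[-1] + 1, run))
    return intervals


def ranked_table(results: Sequence[IdentityResult], path: str | Path | None = None) -> pd.DataFrame:
    df = pd.DataFrame(
        {
            "accession": [r.accession for r in results],
            "n_compared": [r.n_compared for r in results],
            "n_match": [r.n_match for r in results],
            "pct_identity": [round(r.pct_identity, 4) for r in results],
        }
    )
    if path is not None:
        df.to_csv(path, sep="\t", index=False)
    return df


def best_match_report(
    results: Sequence[IdentityResult], path: str | Path | None = None, max_gap: int = 1_000_000
) -> dict:
    """JSON-ready best-match summary with clustered-mismatch diagnostics."""
    best = results[0]
    report = {
        "accession": best.accession,
        "n_compared": best.n_compared,
        "n_match": best.n_match,
        "pct_identity": round(best.pct_identity, 4),
        "runner_up": results[1].accession if len(results) > 1 else None,
        "runner_up_pct_identity": (
            round(results[1].pct_identity, 4) if len(results) > 1 else None
        ),
        "mismatch_intervals": [
            {
                "chrom": iv.chrom,
                "start": iv.start,
                "end": iv.end,
                "n_mismatches": iv.count,
                "note": iv.note,
            }
            for iv in (mismatch_intervals(best, max_gap) if best.mismatch_positions else [])
        ],
    }
    if path is not None:
        Path(path).write_text(json.dumps(report, indent=2))
    return report
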