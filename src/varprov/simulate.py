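"""Synthetic study generator with planted ground truth.

Emulates the data structure of a replicated transgenic-plant resequencing
study — four groups (three transgenic event series plus untransformed
controls) of nine plants each, three families by three sibling seeds — with
the four variation sources the reanalysis pipeline must separate:

* a background swap: one group carries a panel accession's genotypes at
  the expressed subset of panel positions, shared by all nine plants;
* standing heterogeneity: a dense positional cluster of homozygous
  variants confined to one group;
* sparse true de-novo mutations, homozygous and fully concordant within
  their group;
* abundant bioinformatic false positives, private to single samples, with
  the depth / quality / zygosity profile of unfiltered RNA-seq calls
  (depth mass at 1-2 reads, quality mass at Q <= 10, roughly half
  heterozygous).

Annotations (QUAL, FS, QD) for planted true variants are drawn from
pass-region distributions; false positives mix pass and fail annotations so
hard filters remove only part of them — replicate-consensus and uniqueness
filtering must do the rest.

Every draw flows from one numpy Generator seeded by ``SimConfig.seed``:
identical config and seed give byte-identical output.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from varprov.identity import SnpPanel
from varprov.model import (
    GenotypeCall,
    StudyDesign,
    VariantRecord,
    default_design,
    key_str,
    write_vcf,
)

VariantKey = tuple[str, int, str, str]

_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class SimConfig:
    """Study-generator parameters.

    Defaults are the emulated study conditions: a 4-group x 9-sample design;
    a 200-accession, 2000-position panel with per-position alternate-allele
    frequencies uniform on [0.05, 0.95]; a background-swapped first series
    expressing 600 panel positions; a 140-variant heterogeneity cluster over
    an 800 kb interval in the second series; three de-novo mutations per
    group; and 20 000 per-sample false positives with depth mass
    P(1)=0.43 / P(2)=0.20 (geometric tail above), Q<=10 mass 0.55, and
    heterozygous probability 0.5.
    """

    # design
    n_groups: int = 4
    families_per_group: int = 3
    siblings_per_family: int = 3
    # genome
    n_chromosomes: int = 20
    chrom_length: int = 50_000_000
    # panel
    panel_accessions: int = 200
    panel_positions: int = 2_000
    panel_af_low: float = 0.05
    panel_af_high: float = 0.95
    panel_missing_rate: float = 0.02
    # background swap
    swap_group: str | None = None  # default: first group
    swap_accession: str | None = None  # default: drawn from the panel
    n_expressed_panel_positions: int = 600
    # heterogeneity cluster
    het_group: str | None = None  # default: second group
    het_chrom: str = "Chr15"
    het_start: int = 1_400_000
    het_span: int = 800_000
    n_cluster_variants: int = 140
    # de-novo mutations
    de_novo_per_group: int = 3
    # false positives (per-sample independent, never shared among siblings)
    fp_per_sample: int = 20_000
    fp_het_prob: float = 0.5
    fp_depth1_prob: float = 0.43
    fp_depth2_prob: float = 0.20
    fp_depth_tail_p: float = 0.35  # geometric tail over depths >= 3
    fp_lowqual_prob: float = 0.55
    fp_indel_frac: float = 0.10
    fp_fail_fs_prob: float = 0.15
    fp_fail_qd_prob: float = 0.15
    # genotyping noise
    missing_rate: float = 0.002
    seed: int = 0

    def __post_init__(self) -> None:
        probs = (
            self.panel_missing_rate,
            self.fp_het_prob,
            self.fp_depth1_prob,
            self.fp_depth2_prob,
            self.fp_lowqual_prob,
            self.fp_indel_frac,
            self.fp_fail_fs_prob,
            self.fp_fail_qd_prob,
            self.missing_rate,
        )
        if any(not (0.0 <= p <= 1.0) for p in probs):
            raise ValueError("all probabilities must lie in [0, 1]")
        if self.fp_depth1_prob + self.fp_depth2_prob > 1.0:
            raise ValueError("fp_depth1_prob + fp_depth2_prob must be <= 1")
        if not (0.0 < self.fp_depth_tail_p <= 1.0):
            raise ValueError("fp_depth_tail_p must be in (0, 1]")
        if not (0.0 <= self.panel_af_low <= self.panel_af_high <= 1.0):
            raise ValueError("panel allele-frequency bounds must satisfy 0 <= low <= high <= 1")
        if self.n_groups < 2 or self.families_per_group < 1 or self.siblings_per_family < 1:
            raise ValueError("degenerate study design")
        if self.panel_accessions < 2:
            raise ValueError("panel needs at least 2 accessions")
        if self.n_expressed_panel_positions > self.panel_positions:
            raise ValueError("cannot express more panel positions than exist")
        if self.het_start + self.het_span > self.chrom_length:
            raise ValueError("heterogeneity interval exceeds chromosome length")
        if self.n_cluster_variants > self.het_span:
            raise ValueError("more cluster variants than interval positions")

    @property
    def chrom_names(self) -> list[str]:
        return [f"Chr{i:02d}" for i in range(1, self.n_chromosomes + 1)]

    @property
    def group_size(self) -> int:
        return self.families_per_group * self.siblings_per_family


@dataclass
class SimTruth:
    """Planted ground truth for one simulated study.

    The key sets are disjoint by construction (all planted positions are
    collision-free genome-wide).
    """

    accession: str
    swap_group: str
    background_keys: set[VariantKey]
    het_group: str
    cluster_chrom: str
    cluster_start: int
    cluster_end: int  # half-open
    cluster_keys: set[VariantKey]
    de_novo_keys: dict[str, set[VariantKey]]
    fp_keys: dict[str, set[VariantKey]] = field(default_factory=dict)

    def true_keys_for_group(self, group: str) -> set[VariantKey]:
        """All planted non-artifact keys whose unique-set home is `group`."""
        keys = set(self.de_novo_keys.get(group, set()))
        if group == self.swap_group:
            keys |= self.background_keys
        if group == self.het_group:
            keys |= self.cluster_keys
        return keys

    def all_planted_true(self) -> set[VariantKey]:
        out = set(self.background_keys) | set(self.cluster_keys)
        for s in self.de_novo_keys.values():
            out |= s
        return out

    def all_fp(self) -> set[VariantKey]:
        out: set[VariantKey] = set()
        for s in self.fp_keys.values():
            out |= s
        return out

    def to_json(self, path: str | Path) -> Path:
        payload = {
            "accession": self.accession,
            "swap_group": self.swap_group,
            "background_keys": sorted(map(key_str, self.background_keys)),
            "het_group": self.het_group,
            "cluster_chrom": self.cluster_chrom,
            "cluster_start": self.cluster_start,
            "cluster_end": self.cluster_end,
            "cluster_keys": sorted(map(key_str, self.cluster_keys)),
            "de_novo_keys": {g: sorted(map(key_str, s)) for g, s in self.de_novo_keys.items()},
            "fp_keys": {s: sorted(map(key_str, k)) for s, k in self.fp_keys.items()},
        }
        Path(path).write_text(json.dumps(payload, indent=1))
        return Path(path)


def _rng_of(seed_or_rng) -> np.random.Generator:
    if isinstance(seed_or_rng, np.random.Generator):
        return seed_or_rng
    return np.random.default_rng(seed_or_rng)


def _draw_alleles(rng: np.random.Generator, n: int) -> tuple[np.ndarray, np.ndarray]:
    """Random SNP ref/alt base pairs (distinct)."""
    ref_idx = rng.integers(0, 4, size=n)
    alt_idx = (ref_idx + rng.integers(1, 4, size=n)) % 4
    return _BASES[ref_idx], _BASES[alt_idx]


def generate_panel(config: SimConfig, seed_or_rng=None) -> SnpPanel:
    """Simulate an inbred-germplasm genotyping panel.

    Per position an alternate-allele frequency p ~ U(af_low, af_high) is
    drawn; each accession is homozygous alternate with probability p, else
    homozygous reference (inbred lines carry no residual heterozygosity at
    panel scale), with a small independent missing rate.  Deterministic
    given the seed.
    """
    rng = _rng_of(config.seed if seed_or_rng is None else seed_or_rng)
    n_pos, n_acc = config.panel_positions, config.panel_accessions
    codes = _draw_unique_codes(rng, n_pos, config, used=np.empty(0, dtype=np.int64))
    codes.sort()
    chrom_idx = codes // config.chrom_length
    pos = codes % config.chrom_length + 1
    refs, alts = _draw_alleles(rng, n_pos)
    freqs = rng.uniform(config.panel_af_low, config.panel_af_high, size=n_pos)
    geno = np.where(
        rng.random(size=(n_pos, n_acc)) < freqs[:, None],
        np.int8(GenotypeCall.HOM_ALT),
        np.int8(GenotypeCall.HOM_REF),
    ).astype(np.int8)
    geno[rng.random(size=(n_pos, n_acc)) < config.panel_missing_rate] = np.int8(
        GenotypeCall.MISSING
    )
    names = config.chrom_names
    positions = [
        (names[int(c)], int(p), str(r), str(a))
        for c, p, r, a in zip(chrom_idx, pos, refs, alts)
    ]
    accessions = [f"acc_{i:04d}" for i in range(n_acc)]
    return SnpPanel(positions=positions, accessions=accessions, genotypes=geno)


def expected_panel_identity(config: SimConfig) -> float:
    """Closed-form expected pairwise accession identity under the panel model.

    Two independent accessions match at a position with probability
    p^2 + (1-p)^2; averaging over p ~ U(a, b) gives
    1 - 2 E[p] + 2 E[p^2] with E[p] = (a+b)/2 and
    E[p^2] = (a^2 + ab + b^2)/3.
    """
    a, b = config.panel_af_low, config.panel_af_high
    e_p = (a + b) / 2.0
    e_p2 = (a * a + a * b + b * b) / 3.0
    return 1.0 - 2.0 * e_p + 2.0 * e_p2


def _draw_unique_codes(
    rng: np.random.Generator, n: int, config: SimConfig, used: np.ndarray
) -> np.ndarray:
    """Draw n distinct genome positions (linear codes) avoiding `used`."""
    space = config.n_chromosomes * config.chrom_length
    if n > space - used.size:
        raise ValueError("not enough genome positions available")
    acc = np.empty(0, dtype=np.int64)
    while acc.size < n:
        need = n - acc.size
        c = rng.integers(0, config.n_chromosomes, size=need + 64, dtype=np.int64)
        p = rng.integers(0, config.chrom_length, size=need + 64, dtype=np.int64)
        draw = c * config.chrom_length + p
        acc = np.unique(np.concatenate([acc, draw]))
        if used.size:
            acc = acc[~np.isin(acc, used)]
    return rng.permutation(acc)[:n]


def _fp_depths(rng: np.random.Generator, n: int, config: SimConfig) -> np.ndarray:
    """Depths 1 / 2 / geometric tail >= 3 with the configured masses."""
    u = rng.random(size=n)
    tail = 2 + rng.geometric(config.fp_depth_tail_p, size=n)  # support >= 3
    depths = np.where(
        u < config.fp_depth1_prob,
        1,
        np.where(u < config.fp_depth1_prob + config.fp_depth2_prob, 2, tail),
    )
    return depths.astype(np.int32)


def _fp_quals(rng: np.random.Generator, n: int, config: SimConfig) -> np.ndarray:
    low = rng.random(size=n) < config.fp_lowqual_prob
    quals = np.where(
        low, rng.uniform(0.05, 10.0, size=n), rng.uniform(11.0, 100.0, size=n)
    )
    return np.round(quals, 1)


def simulate_study(
    config: SimConfig = SimConfig(),
) -> tuple[list[VariantRecord], StudyDesign, SnpPanel, SimTruth]:
    """Generate one complete simulated study.

    Returns records sorted by (chrom, pos), the study design, the panel and
    the planted truth.  All planted positions (panel, cluster, de-novo,
    false positive) are distinct genome-wide, so the truth key sets are
    disjoint by construction.
    """
    rng = np.random.default_rng(config.seed)
    design = default_design(
        config.n_groups, config.families_per_group, config.siblings_per_family
    )
    samples = design.samples
    n_samples = len(samples)
    names = config.chrom_names
    name_to_idx = {c: i for i, c in enumerate(names)}
    if config.het_chrom not in name_to_idx:
        raise ValueError(f"het_chrom {config.het_chrom!r} not in simulated genome")
    sample_col = {s: i for i, s in enumerate(samples)}
    group_cols = {
        g: np.array([sample_col[s] for s in design.samples_in_group(g)], dtype=np.intp)
        for g in design.groups
    }

    panel = generate_panel(config, rng)
    panel_codes = np.array(
        [name_to_idx[c] * config.chrom_length + (p - 1) for c, p, _r, _a in panel.positions],
        dtype=np.int64,
    )

    # --- background swap -------------------------------------------------
    swap_group = config.swap_group or design.groups[0]
    if config.swap_accession is not None:
        acc_idx = panel.accessions.index(config.swap_accession)
    else:
        acc_idx = int(rng.integers(0, config.panel_accessions))
    accession = panel.accessions[acc_idx]
    expressed = np.sort(
        rng.choice(config.panel_positions, size=config.n_expressed_panel_positions, replace=False)
    )
    bg_rows = expressed[
        panel.genotypes[expressed, acc_idx] == np.int8(GenotypeCall.HOM_ALT)
    ]
    bg_keys = [panel.positions[int(r)] for r in bg_rows]

    used = np.sort(panel_codes)

    # --- heterogeneity cluster -------------------------------------------
    het_group = config.het_group or design.groups[min(1, len(design.groups) - 1)]
    het_chrom_idx = name_to_idx[config.het_chrom]
    interval_codes = np.empty(0, dtype=np.int64)
    while interval_codes.size < config.n_cluster_variants:
        need = config.n_cluster_variants - interval_codes.size
        offs = rng.choice(config.het_span, size=need + 16, replace=False)
        draw = het_chrom_idx * config.chrom_length + (config.het_start - 1) + offs
        draw = draw[~np.isin(draw, used)]
        interval_codes = np.unique(np.concatenate([interval_codes, draw]))
    cluster_codes = np.sort(rng.permutation(interval_codes)[: config.n_cluster_variants])
    used = np.sort(np.concatenate([used, cluster_codes]))

    # --- de-novo mutations ------------------------------------------------
    n_dn_total = config.de_novo_per_group * config.n_groups
    dn_codes = _draw_unique_codes(rng, n_dn_total, config, used)
    used = np.sort(np.concatenate([used, dn_codes]))

    # --- false positives --------------------------------------------------
    n_fp = config.fp_per_sample * n_samples
    fp_codes = _draw_unique_codes(rng, n_fp, config, used)
    fp_sample_idx = np.repeat(np.arange(n_samples, dtype=np.intp), config.fp_per_sample)

    # --- assemble per-record arrays ---------------------------------------
    def decode(codes: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        return codes // config.chrom_length, codes % config.chrom_length + 1

    blocks: list[dict] = []

    # planted true variants (background, cluster, de-novo): pass-region
    # annotations, homozygous-alternate in the carrier group only
    cl_chrom, cl_pos = decode(cluster_codes)
    cl_ref, cl_alt = _draw_alleles(rng, cluster_codes.size)
    dn_chrom, dn_pos = decode(dn_codes)
    dn_ref, dn_alt = _draw_alleles(rng, dn_codes.size)
    dn_groups = np.repeat(np.arange(config.n_groups), config.de_novo_per_group)

    true_chrom = np.concatenate(
        [
            np.array([name_to_idx[k[0]] for k in bg_keys], dtype=np.int64),
            cl_chrom,
            dn_chrom,
        ]
    )
    true_pos = np.concatenate(
        [np.array([k[1] for k in bg_keys], dtype=np.int64), cl_pos, dn_pos]
    )
    true_ref = np.concatenate(
        [np.array([k[2] for k in bg_keys], dtype=object), cl_ref.astype(object), dn_ref.astype(object)]
    )
    true_alt = np.concatenate(
        [np.array([k[3] for k in bg_keys], dtype=object), cl_alt.astype(object), dn_alt.astype(object)]
    )
    n_true = true_pos.size
    true_carrier_group = np.concatenate(
        [
            np.full(len(bg_keys), design.groups.index(swap_group)),
            np.full(cluster_codes.size, design.groups.index(het_group)),
            dn_groups,
        ]
    )
    true_qual = np.round(rng.uniform(200.0, 2000.0, size=n_true), 1)
    true_fs = np.round(rng.uniform(0.0, 5.0, size=n_true), 2)
    true_qd = np.round(rng.uniform(15.0, 35.0, size=n_true), 2)

    # false positives: one carrier sample each, mixed pass/fail annotations
    fp_chrom, fp_pos = decode(fp_codes)
    fp_is_indel = rng.random(size=n_fp) < config.fp_indel_frac
    fp_ref, fp_alt = _draw_alleles(rng, n_fp)
    fp_ref = fp_ref.astype(object)
    fp_alt = fp_alt.astype(object)
    if fp_is_indel.any():
        idx = np.flatnonzero(fp_is_indel)
        ins = rng.random(size=idx.size) < 0.5
        length = rng.integers(1, 3, size=idx.size)  # 1 or 2 bp
        extra1 = _BASES[rng.integers(0, 4, size=idx.size)]
        extra2 = _BASES[rng.integers(0, 4, size=idx.size)]
        for j, i in enumerate(idx):
            tail = extra1[j] + (extra2[j] if length[j] == 2 else "")
            if ins[j]:
                fp_alt[i] = fp_ref[i] + tail
            else:
                fp_ref[i], fp_alt[i] = fp_ref[i] + tail, fp_ref[i]
    fp_is_het = rng.random(size=n_fp) < config.fp_het_prob
    fp_depth = _fp_depths(rng, n_fp, config)
    fp_qual = _fp_quals(rng, n_fp, config)
    fail_fs = rng.random(size=n_fp) < config.fp_fail_fs_prob
    fp_fs = np.where(
        fail_fs & ~fp_is_indel,
        rng.uniform(30.5, 60.0, size=n_fp),
        rng.uniform(0.0, 10.0, size=n_fp),
    )
    fp_fs = np.where(fail_fs & fp_is_indel, rng.uniform(200.5, 300.0, size=n_fp), fp_fs)
    fp_fs = np.round(fp_fs, 2)
    fail_qd = rng.random(size=n_fp) < config.fp_fail_qd_prob
    fp_qd = np.round(
        np.where(fail_qd, rng.uniform(0.0, 1.89, size=n_fp), rng.uniform(2.5, 30.0, size=n_fp)),
        2,
    )

    # --- stack, sort, and materialise records ------------------------------
    all_chrom = np.concatenate([true_chrom, fp_chrom])
    all_pos = np.concatenate([true_pos, fp_pos])
    all_ref = np.concatenate([true_ref, fp_ref])
    all_alt = np.concatenate([true_alt, fp_alt])
    all_qual = np.concatenate([true_qual, fp_qual])
    all_fs = np.concatenate([true_fs, fp_fs])
    all_qd = np.concatenate([true_qd, fp_qd])
    n_total = all_pos.size

    calls = np.zeros((n_total, n_samples), dtype=np.int8)
    for gi, g in enumerate(design.groups):
        rows = np.flatnonzero(true_carrier_group == gi)
        if rows.size:
            calls[np.ix_(rows, group_cols[g])] = np.int8(GenotypeCall.HOM_ALT)
    fp_rows = np.arange(n_true, n_total)
    calls[fp_rows, fp_sample_idx] = np.where(
        fp_is_het, np.int8(GenotypeCall.HET), np.int8(GenotypeCall.HOM_ALT)
    )

    depths = rng.integers(5, 61, size=(n_total, n_samples), dtype=np.int32)
    depths[fp_rows, fp_sample_idx] = fp_depth

    if config.missing_rate > 0:
        miss = rng.random(size=(n_total, n_samples), dtype=np.float32) < config.missing_rate
        calls[miss] = np.int8(GenotypeCall.MISSING)

    order = np.lexsort((all_pos, all_chrom))
    chrom_l = all_chrom[order].tolist()
    pos_l = all_pos[order].tolist()
    ref_l = all_ref[order].tolist()
    alt_l = all_alt[order].tolist()
    qual_l = np.asarray(all_qual)[order].tolist()
    fs_l = np.asarray(all_fs)[order].tolist()
    qd_l = np.asarray(all_qd)[order].tolist()
    calls = calls[order]
    depths = depths[order]

    records = [
        VariantRecord(
            chrom=names[chrom_l[i]],
            pos=pos_l[i],
            ref=str(ref_l[i]),
            alt=str(alt_l[i]),
            qual=qual_l[i],
            fs=fs_l[i],
            qd=qd_l[i],
            calls=calls[i],
            depths=depths[i],
        )
        for i in range(n_total)
    ]

    # --- truth bookkeeping --------------------------------------------------
    def keys_of(chrom_arr, pos_arr, ref_arr, alt_arr) -> list[VariantKey]:
        return [
            (names[int(c)], int(p), str(r), str(a))
            for c, p, r, a in zip(chrom_arr, pos_arr, ref_arr, alt_arr)
        ]

    cluster_keys = set(keys_of(cl_chrom, cl_pos, cl_ref, cl_alt))
    dn_keys_all = keys_of(dn_chrom, dn_pos, dn_ref, dn_alt)
    de_novo_keys: dict[str, set[VariantKey]] = {g: set() for g in design.groups}
    for k, gi in zip(dn_keys_all, dn_groups):
        de_novo_keys[design.groups[int(gi)]].add(k)
    fp_all_keys = keys_of(fp_chrom, fp_pos, fp_ref, fp_alt)
    fp_keys: dict[str, set[VariantKey]] = {s: set() for s in samples}
    for k, si in zip(fp_all_keys, fp_sample_idx):
        fp_keys[samples[int(si)]].add(k)

    truth = SimTruth(
        accession=accession,
        swap_group=swap_group,
        background_keys=set(bg_keys),
        het_group=het_group,
        cluster_chrom=config.het_chrom,
        cluster_start=config.het_start,
        cluster_end=config.het_start + config.het_span,
        cluster_keys=cluster_keys,
        de_novo_keys=de_novo_keys,
        fp_keys=fp_keys,
    )
    return records, design, panel, truth


def write_study(
    out_dir: str | Path, config: SimConfig = SimConfig()
) -> dict[str, Path]:
    """Simulate a study and write VCF + design TSV + panel TSV + truth JSON."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    records, design, panel, truth = simulate_study(config)
    paths = {
        "vcf": write_vcf(records, design.samples, out / "study.vcf",
                         contig_length=config.chrom_length),
        "design": design.to_tsv(out / "design.tsv"),
        "panel": panel.to_tsv(out / "panel.tsv"),
        "truth": truth.to_json(out / "truth.json"),
    }
    return paths
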