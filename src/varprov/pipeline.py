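"""End-to-end orchestration: filters -> unique sets -> identity -> scan -> QC.

Mirrors the order of the reanalysis: hard-filter the calls, find
group-unique homozygous variants, fingerprint the most variant-rich group
against the panel, scan each group's unique set for positional clusters,
and summarise the depth/quality/zygosity/concordance diagnostics.  Each
stage logs its input/output record counts and writes TSV/JSON artifacts
under the output directory.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field as dc_field
from pathlib import Path

import numpy as np

from varprov import clusters as cl
from varprov import filters as flt
from varprov import identity as ident
from varprov import qc
from varprov import unique as uq
from varprov.model import (
    GenotypeCall,
    StudyDesign,
    build_matrix,
    key_str,
    read_vcf,
)

logger = logging.getLogger("varprov")


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name and cause."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunConfig:
    vcf: Path
    design: Path
    panel: Path | None = None
    known_regions: Path | None = None
    out_dir: Path = Path("varprov_out")
    filter_config: flt.FilterConfig = dc_field(default_factory=flt.FilterConfig)
    uniqueness_config: uq.UniquenessConfig = dc_field(default_factory=uq.UniquenessConfig)
    scan_config: cl.ScanConfig = dc_field(default_factory=cl.ScanConfig)
    generations_selfed: dict[str, int] = dc_field(default_factory=dict)
    identity_group: str | None = None  # default: group with most unique variants
    seed: int = 0


def run_pipeline(config: RunConfig) -> dict:
    """Run the full reanalysis; returns the summary report dict.

    The identity stage is skipped when no panel is given; the overlap
    annotation is skipped when no known-regions BED is given.  Reruns on
    identical inputs produce identical reports (no stage draws entropy
    outside the seed).
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"stages": {}}

    def stage(name: str):
        def wrap(fn):
            try:
                return fn()
            except Exception as exc:
                raise StageError(name, exc) from exc
        return wrap

    @stage("read_inputs")
    def _inputs():
        records, samples = read_vcf(config.vcf)
        design = StudyDesign.from_tsv(config.design)
        logger.info("read %d records, %d samples", len(records), len(samples))
        return records, samples, design

    records, samples, design = _inputs

    @stage("site_filters")
    def _filtered():
        flt.apply_hard_filters(records, config.filter_config)
        flt.filter_summary(records, out / "filter_summary.tsv")
        passed = flt.pass_records(records)
        logger.info("hard filters: %d of %d records PASS", len(passed), len(records))
        return passed

    passed = _filtered
    report["stages"]["site_filters"] = {"n_input": len(records), "n_pass": len(passed)}

    @stage("unique_variants")
    def _unique():
        matrix = build_matrix(passed, design, samples=samples)
        sets = uq.unique_homozygous_sets(matrix, design, config.uniqueness_config)
        uq.unique_sets_table(sets, out / "unique_variants.tsv")
        counts = uq.count_table(sets)
        counts.to_csv(out / "unique_counts.tsv", sep="\t", header=True)
        logger.info("unique variants per group: %s", counts.to_dict())
        return sets, counts

    unique_sets, counts = _unique
    report["stages"]["unique_variants"] = {"per_group": counts.to_dict(), "total": int(counts.sum())}

    @stage("accession_identity")
    def _identity():
        if config.panel is None:
            logger.info("no panel given; identity stage skipped")
            return None
        panel = (
            ident.SnpPanel.from_vcf(config.panel)
            if str(config.panel).endswith((".vcf", ".vcf.gz"))
            else ident.SnpPanel.from_tsv(config.panel)
        )
        group = config.identity_group or max(
            unique_sets.sets, key=lambda g: len(unique_sets.sets[g])
        )
        query = [(k, int(GenotypeCall.HOM_ALT)) for k in sorted(unique_sets.sets[group])]
        profile = ident.intersect_panel(query, panel)
        if len(profile) == 0:
            logger.info("group %s shares no positions with the panel", group)
            return {"group": group, "n_panel_overlap": 0, "best_match": None}
        results = ident.identity_scores(profile, panel)
        ident.ranked_table(results, out / "identity_ranked.tsv")
        best = ident.best_match_report(results, out / "identity_best_match.json")
        logger.info(
            "identity: group %s vs %d accessions -> best %s at %.1f%%",
            group, len(panel.accessions), best["accession"], best["pct_identity"],
        )
        return {"group": group, "n_panel_overlap": len(profile), "best_match": best}

    report["stages"]["accession_identity"] = _identity

    @stage("heterogeneity_scan")
    def _scan():
        known = cl.read_bed(config.known_regions) if config.known_regions else []
        per_group = {}
        all_clusters = []
        for g in design.groups:
            found, dispersed = cl.detect_clusters(sorted(unique_sets.sets[g]), config.scan_config)
            overlaps = cl.annotate_overlap(found, known) if known else None
            cl.clusters_table(found, overlaps, out / f"clusters_{g}.tsv")
            cl.dispersed_table(dispersed, out / f"dispersed_{g}.tsv")
            per_group[g] = {
                "clusters": [
                    {
                        "chrom": c.chrom,
                        "start": c.start,
                        "end": c.end,
                        "n_variants": c.count,
                        "overlaps_known_region": (overlaps[i] if overlaps else None),
                    }
                    for i, c in enumerate(found)
                ],
                "n_dispersed": len(dispersed),
            }
            all_clusters.extend(found)
        logger.info("heterogeneity scan: %d cluster(s) across groups", len(all_clusters))
        return per_group

    report["stages"]["heterogeneity_scan"] = _scan

    @stage("qc_metrics")
    def _qc():
        hist = qc.depth_histogram(records)
        hist.to_frame(out / "depth_histogram.tsv")
        lowq = qc.low_quality_fraction(records, config.filter_config.min_qual)
        qc.qual_histogram(records).to_csv(out / "qual_histogram.tsv", sep="\t", index=False)
        sample_pos = {s: i for i, s in enumerate(samples)}
        zyg = {}
        for g in design.groups:
            cols = [sample_pos[s] for s in design.samples_in_group(g)]
            het, hom = qc.zygosity_fractions(records, cols)
            entry = {"het_fraction": het, "hom_alt_fraction": hom}
            if g in config.generations_selfed:
                entry["expected_het_pct"] = qc.expected_het_fraction(
                    config.generations_selfed[g]
                )
                entry["observed_het_pct"] = 100.0 * het
            zyg[g] = entry
        # per-sample variant-key sets for sibling concordance, per family
        per_sample_keys: dict[str, set] = {s: set() for s in samples}
        if records:
            keys_list = [r.key for r in records]
            calls_mat = np.vstack([r.calls for r in records])
            carrier = (calls_mat == int(GenotypeCall.HET)) | (
                calls_mat == int(GenotypeCall.HOM_ALT)
            )
            rows, cols = np.nonzero(carrier)
            for ri, ci in zip(rows.tolist(), cols.tolist()):
                per_sample_keys[samples[ci]].add(keys_list[ri])
        venn = {}
        for (g, fam), members in design.families().items():
            if len(members) < 2:
                continue
            vc = qc.sibling_overlap({s: per_sample_keys[s] for s in members})
            vc.to_frame(out / f"venn_{g}_{fam}.tsv")
            venn[f"{g}/{fam}"] = {
                "union": vc.union_size,
                "all_shared": vc.all_shared,
            }
        indels = qc.indel_class_table(records)
        indels.to_frame(out / "indel_classes.tsv")
        logger.info(
            "qc: depth-1 fraction %.3f, low-quality fraction %.3f",
            hist.fraction_at_depth(1), lowq,
        )
        return {
            "depth1_fraction": hist.fraction_at_depth(1),
            "depth2_fraction": hist.fraction_at_depth(2),
            "depth_calls_total": hist.total,
            "low_quality_fraction": lowq,
            "zygosity_by_group": zyg,
            "sibling_overlap": venn,
            "indel_total": indels.total,
            "indel_all_short": indels.all_short,
        }

    report["stages"]["qc_metrics"] = _qc

    (out / "report.json").write_text(json.dumps(report, indent=2, default=str))
    return report
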