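"""Panel fingerprinting: intersection, identity scoring, mismatch clustering."""

import numpy as np
import pytest

from varprov.identity import (
    SnpPanel,
    identity_scores,
    intersect_panel,
    mismatch_intervals,
)
from varprov.model import GenotypeCall
from varprov.simulate import SimConfig, expected_panel_identity, generate_panel, simulate_study

R, A, H, M = (
    int(GenotypeCall.HOM_REF),
    int(GenotypeCall.HOM_ALT),
    int(GenotypeCall.HET),
    int(GenotypeCall.MISSING),
)


def make_panel(genotype_columns, positions=None):
    """Panel from {accession: genotype vector}; default positions on Chr01."""
    accessions = list(genotype_columns)
    n = len(next(iter(genotype_columns.values())))
    if positions is None:
        positions = [("Chr01", 1000 * (i + 1), "A", "G") for i in range(n)]
    geno = np.array([genotype_columns[a] for a in accessions], dtype=np.int8).T
    return SnpPanel(positions=positions, accessions=accessions, genotypes=geno)


def hom_alt_query(panel, rows):
    return [(panel.positions[r], A) for r in rows]


class TestPanelIO:
    def test_tsv_round_trip_preserves_missing_cells(self, tmp_path):
        panel = make_panel({"accA": [R, A, M, A], "accB": [M, M, R, A]})
        path = panel.to_tsv(tmp_path / "panel.tsv")
        back = SnpPanel.from_tsv(path)
        assert back.positions == panel.positions
        assert back.accessions == panel.accessions
        assert np.array_equal(back.genotypes, panel.genotypes)

    def test_unrecognised_genotype_code_rejected(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("chrom\tpos\tref\talt\tacc1\nChr01\t100\tA\tG\t7\n")
        with pytest.raises(ValueError, match="unrecognised"):
            SnpPanel.from_tsv(path)

    def test_vcf_panel_ingestion(self, tmp_path):
        from varprov.model import VariantRecord, write_vcf

        recs = [VariantRecord(chrom="Chr01", pos=100, ref="A", alt="G",
                              calls=np.array([R, A, M], dtype=np.int8),
                              depths=np.full(3, 10, dtype=np.int32))]
        path = write_vcf(recs, ["acc1", "acc2", "acc3"], tmp_path / "p.vcf")
        panel = SnpPanel.from_vcf(path)
        assert panel.accessions == ["acc1", "acc2", "acc3"]
        assert panel.positions == [("Chr01", 100, "A", "G")]
        assert list(panel.genotypes[0]) == [R, A, M]


class TestIntersectPanel:
    def test_disjoint_query_gives_empty_profile(self):
        panel = make_panel({"x": [R, A, R]})
        profile = intersect_panel([(("Chr09", 5, "A", "G"), A)], panel)
        assert len(profile) == 0

    def test_intersection_size(self):
        cfg = SimConfig(seed=3, panel_positions=1000, panel_accessions=10)
        panel = generate_panel(cfg)
        rows = np.random.default_rng(0).choice(1000, size=120, replace=False)
        profile = intersect_panel(hom_alt_query(panel, rows), panel)
        # set-intersection oracle
        shared = {(panel.positions[r][0], panel.positions[r][1]) for r in rows} & {
            (c, p) for c, p, _r, _a in panel.positions
        }
        assert len(profile) == len(shared) == 120

    def test_swapped_alleles_remapped(self):
        panel = make_panel({"x": [A]}, positions=[("Chr01", 100, "G", "A")])
        profile = intersect_panel([(("Chr01", 100, "A", "G"), A)], panel)
        assert list(profile.calls) == [R]  # query HOM_ALT flips onto panel orientation

    def test_discordant_alleles_dropped_with_warning(self):
        panel = make_panel({"x": [A]}, positions=[("Chr01", 100, "A", "T")])
        with pytest.warns(UserWarning, match="allele mismatch"):
            profile = intersect_panel([(("Chr01", 100, "A", "G"), A)], panel)
        assert len(profile) == 0


class TestIdentityScores:
    def test_self_accession_scores_100_and_ranks_first(self):
        rng = np.random.default_rng(1)
        geno = {f"acc{i}": rng.choice([R, A], size=50) for i in range(5)}
        panel = make_panel(geno)
        profile = intersect_panel(
            [(panel.positions[i], int(geno["acc3"][i])) for i in range(50)], panel
        )
        results = identity_scores(profile, panel)
        assert results[0].accession == "acc3"
        assert results[0].pct_identity == 100.0

    def test_fully_discordant_accession_scores_zero(self):
        panel = make_panel({"x": [R] * 10})
        profile = intersect_panel(hom_alt_query(panel, range(10)), panel)
        (res,) = identity_scores(profile, panel)
        assert res.pct_identity == 0.0 and res.n_compared == 10

    def test_missing_on_either_side_excluded_from_denominator(self):
        panel = make_panel({"x": [A, M, A, R]})
        query = [
            (panel.positions[0], A),
            (panel.positions[1], A),  # panel missing
            (panel.positions[2], M),  # query missing
            (panel.positions[3], A),
        ]
        (res,) = identity_scores(intersect_panel(query, panel), panel)
        assert (res.n_compared, res.n_match) == (2, 1)

    def test_het_vs_hom_is_a_mismatch(self):
        panel = make_panel({"x": [H]})
        (res,) = identity_scores(intersect_panel(hom_alt_query(panel, [0]), panel), panel)
        assert res.n_match == 0

    def test_empty_profile_is_an_error(self):
        panel = make_panel({"x": [R]})
        profile = intersect_panel([], panel)
        with pytest.raises(ValueError, match="empty profile"):
            identity_scores(profile, panel)

    def test_ties_broken_by_accession_id(self):
        panel = make_panel({"b": [A, A], "a": [A, A], "c": [R, R]})
        results = identity_scores(intersect_panel(hom_alt_query(panel, [0, 1]), panel), panel)
        assert [r.accession for r in results] == ["a", "b", "c"]

    def test_identity_invariant_under_position_reordering(self):
        rng = np.random.default_rng(2)
        geno = {f"acc{i}": rng.choice([R, A, M], size=40) for i in range(4)}
        panel = make_panel(geno)
        query = hom_alt_query(panel, range(40))
        base = identity_scores(intersect_panel(query, panel), panel)
        rng.shuffle(query)
        shuffled = identity_scores(intersect_panel(query, panel), panel)
        assert [(r.accession, r.pct_identity) for r in base] == [
            (r.accession, r.pct_identity) for r in shuffled
        ]


class TestMismatchIntervals:
    def test_no_mismatches_no_intervals(self):
        panel = make_panel({"x": [A] * 3})
        (res,) = identity_scores(intersect_panel(hom_alt_query(panel, range(3)), panel), panel)
        assert mismatch_intervals(res) == []

    def test_four_clustered_mismatches_merge_into_one_interval(self):
        # near-perfect match with residual mismatches confined to ~1 Mb on one
        # chromosome: the standing-heterogeneity signature
        positions = [("Chr15", int(4_900_000 + i * 330_000), "A", "G") for i in range(4)]
        positions += [("Chr02", 1_000 * (i + 1), "A", "G") for i in range(40)]
        geno = [R] * 4 + [A] * 40
        panel = make_panel({"x": geno}, positions=positions)
        (res,) = identity_scores(intersect_panel(hom_alt_query(panel, range(44)), panel), panel)
        intervals = mismatch_intervals(res, max_gap=1_000_000)
        assert len(intervals) == 1
        iv = intervals[0]
        assert iv.chrom == "Chr15" and iv.count == 4
        assert iv.start == 4_900_000 and iv.end == 4_900_000 + 3 * 330_000 + 1
        assert "heterogeneity" in iv.note

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force_gap_merge(self, seed):
        rng = np.random.default_rng(seed)
        n = 60
        mismatches = sorted(
            {("Chr%02d" % rng.integers(1, 4), int(rng.integers(1, 3_000_000))) for _ in range(n)}
        )
        from varprov.identity import IdentityResult

        res = IdentityResult(accession="x", n_compared=n, n_match=0,
                             mismatch_positions=list(mismatches))
        max_gap = 100_000
        got = mismatch_intervals(res, max_gap=max_gap)
        # oracle: naive per-chromosome scan
        expected = []
        for chrom in sorted({c for c, _ in mismatches}):
            pos = sorted(p for c, p in mismatches if c == chrom)
            runs = [[pos[0]]]
            for p in pos[1:]:
                (runs[-1].append(p) if p - runs[-1][-1] <= max_gap else runs.append([p]))
            expected.extend((chrom, r[0], r[-1] + 1, len(r)) for r in runs)
        assert [(iv.chrom, iv.start, iv.end, iv.count) for iv in got] == expected


class TestParameterRecovery:
    def test_planted_accession_recovered_across_seeds(self):
        """On 20 small studies with independent panel accessions, the planted
        background accession ranks first with a >= 10-point margin."""
        for seed in range(20, 40):
            cfg = SimConfig(
                seed=seed, fp_per_sample=60, panel_positions=300, panel_accessions=20,
                n_expressed_panel_positions=120, n_cluster_variants=20,
            )
            records, design, panel, truth = simulate_study(cfg)
            query = [(k, A) for k in sorted(truth.background_keys)]
            results = identity_scores(intersect_panel(query, panel), panel)
            assert results[0].accession == truth.accession
            assert results[0].pct_identity - results[1].pct_identity >= 10.0

    def test_panel_pairwise_identity_matches_closed_form(self):
        cfg = SimConfig(seed=123, panel_positions=2000, panel_accessions=40,
                        panel_missing_rate=0.0)
        panel = generate_panel(cfg)
        rng = np.random.default_rng(0)
        pairs = rng.choice(40, size=(200, 2))
        pairs = pairs[pairs[:, 0] != pairs[:, 1]]
        obs = np.mean(
            [np.mean(panel.genotypes[:, i] == panel.genotypes[:, j]) for i, j in pairs]
        )
        assert abs(obs - expected_panel_identity(cfg)) < 0.02

    def test_single_accession_panel_rejected(self):
        with pytest.raises(ValueError, match="2 accessions"):
            SimConfig(seed=0, panel_accessions=1)
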