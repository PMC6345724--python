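"""SNP context extraction, ddGs annotation and cohort statistics."""

import itertools
import math

import numpy as np
import pytest
from scipy import integrate, stats

from tristack import (
    annotate_snp,
    build_difference_matrix,
    build_trimer_matrix,
    compare_bin_series,
    extract_context,
    hypergeometric_enrichment,
    matrix_background,
    read_snp_table,
    summarize_cohort,
)
from tristack._util import revcomp
from tristack.snp import SnpAnnotation, SnpRecord, write_annotations


@pytest.fixture
def meis1_reference(tmp_path):
    """The MEIS1 binding-site sequence with the A->G SNP at position 4."""
    path = tmp_path / "ref.fa"
    path.write_text(">chr1\nACTATCGA\n")
    return path


class TestExtractContext:
    def test_meis1_site(self, meis1_reference):
        rec = extract_context("chr1", 4, "A", "G", meis1_reference)
        assert (rec.context, rec.ref, rec.alt) == ("TAT", "A", "G")

    @pytest.mark.parametrize("pos", [1, 8])
    def test_contig_edges_skipped_with_warning(self, meis1_reference, pos):
        with pytest.warns(UserWarning, match="skipped"):
            base = "A" if pos == 1 else "A"
            assert extract_context("chr1", pos, base, "G", meis1_reference) is None

    def test_ref_mismatch_reports_both_bases(self, meis1_reference):
        with pytest.raises(ValueError, match="reference has A but record says C"):
            extract_context("chr1", 4, "C", "G", meis1_reference)

    def test_ambiguous_context_skipped(self, tmp_path):
        path = tmp_path / "ref.fa"
        path.write_text(">c\nANTAT\n")
        with pytest.warns(UserWarning, match="ambiguous"):
            assert extract_context("c", 3, "T", "C", path) is None


class TestSnpRecordValidation:
    def test_central_base_must_match_ref(self):
        with pytest.raises(ValueError, match="central base"):
            SnpRecord("x", "TAT", "G", "C")

    def test_ref_equal_alt_rejected(self):
        with pytest.raises(ValueError, match="identical"):
            SnpRecord("x", "TAT", "A", "A")


class TestAnnotateSnp:
    def test_meis1_snp_enhances_stacking(self, diff_matrix):
        ann = annotate_snp(SnpRecord("rs", "TAT", "A", "G"), diff_matrix)
        # dG(TGT) - dG(TAT) = -2.36 - (-1.53)
        assert ann.ddg == pytest.approx(-0.83)
        assert ann.enhanced and ann.abs_bin == "high"
        assert ann.mutation_type == "A>G"

    def test_extreme_substitution(self, diff_matrix):
        ann = annotate_snp(SnpRecord("rs", "CTA", "T", "G"), diff_matrix)
        assert ann.ddg == pytest.approx(-1.09)
        assert ann.enhanced

    def test_strand_flip_invariance_all_substitutions(self, diff_matrix):
        for (ctx, alt), v in diff_matrix.substitutions().items():
            flipped = diff_matrix[(revcomp(ctx), revcomp(alt))]
            assert flipped == pytest.approx(v)


class TestCohortSummary:
    def _ann(self, ddg, in_tfbs=None, ctx="TAT", ref="A", alt="G"):
        rec = SnpRecord("x", ctx, ref, alt, in_tfbs=in_tfbs)
        from tristack.snp import abs_bin

        return SnpAnnotation(rec, ddg, abs_bin(ddg), f"{ref}>{alt}", ddg < 0)

    def test_bin_fractions(self):
        anns = [self._ann(d) for d in (0.1, -0.4, 0.7, -0.9)]
        summary = summarize_cohort(anns)
        assert summary.bin_fractions == pytest.approx((25.0, 25.0, 50.0))
        assert summary.enhanced_fraction == pytest.approx(50.0)

    def test_single_type_cohort(self):
        summary = summarize_cohort([self._ann(-0.4), self._ann(-0.6)])
        percents = {t: p for t, (p, _) in summary.per_type.items()}
        assert percents["A>G"] == pytest.approx(100.0)
        assert sum(percents.values()) == pytest.approx(100.0)
        assert summary.per_type["A>G"][1] == pytest.approx(0.5)

    def test_empty_cohort_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            summarize_cohort([self._ann(0.1)], subset_filter=lambda a: False)

    def test_uniform_matrix_draws_match_background(self, diff_matrix):
        # Monte-Carlo: cohort drawn uniformly over the 192 substitutions
        rng = np.random.default_rng(11)
        subs = sorted(diff_matrix.substitutions())
        picks = rng.integers(len(subs), size=4000)
        anns = [
            annotate_snp(
                SnpRecord(f"s{i}", subs[j][0], subs[j][0][1], subs[j][1]),
                diff_matrix,
            )
            for i, j in enumerate(picks)
        ]
        got = summarize_cohort(anns).bin_fractions
        expected = matrix_background(diff_matrix)
        for g, e in zip(got, expected):
            sd = math.sqrt(e / 100 * (1 - e / 100) / 4000) * 100
            assert abs(g - e) < 4 * sd


class TestMatrixBackground:
    def test_fractions_sum_and_high_bin(self, diff_matrix):
        low, mid, high = matrix_background(diff_matrix)
        assert low + mid + high == pytest.approx(100.0)
        # brute-force re-derivation from the 192 entries
        vals = [abs(v) for v in diff_matrix.substitutions().values()]
        assert high == pytest.approx(100 * sum(v >= 0.6 for v in vals) / 192)
        assert high == pytest.approx(31.25)

    def test_constant_table_collapses_to_low_bin(self, constant_table):
        dm = build_difference_matrix(build_trimer_matrix(constant_table))
        assert matrix_background(dm) == pytest.approx((100.0, 0.0, 0.0))


class TestHypergeometricEnrichment:
    def test_certain_and_empty_tails(self):
        assert hypergeometric_enrichment(5, 5, 10, 10) == pytest.approx(1.0)
        assert hypergeometric_enrichment(0, 4, 3, 12) == pytest.approx(1.0)

    def test_matches_exhaustive_enumeration_small_populations(self):
        # oracle: enumerate all C(N, n) draws for every instance with N <= 12
        for N in range(1, 13):
            population = range(N)
            for K in range(N + 1):
                for n in range(N + 1):
                    counts = [0] * (n + 1)
                    total = 0
                    for draw in itertools.combinations(population, n):
                        counts[sum(1 for x in draw if x < K)] += 1
                        total += 1
                    for k in range(min(n, K) + 1):
                        expected = sum(counts[k:]) / total
                        got = hypergeometric_enrichment(k, n, K, N)
                        assert got == pytest.approx(expected, abs=1e-12)

    def test_inconsistent_counts_rejected(self):
        with pytest.raises(ValueError):
            hypergeometric_enrichment(5, 4, 3, 12)


class TestCompareBinSeries:
    def test_identical_series(self):
        assert compare_bin_series([1, 2, 3], [1, 2, 3], "paired") == (0.0, 1.0)
        stat, p = compare_bin_series([1, 2, 3], [1, 2, 3], "two-sample")
        assert stat == pytest.approx(0.0) and p == pytest.approx(1.0)

    def test_p_value_matches_numeric_t_integration(self):
        a, b = [17.7, 34.5, 47.8], [31.25, 37.5, 31.25]
        stat, p = compare_bin_series(a, b, "two-sample")
        df = 4
        pdf = lambda x: (
            math.gamma((df + 1) / 2)
            / (math.sqrt(df * math.pi) * math.gamma(df / 2))
            * (1 + x**2 / df) ** (-(df + 1) / 2)
        )
        tail, _ = integrate.quad(pdf, abs(stat), np.inf)
        assert p == pytest.approx(2 * tail, abs=1e-10)

    def test_zero_variance_both_series(self):
        with pytest.raises(ValueError, match="zero variance"):
            compare_bin_series([1, 1, 1], [2, 2, 2], "two-sample")


class TestReadSnpTable:
    def test_tsv_row_with_flag(self, tmp_path):
        path = tmp_path / "snps.tsv"
        path.write_text("rs1\tTAT\tA\tG\t1\n")
        (rec,) = read_snp_table(path)
        assert (rec.context, rec.ref, rec.alt, rec.in_tfbs) == ("TAT", "A", "G", True)

    def test_pvalue_filter(self, tmp_path):
        path = tmp_path / "snps.tsv"
        path.write_text("rs1\tTAT\tA\tG\t1\t1e-9\nrs2\tTAT\tA\tC\t0\t1e-4\n")
        records = read_snp_table(path, max_pvalue=1e-8)
        assert [r.id for r in records] == ["rs1"]

    def test_mostly_malformed_input_is_an_error(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("rs1\tTAT\tA\tG\njunk\nmore junk\n")
        with pytest.raises(ValueError, match="skipped"):
            read_snp_table(path)

    def test_vcf_with_indel_skipped(self, tmp_path, meis1_reference):
        vcf = tmp_path / "in.vcf"
        vcf.write_text(
            "##fileformat=VCFv4.2\n"
            '##contig=<ID=chr1,length=8>\n'
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n"
            "chr1\t4\trs_snv\tA\tG\t.\tPASS\t.\n"
            "chr1\t5\trs_indel\tT\tAG\t.\tPASS\t.\n"
        )
        records = read_snp_table(vcf, format="vcf", reference=meis1_reference)
        assert len(records) == 1
        assert (records[0].id, records[0].context) == ("rs_snv", "TAT")

    def test_annotation_tsv_writer(self, tmp_path, diff_matrix):
        ann = annotate_snp(SnpRecord("rs", "TAT", "A", "G", in_tfbs=True), diff_matrix)
        path = write_annotations([ann], tmp_path / "ann.tsv")
        lines = path.read_text().splitlines()
        assert lines[0].startswith("id\tcontext")
        assert lines[1].split("\t")[-1] == "1"  # enhanced


class TestPlantedEnrichmentPower:
    def test_p_value_drops_with_planted_effect(self, diff_matrix):
        from tristack.simulate import SnpCohortSpec, gen_snp_cohort

        mean_log_p = []
        for effect in (0.0, 0.3, 0.6):
            logs = []
            for seed in (1, 2, 3):
                cohort = gen_snp_cohort(
                    SnpCohortSpec(
                        n_snps=800, planted_enrichment=effect, seed=seed
                    ),
                    diff_matrix,
                )
                anns = [annotate_snp(r, diff_matrix) for r in cohort]
                high = [a for a in anns if a.abs_bin == "high"]
                tfbs = [a for a in anns if a.record.in_tfbs]
                k = sum(1 for a in tfbs if a.abs_bin == "high")
                p = hypergeometric_enrichment(
                    k, len(tfbs), len(high), len(anns)
                )
                logs.append(math.log10(max(p, 1e-300)))
            mean_log_p.append(np.mean(logs))
        assert mean_log_p[0] > mean_log_p[1] > mean_log_p[2]
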