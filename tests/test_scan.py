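"""Scan pipeline: VCF IO, QC filters, per-SNP scan, fixture generation."""

import numpy as np
import pytest
from scipy import stats

from grm_assoc import (
    DiseaseModel,
    FixtureSpec,
    GenotypeCounts,
    QCThresholds,
    SampleSet,
    apply_qc,
    grm_test,
    make_fixture_vcf,
    read_genotypes,
    run_scan,
    write_counts_tsv,
)
from grm_assoc.scan import MISSING, read_phenotypes


def write_vcf(path, sample_ids, rows):
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n##contig=<ID=1>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
        fh.write("\t".join(sample_ids) + "\n")
        for row in rows:
            fh.write(row + "\n")


def write_pheno(path, sample_ids, statuses):
    with open(path, "w") as fh:
        fh.write("sample_id\tstatus\n")
        for s, st in zip(sample_ids, statuses):
            fh.write(f"{s}\t{st}\n")


@pytest.fixture
def tiny_vcf(tmp_path):
    samples = [f"S{i}" for i in range(8)]
    gt = {0: "0/0", 1: "0/1", 2: "1/1", None: "./."}
    # SNP1: cases (0,1,2,2) controls (0,0,1,1); SNP2 has one missing call;
    # SNP3 multiallelic (skipped)
    rows = [
        "1\t100\tsnp1\tA\tG\t.\tPASS\t.\tGT\t" + "\t".join(gt[v] for v in [0, 1, 2, 2, 0, 0, 1, 1]),
        "1\t200\tsnp2\tC\tT\t.\tPASS\t.\tGT\t" + "\t".join(gt[v] for v in [1, 1, None, 0, 2, 0, 1, 0]),
        "1\t300\tsnp3\tG\tA,T\t.\tPASS\t.\tGT\t" + "\t".join(["0/1"] * 8),
    ]
    vcf = tmp_path / "tiny.vcf"
    pheno = tmp_path / "tiny.pheno.tsv"
    write_vcf(vcf, samples, rows)
    write_pheno(pheno, samples, [2, 2, 2, 2, 1, 1, 1, 1])
    return vcf, pheno


class TestReadGenotypes:
    def test_round_trip_counts(self, tiny_vcf):
        with pytest.warns(UserWarning):
            data = read_genotypes(*tiny_vcf)
        assert data.n_snps == 2  # multiallelic record skipped
        assert data.snp_ids == ["snp1", "snp2"]
        c1 = data.snp_counts(0)
        assert c1.case_counts == (1, 1, 2)
        assert c1.control_counts == (2, 2, 0)

    def test_missing_call_excluded_from_that_snp_only(self, tiny_vcf):
        with pytest.warns(UserWarning):
            data = read_genotypes(*tiny_vcf)
        c2 = data.snp_counts(1)
        assert c2.n_cases == 3  # S2's missing call dropped here
        assert data.snp_counts(0).n_cases == 4  # but not for snp1

    def test_sample_without_phenotype_errors(self, tiny_vcf, tmp_path):
        vcf, _ = tiny_vcf
        bad = tmp_path / "short.pheno.tsv"
        write_pheno(bad, [f"S{i}" for i in range(7)], [2, 2, 2, 2, 1, 1, 1])
        with pytest.raises(ValueError, match="absent from phenotype"):
            read_genotypes(vcf, bad)

    def test_minor_allele_orientation_flips_counts_not_p_values(self, tmp_path):
        samples = [f"S{i}" for i in range(8)]
        # ALT is the major allele here (12 of 16 copies)
        rows = ["1\t100\tsnpM\tA\tG\t.\tPASS\t.\tGT\t"
                + "\t".join(["1/1", "1/1", "0/1", "1/1", "1/1", "0/1", "0/0", "1/1"])]
        vcf, pheno = tmp_path / "m.vcf", tmp_path / "m.pheno.tsv"
        write_vcf(vcf, samples, rows)
        write_pheno(pheno, samples, [2, 2, 2, 2, 1, 1, 1, 1])
        alt = read_genotypes(vcf, pheno, effect_allele="alt")
        minor = read_genotypes(vcf, pheno, effect_allele="minor")
        assert minor.effect_allele_flipped[0]
        assert minor.snp_counts(0).case_counts == alt.snp_counts(0).case_counts[::-1]
        assert grm_test(minor.snp_counts(0)).p_value == pytest.approx(
            grm_test(alt.snp_counts(0)).p_value, abs=1e-12
        )

    def test_phenotype_status_validation(self, tmp_path):
        bad = tmp_path / "bad.tsv"
        write_pheno(bad, ["A", "B"], [2, 3])
        with pytest.raises(ValueError, match="status"):
            read_phenotypes(bad)


def make_sample_set(rng, n_cases=100, n_controls=100, n_snps=40, maf=0.18):
    """Null sample set whose heterozygosity sits inside the default QC band."""
    n = n_cases + n_controls
    probs = [(1 - maf) ** 2, 2 * maf * (1 - maf), maf**2]
    g = rng.choice(3, size=(n, n_snps), p=probs).astype(np.int8)
    return SampleSet(
        [f"S{i}" for i in range(n)],
        np.array([1] * n_cases + [0] * n_controls, dtype=np.int8),
        g,
        [f"snp{j}" for j in range(n_snps)],
        ["1"] * n_snps,
        np.arange(n_snps) * 50 + 1000,
        ["A"] * n_snps,
        ["G"] * n_snps,
    )


class TestQC:
    def test_low_maf_snp_excluded(self, rng):
        data = make_sample_set(rng)
        # engineer SNP 0 to MAF ~0.02
        col = np.zeros(data.n_samples, dtype=np.int8)
        col[:8] = 1
        data.genotypes[:, 0] = col
        filtered, report = apply_qc(data)
        assert ("snp0", "maf") in report.excluded_snps
        assert "snp0" not in filtered.snp_ids

    def test_high_missingness_sample_excluded(self, rng):
        data = make_sample_set(rng)
        data.genotypes[0, :2] = MISSING  # 2/40 = 5% missing
        filtered, report = apply_qc(data)
        assert ("S0", "missingness") in report.excluded_samples
        assert "S0" not in filtered.sample_ids

    def test_heterozygosity_outlier_excluded(self, rng):
        data = make_sample_set(rng)
        data.genotypes[1, :] = 1  # 100% heterozygous
        _, report = apply_qc(data)
        assert ("S1", "heterozygosity") in report.excluded_samples

    def test_hwe_violating_snp_excluded(self, rng):
        data = make_sample_set(rng, n_controls=100)
        controls = data.phenotype == 0
        col = data.genotypes[:, 3].copy()
        ctrl_col = np.array([0] * 50 + [2] * 50, dtype=np.int8)  # (50, 0, 50)
        col[controls] = ctrl_col
        col[~controls] = np.array([0, 1, 2] * 34)[:100]
        data.genotypes[:, 3] = col
        _, report = apply_qc(data)
        assert ("snp3", "hwe_controls") in report.excluded_snps

    def test_call_rate_filter_uses_retained_samples(self, rng):
        data = make_sample_set(rng)
        # sample S0 fails missingness; SNP 5 is missing only in S0, so its
        # call rate on retained samples is 100%
        data.genotypes[0, :3] = MISSING
        data.genotypes[0, 5] = MISSING
        filtered, report = apply_qc(data)
        assert ("S0", "missingness") in report.excluded_samples
        assert "snp5" in filtered.snp_ids

    def test_all_samples_removed_raises(self, rng):
        data = make_sample_set(rng, n_cases=3, n_controls=3)
        data.genotypes[:, :] = 1
        with pytest.raises(ValueError):
            apply_qc(data)


class TestRunScan:
    def test_counts_tsv_mode_matches_direct_tests(self, tmp_path):
        tables = [
            ("a", GenotypeCounts((10, 20, 30), (30, 20, 10))),
            ("b", GenotypeCounts((590, 290, 120), (640, 320, 40))),
        ]
        path = tmp_path / "counts.tsv"
        write_counts_tsv(path, tables)
        from grm_assoc import read_counts_tsv

        records = run_scan(read_counts_tsv(path), assoc_threshold=1e-5)
        by_id = {r.snp_id: r for r in records}
        for snp_id, counts in tables:
            assert by_id[snp_id].p_grm == pytest.approx(grm_test(counts).p_value, abs=1e-12)
        assert by_id["b"].retained_model == "recessive"
        assert records[0].snp_id == "b"  # sorted by p_grm

    def test_null_scan_p_values_uniform(self, rng):
        data = make_sample_set(rng, n_cases=200, n_controls=200, n_snps=200, maf=0.25)
        records = run_scan(data)
        ps = np.array([r.p_grm for r in records])
        assert (ps < 5e-7).sum() == 0
        assert stats.kstest(ps, "uniform").pvalue > 0.001

    def test_planted_recessive_snp_recovered(self, rng):
        spec = FixtureSpec(
            n_cases=2000, n_controls=2000, n_null_snps=50,
            planted=(DiseaseModel("recessive", 0.3, 3.0, 0.05),),
            maf_range=(0.1, 0.3),
        )
        import os, tempfile

        with tempfile.TemporaryDirectory() as d:
            vcf, pheno = make_fixture_vcf(spec, seed=77, out_prefix=os.path.join(d, "fix"))
            data = read_genotypes(vcf, pheno)
            records = run_scan(data)
        assert records[0].snp_id.startswith("planted0")
        assert records[0].tier == "significant"
        assert records[0].retained_model == "recessive"
        assert records[0].p_grm < min(r.p_grm for r in records[1:])

    def test_scan_output_deterministic(self, rng, tmp_path):
        data = make_sample_set(rng, n_snps=20)
        out1, out2 = tmp_path / "a.tsv", tmp_path / "b.tsv"
        run_scan(data, out_tsv=str(out1))
        run_scan(data, out_tsv=str(out2))
        assert out1.read_bytes() == out2.read_bytes()


class TestFixtures:
    def test_fixture_round_trip_shapes(self, tmp_path):
        spec = FixtureSpec(n_cases=30, n_controls=40, n_null_snps=12)
        vcf, pheno = make_fixture_vcf(spec, seed=5, out_prefix=str(tmp_path / "fx"))
        data = read_genotypes(vcf, pheno)
        assert data.n_samples == 70
        assert data.n_snps == 12
        assert int(data.phenotype.sum()) == 30

    def test_fixture_byte_identical_under_fixed_seed(self, tmp_path):
        spec = FixtureSpec(n_cases=20, n_controls=20, n_null_snps=6,
                           planted=(DiseaseModel("dominant", 0.2, 2.0, 0.05),))
        v1, p1 = make_fixture_vcf(spec, seed=9, out_prefix=str(tmp_path / "one"))
        v2, p2 = make_fixture_vcf(spec, seed=9, out_prefix=str(tmp_path / "two"))
        assert open(v1, "rb").read() == open(v2, "rb").read()
        assert open(p1, "rb").read() == open(p2, "rb").read()

    def test_planted_genotype_frequencies_match_distribution(self, tmp_path):
        disease = DiseaseModel("recessive", 0.3, 2.5, 0.05)
        spec = FixtureSpec(n_cases=1500, n_controls=1500, n_null_snps=1, planted=(disease,))
        vcf, pheno = make_fixture_vcf(spec, seed=13, out_prefix=str(tmp_path / "pl"))
        data = read_genotypes(vcf, pheno)
        j = data.snp_ids.index("planted0_recessive")
        counts = data.snp_counts(j)
        from grm_assoc import solve_penetrances

        dist = solve_penetrances(disease)
        observed = np.array(counts.case_counts) / counts.n_cases
        se = np.sqrt(dist.case_probs * (1 - dist.case_probs) / counts.n_cases)
        np.testing.assert_array_less(np.abs(observed - dist.case_probs), 4 * se + 1e-9)
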