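"""Genome-scan application: QC, per-SNP association tests, model inference.

Reads genotypes from a VCF (biallelic SNPs, GT field) together with a
phenotype table, applies WTCCC-style quality-control filters (sample
missingness and heterozygosity, then SNP call rate, MAF and
Hardy-Weinberg equilibrium in controls), runs the four association tests
per SNP, applies the genetic-model decision tree to SNPs passing the
association threshold, and writes a ranked results table. A fixture
generator emits small synthetic VCFs with optional planted disease SNPs
for end-to-end testing.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .association import cat_test, effect_estimates, grm_test, model_selection
from .counts import GenotypeCounts, read_counts_tsv
from .hwe import hwe_exact_test
from .simulate import DiseaseModel, solve_penetrances

MISSING = -1  # genotype code for a missing call


@dataclass
class SampleSet:
    """Per-sample genotypes of biallelic SNPs with case/control phenotypes.

    ``genotypes`` is a samples x SNPs int8 matrix counting copies of the
    effect allele (0/1/2), with -1 for missing calls.
    """

    sample_ids: list[str]
    phenotype: np.ndarray  # 1 = case, 0 = control
    genotypes: np.ndarray
    snp_ids: list[str]
    chroms: list[str]
    positions: np.ndarray
    ref_alleles: list[str]
    alt_alleles: list[str]
    effect_allele_flipped: np.ndarray = None  # per-SNP: True if counted allele is REF

    def __post_init__(self):
        self.phenotype = np.asarray(self.phenotype, dtype=np.int8)
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        if self.genotypes.shape != (len(self.sample_ids), len(self.snp_ids)):
            raise ValueError("genotype matrix shape does not match sample/SNP lists")
        if not set(np.unique(self.genotypes)) <= {MISSING, 0, 1, 2}:
            raise ValueError("genotypes must be coded 0/1/2 or -1 (missing)")
        if self.phenotype.sum() < 1 or (1 - self.phenotype).sum() < 1:
            raise ValueError("need at least one case and one control")
        if self.effect_allele_flipped is None:
            self.effect_allele_flipped = np.zeros(len(self.snp_ids), dtype=bool)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_snps(self) -> int:
        return len(self.snp_ids)

    def snp_counts(self, j: int) -> GenotypeCounts:
        """Complete-case 2x3 genotype counts for SNP ``j``."""
        g = self.genotypes[:, j]
        keep = g != MISSING
        cases = np.bincount(g[keep & (self.phenotype == 1)], minlength=3)[:3]
        controls = np.bincount(g[keep & (self.phenotype == 0)], minlength=3)[:3]
        return GenotypeCounts(tuple(int(v) for v in cases), tuple(int(v) for v in controls))


@dataclass(frozen=True)
class QCThresholds:
    """SNP- and sample-level quality-control thresholds.

    Defaults follow WTCCC-style GWAS filtering: samples dropped above 3%
    missingness or outside 23-30% genome-wide heterozygosity; SNPs dropped
    below 5% MAF, below 97% call rate, or with control-group HWE exact-test
    p below 5.7e-7.
    """

    maf_min: float = 0.05
    hwe_p_min: float = 5.7e-7
    snp_call_rate_min: float = 0.97
    sample_missing_max: float = 0.03
    heterozygosity_bounds: tuple[float, float] = (0.23, 0.30)


@dataclass
class QCReport:
    excluded_samples: list[tuple[str, str]] = field(default_factory=list)
    excluded_snps: list[tuple[str, str]] = field(default_factory=list)
    n_samples_in: int = 0
    n_snps_in: int = 0
    n_samples_kept: int = 0
    n_snps_kept: int = 0


@dataclass
class ScanRecord:
    """Per-SNP association results after QC."""

    snp_id: str
    chrom: str
    position: int
    ref: str
    alt: str
    counts: GenotypeCounts
    p_grm: float
    p_cat_add: float
    p_cat_dom: float
    p_cat_rec: float
    beta_add: float
    beta_domdev: float
    retained_model: str  # populated only below the association threshold
    tier: str  # "significant", "suggestive" or ""
    qc_flags: str = ""


def read_phenotypes(path) -> dict[str, int]:
    """Read a ``sample_id<TAB>status`` table (1 = control, 2 = case)."""
    df = pd.read_csv(path, sep="\t", dtype={0: str})
    if df.shape[1] < 2:
        raise ValueError("phenotype file needs sample_id and status columns")
    sid, status = df.columns[:2]
    out = {}
    for row in df.itertuples(index=False):
        s = int(getattr(row, status))
        if s not in (1, 2):
            raise ValueError(f"status must be 1 (control) or 2 (case), got {s}")
        out[str(getattr(row, sid))] = s - 1  # internal coding: 1 = case
    return out


def read_genotypes(
    vcf_path,
    phenotype_path,
    effect_allele: str = "alt",
) -> SampleSet:
    """Load biallelic SNP genotypes from a VCF plus a phenotype table.

    The counted (effect) allele is the VCF ALT allele by default;
    ``effect_allele="minor"`` re-orients each SNP to count its minor
    allele. Multi-allelic records are skipped with a warning; a VCF sample
    absent from the phenotype file is an error; missing genotype calls are
    preserved as missing.
    """
    from cyvcf2 import VCF

    if effect_allele not in ("alt", "minor"):
        raise ValueError("effect_allele must be 'alt' or 'minor'")

    phenotypes = read_phenotypes(phenotype_path)
    vcf = VCF(str(vcf_path), gts012=True)
    sample_ids = list(vcf.samples)
    missing_pheno = [s for s in sample_ids if s not in phenotypes]
    if missing_pheno:
        raise ValueError(f"samples absent from phenotype file: {missing_pheno[:5]}")

    geno_cols, snp_ids, chroms, positions, refs, alts = [], [], [], [], [], []
    for variant in vcf:
        if len(variant.ALT) != 1 or variant.var_type != "snp":
            warnings.warn(f"skipping non-biallelic-SNP record at {variant.CHROM}:{variant.POS}")
            continue
        g = variant.gt_types.astype(np.int8)  # gts012: 0/1/2 alt copies, 3 unknown
        g[g == 3] = MISSING
        geno_cols.append(g)
        snp_ids.append(variant.ID or f"{variant.CHROM}:{variant.POS}")
        chroms.append(variant.CHROM)
        positions.append(variant.POS)
        refs.append(variant.REF)
        alts.append(variant.ALT[0])
    vcf.close()
    if not geno_cols:
        raise ValueError("no biallelic SNP records in VCF")

    genotypes = np.column_stack(geno_cols)
    flipped = np.zeros(len(snp_ids), dtype=bool)
    if effect_allele == "minor":
        for j in range(genotypes.shape[1]):
            g = genotypes[:, j]
            obs = g[g != MISSING]
            if obs.size and obs.mean() / 2.0 > 0.5:  # ALT is the major allele
                genotypes[g != MISSING, j] = 2 - obs
                flipped[j] = True

    phenotype = np.array([phenotypes[s] for s in sample_ids], dtype=np.int8)
    return SampleSet(
        sample_ids, phenotype, genotypes, snp_ids, chroms,
        np.asarray(positions), refs, alts, flipped,
    )


def _allele_freq_test(g1: np.ndarray, g2: np.ndarray) -> float:
    """Chi-square test of allele-frequency difference between two groups."""
    from scipy.stats import chi2_contingency

    def alleles(g):
        obs = g[g != MISSING]
        alt = int(obs.sum())
        return [2 * obs.size - alt, alt]

    table = np.array([alleles(g1), alleles(g2)])
    if table.sum(axis=0).min() == 0 or table.sum(axis=1).min() == 0:
        return 1.0
    return float(chi2_contingency(table, correction=False)[1])


def apply_qc(
    data: SampleSet,
    thresholds: QCThresholds = QCThresholds(),
    control_split: Optional[dict[str, int]] = None,
) -> tuple[SampleSet, QCReport]:
    """Apply sample-level then SNP-level quality control.

    Samples failing the missingness or heterozygosity bounds are removed
    first; SNP call rate, MAF and control HWE are then computed on the
    retained samples only. When ``control_split`` assigns controls to two
    groups, SNPs whose control-group allele frequencies differ at the HWE
    p-value threshold are additionally excluded (off by default).
    """
    report = QCReport(n_samples_in=data.n_samples, n_snps_in=data.n_snps)
    g = data.genotypes
    missing = g == MISSING

    # sample filters, computed genome-wide over all SNPs
    miss_rate = missing.mean(axis=1)
    with np.errstate(invalid="ignore"):
        het_rate = (g == 1).sum(axis=1) / np.maximum((~missing).sum(axis=1), 1)
    lo, hi = thresholds.heterozygosity_bounds
    keep_sample = np.ones(data.n_samples, dtype=bool)
    for i, sid in enumerate(data.sample_ids):
        if miss_rate[i] > thresholds.sample_missing_max:
            report.excluded_samples.append((sid, "missingness"))
            keep_sample[i] = False
        elif not lo <= het_rate[i] <= hi:
            report.excluded_samples.append((sid, "heterozygosity"))
            keep_sample[i] = False
    if not keep_sample.any():
        raise ValueError("all samples removed by QC")

    g = g[keep_sample]
    phenotype = data.phenotype[keep_sample]
    sample_ids = [s for s, k in zip(data.sample_ids, keep_sample) if k]
    if phenotype.sum() < 1 or (1 - phenotype).sum() < 1:
        raise ValueError("QC removed all cases or all controls")

    # SNP filters on retained samples
    keep_snp = np.ones(data.n_snps, dtype=bool)
    controls = phenotype == 0
    for j, snp in enumerate(data.snp_ids):
        gj = g[:, j]
        obs = gj != MISSING
        call_rate = obs.mean()
        if call_rate < thresholds.snp_call_rate_min:
            report.excluded_snps.append((snp, "call_rate"))
            keep_snp[j] = False
            continue
        freq = gj[obs].mean() / 2.0
        if min(freq, 1 - freq) < thresholds.maf_min:
            report.excluded_snps.append((snp, "maf"))
            keep_snp[j] = False
            continue
        ctrl = gj[controls & obs]
        hwe_counts = tuple(int(v) for v in np.bincount(ctrl, minlength=3)[:3])
        if hwe_exact_test(hwe_counts) < thresholds.hwe_p_min:
            report.excluded_snps.append((snp, "hwe_controls"))
            keep_snp[j] = False
            continue
        if control_split is not None:
            group = np.array([control_split.get(s, 0) for s in sample_ids])
            g1 = gj[controls & (group == 1)]
            g2 = gj[controls & (group == 2)]
            if g1.size and g2.size and _allele_freq_test(g1, g2) < thresholds.hwe_p_min:
                report.excluded_snps.append((snp, "control_group_difference"))
                keep_snp[j] = False
    if not keep_snp.any():
        raise ValueError("all SNPs removed by QC")

    filtered = SampleSet(
        sample_ids,
        phenotype,
        g[:, keep_snp],
        [s for s, k in zip(data.snp_ids, keep_snp) if k],
        [c for c, k in zip(data.chroms, keep_snp) if k],
        data.positions[keep_snp],
        [r for r, k in zip(data.ref_alleles, keep_snp) if k],
        [a for a, k in zip(data.alt_alleles, keep_snp) if k],
        data.effect_allele_flipped[keep_snp],
    )
    report.n_samples_kept = filtered.n_samples
    report.n_snps_kept = filtered.n_snps
    return filtered, report


SCAN_TSV_COLUMNS = [
    "snp_id", "chrom", "position", "ref", "alt",
    "case_AA", "case_Aa", "case_aa", "ctrl_AA", "ctrl_Aa", "ctrl_aa",
    "p_grm", "p_cat_add", "p_cat_dom", "p_cat_rec",
    "beta_add", "beta_domdev", "retained_model", "tier", "qc_flags",
]


def _scan_one(counts: GenotypeCounts, assoc_threshold: float, model_threshold: float):
    res_grm = grm_test(counts)
    p_cats = {m: cat_test(counts, m).p_value for m in ("additive", "dominant", "recessive")}
    est = effect_estimates(counts)
    flags = [] if est.converged else ["fit_not_converged"]
    retained = ""
    if res_grm.p_value < assoc_threshold:
        retained = model_selection(counts, assoc_threshold, model_threshold).outcome
    return res_grm.p_value, p_cats, est, retained, ";".join(flags)


def run_scan(
    data: SampleSet | Sequence[tuple[str, GenotypeCounts]],
    assoc_threshold: float = 5e-7,
    suggestive_threshold: float = 5e-5,
    model_threshold: float = 0.01,
    out_tsv: Optional[str] = None,
) -> list[ScanRecord]:
    """Run all association tests per SNP and rank by the 2-df p-value.

    Accepts either a post-QC :class:`SampleSet` or pre-tabulated
    ``(snp_id, GenotypeCounts)`` pairs (counts-TSV mode). SNPs below
    ``assoc_threshold`` get a genetic-model decision and the
    ``significant`` tier; those below ``suggestive_threshold`` only are
    tiered ``suggestive``. Per-SNP fit failures are recorded in
    ``qc_flags`` and the scan continues. Deterministic given its inputs.
    """
    if isinstance(data, SampleSet):
        items = [
            (data.snp_ids[j], data.chroms[j], int(data.positions[j]),
             data.ref_alleles[j], data.alt_alleles[j], data.snp_counts(j))
            for j in range(data.n_snps)
        ]
    else:
        items = [(sid, ".", 0, ".", ".", c) for sid, c in data]

    records = []
    for snp_id, chrom, pos, ref, alt, counts in items:
        try:
            p_grm, p_cats, est, retained, flags = _scan_one(
                counts, assoc_threshold, model_threshold
            )
        except Exception as exc:
            records.append(ScanRecord(
                snp_id, chrom, pos, ref, alt, counts,
                np.nan, np.nan, np.nan, np.nan, np.nan, np.nan,
                "", "", f"test_failed:{exc}",
            ))
            continue
        tier = ""
        if p_grm < assoc_threshold:
            tier = "significant"
        elif p_grm < suggestive_threshold:
            tier = "suggestive"
        records.append(ScanRecord(
            snp_id, chrom, pos, ref, alt, counts,
            p_grm, p_cats["additive"], p_cats["dominant"], p_cats["recessive"],
            est.beta_add, est.beta_domdev, retained, tier, flags,
        ))

    records.sort(key=lambda r: (np.inf if np.isnan(r.p_grm) else r.p_grm, r.snp_id))
    if out_tsv is not None:
        rows = [
            (r.snp_id, r.chrom, r.position, r.ref, r.alt,
             *r.counts.case_counts, *r.counts.control_counts,
             r.p_grm, r.p_cat_add, r.p_cat_dom, r.p_cat_rec,
             r.beta_add, r.beta_domdev, r.retained_model, r.tier, r.qc_flags)
            for r in records
        ]
        pd.DataFrame(rows, columns=SCAN_TSV_COLUMNS).to_csv(
            out_tsv, sep="\t", index=False, float_format="%.6g"
        )
    return records


@dataclass(frozen=True)
class FixtureSpec:
    """Specification for a synthetic VCF fixture with planted signals."""

    n_cases: int = 200
    n_controls: int = 200
    n_null_snps: int = 50
    planted: tuple[DiseaseModel, ...] = ()
    missing_rate: float = 0.0
    maf_range: tuple[float, float] = (0.05, 0.5)


def make_fixture_vcf(spec: FixtureSpec, seed: int, out_prefix: str) -> tuple[str, str]:
    """Write a synthetic VCF (v4.2, GT field) and phenotype TSV.

    Null SNPs draw genotypes from HWE at a random MAF independently of the
    phenotype; planted SNPs draw cases and controls from the genotype
    distributions implied by their disease models. Fixed seed gives
    byte-identical files. Returns (vcf_path, phenotype_path).
    """
    rng = np.random.default_rng(seed)
    n = spec.n_cases + spec.n_controls
    sample_ids = [f"S{i:04d}" for i in range(n)]
    phenotype = np.array([1] * spec.n_cases + [0] * spec.n_controls)

    columns, ids = [], []
    for k, disease in enumerate(spec.planted):
        dist = solve_penetrances(disease)
        g = np.empty(n, dtype=np.int8)
        g[phenotype == 1] = rng.choice(3, size=spec.n_cases, p=dist.case_probs)
        g[phenotype == 0] = rng.choice(3, size=spec.n_controls, p=dist.control_probs)
        columns.append(g)
        ids.append(f"planted{k}_{disease.model}")
    for k in range(spec.n_null_snps):
        maf = rng.uniform(*spec.maf_range)
        probs = [(1 - maf) ** 2, 2 * maf * (1 - maf), maf**2]
        columns.append(rng.choice(3, size=n, p=probs).astype(np.int8))
        ids.append(f"null{k}")
    genotypes = np.column_stack(columns)
    if spec.missing_rate > 0:
        mask = rng.random(genotypes.shape) < spec.missing_rate
        genotypes[mask] = MISSING

    order = rng.permutation(genotypes.shape[1])
    genotypes, ids = genotypes[:, order], [ids[j] for j in order]

    gt_strings = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}
    vcf_path = f"{out_prefix}.vcf"
    pheno_path = f"{out_prefix}.pheno.tsv"
    with open(vcf_path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=grm-assoc synthetic fixture\n")
        fh.write("##contig=<ID=1>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
        fh.write("\t".join(sample_ids) + "\n")
        for j, snp_id in enumerate(ids):
            gts = "\t".join(gt_strings[int(v)] for v in genotypes[:, j])
            fh.write(f"1\t{1000 + j * 100}\t{snp_id}\tA\tG\t.\tPASS\t.\tGT\t{gts}\n")
    with open(pheno_path, "w") as fh:
        fh.write("sample_id\tstatus\n")
        for sid, ph in zip(sample_ids, phenotype):
            fh.write(f"{sid}\t{2 if ph == 1 else 1}\n")
    return vcf_path, pheno_path
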