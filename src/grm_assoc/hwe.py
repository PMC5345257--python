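"""Exact test of Hardy-Weinberg equilibrium from genotype counts.

The conditional distribution of the heterozygote count given the allele
counts is enumerated exactly and the two-sided p-value is the summed
probability of all configurations no more probable than the observed one
(no mid-p adjustment), the form standard in GWAS quality control.
"""

from __future__ import annotations

import numpy as np
from scipy.special import gammaln


def hwe_exact_test(counts: tuple[int, int, int]) -> float:
    """Exact HWE p-value for (AA, Aa, aa) genotype counts.

    Conditional on the observed allele counts, the heterozygote count
    ranges over values of fixed parity; each configuration's probability is
    multinomial over genotypes divided by the binomial over alleles. The
    p-value sums configurations with probability <= the observed one, and
    is 1 when either allele is absent (a monomorphic site carries no
    information about HWE). Invariant to swapping AA and aa.
    """
    n_aa_hom, n_het, n_bb_hom = (int(c) for c in counts)
    if min(n_aa_hom, n_het, n_bb_hom) < 0:
        raise ValueError("genotype counts must be non-negative")
    n = n_aa_hom + n_het + n_bb_hom
    if n == 0:
        raise ValueError("need at least one genotyped sample")

    n_a = 2 * n_aa_hom + n_het  # allele counts
    n_b = 2 * n_bb_hom + n_het
    rare = min(n_a, n_b)
    if rare == 0:
        return 1.0

    # feasible heterozygote counts share the parity of the rare-allele count
    hets = np.arange(rare % 2, rare + 1, 2)
    homs_rare = (rare - hets) // 2
    homs_common = n - hets - homs_rare

    # log P(het | allele counts): multinomial over genotypes x 2^het,
    # normalised by the allele-level binomial C(2n, rare)
    logp = (
        gammaln(n + 1)
        - gammaln(homs_rare + 1)
        - gammaln(hets + 1)
        - gammaln(homs_common + 1)
        + hets * np.log(2.0)
        + gammaln(rare + 1)
        + gammaln(2 * n - rare + 1)
        - gammaln(2 * n + 1)
    )
    prob = np.exp(logp - logp.max())
    prob /= prob.sum()

    observed = np.flatnonzero(hets == n_het)
    if observed.size == 0:  # inconsistent table cannot occur for valid counts
        raise AssertionError("observed heterozygote count not in support")
    p_obs = prob[observed[0]]
    return float(min(prob[prob <= p_obs * (1 + 1e-12)].sum(), 1.0))
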