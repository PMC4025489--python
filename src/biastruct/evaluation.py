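"""Accuracy and differentiation metrics.

Ancestry-recovery accuracy is the squared Pearson correlation between the true
ancestry proportions and the inferred ones.  For a two-way admixture the
measure is symmetric in the two ancestry columns (corr(theta, Q1)^2 =
corr(theta, Q2)^2 since Q2 = 1 - Q1), so label switching cannot change it.
Significance is assessed by permutation, and founder differentiation by the
Hudson F_ST estimator (ratio of averages).
"""

from __future__ import annotations

import numpy as np
from scipy import stats


def squared_correlation(true_theta: np.ndarray, inferred: np.ndarray) -> float:
    """Squared Pearson correlation between true and inferred ancestry.

    Raises on constant input (the correlation is undefined there) rather than
    returning 0.
    """
    true_theta = np.asarray(true_theta, dtype=float)
    inferred = np.asarray(inferred, dtype=float)
    if true_theta.shape != inferred.shape:
        raise ValueError("vectors must have equal length")
    if true_theta.size < 3:
        raise ValueError("need at least 3 individuals")
    if np.ptp(true_theta) == 0 or np.ptp(inferred) == 0:
        raise ValueError("correlation undefined for a constant vector")
    r = stats.pearsonr(true_theta, inferred).statistic
    return float(r * r)


def tau_sample(x: int, y: int, z: int | None = None, *, strict: bool = True) -> float:
    """Bias ratio tau = y / x: admixed count over unmixed count per population.

    Defined for symmetric designs (x == z).  With ``strict=False`` an
    asymmetric design only warns and y/x is returned anyway.
    """
    if x <= 0:
        raise ValueError("x must be positive")
    if z is not None and z != x:
        if strict:
            raise ValueError(f"tau undefined for asymmetric design x={x}, z={z}")
        import warnings

        warnings.warn(f"asymmetric design x={x}, z={z}; using y/x", stacklevel=2)
    return y / x


def permutation_pvalue(
    true_theta: np.ndarray,
    inferred: np.ndarray,
    n_perm: int = 999,
    seed: int | None = None,
) -> float:
    """Permutation (Mantel-style) p-value for the squared correlation.

    p = (1 + #{r2_perm >= r2_obs}) / (n_perm + 1) over random permutations of
    the inferred vector; the add-one rule keeps p in (0, 1].
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    true_theta = np.asarray(true_theta, dtype=float)
    inferred = np.asarray(inferred, dtype=float)
    r2_obs = squared_correlation(true_theta, inferred)
    rng = np.random.default_rng(seed)
    # r^2 under permutation via the closed-form Pearson statistic
    tc = true_theta - true_theta.mean()
    ic = inferred - inferred.mean()
    denom = np.sqrt((tc @ tc) * (ic @ ic))
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(ic)
        r = (tc @ perm) / denom
        if r * r >= r2_obs - 1e-12:
            count += 1
    return (1 + count) / (n_perm + 1)


def hudson_fst(genotypes_pop1: np.ndarray, genotypes_pop2: np.ndarray) -> float:
    """Hudson F_ST between two diploid samples, ratio-of-averages form.

    Per locus the numerator is (p1 - p2)^2 - p1(1-p1)/(n1-1) - p2(1-p2)/(n2-1)
    and the denominator p1(1-p2) + p2(1-p1), with p the sample allele
    frequency and n the number of sampled alleles (2 x individuals).  Loci
    monomorphic in both samples are dropped; the per-locus terms are averaged
    separately and then divided (robust to rare alleles).
    """
    g1 = np.asarray(genotypes_pop1, dtype=float)
    g2 = np.asarray(genotypes_pop2, dtype=float)
    if g1.shape[0] < 2 or g2.shape[0] < 2:
        raise ValueError("need at least 2 individuals per population")
    n1 = 2.0 * g1.shape[0]
    n2 = 2.0 * g2.shape[0]
    p1 = g1.mean(axis=0) / 2.0
    p2 = g2.mean(axis=0) / 2.0
    keep = ~(((p1 == 0) & (p2 == 0)) | ((p1 == 1) & (p2 == 1)))
    p1, p2 = p1[keep], p2[keep]
    if p1.size == 0:
        raise ValueError("all loci monomorphic in both populations")
    num = (p1 - p2) ** 2 - p1 * (1 - p1) / (n1 - 1) - p2 * (1 - p2) / (n2 - 1)
    den = p1 * (1 - p2) + p2 * (1 - p1)
    return float(num.mean() / den.mean())
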