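"""Ancestry inference engines: admixture-likelihood EM and eigenanalysis.

Both engines follow the model/results pattern: construct a model object from
a genotype matrix, call :meth:`fit`, and read estimates off the returned
results object.

The admixture model treats each genotype g_ij in {0,1,2} as Binomial(2,
pi_ij) with pi_ij = sum_k q_ik p_kj: individual i draws each of its two
allele copies from ancestral population k with probability q_ik, and a copy
from population k carries the alternate allele with probability p_kj.  The
(weighted) log-likelihood

    l = sum_i w_i sum_j [ g_ij log pi_ij + (2 - g_ij) log(1 - pi_ij) ]

is maximized by EM with the classical responsibilities
a_ijk = q_ik p_kj / pi_ij (alternate copies) and b_ijk = q_ik (1-p_kj) /
(1-pi_ij) (reference copies).  Per-individual weights w_i implement the
selection-bias correction without resampling: integer weights are exactly
equivalent to physically duplicating rows.  Individuals of known ancestry
can be pinned to a single component (semi-supervised mode); pinned
individuals keep a vertex ancestry vector but still inform the allele
frequency updates.

The eigen engine standardizes each locus by its (weighted) sample allele
frequency and eigendecomposes the individual-by-individual covariance; the
top projection proxies ancestry in a two-population admixture.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy import linalg as sla

from .io_formats import MISSING, GenotypeTable

EPS = 1e-6  # allele-frequency clamp


def _as_matrix(genotypes) -> np.ndarray:
    if isinstance(genotypes, GenotypeTable):
        return genotypes.matrix
    return np.asarray(genotypes)


def _split_missing(matrix: np.ndarray, dtype=np.float64):
    """Return (g_valid, two_minus_g_valid) with missing entries zeroed."""
    valid = matrix != MISSING
    g = np.where(valid, matrix, 0).astype(dtype)
    g2 = np.where(valid, 2 - matrix, 0).astype(dtype)
    return g, g2


def loglikelihood(genotypes, Q, P, weights=None) -> float:
    """Weighted binomial log-likelihood of an ancestry decomposition.

    Missing genotypes contribute nothing; an all-missing matrix scores 0.
    """
    matrix = _as_matrix(genotypes)
    Q = np.asarray(Q, dtype=float)
    P = np.asarray(P, dtype=float)
    pi = np.clip(Q @ P, EPS / 2, 1 - EPS / 2)
    g, g2 = _split_missing(matrix)
    per_ind = np.einsum("ij,ij->i", g, np.log(pi)) + np.einsum(
        "ij,ij->i", g2, np.log1p(-pi)
    )
    if weights is None:
        return float(per_ind.sum())
    return float(np.asarray(weights, dtype=float) @ per_ind)


@dataclasses.dataclass
class AdmixtureResults:
    """EM fit: ancestry matrix Q (rows on the simplex), ancestral allele
    frequencies P, and the log-likelihood trace."""

    model: "AdmixtureModel"
    Q: np.ndarray
    P: np.ndarray
    loglik_trace: np.ndarray
    converged: bool
    n_iter: int

    @property
    def llf(self) -> float:
        return float(self.loglik_trace[-1])

    @property
    def ancestry(self) -> np.ndarray:
        """Ancestry proportions from the first component (K=2 convention)."""
        return self.Q[:, 0]

    def align_to(self, reference: np.ndarray) -> "AdmixtureResults":
        """Resolve label switching: permute components so column 1 correlates
        maximally with `reference` (true ancestry or pinned labels).

        The squared-correlation accuracy measure is itself symmetric under
        the swap; alignment only fixes the reporting convention.
        """
        reference = np.asarray(reference, dtype=float)
        if np.ptp(reference) == 0:
            return self
        cors = []
        for k in range(self.Q.shape[1]):
            col = self.Q[:, k]
            if np.ptp(col) == 0:
                cors.append(-np.inf)
            else:
                cors.append(np.corrcoef(reference, col)[0, 1])
        best = int(np.argmax(cors))
        order = [best] + [k for k in range(self.Q.shape[1]) if k != best]
        return dataclasses.replace(self, Q=self.Q[:, order], P=self.P[order])

    def summary(self) -> str:
        n, k = self.Q.shape
        lines = [
            "Admixture model (binomial likelihood, EM)",
            "=" * 42,
            f"Individuals:        {n}",
            f"Components (K):     {k}",
            f"Loci:               {self.P.shape[1]}",
            f"Log-likelihood:     {self.llf:.3f}",
            f"Iterations:         {self.n_iter}",
            f"Converged:          {self.converged}",
            "",
            "Mean ancestry per component:",
        ]
        for j, m in enumerate(self.Q.mean(axis=0)):
            lines.append(f"  Q{j + 1}: {m:.4f}")
        return "\n".join(lines)


class AdmixtureModel:
    """Maximum-likelihood admixture model for a genotype matrix.

    Parameters
    ----------
    genotypes : GenotypeTable or (N, M) array of 0/1/2 with 9 = missing
    K : number of ancestral components
    weights : optional positive per-individual likelihood weights; they are
        rescaled to mean 1.  Integer weights reproduce row duplication.
    fixed_labels : optional length-N integer array; entry k >= 0 pins the
        individual to component k (its ancestry row stays that vertex), -1
        leaves the individual free.  Pinned individuals still enter the
        allele-frequency updates.
    """

    def __init__(self, genotypes, K: int = 2, weights=None, fixed_labels=None):
        self.matrix = _as_matrix(genotypes)
        n, m = self.matrix.shape
        if K < 1:
            raise ValueError("K must be >= 1")
        if K > n:
            raise ValueError(f"K={K} exceeds the {n} individuals")
        self.K = K
        if weights is None:
            self.weights = np.ones(n)
        else:
            weights = np.asarray(weights, dtype=float)
            if weights.shape != (n,) or (weights <= 0).any():
                raise ValueError("weights must be positive, one per individual")
            self.weights = weights / weights.mean()
        if fixed_labels is None:
            self.fixed_labels = np.full(n, -1)
        else:
            self.fixed_labels = np.asarray(fixed_labels, dtype=int)
            if self.fixed_labels.shape != (n,):
                raise ValueError("fixed_labels must have one entry per individual")
            if (self.fixed_labels >= K).any():
                raise ValueError("fixed label out of range")

    @classmethod
    def from_cohort(cls, cohort, K: int = 2, weights=None, supervised: bool = False):
        """Build from a Cohort; with ``supervised=True`` unmixed individuals
        (groups 1 and 2) are pinned to components 1 and 0 respectively, so
        component 0 tracks pop-2 ancestry like theta does."""
        fixed = None
        if supervised:
            group = cohort.labels.group
            fixed = np.where(group == 2, 0, np.where(group == 1, 1, -1))
        return cls(cohort.genotypes, K=K, weights=weights, fixed_labels=fixed)

    def loglike(self, Q, P) -> float:
        return loglikelihood(self.matrix, Q, P, self.weights)

    def _moment_freqs(self, Q):
        """M-step-style moment estimate of P given an ancestry guess."""
        valid = self.matrix != MISSING
        g = np.where(valid, self.matrix, 0).astype(float)
        wq = self.weights[:, None] * Q  # N x K
        num = wq.T @ g
        den = 2.0 * (wq.T @ valid.astype(float))
        return np.clip(num / np.maximum(den, 1e-300), EPS, 1 - EPS)

    def _initial_random(self, rng):
        n, m = self.matrix.shape
        Q = rng.dirichlet(np.ones(self.K), size=n)
        valid = self.matrix != MISSING
        phat = np.where(valid, self.matrix, 0).sum(axis=0) / np.maximum(
            2 * valid.sum(axis=0), 1
        )
        P = np.clip(phat + rng.uniform(-0.1, 0.1, size=(self.K, m)), EPS, 1 - EPS)
        return Q, P

    def _initial_spectral(self, rng):
        """Warm start from eigenanalysis.

        The admixture likelihood on datasets with heavily duplicated rows has
        degenerate global maxima where a component collapses onto one
        repeated individual; started from the leading principal components,
        EM converges to the population-structure optimum instead.  The top
        K-1 weighted-PCA projections are rescaled into the simplex and P is
        set to the corresponding moment estimate.
        """
        n, m = self.matrix.shape
        if self.K == 1:
            Q = np.ones((n, 1))
            return Q, self._moment_freqs(Q)
        try:
            # deliberately unweighted: repeated rows distort the leading
            # eigenvectors (the duplication/colinearity pathology), and the
            # init should reflect distinct genotypes only
            efit = EigenAncestryModel(self.matrix, n_components=self.K - 1).fit()
        except ValueError:  # monomorphic etc.: fall back to random
            return self._initial_random(rng)
        proj = efit.projections
        cols = []
        for c in range(self.K - 1):
            v = proj[:, c] if proj.shape[1] > c else rng.random(n)
            lo, hi = np.quantile(v, [0.02, 0.98])
            if hi <= lo:
                cols.append(np.full(n, 1.0 / self.K))
            else:
                cols.append(np.clip((v - lo) / (hi - lo), 0.02, 0.98))
        # distribute mass: component k gets col_k scaled into the simplex
        Q = np.empty((n, self.K))
        raw = np.column_stack(cols)
        Q[:, : self.K - 1] = raw / max(self.K - 1, 1)
        Q[:, self.K - 1] = 1.0 - Q[:, : self.K - 1].sum(axis=1)
        Q = np.clip(Q, 0.01, 0.99)
        Q /= Q.sum(axis=1, keepdims=True)
        return Q, self._moment_freqs(Q)

    def _initial(self, rng, init: str = "spectral"):
        if init == "spectral":
            Q, P = self._initial_spectral(rng)
        elif init == "random":
            Q, P = self._initial_random(rng)
        else:
            raise ValueError(f"unknown init {init!r}")
        pinned = self.fixed_labels >= 0
        if pinned.any():
            Q[pinned] = np.eye(self.K)[self.fixed_labels[pinned]]
            P = self._moment_freqs(Q) if init == "spectral" else P
        return Q, P

    def fit(
        self,
        tol: float = 1e-4,
        max_iter: int = 2000,
        seed=None,
        initial=None,
        init: str = "spectral",
        prior_strength: float = 0.0,
        dtype=np.float64,
    ) -> AdmixtureResults:
        """Run EM until the log-likelihood gain drops below `tol` (absolute)
        or `max_iter` iterations.

        `initial` may supply (Q0, P0) explicitly; otherwise Q0 is drawn from
        a symmetric Dirichlet(1) with the given seed and P0 perturbs the
        sample allele frequencies.  `dtype=np.float32` halves memory traffic
        and uses SIMD logs — roughly 5x faster on large matrices — at the
        price of log-likelihood resolution of a few units, so pair it with a
        correspondingly loose `tol`.

        `init="spectral"` (default) warm-starts from an unweighted PCA of
        the distinct genotypes; `init="random"` draws Q from a symmetric
        Dirichlet(1).

        `prior_strength` (lambda) adds a symmetric Beta(1 + lambda,
        1 + lambda) prior on every allele frequency, turning the fit into
        MAP-EM.  The plain likelihood has degenerate maxima on datasets with
        heavily repeated rows (a component collapses onto one individual's
        exact genotype, the mixture analogue of a Gaussian-variance
        singularity); a weak prior (lambda ~ 2) makes that collapse
        expensive while shifting well-supported frequency estimates by
        O(lambda / mass) only.  With lambda > 0 the reported trace is the
        penalized objective, which EM increases monotonically.
        """
        rng = np.random.default_rng(seed)
        if initial is None:
            Q, P = self._initial(rng, init)
        else:
            Q = np.array(initial[0], dtype=float)
            P = np.array(initial[1], dtype=float)
        Q = Q.astype(dtype)
        P = P.astype(dtype)
        n, m = self.matrix.shape
        g, g2 = _split_missing(self.matrix, dtype)
        w = self.weights.astype(dtype)
        wcol = w[:, None]
        wg = wcol * g  # fixed across iterations; used for the log-likelihood
        wg2 = wcol * g2
        pinned = self.fixed_labels >= 0
        lam = float(prior_strength)
        lo = dtype(EPS / 2)
        hi = dtype(1 - EPS / 2)
        buf_a = np.empty((n, m), dtype=dtype)
        buf_b = np.empty((n, m), dtype=dtype)
        one = dtype(1.0)
        trace: list[float] = []
        converged = False
        it = 0
        for it in range(max_iter + 1):
            pi = np.clip(Q @ P, lo, hi)
            np.log(pi, out=buf_a)
            np.subtract(one, pi, out=buf_b)
            np.log(buf_b, out=buf_b)
            # accumulate in float64 regardless of the compute dtype
            ll = float(
                np.einsum("ij,ij->", wg, buf_a, dtype=np.float64)
                + np.einsum("ij,ij->", wg2, buf_b, dtype=np.float64)
            )
            if lam > 0:
                P64 = P.astype(np.float64)
                ll += lam * float(np.log(P64).sum() + np.log1p(-P64).sum())
            trace.append(ll)
            if it > 0 and trace[-1] - trace[-2] < tol:
                converged = True
                break
            if it == max_iter:
                break
            np.divide(g, pi, out=buf_a)  # r1 = g / pi
            np.subtract(one, pi, out=pi)
            np.divide(g2, pi, out=buf_b)  # r0 = (2-g) / (1-pi)
            # q_ik <- q_ik/(2 M_i) * sum_j [g_ij p_kj/pi_ij + (2-g_ij)(1-p_kj)/(1-pi_ij)]
            Qnew = Q * (buf_a @ P.T + buf_b @ (one - P).T)
            Qnew /= Qnew.sum(axis=1, keepdims=True)
            if pinned.any():
                Qnew[pinned] = Q[pinned]
            # p_kj <- sum_i w_i g_ij a_ijk / sum_i w_i [g_ij a_ijk + (2-g_ij) b_ijk]
            buf_a *= wcol
            buf_b *= wcol
            t1 = Q.T @ buf_a
            t0 = Q.T @ buf_b
            num = P * t1
            den = num + (one - P) * t0
            if lam > 0:
                num = num + dtype(lam)
                den = den + dtype(2 * lam)
            Pnew = np.clip(num / np.maximum(den, dtype(1e-30)), EPS, 1 - EPS).astype(dtype)
            Q, P = Qnew, Pnew
        return AdmixtureResults(
            model=self,
            Q=Q.astype(np.float64),
            P=P.astype(np.float64),
            loglik_trace=np.array(trace),
            converged=converged,
            n_iter=it,
        )


def admixture_em(
    genotypes,
    K: int = 2,
    weights=None,
    fixed_labels=None,
    tol: float = 1e-4,
    max_iter: int = 2000,
    seed=None,
) -> AdmixtureResults:
    """Functional wrapper: build an :class:`AdmixtureModel` and fit it."""
    return AdmixtureModel(genotypes, K=K, weights=weights, fixed_labels=fixed_labels).fit(
        tol=tol, max_iter=max_iter, seed=seed
    )


def project_ancestry(
    genotypes, P, tol: float = 1e-5, max_iter: int = 300
) -> np.ndarray:
    """ML ancestry vectors for individuals given fixed allele frequencies.

    Runs the EM q-update with P held fixed (each individual's problem is
    independent and concave-like in q); used to read ancestry off for
    individuals that were not part of the parameter-learning dataset, e.g.
    scoring an original sample after parameters were learned on a
    bias-corrected resample of it.
    """
    matrix = _as_matrix(genotypes)
    dtype = np.float32
    P = np.asarray(P, dtype=dtype)
    K = P.shape[0]
    n = matrix.shape[0]
    g, g2 = _split_missing(matrix, dtype)
    Pc = (1 - P).T.copy()
    Pt = P.T.copy()
    Q = np.full((n, K), 1.0 / K, dtype=dtype)
    lo = dtype(EPS / 2)
    hi = dtype(1 - EPS / 2)
    for _ in range(max_iter):
        pi = np.clip(Q @ P, lo, hi)
        r1 = g / pi
        np.subtract(dtype(1.0), pi, out=pi)
        r0 = g2 / pi
        Qnew = Q * (r1 @ Pt + r0 @ Pc)
        Qnew /= Qnew.sum(axis=1, keepdims=True)
        delta = np.abs(Qnew - Q).max()
        Q = Qnew
        if delta < tol:
            break
    return Q.astype(np.float64)


def align_clusters(fit: AdmixtureResults, reference) -> AdmixtureResults:
    """Functional wrapper for :meth:`AdmixtureResults.align_to`."""
    return fit.align_to(reference)


# ---------------------------------------------------------------------------
# eigenanalysis


@dataclasses.dataclass
class EigenFit:
    """Eigenanalysis fit: descending eigenvalues, the individuals'
    coordinates on the top eigenvectors, and the locus-space loadings plus
    standardization needed to project new individuals."""

    eigenvalues: np.ndarray
    projections: np.ndarray
    loadings: np.ndarray | None = None  # (n_poly_loci, C)
    phat: np.ndarray | None = None  # standardization frequencies (poly loci)
    poly: np.ndarray | None = None  # boolean mask of polymorphic loci

    def project_rows(self, genotypes) -> np.ndarray:
        """Coordinates of new individuals in this fit's eigenspace.

        Rows are standardized with the fit's allele frequencies (missing
        entries mean-imputed) and multiplied by the locus loadings.
        """
        if self.loadings is None:
            raise ValueError("fit carries no loadings")
        matrix = _as_matrix(genotypes)
        valid = matrix != MISSING
        g = np.where(valid, matrix, 0).astype(float)[:, self.poly]
        valid = valid[:, self.poly]
        x = (g - 2.0 * self.phat) / np.sqrt(self.phat * (1.0 - self.phat))
        x[~valid] = 0.0
        return x @ self.loadings

    @property
    def ancestry(self) -> np.ndarray:
        """First-eigenvector projection (the two-population ancestry proxy)."""
        return self.projections[:, 0]

    def summary(self) -> str:
        lines = [
            "Eigenanalysis of standardized genotypes",
            "=" * 40,
            f"Individuals:  {self.projections.shape[0]}",
            f"Components:   {self.projections.shape[1]}",
            "Top eigenvalues: "
            + " ".join(f"{v:.4f}" for v in self.eigenvalues[: self.projections.shape[1]]),
        ]
        return "\n".join(lines)


class EigenAncestryModel:
    """PCA of the standardized genotype matrix, optionally weighted.

    Each locus is centred at twice its (weighted) sample allele frequency
    p-hat and scaled by sqrt(p-hat (1 - p-hat)); missing entries are
    mean-imputed (zero after standardization).  The weighted variant
    eigendecomposes W^(1/2) X X^T W^(1/2), whose spectrum equals that of the
    row-duplicated matrix when weights are integer duplication counts.
    """

    def __init__(self, genotypes, n_components: int = 1, weights=None):
        self.matrix = _as_matrix(genotypes)
        n, m = self.matrix.shape
        if n < 2:
            raise ValueError("need at least 2 individuals")
        self.n_components = int(n_components)
        if weights is None:
            self.weights = np.ones(n)
        else:
            weights = np.asarray(weights, dtype=float)
            if weights.shape != (n,) or (weights <= 0).any():
                raise ValueError("weights must be positive, one per individual")
            self.weights = weights

    def fit(self) -> EigenFit:
        matrix = self.matrix
        w = self.weights
        valid = matrix != MISSING
        g = np.where(valid, matrix, 0).astype(float)
        wv = w[:, None] * valid
        phat = (w[:, None] * g).sum(axis=0) / np.maximum(2.0 * wv.sum(axis=0), 1e-300)
        poly = (phat > 0) & (phat < 1)
        if not poly.any():
            raise ValueError("all loci monomorphic; eigenanalysis undefined")
        g = g[:, poly]
        valid = valid[:, poly]
        phat = phat[poly]
        x = (g - 2.0 * phat) / np.sqrt(phat * (1.0 - phat))
        x[~valid] = 0.0  # mean imputation
        sw = np.sqrt(w)
        xw = sw[:, None] * x
        cov = xw @ xw.T
        evals, evecs = sla.eigh(cov)
        order = np.argsort(evals)[::-1]
        evals = np.maximum(evals[order], 0.0)
        evecs = evecs[:, order]
        c = min(self.n_components, evals.size)
        proj = (evecs[:, :c] / sw[:, None]) * np.sqrt(evals[:c])
        scale = np.sqrt(np.maximum(evals[:c], 1e-300))
        loadings = xw.T @ evecs[:, :c] / scale
        return EigenFit(
            eigenvalues=evals,
            projections=proj,
            loadings=loadings,
            phat=phat,
            poly=poly,
        )


def eigen_ancestry(genotypes, n_components: int = 1, weights=None) -> EigenFit:
    """Functional wrapper: build an :class:`EigenAncestryModel` and fit it."""
    return EigenAncestryModel(genotypes, n_components=n_components, weights=weights).fit()
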