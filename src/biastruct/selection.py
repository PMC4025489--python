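"""The biased sampling process and its correction.

Each individual carries a group label u (1 = unmixed pop 1, 2 = unmixed
pop 2, 3 = admixed) and a selection indicator s; selection depends on the
genotype only through u, P(s=1 | g, u) = P(s=1 | u).  The observed sample's
distribution D' then relates to the population distribution D by

    P_D(g, u) = c * P_D'(g, u) / P(s=1 | u),

so the reciprocal selection probabilities act as correction factors.  For a
designed sample with group counts (x, y, z) and group prior P(u), Bayes'
rule gives P(s=1 | u=g) proportional to count_g / P(u=g); under a uniform
prior the selection weights are simply proportional to the counts.

Two implementations of the correction are provided: resampling the selected
sample with replacement with inclusion probability proportional to each
point's correction factor, and carrying the correction factors directly as
per-individual likelihood weights.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .synthdata import Cohort

GROUPS = (1, 2, 3)


@dataclasses.dataclass(frozen=True)
class SampleSpec:
    """Counts drawn into a biased dataset: x unmixed pop-1, y admixed,
    z unmixed pop-2 (the S_xyz scheme)."""

    x: int
    y: int
    z: int

    @property
    def size(self) -> int:
        return self.x + self.y + self.z

    def count(self, group: int) -> int:
        return {1: self.x, 2: self.z, 3: self.y}[group]

    @property
    def tau(self) -> float:
        from .evaluation import tau_sample

        return tau_sample(self.x, self.y, self.z)


@dataclasses.dataclass
class SelectionModel:
    """Per-group selection probabilities (up to a constant) and their
    reciprocals, the correction factors."""

    group_prior: dict[int, float]
    selection_weight: dict[int, float]
    correction_factor: dict[int, float]


def selection_probabilities(
    spec: SampleSpec, group_prior: dict[int, float] | None = None
) -> SelectionModel:
    """Selection weights P(s=1|u) up to a constant, from design counts.

    P(s=1|u=g) = P(u=g|s=1) P(s=1) / P(u=g) ~ count_g / prior_g; under the
    default uniform prior the weights are proportional to (x, z, y) for
    groups (1, 2, 3).  A group with positive prior but zero count has an
    undefined correction factor and raises.
    """
    if group_prior is None:
        group_prior = {g: 1.0 / 3.0 for g in GROUPS}
    total_prior = sum(group_prior.values())
    if total_prior <= 0:
        raise ValueError("prior must have positive mass")
    prior = {g: group_prior.get(g, 0.0) / total_prior for g in GROUPS}
    counts = {g: spec.count(g) for g in GROUPS}
    if all(c == 0 for c in counts.values()):
        raise ValueError("at least one group count must be positive")
    weight: dict[int, float] = {}
    correction: dict[int, float] = {}
    for g in GROUPS:
        if prior[g] == 0.0:
            weight[g] = float("inf") if counts[g] > 0 else 0.0
            correction[g] = 0.0
            continue
        if counts[g] == 0:
            raise ValueError(
                f"group {g} has prior {prior[g]:.3g} but no sampled individuals; "
                "correction factor undefined"
            )
        weight[g] = counts[g] / prior[g]
        correction[g] = prior[g] / counts[g]
    # normalize for readability: weights sum to 1 over groups present
    wsum = sum(w for w in weight.values() if np.isfinite(w))
    if wsum > 0:
        weight = {g: w / wsum for g, w in weight.items()}
    csum = sum(correction.values())
    if csum > 0:
        correction = {g: c / csum for g, c in correction.items()}
    return SelectionModel(prior, weight, correction)


def draw_biased_sample(cohort: Cohort, spec: SampleSpec, seed=None) -> Cohort:
    """Draw x/y/z individuals with replacement from groups 1/3/2.

    Sampled rows keep provenance: individual ids carry the source row index,
    so duplicated individuals appear as distinct rows that can be traced back
    (and collapsed into weights) later.
    """
    rng = np.random.default_rng(seed)
    group = cohort.labels.group
    picks = []
    for g, n_draw in ((1, spec.x), (2, spec.z), (3, spec.y)):
        pool = np.flatnonzero(group == g)
        if n_draw > 0 and pool.size == 0:
            raise ValueError(f"group {g} absent from cohort but {n_draw} requested")
        if n_draw > 0:
            picks.append(rng.choice(pool, size=n_draw, replace=True))
    indices = np.concatenate(picks)
    ids = [f"{cohort.genotypes.individual_ids[i]}@{i}" for i in indices]
    sample = cohort.take(indices, ids)
    sample.source_index = indices  # provenance for paired designs
    return sample


def inclusion_probabilities(sample: Cohort, model: SelectionModel) -> np.ndarray:
    """Per-point resampling inclusion probabilities.

    For a selected sample of N points the i-th point is included with
    probability (1/p(s=1|u_i)) / sum_j (1/p(s=1|u_j)).
    """
    factors = np.array([model.correction_factor[g] for g in sample.labels.group])
    total = factors.sum()
    if total <= 0:
        raise ValueError("degenerate correction factors: no positive weight")
    return factors / total


def resample_corrected(sample: Cohort, model: SelectionModel, seed=None) -> Cohort:
    """Resample the selected sample with replacement, N draws, with inclusion
    probability proportional to each point's correction factor 1/p(s=1|u).

    The corrected sample may contain non-unique points; ids keep provenance.
    """
    rng = np.random.default_rng(seed)
    probs = inclusion_probabilities(sample, model)
    n = sample.n_individuals
    indices = rng.choice(n, size=n, replace=True, p=probs)
    ids = [sample.genotypes.individual_ids[i] for i in indices]
    corrected = sample.take(indices, ids)
    if hasattr(sample, "source_index"):
        corrected.source_index = np.asarray(sample.source_index)[indices]
    return corrected


def likelihood_weights(sample: Cohort, model: SelectionModel) -> np.ndarray:
    """Per-individual likelihood weights proportional to the correction
    factor of the individual's group, normalized to mean 1 (so weighted and
    unweighted log-likelihoods are on the same scale)."""
    factors = np.array([model.correction_factor[g] for g in sample.labels.group])
    mean = factors.mean()
    if mean <= 0:
        raise ValueError("degenerate correction factors: no positive weight")
    return factors / mean


def collapse_duplicates(sample: Cohort) -> tuple[Cohort, np.ndarray, np.ndarray]:
    """Collapse genotype-identical rows into unique rows + counts.

    Sampling with replacement (and pool expansion before it) leaves exact
    copies of the same genotype as separate rows.  Returns (unique cohort,
    multiplicity per unique row, inverse index mapping each original row to
    its representative).  Fitting the unique rows with the multiplicities as
    likelihood weights is algebraically equivalent to fitting the duplicated
    matrix; rows are keyed by genotype content, so copies that entered
    through different sampling paths still merge.
    """
    matrix = sample.genotypes.matrix
    seen: dict[bytes, int] = {}
    first: list[int] = []
    inverse = np.empty(matrix.shape[0], dtype=np.int64)
    for i in range(matrix.shape[0]):
        key = matrix[i].tobytes()
        idx = seen.get(key)
        if idx is None:
            idx = len(first)
            seen[key] = idx
            first.append(i)
        inverse[i] = idx
    counts = np.bincount(inverse, minlength=len(first)).astype(float)
    unique_cohort = sample.take(np.asarray(first))
    return unique_cohort, counts, inverse
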