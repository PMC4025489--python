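"""Desk-scale experiment runners.

Three experiments quantify how biased sampling degrades ancestry inference
and how the selection-model correction restores it:

* the grid experiment draws biased datasets S_xyz (x unmixed pop-1, y
  admixed, z unmixed pop-2, with replacement) from a synthetic two-population
  study cohort and measures the squared correlation between true and
  inferred ancestry, optionally after a correction;
* the tau scan sweeps the bias ratio tau = y/x at fixed x = z and estimates
  the largest tau at which mean accuracy stays at or above 0.95;
* the bottleneck experiment builds founder pairs whose drift reflects a
  piecewise demography (one branch bottlenecked), showing that the impact of
  biased sampling follows effective, not census, population size, and that a
  correction using harmonic-mean effective sizes as the group prior helps
  exactly when unmixed individuals are under-represented.

Fitting always collapses repeated rows (the samples are drawn with
replacement) into unique rows with integer likelihood weights — an exact
algebraic equivalence for the admixture likelihood — and expands the
inferred ancestries back over the duplicated rows before scoring.
"""

from __future__ import annotations

import hashlib

import numpy as np
import pandas as pd

from . import demography as demo
from .evaluation import squared_correlation
from .inference import AdmixtureModel, EigenAncestryModel, project_ancestry
from .io_formats import ExperimentConfig, build_config
from .selection import (
    SampleSpec,
    collapse_duplicates,
    draw_biased_sample,
    likelihood_weights,
    resample_corrected,
    selection_probabilities,
)
from .synthdata import (
    Cohort,
    assemble_study_population,
    gen_founder_frequencies,
    sample_founder_genotypes,
    simulate_admixture,
)

# Desk-scale EM settings: single-precision EM with a one-log-likelihood-unit
# stopping rule; the accuracy measure stabilizes well before tighter
# tolerances are reachable, and on 10^3 x 10^4 matrices this is ~5x faster.
# The weak allele-frequency prior guards against frequency collapse onto
# heavily duplicated rows (resampling with replacement makes those common).
EM_TOL = 1.0
EM_MAX_ITER = 2000
EM_PRIOR_STRENGTH = 2.0


def _config_hash(config: ExperimentConfig) -> str:
    return hashlib.sha1(repr(config).encode()).hexdigest()[:10]


def build_study_population(config: ExperimentConfig, seed=None) -> Cohort:
    """Founder frequencies + three-group cohort for a config."""
    ss = np.random.SeedSequence(seed if seed is not None else config.seed)
    s_freq, s_pop = ss.spawn(2)
    freqs = gen_founder_frequencies(config.n_loci, config.fst, seed=s_freq)
    return assemble_study_population(freqs, config, seed=s_pop)


def fit_dataset(
    dataset: Cohort,
    engine: str = "em",
    weights: np.ndarray | None = None,
    seed=None,
    tol: float = EM_TOL,
    max_iter: int = EM_MAX_ITER,
    score: Cohort | None = None,
) -> np.ndarray:
    """Learn ancestry structure on `dataset`, report ancestry per row.

    Genotype-identical rows are fitted once with duplication counts as
    likelihood weights, then the inferred ancestry is broadcast back.
    Optional extra `weights` (the likelihood-weighting correction) multiply
    the duplication counts.

    If `score` is given, parameters are learned on `dataset` but ancestry is
    reported for the rows of `score` instead: for the admixture engine the
    ancestry of each score row is its ML projection onto the learned allele
    frequencies; for the eigen engine its coordinate on the learned leading
    eigenvector.  This is how a bias-corrected resample is used — it corrects
    parameter learning, while accuracy is read off the selected sample.
    """
    unique, counts, inverse = collapse_duplicates(dataset)
    w = counts.copy()
    if weights is not None:
        # aggregate the per-row weights onto the unique representatives
        w = np.bincount(inverse, weights=weights, minlength=len(counts))
    if engine == "em":
        fit = AdmixtureModel(unique.genotypes, K=2, weights=w).fit(
            tol=tol,
            max_iter=max_iter,
            seed=seed,
            prior_strength=EM_PRIOR_STRENGTH,
            dtype=np.float32,
        )
        if score is None:
            return fit.Q[:, 0][inverse]
        return project_ancestry(score.genotypes, fit.P)[:, 0]
    if engine == "eigen":
        fit = EigenAncestryModel(unique.genotypes, n_components=1, weights=w).fit()
        if score is None:
            return fit.projections[:, 0][inverse]
        return fit.project_rows(score.genotypes)[:, 0]
    raise ValueError(f"unknown engine {engine!r}")


def _score_sample(sample: Cohort, engine: str, weights, seed, train: Cohort | None = None) -> float:
    """r^2 over the rows of `sample`; parameters learned on `train` if given."""
    if train is None:
        inferred = fit_dataset(sample, engine=engine, weights=weights, seed=seed)
    else:
        inferred = fit_dataset(train, engine=engine, weights=weights, seed=seed, score=sample)
    return squared_correlation(sample.labels.true_theta, inferred)


def run_cell(
    cohort: Cohort,
    spec: SampleSpec,
    correction: str = "none",
    engine: str = "em",
    group_prior: dict[int, float] | None = None,
    seed=None,
) -> dict:
    """One biased dataset: draw, optionally correct, fit, score."""
    ss = np.random.SeedSequence(seed)
    s_draw, s_corr, s_fit = ss.spawn(3)
    sample = draw_biased_sample(cohort, spec, s_draw)
    model = selection_probabilities(spec, group_prior)
    weights = None
    train = None
    if correction == "resample":
        train = resample_corrected(sample, model, s_corr)
    elif correction == "weights":
        weights = likelihood_weights(sample, model)
    elif correction != "none":
        raise ValueError(f"unknown correction {correction!r}")
    r2 = _score_sample(sample, engine, weights, s_fit, train=train)
    return {
        "x": spec.x,
        "y": spec.y,
        "z": spec.z,
        "tau": spec.y / spec.x if spec.x == spec.z else np.nan,
        "engine": engine,
        "correction": correction,
        "r2": r2,
    }


def run_grid_experiment(
    config: ExperimentConfig, cohort: Cohort | None = None
) -> pd.DataFrame:
    """The grid experiment: every cell x replicates, one row per dataset."""
    if cohort is None:
        cohort = build_study_population(config)
    chash = _config_hash(config)
    rows = []
    for ci, (x, y, z) in enumerate(config.cells):
        spec = SampleSpec(x, y, z)
        for rep in range(config.n_replicates):
            seed = np.random.SeedSequence((config.seed, ci, rep)).generate_state(1)[0]
            row = run_cell(
                cohort, spec, correction=config.correction, engine=config.engine, seed=int(seed)
            )
            row.update(replicate=rep, seed=int(seed), config=chash)
            rows.append(row)
    return pd.DataFrame(rows)


def aggregate_results(results: pd.DataFrame, by=("x", "y", "z", "correction")) -> pd.DataFrame:
    """Mean and standard error of r^2 per cell (standard error over the
    replicates, requiring at least two)."""
    grouped = results.groupby(list(by))["r2"]
    agg = grouped.agg(["mean", "sem", "count"]).reset_index()
    return agg.rename(columns={"mean": "r2_mean", "sem": "r2_se", "count": "n"})


def estimate_tau_threshold(
    cohort: Cohort,
    config: ExperimentConfig,
    x: int = 30,
    taus: tuple[int, ...] = tuple(range(1, 11)),
    threshold: float = 0.95,
) -> tuple[float, pd.DataFrame]:
    """Scan tau = y/x at fixed x = z and return the largest tau whose mean
    uncorrected accuracy stays >= `threshold`, plus the per-tau table."""
    rows = []
    for ti, tau in enumerate(taus):
        spec = SampleSpec(x, int(round(tau * x)), x)
        for rep in range(config.n_replicates):
            seed = np.random.SeedSequence((config.seed, 1000 + ti, rep)).generate_state(1)[0]
            row = run_cell(cohort, spec, correction="none", engine=config.engine, seed=int(seed))
            row.update(replicate=rep)
            rows.append(row)
    table = pd.DataFrame(rows)
    means = table.groupby("tau")["r2"].mean()
    passing = [t for t in taus if means.loc[float(t)] >= threshold]
    est = float(max(passing)) if passing else 0.0
    return est, table


def run_correction_comparison(
    config: ExperimentConfig, cohort: Cohort | None = None
) -> pd.DataFrame:
    """Paired corrected-vs-uncorrected runs on identical biased samples.

    Per cell and replicate the same drawn sample feeds both arms; the table
    reports r2_uncorrected, r2_corrected and their difference.
    """
    if cohort is None:
        cohort = build_study_population(config)
    rows = []
    for ci, (x, y, z) in enumerate(config.cells):
        spec = SampleSpec(x, y, z)
        for rep in range(config.n_replicates):
            ss = np.random.SeedSequence((config.seed, 2000 + ci, rep))
            s_draw, s_corr, s_fit = ss.spawn(3)
            sample = draw_biased_sample(cohort, spec, s_draw)
            model = selection_probabilities(spec)
            r2_raw = _score_sample(sample, config.engine, None, s_fit)
            corrected = resample_corrected(sample, model, s_corr)
            r2_cor = _score_sample(sample, config.engine, None, s_fit, train=corrected)
            rows.append(
                {
                    "x": x,
                    "y": y,
                    "z": z,
                    "tau": y / x if x == z else np.nan,
                    "replicate": rep,
                    "r2_uncorrected": r2_raw,
                    "r2_corrected": r2_cor,
                    "delta_r2": r2_cor - r2_raw,
                }
            )
    return pd.DataFrame(rows)


def run_bottleneck_experiment(
    config: ExperimentConfig,
    alphas: tuple[float, ...] = (0.99, 0.5, 0.1),
    xs: tuple[int, ...] = (5, 10, 20, 30, 40, 50),
    n0: float = 10_000.0,
    n_founders: int = 50,
    n_admixed: int = 50,
    correction: str = "none",
) -> pd.DataFrame:
    """Accuracy vs. number of pop-2 individuals under a pop-2 bottleneck.

    For each contraction factor alpha, founders are drawn with per-branch
    drift from the demography (population 1: constant size N0 for the 1000
    generations since the split; population 2: the bottleneck history), a
    50-50 admixed pool is simulated (one admixture generation plus five of
    random mating), and the study dataset combines all pop-1 individuals,
    all admixed individuals and x pop-2 individuals.  With
    ``correction="resample"``, the group prior is proportional to effective
    sizes: harmonic-mean Ne for population 2, N0 for population 1 and (by
    assumption) for the admixed group.
    """
    if config.demography:
        alphas = tuple(config.demography.get("alphas", alphas))
        n0 = float(config.demography.get("n0", n0))
    f1 = demo.demography_to_drift(demo.constant_scenario(n0, 1000.0))
    rows = []
    for ai, alpha in enumerate(alphas):
        scenario = demo.bottleneck_scenario(alpha, n0)
        f2 = demo.demography_to_drift(scenario)
        ne2 = demo.harmonic_mean_ne(scenario)
        for rep in range(config.n_replicates):
            ss = np.random.SeedSequence((config.seed, 3000 + ai, rep))
            s_freq, s_founders, s_sim, s_pick, s_fit = ss.spawn(5)
            freqs = gen_founder_frequencies(config.n_loci, drift_f=(f1, f2), seed=s_freq)
            founders = sample_founder_genotypes(freqs, n_founders, s_founders)
            admixed = simulate_admixture(
                founders.by_group(1),
                founders.by_group(2),
                n_offspring=n_admixed,
                n_generations=6,
                seed=s_sim,
            )
            pop1 = founders.by_group(1)
            pop2 = founders.by_group(2)
            pick_rng = np.random.default_rng(s_pick)
            for x in xs:
                chosen = pick_rng.choice(n_founders, size=x, replace=False)
                dataset = Cohort.concat([pop1, admixed, pop2.take(chosen)])
                train = None
                if correction == "resample":
                    spec = SampleSpec(n_founders, n_admixed, x)
                    prior = {1: n0, 2: ne2, 3: n0}
                    model = selection_probabilities(spec, prior)
                    train = resample_corrected(
                        dataset, model, np.random.SeedSequence((config.seed, 4000 + ai, rep, x))
                    )
                r2 = _score_sample(dataset, config.engine, None, s_fit, train=train)
                rows.append(
                    {
                        "alpha": alpha,
                        "x": x,
                        "replicate": rep,
                        "correction": correction,
                        "ne2": ne2,
                        "r2": r2,
                    }
                )
    return pd.DataFrame(rows)


def default_grid_config(**overrides) -> ExperimentConfig:
    """Desk-scale defaults: symmetric cells, 5 replicates, 10,000 loci."""
    return build_config(overrides)
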