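"""Canned simulation studies exercising the full pipeline.

Each function generates its inputs from a seed, runs the relevant pipeline
stages, and measures how well the known ground truth is recovered.  They are
the package's built-in validation studies: the same routines back the test
suite and the ``scripts/acceptance.py`` reproduction script.

Problem sizes are chosen so the whole battery runs in a few minutes on one
core: 50 random tables for the exhaustive-search comparison, 10 replicate
cohorts at study scale (Z = 18 events, 119/120/118 subjects) for ordering
recovery, 1,000 subjects for staging, 20 replicates for mixture recovery.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import kendalltau, norm

from .distributions import EventLikelihoodTable, GaussianParams, fit_patient_mixture
from .model import EventBasedModel
from .sequence import (exhaustive_ml_sequence, find_ml_sequence, mcmc_sample,
                       positional_variance, sequence_log_likelihood)
from .simulate import CohortConfig, generate_cohort, generate_longitudinal
from .staging import bootstrap_pvd, predict_conversion, stage_subjects

__all__ = [
    "balanced_accuracy_worked_example",
    "ml_oracle_agreement",
    "planted_order_recovery",
    "stage_recovery",
    "mixture_recovery",
    "pvd_normalization",
    "longitudinal_progression",
    "eq1_naive_agreement",
]


def _spawn(seed: int, n: int) -> list[int]:
    return [int(s.generate_state(1)[0] % 2**31)
            for s in np.random.SeedSequence(seed).spawn(n)]


def balanced_accuracy_worked_example():
    """Threshold sweep on a staged cohort whose best operating point has 75%
    sensitivity and 55% specificity; returns the ConversionResult."""
    stages = pd.Series([1, 8, 8, 8] + [2] * 11 + [8] * 9,
                       index=[f"s{j}" for j in range(24)])
    converted = pd.Series([True] * 4 + [False] * 20, index=stages.index)
    return predict_conversion(stages, converted, n_stages=18)


def _random_table(z, n, rng):
    return EventLikelihoodTable(rng.standard_normal((n, z)),
                                rng.standard_normal((n, z)),
                                [f"bm{i}" for i in range(z)],
                                [f"s{j}" for j in range(n)])


def ml_oracle_agreement(seed: int, n_tables: int = 50) -> float:
    """Fraction of random tables (Z = 3..6) on which greedy restarts attain
    the exhaustive-enumeration optimum's log-likelihood."""
    rng = np.random.default_rng(seed)
    hits = 0
    for t in range(n_tables):
        z = 3 + t % 4
        table = _random_table(z, 12, rng)
        greedy = find_ml_sequence(table, n_restarts=5,
                                  seed=int(rng.integers(2**31)))
        exact = exhaustive_ml_sequence(table)
        hits += abs(sequence_log_likelihood(table, greedy)
                    - sequence_log_likelihood(table, exact)) < 1e-9
    return hits / n_tables


def _positions(sequence):
    pos = np.empty(len(sequence))
    pos[np.asarray(sequence)] = np.arange(len(sequence))
    return pos


def planted_order_recovery(seed: int, n_replicates: int = 10,
                           n_restarts: int = 8) -> list[float]:
    """Kendall tau between recovered and planted orderings on replicate
    study-scale cohorts (Z = 18, groups 119/120/118, 2.5-4 SD shifts)."""
    taus = []
    for s in _spawn(seed, n_replicates):
        rng = np.random.default_rng(s)
        cohort = generate_cohort(CohortConfig(
            seed=s, planted_sequence=rng.permutation(18)))
        model = EventBasedModel.from_dataframe(cohort.data)
        results = model.fit(n_restarts=n_restarts, mcmc_samples=0, seed=s)
        tau = kendalltau(_positions(results.ml_sequence),
                         _positions(cohort.planted_sequence)).statistic
        taus.append(float(tau))
    return taus


def stage_recovery(seed: int, n_subjects: int = 1000, z: int = 18,
                   shift: float = 3.0) -> float:
    """Fraction of subjects staged within +-1 of their planted stage under
    3-SD normal/abnormal separation (direct stage-likelihood evaluation)."""
    rng = np.random.default_rng(seed)
    sequence = rng.permutation(z)
    stages = rng.integers(0, z + 1, n_subjects)
    rank = np.empty(z, dtype=int)
    rank[sequence] = np.arange(1, z + 1)
    abnormal = rank[None, :] <= stages[:, None]
    x = np.where(abnormal, -shift, 0.0) + rng.standard_normal((n_subjects, z))
    table = EventLikelihoodTable(
        norm.logpdf(x, -shift, 1.0), norm.logpdf(x, 0.0, 1.0),
        [f"bm{i}" for i in range(z)], [f"s{j}" for j in range(n_subjects)])
    got = stage_subjects(table, sequence).table["stage"].to_numpy()
    return float(np.mean(np.abs(got - stages) <= 1))


def mixture_recovery(seed: int, n_replicates: int = 20, n_patients: int = 118,
                     shift: float = -3.0, abnormal_sd: float = 1.3,
                     weight: float = 0.5) -> float:
    """Mean abnormal-mean bias, as a fraction of the planted shift, across
    replicate fixed-component mixture fits."""
    normal = GaussianParams(0.0, 1.0)
    errors = []
    for s in _spawn(seed, n_replicates):
        rng = np.random.default_rng(s)
        lab = rng.random(n_patients) < weight
        x = np.where(lab, rng.normal(shift, abnormal_sd, n_patients),
                     rng.standard_normal(n_patients))
        fit = fit_patient_mixture(x, normal)
        errors.append(fit.abnormal.mean - shift)
    return float(abs(np.mean(errors)) / abs(shift))


def pvd_normalization(seed: int) -> float:
    """Largest |row or column sum - 1| over an MCMC PVD and a
    bootstrap-averaged PVD built on a small planted cohort."""
    from .prep import BiomarkerMatrix

    rng = np.random.default_rng(seed)
    z, n_per = 5, 12
    stages = np.repeat(np.arange(z + 1), n_per)
    abnormal = np.arange(1, z + 1)[None, :] <= stages[:, None]
    vals = np.where(abnormal, -3.0, 0.0) + rng.standard_normal((len(stages), z))
    idx = [f"s{j}" for j in range(len(stages))]
    matrix = BiomarkerMatrix(
        pd.DataFrame(vals, index=idx, columns=[f"bm{i}" for i in range(z)]),
        pd.Series(np.where(stages == 0, "HC", "HD"), index=idx))
    table = EventLikelihoodTable(
        norm.logpdf(vals, -3.0, 1.0), norm.logpdf(vals, 0.0, 1.0),
        matrix.biomarker_names, idx)
    trace = mcmc_sample(table, np.arange(z), n_samples=2000, n_burn_in=200,
                        seed=seed)
    mats = [positional_variance(trace).matrix,
            bootstrap_pvd(matrix, n_bootstrap=20, seed=seed,
                          n_restarts=3).matrix]
    dev = 0.0
    for m in mats:
        dev = max(dev, np.abs(m.sum(axis=0) - 1).max(),
                  np.abs(m.sum(axis=1) - 1).max())
    return float(dev)


def longitudinal_progression(seed: int) -> dict:
    """Mean recovered stage progression over 3 annual visits at a planted
    rate of 1 stage/year.

    Manifest patients keep their usual late-stage occupancy so every event
    has abnormal examples for the mixture fits; premanifest carriers start in
    the lower stages (0..10 of 18), leaving headroom below the stage ceiling,
    and progression is measured on them.  The model is fitted on baseline
    and every visit is staged with the baseline model.  Returns mean, SE and
    n over the premanifest group.
    """
    z = 18
    config = CohortConfig(
        seed=seed, n_biomarkers=z,
        stage_occupancy={
            "HC": np.r_[1.0, np.zeros(z)],
            "preHD": np.r_[np.full(11, 1 / 11), np.zeros(z - 10)],
            "HD": CohortConfig(seed=0).stage_occupancy["HD"],
        })
    cohort = generate_longitudinal(generate_cohort(config), n_visits=4,
                                   stages_per_year=1.0)
    model = EventBasedModel.from_dataframe(cohort.baseline)
    results = model.fit(n_restarts=6, mcmc_samples=0, seed=seed)
    assignments = results.stage_cohort(cohort.data)
    tab = assignments.table.merge(
        cohort.data[["subject_id", "visit_months", "diagnosis"]],
        on=["subject_id", "visit_months"])
    patients = tab[tab["diagnosis"] == "preHD"]
    wide = patients.pivot(index="subject_id", columns="visit_months",
                          values="stage").sort_index(axis=1)
    advance = (wide.iloc[:, -1] - wide.iloc[:, 0]).dropna()
    return {"mean": float(advance.mean()),
            "se": float(advance.std(ddof=1) / np.sqrt(len(advance))),
            "n": int(len(advance))}


def eq1_naive_agreement(seed: int, n_tables: int = 10) -> float:
    """Max |log-sum-exp evaluation - literal naive product evaluation| of
    the sequence likelihood over random Z = 4, N = 10 tables."""
    rng = np.random.default_rng(seed)
    worst = 0.0
    for _ in range(n_tables):
        table = _random_table(4, 10, rng)
        order = rng.permutation(4)
        naive_total = 0.0
        for j in range(10):
            subject = 0.0
            for k in range(5):
                term = 1.0 / 5
                for pos, i in enumerate(order, start=1):
                    lp = (table.log_p_event[j, i] if pos <= k
                          else table.log_p_not_event[j, i])
                    term *= np.exp(lp)
                subject += term
            naive_total += np.log(subject)
        fast = sequence_log_likelihood(table, order)
        worst = max(worst, abs(fast - naive_total))
    return float(worst)
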