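"""Patient staging and the validation analyses built on it.

Given the characteristic ordering S and the per-biomarker event
distributions, a subject's stage is the k maximising

    P(X_j | S, k) = P(k) prod_{i<=k} P(x_ij|E_si) prod_{i>k} P(x_ij|not-E_si)

over k = 0..Z (uniform P(k); ties resolved to the smallest k, a conservative
choice).  Validation covers bootstrap cross-validation of the ordering,
longitudinal consistency of stages over follow-up visits, prediction of
premanifest-to-manifest conversion by a stage threshold, and OLS regression
of phenotype scores on stage.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .distributions import event_likelihoods, fit_all_biomarkers
from .prep import BiomarkerMatrix
from .sequence import (PositionalVarianceDiagram, find_ml_sequence,
                       mcmc_sample, positional_variance,
                       stage_log_likelihoods)

__all__ = [
    "StageAssignments",
    "ConversionResult",
    "stage_subjects",
    "stage_subject",
    "stage_distribution",
    "bootstrap_pvd",
    "longitudinal_consistency",
    "predict_conversion",
    "phenotype_regression",
]


@dataclass
class StageAssignments:
    """Stages for a set of subjects (optionally subject-visits).

    ``table`` has columns ``subject_id``, ``visit_months``, ``stage``;
    ``log_likelihood_by_stage`` holds the full (n, Z+1) stage log-likelihood
    array in the same row order.
    """

    table: pd.DataFrame
    log_likelihood_by_stage: np.ndarray

    @property
    def stages(self) -> pd.Series:
        return self.table.set_index("subject_id")["stage"]

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


def stage_subjects(table_or_matrix, sequence, fits=None,
                   visit_months=None) -> StageAssignments:
    """Assign every subject its maximum-likelihood stage.

    Accepts either a prebuilt EventLikelihoodTable or a BiomarkerMatrix plus
    per-biomarker fits.  Ties go to the smallest stage.
    """
    if fits is not None:
        table = event_likelihoods(table_or_matrix, fits)
    else:
        table = table_or_matrix
    if np.isnan(table.log_p_event).any():
        raise ValueError("missing biomarker values; imputation is out of scope")
    stage_ll = stage_log_likelihoods(table, sequence)
    stages = np.argmax(stage_ll, axis=1)  # argmax returns first max -> smallest k
    frame = pd.DataFrame({
        "subject_id": table.subject_ids,
        "visit_months": 0 if visit_months is None else np.asarray(visit_months),
        "stage": stages,
    })
    return StageAssignments(frame, stage_ll)


def stage_subject(x_j, sequence, fits: dict, biomarker_names=None) -> int:
    """Stage a single complete biomarker vector; returns the stage."""
    if biomarker_names is None:
        biomarker_names = list(fits)
    x = np.asarray(x_j, dtype=float)
    if x.shape != (len(biomarker_names),) or np.isnan(x).any():
        raise ValueError("x_j must be a complete vector, one value per biomarker")
    values = pd.DataFrame([x], columns=biomarker_names, index=["subject"])
    matrix = BiomarkerMatrix(values, pd.Series(["?"], index=["subject"]))
    return int(stage_subjects(matrix, sequence, fits).table["stage"].iloc[0])


def stage_distribution(assignments: StageAssignments, groups: pd.Series,
                       n_stages: int | None = None,
                       lower_half_max: int | None = None) -> pd.DataFrame:
    """Per-group stage occupancy proportions plus a lower/upper-half split.

    ``lower_half_max`` is the largest stage counted as "lower half"
    (default floor(Z/2)).  Returns one row per group with columns
    ``stage_0..stage_Z``, ``lower_half``, ``upper_half``.
    """
    stages = assignments.table.set_index("subject_id")["stage"]
    groups = groups.reindex(stages.index)
    if groups.isna().any():
        missing = groups.index[groups.isna()].tolist()
        raise ValueError(f"no group label for subjects {missing[:5]}")
    z = n_stages if n_stages is not None else assignments.log_likelihood_by_stage.shape[1] - 1
    if lower_half_max is None:
        lower_half_max = z // 2
    rows = []
    for g, sub in stages.groupby(groups):
        props = np.bincount(sub.to_numpy(), minlength=z + 1) / len(sub)
        row = {"group": g, **{f"stage_{k}": props[k] for k in range(z + 1)}}
        row["lower_half"] = props[: lower_half_max + 1].sum()
        row["upper_half"] = props[lower_half_max + 1:].sum()
        rows.append(row)
    return pd.DataFrame(rows).set_index("group")


def bootstrap_pvd(matrix: BiomarkerMatrix, n_bootstrap: int = 100,
                  seed: int | None = None, n_restarts: int = 5,
                  mcmc_samples_per_resample: int = 0,
                  **em_kwargs) -> PositionalVarianceDiagram:
    """Cross-validated positional variance by bootstrap resampling.

    For each resample (subjects drawn with replacement, stratified by
    diagnosis so the distribution-fitting groups are never empty), the
    mixture models are refitted and the ordering re-estimated; the resample's
    PVD — the ML ordering's permutation matrix, or the PVD of a short MCMC
    chain when ``mcmc_samples_per_resample`` > 0 — is accumulated and the
    element-wise mean returned.
    """
    if n_bootstrap < 2:
        raise ValueError("n_bootstrap must be >= 2")
    rng = np.random.default_rng(seed)
    z = len(matrix.biomarker_names)
    acc = np.zeros((z, z))
    group_idx = {g: np.flatnonzero((matrix.diagnosis == g).to_numpy())
                 for g in matrix.diagnosis.unique()}
    for _ in range(n_bootstrap):
        take = np.concatenate([rng.choice(idx, size=len(idx), replace=True)
                               for idx in group_idx.values()])
        values = matrix.values.iloc[take].reset_index(drop=True)
        values.index = [f"b{i}" for i in range(len(values))]
        diag = pd.Series(matrix.diagnosis.iloc[take].to_numpy(), index=values.index)
        bmat = BiomarkerMatrix(values, diag)
        fits = fit_all_biomarkers(bmat, **em_kwargs)
        table = event_likelihoods(bmat, fits)
        order = find_ml_sequence(table, n_restarts=n_restarts,
                                 seed=int(rng.integers(2**31)))
        if mcmc_samples_per_resample > 0:
            trace = mcmc_sample(table, order, mcmc_samples_per_resample,
                                seed=int(rng.integers(2**31)))
            acc += positional_variance(trace).matrix
        else:
            perm = np.zeros((z, z))
            perm[order, np.arange(z)] = 1.0
            acc += perm
    return PositionalVarianceDiagram(acc / n_bootstrap, matrix.biomarker_names)


def longitudinal_consistency(assignments: StageAssignments) -> dict:
    """Compare each subject's follow-up stages with baseline.

    Returns the fraction of subjects whose final-visit stage is >= baseline,
    mean progression among progressors, mean |regression| among regressors,
    and per-visit (baseline, follow-up) stage pairs for plotting.
    """
    tab = assignments.table
    base = tab[tab["visit_months"] == 0].set_index("subject_id")["stage"]
    later = tab[tab["visit_months"] > 0]
    if later.empty or not later["subject_id"].isin(base.index).any():
        raise ValueError("no follow-up visits matched to baseline subjects")
    final = (later.sort_values("visit_months").groupby("subject_id")["stage"].last())
    common = base.index.intersection(final.index)
    delta = final[common] - base[common]
    progress = delta[delta > 0]
    regress = delta[delta < 0]
    per_visit = {
        int(m): sub.set_index("subject_id")["stage"].reindex(common).dropna()
        for m, sub in later.groupby("visit_months")
    }
    return {
        "n_subjects": int(len(common)),
        "fraction_non_regressing": float((delta >= 0).mean()),
        "mean_progression": float(progress.mean()) if len(progress) else 0.0,
        "n_progressors": int(len(progress)),
        "mean_regression": float(-regress.mean()) if len(regress) else 0.0,
        "n_regressors": int(len(regress)),
        "mean_stage_change": float(delta.mean()),
        "per_visit_stages": per_visit,
        "baseline_stages": base[common],
    }


@dataclass(frozen=True)
class ConversionResult:
    """Best stage threshold for predicting conversion and its operating
    point.  ``balanced_accuracy`` is exactly (sensitivity + specificity)/2."""

    threshold_stage: int
    sensitivity: float
    specificity: float

    @property
    def balanced_accuracy(self) -> float:
        return 0.5 * (self.sensitivity + self.specificity)


def predict_conversion(baseline_stages: pd.Series, converted: pd.Series,
                       n_stages: int) -> ConversionResult:
    """Sweep every stage threshold and keep the one maximising balanced
    accuracy (smallest threshold on ties).

    A subject is predicted to convert iff its baseline stage is strictly
    greater than the threshold.
    """
    conv = converted.reindex(baseline_stages.index).astype(bool)
    stages = baseline_stages.to_numpy()
    y = conv.to_numpy()
    if y.all() or not y.any():
        raise ValueError("need at least one converter and one non-converter")
    best = None
    for t in range(0, n_stages + 1):
        pred = stages > t
        sens = float((pred & y).sum() / y.sum())
        spec = float((~pred & ~y).sum() / (~y).sum())
        ba = 0.5 * (sens + spec)
        if best is None or ba > best_ba:  # strict '>' keeps the smallest t
            best, best_ba = ConversionResult(t, sens, spec), ba
    return best


def phenotype_regression(assignments: StageAssignments,
                         phenotypes: pd.DataFrame) -> pd.DataFrame:
    """OLS of each phenotype score on assigned stage.

    One row per phenotype column: slope, intercept, two-sided slope p-value,
    n.  Positive slope means the score worsens (rises) with stage.
    """
    stages = assignments.table.set_index("subject_id")["stage"]
    common = stages.index.intersection(phenotypes.index)
    if len(common) < 3:
        raise ValueError("need >= 3 paired stage/phenotype observations")
    s = stages[common].to_numpy(dtype=float)
    if np.ptp(s) == 0:
        raise ValueError("stage has zero variance; regression undefined")
    X = sm.add_constant(s)
    rows = []
    for name in phenotypes.columns:
        yv = phenotypes.loc[common, name].to_numpy(dtype=float)
        ok = ~np.isnan(yv)
        res = sm.OLS(yv[ok], X[ok]).fit()
        rows.append({
            "phenotype": name,
            "slope": float(res.params[1]),
            "intercept": float(res.params[0]),
            "p_value": float(res.pvalues[1]),
            "n": int(ok.sum()),
        })
    return pd.DataFrame(rows).set_index("phenotype")
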