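"""Model/Results surface tying the pipeline together.

``EventBasedModel`` is constructed from a prepared biomarker matrix (or a raw
cohort DataFrame via :meth:`EventBasedModel.from_dataframe`, which applies
covariate correction, optional selection, and outlier removal).  ``fit()``
fits the per-biomarker event distributions on controls and manifest patients,
infers the maximum-likelihood event ordering using all subjects, samples the
posterior over orderings by MCMC, and returns an :class:`EBMResults` carrying
the ordering, its positional uncertainty, the mixture parameters, and
staging / validation methods.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import prep as _prep
from . import staging as _staging
from .distributions import (EventDistributionFit, abnormality_threshold,
                            event_likelihoods, fit_all_biomarkers)
from .prep import BiomarkerMatrix, CovariateModel
from .sequence import (MCMCTrace, PositionalVarianceDiagram,
                       find_ml_sequence, mcmc_sample, positional_variance,
                       sequence_log_likelihood)

__all__ = ["EventBasedModel", "EBMResults"]

COVARIATE_COLS = ("age", "site", "tiv")
ID_COLS = ("subject_id", "visit_months", "diagnosis")


class EventBasedModel:
    """Event-based model of biomarker abnormality ordering.

    Parameters
    ----------
    matrix : BiomarkerMatrix
        Covariate-corrected baseline values with diagnosis labels containing
        at least the control and patient groups.
    control_label, patient_label : str
        Groups used to fit the normal / abnormal distributions.  All subjects
        in ``matrix`` (including premanifest carriers) inform the ordering.
    """

    def __init__(self, matrix: BiomarkerMatrix, control_label: str = "HC",
                 patient_label: str = "HD"):
        self.matrix = matrix
        self.control_label = control_label
        self.patient_label = patient_label
        self.covariate_model: CovariateModel | None = None

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, biomarkers: list[str] | None = None,
                       correct: bool = True, fit_group: str = "HC",
                       select: bool = False, p_threshold: float = 0.001,
                       t_threshold: float = 8.0,
                       bilateral_map: dict[str, str] | None = None,
                       outlier_sigma: float | None = 5.0,
                       ) -> "EventBasedModel":
        """Build a model from a canonical cohort table.

        ``df`` needs ``subject_id``, ``diagnosis``, the covariate columns
        (when ``correct``) and one column per biomarker; only baseline rows
        (``visit_months == 0``, if present) enter the model.  Preparation
        order: covariate correction, then selection, then outlier removal.
        """
        if "visit_months" in df.columns:
            df = df[df["visit_months"] == 0]
        df = df.set_index("subject_id") if "subject_id" in df.columns else df
        if biomarkers is None:
            from .simulate import PHENOTYPES
            skip = set(ID_COLS) | set(COVARIATE_COLS) | set(PHENOTYPES) | {"converter"}
            biomarkers = [c for c in df.columns
                          if c not in skip and pd.api.types.is_numeric_dtype(df[c])]
        diagnosis = df["diagnosis"]
        raw = df[biomarkers]
        if correct:
            matrix, cov_model = _prep.correct_covariates(
                raw, df[list(COVARIATE_COLS)], diagnosis, fit_group=fit_group)
        else:
            matrix, cov_model = BiomarkerMatrix(raw.copy(), diagnosis.copy()), None
        if select:
            report = _prep.select_biomarkers(matrix, p_threshold, t_threshold,
                                             bilateral_map)
            matrix = matrix.select(report.selected)
        if outlier_sigma is not None:
            matrix, _ = _prep.remove_outliers(matrix, n_sigma=outlier_sigma)
        obj = cls(matrix)
        obj.covariate_model = cov_model
        return obj

    def fit(self, n_restarts: int = 10, mcmc_samples: int = 100_000,
            mcmc_burn_in: int = 10_000, seed: int | None = None,
            **em_kwargs) -> "EBMResults":
        """Fit distributions, find the ML ordering, sample the posterior."""
        rng = np.random.default_rng(seed)
        fits = fit_all_biomarkers(self.matrix, self.control_label,
                                  self.patient_label, **em_kwargs)
        table = event_likelihoods(self.matrix, fits)
        order = find_ml_sequence(table, n_restarts=n_restarts,
                                 seed=int(rng.integers(2**31)))
        trace = None
        pvd = None
        if mcmc_samples > 0:
            trace = mcmc_sample(table, order, mcmc_samples, mcmc_burn_in,
                                seed=int(rng.integers(2**31)))
            best = trace.ml_sample
            if (sequence_log_likelihood(table, best)
                    > sequence_log_likelihood(table, order)):
                order = best.copy()
            pvd = positional_variance(trace, self.matrix.biomarker_names)
        return EBMResults(self, fits, table, np.asarray(order), trace, pvd, seed)


@dataclass
class EBMResults:
    """Fitted event-based model: ordering, uncertainty, staging."""

    model: EventBasedModel
    fits: dict[str, EventDistributionFit]
    likelihood_table: object
    ml_sequence: np.ndarray
    trace: MCMCTrace | None
    pvd: PositionalVarianceDiagram | None
    seed: int | None = None

    @property
    def biomarker_names(self) -> list[str]:
        return self.model.matrix.biomarker_names

    @property
    def n_events(self) -> int:
        return len(self.ml_sequence)

    @property
    def ordered_biomarkers(self) -> list[str]:
        names = self.biomarker_names
        return [names[i] for i in self.ml_sequence]

    @property
    def log_likelihood(self) -> float:
        return sequence_log_likelihood(self.likelihood_table, self.ml_sequence)

    def fit_table(self) -> pd.DataFrame:
        """Per-biomarker mixture parameters and abnormality threshold."""
        rows = []
        for name in self.biomarker_names:
            f = self.fits[name]
            rows.append({
                "biomarker": name,
                "normal_mean": f.normal.mean, "normal_sd": f.normal.sd,
                "abnormal_mean": f.abnormal.mean, "abnormal_sd": f.abnormal.sd,
                "weight": f.mixing_weight,
                "threshold": abnormality_threshold(f),
                "converged": f.converged,
            })
        return pd.DataFrame(rows).set_index("biomarker")

    def stage(self, matrix: BiomarkerMatrix | None = None,
              visit_months=None) -> _staging.StageAssignments:
        """Stage the model's own subjects, or new (already corrected) data."""
        if matrix is None:
            return _staging.stage_subjects(self.likelihood_table, self.ml_sequence)
        return _staging.stage_subjects(matrix, self.ml_sequence, self.fits,
                                       visit_months=visit_months)

    def stage_cohort(self, df: pd.DataFrame) -> _staging.StageAssignments:
        """Stage every subject-visit of a raw cohort table, reusing the
        baseline covariate model (follow-ups are corrected with the
        baseline-fitted coefficients, not refitted)."""
        if self.model.covariate_model is None:
            raise ValueError("model was built without covariate correction; "
                             "pass a prepared BiomarkerMatrix to .stage()")
        df = df.reset_index() if df.index.name == "subject_id" else df
        names = self.biomarker_names
        matrix = self.model.covariate_model.transform(
            df.set_index("subject_id")[names],
            df.set_index("subject_id")[list(COVARIATE_COLS)],
            df.set_index("subject_id")["diagnosis"],
        )
        visit = df["visit_months"].to_numpy() if "visit_months" in df.columns else None
        return _staging.stage_subjects(matrix, self.ml_sequence, self.fits,
                                       visit_months=visit)

    def bootstrap_pvd(self, n_bootstrap: int = 100, seed: int | None = None,
                      **kwargs) -> PositionalVarianceDiagram:
        return _staging.bootstrap_pvd(self.model.matrix, n_bootstrap=n_bootstrap,
                                      seed=seed, **kwargs)

    def positional_sd(self) -> pd.Series:
        """Posterior SD of each biomarker's sequence position (needs MCMC)."""
        if self.trace is None:
            raise ValueError("no MCMC trace; fit with mcmc_samples > 0")
        pos = np.empty_like(self.trace.samples)
        n, z = self.trace.samples.shape
        pos[np.arange(n)[:, None], self.trace.samples] = np.arange(z)[None, :]
        return pd.Series(pos.std(axis=0), index=self.biomarker_names)

    def plot_positional_variance(self, ax=None):
        if self.pvd is None:
            raise ValueError("no PVD available; fit with mcmc_samples > 0")
        return self.pvd.plot(sequence=self.ml_sequence, ax=ax)

    def summary(self) -> str:
        """Human-readable fit summary: ordering with positional uncertainty
        and the mixture parameters per biomarker."""
        lines = [
            "Event-Based Model Results",
            "=" * 68,
            f"Subjects: {len(self.model.matrix.subject_ids)}    "
            f"Events: {self.n_events}    "
            f"Log-likelihood: {self.log_likelihood:.2f}",
        ]
        if self.trace is not None:
            lines.append(f"MCMC samples: {len(self.trace.samples)}    "
                         f"acceptance rate: {self.trace.acceptance_rate:.3f}")
        lines.append("-" * 68)
        lines.append(f"{'pos':>3}  {'biomarker':<22}{'abn. mean':>10}"
                     f"{'abn. sd':>9}{'weight':>8}{'pos. sd':>9}")
        pos_sd = self.positional_sd() if self.trace is not None else None
        names = self.biomarker_names
        for p, i in enumerate(self.ml_sequence, start=1):
            f = self.fits[names[i]]
            sd_txt = f"{pos_sd[names[i]]:>9.2f}" if pos_sd is not None else f"{'--':>9}"
            lines.append(f"{p:>3}  {names[i]:<22}{f.abnormal.mean:>10.3f}"
                         f"{f.abnormal.sd:>9.3f}{f.mixing_weight:>8.2f}{sd_txt}")
        lines.append("=" * 68)
        return "\n".join(lines)
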