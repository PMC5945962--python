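"""Covariate correction, data-driven biomarker selection, and outlier removal.

Raw regional volumes are confounded by age, head size (total intracranial
volume, TIV) and acquisition site.  Preparation regresses these out with OLS
— by default the regression is fitted on healthy controls only and applied to
everyone, so control residuals are centred at zero and disease effects cannot
leak into the covariate coefficients — then keeps only biomarkers that
strongly separate controls from manifest patients, and drops subjects with
extreme values.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "BiomarkerMatrix",
    "CovariateModel",
    "SelectionReport",
    "correct_covariates",
    "select_biomarkers",
    "remove_outliers",
    "volumetric_summary",
]


@dataclass
class BiomarkerMatrix:
    """Covariate-corrected residual volumes for a set of subjects.

    ``values`` is indexed by subject id with one column per biomarker;
    ``diagnosis`` is aligned to the same index.
    """

    values: pd.DataFrame
    diagnosis: pd.Series

    def __post_init__(self) -> None:
        if not self.values.index.equals(self.diagnosis.index):
            self.diagnosis = self.diagnosis.reindex(self.values.index)
        if self.values.isna().any().any():
            raise ValueError("BiomarkerMatrix must have no missing values")

    @property
    def biomarker_names(self) -> list[str]:
        return list(self.values.columns)

    @property
    def subject_ids(self) -> list:
        return list(self.values.index)

    def group(self, label: str) -> pd.DataFrame:
        return self.values[self.diagnosis == label]

    def select(self, names: list[str]) -> "BiomarkerMatrix":
        return BiomarkerMatrix(self.values[names].copy(), self.diagnosis.copy())


def _design_matrix(covariates: pd.DataFrame) -> tuple[np.ndarray, list[str]]:
    """Intercept + centred age/TIV + reference-coded site dummies."""
    cols: list[str] = ["intercept"]
    parts = [np.ones(len(covariates))]
    for cont in ("age", "tiv"):
        x = pd.to_numeric(covariates[cont], errors="raise").to_numpy(dtype=float)
        parts.append(x)
        cols.append(cont)
    site = covariates["site"].astype(str)
    levels = sorted(site.unique())
    for lev in levels[1:]:  # first level (lexicographic) is the reference
        parts.append((site == lev).to_numpy(dtype=float))
        cols.append(f"site[{lev}]")
    return np.column_stack(parts), cols


@dataclass
class CovariateModel:
    """Fitted OLS correction, reusable on follow-up visits.

    ``coefficients`` has one column per biomarker, rows indexed by design
    column (intercept, age, tiv, site dummies).
    """

    coefficients: pd.DataFrame
    fit_group: str

    def transform(self, raw: pd.DataFrame, covariates: pd.DataFrame,
                  diagnosis: pd.Series) -> BiomarkerMatrix:
        X, cols = _design_matrix(covariates)
        beta = self.coefficients.reindex(cols)
        if beta.isna().any().any():
            missing = beta.index[beta.isna().any(axis=1)].tolist()
            raise ValueError(f"covariate model lacks coefficients for {missing} "
                             "(e.g. an unseen site level)")
        fitted = X @ beta.to_numpy()
        resid = raw[self.coefficients.columns].to_numpy(dtype=float) - fitted
        values = pd.DataFrame(resid, index=raw.index, columns=self.coefficients.columns)
        return BiomarkerMatrix(values, diagnosis)


def correct_covariates(raw: pd.DataFrame, covariates: pd.DataFrame,
                       diagnosis: pd.Series, fit_group: str = "HC",
                       ) -> tuple[BiomarkerMatrix, CovariateModel]:
    """Regress age, site and TIV out of every biomarker.

    Parameters
    ----------
    raw : DataFrame, subjects x biomarkers, raw volumes.
    covariates : DataFrame with columns ``age``, ``site``, ``tiv``.
    diagnosis : Series of group labels aligned to ``raw``.
    fit_group : diagnosis group the regression is fitted on (``"all"`` to fit
        on every subject).  The default anchors control residuals at zero.

    Returns the residual matrix (subject order preserved) and the fitted
    model, which can be re-applied to follow-up visits.
    """
    if covariates[["age", "tiv"]].isna().any().any() or covariates["site"].isna().any():
        raise ValueError("missing covariate values are not allowed")
    for cont in ("age", "tiv"):
        if covariates[cont].nunique() < 2:
            raise ValueError(f"covariate {cont!r} needs >= 2 distinct values")

    X, cols = _design_matrix(covariates)
    if fit_group == "all":
        fit_mask = np.ones(len(raw), dtype=bool)
    else:
        fit_mask = (diagnosis == fit_group).to_numpy()
        if fit_mask.sum() < X.shape[1]:
            raise ValueError(f"too few {fit_group!r} subjects to fit the covariate model")
    Xf = X[fit_mask]
    rank = np.linalg.matrix_rank(Xf)
    if rank < Xf.shape[1]:
        bad = _collinear_columns(Xf, cols)
        raise ValueError(f"rank-deficient covariate design; collinear columns: {bad}")
    Y = raw.to_numpy(dtype=float)[fit_mask]
    beta, *_ = np.linalg.lstsq(Xf, Y, rcond=None)
    coefficients = pd.DataFrame(beta, index=cols, columns=raw.columns)
    model = CovariateModel(coefficients, fit_group)
    return model.transform(raw, covariates, diagnosis), model


def _collinear_columns(X: np.ndarray, cols: list[str]) -> list[str]:
    """Name design columns involved in a rank deficiency (QR pivot heuristic)."""
    kept: list[int] = []
    bad: list[str] = []
    for j in range(X.shape[1]):
        trial = X[:, kept + [j]]
        if np.linalg.matrix_rank(trial) == len(kept) + 1:
            kept.append(j)
        else:
            bad.append(cols[j])
    return bad


@dataclass
class SelectionReport:
    """Per-biomarker t-test results and the selection decision."""

    table: pd.DataFrame  # biomarker, t, p_raw, p_corrected, selected, reason
    p_threshold: float
    t_threshold: float

    @property
    def selected(self) -> list[str]:
        return self.table.loc[self.table["selected"], "biomarker"].tolist()


def select_biomarkers(matrix: BiomarkerMatrix, p_threshold: float = 0.001,
                      t_threshold: float = 8.0,
                      bilateral_map: dict[str, str] | None = None,
                      correction: str = "bonferroni") -> SelectionReport:
    """Keep biomarkers that strongly separate controls from manifest patients.

    A biomarker passes if its Welch two-tailed t-test (HC vs HD) survives the
    multiplicity correction at ``p_threshold`` and has effect size
    ``|t| > t_threshold``.  A left/right bilateral pair is kept only if both
    sides pass; if either fails, both are dropped.
    """
    hc = matrix.group("HC")
    hd = matrix.group("HD")
    if len(hc) < 3 or len(hd) < 3:
        raise ValueError("need >= 3 subjects in both HC and HD groups")

    t, p = stats.ttest_ind(hc.to_numpy(), hd.to_numpy(), equal_var=False, axis=0)
    _, p_corr, *_ = multipletests(p, method=correction)
    passes = (p_corr < p_threshold) & (np.abs(t) > t_threshold)
    names = matrix.biomarker_names
    reason = []
    for i in range(len(names)):
        if p_corr[i] >= p_threshold:
            reason.append("corrected p above threshold")
        elif abs(t[i]) <= t_threshold:
            reason.append("|t| below threshold")
        else:
            reason.append("")
    reason = np.array(reason, dtype=object)

    selected = passes.copy()
    if bilateral_map:
        for left, right in bilateral_map.items():
            for side in (left, right):
                if side not in names:
                    raise ValueError(f"bilateral_map names unknown biomarker {side!r}")
            li, ri = names.index(left), names.index(right)
            if not (passes[li] and passes[ri]):
                for i, j in ((li, ri), (ri, li)):
                    if passes[i]:
                        selected[i] = False
                        reason[i] = f"contralateral {names[j]!r} failed"
    table = pd.DataFrame({
        "biomarker": names,
        "t": t,
        "p_raw": p,
        "p_corrected": p_corr,
        "selected": selected,
        "reason": np.where(selected, "", reason),
    })
    return SelectionReport(table, p_threshold, t_threshold)


def remove_outliers(matrix: BiomarkerMatrix, n_sigma: float = 5.0,
                    ) -> tuple[BiomarkerMatrix, pd.DataFrame]:
    """Drop whole subjects with any biomarker beyond ``n_sigma`` within-group SDs.

    Group statistics (mean, SD per diagnosis group) are computed once on the
    input, so removal is idempotent on its own output under those frozen
    statistics.  Returns the filtered matrix and a log of
    (subject_id, biomarker, z) for every offending cell.
    """
    values = matrix.values
    records = []
    drop: set = set()
    for g in matrix.diagnosis.unique():
        sub = values[matrix.diagnosis == g]
        mu = sub.mean(axis=0)
        sd = sub.std(axis=0, ddof=1)
        if (sd <= 0).any():
            bad = sd.index[sd <= 0].tolist()
            raise ValueError(f"zero within-group SD in group {g!r} for {bad}")
        z = (sub - mu) / sd
        mask = z.abs() > n_sigma
        for sid in sub.index[mask.any(axis=1)]:
            drop.add(sid)
            for bm in values.columns[mask.loc[sid]]:
                records.append({"subject_id": sid, "biomarker": bm,
                                "group": g, "z": z.loc[sid, bm]})
    log = pd.DataFrame(records, columns=["subject_id", "biomarker", "group", "z"])
    keep = [s for s in values.index if s not in drop]
    if not keep:
        import warnings
        warnings.warn("outlier removal excluded every subject", stacklevel=2)
    out = BiomarkerMatrix(values.loc[keep].copy(), matrix.diagnosis.loc[keep].copy())
    return out, log


def volumetric_summary(matrix: BiomarkerMatrix, fits: dict,
                       control_raw_means: pd.Series) -> pd.DataFrame:
    """Percent volume change per biomarker, region-based-analysis style.

    Reports the HD residual mean as a percentage of the HC raw-volume mean,
    and the equal-likelihood abnormality threshold (where the normal and
    abnormal densities cross) on the same percentage scale.  Thresholds are
    descriptive only — the event-based model itself never uses cut points.
    """
    from .distributions import abnormality_threshold

    hd = matrix.group("HD")
    rows = []
    for name in matrix.biomarker_names:
        base = control_raw_means[name]
        row = {"biomarker": name}
        if base == 0:
            row["error"] = "HC raw mean is zero"
            row["hd_mean_pct_change"] = np.nan
            row["threshold_pct_change"] = np.nan
        else:
            row["error"] = ""
            row["hd_mean_pct_change"] = 100.0 * hd[name].mean() / base
            row["threshold_pct_change"] = 100.0 * abnormality_threshold(fits[name]) / base
        rows.append(row)
    return pd.DataFrame(rows)
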