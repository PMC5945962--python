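"""Synthetic cohorts with the generative structure the event-based model assumes.

The event-based model (EBM) treats disease progression as a fixed ordering of
"events" — transitions of individual biomarkers from a normal to an abnormal
distribution — and places every subject at a stage ``k``: the first ``k``
events of the sequence have occurred, the rest have not.  The generator here
produces cross-sectional (and optionally longitudinal) cohorts that satisfy
exactly those assumptions: each subject has a latent true stage, biomarkers at
positions ``1..k`` of the planted sequence are drawn from their abnormal
component, positions ``k+1..Z`` from the normal component, and linear age /
site / total-intracranial-volume (TIV) confounds are added on the raw scale.

Group structure mirrors a three-arm observational neuroimaging study: healthy
controls (HC), premanifest gene carriers (preHD) spread across the whole stage
range, and manifest patients (HD) concentrated at late stages.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "CohortConfig",
    "SyntheticCohort",
    "generate_cohort",
    "generate_longitudinal",
    "generate_phenotypes",
    "default_biomarker_names",
    "DIAGNOSES",
    "PHENOTYPES",
]

DIAGNOSES = ("HC", "preHD", "HD")
SITES = ("leiden", "london", "paris", "vancouver")

#: phenotype -> (intercept, slope per stage, noise SD); signs follow clinical
#: convention: motor score (TMS) and genetic burden (CAP) worsen upward,
#: cognitive scores (SDMT, Stroop) worsen downward.
PHENOTYPES: dict[str, tuple[float, float, float]] = {
    "TMS": (4.0, 0.98, 5.0),
    "SDMT": (50.0, -1.0, 8.0),
    "Stroop": (110.0, -1.4, 12.0),
    "CAP": (0.80, 0.014, 0.10),
}

# Age / TIV distributions per diagnosis group (mean, SD), volume-study-like.
_AGE_DIST = {"HC": (46.3, 10.2), "preHD": (40.8, 8.8), "HD": (48.5, 9.9)}
_TIV_DIST = {"HC": (1392.0, 136.0), "preHD": (1408.0, 151.0), "HD": (1362.0, 130.0)}

# Fixed sub-stream indices so adding one output never perturbs another.
_STREAMS = {"covariates": 0, "stages": 1, "biomarkers": 2, "longitudinal": 3, "phenotypes": 4}


def default_biomarker_names(n: int = 18) -> list[str]:
    """Region-volume-style names for the default 18 events.

    Seven bilateral subcortical/cortical regions, three midline volumes, and a
    ventricular-CSF event.  For other ``n`` the list is truncated or padded
    with generic ``region_k`` names.
    """
    base = [
        "putamen_l", "putamen_r",
        "caudate_l", "caudate_r",
        "pallidum_l", "pallidum_r",
        "insula_wm_l", "insula_wm_r",
        "csf",
        "amygdala_l", "amygdala_r",
        "optic_chiasm",
        "third_ventricle",
        "posterior_insula_l", "posterior_insula_r",
        "basal_forebrain_l", "basal_forebrain_r",
        "ventricular_csf",
    ]
    if n <= len(base):
        return base[:n]
    return base + [f"region_{k}" for k in range(len(base), n)]


def _default_abnormal_shift(names: list[str]) -> np.ndarray:
    """Signed shift of the abnormal mean, in control-SD units.

    Tissue volumes shrink (negative); CSF spaces and ventricles expand
    (positive).  Earlier default-sequence events get larger magnitudes so a
    cohort spanning all stages separates groups strongly.
    """
    z = len(names)
    mags = np.linspace(4.0, 2.5, z)
    signs = np.array([+1.0 if ("csf" in n or "ventricle" in n) else -1.0 for n in names])
    return signs * mags


def _geometric_occupancy(z: int, p: float, reverse: bool = False) -> np.ndarray:
    w = p * (1 - p) ** np.arange(z + 1)
    w /= w.sum()
    return w[::-1].copy() if reverse else w


def _default_stage_occupancy(z: int) -> dict[str, np.ndarray]:
    """HC piled at stage 0 with a geometric tail; preHD uniform across all
    stages; HD weighted toward the final stages (reversed geometric)."""
    return {
        "HC": _geometric_occupancy(z, 0.7),
        "preHD": np.full(z + 1, 1.0 / (z + 1)),
        "HD": _geometric_occupancy(z, 0.25, reverse=True),
    }


@dataclass
class CohortConfig:
    """Everything needed to generate a cohort reproducibly.

    ``abnormal_shift`` and ``abnormal_sds`` are expressed in control-SD units
    (an abnormal SD of 1.2 means 1.2x the control SD of that biomarker).
    ``covariate_effects`` maps 'age'/'tiv' to per-biomarker slopes on the
    centred covariate and 'site' to a (4, Z) array of additive offsets.
    ``stage_occupancy`` maps diagnosis group to a length Z+1 probability
    vector over true stages.
    """

    n_control: int = 119
    n_premanifest: int = 120
    n_manifest: int = 118
    n_biomarkers: int = 18
    planted_sequence: np.ndarray | None = None
    biomarker_names: list[str] | None = None
    control_means: np.ndarray | None = None
    control_sds: np.ndarray | None = None
    abnormal_shift: np.ndarray | None = None
    abnormal_sds: np.ndarray | None = None
    covariate_effects: dict[str, np.ndarray] | None = None
    stage_occupancy: dict[str, np.ndarray] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        z = int(self.n_biomarkers)
        if z < 2:
            raise ValueError("n_biomarkers must be >= 2")
        for name in ("n_control", "n_premanifest", "n_manifest"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.biomarker_names is None:
            self.biomarker_names = default_biomarker_names(z)
        if len(self.biomarker_names) != z:
            raise ValueError("biomarker_names length must equal n_biomarkers")
        if self.planted_sequence is None:
            self.planted_sequence = np.arange(z)
        self.planted_sequence = np.asarray(self.planted_sequence, dtype=int)
        if sorted(self.planted_sequence.tolist()) != list(range(z)):
            raise ValueError("planted_sequence must be a permutation of 0..Z-1")
        if self.control_means is None:
            # volume-like magnitudes (mL), spread over a realistic range
            self.control_means = np.linspace(4.0, 1.0, z)
        if self.control_sds is None:
            self.control_sds = 0.1 * np.asarray(self.control_means, dtype=float)
        self.control_means = np.asarray(self.control_means, dtype=float)
        self.control_sds = np.asarray(self.control_sds, dtype=float)
        if np.any(self.control_sds <= 0):
            raise ValueError("control_sds must be positive")
        if self.abnormal_shift is None:
            self.abnormal_shift = _default_abnormal_shift(self.biomarker_names)
        self.abnormal_shift = np.asarray(self.abnormal_shift, dtype=float)
        if self.abnormal_sds is None:
            # abnormal spread is typically wider than control, except regions
            # (e.g. basal forebrain) where the patient distribution narrows
            sds = np.full(z, 1.2)
            for i, n in enumerate(self.biomarker_names):
                if "basal_forebrain" in n:
                    sds[i] = 0.8
            self.abnormal_sds = sds
        self.abnormal_sds = np.asarray(self.abnormal_sds, dtype=float)
        if np.any(self.abnormal_sds <= 0):
            raise ValueError("abnormal_sds must be positive")
        for arr_name in ("control_means", "control_sds", "abnormal_shift", "abnormal_sds"):
            if len(getattr(self, arr_name)) != z:
                raise ValueError(f"{arr_name} must have length n_biomarkers")
        if self.covariate_effects is None:
            means = self.control_means
            self.covariate_effects = {
                "age": -0.003 * means,          # per year of (centred) age
                "tiv": 0.0005 * means,          # per mL of (centred) TIV
                "site": np.outer([0.02, -0.01, 0.0, -0.02], means),
            }
        site_fx = np.asarray(self.covariate_effects["site"], dtype=float)
        if site_fx.shape != (len(SITES), z):
            raise ValueError(f"site effects must have shape {(len(SITES), z)}")
        if self.stage_occupancy is None:
            self.stage_occupancy = _default_stage_occupancy(z)
        for group, occ in self.stage_occupancy.items():
            occ = np.asarray(occ, dtype=float)
            if occ.shape != (z + 1,) or not np.isclose(occ.sum(), 1.0):
                raise ValueError(f"stage_occupancy[{group!r}] must be a length Z+1 distribution")
            self.stage_occupancy[group] = occ

    @property
    def n_subjects(self) -> int:
        return self.n_control + self.n_premanifest + self.n_manifest


@dataclass
class SyntheticCohort:
    """A generated cohort in canonical long format.

    ``data`` has one row per subject-visit with columns ``subject_id,
    visit_months, diagnosis, age, site, tiv`` then one column per biomarker,
    plus any phenotype / converter columns added later.  ``truth`` carries the
    latent stage per subject-visit; ``planted_sequence`` is the ground-truth
    event ordering.
    """

    data: pd.DataFrame
    truth: pd.DataFrame
    planted_sequence: np.ndarray
    biomarker_names: list[str]
    config: CohortConfig

    @property
    def baseline(self) -> pd.DataFrame:
        return self.data[self.data["visit_months"] == 0]

    def to_csv(self, cohort_path, truth_path=None) -> None:
        """Write the cohort CSV and, optionally, the ground-truth sidecar
        (true stages, with the planted sequence as a header comment)."""
        self.data.to_csv(cohort_path, index=False)
        if truth_path is not None:
            buf = _io.StringIO()
            buf.write("# planted_sequence: " + ",".join(map(str, self.planted_sequence)) + "\n")
            self.truth.to_csv(buf, index=False)
            with open(truth_path, "w") as fh:
                fh.write(buf.getvalue())


def _rng(config: CohortConfig, stream: str) -> np.random.Generator:
    return np.random.default_rng([int(config.seed), _STREAMS[stream]])


def _draw_biomarkers(config: CohortConfig, stages: np.ndarray,
                     rng: np.random.Generator) -> np.ndarray:
    """Stage-conditional draws on the standardised scale, one row per subject."""
    z = config.n_biomarkers
    n = len(stages)
    # event_rank[i] = position of biomarker i in the planted sequence (1-based)
    event_rank = np.empty(z, dtype=int)
    event_rank[config.planted_sequence] = np.arange(1, z + 1)
    abnormal = event_rank[None, :] <= stages[:, None]
    zscores = rng.standard_normal((n, z))
    values = np.where(
        abnormal,
        config.abnormal_shift[None, :] + config.abnormal_sds[None, :] * zscores,
        zscores,
    )
    return values


def generate_cohort(config: CohortConfig) -> SyntheticCohort:
    """Generate a cross-sectional baseline cohort.

    Raw (uncorrected) biomarker values are
    ``control_mean + control_sd * stage-conditional draw + covariate terms``,
    with covariate terms linear in centred age and TIV plus a site offset.
    Bitwise reproducible for a given config: each output block (covariates,
    stages, biomarker noise) uses its own seeded stream.
    """
    z = config.n_biomarkers
    groups = (
        ["HC"] * config.n_control
        + ["preHD"] * config.n_premanifest
        + ["HD"] * config.n_manifest
    )
    n = len(groups)
    diagnosis = pd.Series(groups, name="diagnosis")

    rng_cov = _rng(config, "covariates")
    age = np.empty(n)
    tiv = np.empty(n)
    for g in DIAGNOSES:
        mask = diagnosis.to_numpy() == g
        age[mask] = rng_cov.normal(*_AGE_DIST[g], size=mask.sum())
        tiv[mask] = rng_cov.normal(*_TIV_DIST[g], size=mask.sum())
    site_idx = rng_cov.integers(0, len(SITES), size=n)

    rng_stage = _rng(config, "stages")
    stages = np.empty(n, dtype=int)
    for g in DIAGNOSES:
        mask = diagnosis.to_numpy() == g
        occ = config.stage_occupancy[g]
        stages[mask] = rng_stage.choice(z + 1, size=mask.sum(), p=occ)

    rng_bio = _rng(config, "biomarkers")
    std_values = _draw_biomarkers(config, stages, rng_bio)
    raw = config.control_means[None, :] + config.control_sds[None, :] * std_values
    raw = raw + np.outer(age - age.mean(), np.ones(z)) * config.covariate_effects["age"][None, :]
    raw = raw + np.outer(tiv - tiv.mean(), np.ones(z)) * config.covariate_effects["tiv"][None, :]
    raw = raw + np.asarray(config.covariate_effects["site"])[site_idx, :]

    subject_ids = [f"S{i:04d}" for i in range(n)]
    data = pd.DataFrame({
        "subject_id": subject_ids,
        "visit_months": 0,
        "diagnosis": groups,
        "age": age,
        "site": [SITES[i] for i in site_idx],
        "tiv": tiv,
    })
    for j, name in enumerate(config.biomarker_names):
        data[name] = raw[:, j]
    truth = pd.DataFrame({
        "subject_id": subject_ids,
        "visit_months": 0,
        "true_stage": stages,
    })
    return SyntheticCohort(data, truth, config.planted_sequence.copy(),
                           list(config.biomarker_names), config)


def generate_longitudinal(cohort: SyntheticCohort, n_visits: int,
                          stages_per_year: float,
                          groups: tuple[str, ...] = ("preHD", "HD"),
                          visit_interval_months: float = 12.0) -> SyntheticCohort:
    """Append follow-up visits with monotone stage advance.

    Each follow-up advances a subject's latent stage by a Poisson increment
    with mean ``stages_per_year * interval_years``, truncated at Z; controls
    (or any group not in ``groups``) keep their baseline stage.  Biomarkers are
    re-drawn at the visit's stage; age advances, site and TIV stay fixed.
    """
    if n_visits < 2:
        raise ValueError("n_visits must be >= 2 (baseline plus followups)")
    if stages_per_year < 0:
        raise ValueError("stages_per_year must be non-negative")
    config = cohort.config
    z = config.n_biomarkers
    rng = _rng(config, "longitudinal")

    base = cohort.baseline.reset_index(drop=True)
    base_truth = cohort.truth[cohort.truth["visit_months"] == 0].reset_index(drop=True)
    advance_mask = base["diagnosis"].isin(groups).to_numpy()
    dt_years = visit_interval_months / 12.0

    frames = [base]
    truth_frames = [base_truth]
    stages = base_truth["true_stage"].to_numpy().copy()
    for v in range(1, n_visits):
        months = int(round(v * visit_interval_months))
        inc = rng.poisson(stages_per_year * dt_years, size=len(stages))
        stages = np.where(advance_mask, np.minimum(z, stages + inc), stages)
        std_values = _draw_biomarkers(config, stages, rng)
        raw = config.control_means[None, :] + config.control_sds[None, :] * std_values
        age_v = base["age"].to_numpy() + months / 12.0
        tiv_v = base["tiv"].to_numpy()
        site_idx = np.array([SITES.index(s) for s in base["site"]])
        raw = raw + np.outer(age_v - age_v.mean(), config.covariate_effects["age"])
        raw = raw + np.outer(tiv_v - tiv_v.mean(), config.covariate_effects["tiv"])
        raw = raw + np.asarray(config.covariate_effects["site"])[site_idx, :]
        visit = base[["subject_id", "diagnosis", "site"]].copy()
        visit.insert(1, "visit_months", months)
        visit.insert(3, "age", age_v)
        visit["tiv"] = tiv_v
        for j, name in enumerate(cohort.biomarker_names):
            visit[name] = raw[:, j]
        visit = visit[base.columns[: 6].tolist() + cohort.biomarker_names]
        frames.append(visit)
        truth_frames.append(pd.DataFrame({
            "subject_id": base["subject_id"],
            "visit_months": months,
            "true_stage": stages,
        }))
    data = pd.concat(frames, ignore_index=True)
    truth = pd.concat(truth_frames, ignore_index=True)
    return SyntheticCohort(data, truth, cohort.planted_sequence.copy(),
                           list(cohort.biomarker_names), config)


def generate_phenotypes(cohort: SyntheticCohort,
                        slopes: dict[str, float] | None = None,
                        noise_sd: dict[str, float] | None = None,
                        intercepts: dict[str, float] | None = None) -> SyntheticCohort:
    """Attach stage-linked phenotype scores.

    ``phenotype = intercept + slope * true_stage + N(0, noise_sd)`` per
    subject-visit.  Defaults plant motor/genetic markers increasing and
    cognitive markers decreasing with stage.
    """
    slopes = dict(slopes) if slopes is not None else {k: v[1] for k, v in PHENOTYPES.items()}
    for name in slopes:
        if name not in PHENOTYPES:
            raise ValueError(f"unknown phenotype {name!r}; known: {sorted(PHENOTYPES)}")
    noise_sd = dict(noise_sd) if noise_sd is not None else {k: PHENOTYPES[k][2] for k in slopes}
    intercepts = dict(intercepts) if intercepts is not None else {k: PHENOTYPES[k][0] for k in slopes}
    if any(sd < 0 for sd in noise_sd.values()):
        raise ValueError("noise_sd must be non-negative")

    rng = _rng(cohort.config, "phenotypes")
    merged = cohort.data.merge(cohort.truth, on=["subject_id", "visit_months"], how="left")
    stage = merged["true_stage"].to_numpy()
    data = cohort.data.copy()
    for name in slopes:
        data[name] = (intercepts[name] + slopes[name] * stage
                      + noise_sd[name] * rng.standard_normal(len(stage)))
    return replace(cohort, data=data)
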