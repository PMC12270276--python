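"""Synthetic study inputs with known ground truth.

Generates the four inputs the analysis consumes — a subject table, raw
metabolite peak-area panels (one per ion mode), band-limited 4D volumes,
and pathway annotations are left to the caller — with every plantable
effect controlled by :class:`CohortConfig`:

* a group shift in log microbe abundance (Cohen's d on the log scale),
* microbe -> metabolite loadings on designated index sets (positive and
  negative sign),
* metabolite -> imaging -> behavior mediation chains with explicit
  (a, b, c') path coefficients,
* linear covariate effects on every layer, so partial (not marginal)
  correlations are the correct recovery target,
* deliberately-failing metabolites for each QC filter, labeled in
  :class:`GroundTruth` so filter tests are exact set comparisons.

Effect-size defaults are chosen for test power, not biological realism.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .metabolome_qc import MetabolitePanel

__all__ = [
    "BEHAVIOR_COLUMNS",
    "MediationSpec",
    "CohortConfig",
    "GroundTruth",
    "simulate_subjects",
    "simulate_metabolite_panel",
    "simulate_volume4d",
    "simulate_cohort",
]

BEHAVIOR_COLUMNS = (
    "hamd", "hama", "bdi", "rsas", "rpas", "teps",
    "cpt_ip_2", "cpt_ip_3", "cpt_ip_4", "dst_forward", "dst_backward",
)

#: covariates whose standardized values feed linearly into each layer
_COVARIATES = ("age", "gender", "education", "site", "tiv", "fd")


@dataclass(frozen=True)
class MediationSpec:
    """One planted chain: metabolite X -> imaging feature M -> behavior Y.

    ``a`` is the effect of X on M, ``b`` of M on Y given X, ``c_prime`` the
    direct X->Y effect; the planted indirect effect is ``a * b``.
    """

    metabolite_idx: int
    imaging_idx: int
    behavior_idx: int
    a: float
    b: float
    c_prime: float


def _default_specs() -> list[MediationSpec]:
    return [
        MediationSpec(0, 0, 1, a=0.5, b=0.4, c_prime=0.1),
        MediationSpec(1, 1, 4, a=0.5, b=-0.4, c_prime=0.0),
        MediationSpec(10, 2, 7, a=-0.5, b=0.4, c_prime=0.0),
    ]


@dataclass
class CohortConfig:
    """All knobs of the generator; defaults give a well-powered cohort."""

    n_patients: int = 111
    n_controls: int = 102
    n_metabolites: int = 100
    microbe_group_shift: float = 0.8  # Cohen's d on log abundance
    planted_pos_idx: tuple = tuple(range(10))
    planted_neg_idx: tuple = tuple(range(10, 20))
    beta_metab: float = 0.8  # per-SD microbe effect on planted metabolites
    mediation_specs: list = field(default_factory=_default_specs)
    n_imaging_features: int = 5
    noise_sd: dict = field(default_factory=lambda: {
        "microbe": 1.0, "metabolite": 0.6, "imaging": 0.8, "behavior": 0.8,
    })
    covariate_effects: dict = field(default_factory=lambda: {
        "metabolite": {"age": 0.15, "gender": 0.1},
        "imaging": {"age": 0.2, "fd": 0.25, "site": 0.15},
        "behavior": {"age": 0.15, "education": -0.2},
        "microbe": {"age": 0.1},
    })
    n_qc: int = 8
    n_blank: int = 3
    zero_fraction: float = 0.02
    fail_blank_idx: tuple = (94, 95)
    fail_rsd_idx: tuple = (96, 97)
    fail_presence_idx: tuple = (98, 99)
    microbe_name: str = "microbe"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients <= 0 or self.n_controls <= 0:
            raise ValueError("subject counts must be positive")
        if self.n_metabolites <= 0:
            raise ValueError("n_metabolites must be positive")
        pos, neg = set(self.planted_pos_idx), set(self.planted_neg_idx)
        if pos & neg:
            raise ValueError("planted_pos_idx and planted_neg_idx must be disjoint")
        all_idx = (pos | neg | set(self.fail_blank_idx) | set(self.fail_rsd_idx)
                   | set(self.fail_presence_idx)
                   | {s.metabolite_idx for s in self.mediation_specs})
        if all_idx and (min(all_idx) < 0 or max(all_idx) >= self.n_metabolites):
            raise ValueError("metabolite index set out of range")
        for s in self.mediation_specs:
            if not 0 <= s.imaging_idx < self.n_imaging_features:
                raise ValueError("imaging feature index out of range")
            if not 0 <= s.behavior_idx < len(BEHAVIOR_COLUMNS):
                raise ValueError("behavior index out of range")
        if any(v < 0 for v in self.noise_sd.values()):
            raise ValueError("noise_sd values must be >= 0")

    @property
    def n_subjects(self) -> int:
        return self.n_patients + self.n_controls


@dataclass
class GroundTruth:
    """The realized configuration plus everything tests need to check
    recovery: planted column names, intended QC survivors, chain labels."""

    config: dict
    planted_pos_ids: list
    planted_neg_ids: list
    qc_fail_ids: dict  # filter name -> list of metabolite ids
    intended_survivor_ids: list
    imaging_columns: list
    latent_metabolite_columns: dict  # metabolite index (str) -> column name
    mediation_chains: list  # dicts with x/m/y column names and (a, b, c_prime)

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "GroundTruth":
        return cls(**json.loads(text))


def _covariate_design(rng: np.random.Generator, n: int) -> pd.DataFrame:
    age = rng.normal(40.0, 12.0, n)
    gender = rng.integers(0, 2, n)
    education = rng.integers(6, 19, n)
    site = rng.integers(0, 2, n)
    tiv = np.maximum(rng.normal(1450.0, 120.0, n), 1.0)
    fd = np.maximum(rng.normal(0.12, 0.04, n), 1e-3)
    return pd.DataFrame({
        "age": age, "gender": gender, "education": education,
        "site": site, "tiv": tiv, "fd": fd,
    })


def _z(v: np.ndarray) -> np.ndarray:
    sd = v.std(ddof=1)
    return (v - v.mean()) / sd if sd > 0 else v - v.mean()


def _cov_term(cov_z: dict, effects: dict) -> np.ndarray:
    """Linear combination of standardized covariates for one layer."""
    n = len(next(iter(cov_z.values())))
    out = np.zeros(n)
    for name, coef in effects.items():
        out += coef * cov_z[name]
    return out


def _metabolite_sign(config: CohortConfig) -> np.ndarray:
    sign = np.zeros(config.n_metabolites)
    sign[list(config.planted_pos_idx)] = 1.0
    sign[list(config.planted_neg_idx)] = -1.0
    return sign


def metabolite_ids(config: CohortConfig) -> list[str]:
    return [f"met{j:04d}" for j in range(config.n_metabolites)]


def simulate_subjects(config: CohortConfig) -> pd.DataFrame:
    """Subject table: group, covariates, behaviors, microbe relative
    abundance, imaging features, and hidden latent columns (underscore
    prefix) reused by :func:`simulate_metabolite_panel` so planted chains
    are exactly consistent across layers.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0]))
    n = config.n_subjects
    is_patient = np.concatenate([np.ones(config.n_patients),
                                 np.zeros(config.n_controls)])

    cov = _covariate_design(rng, n)
    cov_z = {c: _z(cov[c].to_numpy(dtype=float)) for c in _COVARIATES}
    eff = config.covariate_effects

    # microbe: log-normal abundance, additive log-scale group shift scaled so
    # the shift is microbe_group_shift residual SDs (Cohen's d on log scale)
    sd_mic = config.noise_sd["microbe"]
    log_abund = (
        -4.0
        + config.microbe_group_shift * sd_mic * is_patient
        + _cov_term(cov_z, eff.get("microbe", {}))
        + rng.normal(0.0, sd_mic, n)
    )
    raw = np.exp(log_abund)
    rel_abund = raw / (raw + 1.0)  # closed to (0, 1)
    microbe_z = _z(log_abund)

    # latent metabolites referenced by mediation chains, stored so the panel
    # generator reuses the exact same draws
    sign = _metabolite_sign(config)
    sd_met = config.noise_sd["metabolite"]
    latents: dict[int, np.ndarray] = {}
    for j in sorted({s.metabolite_idx for s in config.mediation_specs}):
        latents[j] = (
            sign[j] * config.beta_metab * microbe_z
            + _cov_term(cov_z, eff.get("metabolite", {}))
            + rng.normal(0.0, sd_met, n)
        )

    sd_img = config.noise_sd["imaging"]
    imaging = np.zeros((n, config.n_imaging_features))
    for k in range(config.n_imaging_features):
        signal = np.zeros(n)
        for s in config.mediation_specs:
            if s.imaging_idx == k:
                signal += s.a * latents[s.metabolite_idx]
        imaging[:, k] = (signal + _cov_term(cov_z, eff.get("imaging", {}))
                         + rng.normal(0.0, sd_img, n))

    sd_beh = config.noise_sd["behavior"]
    behaviors = np.zeros((n, len(BEHAVIOR_COLUMNS)))
    for i in range(len(BEHAVIOR_COLUMNS)):
        signal = np.zeros(n)
        for s in config.mediation_specs:
            if s.behavior_idx == i:
                signal += (s.b * imaging[:, s.imaging_idx]
                           + s.c_prime * latents[s.metabolite_idx])
        behaviors[:, i] = (signal + _cov_term(cov_z, eff.get("behavior", {}))
                           + rng.normal(0.0, sd_beh, n))

    table = pd.DataFrame({
        "subject_id": [f"S{i:04d}" for i in range(n)],
        "group": np.where(is_patient == 1, "patient", "control"),
    })
    table = pd.concat([table, cov], axis=1)
    table["bmi"] = rng.normal(23.0, 3.0, n)
    table["illness_duration"] = np.where(
        is_patient == 1, rng.exponential(24.0, n), 0.0)
    table["antidepressant_type"] = np.where(
        is_patient == 1, rng.choice(["ssri", "snri", "nassa"], n), "none")
    table[config.microbe_name] = rel_abund
    for i, b in enumerate(BEHAVIOR_COLUMNS):
        table[b] = behaviors[:, i]
    for k in range(config.n_imaging_features):
        table[f"img_{k}"] = imaging[:, k]
    table["_microbe_z"] = microbe_z
    for j, v in latents.items():
        table[f"_lat_met{j:04d}"] = v
    return table.set_index("subject_id")


def simulate_metabolite_panel(
    config: CohortConfig,
    subjects: pd.DataFrame,
    ion_mode: str = "positive",
) -> MetabolitePanel:
    """Raw peak-area panel with planted microbe loadings and labeled
    QC-filter failures.

    Metabolite j's latent value is ``sign_j * beta_metab * microbe_z`` plus
    covariate effects and noise (latents already drawn in the subject table
    are reused); areas are the exponential of a per-metabolite baseline
    plus the latent.  QC replicates are the pooled sample mean with a small
    log-normal CV, blanks sit a factor ~20 below QC (factor 2 for the
    blank-ratio failures).
    """
    if "_microbe_z" not in subjects.columns:
        raise ValueError("subject table was not produced by simulate_subjects")
    mode_key = 1 if ion_mode == "positive" else 2
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, mode_key]))
    n = len(subjects)
    p = config.n_metabolites
    ids = metabolite_ids(config)
    microbe_z = subjects["_microbe_z"].to_numpy(dtype=float)
    cov_z = {c: _z(subjects[c].to_numpy(dtype=float)) for c in _COVARIATES}
    cov_term = _cov_term(cov_z, config.covariate_effects.get("metabolite", {}))
    sign = _metabolite_sign(config)
    sd_met = config.noise_sd["metabolite"]

    latent = np.empty((n, p))
    for j in range(p):
        stored = f"_lat_met{j:04d}"
        if stored in subjects.columns:
            latent[:, j] = subjects[stored].to_numpy(dtype=float)
        else:
            latent[:, j] = (sign[j] * config.beta_metab * microbe_z + cov_term
                            + rng.normal(0.0, sd_met, n))

    base = rng.uniform(np.log(1e5), np.log(1e7), p)
    areas = np.exp(base[None, :] + 0.5 * latent)

    # sporadic zeros (missingness code), plus forced low presence for the
    # designated presence-filter failures
    zero_mask = rng.random((n, p)) < config.zero_fraction
    for j in config.fail_presence_idx:
        k = int(np.ceil(0.3 * n))  # > 20% zeros -> presence < 80%
        rows = rng.choice(n, size=k, replace=False)
        zero_mask[rows, j] = True
    areas[zero_mask] = 0.0

    col_mean = areas.mean(axis=0)
    col_mean[col_mean == 0] = np.exp(base[col_mean == 0])

    qc_cv = np.full(p, 0.05)
    qc_cv[list(config.fail_rsd_idx)] = 0.8
    qc = col_mean[None, :] * np.exp(rng.normal(0.0, qc_cv[None, :],
                                               (config.n_qc, p)))

    blank_factor = np.full(p, 20.0)
    blank_factor[list(config.fail_blank_idx)] = 2.0
    qc_mean = qc.mean(axis=0)
    blank = (qc_mean / blank_factor)[None, :] * np.exp(
        rng.normal(0.0, 0.05, (config.n_blank, p)))

    idx = subjects.index
    return MetabolitePanel(
        sample_areas=pd.DataFrame(areas, index=idx, columns=ids),
        qc_areas=pd.DataFrame(qc, index=[f"QC{i}" for i in range(config.n_qc)],
                              columns=ids),
        blank_areas=pd.DataFrame(blank,
                                 index=[f"BLK{i}" for i in range(config.n_blank)],
                                 columns=ids),
        ion_mode=ion_mode,
    )


def ground_truth(config: CohortConfig) -> GroundTruth:
    ids = metabolite_ids(config)
    fail = {
        "qc_blank_ratio": [ids[j] for j in config.fail_blank_idx],
        "rsd": [ids[j] for j in config.fail_rsd_idx],
        "presence": [ids[j] for j in config.fail_presence_idx],
    }
    failing = {m for v in fail.values() for m in v}
    cfg = dataclasses.asdict(config)
    cfg["planted_pos_idx"] = list(config.planted_pos_idx)
    cfg["planted_neg_idx"] = list(config.planted_neg_idx)
    cfg["fail_blank_idx"] = list(config.fail_blank_idx)
    cfg["fail_rsd_idx"] = list(config.fail_rsd_idx)
    cfg["fail_presence_idx"] = list(config.fail_presence_idx)
    return GroundTruth(
        config=cfg,
        planted_pos_ids=[ids[j] for j in config.planted_pos_idx],
        planted_neg_ids=[ids[j] for j in config.planted_neg_idx],
        qc_fail_ids=fail,
        intended_survivor_ids=[m for m in ids if m not in failing],
        imaging_columns=[f"img_{k}" for k in range(config.n_imaging_features)],
        latent_metabolite_columns={
            str(s.metabolite_idx): f"_lat_met{s.metabolite_idx:04d}"
            for s in config.mediation_specs
        },
        mediation_chains=[
            {
                "x": f"_lat_met{s.metabolite_idx:04d}",
                "x_id": ids[s.metabolite_idx],
                "m": f"img_{s.imaging_idx}",
                "y": BEHAVIOR_COLUMNS[s.behavior_idx],
                "a": s.a, "b": s.b, "c_prime": s.c_prime,
            }
            for s in config.mediation_specs
        ],
    )


def simulate_cohort(config: CohortConfig, ion_modes=("positive", "negative")):
    """Convenience wrapper: (subjects, {ion_mode: panel}, GroundTruth)."""
    subjects = simulate_subjects(config)
    panels = {m: simulate_metabolite_panel(config, subjects, m) for m in ion_modes}
    return subjects, panels, ground_truth(config)


def simulate_volume4d(
    shape=(12, 12, 6),
    n_timepoints: int = 175,
    tr: float = 2.0,
    components=((0.05, 1.0, None),),
    noise_sd: float = 0.0,
    mirror_symmetric: bool = False,
    seed: int = 0,
):
    """Band-limited 4D series: per voxel, a sum of supported sinusoids plus
    Gaussian noise.

    ``components`` is a list of ``(frequency_hz, amplitude, support)`` where
    ``support`` is a boolean 3D array or ``None`` for everywhere.  With
    ``mirror_symmetric`` the volume equals its reflection across the first
    spatial axis exactly (noise included).

    Returns a :class:`~gutbrainlink.rsfmri_metrics.Volume4D`.
    """
    from .rsfmri_metrics import Volume4D

    nyquist = 1.0 / (2.0 * tr)
    for f, _, _ in components:
        if f >= nyquist:
            raise ValueError(f"component frequency {f} Hz >= Nyquist {nyquist} Hz")
    rng = np.random.default_rng(seed)
    t = np.arange(n_timepoints) * tr
    data = np.zeros(shape + (n_timepoints,))
    for f, amp, support in components:
        phase = rng.uniform(0.0, 2.0 * np.pi)
        series = amp * np.sin(2.0 * np.pi * f * t + phase)
        if support is None:
            data += series
        else:
            data[np.asarray(support, dtype=bool)] += series
    if noise_sd > 0:
        data += rng.normal(0.0, noise_sd, data.shape)
    if mirror_symmetric:
        nx = shape[0]
        for i in range(nx // 2):
            data[nx - 1 - i] = data[i]
    mask = np.ones(shape, dtype=bool)
    return Volume4D(data=data, tr=tr, mask=mask)
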