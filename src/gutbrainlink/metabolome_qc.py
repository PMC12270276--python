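"""Untargeted-metabolomics QC filter and normalization cascade.

A raw peak-area panel (study samples + pooled-QC technical replicates +
instrument blanks) is passed through a fixed cascade:

    blank-ratio filter -> QC-RSD filter -> presence filter ->
    zero imputation -> QC-mean normalization -> glog -> z-score

Zeros are the missingness code throughout: untargeted peak tables carry no
NA convention, so a zero area is treated as "not detected".  Boundary
conventions are literal: a QC/blank ratio strictly below the threshold
removes, an RSD strictly above the threshold removes, and presence at or
above the minimum fraction keeps.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "MetabolitePanel",
    "ProcessedMetabolome",
    "filter_blank_ratio",
    "filter_rsd",
    "filter_presence",
    "impute_missing",
    "normalize_and_scale",
    "run_qc",
    "glog",
    "read_panel_tsv",
    "write_panel_tsv",
]


@dataclass
class MetabolitePanel:
    """Raw peak areas for one ion mode.

    Attributes
    ----------
    sample_areas : DataFrame, subjects x metabolites, peak areas >= 0.
    qc_areas : DataFrame, QC technical replicates x metabolites.
    blank_areas : DataFrame, instrument blanks x metabolites.
    ion_mode : ``"positive"`` or ``"negative"``.
    """

    sample_areas: pd.DataFrame
    qc_areas: pd.DataFrame
    blank_areas: pd.DataFrame
    ion_mode: str = "positive"

    def __post_init__(self) -> None:
        cols = list(self.sample_areas.columns)
        if list(self.qc_areas.columns) != cols or list(self.blank_areas.columns) != cols:
            raise ValueError("sample/qc/blank matrices must share metabolite columns")
        for name, df in (("sample", self.sample_areas), ("qc", self.qc_areas),
                         ("blank", self.blank_areas)):
            if (df.to_numpy(dtype=float) < 0).any():
                raise ValueError(f"negative peak areas in {name} matrix")
        if self.ion_mode not in ("positive", "negative"):
            raise ValueError(f"unknown ion mode: {self.ion_mode!r}")

    @property
    def metabolite_ids(self) -> list[str]:
        return list(self.sample_areas.columns)

    def subset(self, keep: list[str]) -> "MetabolitePanel":
        """Panel restricted to metabolite columns ``keep`` (order preserved)."""
        return replace(
            self,
            sample_areas=self.sample_areas[keep],
            qc_areas=self.qc_areas[keep],
            blank_areas=self.blank_areas[keep],
        )


@dataclass
class ProcessedMetabolome:
    """Output of the cascade: z-scored survivors plus a complete filter log.

    ``filter_log`` has one row per *input* metabolite with columns
    ``qc_blank_ratio``, ``rsd_percent``, ``presence_fraction``, ``kept``
    and ``removal_reason`` (empty string for survivors).
    """

    z_matrix: pd.DataFrame
    filter_log: pd.DataFrame
    ion_mode: str = "positive"
    notes: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# per-metabolite statistics

def qc_blank_ratio(panel: MetabolitePanel) -> pd.Series:
    """Mean QC area / mean blank area per metabolite; inf when blank mean is 0
    and QC mean > 0; nan when both are 0."""
    qc_mean = panel.qc_areas.mean(axis=0)
    blank_mean = panel.blank_areas.mean(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = qc_mean / blank_mean
    ratio[(blank_mean == 0) & (qc_mean > 0)] = np.inf
    return ratio


def qc_rsd_percent(panel: MetabolitePanel) -> pd.Series:
    """Relative standard deviation (%) over QC replicates (ddof=1);
    +inf where the QC mean is 0."""
    mean = panel.qc_areas.mean(axis=0)
    sd = panel.qc_areas.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        rsd = 100.0 * sd / mean
    rsd[mean == 0] = np.inf
    return rsd


def presence_fraction(panel: MetabolitePanel) -> pd.Series:
    """Fraction of study samples (not QCs/blanks) with a nonzero area."""
    return (panel.sample_areas > 0).mean(axis=0)


# ---------------------------------------------------------------------------
# filters

def filter_blank_ratio(panel: MetabolitePanel, threshold: float = 3.0) -> MetabolitePanel:
    """Drop metabolites whose mean QC / mean blank area ratio is < threshold.

    A ratio of exactly ``threshold`` is kept (the rule is strict ``<``).
    """
    if panel.qc_areas.shape[0] < 1 or panel.blank_areas.shape[0] < 1:
        raise ValueError("blank-ratio filter needs >=1 QC row and >=1 blank row")
    ratio = qc_blank_ratio(panel)
    keep = [m for m in panel.metabolite_ids if not (ratio[m] < threshold)]
    return panel.subset(keep)


def filter_rsd(panel: MetabolitePanel, max_rsd_percent: float = 30.0) -> MetabolitePanel:
    """Drop metabolites whose QC-replicate RSD is strictly > the limit (%)."""
    if panel.qc_areas.shape[0] < 2:
        raise ValueError("RSD filter needs >=2 QC replicate rows")
    rsd = qc_rsd_percent(panel)
    keep = [m for m in panel.metabolite_ids if not (rsd[m] > max_rsd_percent)]
    return panel.subset(keep)


def filter_presence(panel: MetabolitePanel, min_fraction: float = 0.80) -> MetabolitePanel:
    """Keep metabolites detected (area > 0) in at least ``min_fraction`` of
    the study samples."""
    if panel.sample_areas.shape[0] < 1:
        raise ValueError("presence filter needs >=1 subject row")
    frac = presence_fraction(panel)
    keep = [m for m in panel.metabolite_ids if frac[m] >= min_fraction]
    return panel.subset(keep)


def impute_missing(panel: MetabolitePanel) -> MetabolitePanel:
    """Replace zeros in the sample matrix by one fifth of the column's
    minimum positive value.  QC and blank matrices are untouched."""
    areas = panel.sample_areas.to_numpy(dtype=float).copy()
    for j, mid in enumerate(panel.metabolite_ids):
        col = areas[:, j]
        pos = col[col > 0]
        if (col == 0).any():
            if pos.size == 0:
                raise ValueError(
                    f"cannot impute metabolite {mid!r}: no positive value in column"
                )
            col[col == 0] = pos.min() / 5.0
    sample = pd.DataFrame(areas, index=panel.sample_areas.index,
                          columns=panel.sample_areas.columns)
    return replace(panel, sample_areas=sample)


# ---------------------------------------------------------------------------
# normalization

def glog(x: np.ndarray, lam: float) -> np.ndarray:
    """Generalized log: log2((x + sqrt(x^2 + lam^2)) / 2)."""
    x = np.asarray(x, dtype=float)
    return np.log2((x + np.sqrt(x * x + lam * lam)) / 2.0)


def normalize_and_scale(
    panel: MetabolitePanel,
    glog_lambda: float | None = None,
    filter_log: pd.DataFrame | None = None,
) -> ProcessedMetabolome:
    """QC-mean normalization, glog transform, and per-column z-scoring.

    Each column is divided by its QC-replicate mean, glog-transformed with
    ``lam = glog_lambda`` (default: the column's minimum positive normalized
    value, a per-column lambda), then z-scored (ddof=1).

    Expects filters and imputation to have been applied already.
    """
    if glog_lambda is not None and glog_lambda <= 0:
        raise ValueError("glog lambda must be positive")
    sample = panel.sample_areas.to_numpy(dtype=float)
    qc_mean = panel.qc_areas.mean(axis=0).to_numpy(dtype=float)
    if (qc_mean <= 0).any():
        bad = [m for m, q in zip(panel.metabolite_ids, qc_mean) if q <= 0]
        raise ValueError(f"non-positive QC mean for columns {bad}")
    norm = sample / qc_mean

    z = np.empty_like(norm)
    for j, mid in enumerate(panel.metabolite_ids):
        col = norm[:, j]
        if glog_lambda is None:
            pos = col[col > 0]
            if pos.size == 0:
                raise ValueError(f"no positive value to set glog lambda for {mid!r}")
            lam = float(pos.min())
        else:
            lam = float(glog_lambda)
        g = glog(col, lam)
        sd = g.std(ddof=1)
        if sd == 0 or not np.isfinite(sd):
            raise ValueError(f"zero variance after glog in column {mid!r}")
        z[:, j] = (g - g.mean()) / sd

    zdf = pd.DataFrame(z, index=panel.sample_areas.index,
                       columns=panel.sample_areas.columns)
    if filter_log is None:
        filter_log = pd.DataFrame(
            {
                "metabolite_id": panel.metabolite_ids,
                "qc_blank_ratio": qc_blank_ratio(panel).to_numpy(),
                "rsd_percent": qc_rsd_percent(panel).to_numpy(),
                "presence_fraction": presence_fraction(panel).to_numpy(),
                "kept": True,
                "removal_reason": "",
            }
        )
    return ProcessedMetabolome(z_matrix=zdf, filter_log=filter_log,
                               ion_mode=panel.ion_mode)


def run_qc(
    panel: MetabolitePanel,
    blank_threshold: float = 3.0,
    max_rsd_percent: float = 30.0,
    min_presence: float = 0.80,
    glog_lambda: float | None = None,
) -> ProcessedMetabolome:
    """Full cascade in the fixed order blank ratio -> RSD -> presence ->
    imputation -> normalize/scale, with a complete per-metabolite log.

    Every removed metabolite carries exactly one removal reason: the first
    filter in the cascade order that it fails.
    """
    ids = panel.metabolite_ids
    ratio = qc_blank_ratio(panel)
    rsd = qc_rsd_percent(panel)
    frac = presence_fraction(panel)

    reason = {}
    for m in ids:
        if ratio[m] < blank_threshold:
            reason[m] = "qc_blank_ratio"
        elif rsd[m] > max_rsd_percent:
            reason[m] = "rsd"
        elif frac[m] < min_presence:
            reason[m] = "presence"
        else:
            reason[m] = ""

    survivors = [m for m in ids if reason[m] == ""]
    log = pd.DataFrame(
        {
            "metabolite_id": ids,
            "qc_blank_ratio": [ratio[m] for m in ids],
            "rsd_percent": [rsd[m] for m in ids],
            "presence_fraction": [frac[m] for m in ids],
            "kept": [reason[m] == "" for m in ids],
            "removal_reason": [reason[m] for m in ids],
        }
    )
    filtered = panel.subset(survivors)
    imputed = impute_missing(filtered)
    return normalize_and_scale(imputed, glog_lambda=glog_lambda, filter_log=log)


# ---------------------------------------------------------------------------
# TSV round-trip: long-ish layout with a `role` column (sample|qc|blank)

def write_panel_tsv(panel: MetabolitePanel, path) -> None:
    parts = []
    for role, df in (("sample", panel.sample_areas), ("qc", panel.qc_areas),
                     ("blank", panel.blank_areas)):
        block = df.copy()
        block.insert(0, "role", role)
        parts.append(block)
    out = pd.concat(parts)
    out.index.name = "id"
    out.to_csv(path, sep="\t")


def read_panel_tsv(path, ion_mode: str = "positive") -> MetabolitePanel:
    df = pd.read_csv(path, sep="\t", index_col=0)
    if "role" not in df.columns:
        raise ValueError("panel TSV must carry a 'role' column (sample|qc|blank)")
    role = df.pop("role")
    unknown = set(role.unique()) - {"sample", "qc", "blank"}
    if unknown:
        warnings.warn(f"ignoring rows with unknown roles {sorted(unknown)}")
    return MetabolitePanel(
        sample_areas=df[role == "sample"].astype(float),
        qc_areas=df[role == "qc"].astype(float),
        blank_areas=df[role == "blank"].astype(float),
        ion_mode=ion_mode,
    )
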