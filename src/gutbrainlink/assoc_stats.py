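"""Group comparison and covariate-adjusted rank-correlation chains.

* :func:`mann_whitney` — rank-sum comparison with the tie-corrected normal
  approximation (continuity-corrected) and an exact-enumeration mode for
  tiny samples.
* :func:`partial_spearman` — rank both variables (midranks), residualize
  both rank vectors on [intercept + rank-transformed covariates] by least
  squares, and take the Pearson correlation of the residuals; p from the t
  distribution with n - k - 2 degrees of freedom.  Categorical covariates
  are expanded to indicator columns before ranking.
* :func:`fdr_adjust` — Benjamini-Hochberg step-up.
* :func:`correlation_screen` — all feature x target partial correlations
  with BH applied within a configurable family.

Complete-case handling throughout: rows with any missing value among the
variables and covariates in play are dropped and the retained count is
reported.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "GroupTestResult",
    "PartialCorrResult",
    "mann_whitney",
    "partial_spearman",
    "fdr_adjust",
    "correlation_screen",
]


@dataclass
class GroupTestResult:
    u_statistic: float
    z_value: float
    p_value: float
    direction: int  # sign of group_a - group_b location shift
    n_a: int
    n_b: int
    method: str = "normal"


@dataclass
class PartialCorrResult:
    x_id: str
    y_id: str
    pr: float
    p_raw: float
    q_fdr: float | None
    n_effective: int
    covariates: tuple


def mann_whitney(group_a, group_b, method: str = "normal") -> GroupTestResult:
    """Two-sided Mann-Whitney U test; ``group_a`` is the patient group for
    the reported direction.

    ``method="normal"`` uses the tie-corrected normal approximation with a
    continuity correction; ``method="exact"`` enumerates all C(n1+n2, n1)
    group assignments (n1 + n2 <= 12).
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups need >= 1 observation")
    n1, n2 = a.size, b.size
    combined = np.concatenate([a, b])
    ranks = stats.rankdata(combined)
    r1 = ranks[:n1].sum()
    u = r1 - n1 * (n1 + 1) / 2.0  # U for group_a
    mu = n1 * n2 / 2.0
    direction = int(np.sign(u - mu))

    if method == "exact":
        if n1 + n2 > 12:
            raise ValueError("exact enumeration limited to n1 + n2 <= 12")
        u_all = []
        idx_all = range(n1 + n2)
        for comb in itertools.combinations(idx_all, n1):
            u_all.append(ranks[list(comb)].sum() - n1 * (n1 + 1) / 2.0)
        u_all = np.asarray(u_all)
        n_tot = len(u_all)
        p_low = (u_all <= u + 1e-9).sum() / n_tot
        p_high = (u_all >= u - 1e-9).sum() / n_tot
        p = min(1.0, 2.0 * min(p_low, p_high))
        # z reported from the tie-corrected approximation for reference
        z = _mw_z(u, n1, n2, combined)
        return GroupTestResult(u, z, float(p), direction, n1, n2, "exact")

    z = _mw_z(u, n1, n2, combined)
    p = min(1.0, 2.0 * stats.norm.sf(abs(z)))
    return GroupTestResult(u, float(z), float(p), direction, n1, n2, "normal")


def _mw_z(u: float, n1: int, n2: int, combined: np.ndarray) -> float:
    """Tie-corrected, continuity-corrected normal-approximation z."""
    n = n1 + n2
    mu = n1 * n2 / 2.0
    _, counts = np.unique(combined, return_counts=True)
    tie_term = (counts**3 - counts).sum()
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    if var <= 0:
        return 0.0  # all observations tied
    diff = u - mu
    cc = 0.5 * np.sign(diff)  # continuity correction toward the null
    return (diff - cc) / np.sqrt(var)


def _expand_covariates(cov: pd.DataFrame) -> pd.DataFrame:
    """Numeric columns pass through; object/category columns become 0/1
    indicators (first level dropped)."""
    parts = []
    for col in cov.columns:
        s = cov[col]
        if pd.api.types.is_numeric_dtype(s) and not isinstance(
                s.dtype, pd.CategoricalDtype):
            parts.append(s.astype(float).to_frame())
        else:
            d = pd.get_dummies(s, prefix=col, drop_first=True, dtype=float)
            parts.append(d)
    if not parts:
        return pd.DataFrame(index=cov.index)
    return pd.concat(parts, axis=1)


def _residualize(v: np.ndarray, design: np.ndarray) -> np.ndarray:
    beta, *_ = np.linalg.lstsq(design, v, rcond=None)
    return v - design @ beta


def partial_spearman(x, y, covariates: pd.DataFrame | None = None,
                     x_id: str = "x", y_id: str = "y") -> PartialCorrResult:
    """Partial Spearman correlation of x and y given covariates."""
    x = pd.Series(np.asarray(x, dtype=float))
    y = pd.Series(np.asarray(y, dtype=float))
    if covariates is None:
        covariates = pd.DataFrame(index=x.index)
    else:
        covariates = covariates.reset_index(drop=True)
    if len(x) != len(y) or len(x) != len(covariates):
        raise ValueError("x, y and covariates must have equal length")

    keep = x.notna() & y.notna() & ~covariates.isna().any(axis=1)
    x, y = x[keep].to_numpy(), y[keep].to_numpy()
    cov = _expand_covariates(covariates.loc[keep])
    n = x.shape[0]
    k = cov.shape[1]
    if n <= k + 2:
        raise ValueError(f"need n > k + 2 complete cases (n={n}, k={k})")

    # rank-transform covariate columns too: the standard partial-Spearman
    # construction works entirely in rank space (for 0/1 indicators ranking
    # is affine, so the residuals are unchanged)
    cov_ranked = np.column_stack(
        [stats.rankdata(cov[c].to_numpy(dtype=float)) for c in cov.columns]
    ) if k else np.empty((n, 0))
    design = np.column_stack([np.ones(n), cov_ranked])
    rank_def = np.linalg.matrix_rank(design) < design.shape[1]
    if rank_def:
        # name the offending columns: those whose removal restores full rank
        bad = [c for i, c in enumerate(cov.columns)
               if np.linalg.matrix_rank(np.delete(design, i + 1, axis=1))
               == np.linalg.matrix_rank(design)]
        raise ValueError(f"rank-deficient covariate design; collinear "
                         f"columns: {bad}")

    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    ex = _residualize(rx, design)
    ey = _residualize(ry, design)
    sx, sy = np.linalg.norm(ex), np.linalg.norm(ey)
    tol_x = 1e-8 * max(np.linalg.norm(rx - rx.mean()), 1.0)
    tol_y = 1e-8 * max(np.linalg.norm(ry - ry.mean()), 1.0)
    if sx <= tol_x or sy <= tol_y:
        raise ValueError("zero residual variance after adjusting for "
                         "covariates")
    pr = float(np.clip((ex @ ey) / (sx * sy), -1.0, 1.0))
    df = n - k - 2
    if abs(pr) == 1.0:
        p = 0.0
    else:
        t = pr * np.sqrt(df / (1.0 - pr * pr))
        p = float(2.0 * stats.t.sf(abs(t), df))
    return PartialCorrResult(x_id, y_id, pr, p, None, n,
                             tuple(covariates.columns))


def fdr_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if ((p < 0) | (p > 1)).any() or not np.isfinite(p).all():
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def correlation_screen(
    features: pd.DataFrame,
    targets: pd.DataFrame,
    covariates: pd.DataFrame | None = None,
    family: str = "all",
    fdr_level: float = 0.05,
) -> pd.DataFrame:
    """All feature x target partial Spearman correlations with BH-FDR.

    ``family`` sets the FDR family: ``"all"`` (one family per call, the
    default feature-set x target-set block), ``"per_feature"`` or
    ``"per_target"``.  Returns a DataFrame with one row per pair, columns
    ``feature``, ``target``, ``pr``, ``p``, ``q``, ``n``, ``significant``,
    ``covariates``.
    """
    if features.shape[1] == 0 or targets.shape[1] == 0:
        raise ValueError("empty feature or target family")
    if family not in ("all", "per_feature", "per_target"):
        raise ValueError(f"unknown family rule {family!r}")
    rows = []
    for f in features.columns:
        for t in targets.columns:
            res = partial_spearman(features[f].to_numpy(),
                                   targets[t].to_numpy(),
                                   covariates, x_id=str(f), y_id=str(t))
            rows.append({"feature": f, "target": t, "pr": res.pr,
                         "p": res.p_raw, "n": res.n_effective,
                         "covariates": ",".join(map(str, res.covariates))})
    out = pd.DataFrame(rows)
    if family == "all":
        out["q"] = fdr_adjust(out["p"].to_numpy())
    else:
        key = "feature" if family == "per_feature" else "target"
        out["q"] = np.nan
        for _, idx in out.groupby(key).groups.items():
            out.loc[idx, "q"] = fdr_adjust(out.loc[idx, "p"].to_numpy())
    out["significant"] = out["q"] < fdr_level
    return out[["feature", "target", "pr", "p", "q", "n", "significant",
                "covariates"]]
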