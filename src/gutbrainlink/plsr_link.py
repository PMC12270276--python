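"""First-component PLSR between a univariate microbe abundance and a
metabolite z-matrix, with a permutation null, contribution loadings, and
top-20% selection.

For a univariate response the first PLS component has a closed form: the
weight vector is the normalized cross-covariance between the (centered)
metabolite columns and the microbe vector.  This is identical to the first
left singular vector of the cross-covariance and to what iterative NIPALS
converges to, but deterministic and directly testable against an SVD
oracle.  The sign convention cov(scores, microbe) >= 0 holds by
construction, so the overall Pearson r is >= 0.

The permutation p-value is one-sided on the sign-fixed r and uses the
add-one (Phipson-Smyth) formula, p = (1 + #{r_perm >= r_obs}) / (1 + B),
so the smallest achievable p at B = 5000 is 1/5001.
"""

from __future__ import annotations

import itertools
import json
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "PLSRResult",
    "plsr_first_component",
    "overall_association",
    "permutation_test",
    "contribution_loadings",
    "select_top20",
    "fit_plsr",
]


@dataclass
class PLSRResult:
    weights: pd.Series
    scores: pd.Series
    overall_r: float
    p_perm: float
    n_perm: int
    loadings: pd.Series
    plsr_pos: list
    plsr_neg: list
    ion_mode: str = "positive"
    seed: int | None = None
    constant_loading_ids: list = field(default_factory=list)

    def to_json(self) -> str:
        return json.dumps({
            "overall_r": self.overall_r,
            "p_perm": self.p_perm,
            "n_perm": self.n_perm,
            "ion_mode": self.ion_mode,
            "seed": self.seed,
            "plsr_pos": list(self.plsr_pos),
            "plsr_neg": list(self.plsr_neg),
            "weights": self.weights.to_dict(),
            "loadings": self.loadings.to_dict(),
        }, indent=2, sort_keys=True)

    def ranked_loadings(self) -> pd.DataFrame:
        """Loadings ranked high to low with selection flags."""
        df = pd.DataFrame({"metabolite_id": self.loadings.index,
                           "loading": self.loadings.to_numpy()})
        df = df.sort_values("loading", ascending=False, kind="mergesort")
        df["selected"] = [
            "plsr_pos" if m in set(self.plsr_pos)
            else "plsr_neg" if m in set(self.plsr_neg) else ""
            for m in df["metabolite_id"]
        ]
        return df.reset_index(drop=True)


def _as_matrix(z_matrix) -> tuple[np.ndarray, list]:
    if isinstance(z_matrix, pd.DataFrame):
        return z_matrix.to_numpy(dtype=float), list(z_matrix.columns)
    z = np.asarray(z_matrix, dtype=float)
    return z, [f"m{j}" for j in range(z.shape[1])]


def plsr_first_component(z_matrix, microbe):
    """Weights (unit norm) maximizing cov(z_matrix @ w, microbe), and the
    per-subject scores z_matrix @ w.

    Returns ``(weights, scores)`` as pandas Series.
    """
    Z, ids = _as_matrix(z_matrix)
    y = np.asarray(microbe, dtype=float)
    if Z.shape[0] < 3:
        raise ValueError("need >= 3 subjects for PLSR")
    if Z.shape[0] != y.shape[0]:
        raise ValueError("row mismatch between z-matrix and microbe vector")
    if np.ptp(y) == 0:
        raise ValueError("microbe vector is constant")
    Zc = Z - Z.mean(axis=0)
    yc = y - y.mean()
    c = Zc.T @ yc  # proportional to the cross-covariance vector
    norm = np.linalg.norm(c)
    if norm == 0:
        raise ValueError("zero cross-covariance: metabolites uncorrelated "
                         "with microbe to machine precision")
    w = c / norm
    scores = Z @ w
    index = getattr(z_matrix, "index", None)
    return (pd.Series(w, index=ids, name="weight"),
            pd.Series(scores, index=index, name="score"))


def overall_association(scores, microbe) -> float:
    """Pearson r between metabolite scores and microbe abundance
    (>= 0 under the component's sign convention)."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(microbe, dtype=float)
    if s.std() == 0 or y.std() == 0:
        raise ValueError("zero variance in scores or microbe")
    return float(np.corrcoef(s, y)[0, 1])


def _perm_r(Zc: np.ndarray, Y: np.ndarray) -> np.ndarray:
    """Sign-fixed overall r for each column of permuted responses Y (n, B).

    Refits the full first component per column, vectorized."""
    Yc = Y - Y.mean(axis=0, keepdims=True)
    G = Zc.T @ Yc                      # (p, B) cross-covariances
    S = Zc @ G                         # (n, B) unnormalized scores
    Sc = S - S.mean(axis=0, keepdims=True)
    num = (Sc * Yc).sum(axis=0)
    den = np.linalg.norm(Sc, axis=0) * np.linalg.norm(Yc, axis=0)
    r = np.zeros(Y.shape[1])
    nz = den > 0
    r[nz] = num[nz] / den[nz]
    return r


def permutation_test(z_matrix, microbe, n_perm: int = 5000,
                     seed: int | None = None, exhaustive: bool = False) -> float:
    """One-sided permutation p for the sign-fixed overall r.

    Shuffles the microbe labels across participants, refits the first
    component each time, and applies the add-one formula.  With
    ``exhaustive=True`` all n! permutations are enumerated (n <= 8 only)
    and p = #{r_perm >= r_obs} / n!.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    Z, _ = _as_matrix(z_matrix)
    y = np.asarray(microbe, dtype=float)
    Zc = Z - Z.mean(axis=0)
    w, scores = plsr_first_component(Z, y)
    r_obs = overall_association(scores, y)

    n = y.shape[0]
    if exhaustive:
        if n > 8:
            raise ValueError("exhaustive enumeration limited to n <= 8")
        perms = np.array(list(itertools.permutations(range(n))))
        r_perm = _perm_r(Zc, y[perms.T])
        return float((r_perm >= r_obs - 1e-12).sum() / len(perms))

    rng = np.random.default_rng(seed)
    Y = np.empty((n, n_perm))
    for b in range(n_perm):
        Y[:, b] = y[rng.permutation(n)]
    r_perm = _perm_r(Zc, Y)
    return float((1 + (r_perm >= r_obs).sum()) / (1 + n_perm))


def contribution_loadings(z_matrix, scores) -> pd.Series:
    """Per-metabolite Pearson r with the score vector; constant columns get
    loading 0 with a warning."""
    Z, ids = _as_matrix(z_matrix)
    s = np.asarray(scores, dtype=float)
    if s.std() == 0:
        raise ValueError("score vector is constant")
    sc = s - s.mean()
    Zc = Z - Z.mean(axis=0)
    col_norm = np.linalg.norm(Zc, axis=0)
    const = col_norm == 0
    if const.any():
        warnings.warn(f"{const.sum()} constant metabolite columns assigned "
                      "loading 0")
    safe = np.where(const, 1.0, col_norm)
    load = (Zc.T @ sc) / (safe * np.linalg.norm(sc))
    load[const] = 0.0
    return pd.Series(np.clip(load, -1.0, 1.0), index=ids, name="loading")


def select_top20(loadings: pd.Series, fraction: float = 0.20):
    """The k = floor(fraction * n) most-positive and k most-negative
    loadings, as (plsr_pos, plsr_neg) identifier lists.

    Only loadings with the required sign qualify; if fewer than k exist the
    set is truncated with a warning.  Ties break by identifier order.
    """
    n = len(loadings)
    if n < 5:
        raise ValueError("need >= 5 metabolites for top-20% selection")
    k = math.floor(fraction * n)
    if k == 0:
        raise ValueError("selection quota is zero; increase fraction or n")
    df = pd.DataFrame({"id": loadings.index, "loading": loadings.to_numpy()})
    pos = df[df["loading"] > 0].sort_values(
        ["loading", "id"], ascending=[False, True], kind="mergesort")
    neg = df[df["loading"] < 0].sort_values(
        ["loading", "id"], ascending=[True, True], kind="mergesort")
    if len(pos) < k or len(neg) < k:
        warnings.warn("fewer loadings than the selection quota carry the "
                      "required sign; sets truncated")
    return list(pos["id"].head(k)), list(neg["id"].head(k))


def fit_plsr(z_matrix, microbe, n_perm: int = 5000, seed: int | None = None,
             ion_mode: str = "positive", fraction: float = 0.20) -> PLSRResult:
    """Full linkage: component, overall r, permutation p, loadings, and
    PLSR+/PLSR- selection."""
    weights, scores = plsr_first_component(z_matrix, microbe)
    r = overall_association(scores, microbe)
    p = permutation_test(z_matrix, microbe, n_perm=n_perm, seed=seed)
    loadings = contribution_loadings(z_matrix, scores)
    plsr_pos, plsr_neg = select_top20(loadings, fraction=fraction)
    Z, ids = _as_matrix(z_matrix)
    const_ids = [m for m, flat in zip(ids, np.ptp(Z, axis=0) == 0) if flat]
    return PLSRResult(
        weights=weights, scores=scores, overall_r=r, p_perm=p, n_perm=n_perm,
        loadings=loadings, plsr_pos=plsr_pos, plsr_neg=plsr_neg,
        ion_mode=ion_mode, seed=seed, constant_loading_ids=const_ids,
    )
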