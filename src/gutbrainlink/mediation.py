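"""Single-mediator regression mediation with bootstrap percentile CIs.

Three least-squares fits, all with intercept + nuisance covariates:

    M ~ X            -> a
    Y ~ X + M        -> c' (X) and b (M)
    Y ~ X            -> c

The decomposition c = a*b + c' is an exact identity for OLS with identical
covariate sets in all three models.  Significance of the indirect effect
a*b uses the percentile bootstrap: resample subjects with replacement,
refit, and take the empirical 2.5/97.5 percentiles; the effect is
significant when the interval excludes zero.  Rank-deficient resamples are
redrawn (capped at 10x the bootstrap count).

X, M, Y enter raw by default; ``standardize=True`` z-scores all three
first (the scale of reported indirect effects depends on this choice).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

__all__ = [
    "MediationResult",
    "fit_mediation",
    "bootstrap_ci",
    "mediation_screen",
    "chain_candidates",
]

_COND_MAX = 1e10  # resample condition-number cutoff for "degenerate"


@dataclass
class MediationResult:
    x_id: str
    m_id: str
    y_id: str
    a: float
    b: float
    c: float
    c_prime: float
    indirect: float
    ci_low: float | None = None
    ci_high: float | None = None
    n_boot: int = 0
    significant: bool | None = None
    n: int = 0
    seed: int | None = None
    covariates: tuple = ()


def _complete_cases(x, m, y, covariates):
    x = pd.Series(np.asarray(x, dtype=float))
    m = pd.Series(np.asarray(m, dtype=float))
    y = pd.Series(np.asarray(y, dtype=float))
    if covariates is None:
        cov = pd.DataFrame(index=x.index)
    else:
        cov = covariates.reset_index(drop=True)
    keep = x.notna() & m.notna() & y.notna() & ~cov.isna().any(axis=1)
    from .assoc_stats import _expand_covariates
    C = _expand_covariates(cov.loc[keep]).to_numpy(dtype=float)
    return (x[keep].to_numpy(), m[keep].to_numpy(), y[keep].to_numpy(),
            C, tuple(cov.columns))


def _paths(x, m, y, C):
    """(a, b, c, c_prime) from the three OLS fits; raises on rank
    deficiency or zero variance."""
    n = x.shape[0]
    for name, v in (("x", x), ("m", m), ("y", y)):
        if np.ptp(v) == 0:
            raise ValueError(f"zero variance in {name}")
    ones = np.ones((n, 1))
    D1 = np.column_stack([ones, C, x])            # M ~ X
    D2 = np.column_stack([ones, C, x, m])         # Y ~ X + M
    for D in (D1, D2):
        if np.linalg.matrix_rank(D) < D.shape[1]:
            raise ValueError("rank-deficient design in mediation fit")
    beta1, *_ = np.linalg.lstsq(D1, m, rcond=None)
    a = beta1[-1]
    beta2, *_ = np.linalg.lstsq(D2, y, rcond=None)
    c_prime, b = beta2[-2], beta2[-1]
    beta3, *_ = np.linalg.lstsq(D1, y, rcond=None)  # Y ~ X, same design as D1
    c = beta3[-1]
    return float(a), float(b), float(c), float(c_prime)


def fit_mediation(x, m, y, covariates: pd.DataFrame | None = None,
                  standardize: bool = False,
                  x_id: str = "x", m_id: str = "m", y_id: str = "y",
                  ) -> MediationResult:
    """Point estimates of a, b, c, c' and the indirect effect a*b."""
    xv, mv, yv, C, cov_names = _complete_cases(x, m, y, covariates)
    n = xv.shape[0]
    if n <= C.shape[1] + 3:
        raise ValueError(f"need n > covariate columns + 3 complete cases "
                         f"(n={n}, k={C.shape[1]})")
    if standardize:
        xv, mv, yv = (
            (v - v.mean()) / v.std(ddof=1) for v in (xv, mv, yv))
    a, b, c, c_prime = _paths(xv, mv, yv, C)
    return MediationResult(x_id, m_id, y_id, a, b, c, c_prime,
                           indirect=a * b, n=n, covariates=cov_names)


def _batched_indirect(xv, mv, yv, C, idx):
    """Indirect effects for bootstrap index matrix idx (B, n); NaN marks
    degenerate (ill-conditioned) resamples."""
    B, n = idx.shape
    ones = np.ones((B, n, 1))
    Cb = C[idx] if C.shape[1] else np.empty((B, n, 0))
    xb, mb, yb = xv[idx], mv[idx], yv[idx]
    D1 = np.concatenate([ones, Cb, xb[..., None]], axis=2)
    D2 = np.concatenate([ones, Cb, xb[..., None], mb[..., None]], axis=2)

    out = np.full(B, np.nan)
    G2 = np.einsum("bni,bnj->bij", D2, D2)
    bad = np.linalg.cond(G2) > _COND_MAX
    good = ~bad
    if not good.any():
        return out
    g = np.where(good)[0]
    G1 = np.einsum("bni,bnj->bij", D1[g], D1[g])
    r1 = np.einsum("bni,bn->bi", D1[g], mb[g])
    beta1 = np.linalg.solve(G1, r1[..., None])[..., 0]
    a = beta1[:, -1]
    r2 = np.einsum("bni,bn->bi", D2[g], yb[g])
    beta2 = np.linalg.solve(G2[g], r2[..., None])[..., 0]
    b = beta2[:, -1]
    out[g] = a * b
    return out


def bootstrap_ci(x, m, y, covariates: pd.DataFrame | None = None,
                 n_boot: int = 5000, level: float = 0.95,
                 seed: int | None = None, standardize: bool = False):
    """Percentile bootstrap CI for the indirect effect.

    Returns ``(ci_low, ci_high, significant)``.  Degenerate resamples are
    redrawn, with a total redraw budget of 10 * n_boot.
    """
    if n_boot < 100:
        raise ValueError("n_boot must be >= 100")
    xv, mv, yv, C, _ = _complete_cases(x, m, y, covariates)
    if standardize:
        xv, mv, yv = ((v - v.mean()) / v.std(ddof=1) for v in (xv, mv, yv))
    n = xv.shape[0]
    rng = np.random.default_rng(seed)

    idx = rng.integers(0, n, size=(n_boot, n))
    indirect = _batched_indirect(xv, mv, yv, C, idx)
    redraws = 0
    while np.isnan(indirect).any():
        bad = np.where(np.isnan(indirect))[0]
        redraws += bad.size
        if redraws > 10 * n_boot:
            raise RuntimeError("bootstrap redraw cap exceeded: data too "
                               "degenerate for resampling")
        idx_new = rng.integers(0, n, size=(bad.size, n))
        indirect[bad] = _batched_indirect(xv, mv, yv, C, idx_new)

    alpha = (1.0 - level) / 2.0
    ci_low, ci_high = np.percentile(indirect, [100 * alpha, 100 * (1 - alpha)])
    significant = bool(ci_low > 0 or ci_high < 0)
    return float(ci_low), float(ci_high), significant


def mediate(x, m, y, covariates=None, n_boot: int = 5000, level: float = 0.95,
            seed: int | None = None, standardize: bool = False,
            x_id="x", m_id="m", y_id="y") -> MediationResult:
    """Point estimates plus bootstrap CI in one call."""
    res = fit_mediation(x, m, y, covariates, standardize, x_id, m_id, y_id)
    lo, hi, sig = bootstrap_ci(x, m, y, covariates, n_boot, level, seed,
                               standardize)
    return replace(res, ci_low=lo, ci_high=hi, n_boot=n_boot,
                   significant=sig, seed=seed)


def chain_candidates(xm_screen: pd.DataFrame, my_screen: pd.DataFrame,
                     q_threshold: float = 0.05) -> list[tuple]:
    """Mediation triples (x, m, y) from two correlation screens: x-m pairs
    flagged in the first AND m-y pairs flagged in the second, joined on m."""
    xm = xm_screen[xm_screen["q"] < q_threshold]
    my = my_screen[my_screen["q"] < q_threshold]
    triples = set()
    for _, r1 in xm.iterrows():
        for _, r2 in my.iterrows():
            if r1["target"] == r2["feature"]:
                triples.add((r1["feature"], r1["target"], r2["target"]))
    return sorted(triples)


def mediation_screen(data: pd.DataFrame, candidates,
                     covariate_columns=(), n_boot: int = 5000,
                     level: float = 0.95, seed: int | None = None,
                     standardize: bool = False) -> list[MediationResult]:
    """One bootstrap mediation per (x, m, y) candidate triple.

    Output is ordered by the (x, m, y) identifiers; each triple gets an
    independent child seed spawned deterministically from ``seed``.
    """
    if len(candidates) == 0:
        warnings.warn("empty candidate list: no mediation models fitted")
        return []
    missing = {c for t in candidates for c in t} - set(data.columns)
    if missing:
        raise KeyError(f"candidate columns absent from data: {sorted(missing)}")
    cov = data[list(covariate_columns)] if covariate_columns else None
    ordered = sorted(tuple(map(str, t)) for t in candidates)
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(len(ordered))
    results = []
    for (x_id, m_id, y_id), child in zip(ordered, children):
        child_seed = int(child.generate_state(1)[0])
        results.append(mediate(
            data[x_id], data[m_id], data[y_id], covariates=cov,
            n_boot=n_boot, level=level, seed=child_seed,
            standardize=standardize, x_id=x_id, m_id=m_id, y_id=y_id))
    return results


def results_frame(results) -> pd.DataFrame:
    """MediationResult list -> tidy DataFrame."""
    return pd.DataFrame([{
        "x": r.x_id, "m": r.m_id, "y": r.y_id, "a": r.a, "b": r.b,
        "c": r.c, "c_prime": r.c_prime, "indirect": r.indirect,
        "ci_low": r.ci_low, "ci_high": r.ci_high, "n_boot": r.n_boot,
        "significant": r.significant, "n": r.n, "seed": r.seed,
        "covariates": ",".join(map(str, r.covariates)),
    } for r in results])
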