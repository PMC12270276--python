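"""Hypergeometric over-representation of selected metabolite sets against
user-supplied pathway annotations.

The universe defaults to metabolites that both survived QC and appear in
the annotation map; the test per pathway is the upper-tail hypergeometric
probability P(X >= k) with population N (universe), K annotated, n
selected.  BH-FDR is applied across pathways.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .assoc_stats import fdr_adjust

__all__ = ["AnnotationMap", "EnrichmentResult", "enrich", "read_annotation_tsv"]


@dataclass
class AnnotationMap:
    """pathway_id -> metabolite-id set, plus the annotatable universe."""

    pathways: dict
    universe: set = field(default_factory=set)

    def __post_init__(self) -> None:
        self.pathways = {p: set(s) for p, s in self.pathways.items()}
        if not self.universe:
            self.universe = set().union(*self.pathways.values()) \
                if self.pathways else set()
        self.universe = set(self.universe)
        for p, s in self.pathways.items():
            if not s:
                raise ValueError(f"pathway {p!r} is empty")
            if not s <= self.universe:
                raise ValueError(f"pathway {p!r} contains metabolites outside "
                                 "the universe")

    def restrict(self, metabolites) -> "AnnotationMap":
        """Universe intersected with ``metabolites`` (e.g. QC survivors);
        pathways trimmed accordingly, empty ones dropped."""
        uni = self.universe & set(metabolites)
        paths = {p: s & uni for p, s in self.pathways.items() if s & uni}
        return AnnotationMap(pathways=paths, universe=uni)


@dataclass
class EnrichmentResult:
    pathway_id: str
    k: int       # overlap
    K: int       # pathway size
    n: int       # selected set size within universe
    N: int       # universe size
    p_hyper: float
    q_fdr: float
    neg_log10_p: float


def enrich(selected, annotations: AnnotationMap) -> list[EnrichmentResult]:
    """Upper-tail hypergeometric ORA of ``selected`` against every pathway,
    BH-corrected, sorted by p (ties by pathway id)."""
    selected = set(selected)
    sel_in = selected & annotations.universe
    if not sel_in:
        unmapped = sorted(selected)
        raise ValueError("no selected metabolite maps into the annotation "
                         f"universe; unmapped: {unmapped}")
    N = len(annotations.universe)
    n = len(sel_in)
    rows = []
    for pid in sorted(annotations.pathways):
        pset = annotations.pathways[pid]
        K = len(pset)
        k = len(pset & sel_in)
        p = float(hypergeom.sf(k - 1, N, K, n))  # P(X >= k)
        p = min(1.0, max(p, 0.0))
        rows.append((pid, k, K, p))
    qs = fdr_adjust([r[3] for r in rows])
    results = [
        EnrichmentResult(pid, k, K, n, N, p, float(q),
                         float(-math.log10(p)) if p > 0 else math.inf)
        for (pid, k, K, p), q in zip(rows, qs)
    ]
    return sorted(results, key=lambda r: (r.p_hyper, r.pathway_id))


def results_frame(results) -> pd.DataFrame:
    return pd.DataFrame([{
        "pathway_id": r.pathway_id, "k": r.k, "K": r.K, "n": r.n, "N": r.N,
        "p_hyper": r.p_hyper, "q_fdr": r.q_fdr, "neg_log10_p": r.neg_log10_p,
    } for r in results])


def read_annotation_tsv(path) -> AnnotationMap:
    """Two-column TSV (metabolite_id, pathway_id), header optional."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype=str)
    if df.shape[1] < 2:
        raise ValueError("annotation TSV needs two columns "
                         "(metabolite_id, pathway_id)")
    if df.iloc[0, 0] in ("metabolite_id", "metabolite"):
        df = df.iloc[1:]
    paths: dict[str, set] = {}
    for met, pw in zip(df.iloc[:, 0], df.iloc[:, 1]):
        paths.setdefault(pw, set()).add(met)
    return AnnotationMap(pathways=paths)
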