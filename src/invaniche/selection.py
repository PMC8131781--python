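"""Collinearity screening of candidate climate variables.

Bioclimatic layers are strongly inter-correlated; fitting them all inflates
variance and muddies response curves.  The screen here mirrors common SDM
practice: cluster variables by pairwise Pearson |r| > 0.7 (transitive
closure), keep the best-scoring member of each cluster, then iteratively
drop the worst-scoring variable whose variance inflation factor exceeds 10
until every survivor passes both thresholds.  The default score is the
training gain of a univariate maximum-entropy fit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["pearson_matrix", "vif_scores", "select_variables",
           "SelectionReport", "maxent_gain_scorer"]

VIF_SENTINEL = 1e12


def pearson_matrix(samples: pd.DataFrame) -> pd.DataFrame:
    """Pairwise Pearson correlation; errors on a zero-variance variable."""
    if samples.shape[0] < 3 or samples.shape[1] < 2:
        raise ValueError("need at least 3 samples and 2 variables")
    sds = samples.std(ddof=0)
    dead = sds[sds == 0].index.tolist()
    if dead:
        raise ValueError(f"zero-variance variable(s): {dead}")
    corr = np.corrcoef(samples.to_numpy(dtype=float), rowvar=False)
    return pd.DataFrame(corr, index=samples.columns, columns=samples.columns)


def vif_scores(samples: pd.DataFrame) -> pd.Series:
    """Variance inflation factor 1/(1−R²_j) per variable.

    R²_j comes from an ordinary least-squares regression of variable j on
    all the others (with intercept).  Exact collinearity (R² ≥ 1 − 1e-12)
    returns a large sentinel instead of infinity.
    """
    x = samples.to_numpy(dtype=float)
    n, k = x.shape
    if n <= k:
        raise ValueError("need more samples than variables for VIF")
    out = {}
    for j, name in enumerate(samples.columns):
        y = x[:, j]
        others = np.column_stack([np.ones(n), np.delete(x, j, axis=1)])
        coef, _, _, _ = np.linalg.lstsq(others, y, rcond=None)
        resid = y - others @ coef
        ss_tot = np.sum((y - y.mean()) ** 2)
        if ss_tot == 0:
            raise ValueError(f"zero-variance variable {name!r}")
        r2 = 1.0 - np.sum(resid**2) / ss_tot
        out[name] = VIF_SENTINEL if r2 >= 1.0 - 1e-12 else 1.0 / (1.0 - r2)
    return pd.Series(out)


def maxent_gain_scorer(presences: pd.DataFrame, background: pd.DataFrame,
                       beta: float = 3.0):
    """Scorer: training gain of a single-variable maximum-entropy fit."""
    from .maxent import fit

    def score(variable: str) -> float:
        model = fit(presences[[variable]], background[[variable]], beta=beta)
        return model.gain

    return score


@dataclass
class SelectionReport:
    correlation: pd.DataFrame
    vif: pd.Series  # on the kept set, after selection
    clusters: list[list[str]]
    kept: list[str]
    dropped: dict[str, str]  # variable -> reason code
    scores: dict[str, float]

    def to_dict(self) -> dict:
        return {
            "correlation": self.correlation.to_dict(),
            "vif": self.vif.to_dict(),
            "clusters": self.clusters,
            "kept": self.kept,
            "dropped": self.dropped,
            "scores": self.scores,
        }


def select_variables(
    samples: pd.DataFrame,
    r_threshold: float = 0.7,
    vif_threshold: float = 10.0,
    scorer=None,
    presences: pd.DataFrame | None = None,
    beta: float = 3.0,
    force_keep: list[str] | None = None,
    force_drop: list[str] | None = None,
) -> SelectionReport:
    """Greedy collinearity screen over the background sample.

    ``scorer`` maps a variable name to a univariate contribution; when
    omitted it defaults to the maximum-entropy training gain against
    ``presences`` (which must then be provided).  ``force_keep`` /
    ``force_drop`` are manual overrides for expert judgment: forced drops
    are removed up front, forced keeps are immune to both screens.
    Exact score ties keep the variable earlier in column order.
    """
    if scorer is None:
        if presences is None:
            raise ValueError("provide a scorer or a presence table for the default")
        scorer = maxent_gain_scorer(presences, samples, beta=beta)
    force_keep = list(force_keep or [])
    candidates = [c for c in samples.columns if c not in set(force_drop or [])]
    dropped: dict[str, str] = {c: "forced" for c in (force_drop or []) if c in samples.columns}
    if not candidates:
        raise ValueError("all variables dropped")

    corr = pearson_matrix(samples[candidates])
    scores = {v: float(scorer(v)) for v in candidates}
    order = {v: i for i, v in enumerate(candidates)}  # tie-break rank

    def better(a: str, b: str) -> bool:
        return (scores[a], -order[a]) > (scores[b], -order[b])

    # transitive closure of |r| > threshold via union-find
    parent = {v: v for v in candidates}

    def find(v):
        while parent[v] != v:
            parent[v] = parent[parent[v]]
            v = parent[v]
        return v

    for i, a in enumerate(candidates):
        for b in candidates[i + 1:]:
            if abs(corr.loc[a, b]) > r_threshold:
                parent[find(a)] = find(b)
    clusters_map: dict[str, list[str]] = {}
    for v in candidates:
        clusters_map.setdefault(find(v), []).append(v)
    clusters = list(clusters_map.values())

    kept: list[str] = []
    for cluster in clusters:
        keepers = [v for v in cluster if v in force_keep]
        best = max(cluster, key=lambda v: (scores[v], -order[v]))
        winners = set(keepers) | {best}
        for v in cluster:
            if v in winners:
                kept.append(v)
            else:
                dropped[v] = "pairwise"
    kept.sort(key=lambda v: order[v])

    # iterative VIF pruning on the survivors
    while len(kept) > 1:
        vifs = vif_scores(samples[kept])
        offenders = [v for v in kept if vifs[v] > vif_threshold and v not in force_keep]
        if not offenders:
            break
        worst = min(offenders, key=lambda v: (scores[v], -order[v]))
        kept.remove(worst)
        dropped[worst] = "vif"
    if not kept:
        raise ValueError("all variables dropped")
    final_vif = vif_scores(samples[kept]) if len(kept) > 1 else pd.Series({kept[0]: 1.0})
    return SelectionReport(
        correlation=corr, vif=final_vif, clusters=clusters,
        kept=kept, dropped=dropped, scores=scores,
    )
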