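"""Mass-domain feature utilities.

ppm matching of query masses to table features, electrospray adduct and
13C-isotopologue arithmetic, QC filtering of features by replicate
reproducibility, replicate averaging, and cross-study feature overlap.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .tabular import FeatureTable, TargetQuery

# exact monoisotopic mass shifts, Th (CODATA/IUPAC; singly charged)
PROTON = 1.0072765
NA_FOR_H = 21.9819442   # Na replaces H
H2O = 18.0105646
C13_SHIFT = 1.0033548   # 13C - 12C

#: registry of singly-charged positive-mode adducts: shift from neutral M.
ADDUCTS: dict[str, float] = {
    "[M+H]+": PROTON,
    "[M+Na]+": PROTON + NA_FOR_H,
    "[M+2Na-H]+": PROTON + 2 * NA_FOR_H,
    "[M-H2O]+": PROTON - H2O,  # water loss from the protonated ion
}
# one-13C isotopologue of each adduct form
ADDUCTS.update({f"13C{name}": delta + C13_SHIFT for name, delta in list(ADDUCTS.items())})


@dataclass(frozen=True)
class FeatureMatch:
    """A query mass paired to a table feature within tolerance."""

    query_index: int
    feature_index: int
    ppm_error: float
    rt_delta: Optional[float] = None


@dataclass
class QcReport:
    """Per-feature QC metrics and pass/fail flags.

    ``metrics`` columns: feature_id, median_cv_pct, replicate_cor,
    missing_pct, pass_cv, pass_cor, pass_missing, cor_skipped, retained.
    """

    metrics: pd.DataFrame
    cv_max: float
    rep_cor_min: float
    missing_max: float

    @property
    def retained_indices(self) -> np.ndarray:
        return np.flatnonzero(self.metrics["retained"].to_numpy())


def ppm_difference(observed_mz: float, reference_mz: float) -> float:
    """Signed relative mass deviation, 1e6 * (observed - reference) / reference."""
    if observed_mz <= 0 or reference_mz <= 0:
        raise ValueError("masses must be positive")
    return 1e6 * (observed_mz - reference_mz) / reference_mz


def adduct_transform(mz: float, from_adduct: str, to_adduct: str) -> float:
    """Predict the m/z of ``to_adduct`` given an observed ``from_adduct`` ion.

    Exact monoisotopic arithmetic for singly charged ions:
    mz - delta(from) + delta(to).
    """
    for name in (from_adduct, to_adduct):
        if name not in ADDUCTS:
            raise KeyError(
                f"unknown adduct {name!r}; registry: {sorted(ADDUCTS)}"
            )
    return mz - ADDUCTS[from_adduct] + ADDUCTS[to_adduct]


def isotopologue_mz(mz: float, n_13c: int = 1) -> float:
    """m/z of the n-13C isotopologue of an ion (same charge/adduct)."""
    return mz + n_13c * C13_SHIFT


def match_features(
    table: FeatureTable,
    queries: Sequence[TargetQuery],
    ppm_tol: float = 10.0,
    rt_tol: float = 30.0,
) -> list[FeatureMatch]:
    """All features within ``ppm_tol`` (and ``rt_tol`` when the query has an
    rt) of each query, sorted per query by absolute ppm error."""
    if ppm_tol <= 0:
        raise ValueError("ppm_tol must be positive")
    if any(q.rt is not None for q in queries) and rt_tol <= 0:
        raise ValueError("rt_tol must be positive when queries carry rt")
    out: list[FeatureMatch] = []
    for qi, q in enumerate(queries):
        ppm = 1e6 * (table.mz - q.mz) / q.mz
        ok = np.abs(ppm) <= ppm_tol
        if q.rt is not None:
            ok &= np.abs(table.rt - q.rt) <= rt_tol
        hits = np.flatnonzero(ok)
        hits = hits[np.argsort(np.abs(ppm[hits]), kind="stable")]
        for fi in hits:
            out.append(
                FeatureMatch(
                    query_index=qi,
                    feature_index=int(fi),
                    ppm_error=float(ppm[fi]),
                    rt_delta=None if q.rt is None else float(table.rt[fi] - q.rt),
                )
            )
    return out


def _normalize_replicate_map(
    table: FeatureTable, replicate_map: Optional[dict[str, list[str]]]
) -> list[list[int]]:
    """Groups of column indices; identity grouping when map is None."""
    if replicate_map is None:
        return [[j] for j in range(table.n_samples)]
    col = {s: j for j, s in enumerate(table.sample_ids)}
    groups: list[list[int]] = []
    seen: set[int] = set()
    for name, members in replicate_map.items():
        idx = []
        for m in members:
            if m not in col:
                raise KeyError(f"replicate map names unknown sample {m!r}")
            if col[m] in seen:
                raise ValueError(f"sample {m!r} appears in more than one group")
            seen.add(col[m])
            idx.append(col[m])
        if not idx:
            raise ValueError(f"replicate group {name!r} is empty")
        groups.append(idx)
    if len(seen) != table.n_samples:
        missing = [s for s in table.sample_ids if col[s] not in seen]
        raise ValueError(f"replicate map does not cover samples {missing}")
    return groups


def qc_filter(
    table: FeatureTable,
    replicate_map: Optional[dict[str, list[str]]] = None,
    cv_max: float = 50.0,
    rep_cor_min: float = 0.7,
    missing_max: float = 30.0,
) -> tuple[FeatureTable, QcReport]:
    """Retain features reproducible across technical replicates.

    A feature passes when its median coefficient of variation across
    replicate groups is strictly below ``cv_max`` (%), its Pearson
    correlation among pooled technical-replicate pairs is strictly
    above ``rep_cor_min``, and strictly less than ``missing_max`` % of
    its cells are missing. The replicate-correlation criterion is
    skipped (with a flag) when no group has >= 2 replicates or the
    correlation is undefined (constant values).
    """
    groups = _normalize_replicate_map(table, replicate_map)
    X = table.intensities
    n_feat = table.n_features

    missing_pct = 100.0 * np.isnan(X).mean(axis=1)

    median_cv = np.zeros(n_feat)
    rep_cor = np.full(n_feat, np.nan)
    cor_skipped = np.zeros(n_feat, dtype=bool)
    pair_idx = [(g[a], g[b]) for g in groups if len(g) >= 2
                for a in range(len(g)) for b in range(a + 1, len(g))]

    for i in range(n_feat):
        cvs = []
        for g in groups:
            vals = X[i, g]
            vals = vals[~np.isnan(vals)]
            if len(vals) == 0:
                continue
            mean = vals.mean()
            if len(vals) == 1 or mean == 0:
                cvs.append(0.0 if len(vals) == 1 else np.nan)
            else:
                cvs.append(100.0 * vals.std(ddof=1) / mean)
        cvs = [c for c in cvs if not np.isnan(c)]
        median_cv[i] = np.median(cvs) if cvs else np.nan

        if pair_idx:
            a = np.array([X[i, u] for u, _ in pair_idx])
            b = np.array([X[i, v] for _, v in pair_idx])
            m = ~np.isnan(a) & ~np.isnan(b)
            if m.sum() >= 3 and a[m].std() > 0 and b[m].std() > 0:
                rep_cor[i] = np.corrcoef(a[m], b[m])[0, 1]
            else:
                cor_skipped[i] = True
        else:
            cor_skipped[i] = True

    pass_cv = median_cv < cv_max
    pass_missing = missing_pct < missing_max
    pass_cor = np.where(cor_skipped, True, rep_cor > rep_cor_min)
    retained = pass_cv & pass_missing & pass_cor

    report = QcReport(
        metrics=pd.DataFrame(
            {
                "feature_id": table.feature_ids,
                "median_cv_pct": median_cv,
                "replicate_cor": rep_cor,
                "missing_pct": missing_pct,
                "pass_cv": pass_cv,
                "pass_cor": pass_cor,
                "pass_missing": pass_missing,
                "cor_skipped": cor_skipped,
                "retained": retained,
            }
        ),
        cv_max=cv_max,
        rep_cor_min=rep_cor_min,
        missing_max=missing_max,
    )
    return table.subset(np.flatnonzero(retained)), report


def average_replicates(
    table: FeatureTable, replicate_map: Optional[dict[str, list[str]]]
) -> FeatureTable:
    """Collapse technical replicates to per-sample means of non-missing values."""
    if replicate_map is None:
        return table
    groups = _normalize_replicate_map(table, replicate_map)
    names = list(replicate_map.keys())
    X = table.intensities
    cols = []
    for g in groups:
        with np.errstate(invalid="ignore"):
            cols.append(np.nanmean(X[:, g], axis=1))
    return FeatureTable(
        mz=table.mz.copy(),
        rt=table.rt.copy(),
        intensities=np.column_stack(cols),
        sample_ids=names,
        feature_ids=list(table.feature_ids),
    )


def overlap_features(
    a: Sequence[TargetQuery],
    b: Sequence[TargetQuery],
    ppm_tol: float = 10.0,
    rt_tol: Optional[float] = None,
) -> tuple[list[tuple[int, int]], list[int], list[int]]:
    """Cross-study feature overlap by greedy nearest-ppm one-to-one matching.

    Returns (common pairs as (index in a, index in b), a-only indices,
    b-only indices); counts satisfy |a| = common + a_only and
    |b| = common + b_only.
    """
    if ppm_tol <= 0 or (rt_tol is not None and rt_tol <= 0):
        raise ValueError("tolerances must be positive")
    candidates = []
    for i, qa in enumerate(a):
        for j, qb in enumerate(b):
            ppm = ppm_difference(qa.mz, qb.mz)
            if abs(ppm) > ppm_tol:
                continue
            if rt_tol is not None and qa.rt is not None and qb.rt is not None:
                if abs(qa.rt - qb.rt) > rt_tol:
                    continue
            candidates.append((abs(ppm), i, j))
    candidates.sort()
    used_a: set[int] = set()
    used_b: set[int] = set()
    pairs: list[tuple[int, int]] = []
    for _, i, j in candidates:
        if i in used_a or j in used_b:
            continue
        pairs.append((i, j))
        used_a.add(i)
        used_b.add(j)
    a_only = [i for i in range(len(a)) if i not in used_a]
    b_only = [j for j in range(len(b)) if j not in used_b]
    return pairs, a_only, b_only
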