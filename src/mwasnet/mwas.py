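"""Targeted metabolome-wide association study.

Correlate an anchor metabolite's intensity profile (a table feature or
an external assay vector) against every m/z feature in the table,
attach two-sided p-values from the t transform of the correlation
coefficient, and control the false discovery rate with the
Benjamini-Hochberg step-up procedure.

Intensities are log10-transformed by default before Pearson
correlation (LC/MS ion intensities are heavy-tailed; zeros become
missing). Missing data are handled by pairwise-complete deletion with
a minimum-pairs requirement; features failing it are reported with
undefined r and excluded from the multiple-testing correction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .tabular import FeatureTable, TargetQuery
from .features import ADDUCTS, C13_SHIFT, match_features

DEFAULT_MIN_PAIRS = 10


@dataclass
class MwasResult:
    """Per-feature association records against one named target.

    ``records`` columns: feature_id, mz, rt, r, n_used, p, q,
    mean_log_intensity. ``method`` is "pearson" or "spearman".
    """

    target_id: str
    method: str
    records: pd.DataFrame
    alpha: float = 0.05
    excluded_self: list[str] = field(default_factory=list)

    def significant(self, alpha: Optional[float] = None) -> pd.DataFrame:
        a = self.alpha if alpha is None else alpha
        q = self.records["q"]
        return self.records[q.notna() & (q < a)]


def _log10_missing_zeros(x: np.ndarray) -> np.ndarray:
    """log10 with zeros (and negatives) mapped to missing."""
    out = np.where(np.asarray(x, dtype=float) > 0, x, np.nan)
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.log10(out)


def correlate_profile(
    x: np.ndarray,
    y: np.ndarray,
    method: str = "pearson",
    min_pairs: int = DEFAULT_MIN_PAIRS,
) -> tuple[float, int]:
    """Correlation of two intensity profiles on pairwise-complete samples.

    Returns (r, n_used); r is NaN when fewer than ``min_pairs`` complete
    pairs remain or either profile is constant. Spearman uses midrank
    ties via scipy.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("profiles must have equal length")
    m = np.isfinite(x) & np.isfinite(y)
    n_used = int(m.sum())
    if n_used < min_pairs:
        return np.nan, n_used
    xs, ys = x[m], y[m]
    if xs.std() == 0 or ys.std() == 0:
        return np.nan, n_used
    if method == "pearson":
        r = float(stats.pearsonr(xs, ys).statistic)
    elif method == "spearman":
        r = float(stats.spearmanr(xs, ys).statistic)
    else:
        raise ValueError(f"unknown method {method!r}")
    return r, n_used


def correlation_pvalue(r: float, n_used: int, method: str = "pearson") -> float:
    """Two-sided p-value for a correlation coefficient.

    Uses t = r*sqrt(n-2)/sqrt(1-r^2) on n-2 degrees of freedom; the
    same t approximation is applied to Spearman's rho. |r| = 1 maps to
    p = 0 by convention.
    """
    if method not in ("pearson", "spearman"):
        raise ValueError(f"unknown method {method!r}")
    if not np.isfinite(r):
        return np.nan
    if n_used < 3:
        raise ValueError("need at least 3 complete pairs for a p-value")
    if abs(r) >= 1.0:
        return 0.0
    df = n_used - 2
    t = r * np.sqrt(df) / np.sqrt(1.0 - r * r)
    return float(2.0 * stats.t.sf(abs(t), df))


def bh_adjust(p: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted values (q-values).

    Undefined (NaN) entries are excluded from the adjustment (m is
    reduced accordingly) and returned as NaN in their original
    positions.
    """
    p = np.asarray(p, dtype=float)
    out = np.full(p.shape, np.nan)
    ok = np.isfinite(p)
    if ok.sum() == 0:
        return out
    if np.any((p[ok] < 0) | (p[ok] > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    out[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return out


def _pairwise_pearson_matrix(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized pairwise-complete Pearson r of each row of X against y."""
    My = np.isfinite(y)
    M = np.isfinite(X) & My[None, :]
    Xz = np.where(M, X, 0.0)
    Yz = np.where(My, y, 0.0)
    Yb = M * Yz[None, :]
    n = M.sum(axis=1).astype(float)
    sx = Xz.sum(axis=1)
    sy = Yb.sum(axis=1)
    sxx = (Xz * Xz).sum(axis=1)
    syy = (Yb * Yz[None, :]).sum(axis=1)
    sxy = (Xz * Yz[None, :]).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        cov = n * sxy - sx * sy
        varx = n * sxx - sx * sx
        vary = n * syy - sy * sy
        r = cov / np.sqrt(varx * vary)
    r[(varx <= 0) | (vary <= 0)] = np.nan
    return np.clip(r, -1.0, 1.0), n.astype(int)


def _self_exclusion_masses(target_mz: float) -> list[float]:
    """Masses of registered adduct/isotopologue forms of the target ion.

    The observed target m/z is taken as the [M+H]+ ion; every registry
    adduct of the same neutral plus one- and two-13C isotopologues of
    each are excluded as self-correlations.
    """
    masses = []
    for name, delta in ADDUCTS.items():
        base = target_mz - ADDUCTS["[M+H]+"] + delta
        masses.extend([base, base + C13_SHIFT, base + 2 * C13_SHIFT])
    masses.append(target_mz)
    return masses


def run_targeted_mwas(
    table: FeatureTable,
    targets: Sequence[TargetQuery],
    method: str = "pearson",
    alpha: float = 0.05,
    exclude_self: bool = True,
    sig_features: Optional[Sequence[float]] = None,
    target_vectors: Optional[dict[str, np.ndarray]] = None,
    ppm_tol: float = 10.0,
    rt_tol: float = 30.0,
    log_transform: bool = True,
    min_pairs: int = DEFAULT_MIN_PAIRS,
) -> list[MwasResult]:
    """Run one targeted MWAS per target.

    Each target is resolved to its best-matching table feature (by
    |ppm error|) unless an external assay vector for it is supplied in
    ``target_vectors`` (keyed by the target's label). The target
    profile is correlated against every scanned feature; features
    within ``ppm_tol`` of the target mass or any registered
    adduct/isotopologue form of it are dropped when ``exclude_self``.
    When ``sig_features`` is given the scan is restricted to features
    matching those masses. q < alpha defines the significant set.
    """
    if method not in ("pearson", "spearman"):
        raise ValueError(f"unknown method {method!r}")
    X = table.intensities
    if log_transform:
        X = _log10_missing_zeros(X)

    scan_idx = np.arange(table.n_features)
    if sig_features is not None:
        sig_q = [TargetQuery(mz=m) for m in sig_features]
        hits = match_features(table, sig_q, ppm_tol=ppm_tol, rt_tol=rt_tol)
        scan_idx = np.array(sorted({h.feature_index for h in hits}), dtype=int)

    results: list[MwasResult] = []
    for q in targets:
        label = q.label
        if target_vectors is not None and label in target_vectors:
            y = np.asarray(target_vectors[label], dtype=float)
            if y.shape[0] != table.n_samples:
                raise ValueError(
                    f"external vector for {label!r} has length {y.shape[0]}, "
                    f"expected {table.n_samples}"
                )
            if log_transform:
                y = _log10_missing_zeros(y)
        else:
            hits = match_features(table, [q], ppm_tol=ppm_tol, rt_tol=rt_tol)
            if not hits:
                raise ValueError(
                    f"target {label!r} matches no table feature and no "
                    f"external vector was supplied"
                )
            y = X[hits[0].feature_index, :]

        keep = scan_idx
        excluded_ids: list[str] = []
        if exclude_self:
            self_mass = np.array(_self_exclusion_masses(q.mz))
            ppm = 1e6 * np.abs(table.mz[keep][:, None] - self_mass[None, :]) / self_mass[None, :]
            is_self = (ppm <= ppm_tol).any(axis=1)
            excluded_ids = [table.feature_ids[i] for i in keep[is_self]]
            keep = keep[~is_self]

        sub = X[keep, :]
        if method == "pearson":
            r, n_used = _pairwise_pearson_matrix(sub, y)
        else:
            r = np.empty(len(keep))
            n_used = np.empty(len(keep), dtype=int)
            for k in range(len(keep)):
                r[k], n_used[k] = correlate_profile(
                    sub[k, :], y, method="spearman", min_pairs=1
                )
        low = n_used < min_pairs
        r = np.where(low, np.nan, r)

        p = np.array(
            [
                correlation_pvalue(ri, ni, method) if np.isfinite(ri) and ni >= 3 else np.nan
                for ri, ni in zip(r, n_used)
            ]
        )
        qvals = bh_adjust(p)
        with np.errstate(all="ignore"):
            mean_log = np.nanmean(
                X[keep, :] if log_transform else _log10_missing_zeros(table.intensities[keep, :]),
                axis=1,
            )
        records = pd.DataFrame(
            {
                "feature_id": [table.feature_ids[i] for i in keep],
                "mz": table.mz[keep],
                "rt": table.rt[keep],
                "r": r,
                "n_used": n_used,
                "p": p,
                "q": qvals,
                "mean_log_intensity": mean_log,
            }
        )
        results.append(
            MwasResult(
                target_id=label,
                method=method,
                records=records,
                alpha=alpha,
                excluded_self=excluded_ids,
            )
        )
    return results
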