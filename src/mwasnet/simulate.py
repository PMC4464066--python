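"""Synthetic LC/MS feature tables with known ground truth.

The generator emulates the statistical structure of a targeted-MWAS
experiment: an anchor metabolite, modules of features correlated with
it on the log-intensity scale (e.g. a late-eluting lipid cluster),
companion ions (adduct/isotopologue copies of a parent with nearly
identical intensity profiles), and a sea of independent null features.
Log10 intensities are drawn from a multivariate normal realizing the
requested correlation structure, then exponentiated to the intensity
scale; a ground-truth ledger records every feature's role so any
discovery run can be scored for precision and recall.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .tabular import FeatureTable, TargetQuery
from .features import C13_SHIFT
from .mwas import _self_exclusion_masses


@dataclass
class ModuleSpec:
    """A block of features correlated with the anchor.

    ``r_anchor`` is each member's true log-scale correlation with the
    anchor; ``r_within`` the member-member correlation (default
    r_anchor**2, i.e. conditionally independent given the anchor).
    Optional explicit m/z and rt place members at chosen coordinates,
    otherwise masses are drawn uniformly and rts from ``rt_range``.
    """

    size: int
    r_anchor: float
    r_within: Optional[float] = None
    rt_range: tuple[float, float] = (350.0, 600.0)
    mz: Optional[Sequence[float]] = None
    rt: Optional[Sequence[float]] = None

    def within(self) -> float:
        return self.r_anchor ** 2 if self.r_within is None else self.r_within


@dataclass
class CompanionSpec:
    """An adduct/isotopologue copy of a structured feature.

    ``parent`` indexes the structured block (0 = anchor, then module
    members in order). The companion's intensity is
    parent * scale + Gaussian noise with sd = noise_sd_frac * sd(parent),
    giving a near-unit correlation, and its m/z is the parent's plus
    ``mz_shift`` (e.g. the 13C-12C mass difference).
    """

    parent: int
    mz_shift: float = C13_SHIFT
    scale: float = 0.1
    noise_sd_frac: float = 0.05
    rt_shift: float = 2.0


@dataclass
class SimConfig:
    """Study conditions for one simulated feature table."""

    n_samples: int = 50
    n_null_features: int = 1000
    modules: list[ModuleSpec] = field(default_factory=list)
    companions: list[CompanionSpec] = field(default_factory=list)
    missing_rate: float = 0.0
    log_mean: float = 6.0
    log_between_sd: float = 1.0   # spread of per-feature baselines
    log_within_sd: float = 0.4    # per-feature biological variation
    anchor_mz: float = 104.1062
    anchor_rt: float = 51.0
    null_rt_range: tuple[float, float] = (30.0, 600.0)
    null_mz_range: tuple[float, float] = (85.0, 1000.0)
    seed: int = 0

    def validate(self) -> None:
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("missing_rate must lie in [0, 1)")
        for k, m in enumerate(self.modules):
            if m.size < 1:
                raise ValueError(f"module {k}: size must be >= 1")
            if not -1.0 < m.r_anchor < 1.0:
                raise ValueError(f"module {k}: r_anchor must lie in (-1, 1)")
            if not -1.0 < m.within() < 1.0:
                raise ValueError(f"module {k}: within-module correlation out of range")


@dataclass
class SimTruth:
    """Ground-truth ledger: per-feature role and planted correlation.

    ``table`` columns: feature_id, role (anchor | module | companion |
    null), true_r (log-scale correlation with the anchor), module_id,
    parent (feature_id of a companion's parent).
    """

    table: pd.DataFrame

    def indices(self, role: str) -> np.ndarray:
        return np.flatnonzero((self.table["role"] == role).to_numpy())

    @property
    def anchor_index(self) -> int:
        return int(self.indices("anchor")[0])


def _structured_correlation(modules: Sequence[ModuleSpec]) -> np.ndarray:
    """Correlation matrix over [anchor, module members...]; single-factor
    across modules (cross-module correlation = product of anchor loadings)."""
    sizes = [m.size for m in modules]
    k = 1 + sum(sizes)
    C = np.eye(k)
    offsets = np.cumsum([1] + sizes[:-1])
    for mod, off in zip(modules, offsets):
        C[0, off:off + mod.size] = mod.r_anchor
        C[off:off + mod.size, 0] = mod.r_anchor
        block = np.full((mod.size, mod.size), mod.within())
        np.fill_diagonal(block, 1.0)
        C[off:off + mod.size, off:off + mod.size] = block
    for a, (ma, off_a) in enumerate(zip(modules, offsets)):
        for b, (mb, off_b) in enumerate(zip(modules, offsets)):
            if a < b:
                cross = ma.r_anchor * mb.r_anchor
                C[off_a:off_a + ma.size, off_b:off_b + mb.size] = cross
                C[off_b:off_b + mb.size, off_a:off_a + ma.size] = cross
    return C


def simulate_feature_table(config: SimConfig) -> tuple[FeatureTable, SimTruth]:
    """Draw one feature table plus its ground-truth ledger.

    Deterministic under ``config.seed``. Raises when a module's
    requested correlation block is not positive definite.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_samples

    C = _structured_correlation(config.modules)
    for k, m in enumerate(config.modules):
        block = _structured_correlation([m])
        if np.linalg.eigvalsh(block).min() <= 1e-12:
            raise ValueError(
                f"module {k}: correlation block (r_anchor={m.r_anchor}, "
                f"r_within={m.within()}) is not positive definite"
            )
    try:
        L = np.linalg.cholesky(C)
    except np.linalg.LinAlgError:
        raise ValueError("combined module correlation matrix is not positive definite")

    m_struct = C.shape[0]
    Z = (L @ rng.standard_normal((m_struct, n)))
    Z_null = rng.standard_normal((config.n_null_features, n))
    Z_all = np.vstack([Z, Z_null])
    p = Z_all.shape[0]

    baselines = rng.normal(config.log_mean, config.log_between_sd, size=p)
    log_int = baselines[:, None] + config.log_within_sd * Z_all
    intensities = 10.0 ** log_int

    # coordinates; random masses are kept >25 ppm away from the anchor's
    # adduct/isotopologue forms so self-exclusion windows stay clean
    def draw_clear(size: int, lo: float, hi: float, guard: np.ndarray) -> np.ndarray:
        out = rng.uniform(lo, hi, size=size)
        for _ in range(100):
            ppm = 1e6 * np.abs(out[:, None] - guard[None, :]) / guard[None, :]
            bad = (ppm <= 25.0).any(axis=1)
            if not bad.any():
                break
            out[bad] = rng.uniform(lo, hi, size=int(bad.sum()))
        return out

    anchor_guard = np.array(_self_exclusion_masses(config.anchor_mz))
    mz = np.empty(p)
    rt = np.empty(p)
    mz[0], rt[0] = config.anchor_mz, config.anchor_rt
    pos = 1
    roles = ["anchor"]
    true_r = [1.0]
    module_id: list[Optional[int]] = [None]
    parent: list[Optional[int]] = [None]
    for k, mod in enumerate(config.modules):
        if mod.mz is not None:
            mz[pos:pos + mod.size] = np.asarray(mod.mz, dtype=float)
        else:
            mz[pos:pos + mod.size] = draw_clear(
                mod.size, *config.null_mz_range, guard=anchor_guard
            )
        if mod.rt is not None:
            rt[pos:pos + mod.size] = np.asarray(mod.rt, dtype=float)
        else:
            rt[pos:pos + mod.size] = rng.uniform(*mod.rt_range, size=mod.size)
        roles += ["module"] * mod.size
        true_r += [mod.r_anchor] * mod.size
        module_id += [k] * mod.size
        parent += [None] * mod.size
        pos += mod.size
    guard = np.concatenate([
        mz[:pos],
        [mz[s.parent] + s.mz_shift for s in config.companions],
        anchor_guard,
    ]) if config.companions else np.concatenate([mz[:pos], anchor_guard])
    mz[pos:] = draw_clear(config.n_null_features, *config.null_mz_range, guard=guard)
    rt[pos:] = rng.uniform(*config.null_rt_range, size=config.n_null_features)
    roles += ["null"] * config.n_null_features
    true_r += [0.0] * config.n_null_features
    module_id += [None] * config.n_null_features
    parent += [None] * config.n_null_features

    # companion ions appended after nulls
    comp_rows = []
    for spec in config.companions:
        if not 0 <= spec.parent < m_struct:
            raise ValueError(f"companion parent {spec.parent} outside structured block")
        par = intensities[spec.parent, :]
        signal = par * spec.scale
        noise = rng.normal(0.0, spec.noise_sd_frac * signal.std(), size=n)
        comp = np.clip(signal + noise, 0.0, None)
        comp_rows.append(comp)
        mz = np.append(mz, mz[spec.parent] + spec.mz_shift)
        rt = np.append(rt, rt[spec.parent] + spec.rt_shift)
        roles.append("companion")
        true_r.append(true_r[spec.parent])
        module_id.append(module_id[spec.parent])
        parent.append(spec.parent)
    if comp_rows:
        intensities = np.vstack([intensities, np.array(comp_rows)])

    if config.missing_rate > 0:
        mask = rng.random(intensities.shape) < config.missing_rate
        intensities = np.where(mask, np.nan, intensities)

    table = FeatureTable(
        mz=mz, rt=rt, intensities=intensities,
        sample_ids=[f"S{j + 1}" for j in range(n)],
    )
    truth = SimTruth(
        table=pd.DataFrame(
            {
                "feature_id": table.feature_ids,
                "role": roles,
                "true_r": true_r,
                "module_id": module_id,
                "parent": [None if pi is None else table.feature_ids[pi] for pi in parent],
            }
        )
    )
    return table, truth


# masses/rts reused as fixture coordinates: phosphocholine-pathway ions
_LIPID_MODULE_MZ = [184.0719, 258.1083, 494.3207, 476.3099,
                    516.3030, 517.3063, 496.3376, 522.3532]
_LIPID_MODULE_RT = [417.0, 426.0, 378.0, 380.0, 379.0, 377.0, 442.0, 460.0]


def choline_casestudy_fixture(
    seed: int = 0,
    n_null_features: int = 500,
) -> tuple[FeatureTable, TargetQuery, SimTruth]:
    """A ready-made choline-like case study.

    The anchor sits at m/z 104.1062 / 51 s with a 13C companion one
    isotope shift up; a phosphocholine-like module of 8 features elutes
    after 350 s with true anchor correlation 0.6; the remainder are
    independent nulls. A targeted MWAS on the fixture concentrates its
    significant features after 350 s plus the isotopologue pair.
    """
    config = SimConfig(
        n_samples=50,
        n_null_features=n_null_features,
        modules=[
            ModuleSpec(
                size=len(_LIPID_MODULE_MZ),
                r_anchor=0.6,
                mz=_LIPID_MODULE_MZ,
                rt=_LIPID_MODULE_RT,
            )
        ],
        companions=[CompanionSpec(parent=0, mz_shift=C13_SHIFT)],
        seed=seed,
    )
    table, truth = simulate_feature_table(config)
    target = TargetQuery(mz=104.1062, rt=51.0, name="choline")
    return table, target, truth
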