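"""Permutation tests, FDR adjustment and the gated two-level test batteries.

Group differences are assessed nonparametrically: the statistic is the
absolute difference of group means, labels are permuted uniformly at
random, and the p-value uses the add-one estimate
``p = (1 + #{permuted >= observed}) / (n_perm + 1)`` so it is never zero
and the test is valid at its nominal level.

The batteries mirror a hierarchical (gated) protocol: connectivity is
tested globally per band first, and only bands with a significant global
difference (P < 0.05) are examined regionally (12 within-region and 66
between-region tests at a fixed P < 0.01, no FDR).  Topology runs a
Benjamini-Hochberg FDR over the three traditional graph measures per band,
and gates the seven tree measures behind a per-band tree-dissimilarity
test, again with FDR over the seven.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as spstats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "PermutationResult",
    "GateReport",
    "permutation_test",
    "fdr_adjust",
    "run_connectivity_battery",
    "run_topology_battery",
    "spearman_correlate",
]


@dataclass
class PermutationResult:
    observed_diff: float
    p_value: float
    n_permutations: int
    seed: int | None


@dataclass
class GateReport:
    """Stage-1 (gating) results per band and gated stage-2 results."""

    stage1: pd.DataFrame
    stage2: pd.DataFrame
    passed_bands: tuple[str, ...] = field(default_factory=tuple)


def _tidy(df: pd.DataFrame) -> pd.DataFrame:
    """Stable column dtypes (empty frames otherwise come out all-object)."""
    casts = {
        c: t
        for c, t in (("observed", float), ("p", float),
                     ("significant", bool), ("passed", bool))
        if c in df.columns
    }
    return df.astype(casts)


def _group_arrays(
    values: Sequence[float], labels: Sequence[str]
) -> tuple[np.ndarray, np.ndarray]:
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    if values.shape[0] != labels.shape[0]:
        raise ValueError("values and labels must have equal length")
    uniq = np.unique(labels)
    if len(uniq) != 2:
        raise ValueError(f"need exactly two groups, got {list(uniq)}")
    a = values[labels == uniq[0]]
    b = values[labels == uniq[1]]
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both groups must be non-empty")
    return a, b


def permutation_test(
    values: Sequence[float],
    labels: Sequence[str],
    n_perm: int = 10000,
    seed: int | None = None,
) -> PermutationResult:
    """Two-sided permutation test of the absolute group-mean difference."""
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    a, b = _group_arrays(values, labels)
    values = np.concatenate([a, b])
    na = len(a)
    observed = abs(a.mean() - b.mean())
    rng = np.random.default_rng(seed)
    n = len(values)
    # vectorized label permutations: argsort of uniforms = random permutation
    idx = np.argsort(rng.random((n_perm, n)), axis=1)
    perm_vals = values[idx]
    diff = np.abs(
        perm_vals[:, :na].mean(axis=1) - perm_vals[:, na:].mean(axis=1)
    )
    count = int((diff >= observed - 1e-12).sum())
    p = (1 + count) / (n_perm + 1)
    return PermutationResult(float(observed), float(p), n_perm, seed)


def fdr_adjust(p_values: Sequence[float], q: float = 0.05) -> np.ndarray:
    """Benjamini-Hochberg step-up over one family; returns boolean flags."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value vector")
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    rejected, _, _, _ = multipletests(p, alpha=q, method="fdr_bh")
    return rejected


def run_connectivity_battery(
    global_df: pd.DataFrame,
    within_df: pd.DataFrame,
    between_df: pd.DataFrame,
    labels: Sequence[str],
    alpha_global: float = 0.05,
    alpha_local: float = 0.01,
    n_perm: int = 10000,
    seed: int | None = None,
) -> GateReport:
    """Gated connectivity battery.

    ``global_df``: subjects x bands.  ``within_df`` / ``between_df``:
    subjects x (band, region[-pair]) MultiIndex columns.  Stage 2 runs only
    for bands whose global test passes ``alpha_global``; the local tests use
    the fixed ``alpha_local`` with no FDR.
    """
    labels = list(labels)
    rng = np.random.default_rng(seed)
    stage1_rows = []
    passed: list[str] = []
    for band in global_df.columns:
        res = permutation_test(
            global_df[band].to_numpy(), labels, n_perm,
            seed=int(rng.integers(2**31)),
        )
        ok = res.p_value < alpha_global
        stage1_rows.append(
            dict(band=band, observed=res.observed_diff, p=res.p_value, passed=ok)
        )
        if ok:
            passed.append(band)
    stage2_rows = []
    for band in passed:
        for kind, df in (("within", within_df), ("between", between_df)):
            if df is None or band not in df.columns.get_level_values(0):
                continue
            for name in df[band].columns:
                res = permutation_test(
                    df[(band, name)].to_numpy(), labels, n_perm,
                    seed=int(rng.integers(2**31)),
                )
                stage2_rows.append(
                    dict(
                        band=band, kind=kind, name=name,
                        observed=res.observed_diff, p=res.p_value,
                        significant=res.p_value < alpha_local,
                    )
                )
    return GateReport(
        stage1=_tidy(pd.DataFrame(stage1_rows)),
        stage2=_tidy(pd.DataFrame(
            stage2_rows,
            columns=["band", "kind", "name", "observed", "p", "significant"],
        )),
        passed_bands=tuple(passed),
    )


def run_topology_battery(
    traditional_df: pd.DataFrame,
    dissimilarity_df: pd.DataFrame,
    tree_df: pd.DataFrame,
    labels: Sequence[str],
    alpha: float = 0.05,
    q: float = 0.05,
    n_perm: int = 10000,
    seed: int | None = None,
) -> GateReport:
    """Topology battery: FDR over the traditional trio per band, then tree
    measures gated behind the per-band dissimilarity test.

    ``traditional_df`` and ``tree_df`` have (band, measure) MultiIndex
    columns; ``dissimilarity_df`` has one column per band.
    """
    labels = list(labels)
    rng = np.random.default_rng(seed)
    stage1_rows = []
    # traditional measures: per band, permutation p over each of the three
    # measures, BH-corrected within the band's family
    for band in sorted(set(traditional_df.columns.get_level_values(0))):
        sub = traditional_df[band]
        results = {
            m: permutation_test(
                sub[m].to_numpy(), labels, n_perm, seed=int(rng.integers(2**31))
            )
            for m in sub.columns
        }
        flags = fdr_adjust([results[m].p_value for m in sub.columns], q=q)
        for m, flag in zip(sub.columns, flags):
            stage1_rows.append(
                dict(
                    band=band, kind="traditional", name=m,
                    observed=results[m].observed_diff, p=results[m].p_value,
                    significant=bool(flag), passed=bool(flag),
                )
            )
    passed: list[str] = []
    dissim_rows = []
    for band in dissimilarity_df.columns:
        res = permutation_test(
            dissimilarity_df[band].to_numpy(), labels, n_perm,
            seed=int(rng.integers(2**31)),
        )
        ok = res.p_value < alpha
        dissim_rows.append(
            dict(
                band=band, kind="dissimilarity", name="dissimilarity",
                observed=res.observed_diff, p=res.p_value,
                significant=ok, passed=ok,
            )
        )
        if ok:
            passed.append(band)
    stage2_rows = []
    for band in passed:
        sub = tree_df[band]
        results = {
            m: permutation_test(
                sub[m].to_numpy(), labels, n_perm, seed=int(rng.integers(2**31))
            )
            for m in sub.columns
        }
        flags = fdr_adjust([results[m].p_value for m in sub.columns], q=q)
        for m, flag in zip(sub.columns, flags):
            stage2_rows.append(
                dict(
                    band=band, kind="tree", name=m,
                    observed=results[m].observed_diff, p=results[m].p_value,
                    significant=bool(flag),
                )
            )
    return GateReport(
        stage1=_tidy(pd.DataFrame(stage1_rows + dissim_rows)),
        stage2=_tidy(pd.DataFrame(
            stage2_rows,
            columns=["band", "kind", "name", "observed", "p", "significant"],
        )),
        passed_bands=tuple(passed),
    )


@dataclass
class SpearmanResult:
    rho: float
    p_value: float
    valid: bool


def spearman_correlate(
    a: Sequence[float],
    b: Sequence[float],
    n_perm: int = 10000,
    seed: int | None = None,
) -> SpearmanResult:
    """Spearman rank correlation with a permutation p-value.

    Constant input leaves the correlation undefined; the result is flagged
    rather than raising.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("inputs must be equal-length vectors")
    if a.size < 4:
        raise ValueError("need at least four observations")
    if np.all(a == a[0]) or np.all(b == b[0]):
        return SpearmanResult(float("nan"), float("nan"), False)
    rho = float(spstats.spearmanr(a, b).statistic)
    rng = np.random.default_rng(seed)
    ra = spstats.rankdata(a)
    rb = spstats.rankdata(b)
    idx = np.argsort(rng.random((n_perm, a.size)), axis=1)
    perm_rb = rb[idx]
    ra_c = ra - ra.mean()
    prb_c = perm_rb - perm_rb.mean(axis=1, keepdims=True)
    denom = np.sqrt((ra_c**2).sum() * (prb_c**2).sum(axis=1))
    perm_rho = (prb_c @ ra_c) / denom
    count = int((np.abs(perm_rho) >= abs(rho) - 1e-12).sum())
    return SpearmanResult(rho, (1 + count) / (n_perm + 1), True)
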