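"""Group-level statistics for spectra, behavior tables and neurochemistry.

The frequency-wise spectral comparison reproduces the Bonferroni construction
used for absence-seizure spectra: with a 0.5 Hz grid over 0.5-26 Hz there are
52 analyzed frequencies, and with 6 pairwise group comparisons in the design
the multiplicity factor is 52 x 6 = 312, applied to every per-frequency
Mann-Whitney p-value.  ``n_comparisons`` is always an explicit input — it is
a property of the experimental design, never inferred from the data.
"""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd
from scipy import stats as sst

from .types import (
    DegenerateSignalError,
    ParameterError,
    PowerSpectrum,
    SpectralComparison,
    StatResult,
)

__all__ = [
    "bonferroni_factor",
    "mann_whitney",
    "kruskal_wallis",
    "one_way_anova",
    "compare_spectra",
    "percent_of_control",
    "turnover_ratio",
    "group_turnover",
    "analyze_group_table",
]

EXACT_MAX_N = 20  # exact Mann-Whitney null distribution up to this total N


def bonferroni_factor(n_frequencies: int, n_comparisons: int) -> int:
    """Multiplicity factor: analyzed frequencies x group comparisons."""
    if n_frequencies < 1 or n_comparisons < 1:
        raise ParameterError("both inputs must be positive integers")
    return int(n_frequencies) * int(n_comparisons)


def _as_groups(groups) -> list[np.ndarray]:
    out = [np.asarray(g, dtype=float).ravel() for g in groups]
    if any(g.size == 0 for g in out):
        raise ParameterError("empty group")
    return out


def mann_whitney(
    group_a, group_b, multiplicity_factor: int = 1
) -> StatResult:
    """Two-sided Mann-Whitney U test.

    Uses the exact null distribution for small samples (total N <= 20, no
    ties) and the tie-corrected, continuity-corrected normal approximation
    otherwise.
    """
    a, b = _as_groups([group_a, group_b])
    pooled = np.concatenate([a, b])
    has_ties = np.unique(pooled).size < pooled.size
    method = "exact" if (pooled.size <= EXACT_MAX_N and not has_ties) else "asymptotic"
    res = sst.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return StatResult(
        test="mann-whitney",
        statistic=float(res.statistic),
        df=None,
        p_raw=float(res.pvalue),
        multiplicity_factor=multiplicity_factor,
    )


def kruskal_wallis(groups, multiplicity_factor: int = 1) -> StatResult:
    """Kruskal-Wallis H test (one-way ANOVA by ranks) across k groups."""
    gs = _as_groups(groups)
    if len(gs) < 2:
        raise ParameterError("need at least two groups")
    res = sst.kruskal(*gs)
    return StatResult(
        test="kruskal-wallis",
        statistic=float(res.statistic),
        df=(len(gs) - 1,),
        p_raw=float(res.pvalue),
        multiplicity_factor=multiplicity_factor,
    )


def one_way_anova(groups, multiplicity_factor: int = 1) -> StatResult:
    """Classical one-way ANOVA: between/within F on (k-1, N-k) df."""
    gs = _as_groups(groups)
    if len(gs) < 2 or any(g.size < 2 for g in gs):
        raise ParameterError("need >= 2 groups with >= 2 values each")
    n_total = sum(g.size for g in gs)
    k = len(gs)
    ssw = sum(np.sum((g - g.mean()) ** 2) for g in gs)
    if ssw == 0.0:
        raise DegenerateSignalError("zero within-group variance; F undefined")
    res = sst.f_oneway(*gs)
    return StatResult(
        test="one-way-anova",
        statistic=float(res.statistic),
        df=(k - 1, n_total - k),
        p_raw=float(res.pvalue),
        multiplicity_factor=multiplicity_factor,
    )


def compare_spectra(
    group_a: list[PowerSpectrum],
    group_b: list[PowerSpectrum],
    alpha: float = 0.05,
    n_comparisons: int = 1,
) -> SpectralComparison:
    """Frequency-wise two-sided Mann-Whitney comparison of two spectrum groups.

    Every per-frequency p-value carries the Bonferroni multiplicity factor
    ``n_frequencies * n_comparisons``; bins with adjusted p below ``alpha``
    are flagged.
    """
    if len(group_a) < 2 or len(group_b) < 2:
        raise ParameterError("need at least two spectra per group")
    grid = group_a[0].frequencies
    for s in list(group_a) + list(group_b):
        if s.frequencies.shape != grid.shape or not np.allclose(s.frequencies, grid):
            raise ParameterError("spectra are on different frequency grids")
    n_freq = grid.size
    factor = bonferroni_factor(n_freq, n_comparisons)
    mat_a = np.stack([s.power for s in group_a])  # (n_a, n_freq)
    mat_b = np.stack([s.power for s in group_b])
    results = tuple(
        mann_whitney(mat_a[:, j], mat_b[:, j], multiplicity_factor=factor)
        for j in range(n_freq)
    )
    return SpectralComparison(
        frequencies=grid.copy(),
        results=results,
        n_frequencies=n_freq,
        n_comparisons=n_comparisons,
        alpha=alpha,
    )


def percent_of_control(drug_mean: float, vehicle_mean: float) -> float:
    """Treated-group mean as a percent of the vehicle mean, one decimal, half-up."""
    if vehicle_mean == 0:
        raise ParameterError("vehicle mean must be non-zero")
    pct = Decimal(100) * Decimal(repr(float(drug_mean))) / Decimal(repr(float(vehicle_mean)))
    return float(pct.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


def turnover_ratio(metabolite: float, parent: float) -> float:
    """Monoamine turnover: metabolite concentration over the parent amine."""
    if parent <= 0:
        raise ParameterError("parent amine concentration must be positive")
    return float(metabolite) / float(parent)


def group_turnover(metabolite, parent) -> float:
    """Group turnover summary: mean of per-sample metabolite/parent ratios."""
    m, p = _as_groups([metabolite, parent])
    if m.shape != p.shape:
        raise ParameterError("metabolite and parent arrays must align per sample")
    return float(np.mean([turnover_ratio(mi, pi) for mi, pi in zip(m, p)]))


_TABLE_TESTS = {
    "mann-whitney": mann_whitney,
    "anova": one_way_anova,
    "kruskal-wallis": kruskal_wallis,
}


def analyze_group_table(
    table: pd.DataFrame,
    group_col: str,
    measures: list[str] | None = None,
    test: str = "mann-whitney",
    multiplicity_factor: int | None = None,
) -> pd.DataFrame:
    """Run one test per measure column of a one-row-per-animal group table.

    The Bonferroni factor defaults to the number of measures tested.  Returns
    a tidy frame with statistic, raw and adjusted p per measure.
    """
    if group_col not in table.columns:
        raise ParameterError(f"missing group column {group_col!r}")
    if test not in _TABLE_TESTS:
        raise ParameterError(f"unknown test {test!r}; have {sorted(_TABLE_TESTS)}")
    measures = measures or [c for c in table.columns if c != group_col]
    factor = multiplicity_factor if multiplicity_factor is not None else len(measures)
    labels = list(pd.unique(table[group_col]))
    rows = []
    for col in measures:
        groups = [table.loc[table[group_col] == lab, col].dropna().to_numpy()
                  for lab in labels]
        if test == "mann-whitney":
            if len(groups) != 2:
                raise ParameterError("mann-whitney needs exactly two groups")
            r = mann_whitney(*groups, multiplicity_factor=factor)
        else:
            r = _TABLE_TESTS[test](groups, multiplicity_factor=factor)
        rows.append({
            "measure": col,
            "test": r.test,
            "statistic": r.statistic,
            "df": "x".join(str(d) for d in r.df) if r.df else "",
            "p_raw": r.p_raw,
            "p_adjusted": r.p_adjusted,
            "multiplicity_factor": r.multiplicity_factor,
        })
    return pd.DataFrame(rows)
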