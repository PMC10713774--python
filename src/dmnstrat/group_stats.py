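"""Univariate subgroup comparisons with per-modality FDR control.

Once connectivity-derived subgroups exist, every demographic, connectivity,
cognitive and psychopathological variable is compared between subgroup 1 and
subgroup 2 (and post hoc between each subgroup and the healthy controls).
The test is chosen per variable: chi-square for categorical variables
(Fisher's exact for sparse 2x2 tables), Welch's two-sample t test for
continuous variables that pass a Shapiro-Wilk normality screen in both
groups, and the Mann-Whitney U test otherwise.  Raw p values are adjusted
with the Benjamini-Hochberg step-up procedure *within each modality*, and
a comparison is called significant at p_FDR < 0.05.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sp_stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "MODALITIES",
    "ClinicalTable",
    "TestResult",
    "compare_groups",
    "fdr_adjust",
    "subgroup_comparison_suite",
]

#: Valid modality tags; FDR adjustment is applied separately within each.
MODALITIES = ("demography", "connectivity", "cognition", "psychopathology")

#: Clinical variable registry: name -> (modality, patient mean, control mean, sd).
#: PANSS sub-scores are only defined for patients (controls carry NaN).
#: Reference locations/scales are typical first-episode values; ``mental_flexibility``
#: counts set-shifting errors and ``reaction_time`` is in milliseconds (both
#: higher-is-worse), the remaining cognitive scores are higher-is-better.
CLINICAL_VARIABLES: dict[str, tuple[str, float, float, float]] = {
    "panss_pos": ("psychopathology", 18.2, np.nan, 4.3),
    "panss_neg": ("psychopathology", 18.1, np.nan, 7.4),
    "panss_gen": ("psychopathology", 36.8, np.nan, 9.7),
    "verbal_iq": ("cognition", 100.6, 112.6, 14.0),
    "verbal_memory": ("cognition", 55.8, 58.2, 9.0),
    "verbal_fluency": ("cognition", 13.7, 16.8, 4.5),
    "mental_flexibility": ("cognition", 25.4, 16.1, 15.0),
    "reaction_time": ("cognition", 336.6, 318.9, 45.0),
}


@dataclass
class ClinicalTable:
    """Clinical measures keyed to participants.

    ``data`` must contain ``participant_id`` and ``group`` (``patient`` /
    ``control``) columns; every remaining column is a variable and must have
    a modality tag in ``modalities``.
    """

    data: pd.DataFrame
    modalities: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for col in ("participant_id", "group"):
            if col not in self.data.columns:
                raise ValueError(f"clinical table must contain a {col!r} column")
        if not self.modalities:
            self.modalities = {
                v: CLINICAL_VARIABLES[v][0] for v in self.variables if v in CLINICAL_VARIABLES
            }
        for var in self.variables:
            tag = self.modalities.get(var)
            if tag not in MODALITIES:
                raise ValueError(f"variable {var!r} lacks a valid modality tag (got {tag!r})")

    @property
    def variables(self) -> list[str]:
        return [c for c in self.data.columns if c not in ("participant_id", "group")]

    def values_for(self, variable: str, participant_ids: Iterable[str]) -> np.ndarray:
        sub = self.data.set_index("participant_id").loc[list(participant_ids), variable]
        return sub.to_numpy(dtype=float)


@dataclass
class TestResult:
    variable: str
    comparison: str
    modality: str
    test_name: str  # chi2 | fisher | t | mann_whitney
    statistic: float
    p_raw: float
    p_fdr: float | None = None
    group_summaries: dict = field(default_factory=dict)

    @property
    def significant(self) -> bool:
        return self.p_fdr is not None and self.p_fdr < 0.05


def _is_normalish(x: np.ndarray) -> bool:
    # Shapiro-Wilk screen; tiny groups and degenerate samples are handled by
    # the caller's fallbacks, here we only answer the normality question.
    if len(x) < 3 or np.ptp(x) == 0:
        return False
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return sp_stats.shapiro(x).pvalue > 0.05


def compare_groups(
    values_a: Sequence,
    values_b: Sequence,
    variable_type: str = "continuous",
    variable: str = "",
    modality: str = "connectivity",
    comparison: str = "",
    force_test: str | None = None,
) -> TestResult:
    """Two-group comparison with the documented test-dispatch rule.

    Continuous: Welch t if Shapiro-Wilk p > 0.05 in both groups, else
    Mann-Whitney U (exact null for combined n <= 20 without ties, mid-rank /
    tie-corrected normal approximation otherwise).  Categorical: the two
    inputs are category-label sequences; chi-square on the contingency
    table, replaced by Fisher's exact test when any expected cell count is
    below 5 (2x2 tables; larger sparse tables keep chi-square with a
    warning).  ``force_test`` overrides the dispatch.
    """
    if variable_type == "categorical":
        a = pd.Series(list(values_a))
        b = pd.Series(list(values_b))
        if a.empty or b.empty:
            raise ValueError("categorical comparison requires non-empty groups")
        cats = sorted(set(a) | set(b), key=str)
        table = np.array(
            [[(a == c).sum() for c in cats], [(b == c).sum() for c in cats]], dtype=float
        )
        table = table[:, table.sum(axis=0) > 0]
        summaries = {"counts_a": table[0].tolist(), "counts_b": table[1].tolist(), "categories": cats}
        if table.shape[1] < 2:
            return TestResult(variable, comparison, modality, "chi2", 0.0, 1.0, None, summaries)
        expected = np.outer(table.sum(1), table.sum(0)) / table.sum()
        test = force_test or ("fisher" if (expected < 5).any() and table.shape == (2, 2) else "chi2")
        if (expected < 5).any() and table.shape != (2, 2) and force_test is None:
            warnings.warn(
                f"{variable or 'categorical variable'}: expected cell below 5 in a "
                f"{table.shape[1]}-category table; keeping chi-square",
                stacklevel=2,
            )
        if test == "fisher":
            stat, p = sp_stats.fisher_exact(table)
        else:
            chi2 = sp_stats.chi2_contingency(table, correction=False)
            stat, p = chi2.statistic, chi2.pvalue
        return TestResult(variable, comparison, modality, test, float(stat), float(p), None, summaries)

    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    a, b = a[~np.isnan(a)], b[~np.isnan(b)]
    if len(a) < 2 or len(b) < 2:
        raise ValueError(
            f"{variable or 'variable'}: need >=2 observations per group "
            f"(got {len(a)}, {len(b)})"
        )
    summaries = {
        "mean_a": float(a.mean()), "mean_b": float(b.mean()),
        "median_a": float(np.median(a)), "median_b": float(np.median(b)),
        "n_a": len(a), "n_b": len(b),
    }
    test = force_test
    if test is None:
        if np.ptp(a) == 0 and np.ptp(b) == 0:
            if a[0] == b[0]:
                return TestResult(variable, comparison, modality, "t", 0.0, 1.0, None, summaries)
            warnings.warn(
                f"{variable or 'variable'}: zero variance in both groups; "
                "falling back to Mann-Whitney U",
                stacklevel=2,
            )
            test = "mann_whitney"
        else:
            test = "t" if (_is_normalish(a) and _is_normalish(b)) else "mann_whitney"
    if test == "t":
        res = sp_stats.ttest_ind(a, b, equal_var=False)
        stat, p = res.statistic, res.pvalue
    elif test == "mann_whitney":
        has_ties = len(np.unique(np.concatenate([a, b]))) < len(a) + len(b)
        method = "exact" if (len(a) + len(b) <= 20 and not has_ties) else "asymptotic"
        res = sp_stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
        stat, p = res.statistic, res.pvalue
    else:
        raise ValueError(f"unknown test {test!r} for continuous data")
    return TestResult(variable, comparison, modality, test, float(stat), float(min(p, 1.0)), None, summaries)


def fdr_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p values (monotone, capped at 1)."""
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _adjust_within_modality(results: list[TestResult]) -> None:
    groups: dict[tuple[str, str], list[TestResult]] = {}
    for r in results:
        groups.setdefault((r.comparison, r.modality), []).append(r)
    for rs in groups.values():
        adj = fdr_adjust([r.p_raw for r in rs])
        for r, q in zip(rs, adj):
            r.p_fdr = float(q)


def subgroup_comparison_suite(
    labels: Mapping[str, int],
    clinical: ClinicalTable,
    features: pd.DataFrame | None = None,
    categorical_variables: Sequence[str] = (),
    include_posthoc_vs_controls: bool = True,
) -> list[TestResult]:
    """Full univariate validation suite for a two-subgroup solution.

    ``labels`` maps patient ids to subgroup numbers (1, 2).  ``features`` is
    an optional per-participant connectivity table (index or
    ``participant_id`` column, one column per ROI pair) covering patients
    and controls.  Runs subgroup-1 vs subgroup-2 on every variable, plus
    post hoc comparisons of each subgroup against the controls, and applies
    BH-FDR within each (comparison, modality) family.  Variables with fewer
    than two observations in either group (e.g. PANSS for controls) are
    skipped.
    """
    sz1 = [p for p, l in labels.items() if l == 1]
    sz2 = [p for p, l in labels.items() if l == 2]
    if len(sz1) < 2 or len(sz2) < 2:
        raise ValueError(
            f"subgroup too small for comparison suite (sizes {len(sz1)}, {len(sz2)})"
        )
    hc = clinical.data.loc[clinical.data["group"] == "control", "participant_id"].tolist()

    feat = None
    if features is not None:
        feat = features.set_index("participant_id") if "participant_id" in features.columns else features

    comparisons = [("SZ1-vs-SZ2", sz1, sz2)]
    if include_posthoc_vs_controls and hc:
        comparisons += [("SZ1-vs-HC", sz1, hc), ("SZ2-vs-HC", sz2, hc)]

    results: list[TestResult] = []
    for name, ga, gb in comparisons:
        for var in clinical.variables:
            vtype = "categorical" if var in categorical_variables else "continuous"
            va = clinical.values_for(var, ga) if vtype == "continuous" else \
                clinical.data.set_index("participant_id").loc[ga, var]
            vb = clinical.values_for(var, gb) if vtype == "continuous" else \
                clinical.data.set_index("participant_id").loc[gb, var]
            if vtype == "continuous":
                if np.sum(~np.isnan(va)) < 2 or np.sum(~np.isnan(vb)) < 2:
                    continue
            try:
                results.append(
                    compare_groups(va, vb, vtype, var, clinical.modalities[var], name)
                )
            except ValueError:
                continue
        if feat is not None:
            for col in feat.columns:
                if col == "group":
                    continue
                va = feat.loc[[p for p in ga if p in feat.index], col].to_numpy(dtype=float)
                vb = feat.loc[[p for p in gb if p in feat.index], col].to_numpy(dtype=float)
                if len(va) >= 2 and len(vb) >= 2:
                    results.append(
                        compare_groups(va, vb, "continuous", col, "connectivity", name)
                    )
    _adjust_within_modality(results)
    return results


def results_to_frame(results: Iterable[TestResult]) -> pd.DataFrame:
    """Tabular export: one row per (variable, comparison) test."""
    return pd.DataFrame(
        [
            {
                "variable": r.variable,
                "modality": r.modality,
                "comparison": r.comparison,
                "test": r.test_name,
                "statistic": r.statistic,
                "p_raw": r.p_raw,
                "p_fdr": r.p_fdr,
                "significant": r.significant,
            }
            for r in results
        ]
    )
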