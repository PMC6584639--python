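"""Standard statistical comparisons used across the analyses.

Thin delegations to scipy/statsmodels: two-tailed two-sample t (equal
variance), Mann–Whitney U, Kolmogorov–Smirnov, and one-way ANOVA with Tukey
post hoc; Bonferroni or Holm–Šídák adjustment across pairwise comparisons.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = ["group_compare"]

_TESTS = {"t", "mann_whitney", "ks", "anova_tukey"}
_CORRECTIONS = {"none", "bonferroni", "holm_sidak"}


def _pairwise_p(a, b, test: str) -> float:
    if test == "t":
        if np.ptp(a) == 0 and np.ptp(b) == 0:
            raise ValueError("degenerate zero-variance groups for t-test")
        return float(sps.ttest_ind(a, b, equal_var=True).pvalue)
    if test == "mann_whitney":
        return float(sps.mannwhitneyu(a, b, alternative="two-sided").pvalue)
    if test == "ks":
        return float(sps.ks_2samp(a, b).pvalue)
    raise ValueError(test)


def group_compare(
    groups: dict,
    test: str = "t",
    correction: str = "none",
) -> pd.DataFrame:
    """Two-sided comparisons between named groups of scalars.

    ``groups`` maps name -> 1D sample (each n >= 3). For ``t``,
    ``mann_whitney`` and ``ks`` every pair of groups is compared;
    ``anova_tukey`` runs one-way ANOVA with Tukey's HSD. Returns a
    DataFrame with raw and adjusted p-values (Bonferroni multiplies by the
    number of comparisons, capped at 1; Holm–Šídák via statsmodels).
    """
    if test not in _TESTS:
        raise ValueError(f"unknown test {test!r}")
    if correction not in _CORRECTIONS:
        raise ValueError(f"unknown correction {correction!r}")
    names = list(groups)
    samples = {k: np.asarray(v, dtype=float) for k, v in groups.items()}
    if len(names) < 2:
        raise ValueError("need at least two groups")
    for k, v in samples.items():
        if v.size < 3:
            raise ValueError(f"group {k!r} has n < 3")

    rows = []
    if test == "anova_tukey":
        res = sps.tukey_hsd(*samples.values())
        for i, j in combinations(range(len(names)), 2):
            rows.append((names[i], names[j], float(res.pvalue[i, j])))
        # Tukey already controls the family-wise rate; no extra correction
        df = pd.DataFrame(rows, columns=["group_a", "group_b", "p_raw"])
        df["p_adj"] = df["p_raw"]
        df.attrs["anova_p"] = float(sps.f_oneway(*samples.values()).pvalue)
        return df
    for a, b in combinations(names, 2):
        rows.append((a, b, _pairwise_p(samples[a], samples[b], test)))
    df = pd.DataFrame(rows, columns=["group_a", "group_b", "p_raw"])
    if correction == "none" or len(df) == 1 and correction == "bonferroni":
        padj = (
            np.minimum(df["p_raw"] * len(df), 1.0)
            if correction == "bonferroni"
            else df["p_raw"]
        )
    elif correction == "bonferroni":
        padj = np.minimum(df["p_raw"] * len(df), 1.0)
    else:
        padj = multipletests(df["p_raw"], method="holm-sidak")[1]
    df["p_adj"] = np.asarray(padj, dtype=float)
    return df
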