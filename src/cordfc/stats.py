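"""Group statistics and the cross-modal comparison.

Nonparametric two-sided Mann-Whitney tests between connectivity groups with
Bonferroni-Holm (primary) or Benjamini-Hochberg (depth-profile) multiple-
comparison corrections, the Pearson agreement between modality means over
pair classes, and the per-subject coherence-vs-correlation regression.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

#: combined sample size at or below which the exact U distribution is used
EXACT_N_MAX = 12


def mann_whitney(a, b) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test.

    Uses the exact null distribution when the combined sample size is at
    most :data:`EXACT_N_MAX` and there are no ties, and the tie-corrected
    normal approximation otherwise.  Returns (U of the first sample,
    two-sided p).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([a, b])
    has_ties = np.unique(pooled).size < pooled.size
    method = "exact" if (a.size + b.size <= EXACT_N_MAX and not has_ties) else "asymptotic"
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def holm_adjust(p) -> np.ndarray:
    """Step-down Bonferroni-Holm adjusted p-values (clipped, monotone)."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="holm")[1]


def fdr_bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (clipped, monotone)."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def modality_agreement(bold_means, lfp_means) -> float:
    """Pearson correlation of the two modalities' pair-class means."""
    x = np.asarray(bold_means, dtype=float)
    y = np.asarray(lfp_means, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need the same >= 3 pair classes in both modalities")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("undefined correlation: a modality has zero variance")
    return float(sps.pearsonr(x, y).statistic)


def per_subject_regression(coherence, bold_r) -> tuple[float, float, float]:
    """OLS of per-subject BOLD correlation on LFP coherence.

    Returns (slope, Pearson r, two-sided p from the t-test on r).
    """
    x = np.asarray(coherence, dtype=float)
    y = np.asarray(bold_r, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need >= 3 paired observations")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("undefined regression: zero variance input")
    res = sps.linregress(x, y)
    return float(res.slope), float(res.rvalue), float(res.pvalue)


@dataclass
class GroupComparison:
    """One pairwise group test with its corrected p-value."""

    name_a: str
    name_b: str
    u_stat: float
    p_raw: float
    p_adjusted: float = np.nan
    method: str = "holm"

    @property
    def stars(self) -> str:
        """Significance tier annotation: * <0.05, ** <0.0005, *** <0.00005."""
        p = self.p_adjusted
        if p < 0.00005:
            return "***"
        if p < 0.0005:
            return "**"
        if p < 0.05:
            return "*"
        return ""


def compare_groups(groups: dict[str, np.ndarray], method: str = "holm",
                   pairs: list[tuple[str, str]] | None = None) -> list[GroupComparison]:
    """All pairwise Mann-Whitney tests with multiplicity correction."""
    names = list(groups)
    if pairs is None:
        pairs = [(a, b) for i, a in enumerate(names) for b in names[i + 1:]]
    comps = [GroupComparison(a, b, *mann_whitney(groups[a], groups[b]), method=method)
             for a, b in pairs]
    adjust = holm_adjust if method == "holm" else fdr_bh_adjust
    adjusted = adjust([c.p_raw for c in comps])
    for c, p_adj in zip(comps, adjusted):
        c.p_adjusted = float(p_adj)
    return comps
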