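"""Normative cutoffs and pairwise battery sensitivity comparison.

Scores are classified impaired when they fall strictly below a normative
cutoff (control mean − k·SD, default k = 2; a score exactly at the cutoff
counts as intact).  For each matched pair of tests — one from a shallow
screening battery, one from a deeper battery — the comparison reports the
percent of patients intact/impaired on each test, the squared Pearson
correlation between the two score columns, and the two directional
"miss" percentages (impaired on one test but within the normal range on the
other).  Directional miss rates across all pairs are summarised with an
exact two-sided Wilcoxon signed-rank test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .dimension import ScoreMatrix

__all__ = [
    "CutoffTable",
    "PairComparison",
    "MissSummary",
    "cutoffs_from_controls",
    "classify_impairment",
    "compare_pair",
    "summarize_misses",
    "misclassified_profile",
    "wilcoxon_signed_rank_exact",
]


@dataclass
class CutoffTable:
    """Per-test normative cutoff = control mean − k·SD (lower = impaired)."""

    table: pd.DataFrame  # index test, columns control_mean, control_sd, cutoff
    k: float

    def cutoff(self, test: str) -> float:
        if test not in self.table.index:
            raise KeyError(f"no cutoff for test {test}")
        return float(self.table.loc[test, "cutoff"])


@dataclass
class PairComparison:
    """One row of a pairwise battery sensitivity table."""

    test_a: str
    test_b: str
    pct_intact_a: float
    pct_impaired_a: float
    pct_intact_b: float
    pct_impaired_b: float
    r_squared: float
    pct_missed_by_a: float  # impaired on b, intact on a
    pct_missed_by_b: float  # impaired on a, intact on b
    n_shared: int


@dataclass
class MissSummary:
    """Directional miss-rate summary with exact Wilcoxon signed-rank p."""

    mean_a: float
    sd_a: float
    mean_b: float
    sd_b: float
    wilcoxon_p: float
    n_pairs: int


def cutoffs_from_controls(controls: ScoreMatrix, k: float = 2.0) -> CutoffTable:
    """Normative cutoffs per test from a control sample (sd with n−1)."""
    if controls.n_patients < 2:
        raise ValueError("need at least 2 controls")
    means = np.nanmean(controls.values, axis=0)
    sds = np.nanstd(controls.values, axis=0, ddof=1)
    bad = np.flatnonzero(~(sds > 0))
    if bad.size:
        names = ", ".join(controls.test_names[j] for j in bad)
        raise ValueError(f"zero-SD control test(s): {names}")
    df = pd.DataFrame({"control_mean": means, "control_sd": sds,
                       "cutoff": means - k * sds}, index=controls.test_names)
    return CutoffTable(df, k)


def classify_impairment(scores: ScoreMatrix, cutoffs: CutoffTable) -> pd.DataFrame:
    """Binary impairment flags: 1 below cutoff, 0 at/above, NaN missing."""
    missing = [t for t in scores.test_names if t not in cutoffs.table.index]
    if missing:
        raise KeyError("tests without cutoffs: " + ", ".join(missing))
    cut = cutoffs.table.loc[scores.test_names, "cutoff"].to_numpy()
    flags = np.where(np.isnan(scores.values), np.nan,
                     (scores.values < cut).astype(float))
    return pd.DataFrame(flags, index=scores.patient_ids, columns=scores.test_names)


def compare_pair(a_scores: pd.Series, b_scores: pd.Series, cutoff_a: float,
                 cutoff_b: float, name_a: str = "A", name_b: str = "B",
                 ) -> PairComparison:
    """Pairwise sensitivity comparison of two score columns.

    Restricted to patients with both scores present.  ``pct_missed_by_a``
    counts patients within the normal range on A but impaired on B (and
    vice versa); all percentages are over the shared patients.
    """
    joined = pd.concat([a_scores, b_scores], axis=1, join="inner").dropna()
    n = len(joined)
    if n < 3:
        raise ValueError("need at least 3 shared patients")
    a, b = joined.iloc[:, 0].to_numpy(), joined.iloc[:, 1].to_numpy()
    if np.std(a) == 0 or np.std(b) == 0:
        raise ValueError("constant score vector, correlation undefined")
    r = np.corrcoef(a, b)[0, 1]
    imp_a, imp_b = a < cutoff_a, b < cutoff_b
    return PairComparison(
        test_a=name_a, test_b=name_b,
        pct_intact_a=100.0 * np.mean(~imp_a), pct_impaired_a=100.0 * np.mean(imp_a),
        pct_intact_b=100.0 * np.mean(~imp_b), pct_impaired_b=100.0 * np.mean(imp_b),
        r_squared=float(r**2),
        pct_missed_by_a=100.0 * np.mean(~imp_a & imp_b),
        pct_missed_by_b=100.0 * np.mean(imp_a & ~imp_b),
        n_shared=n,
    )


# ---------------------------------------------------------------------------
# exact Wilcoxon signed-rank test
# ---------------------------------------------------------------------------


def wilcoxon_signed_rank_exact(x: np.ndarray, y: np.ndarray,
                               exact_limit: int = 25) -> float:
    """Two-sided paired Wilcoxon signed-rank p-value.

    Zero differences are dropped; ties get midranks.  For m ≤ ``exact_limit``
    the p-value is exact, equal to enumerating all 2^m sign assignments of
    the rank magnitudes (computed by dynamic programming over the signed-rank
    sum distribution, which is mathematically identical to the enumeration).
    Above the limit a continuity-corrected normal approximation is used.
    The two-sided p doubles the smaller tail, capped at 1.
    """
    d = np.asarray(x, dtype=float) - np.asarray(y, dtype=float)
    d = d[d != 0]
    m = d.size
    if m == 0:
        raise ValueError("all paired differences are zero; p undefined")
    ranks = pd.Series(np.abs(d)).rank(method="average").to_numpy()
    w_plus = float(ranks[d > 0].sum())
    total = float(ranks.sum())

    if m <= exact_limit:
        # distribution of W+ over all 2^m equally likely sign assignments;
        # work on doubled ranks so midranks (x.5) become integers
        r2 = np.rint(2 * ranks).astype(int)
        max_sum = int(r2.sum())
        counts = np.zeros(max_sum + 1)
        counts[0] = 1.0
        for r in r2:
            shifted = np.zeros_like(counts)
            shifted[r:] = counts[: max_sum + 1 - r]
            counts = counts + shifted
        w2 = int(round(2 * w_plus))
        p_low = counts[: w2 + 1].sum() / 2.0**m
        p_high = counts[w2:].sum() / 2.0**m
        return float(min(1.0, 2.0 * min(p_low, p_high)))

    mu = total / 2.0
    # variance of W+ with midranks: sum(r_i^2)/4
    sigma = np.sqrt(np.sum(ranks**2) / 4.0)
    z = (w_plus - mu - 0.5 * np.sign(w_plus - mu)) / sigma
    from scipy.stats import norm
    return float(min(1.0, 2.0 * norm.sf(abs(z))))


def summarize_misses(rows: list[PairComparison]) -> MissSummary:
    """Summarise the two directional miss-rate columns across pairs.

    Means and SDs (n−1) of ``pct_missed_by_a`` and ``pct_missed_by_b``,
    with an exact two-sided Wilcoxon signed-rank test on the paired
    differences.
    """
    if len(rows) < 2:
        raise ValueError("need at least 2 comparison rows")
    a = np.array([r.pct_missed_by_a for r in rows])
    b = np.array([r.pct_missed_by_b for r in rows])
    p = wilcoxon_signed_rank_exact(a, b)
    return MissSummary(
        mean_a=float(a.mean()), sd_a=float(a.std(ddof=1)),
        mean_b=float(b.mean()), sd_b=float(b.std(ddof=1)),
        wilcoxon_p=p, n_pairs=len(rows),
    )


def misclassified_profile(missed_ids_by_pair: dict[str, list[str]],
                          demographics: pd.DataFrame) -> pd.DataFrame:
    """Median demographic z-scores of the patients missed in each pair.

    Demographics (e.g. age, lesion volume, overall severity) are z-scored
    against the full sample (n−1 SD); per pair the median z of the missed
    subset is reported for each variable, with no significance test.  An
    empty missed subset yields NaN medians (flagged by n_missed = 0).
    """
    z = (demographics - demographics.mean()) / demographics.std(ddof=1)
    records = []
    for pair, ids in missed_ids_by_pair.items():
        present = [i for i in ids if i in z.index]
        for var in demographics.columns:
            med = float(z.loc[present, var].median()) if present else np.nan
            records.append({"pair": pair, "variable": var,
                            "median_z": med, "n_missed": len(present)})
    return pd.DataFrame.from_records(records)
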