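"""CYP3A5 analyses: genotype classification, allele frequencies, Hardy-Weinberg
goodness of fit, and the group-difference tests for dose and exposure.

The SNP of interest is rs776746: the *3 allele abolishes CYP3A5 expression, so
*3/*3 carriers are "non-expressors" with lower tacrolimus dose requirements,
while *1/*1 and *1/*3 carriers are "expressors".
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DegenerateCountsError, EmptyCountsError, ValidationError

GENOTYPE_TOKENS = ("*1/*1", "*1/*3", "*3/*3")
MISSING_TOKENS = ("missing", "", "na", "nan", "none")


@dataclass(frozen=True)
class GenotypeCounts:
    """Genotype tallies at a biallelic locus (*1/*1, *1/*3, *3/*3)."""

    n11: int
    n13: int
    n33: int

    def __post_init__(self):
        if min(self.n11, self.n13, self.n33) < 0:
            raise ValidationError("genotype counts must be non-negative")

    @property
    def n(self) -> int:
        return self.n11 + self.n13 + self.n33


def classify_expressor(genotype: str) -> str:
    """Map a CYP3A5 genotype to expressor / non_expressor / unknown."""
    g = genotype.strip()
    if g in ("*1/*1", "*1/*3"):
        return "expressor"
    if g == "*3/*3":
        return "non_expressor"
    if g.lower() in MISSING_TOKENS:
        return "unknown"
    raise ValidationError(
        f"unrecognized genotype {genotype!r}; accepted tokens: {GENOTYPE_TOKENS + ('missing',)}"
    )


def genotype_counts(genotypes: Sequence[str]) -> GenotypeCounts:
    """Tally genotypes, silently dropping missing entries."""
    tally = {g: 0 for g in GENOTYPE_TOKENS}
    for g in genotypes:
        g = str(g).strip()
        if g in tally:
            tally[g] += 1
        elif g.lower() not in MISSING_TOKENS:
            raise ValidationError(f"unrecognized genotype {g!r}")
    return GenotypeCounts(tally["*1/*1"], tally["*1/*3"], tally["*3/*3"])


def allele_frequencies(counts: GenotypeCounts) -> tuple[float, float]:
    """(freq *1, freq *3) from genotype counts by the allele-counting method."""
    if counts.n == 0:
        raise EmptyCountsError("cannot compute allele frequencies from zero genotypes")
    q3 = (counts.n13 + 2 * counts.n33) / (2 * counts.n)
    return 1.0 - q3, q3


def hwe_chi_square(counts: GenotypeCounts) -> tuple[float, int, float]:
    """Hardy-Weinberg goodness-of-fit chi-square.

    Expected counts are n*(p^2, 2pq, q^2) with the allele frequencies estimated
    from the observed genotypes; df = 1 (3 classes - 1 - 1 estimated frequency).
    Returns (chi2, df, p).
    """
    if counts.n == 0:
        raise EmptyCountsError("cannot test HWE on zero genotypes")
    p1, q3 = allele_frequencies(counts)
    expected = counts.n * np.array([p1 * p1, 2 * p1 * q3, q3 * q3])
    observed = np.array([counts.n11, counts.n13, counts.n33], dtype=float)
    chi2 = 0.0
    for o, e in zip(observed, expected):
        if e == 0.0:
            if o > 0:
                raise DegenerateCountsError("expected genotype class of zero with non-zero observed count")
            continue
        chi2 += (o - e) ** 2 / e
    df = 1
    return float(chi2), df, float(stats.chi2.sf(chi2, df))


def round_half_away(x: float, ndigits: int = 1) -> float:
    """Round half away from zero (the convention used for printed percentages)."""
    factor = 10.0**ndigits
    return math.copysign(math.floor(abs(x) * factor + 0.5) / factor, x)


def one_way_anova(groups: Mapping[str, Sequence[float]]) -> tuple[float, int, int, float]:
    """One-way fixed-effects ANOVA via the between/within sum-of-squares decomposition.

    Returns (F, df_between, df_within, p). Degenerate cases: all values
    identical -> F = 0; zero within-group variance with distinct means -> F = inf.
    """
    arrays = [np.asarray(v, dtype=float) for v in groups.values() if len(v) > 0]
    if len(arrays) < 2:
        raise ValidationError("ANOVA needs at least two non-empty groups")
    n_total = sum(a.size for a in arrays)
    k = len(arrays)
    if n_total <= k:
        raise ValidationError("ANOVA needs more observations than groups")
    grand = np.concatenate(arrays).mean()
    ssb = sum(a.size * (a.mean() - grand) ** 2 for a in arrays)
    ssw = sum(((a - a.mean()) ** 2).sum() for a in arrays)
    df1, df2 = k - 1, n_total - k
    msb, msw = ssb / df1, ssw / df2
    if msw == 0.0:
        f = 0.0 if msb == 0.0 else float("inf")
        return f, df1, df2, (1.0 if msb == 0.0 else 0.0)
    f = msb / msw
    return float(f), df1, df2, float(stats.f.sf(f, df1, df2))


def fligner_killeen(groups: Mapping[str, Sequence[float]]) -> tuple[float, int, float]:
    """Fligner-Killeen test of homogeneity of variances.

    Ranks |x - group median| across the pooled sample, scores by the standard
    normal quantile of (1 + rank/(N+1))/2, and forms a chi-square statistic from
    the group mean scores; df = groups - 1. Returns (statistic, df, p).
    """
    arrays = [np.asarray(v, dtype=float) for v in groups.values()]
    if len(arrays) < 2 or any(a.size < 2 for a in arrays):
        raise ValidationError("Fligner-Killeen needs >= 2 groups of size >= 2")
    if all(np.ptp(a) == 0 for a in arrays):
        return 0.0, len(arrays) - 1, 1.0
    statistic, p = stats.fligner(*arrays)
    return float(statistic), len(arrays) - 1, float(p)


def mann_whitney_u(a: Sequence[float], b: Sequence[float]) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test.

    Uses exact enumeration of the U distribution for small, tie-free samples
    (n1*n2 <= 400) and the tie-corrected normal approximation otherwise.
    Returns (U of the first sample, two-sided p).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValidationError("both samples must be non-empty")
    pooled = np.concatenate([a, b])
    has_ties = np.unique(pooled).size < pooled.size
    method = "exact" if (not has_ties and a.size * b.size <= 400) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def pgx_report(
    metadata: pd.DataFrame,
    exposure: pd.DataFrame,
) -> pd.DataFrame:
    """CYP3A5 summary for one cohort: frequencies, HWE, group means and tests.

    Compares TAC-D (weight-normalized daily dose) and dose-normalized AUC
    between expressors and non-expressors with both one-way ANOVA and the
    Mann-Whitney U test (the two tests the field reports for this contrast).
    Returns a tidy (quantity, value) table.
    """
    merged = metadata.merge(exposure, on="patient_id", how="inner")
    merged["expressor_status"] = merged["genotype"].map(classify_expressor)
    known = merged[merged["expressor_status"] != "unknown"]
    counts = genotype_counts(known["genotype"])
    p1, q3 = allele_frequencies(counts)
    chi2, df, p_hwe = hwe_chi_square(counts)

    rows = [
        ("n_total", len(merged)),
        ("n_genotyped", counts.n),
        ("n_11", counts.n11),
        ("n_13", counts.n13),
        ("n_33", counts.n33),
        ("pct_11", round_half_away(100.0 * counts.n11 / counts.n)),
        ("pct_13", round_half_away(100.0 * counts.n13 / counts.n)),
        ("pct_33", round_half_away(100.0 * counts.n33 / counts.n)),
        ("allele_freq_star1_pct", round_half_away(100.0 * p1)),
        ("allele_freq_star3_pct", round_half_away(100.0 * q3)),
        ("hwe_chi2", chi2),
        ("hwe_df", df),
        ("hwe_p", p_hwe),
    ]
    for quantity, column in (("tac_d", "tac_d_mg_per_kg"), ("auc_per_dose", "auc_per_dose")):
        grouped = {
            status: grp[column].to_numpy(float)
            for status, grp in known.groupby("expressor_status")
        }
        for status, values in grouped.items():
            rows.append((f"{quantity}_mean_{status}", float(np.mean(values))))
        if len(grouped) >= 2:
            f, df1, df2, p_f = one_way_anova(grouped)
            u, p_u = mann_whitney_u(grouped["expressor"], grouped["non_expressor"])
            rows += [
                (f"{quantity}_anova_f", f),
                (f"{quantity}_anova_df1", df1),
                (f"{quantity}_anova_df2", df2),
                (f"{quantity}_anova_p", p_f),
                (f"{quantity}_mwu_u", u),
                (f"{quantity}_mwu_p", p_u),
            ]
    return pd.DataFrame(rows, columns=["quantity", "value"])
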