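"""Statistical cores: one-sided Fisher tests, BH correction, hypergeometric
enrichment.

The differential-inclusion test is the one-sided Fisher exact test on the
2x2 table [inclusion reads, exclusion reads] x [cell1, cell2].  Both tails
are computed for every exon; the one-sided Fisher p equals the
hypergeometric tail probability, evaluated here in vectorised form so that
thousands of exons are tested in one call.
"""

from __future__ import annotations

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests


def fisher_one_sided(jir1, jer1, jir2, jer2):
    """One-sided Fisher exact p-values for inclusion-vs-exclusion tables.

    Parameters are (arrays of) non-negative integer read counts.  With the
    convention that X = inclusion reads in cell1 follows a hypergeometric
    law under the null,

    - ``p_more``: probability of a table at least as extreme toward higher
      inclusion in cell2 (i.e. P[X <= jir1]),
    - ``p_less``: toward higher inclusion in cell1 (P[X >= jir1]).

    Returns ``(p_more, p_less)`` as float arrays (or scalars).
    """
    jir1 = np.asarray(jir1, dtype=np.int64)
    jer1 = np.asarray(jer1, dtype=np.int64)
    jir2 = np.asarray(jir2, dtype=np.int64)
    jer2 = np.asarray(jer2, dtype=np.int64)
    total = jir1 + jer1 + jir2 + jer2
    n_incl = jir1 + jir2
    n_cell1 = jir1 + jer1
    # hypergeom(M=total, n=n_incl, N=n_cell1) for X = jir1
    with np.errstate(invalid="ignore"):
        p_more = sps.hypergeom.cdf(jir1, total, n_incl, n_cell1)
        p_less = sps.hypergeom.sf(jir1 - 1, total, n_incl, n_cell1)
    # an empty table carries no evidence in either direction
    p_more = np.where(total == 0, 1.0, p_more)
    p_less = np.where(total == 0, 1.0, p_less)
    p_more = np.clip(p_more, 0.0, 1.0)
    p_less = np.clip(p_less, 0.0, 1.0)
    if p_more.ndim == 0:
        return float(p_more), float(p_less)
    return p_more, p_less


def bh_adjust(p_values):
    """Benjamini-Hochberg step-up adjusted q-values.

    q(i) = min_{j >= i} min(1, m * p(j) / j) over p sorted ascending.
    Empty input yields an empty array.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return np.array([], dtype=float)
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def bonferroni(p, n_tests):
    """Family-wise correction: multiply by the number of tests, cap at 1."""
    return np.minimum(np.asarray(p, dtype=float) * n_tests, 1.0)


def hypergeom_enrichment(k, n_fg, K, M):
    """Upper-tail hypergeometric p for over-representation.

    ``k`` hits in a foreground of size ``n_fg`` drawn from a population of
    size ``M`` containing ``K`` hits in total: P[X >= k].
    """
    return float(sps.hypergeom.sf(np.asarray(k) - 1, M, K, n_fg))


def signed_rank_test(values, exact_max_n=25):
    """Wilcoxon signed-rank test of a sample against zero (two-sided).

    Zero differences are discarded (Wilcoxon's original treatment).  Exact
    null distribution is used for small samples without ties; all-zero
    input returns p = 1.
    """
    v = np.asarray(values, dtype=float)
    v = v[v != 0]
    if v.size == 0:
        return 1.0
    method = "exact" if (v.size <= exact_max_n and np.unique(np.abs(v)).size == v.size) else "auto"
    return float(sps.wilcoxon(v, method=method).pvalue)


def rank_sum_test(x, y):
    """Wilcoxon rank-sum (Mann-Whitney U) test, two-sided."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        return 1.0
    return float(sps.mannwhitneyu(x, y, alternative="two-sided").pvalue)
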