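"""Lineage-specific rapidly evolving GO categories and positively selected genes.

Rapidly evolving categories: for each GO category holding at least
``min_orthologues`` gene families, a one-sided Wilcoxon signed-rank test asks
whether the foreground lineage's per-family nonsynonymous burden (A, or Ka)
exceeds the background lineage's, paired by family.  Zero differences are
discarded; absolute differences are mid-ranked; p-values come from exact
sign-flip enumeration for small samples (the conditional permutation null,
ties included) and otherwise from the normal approximation with
tie-corrected variance and a continuity correction.

Positively selected genes: the branch-site likelihood ratio statistic
2(lnL_alt - lnL_null) (clamped at zero) is referred to the upper tail of
chi-square with one degree of freedom — conservative relative to the 50:50
point-mass/chi-square boundary mixture — and corrected for multiple testing
(Bonferroni by default, Benjamini-Hochberg available).
"""

from __future__ import annotations

from dataclasses import dataclass
import logging

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

EXACT_CUTOFF = 25   # tie-free pairs at or below which the exact null is used


class LineageError(ValueError):
    pass


@dataclass
class WilcoxonResult:
    statistic: float       # signed-rank sum of the foreground-greater direction
    p_one_sided: float
    n_effective: int       # pairs after dropping zero differences
    n_zero: int
    method: str            # "exact" | "normal" | "degenerate"


@dataclass
class GoTestResult:
    go_id: str
    n_families: int
    statistic: float
    p_one_sided: float
    significant: bool


@dataclass
class LrtResult:
    gene_id: str
    lnL_alt: float
    lnL_null: float
    statistic: float
    p_raw: float
    p_corrected: float
    selected: bool


# ---------------------------------------------------------------------------

def _exact_sf(w: float, ranks: np.ndarray) -> float:
    """P(W+ >= w) under the exact sign-flip null for the given mid-ranks.

    Mid-ranks are half-integers, so the subset-sum DP runs on doubled ranks;
    this covers tied |differences| with the conditional permutation null.
    """
    r2 = np.round(2 * np.asarray(ranks)).astype(np.int64)
    counts = np.zeros(int(r2.sum()) + 1)
    counts[0] = 1.0
    for r in r2:
        counts[r:] += counts[:-r].copy()
    total = counts.sum()            # 2**n
    wi = int(np.ceil(2 * w - 1e-9))
    return float(counts[wi:].sum() / total)


def wilcoxon_signed_rank_one_sided(foreground: np.ndarray, background: np.ndarray,
                                   exact_cutoff: int = EXACT_CUTOFF) -> WilcoxonResult:
    """One-sided paired test of foreground exceeding background."""
    fg = np.asarray(foreground, dtype=float)
    bg = np.asarray(background, dtype=float)
    if fg.shape != bg.shape or fg.ndim != 1 or len(fg) == 0:
        raise LineageError("need one or more (foreground, background) pairs")
    d = fg - bg
    nonzero = d != 0
    n_zero = int((~nonzero).sum())
    d = d[nonzero]
    n = len(d)
    if n == 0:
        return WilcoxonResult(0.0, 1.0, 0, n_zero, "degenerate")
    absd = np.abs(d)
    ranks = stats.rankdata(absd)            # mid-ranks on ties
    w_plus = float(ranks[d > 0].sum())
    _, tie_counts = np.unique(absd, return_counts=True)

    if n <= exact_cutoff:
        p = _exact_sf(w_plus, ranks)
        method = "exact"
    else:
        mu = n * (n + 1) / 4.0
        var = n * (n + 1) * (2 * n + 1) / 24.0 - (tie_counts**3 - tie_counts).sum() / 48.0
        if var <= 0:
            return WilcoxonResult(w_plus, 1.0, n, n_zero, "degenerate")
        z = (w_plus - 0.5 - mu) / np.sqrt(var)   # continuity correction
        p = float(stats.norm.sf(z))
        method = "normal"
    return WilcoxonResult(w_plus, min(p, 1.0), n, n_zero, method)


# ---------------------------------------------------------------------------

def rapid_go_test(table: pd.DataFrame, gomap: dict[str, set[str]],
                  foreground: str, background: str, metric: str = "A",
                  min_orthologues: int = 15, alpha: float = 0.025,
                  paired: bool = True) -> list[GoTestResult]:
    """Per-GO-category one-sided tests of accelerated foreground evolution.

    ``table`` must hold one row per family with columns
    ``family_id`` and ``{lineage}_{metric}`` for both lineages (e.g.
    ``milu_A``, ``cow_A``).  Categories with fewer than ``min_orthologues``
    mapped families are excluded.  ``paired=False`` falls back to a
    rank-sum (Mann-Whitney) comparison of the two lineages' values.
    """
    if not gomap:
        raise LineageError("empty GO map")
    for lin in (foreground, background):
        if f"{lin}_{metric}" not in table.columns:
            raise LineageError(f"lineage column {lin}_{metric} absent from table")
    fg_col = table.set_index("family_id")[f"{foreground}_{metric}"]
    bg_col = table.set_index("family_id")[f"{background}_{metric}"]

    by_go: dict[str, set[str]] = {}
    for fam, gos in gomap.items():
        for go in gos:
            by_go.setdefault(go, set()).add(fam)

    results: list[GoTestResult] = []
    for go in sorted(by_go):
        fams = sorted(f for f in by_go[go] if f in fg_col.index)
        if len(fams) < min_orthologues:
            continue
        fg = fg_col.loc[fams].to_numpy(dtype=float)
        bg = bg_col.loc[fams].to_numpy(dtype=float)
        if paired:
            res = wilcoxon_signed_rank_one_sided(fg, bg)
            stat, p = res.statistic, res.p_one_sided
        else:
            stat, p = stats.mannwhitneyu(fg, bg, alternative="greater")
            stat, p = float(stat), float(p)
        results.append(GoTestResult(go_id=go, n_families=len(fams),
                                    statistic=stat, p_one_sided=p,
                                    significant=bool(p < alpha)))
    results.sort(key=lambda r: (r.p_one_sided, r.go_id))
    return results


def go_results_frame(results: list[GoTestResult]) -> pd.DataFrame:
    return pd.DataFrame([(r.go_id, r.n_families, r.statistic, r.p_one_sided,
                          r.significant) for r in results],
                        columns=["go_id", "n", "statistic", "p", "significant"])


# ---------------------------------------------------------------------------

def branch_site_lrt(genes: list[tuple[str, float, float]],
                    correction: str = "bonferroni",
                    alpha: float = 0.01) -> list[LrtResult]:
    """Branch-site LRT from (gene_id, lnL_alt, lnL_null) triples."""
    if correction not in ("bonferroni", "bh"):
        raise LineageError(f"unknown correction {correction!r}")
    ids, stats_, praw = [], [], []
    for gene_id, lnl_alt, lnl_null in genes:
        if not (np.isfinite(lnl_alt) and np.isfinite(lnl_null)):
            raise LineageError(f"non-finite log-likelihood for {gene_id}")
        delta = 2.0 * (lnl_alt - lnl_null)
        if delta < -1e-6:
            logger.warning("gene %s: lnL_alt < lnL_null (2dlnL=%.3g); clamped to 0",
                           gene_id, delta)
        stat = max(0.0, delta)
        ids.append(gene_id)
        stats_.append(stat)
        praw.append(float(stats.chi2.sf(stat, df=1)))
    praw_arr = np.array(praw)
    if correction == "bonferroni":
        pcorr = np.minimum(praw_arr * len(praw_arr), 1.0)
    else:
        from statsmodels.stats.multitest import multipletests
        pcorr = multipletests(praw_arr, method="fdr_bh")[1]
    out = []
    for i, gene_id in enumerate(ids):
        out.append(LrtResult(gene_id=gene_id,
                             lnL_alt=genes[i][1], lnL_null=genes[i][2],
                             statistic=stats_[i], p_raw=praw[i],
                             p_corrected=float(max(pcorr[i], praw[i])),
                             selected=bool(pcorr[i] < alpha)))
    return out


def lrt_results_frame(results: list[LrtResult]) -> pd.DataFrame:
    return pd.DataFrame([(r.gene_id, r.statistic, r.p_raw, r.p_corrected,
                          r.selected) for r in results],
                        columns=["gene_id", "2dlnL", "p_raw", "p_corrected",
                                 "selected"])
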