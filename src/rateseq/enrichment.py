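"""Rank tests for nonrandom decay rates within functional categories.

Each gene category (e.g. a GO SLIM term) is compared against all other
genes with estimates by a two-sided Wilcoxon–Mann–Whitney test on the
decay constants.  Ranks are invariant under monotone transforms, so
testing alpha and testing half-life give identical p-values.  The exact
null distribution is used for small groups without ties; otherwise the
normal approximation with midranks and continuity correction.  P-values
are adjusted across categories by Benjamini–Hochberg.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io import KineticEstimate

__all__ = ["EnrichmentResult", "test_category", "enrich_all", "write_enrichment"]

_EXACT_MAX_N = 20


@dataclass
class EnrichmentResult:
    term_id: str
    term_name: str
    n_in: int
    n_out: int
    rank_sum_statistic: float
    p_value: float
    adjusted_p: float
    direction: str  # "faster" | "slower" | "none" (median alpha in vs out)


def test_category(in_alphas, out_alphas) -> tuple[float, float, str]:
    """Mann–Whitney U of category vs background decay constants.

    Returns (U statistic for the category, two-sided p, direction), where
    direction says whether the category's median alpha is larger ("faster"
    decay) or smaller ("slower") than the background's.
    """
    x = np.asarray(in_alphas, dtype=float)
    y = np.asarray(out_alphas, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be non-empty")
    ties = np.unique(np.concatenate([x, y])).size < x.size + y.size
    if max(x.size, y.size) <= _EXACT_MAX_N and not ties:
        method = "exact"
    else:
        method = "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method,
                             use_continuity=True)
    mx, my = float(np.median(x)), float(np.median(y))
    direction = "faster" if mx > my else ("slower" if mx < my else "none")
    return float(res.statistic), float(res.pvalue), direction


def enrich_all(
    estimates: list[KineticEstimate],
    go_map: pd.DataFrame,
    min_size: int = 5,
) -> list[EnrichmentResult]:
    """Test every annotated category against the rest of the genome.

    ``go_map`` has columns gene_id, term_id, term_name.  Categories with
    fewer than ``min_size`` members carrying estimates are skipped.
    Results are BH-adjusted across the tested categories and sorted by
    adjusted p.
    """
    if go_map is None or len(go_map) == 0:
        raise ValueError("empty GO membership table")
    alpha = {
        e.transcript_id: e.alpha_total for e in estimates if e.converged
    }
    genes = pd.Index(sorted(alpha))  # sorted: results independent of input order
    values = np.array([alpha[g] for g in genes])
    results: list[EnrichmentResult] = []
    for (term_id, term_name), grp in go_map.groupby(["term_id", "term_name"], sort=True):
        members = genes.isin(set(grp["gene_id"]))
        n_in = int(members.sum())
        n_out = int((~members).sum())
        if n_in < min_size or n_out == 0:
            continue
        stat, p, direction = test_category(values[members], values[~members])
        results.append(
            EnrichmentResult(
                term_id=term_id,
                term_name=term_name,
                n_in=n_in,
                n_out=n_out,
                rank_sum_statistic=stat,
                p_value=p,
                adjusted_p=np.nan,
                direction=direction,
            )
        )
    if results:
        adj = _bh_adjust(np.array([r.p_value for r in results]))
        for r, a in zip(results, adj):
            r.adjusted_p = float(a)
        results.sort(key=lambda r: (r.adjusted_p, r.p_value, r.term_id))
    return results


def _bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values."""
    m = len(p)
    order = np.argsort(p)
    ranked = p[order] * m / np.arange(1, m + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(ranked, 1.0)
    return out


def write_enrichment(results: list[EnrichmentResult], path) -> None:
    df = pd.DataFrame([vars(r) for r in results])
    if df.empty:
        df = pd.DataFrame(
            columns=["term_id", "term_name", "n_in", "n_out",
                     "rank_sum_statistic", "p_value", "adjusted_p", "direction"]
        )
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")
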