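"""Statistical core: detection filter, ORA, rank-based FCS and FDR control.

Over-representation analysis (ORA) asks whether a thresholded gene list
overlaps a gene set more than expected under hypergeometric sampling from a
*background* — the universe of genes that had a chance of entering the list.
For RNA-seq that universe is the set of detected genes, not the whole genome
annotation; this module makes the background an explicit, validated argument
precisely because getting it wrong is the most common and most consequential
mistake in published enrichment analyses.

Functional class scoring (FCS) instead ranks all detected genes by a signed
differential-expression score and tests, per gene set, whether member ranks
are shifted relative to non-members (a two-sided rank-sum test).

Both produce many p-values at once, so Benjamini-Hochberg adjustment across
the tested sets of a run is built in.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from itertools import combinations
from typing import Callable, Iterable, Literal

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

#: ORA set-size window defaults; sets whose background overlap falls outside
#: are excluded before FDR adjustment.
DEFAULT_MIN_SET_SIZE = 10
DEFAULT_MAX_SET_SIZE = 500

ORA_COLUMNS = ["set", "direction", "k", "n", "K", "N", "enrichment_ratio", "p", "fdr"]
FCS_COLUMNS = ["set", "set_size", "s_score", "p", "fdr"]


class BackgroundError(ValueError):
    """The query is not contained in the background (strict mode)."""


@dataclass(frozen=True)
class BackgroundSpec:
    """The background gene universe for ORA.

    ``mode`` records how the universe was derived: ``"detected"`` (genes
    passing the detection filter — the appropriate choice for RNA-seq),
    ``"whole_annotation"`` (every gene in the genome annotation — the classic
    misuse), or ``"custom"``.
    """

    mode: Literal["detected", "whole_annotation", "custom"]
    genes: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self):
        if self.mode not in ("detected", "whole_annotation", "custom"):
            raise ValueError(f"unknown background mode {self.mode!r}")
        if not self.genes:
            raise ValueError("background gene set is empty")
        object.__setattr__(self, "genes", frozenset(self.genes))


def detection_filter(counts: pd.DataFrame, min_mean_reads: float = 10) -> frozenset[str]:
    """Genes whose mean count across samples is at or above the threshold.

    The boundary is inclusive: a gene averaging exactly ``min_mean_reads``
    reads per sample counts as detected.
    """
    means = counts.mean(axis=1)
    return frozenset(means.index[means >= min_mean_reads])


def bh_adjust(pvalues: Iterable[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in the input order.

    For sorted p-values ``p_(1) <= ... <= p_(m)`` the adjusted value is
    ``q_(i) = min_{j >= i} p_(j) * m / j``, capped at 1. Output is always
    elementwise >= input.
    """
    p = np.asarray(list(pvalues), dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    q = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.minimum(q, 1.0)
    out = np.empty(m)
    out[order] = q
    return out


def _resolve_background(
    query: frozenset[str],
    background: BackgroundSpec,
    on_missing: Literal["strict", "lenient"],
) -> frozenset[str]:
    missing = query - background.genes
    if not missing:
        return background.genes
    if on_missing == "strict":
        raise BackgroundError(
            f"{len(missing)} query gene(s) absent from the {background.mode} "
            f"background (e.g. {sorted(missing)[:3]}); pass on_missing='lenient' "
            "to union them in"
        )
    logger.warning(
        "unioning %d query gene(s) into the %s background", len(missing), background.mode
    )
    return background.genes | missing


def ora_test(
    query: Iterable[str],
    background: BackgroundSpec,
    library,
    min_set_size: int = DEFAULT_MIN_SET_SIZE,
    max_set_size: int = DEFAULT_MAX_SET_SIZE,
    *,
    direction: str = "up",
    on_missing: Literal["strict", "lenient"] = "strict",
) -> pd.DataFrame:
    """Hypergeometric over-representation test for one query list.

    For each gene set S, with ``N`` the background size, ``K = |S & background|``,
    ``n`` the query size and ``k = |S & query|``, the p-value is the upper
    tail ``P(X >= k)`` of Hypergeometric(N, K, n) — over-representation only,
    equivalent to the one-sided Fisher exact test on the 2x2 table. Sets with
    ``K`` outside ``[min_set_size, max_set_size]`` are dropped *before* BH
    adjustment, so the multiplicity burden reflects only the sets actually
    tested.

    Parameters
    ----------
    query : iterable of str
        The thresholded gene list (e.g. up-regulated DEGs). Must be contained
        in the background; in ``lenient`` mode stragglers are unioned in with
        a warning instead of raising.
    direction : str
        Label recorded in the result (``"up"`` or ``"down"``); ORA is run
        separately per direction.

    Returns
    -------
    DataFrame with columns ``set, direction, k, n, K, N, enrichment_ratio,
    p, fdr``, one row per tested set.
    """
    if min_set_size < 1:
        raise ValueError("min_set_size must be >= 1")
    query = frozenset(query)
    if not query:
        raise ValueError("empty query gene list")
    universe = _resolve_background(query, background, on_missing)
    N = len(universe)
    n = len(query)

    rows = []
    for set_name, members in library.sets.items():
        in_bg = members & universe
        K = len(in_bg)
        if K < min_set_size or K > max_set_size:
            continue
        k = len(in_bg & query)
        rows.append((set_name, k, K))
    if not rows:
        return pd.DataFrame(columns=ORA_COLUMNS)
    names, ks, Ks = zip(*rows)
    ks = np.array(ks)
    Ks = np.array(Ks)
    # survival function: P(X >= k) = sf(k - 1); numerically stable upper tail
    p = stats.hypergeom.sf(ks - 1, N, Ks, n)
    p = np.clip(p, 0.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = (ks / n) / (Ks / N)
    out = pd.DataFrame(
        {
            "set": names,
            "direction": direction,
            "k": ks,
            "n": n,
            "K": Ks,
            "N": N,
            "enrichment_ratio": ratio,
            "p": p,
            "fdr": bh_adjust(p),
        }
    )
    return out.sort_values("p", kind="mergesort", ignore_index=True)


def signed_log_p_score(de: pd.DataFrame) -> pd.Series:
    """Default FCS ranking metric: ``sign(log2fc) * -log10(p)``.

    p-values are floored at 1e-300 to keep the score finite; a zero fold
    change scores 0 regardless of p.
    """
    p = de["p"].clip(lower=1e-300)
    return np.sign(de["log2fc"]) * (-np.log10(p))


def _exact_rank_sum_p(member_ranks: np.ndarray, all_ranks: np.ndarray) -> float:
    """Two-sided exact p for the rank-sum of ``member_ranks`` among ``all_ranks``.

    Enumerates all C(N, k) equally likely member subsets; handles midranks
    (tied scores) exactly. Feasible only for small groups.
    """
    k = len(member_ranks)
    w = member_ranks.sum()
    sums = np.array([sum(c) for c in combinations(all_ranks, k)])
    eps = 1e-9
    p_ge = np.mean(sums >= w - eps)
    p_le = np.mean(sums <= w + eps)
    return min(1.0, 2.0 * min(p_ge, p_le))


def fcs_rank_test(
    de: pd.DataFrame,
    library,
    min_set_size: int = DEFAULT_MIN_SET_SIZE,
    *,
    ranking: Callable[[pd.DataFrame], pd.Series] | None = None,
    exact_max_group: int = 10,
) -> pd.DataFrame:
    """Rank-based functional class scoring over all genes in the DE table.

    Genes are scored with ``ranking`` (default :func:`signed_log_p_score`)
    and converted to midranks. For each set with at least ``min_set_size``
    members among the scored genes, a two-sided rank-sum test compares member
    ranks against non-member ranks: exact enumeration when both groups have
    at most ``exact_max_group`` genes, otherwise the normal approximation
    with tie correction and continuity correction.

    The signed enrichment score is

        ``s = 2 * (mean member rank - mean overall rank) / N``

    which lies in (-1, 1); positive values mean the set's members sit toward
    the up-regulated end of the ranking.

    Sets with no scored members or with every scored gene are skipped with a
    log entry (no rank contrast exists for them).
    """
    if len(de) < 2:
        raise ValueError("DE table must cover at least 2 genes")
    scores = (ranking or signed_log_p_score)(de)
    genes = de.index.to_numpy()
    ranks = stats.rankdata(scores.to_numpy(), method="average")
    rank_of = dict(zip(genes, ranks))
    N = len(genes)
    mean_rank = (N + 1) / 2.0

    # tie correction term for the rank-sum variance
    _, tie_counts = np.unique(ranks, return_counts=True)
    tie_term = np.sum(tie_counts**3 - tie_counts)

    rows = []
    for set_name, members in library.sets.items():
        member_ranks = np.array([rank_of[g] for g in members if g in rank_of])
        k = len(member_ranks)
        if k == 0 or k == N:
            logger.info("skipping set %r: %s scored members", set_name, k or "all")
            continue
        if k < min_set_size:
            continue
        n2 = N - k
        s_score = 2.0 * (member_ranks.mean() - mean_rank) / N
        if k <= exact_max_group and n2 <= exact_max_group:
            p = _exact_rank_sum_p(member_ranks, ranks)
        else:
            w = member_ranks.sum()
            mu = k * mean_rank
            var = (k * n2 / 12.0) * (N + 1 - tie_term / (N * (N - 1)))
            if var <= 0:  # all scores tied
                p = 1.0
            else:
                z = (abs(w - mu) - 0.5) / math.sqrt(var)
                p = min(1.0, 2.0 * stats.norm.sf(max(z, 0.0)))
        rows.append((set_name, k, s_score, p))
    if not rows:
        return pd.DataFrame(columns=FCS_COLUMNS)
    out = pd.DataFrame(rows, columns=["set", "set_size", "s_score", "p"])
    out["fdr"] = bh_adjust(out["p"])
    return out.sort_values("p", kind="mergesort", ignore_index=True)


def significant_sets(
    results: pd.DataFrame,
    mode: Literal["fdr", "nominal"] = "fdr",
    alpha: float = 0.05,
    *,
    label: str = "",
):
    """Select the (set, direction) pairs called significant in one run.

    ``mode="fdr"`` thresholds the BH-adjusted values, ``mode="nominal"`` the
    raw p-values; the inequality is strict (``< alpha``). ORA results carry
    an explicit direction column; for FCS the direction is the sign of the
    enrichment score.

    Returns a :class:`~enrichbench.misuse.SignedResultSet`.
    """
    from .misuse import SignedResultSet  # deferred: avoids a module cycle

    if mode not in ("fdr", "nominal"):
        raise ValueError(f"unknown significance mode {mode!r}")
    column = "fdr" if mode == "fdr" else "p"
    if len(results) == 0:
        return SignedResultSet(label=label, members=frozenset())
    hit = results[results[column] < alpha]
    if "direction" in results.columns:
        members = frozenset(zip(hit["set"], hit["direction"]))
    elif "s_score" in results.columns:
        members = frozenset(
            (s, "up" if sc > 0 else "down") for s, sc in zip(hit["set"], hit["s_score"])
        )
    else:
        raise ValueError("results need a 'direction' or 's_score' column")
    return SignedResultSet(label=label, members=members)
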