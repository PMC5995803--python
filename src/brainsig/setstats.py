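"""Overlap statistics for gene sets and coexpression modules.

The central quantity is fold enrichment: the observed intersection size
divided by its expectation when each set is an independent uniform draw
of its size from the universe.  For two sets

    FE = |D1 n D2| / (|D1| * |D2| / |U|)

and for k sets the expectation generalizes to prod|Di| / |U|^(k-1).
Significance comes from the hypergeometric upper tail (pairwise), from
the exact nested-hypergeometric distribution of the k-way intersection
(each conditional overlap with an independent uniform set is again
hypergeometric), or from seeded Monte Carlo.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from brainsig.signatures import bh_adjust

logger = logging.getLogger(__name__)


@dataclass
class OverlapResult:
    """Intersection of k >= 2 gene sets within a universe."""

    sets: list[frozenset]
    universe: frozenset
    intersection: frozenset
    fold_enrichment: float
    p_value: float

    @property
    def intersection_size(self) -> int:
        return len(self.intersection)


def _validate(sets, universe) -> tuple[list[frozenset], frozenset]:
    universe = frozenset(universe)
    if not universe:
        raise ValueError("universe must be non-empty")
    out = []
    for s in sets:
        fs = frozenset(s)
        if not fs <= universe:
            raise ValueError("every set must be a subset of the universe")
        out.append(fs)
    return out, universe


def fold_enrichment(d1, d2, universe) -> OverlapResult:
    """Pairwise fold enrichment with hypergeometric upper-tail p.

    FE is the observed intersection size over |d1|*|d2|/|U|; the
    p-value is P(X >= observed) for X hypergeometric with |U| items,
    |d1| successes, and |d2| draws.  Empty input sets give FE = 0 and
    p = 1 with a warning.
    """
    (s1, s2), uni = _validate([d1, d2], universe)
    inter = s1 & s2
    if not s1 or not s2:
        logger.warning("fold_enrichment: empty input set; FE defined as 0")
        return OverlapResult([s1, s2], uni, inter, 0.0, 1.0)
    expected = len(s1) * len(s2) / len(uni)
    fe = len(inter) / expected
    p = float(stats.hypergeom.sf(len(inter) - 1, len(uni), len(s1), len(s2)))
    return OverlapResult([s1, s2], uni, inter, fe, p)


def _exact_intersection_tail(sizes: list[int], n_universe: int, observed: int) -> float:
    """P(|D1 n ... n Dk| >= observed) for independent uniform sets.

    Chained exactly: conditional on the running intersection having
    size m, its overlap with the next (independent, uniform) set of
    size s is hypergeometric(N=n_universe, K=m, n=s), so the pmf
    propagates through a k-1 step hypergeometric mixture.
    """
    pmf = np.zeros(n_universe + 1)
    pmf[sizes[0]] = 1.0
    for s in sizes[1:]:
        new = np.zeros_like(pmf)
        for m in np.flatnonzero(pmf > 0):
            lo, hi = max(0, m + s - n_universe), min(m, s)
            ks = np.arange(lo, hi + 1)
            new[ks] += pmf[m] * stats.hypergeom.pmf(ks, n_universe, m, s)
        pmf = new
    return float(pmf[observed:].sum())


def multiset_enrichment(
    sets,
    universe,
    method: str = "exact",
    n_perm: int = 10000,
    seed: int = 0,
) -> OverlapResult:
    """Fold enrichment and p-value of a k-way intersection (k >= 2).

    ``method="exact"`` uses the nested hypergeometric recursion;
    ``method="montecarlo"`` draws each set independently and uniformly
    at its size, with the add-one p-value correction
    (1 + #{sim >= obs}) / (n_perm + 1).
    """
    fsets, uni = _validate(sets, universe)
    if len(fsets) < 2:
        raise ValueError("need at least two sets")
    inter = frozenset.intersection(*fsets)
    sizes = [len(s) for s in fsets]
    if min(sizes) == 0:
        logger.warning("multiset_enrichment: empty input set; FE defined as 0")
        return OverlapResult(fsets, uni, inter, 0.0, 1.0)
    nu = len(uni)
    expected = np.prod([s / nu for s in sizes]) * nu
    fe = len(inter) / expected
    if method == "exact":
        p = _exact_intersection_tail(sizes, nu, len(inter))
    elif method == "montecarlo":
        rng = np.random.default_rng(seed)
        obs = len(inter)
        hits = 0
        batch = max(1, min(n_perm, 200_000 // max(nu, 1)))
        done = 0
        while done < n_perm:
            b = min(batch, n_perm - done)
            # mark membership of each random set, count items in all k
            member_count = np.zeros((b, nu), dtype=np.int8)
            for s in sizes:
                # vectorized uniform subsets via partial argsort of noise
                noise = rng.random((b, nu))
                idx = np.argpartition(noise, s - 1, axis=1)[:, :s]
                rows = np.repeat(np.arange(b), s)
                member_count[rows, idx.ravel()] += 1
            sim = (member_count == len(sizes)).sum(axis=1)
            hits += int((sim >= obs).sum())
            done += b
        p = (1 + hits) / (n_perm + 1)
    else:
        raise ValueError(f"unknown method {method!r}")
    return OverlapResult(fsets, uni, inter, fe, float(p))


def fisher_enrichment(query, annotation_sets: dict, universe) -> pd.DataFrame:
    """Fisher's exact test of a query set against named annotation sets.

    Two-sided FET on the 2x2 membership table per annotation set, with
    BH adjustment across sets.  The odds ratio is reported as inf when
    the off-diagonal product vanishes.
    """
    (q,), uni = _validate([query], universe)
    rows = []
    for name, members in annotation_sets.items():
        (a_set,), _ = _validate([members], uni)
        a = len(q & a_set)
        b = len(q) - a
        c = len(a_set) - a
        d = len(uni) - len(q) - len(a_set) + a
        odds, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
        rows.append(
            {
                "set": name,
                "overlap": a,
                "set_size": len(a_set),
                "odds_ratio": float(odds),
                "p_value": float(p),
            }
        )
    df = pd.DataFrame(rows)
    df["adj_p"] = bh_adjust(df["p_value"].to_numpy())
    return df


@dataclass
class ModuleOverlapMatrix:
    """All-pairs module overlap between two networks.

    ``adj_p`` holds BH-adjusted Fisher p-values (adjusted jointly over
    the full matrix); ``significant`` flags adj_p < alpha; ``summary``
    is the per-column proportion of significant overlaps (significant
    count divided by the number of row modules — the column-normalized
    view).
    """

    adj_p: pd.DataFrame
    significant: pd.DataFrame
    summary: pd.Series
    alpha: float


def module_overlap_matrix(
    mods_a: dict, mods_b: dict, universe, alpha: float = 0.05
) -> ModuleOverlapMatrix:
    """All-pairs one-sided Fisher overlap between two module sets.

    Each (row, column) cell tests whether module A_i and module B_j
    share more genes than expected in the universe; BH is applied
    jointly over all pairs, and each column is summarized by the
    proportion of row modules it significantly overlaps.
    """
    a_sets, uni = _validate(list(mods_a.values()), universe)
    b_sets, _ = _validate(list(mods_b.values()), uni)
    names_a, names_b = list(mods_a.keys()), list(mods_b.keys())
    nu = len(uni)
    pvals = np.empty((len(a_sets), len(b_sets)))
    for i, sa in enumerate(a_sets):
        for j, sb in enumerate(b_sets):
            k = len(sa & sb)
            pvals[i, j] = stats.hypergeom.sf(k - 1, nu, len(sa), len(sb))
    adj = bh_adjust(pvals.ravel()).reshape(pvals.shape)
    adj_df = pd.DataFrame(adj, index=names_a, columns=names_b)
    sig = adj_df < alpha
    summary = sig.sum(axis=0) / len(names_a)
    return ModuleOverlapMatrix(adj_p=adj_df, significant=sig, summary=summary, alpha=alpha)
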