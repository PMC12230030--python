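"""Phylogenetic null-model inference of community assembly processes.

beta-mean nearest taxon distance (bMNTD) between two communities is the
abundance-weighted mean patristic distance from each taxon present in one
community to its closest relative in the other:

    bMNTD(a, b) = 0.5 * [ sum_i f_ia min_j d(i, j) + sum_j f_jb min_i d(j, i) ]

with f the within-sample relative abundances over present taxa. The
beta-nearest taxon index (bNTI) standardizes the observed bMNTD against a
null distribution obtained by shuffling taxon identities across the tips of
the phylogeny (abundances fixed, phylogeny randomized). |bNTI| > 2 indicates
deterministic selection: > +2 heterogeneous (divergence under differing
environments), < -2 homogeneous.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import dendropy
import numpy as np
import pandas as pd

from .io import (FIRST_YEAR, LONG_TERM, SHORT_TERM, AbundanceTable,
                 patristic_matrix)

__all__ = [
    "BetaNTIResult",
    "AssemblySummary",
    "beta_mntd",
    "beta_nti",
    "summarize_assembly",
    "HETEROGENEOUS",
    "HOMOGENEOUS",
    "STOCHASTIC",
]

HETEROGENEOUS = "heterogeneous_selection"
HOMOGENEOUS = "homogeneous_selection"
STOCHASTIC = "stochastic"
UNCLASSIFIED = "unclassified"

BNTI_THRESHOLD = 2.0


@dataclass
class BetaNTIResult:
    pairs: pd.DataFrame  # sample_a, sample_b, bmntd_obs, null_mean, null_sd, bnti, process
    n_null: int
    seed: int | None


@dataclass
class AssemblySummary:
    grouping: str
    n_pairs: int
    pct_heterogeneous: float
    pct_homogeneous: float
    pct_stochastic: float


def _align(table: AbundanceTable, tree: dendropy.Tree):
    labels, dist = patristic_matrix(tree)
    pos = table.values.sum(axis=1) > 0
    present_taxa = [t for t, keep in zip(table.taxon_ids, pos) if keep]
    missing = sorted(set(present_taxa) - set(labels))
    if missing:
        raise ValueError(f"taxa not on the tree: {missing[:5]}")
    idx = {t: i for i, t in enumerate(labels)}
    rows = np.array([idx[t] for t in table.taxon_ids if t in idx])
    kept = [t for t in table.taxon_ids if t in idx]
    values = table.values[[table.taxon_ids.index(t) for t in kept], :]
    return kept, rows, values, dist


def _pair_mntd(dist_sub: np.ndarray, fa: np.ndarray, fb: np.ndarray) -> float:
    # dist_sub: taxa-in-a x taxa-in-b patristic distances
    return 0.5 * (float(fa @ dist_sub.min(axis=1)) +
                  float(fb @ dist_sub.min(axis=0)))


def beta_mntd(table: AbundanceTable, tree: dendropy.Tree,
              sample_a: str, sample_b: str) -> float:
    """Abundance-weighted bMNTD between two samples of the table."""
    kept, rows, values, dist = _align(table, tree)
    ja, jb = table.sample_ids.index(sample_a), table.sample_ids.index(sample_b)
    return _beta_mntd_indexed(values, rows, dist, ja, jb)


def _beta_mntd_indexed(values, rows, dist, ja, jb) -> float:
    ca, cb = values[:, ja], values[:, jb]
    ia, ib = np.flatnonzero(ca > 0), np.flatnonzero(cb > 0)
    if ia.size == 0 or ib.size == 0:
        raise ValueError("sample with no positive taxa")
    fa = ca[ia] / ca[ia].sum()
    fb = cb[ib] / cb[ib].sum()
    sub = dist[np.ix_(rows[ia], rows[ib])]
    return _pair_mntd(sub, fa, fb)


def beta_nti(table: AbundanceTable, tree: dendropy.Tree, n_null: int = 999,
             seed: int | None = None,
             pairs: list[tuple[str, str]] | None = None) -> BetaNTIResult:
    """bNTI for sample pairs via taxon-label shuffling across the tree tips.

    Each of ``n_null`` randomizations permutes the assignment of the table's
    taxa to tip positions (a "taxa labels" null); bNTI is the z-score of the
    observed bMNTD in that null distribution. Pairs whose null distribution
    is degenerate (sd = 0, e.g. on a star tree) are flagged unclassified.
    """
    if n_null < 99:
        raise ValueError("n_null must be >= 99")
    kept, rows, values, dist = _align(table, tree)
    rng = np.random.default_rng(seed)
    sample_idx = {s: j for j, s in enumerate(table.sample_ids)}
    if pairs is None:
        pairs = list(itertools.combinations(table.sample_ids, 2))
    pre = []
    for sa, sb in pairs:
        ja, jb = sample_idx[sa], sample_idx[sb]
        ca, cb = values[:, ja], values[:, jb]
        ia, ib = np.flatnonzero(ca > 0), np.flatnonzero(cb > 0)
        if ia.size == 0 or ib.size == 0:
            raise ValueError(f"sample pair ({sa}, {sb}) has an empty sample")
        fa = ca[ia] / ca[ia].sum()
        fb = cb[ib] / cb[ib].sum()
        obs = _pair_mntd(dist[np.ix_(rows[ia], rows[ib])], fa, fb)
        pre.append((sa, sb, ia, ib, fa, fb, obs))

    nulls = np.empty((len(pre), n_null))
    n_tips = rows.size
    for k in range(n_null):
        perm = rows[rng.permutation(n_tips)]
        for q, (_, _, ia, ib, fa, fb, _) in enumerate(pre):
            nulls[q, k] = _pair_mntd(dist[np.ix_(perm[ia], perm[ib])], fa, fb)

    records = []
    for q, (sa, sb, ia, ib, fa, fb, obs) in enumerate(pre):
        mu = float(nulls[q].mean())
        sd = float(nulls[q].std(ddof=1))
        if sd <= 1e-12:
            bnti = float("nan")
            process = UNCLASSIFIED
        else:
            bnti = (obs - mu) / sd
            if bnti > BNTI_THRESHOLD:
                process = HETEROGENEOUS
            elif bnti < -BNTI_THRESHOLD:
                process = HOMOGENEOUS
            else:
                process = STOCHASTIC
        records.append({"sample_a": sa, "sample_b": sb, "bmntd_obs": obs,
                        "null_mean": mu, "null_sd": sd, "bnti": bnti,
                        "process": process})
    return BetaNTIResult(pairs=pd.DataFrame(records), n_null=n_null, seed=seed)


_GROUPINGS = ("within_short", "within_long", "between")


def summarize_assembly(result: BetaNTIResult, metadata: pd.DataFrame,
                       grouping: str) -> AssemblySummary:
    """Process percentages for pairs within/between duration classes.

    ``within_short``: both samples short-term; ``within_long``: both
    long-term; ``between``: one of each. First-year samples never enter any
    grouping. Percentages are over classified pairs and sum to 100.
    """
    if grouping not in _GROUPINGS:
        raise ValueError(f"grouping must be one of {_GROUPINGS}")
    cls = metadata["duration_class"]

    def _in_grouping(sa: str, sb: str) -> bool:
        da, db = cls.get(sa), cls.get(sb)
        if FIRST_YEAR in (da, db) or None in (da, db):
            return False
        if grouping == "within_short":
            return da == db == SHORT_TERM
        if grouping == "within_long":
            return da == db == LONG_TERM
        return {da, db} == {SHORT_TERM, LONG_TERM}

    sel = result.pairs[[
        _in_grouping(r.sample_a, r.sample_b) for r in result.pairs.itertuples()
    ]]
    sel = sel[sel["process"] != UNCLASSIFIED]
    n = len(sel)
    if n == 0:
        raise ValueError(f"no classified pairs in grouping {grouping!r}")
    return AssemblySummary(
        grouping=grouping, n_pairs=n,
        pct_heterogeneous=100.0 * (sel["process"] == HETEROGENEOUS).sum() / n,
        pct_homogeneous=100.0 * (sel["process"] == HOMOGENEOUS).sum() / n,
        pct_stochastic=100.0 * (sel["process"] == STOCHASTIC).sum() / n,
    )
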