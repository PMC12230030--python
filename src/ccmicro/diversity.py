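"""Alpha/beta diversity, group comparisons and cropping-year trend fits.

Chao1 uses the bias-corrected estimator S_obs + F1(F1-1)/(2(F2+1)); Shannon
entropy is in natural log. Principal coordinates analysis is classical
scaling (Gower double-centering + eigendecomposition) with negative
eigenvalues dropped from the explained-variance denominator.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import pdist, squareform

from .io import LONG_TERM, SHORT_TERM, AbundanceTable

__all__ = [
    "AlphaDiversityResult",
    "OrdinationResult",
    "TrendFit",
    "GroupTestReport",
    "chao1",
    "shannon",
    "alpha_diversity",
    "bray_curtis",
    "pcoa",
    "test_group_differences",
    "fit_ccy_trend",
]


@dataclass
class AlphaDiversityResult:
    sample_id: str
    s_obs: int
    f1: int
    f2: int
    chao1: float
    shannon: float


@dataclass
class OrdinationResult:
    """Classical-scaling coordinates with per-axis explained variance.

    ``explained`` fractions are relative to the sum of positive eigenvalues;
    ``negative_eigenvalue_mass`` records the dropped |negative| mass so the
    correction is visible in output.
    """

    coordinates: pd.DataFrame
    explained: np.ndarray
    eigenvalues: np.ndarray
    negative_eigenvalue_mass: float


@dataclass
class TrendFit:
    model: str  # "linear" or "quadratic"
    coefficients: tuple  # highest order first, intercept last
    r2: float
    pearson_r: float | None
    p_value: float


@dataclass
class GroupTestReport:
    anova_f: float
    anova_p: float
    ttest_t: float
    ttest_p: float
    lsd_pairwise: pd.DataFrame
    letters: dict[str, str]


def chao1(counts) -> tuple[int, int, int, float]:
    """Bias-corrected Chao1 richness: (s_obs, f1, f2, chao1)."""
    counts = np.asarray(counts)
    if np.any(counts < 0):
        raise ValueError("counts must be non-negative")
    if counts.sum() == 0:
        raise ValueError("all-zero count vector")
    s_obs = int(np.count_nonzero(counts))
    f1 = int(np.count_nonzero(counts == 1))
    f2 = int(np.count_nonzero(counts == 2))
    est = s_obs + f1 * (f1 - 1) / (2.0 * (f2 + 1))
    return s_obs, f1, f2, est


def shannon(counts) -> float:
    """Shannon entropy H = -sum p ln p over positive proportions (nats)."""
    counts = np.asarray(counts, dtype=float)
    total = counts.sum()
    if total <= 0:
        raise ValueError("all-zero count vector")
    p = counts[counts > 0] / total
    return float(-(p * np.log(p)).sum())


def alpha_diversity(table: AbundanceTable) -> pd.DataFrame:
    """Per-sample alpha diversity table (on raw counts, no rarefaction)."""
    rows = []
    for j, sid in enumerate(table.sample_ids):
        col = table.values[:, j]
        s_obs, f1, f2, c1 = chao1(col)
        rows.append({"sample_id": sid, "s_obs": s_obs, "f1": f1, "f2": f2,
                     "chao1": c1, "shannon": shannon(col)})
    return pd.DataFrame(rows).set_index("sample_id")


def bray_curtis(table: AbundanceTable) -> pd.DataFrame:
    """Pairwise Bray-Curtis dissimilarity between samples."""
    if table.n_samples < 2:
        raise ValueError("need at least 2 samples")
    totals = table.sample_totals()
    if np.any(totals == 0):
        sid = table.sample_ids[int(np.flatnonzero(totals == 0)[0])]
        raise ValueError(f"sample {sid!r} has zero total")
    dm = squareform(pdist(table.values.T, metric="braycurtis"))
    return pd.DataFrame(dm, index=table.sample_ids, columns=table.sample_ids)


def pcoa(dist: pd.DataFrame | np.ndarray, n_axes: int | None = None) -> OrdinationResult:
    """Principal coordinates analysis by double-centering and eigendecomposition."""
    if isinstance(dist, pd.DataFrame):
        labels = list(dist.index)
        d = dist.to_numpy(dtype=float)
    else:
        d = np.asarray(dist, dtype=float)
        labels = [f"s{i}" for i in range(d.shape[0])]
    if d.shape[0] != d.shape[1] or not np.allclose(d, d.T, atol=1e-10):
        raise ValueError("distance matrix must be square and symmetric")
    if not np.allclose(np.diag(d), 0.0, atol=1e-12):
        raise ValueError("distance matrix must have a zero diagonal")
    n = d.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (d ** 2) @ j
    eigval, eigvec = np.linalg.eigh((b + b.T) / 2.0)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    pos = eigval > max(1e-12, 1e-12 * abs(eigval[0]))
    coords = eigvec[:, pos] * np.sqrt(eigval[pos])
    if n_axes is not None:
        coords = coords[:, :n_axes]
    explained = eigval[pos][: coords.shape[1]] / eigval[pos].sum()
    cols = [f"PCo{i + 1}" for i in range(coords.shape[1])]
    return OrdinationResult(
        coordinates=pd.DataFrame(coords, index=labels, columns=cols),
        explained=explained,
        eigenvalues=eigval,
        negative_eigenvalue_mass=float(-eigval[eigval < 0].sum()),
    )


def _compact_letters(groups: list[str], sig_pairs: set[frozenset]) -> dict[str, str]:
    """Insert-and-absorb compact letter display for pairwise comparisons."""
    letter_sets: list[set] = [set(groups)]
    for pair in sig_pairs:
        a, b = sorted(pair)
        for s in list(letter_sets):
            if a in s and b in s:
                letter_sets.remove(s)
                letter_sets.extend([s - {a}, s - {b}])
        # absorb subsets
        letter_sets = [s for s in letter_sets
                       if s and not any(s < t for t in letter_sets)]
        # deduplicate
        uniq = []
        for s in letter_sets:
            if s not in uniq:
                uniq.append(s)
        letter_sets = uniq
    letter_sets.sort(key=lambda s: sorted(s))
    out = {g: "" for g in groups}
    for ch, s in zip("abcdefghijklmnopqrstuvwxyz", letter_sets):
        for g in s:
            out[g] += ch
    return {g: "".join(sorted(v)) for g, v in out.items()}


def test_group_differences(values: pd.Series, metadata: pd.DataFrame,
                           alpha: float = 0.05) -> GroupTestReport:
    """One-way ANOVA across cropping-year groups, a two-sample t-test between
    the short- and long-term duration classes, and Fisher's LSD pairwise
    comparisons with a compact letter display.

    The t-test is the classical pooled-variance Student test; first-year
    samples are excluded from the short/long contrast but participate in the
    ANOVA as their own group.
    """
    values = values.loc[metadata.index]
    groups = metadata["group"]
    by_group = {g: values[groups == g].to_numpy(dtype=float)
                for g in groups.unique()}
    if len(by_group) < 2:
        raise ValueError("need at least 2 groups")
    for g, v in by_group.items():
        if v.size < 2:
            raise ValueError(f"group {g!r} has fewer than 2 replicates")
    arrays = list(by_group.values())
    if np.allclose(np.concatenate(arrays), arrays[0][0]):
        f_stat, anova_p = float("nan"), 1.0
    else:
        f_stat, anova_p = stats.f_oneway(*arrays)
        f_stat, anova_p = float(f_stat), float(anova_p)
        if np.isnan(anova_p):
            anova_p = 1.0

    short = values[metadata["duration_class"] == SHORT_TERM].to_numpy(dtype=float)
    long_ = values[metadata["duration_class"] == LONG_TERM].to_numpy(dtype=float)
    if short.size >= 2 and long_.size >= 2 and (short.std() + long_.std()) > 0:
        t_stat, t_p = stats.ttest_ind(short, long_, equal_var=True)
        t_stat, t_p = float(t_stat), float(t_p)
    else:
        t_stat, t_p = float("nan"), 1.0

    # Fisher's LSD: pairwise t-tests sharing the ANOVA pooled error variance.
    n_total = sum(v.size for v in arrays)
    df_err = n_total - len(arrays)
    mse = sum(((v - v.mean()) ** 2).sum() for v in arrays) / df_err
    rows = []
    sig_pairs: set[frozenset] = set()
    for ga, gb in itertools.combinations(sorted(by_group), 2):
        va, vb = by_group[ga], by_group[gb]
        if mse == 0:
            p = 1.0 if va.mean() == vb.mean() else 0.0
            t = float("inf") if p == 0.0 else 0.0
        else:
            se = np.sqrt(mse * (1.0 / va.size + 1.0 / vb.size))
            t = (va.mean() - vb.mean()) / se
            p = 2.0 * stats.t.sf(abs(t), df_err)
        rows.append({"group_a": ga, "group_b": gb, "t": t, "p": p})
        if p < alpha:
            sig_pairs.add(frozenset((ga, gb)))
    letters = _compact_letters(sorted(by_group), sig_pairs)
    return GroupTestReport(anova_f=f_stat, anova_p=float(anova_p),
                           ttest_t=t_stat, ttest_p=float(t_p),
                           lsd_pairwise=pd.DataFrame(rows), letters=letters)


def fit_ccy_trend(values, ccy, model: str = "linear") -> TrendFit:
    """Ordinary least squares of a metric against cropping years.

    Linear fits report Pearson's r and its two-sided p; quadratic fits report
    the regression F-test p.
    """
    values = np.asarray(values, dtype=float)
    ccy = np.asarray(ccy, dtype=float)
    if np.unique(ccy).size < 3:
        raise ValueError("need at least 3 distinct ccy values")
    if model == "linear":
        res = stats.linregress(ccy, values)
        return TrendFit(model="linear",
                        coefficients=(float(res.slope), float(res.intercept)),
                        r2=float(res.rvalue ** 2),
                        pearson_r=float(res.rvalue),
                        p_value=float(res.pvalue))
    if model == "quadratic":
        coefs = np.polyfit(ccy, values, deg=2)
        fitted = np.polyval(coefs, ccy)
        sst = ((values - values.mean()) ** 2).sum()
        sse = ((values - fitted) ** 2).sum()
        r2 = 1.0 - sse / sst if sst > 0 else 0.0
        n = values.size
        df1, df2 = 2, n - 3
        if df2 <= 0 or sse <= 0:
            p = 0.0 if r2 == 1.0 else 1.0
        else:
            f = (r2 / df1) / ((1.0 - r2) / df2)
            p = float(stats.f.sf(f, df1, df2))
        return TrendFit(model="quadratic", coefficients=tuple(map(float, coefs)),
                        r2=float(r2), pearson_r=None, p_value=p)
    raise ValueError(f"unknown model {model!r}")
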