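"""Synthetic communities for testing the analysis pipeline end to end.

Three generators cover the statistical regimes the downstream stages assume:

* :func:`simulate_neutral_table` — Sloan-type neutral assembly. Each taxon's
  per-sample relative abundance is drawn from ``Beta(Nm*p, Nm*(1-p))`` around
  its metacommunity abundance ``p``; reads are then binomial. This is the
  generative twin of the neutral community model fitted downstream, so
  migration-parameter recovery is a well-posed test.
* :func:`simulate_selection_table` — deterministic (heterogeneous-selection)
  assembly. A niche optimum evolves on the phylogeny by Brownian motion, a
  per-sample environment filters taxa through a Gaussian kernel, and
  multiplicative lognormal noise plus multinomial read sampling follow. The
  Brownian traits give the phylogenetic signal without which nearest-taxon
  null models have no power.
* :func:`simulate_ccy_dataset` — the full study design: 7 cropping-year
  levels (1, 2, 5, 10, 15, 20, 25) x 4 replicates = 28 samples, one dominant
  taxon set whose summed relative abundance rises linearly with cropping
  years and one that declines, and a neutral background for the rest.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd

from .io import AbundanceTable, duration_class_of, parse_tree

__all__ = [
    "NeutralParams",
    "NicheModel",
    "simulate_tree",
    "brownian_traits",
    "make_metadata",
    "lognormal_metacommunity",
    "simulate_neutral_table",
    "make_niche_model",
    "simulate_selection_table",
    "simulate_ccy_dataset",
]

CCY_LEVELS = (1, 2, 5, 10, 15, 20, 25)


@dataclass
class NeutralParams:
    """Parameters of the neutral (Sloan) generative model.

    metacommunity: relative abundances summing to 1 (entries in [0, 1)).
    N: reads per sample (local community size).
    m: migration probability in (0, 1]; Nm = N * m.
    """

    metacommunity: np.ndarray
    N: int
    m: float

    def __post_init__(self) -> None:
        self.metacommunity = np.asarray(self.metacommunity, dtype=float)
        if not np.isclose(self.metacommunity.sum(), 1.0):
            raise ValueError("metacommunity must sum to 1")
        if np.any(self.metacommunity < 0):
            raise ValueError("metacommunity abundances must be non-negative")
        if np.any(self.metacommunity >= 1.0):
            raise ValueError(
                "metacommunity entry of 1 gives a degenerate Beta(Nm, 0)")
        if not (0 < self.m <= 1):
            raise ValueError("m must be in (0, 1]")
        if self.N <= 0:
            raise ValueError("N must be positive")

    @property
    def nm(self) -> float:
        return self.N * self.m


@dataclass
class NicheModel:
    """Gaussian environmental-filtering model with phylogenetically conserved optima.

    trait: per-tip niche optimum (arbitrary units, typically Brownian on the tree).
    sigma: niche width; larger means weaker filtering (sigma -> inf is neutral).
    env: per-sample environmental value, strictly monotone in cropping years.
    noise_sd: sd of multiplicative lognormal noise on expected abundances.
    """

    trait: dict[str, float]
    sigma: float
    env: dict[str, float]
    noise_sd: float = 0.3

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValueError("niche width sigma must be > 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


def simulate_tree(n_taxa: int, seed: int, prefix: str = "T") -> dendropy.Tree:
    """Random coalescent-style rooted bifurcating tree.

    Pairs of lineages merge uniformly at random with exponential waiting
    times scaled by 2/(k(k-1)); internode lengths are therefore exponential
    and the tree is ultrametric. Deterministic given ``seed``.
    """
    if n_taxa < 2:
        raise ValueError("n_taxa must be >= 2")
    rng = np.random.default_rng(seed)
    width = max(4, len(str(n_taxa)))
    reprs = [f"{prefix}{i + 1:0{width}d}" for i in range(n_taxa)]
    heights = [0.0] * n_taxa
    t = 0.0
    while len(reprs) > 1:
        k = len(reprs)
        t += rng.exponential(2.0 / (k * (k - 1)))
        i, j = sorted(rng.choice(k, size=2, replace=False))
        merged = (f"({reprs[i]}:{t - heights[i]:.10g},"
                  f"{reprs[j]}:{t - heights[j]:.10g})")
        reprs[i] = merged
        heights[i] = t
        del reprs[j], heights[j]
    return parse_tree(reprs[0] + ";")


def brownian_traits(tree: dendropy.Tree, seed: int,
                    rate: float = 1.0) -> dict[str, float]:
    """Evolve a trait on the tree by Brownian motion (variance = rate x length).

    Returns the per-tip trait, standardized to zero mean and unit sd across
    tips so niche widths and environments are on a comparable scale.
    """
    rng = np.random.default_rng(seed)
    value: dict[int, float] = {}
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            value[id(node)] = 0.0
        else:
            step = rng.normal(0.0, np.sqrt(rate * (node.edge.length or 0.0)))
            value[id(node)] = value[id(node.parent_node)] + step
    tips = {leaf.taxon.label: value[id(leaf)] for leaf in tree.leaf_node_iter()}
    vals = np.array(list(tips.values()))
    sd = vals.std()
    if sd == 0:  # degenerate zero-length tree
        return {k: 0.0 for k in tips}
    mean = vals.mean()
    return {k: (v - mean) / sd for k, v in tips.items()}


def make_metadata(ccy_levels=CCY_LEVELS, n_replicates: int = 4) -> pd.DataFrame:
    """Study-design metadata: each cropping-year level x replicates."""
    rows = []
    for ccy in ccy_levels:
        for rep in range(1, n_replicates + 1):
            rows.append({
                "sample_id": f"S{ccy:02d}R{rep}",
                "ccy": ccy,
                "group": f"{ccy}YC",
                "duration_class": duration_class_of(ccy),
                "replicate": rep,
            })
    return pd.DataFrame(rows).set_index("sample_id")


def lognormal_metacommunity(n_taxa: int, seed: int, sd: float = 2.0) -> np.ndarray:
    """Lognormal rank-abundance metacommunity normalized to sum 1."""
    rng = np.random.default_rng(seed)
    raw = rng.lognormal(0.0, sd, size=n_taxa)
    return raw / raw.sum()


def simulate_neutral_table(params: NeutralParams, n_samples: int, seed: int,
                           taxon_ids: list[str] | None = None,
                           sample_ids: list[str] | None = None,
                           rank: str = "genus") -> AbundanceTable:
    """Draw a count table under the neutral model.

    For each taxon with metacommunity abundance p > 0 the per-sample relative
    abundance is Beta(Nm*p, Nm*(1-p)); counts are binomial(N, x). Taxa with
    p = 0 are all-zero rows.
    """
    if n_samples < 2:
        raise ValueError("n_samples must be >= 2")
    rng = np.random.default_rng(seed)
    p = params.metacommunity
    n_taxa = p.size
    nm = params.nm
    counts = np.zeros((n_taxa, n_samples), dtype=float)
    pos = p > 0
    a = nm * p[pos]
    b = nm * (1.0 - p[pos])
    x = rng.beta(a[:, None], b[:, None], size=(pos.sum(), n_samples))
    counts[pos] = rng.binomial(params.N, x)
    if taxon_ids is None:
        width = max(4, len(str(n_taxa)))
        taxon_ids = [f"T{i + 1:0{width}d}" for i in range(n_taxa)]
    if sample_ids is None:
        sample_ids = [f"N{j + 1:03d}" for j in range(n_samples)]
    return AbundanceTable(taxon_ids=taxon_ids, sample_ids=sample_ids,
                          values=counts, rank=rank)


def make_niche_model(tree: dendropy.Tree, metadata: pd.DataFrame, seed: int,
                     sigma: float = 0.3, env_range: tuple[float, float] = (-1.0, 1.0),
                     noise_sd: float = 0.3) -> NicheModel:
    """Brownian niche optima plus an environment linear in cropping years.

    The environment maps the observed ccy range linearly onto ``env_range``,
    which sits inside the standardized trait distribution so both ends of the
    gradient select real subsets of taxa.
    """
    trait = brownian_traits(tree, seed)
    ccy = metadata["ccy"].to_numpy(dtype=float)
    lo, hi = float(ccy.min()), float(ccy.max())
    span = hi - lo
    if span == 0:
        raise ValueError("environment requires at least two distinct ccy values")
    e0, e1 = env_range
    env = {sid: e0 + (e1 - e0) * (c - lo) / span
           for sid, c in zip(metadata.index, ccy)}
    return NicheModel(trait=trait, sigma=sigma, env=env, noise_sd=noise_sd)


def simulate_selection_table(tree: dendropy.Tree, metadata: pd.DataFrame,
                             niche: NicheModel, depth: int, seed: int,
                             rank: str = "genus") -> AbundanceTable:
    """Draw a count table under Gaussian environmental filtering.

    Expected relative abundance of taxon i in sample s is proportional to
    exp(-(trait_i - env_s)^2 / (2 sigma^2)) times lognormal(0, noise_sd)
    noise; reads are multinomial with the given depth.
    """
    tips = sorted(leaf.taxon.label for leaf in tree.leaf_node_iter())
    missing = [t for t in tips if t not in niche.trait]
    if missing:
        raise ValueError(f"niche model lacks traits for tips {missing[:3]}")
    extra = [s for s in metadata.index if s not in niche.env]
    if extra:
        raise ValueError(f"niche model lacks environments for samples {extra[:3]}")
    rng = np.random.default_rng(seed)
    trait = np.array([niche.trait[t] for t in tips])
    env = np.array([niche.env[s] for s in metadata.index])
    weight = np.exp(-((trait[:, None] - env[None, :]) ** 2)
                    / (2.0 * niche.sigma ** 2))
    if niche.noise_sd > 0:
        weight = weight * rng.lognormal(0.0, niche.noise_sd, size=weight.shape)
    probs = weight / weight.sum(axis=0)
    counts = np.column_stack(
        [rng.multinomial(depth, probs[:, j]) for j in range(probs.shape[1])]
    ).astype(float)
    return AbundanceTable(taxon_ids=tips, sample_ids=list(metadata.index),
                          values=counts, rank=rank)


def simulate_ccy_dataset(seed: int, n_taxa: int = 120, n_increasing: int = 8,
                         n_decreasing: int = 8, depth: int = 20000,
                         background_nm: float = 1000.0,
                         taxon_noise_sd: float = 0.05,
                         set_noise_sd: float = 0.05,
                         ) -> tuple[AbundanceTable, pd.DataFrame, dendropy.Tree]:
    """The full 28-sample fixture mirroring the cropping-year study design.

    Dominant set A (``n_increasing`` taxa) has a summed relative abundance
    rising linearly from 10% at 1 year to 30% at 25 years; set B mirrors it
    downward (emulating the opposing bacterial vs fungal genus trends).
    The remaining taxa form a neutral background. Per-sample counts are
    multinomial at the configured depth, so columns sum exactly to ``depth``.

    Within-set shares are fixed (Zipf-like) with multiplicative lognormal
    noise per taxon (sd ``taxon_noise_sd``) and per set total (sd
    ``set_noise_sd``); the shared set-level trend makes within-set pairs
    strongly positively correlated and between-set pairs negatively
    correlated, which is what gives the co-occurrence networks signed
    structure to detect.
    """
    ss = np.random.SeedSequence(seed)
    tree_seed, trend_seed, meta_seed, bg_seed, count_seed = (
        int(s.generate_state(1)[0] % (2 ** 31)) for s in ss.spawn(5))
    metadata = make_metadata()
    tree = simulate_tree(n_taxa, tree_seed, prefix="G")
    taxa = sorted(leaf.taxon.label for leaf in tree.leaf_node_iter())
    n_bg = n_taxa - n_increasing - n_decreasing
    if n_bg < 10:
        raise ValueError("need at least 10 background taxa")
    inc = taxa[:n_increasing]
    dec = taxa[n_increasing:n_increasing + n_decreasing]
    ccy = metadata["ccy"].to_numpy(dtype=float)
    # Linear set totals: 0.10 <-> 0.30 across the 1..25-year span.
    slope = 0.20 / 24.0
    inc_total = 0.10 + slope * (ccy - 1.0)
    dec_total = 0.30 - slope * (ccy - 1.0)
    rng = np.random.default_rng(trend_seed)
    inc_share = 1.0 / np.arange(1, n_increasing + 1)
    dec_share = 1.0 / np.arange(1, n_decreasing + 1)
    inc_share /= inc_share.sum()
    dec_share /= dec_share.sum()
    n_samples = len(metadata)

    def _set_block(share, total):
        noise = rng.lognormal(0.0, taxon_noise_sd, size=(share.size, n_samples))
        block = share[:, None] * noise
        block /= block.sum(axis=0)
        return block * total[None, :] * rng.lognormal(
            0.0, set_noise_sd, size=n_samples)[None, :]

    inc_block = _set_block(inc_share, inc_total)
    dec_block = _set_block(dec_share, dec_total)
    meta_bg = lognormal_metacommunity(n_bg, meta_seed, sd=1.5)
    bg_rng = np.random.default_rng(bg_seed)
    a = background_nm * meta_bg
    b = background_nm * (1.0 - meta_bg)
    bg_block = bg_rng.beta(a[:, None], b[:, None], size=(n_bg, n_samples))
    bg_block /= bg_block.sum(axis=0)
    bg_block *= (1.0 - inc_block.sum(axis=0) - dec_block.sum(axis=0))[None, :]
    expected = np.vstack([inc_block, dec_block, bg_block])
    expected /= expected.sum(axis=0)
    crng = np.random.default_rng(count_seed)
    counts = np.column_stack(
        [crng.multinomial(depth, expected[:, j]) for j in range(n_samples)]
    ).astype(float)
    table = AbundanceTable(taxon_ids=taxa, sample_ids=list(metadata.index),
                           values=counts, rank="genus")
    table.trend_sets = {"increasing": inc, "decreasing": dec}  # type: ignore[attr-defined]
    return table, metadata, tree
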