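"""Sloan neutral community model: occurrence frequency vs mean abundance.

Under neutral assembly with community size N and migration probability m,
the long-run relative abundance of a taxon with metacommunity abundance p
is Beta(Nm*p, Nm*(1-p)), so the probability of detecting it above the limit
d = 1/N is

    Freq(p) = 1 - BetaCDF(d; Nm*p, Nm*(1-p)).

``fit_ncm`` estimates m by least squares of observed occupancy against this
curve, reports R^2 as 1 - SSE/SST, bootstraps taxa (with replacement) for
confidence intervals on m, Nm and R^2, and partitions taxa into those above,
within, or below a 95% band around the predicted frequency. The partition
band is a Wilson binomial interval for an occupancy estimated from
``n_samples`` presence/absence trials (the convention of the standard
Sloan-model implementations); a bootstrap percentile band for the fitted
curve itself is available via ``band="bootstrap"``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .io import AbundanceTable

__all__ = ["NCMFit", "predicted_frequency", "fit_ncm", "summarize_fractions"]

_M_BOUNDS = (1e-6, 1.0)


@dataclass
class NCMFit:
    m: float
    nm: float
    N: float
    d: float
    rsqr: float
    n_boot: int
    band: str
    per_taxon: pd.DataFrame  # taxon, p, freq_obs, freq_pred, ci_lo, ci_hi, partition
    m_ci: tuple[float, float] | None
    nm_ci: tuple[float, float] | None
    rsqr_ci: tuple[float, float] | None
    seed: int | None = None


def predicted_frequency(p, nm: float, d: float) -> np.ndarray | float:
    """Neutral-model occurrence frequency 1 - BetaCDF(d; Nm*p, Nm*(1-p))."""
    p_arr = np.asarray(p, dtype=float)
    if np.any((p_arr <= 0) | (p_arr >= 1)):
        raise ValueError("p must lie strictly inside (0, 1)")
    if nm <= 0:
        raise ValueError("Nm must be positive")
    if not (0 < d < 1):
        raise ValueError("detection limit d must be in (0, 1)")
    out = stats.beta.sf(d, nm * p_arr, nm * (1.0 - p_arr))
    return float(out) if np.isscalar(p) else out


def _fit_m(p: np.ndarray, freq_obs: np.ndarray, n_reads: float, d: float) -> float:
    def sse(m: float) -> float:
        pred = stats.beta.sf(d, n_reads * m * p, n_reads * m * (1.0 - p))
        return float(((freq_obs - pred) ** 2).sum())

    res = optimize.minimize_scalar(sse, bounds=_M_BOUNDS, method="bounded",
                                   options={"xatol": 1e-10})
    if not res.success:
        raise RuntimeError(f"migration-rate optimization failed: {res.message}")
    return float(res.x)


def _wilson_band(freq_pred: np.ndarray, n: int,
                 conf: float = 0.95) -> tuple[np.ndarray, np.ndarray]:
    """Wilson score interval for a proportion freq_pred observed over n trials."""
    z = stats.norm.ppf(0.5 + conf / 2.0)
    ph = freq_pred
    denom = 1.0 + z ** 2 / n
    center = (ph + z ** 2 / (2 * n)) / denom
    half = z * np.sqrt(ph * (1 - ph) / n + z ** 2 / (4 * n ** 2)) / denom
    return np.clip(center - half, 0.0, 1.0), np.clip(center + half, 0.0, 1.0)


def fit_ncm(table: AbundanceTable, n_boot: int = 1000, seed: int | None = None,
            band: str = "wilson", conf: float = 0.95) -> NCMFit:
    """Fit the neutral model to a count table.

    N is the arithmetic mean of sample read totals and d = 1/N; p is the
    grand mean relative abundance of each taxon and occupancy the fraction
    of samples where its count is > 0. Taxa absent everywhere are dropped.
    """
    if table.is_relative:
        raise ValueError("fit_ncm expects a count table")
    counts = table.values
    totals = counts.sum(axis=0)
    if np.any(totals == 0):
        raise ValueError("sample with zero reads")
    n_reads = float(totals.mean())
    d = 1.0 / n_reads
    rel = counts / totals
    p = rel.mean(axis=1)
    freq_obs = (counts > 0).mean(axis=1)
    usable = (p > 0) & (p < 1)
    if usable.sum() < 3:
        raise ValueError("fewer than 3 usable taxa")
    informative = usable & (freq_obs > 0) & (freq_obs < 1)
    if informative.sum() < 10:
        import warnings
        warnings.warn("fewer than 10 taxa with intermediate occupancy; "
                      "the migration estimate may be poorly constrained")
    taxa = [t for t, u in zip(table.taxon_ids, usable) if u]
    p_u = p[usable]
    f_u = freq_obs[usable]
    m_hat = _fit_m(p_u, f_u, n_reads, d)
    pred = predicted_frequency(p_u, n_reads * m_hat, d)
    sst = float(((f_u - f_u.mean()) ** 2).sum())
    sse = float(((f_u - pred) ** 2).sum())
    rsqr = 1.0 - sse / sst if sst > 0 else float("nan")

    rng = np.random.default_rng(seed)
    m_ci = nm_ci = rsqr_ci = None
    boot_preds = None
    if n_boot > 0:
        n_tx = p_u.size
        m_bs = np.empty(n_boot)
        r_bs = np.empty(n_boot)
        boot_preds = np.empty((n_boot, n_tx))
        for b in range(n_boot):
            idx = rng.integers(0, n_tx, size=n_tx)
            mb = _fit_m(p_u[idx], f_u[idx], n_reads, d)
            m_bs[b] = mb
            pb = predicted_frequency(p_u[idx], n_reads * mb, d)
            sstb = float(((f_u[idx] - f_u[idx].mean()) ** 2).sum())
            sseb = float(((f_u[idx] - pb) ** 2).sum())
            r_bs[b] = 1.0 - sseb / sstb if sstb > 0 else np.nan
            boot_preds[b] = predicted_frequency(p_u, n_reads * mb, d)
        lo, hi = (1 - conf) / 2 * 100, (1 + conf) / 2 * 100
        m_ci = tuple(np.percentile(m_bs, [lo, hi]))
        nm_ci = (m_ci[0] * n_reads, m_ci[1] * n_reads)
        rsqr_ci = tuple(np.nanpercentile(r_bs, [lo, hi]))

    if band == "wilson":
        ci_lo, ci_hi = _wilson_band(pred, table.n_samples, conf)
    elif band == "bootstrap":
        if boot_preds is None:
            raise ValueError("bootstrap band requires n_boot > 0")
        lo, hi = (1 - conf) / 2 * 100, (1 + conf) / 2 * 100
        ci_lo = np.minimum(np.percentile(boot_preds, lo, axis=0), pred)
        ci_hi = np.maximum(np.percentile(boot_preds, hi, axis=0), pred)
    else:
        raise ValueError(f"unknown band {band!r}")

    partition = np.where(f_u > ci_hi, "above",
                         np.where(f_u < ci_lo, "below", "within"))
    per_taxon = pd.DataFrame({
        "taxon": taxa, "p": p_u, "freq_obs": f_u, "freq_pred": pred,
        "ci_lo": ci_lo, "ci_hi": ci_hi, "partition": partition,
    }).set_index("taxon")
    return NCMFit(m=m_hat, nm=n_reads * m_hat, N=n_reads, d=d, rsqr=rsqr,
                  n_boot=n_boot, band=band, per_taxon=per_taxon,
                  m_ci=m_ci, nm_ci=nm_ci, rsqr_ci=rsqr_ci, seed=seed)


def summarize_fractions(fit: NCMFit) -> tuple[float, float, float]:
    """Percentages of taxa (above, within, below) the 95% band; sums to 100."""
    part = fit.per_taxon["partition"]
    if len(part) == 0:
        raise ValueError("fit contains no taxa")
    n = len(part)
    return (100.0 * (part == "above").sum() / n,
            100.0 * (part == "within").sum() / n,
            100.0 * (part == "below").sum() / n)
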