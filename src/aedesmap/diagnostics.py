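"""MCMC convergence diagnostics: split rank-normalized R-hat and bulk ESS.

Standard formulas (Vehtari et al. 2021 versions as used by Stan): chains are
split in half, draws are rank-normalized through the inverse normal CDF,
R-hat is the usual between/within variance ratio on the transformed draws,
and the effective sample size comes from Geyer's initial-monotone-sequence
estimate of the autocorrelation time.
"""

from __future__ import annotations

import numpy as np
from scipy.special import ndtri


def _split_chains(draws: np.ndarray) -> np.ndarray:
    """(chains, draws) -> (2*chains, draws//2), dropping an odd last draw."""
    c, d = draws.shape
    half = d // 2
    return np.vstack([draws[:, :half], draws[:, d - half :]])


def _rank_normalize(x: np.ndarray) -> np.ndarray:
    flat = x.ravel()
    ranks = np.argsort(np.argsort(flat)) + 1.0
    z = ndtri((ranks - 0.375) / (flat.size + 0.25))
    return z.reshape(x.shape)


def split_rhat(draws: np.ndarray) -> float:
    """Split rank-normalized R-hat for one scalar parameter.

    Parameters
    ----------
    draws : array (chains, draws)
    """
    x = _rank_normalize(_split_chains(np.asarray(draws, float)))
    m, n = x.shape
    if n < 2:
        return np.nan
    chain_means = x.mean(axis=1)
    b = n * chain_means.var(ddof=1)
    w = x.var(axis=1, ddof=1).mean()
    if w == 0:
        return 1.0
    var_plus = (n - 1) / n * w + b / n
    return float(np.sqrt(var_plus / w))


def _autocovariance(x: np.ndarray) -> np.ndarray:
    """Biased autocovariance of a 1-D series via FFT."""
    n = len(x)
    xc = x - x.mean()
    nfft = int(2 ** np.ceil(np.log2(2 * n)))
    f = np.fft.rfft(xc, nfft)
    acov = np.fft.irfft(f * np.conj(f), nfft)[:n].real
    return acov / n


def ess_bulk(draws: np.ndarray) -> float:
    """Bulk effective sample size for one scalar parameter.

    Rank-normalizes split chains, then applies Geyer's initial monotone
    positive-pair sequence to the chain-averaged autocorrelations.
    """
    x = _rank_normalize(_split_chains(np.asarray(draws, float)))
    m, n = x.shape
    if n < 4:
        return np.nan
    acovs = np.array([_autocovariance(x[i]) for i in range(m)])
    w = x.var(axis=1, ddof=1).mean()
    chain_means = x.mean(axis=1)
    var_plus = (n - 1) / n * w + chain_means.var(ddof=1)
    if var_plus == 0:
        return float(m * n)
    rho = 1.0 - (w - acovs.mean(axis=0)) / var_plus
    # Geyer: sum consecutive pairs while positive, enforce monotone decrease
    tau = 1.0
    prev_pair = np.inf
    t = 1
    while t + 1 < n:
        pair = rho[t] + rho[t + 1]
        if pair < 0:
            break
        pair = min(pair, prev_pair)
        tau += 2.0 * pair
        prev_pair = pair
        t += 2
    return float(m * n / tau)


def diagnostics_table(samples: dict[str, np.ndarray]):
    """R-hat and ESS for a dict of (chains, draws) arrays -> dict of dicts."""
    out = {}
    for name, arr in samples.items():
        out[name] = {"rhat": split_rhat(arr), "ess_bulk": ess_bulk(arr)}
    return out


class ConvergenceError(RuntimeError):
    """Raised when chains fail the R-hat threshold; carries the table."""

    def __init__(self, message, table=None):
        super().__init__(message)
        self.table = table
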