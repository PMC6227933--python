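"""Small internal statistical helpers shared across modules."""

from __future__ import annotations

import numpy as np


def effective_sample_size(x: np.ndarray) -> float:
    """Autocorrelation-based effective sample size of a scalar chain.

    Uses Geyer's initial positive sequence: sum successive lag-pair
    autocorrelations while the pair sums stay positive. Returns ``len(x)``
    for an (effectively) white chain and is clipped to [1, len(x)].
    """
    x = np.asarray(x, dtype=float)
    n = x.size
    if n < 4:
        return float(n)
    x = x - x.mean()
    var = np.dot(x, x) / n
    if var <= 0:
        return float(n)
    # full autocorrelation via FFT
    nfft = int(2 ** np.ceil(np.log2(2 * n)))
    f = np.fft.rfft(x, nfft)
    acov = np.fft.irfft(f * np.conj(f), nfft)[:n].real / n
    rho = acov / var
    tau = 1.0
    for k in range(1, n - 1, 2):
        pair = rho[k] + rho[k + 1]
        if pair <= 0:
            break
        tau += 2.0 * pair
    return float(np.clip(n / tau, 1.0, n))


def equal_tailed_interval(draws: np.ndarray, level: float) -> tuple[float, float]:
    """Central credible interval at the given probability level."""
    if not 0 < level < 1:
        raise ValueError("level must be in (0, 1)")
    alpha = (1.0 - level) / 2.0
    lo, hi = np.quantile(draws, [alpha, 1.0 - alpha])
    return float(lo), float(hi)
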