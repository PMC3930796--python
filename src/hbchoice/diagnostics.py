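"""MCMC convergence diagnostics: split R-hat and effective sample size.

Thin wrapper over ArviZ's rank-normalized split-R-hat and bulk ESS, applied
to the population-level parameters of a fitted hierarchical choice model.
Constant chains (zero variance) are reported explicitly as degenerate
rather than surfacing as division artifacts.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .hb import PosteriorDraws

__all__ = ["rhat_ess", "diagnostics"]

RHAT_FLAG_THRESHOLD = 1.1


def rhat_ess(chains: np.ndarray) -> tuple[float, float]:
    """Split R-hat and bulk ESS for one scalar parameter.

    ``chains`` has shape (n_chains, n_draws).  Returns ``(nan, nan)`` for
    constant chains, which callers should report as degenerate.
    """
    import arviz as az

    chains = np.atleast_2d(np.asarray(chains, dtype=float))
    if np.ptp(chains) == 0.0:
        return float("nan"), float("nan")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        r = float(az.rhat(chains))
        e = float(az.ess(chains))
    return r, e


def diagnostics(draws: PosteriorDraws, include_sigma_diag: bool = True) -> pd.DataFrame:
    """Per-parameter convergence summary for mu (and Sigma's diagonal).

    Returns a frame with columns parameter, mean, sd, rhat, ess, flagged,
    degenerate.  ``flagged`` marks R-hat above 1.1; ``degenerate`` marks
    constant chains for which R-hat is undefined.  With a single chain the
    split statistic is computed within-chain and a warning is issued.
    """
    if draws.n_chains < 2:
        warnings.warn("R-hat with a single chain uses within-chain splits only")
    rows = []

    def add(name: str, chains: np.ndarray) -> None:
        degenerate = np.ptp(chains) == 0.0
        r, e = rhat_ess(chains)
        rows.append(
            {
                "parameter": name,
                "mean": float(chains.mean()),
                "sd": float(chains.std(ddof=1)) if chains.size > 1 else 0.0,
                "rhat": r,
                "ess": e,
                "flagged": bool(r > RHAT_FLAG_THRESHOLD) if np.isfinite(r) else False,
                "degenerate": bool(degenerate),
            }
        )

    for j, name in enumerate(draws.coef_names):
        add(f"mu[{name}]", draws.mu[:, :, j])
    if include_sigma_diag:
        for j, name in enumerate(draws.coef_names):
            add(f"Sigma[{name},{name}]", draws.sigma[:, :, j, j])
    return pd.DataFrame(rows)
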