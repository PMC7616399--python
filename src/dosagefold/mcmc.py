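"""Adaptive random-walk Metropolis sampler with arviz diagnostics.

A small Metropolis-within-Gibbs engine for low-dimensional posteriors
(a handful of parameters per strain): one Gaussian proposal per coordinate
per sweep, with per-coordinate proposal scales adapted toward a 44%
acceptance rate during warmup only, so the post-warmup chain is a valid
(non-adaptive) Markov chain.  Models sample on unconstrained transforms of
their parameters and include the Jacobian in the log-posterior.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

try:  # arviz emits noisy pkg warnings on some stacks; import once here
    import arviz as az
except Exception:  # pragma: no cover
    az = None

TARGET_ACCEPT = 0.44  # optimal for one-dimensional Gaussian updates
ADAPT_WINDOW = 50


@dataclass
class SamplerSettings:
    chains: int = 2
    iterations: int = 2000
    warmup: int = 1000
    init_jitter: float = 0.1
    init_scale: float = 0.1

    def __post_init__(self) -> None:
        if not 0 < self.warmup < self.iterations:
            raise ValueError("need 0 < warmup < iterations")
        if self.chains < 1:
            raise ValueError("need >= 1 chain")


def run_chains(
    log_post,
    x0: np.ndarray,
    settings: SamplerSettings,
    rng: np.random.Generator,
) -> np.ndarray:
    """Sample ``chains x (iterations - warmup) x dim`` post-warmup draws.

    ``log_post`` maps an unconstrained parameter vector to a log-density
    (``-inf`` allowed).  Chains start at ``x0`` plus Gaussian jitter.
    """
    dim = len(x0)
    n_keep = settings.iterations - settings.warmup
    draws = np.empty((settings.chains, n_keep, dim))
    for c in range(settings.chains):
        x = np.asarray(x0, dtype=float) + rng.normal(0, settings.init_jitter, dim)
        lp = log_post(x)
        tries = 0
        while not np.isfinite(lp):
            x = np.asarray(x0, dtype=float) + rng.normal(0, settings.init_jitter, dim)
            lp = log_post(x)
            tries += 1
            if tries > 100:
                raise RuntimeError("could not find a finite-density start point")
        scales = np.full(dim, settings.init_scale)
        accepted = np.zeros(dim)
        proposed = np.zeros(dim)
        for it in range(settings.iterations):
            for j in range(dim):
                prop = x.copy()
                prop[j] += rng.normal(0.0, scales[j])
                lp_prop = log_post(prop)
                proposed[j] += 1
                if np.log(rng.random()) < lp_prop - lp:
                    x, lp = prop, lp_prop
                    accepted[j] += 1
            in_warmup = it < settings.warmup
            if in_warmup and (it + 1) % ADAPT_WINDOW == 0:
                rate = accepted / np.maximum(proposed, 1)
                scales *= np.exp(rate - TARGET_ACCEPT)
                accepted[:] = 0
                proposed[:] = 0
            if not in_warmup:
                draws[c, it - settings.warmup] = x
    return draws


def diagnostics(draws_by_name: dict) -> dict:
    """Split R-hat and bulk ESS per named parameter.

    ``draws_by_name`` maps parameter name to a chains x draws array.
    """
    out = {}
    for name, arr in draws_by_name.items():
        arr = np.asarray(arr)
        if az is not None:
            out[name] = {
                "rhat": float(az.rhat(az.convert_to_dataset(arr)).x.values),
                "ess": float(az.ess(az.convert_to_dataset(arr)).x.values),
            }
        else:  # pragma: no cover
            out[name] = {"rhat": _split_rhat(arr), "ess": float(arr.size)}
    return out


def _split_rhat(arr: np.ndarray) -> float:  # pragma: no cover - fallback only
    c, n = arr.shape
    half = n // 2
    chains = arr[:, : 2 * half].reshape(2 * c, half)
    w = chains.var(axis=1, ddof=1).mean()
    b = half * chains.mean(axis=1).var(ddof=1)
    return float(np.sqrt(((half - 1) / half * w + b / half) / w))
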