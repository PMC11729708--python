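"""Shared ensemble-MCMC plumbing (emcee wrappers, convergence checks)."""

from __future__ import annotations

import warnings

import arviz as az
import emcee
import numpy as np

__all__ = ["ConvergenceError", "run_ensemble", "split_rhat", "derive_seed"]

RHAT_GATE = 1.05


class ConvergenceError(RuntimeError):
    """Raised when split-R-hat exceeds the convergence gate."""

    def __init__(self, message, rhat=None):
        super().__init__(message)
        self.rhat = rhat


def derive_seed(base: int, *parts) -> int:
    """Derive a reproducible sub-seed below 2**31 from a base seed and labels."""
    import zlib

    h = int(base) & 0x7FFFFFFF
    for p in parts:
        h = (h * 1000003 + zlib.crc32(str(p).encode("utf8"))) % (2**61)
    return h % (2**31)


def run_ensemble(
    log_prob,
    p0: np.ndarray,
    n_steps: int,
    n_burn: int,
    seed: int,
    moves=None,
    thin: int = 1,
) -> np.ndarray:
    """Run a seeded, vectorised emcee ensemble.

    Parameters
    ----------
    log_prob
        Vectorised log-posterior accepting an (n_walkers, ndim) array and
        returning (n_walkers,) log densities (-inf outside the support).
    p0
        Initial walker positions, shape (n_walkers, ndim).
    n_steps, n_burn
        Total steps and discarded warm-up steps.
    seed
        Seed for the sampler's internal RNG.
    thin
        Keep every ``thin``-th post-warm-up step.

    Returns
    -------
    chain : ndarray, shape (n_walkers, n_kept, ndim)
        Post-warm-up, thinned walker chains (walkers play the role of chains
        in the split-R-hat diagnostic).
    """
    n_walkers, ndim = p0.shape
    sampler = emcee.EnsembleSampler(
        n_walkers, ndim, log_prob, vectorize=True, moves=moves
    )
    sampler.random_state = np.random.RandomState(seed).get_state()
    # thin at the sampler level so only kept steps are ever stored
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        sampler.run_mcmc(
            p0, max(n_steps // thin, 1), thin_by=thin,
            skip_initial_state_check=True,
        )
    chain = sampler.get_chain(discard=n_burn // thin)  # (n_kept, n_walkers, ndim)
    return np.moveaxis(chain, 0, 1)


def split_rhat(chain: np.ndarray) -> np.ndarray:
    """Split-R-hat per parameter for a (n_chains, n_draws, ndim) array."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        ds = az.convert_to_dataset(np.asarray(chain))
        r = az.rhat(ds)["x"].values
    return np.atleast_1d(r)


def check_rhat(chain: np.ndarray, context: str, labels=None, gate: float = RHAT_GATE):
    """Raise :class:`ConvergenceError` if any split-R-hat exceeds ``gate``."""
    r = split_rhat(chain)
    bad = np.where(~np.isfinite(r) | (r > gate))[0]
    if bad.size:
        if labels is None:
            labels = [str(i) for i in range(len(r))]
        worst = ", ".join(f"{labels[i]} (rhat={r[i]:.3f})" for i in bad[:8])
        raise ConvergenceError(
            f"{context}: split-R-hat above {gate} for: {worst}", rhat=r
        )
    return r
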