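"""Replication-level arithmetic derived from kinetic estimates.

Turns measured bound times into biology-scale numbers for the *E. coli*
replisome: how often a new β clamp is loaded at a fork, how fast the fork
moves, the implied Okazaki-fragment length, and how much DNA is synthesized
before a Pol III* exchange.  All functions are exact arithmetic; rounding to
reporting precision lives in the ``rounded_*`` helpers and is never fed back
into computation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .errors import InputError

E_COLI_GENOME_BP = 4.6e6
N_FORKS = 2
BETA_DIMERS_PER_FORK = 23


@dataclass(frozen=True)
class ReplicationModel:
    """Chromosome-scale constants entering the derived metrics."""

    genome_size: float = E_COLI_GENOME_BP  # bp
    n_forks: int = N_FORKS
    replication_time: float = 150.0 * 60.0  # s
    beta_dimers_per_fork: int = BETA_DIMERS_PER_FORK
    beta_unload_time: float = 47.0  # s

    def __post_init__(self) -> None:
        for name in ("genome_size", "n_forks", "replication_time",
                     "beta_dimers_per_fork", "beta_unload_time"):
            if not getattr(self, name) > 0:
                raise InputError(f"{name} must be positive")


def clamp_loading_interval(beta_dimers_per_fork: float, beta_unload_time: float) -> float:
    """Seconds between β-dimer loading events at one fork.

    At steady state the per-fork loading rate balances unloading of the
    ``beta_dimers_per_fork`` DNA-bound clamps, each resident for
    ``beta_unload_time``: the loading interval is ``T_unload / n_dimers``.
    """
    if beta_dimers_per_fork <= 0:
        raise InputError("beta_dimers_per_fork must be positive")
    if beta_unload_time <= 0:
        raise InputError("beta_unload_time must be positive")
    return beta_unload_time / beta_dimers_per_fork


def fork_rate(genome_size: float, n_forks: float, replication_time: float) -> float:
    """Average fork progression in bp/s: genome / forks / replication time."""
    if genome_size <= 0 or n_forks <= 0 or replication_time <= 0:
        raise InputError("all inputs must be positive")
    return genome_size / n_forks / replication_time


def okazaki_length(loading_interval: float, fork_rate_bp_s: float) -> float:
    """Okazaki-fragment length (bp): one clamp load per fragment cycle."""
    if loading_interval < 0 or fork_rate_bp_s < 0:
        raise InputError("inputs must be non-negative")
    return loading_interval * fork_rate_bp_s


def synthesis_before_exchange(bound_time: float, fork_rate_bp_s: float) -> float:
    """DNA synthesized (bp) during one polymerase residence at the fork."""
    if bound_time < 0 or fork_rate_bp_s < 0:
        raise InputError("inputs must be non-negative")
    return bound_time * fork_rate_bp_s


# ---------------------------------------------------------------------------
# reporting-precision helpers (display only)
# ---------------------------------------------------------------------------


def round_to_sigfigs(x: float, n: int = 1) -> float:
    if x == 0:
        return 0.0
    return round(x, -int(math.floor(math.log10(abs(x)))) + (n - 1))


def round_to_nearest(x: float, base: float = 10.0) -> float:
    return base * round(x / base)


def replication_report(model: ReplicationModel) -> dict:
    """Exact and reporting-precision chain of derived metrics.

    The ``rounded_chain`` Okazaki length multiplies the one-sig-fig loading
    interval by the nearest-10 fork rate (the conventional back-of-envelope
    chain); ``exact_chain`` propagates full precision.
    """
    interval = clamp_loading_interval(model.beta_dimers_per_fork, model.beta_unload_time)
    rate = fork_rate(model.genome_size, model.n_forks, model.replication_time)
    interval_r = round_to_sigfigs(interval, 1)
    rate_r = round_to_nearest(rate, 10)
    return {
        "clamp_loading_interval_s": interval,
        "clamp_loading_interval_s_rounded": interval_r,
        "fork_rate_bp_s": rate,
        "fork_rate_bp_s_rounded": rate_r,
        "okazaki_length_bp_exact_chain": okazaki_length(interval, rate),
        "okazaki_length_bp_rounded_chain": okazaki_length(interval_r, rate_r),
    }
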