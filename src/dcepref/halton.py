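"""Halton low-discrepancy draws for simulated maximum likelihood.

The mixing integral of the mixed logit is approximated with quasi-random
normal draws: radical-inverse (Halton) sequences in prime bases, one base
per random coefficient, mapped through the standard-normal inverse CDF.
Each respondent receives a contiguous block of the common sequence, the
standard panel-data convention, so the draws are fully deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import ndtri

__all__ = ["HaltonConfig", "halton_sequence", "normal_draws"]

#: Default prime bases, assigned to random coefficients in order.
DEFAULT_PRIMES = (2, 3, 5, 7, 11, 13, 17, 19, 23, 29)


def _is_prime(n: int) -> bool:
    if n < 2:
        return False
    return all(n % d for d in range(2, int(n**0.5) + 1))


@dataclass(frozen=True)
class HaltonConfig:
    """Settings of the quasi-random integration.

    n_draws: draws per respondent (the study used 1000); burn_in: leading
    sequence elements discarded (they are the coarsest and most correlated
    across bases); primes: bases by random-coefficient order.
    """

    n_draws: int = 1000
    burn_in: int = 10
    primes: tuple[int, ...] = DEFAULT_PRIMES

    def __post_init__(self) -> None:
        if self.n_draws < 1:
            raise ValueError("n_draws must be >= 1")
        if self.burn_in < 0:
            raise ValueError("burn_in must be >= 0")
        if len(set(self.primes)) != len(self.primes):
            raise ValueError("primes must be distinct")


def halton_sequence(prime: int, count: int, burn_in: int = 0) -> np.ndarray:
    """Radical-inverse sequence elements burn_in+1 ... burn_in+count in (0, 1).

    The radical inverse of integer i in base b mirrors i's base-b digits
    about the radix point: in base 2 the sequence starts 1/2, 1/4, 3/4, 1/8.
    """
    if not _is_prime(prime):
        raise ValueError(f"base {prime} is not prime")
    if count < 1:
        raise ValueError("count must be >= 1")
    idx = np.arange(burn_in + 1, burn_in + count + 1, dtype=np.int64)
    out = np.zeros(count)
    f = 1.0
    while idx.any():
        f /= prime
        out += f * (idx % prime)
        idx //= prime
    return out


def normal_draws(
    config: HaltonConfig, n_respondents: int, n_random: int
) -> np.ndarray:
    """Per-respondent standard-normal Halton draws, shape (N, R, n_random).

    Dimension d uses the d-th configured prime; respondent r gets the r-th
    contiguous block of R = n_draws values of each dimension's common
    sequence.  No pseudo-randomness is involved: identical configs yield
    identical draws.
    """
    if n_random > len(config.primes):
        raise ValueError(
            f"{n_random} random coefficients but only {len(config.primes)} primes configured"
        )
    total = n_respondents * config.n_draws
    z = np.empty((n_respondents, config.n_draws, n_random))
    for d in range(n_random):
        u = halton_sequence(config.primes[d], total, config.burn_in)
        z[:, :, d] = ndtri(u).reshape(n_respondents, config.n_draws)
    return z
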