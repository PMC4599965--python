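"""Synthetic data for the 2PL parameter-recovery study.

Provides a documented 20-item fixture bank, a generator for arbitrary
banks, ability sampling from a standard normal or a standardized
skew-normal distribution, binary response generation under the 2PL, and
the seed-sharing map that ties every estimation-side condition within a
study cell to the identical response matrix.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .estimation import response_probability

__all__ = [
    "ItemBank",
    "AbilitySpec",
    "AbilitySample",
    "ResponseMatrix",
    "default_item_bank",
    "make_item_bank",
    "sample_abilities",
    "skew_normal_population_moments",
    "skew_normal_population_skewness",
    "generate_responses",
    "condition_seed",
    "TLD_LEVELS",
]

TLD_LEVELS = ("normal", "skew_normal")


@dataclass(frozen=True)
class ItemBank:
    """True or estimated (a, b) pairs for a test of k items."""

    a: np.ndarray
    b: np.ndarray
    item_id: np.ndarray | None = None

    def __post_init__(self) -> None:
        a = np.asarray(self.a, dtype=float)
        b = np.asarray(self.b, dtype=float)
        if a.ndim != 1 or a.shape != b.shape:
            raise ValueError("a and b must be 1-d arrays of equal length")
        if a.size < 2:
            raise ValueError("an item bank needs at least 2 items")
        if not (np.all(np.isfinite(a)) and np.all(np.isfinite(b))):
            raise ValueError("item parameters must be finite")
        if np.any(a <= 0):
            raise ValueError("discriminations must be positive")
        object.__setattr__(self, "a", a)
        object.__setattr__(self, "b", b)
        ids = self.item_id
        if ids is None:
            ids = np.arange(1, a.size + 1)
        object.__setattr__(self, "item_id", np.asarray(ids))

    @property
    def k(self) -> int:
        return int(self.a.size)


# Fixture bank for a 20-item achievement-type test.  Synthetic: constructed
# to span easy-to-very-difficult items (b in [-2.5, 2.5]) and low-to-very-high
# discriminations (a in [0.5, 3.0]), including one very highly discriminating
# item (a = 3.00) and one very difficult item (b = 2.43) so that analyses of
# extreme-item sensitivity have their anchor items.
_FIXTURE_A = np.array(
    [0.50, 0.80, 1.60, 0.70, 1.20, 2.20, 0.90, 1.40, 3.00, 1.00,
     1.80, 0.60, 1.10, 2.60, 0.85, 1.30, 2.00, 0.75, 1.50, 0.95]
)
_FIXTURE_B = np.array(
    [-2.50, -2.10, -1.70, -1.30, -1.00, -0.75, -0.50, -0.25, 0.00, 0.20,
      0.45,  0.70,  0.95,  1.20,  1.45,  1.70,  2.00,  2.20,  2.43,  2.50]
)


def default_item_bank() -> ItemBank:
    """The packaged 20-item fixture bank (synthetic; see module docstring)."""
    return ItemBank(a=_FIXTURE_A.copy(), b=_FIXTURE_B.copy())


def make_item_bank(k: int = 20, seed: int | None = None) -> ItemBank:
    """A reproducible 2PL item bank.

    With default arguments (``k=20``, ``seed=None``) this returns the
    packaged fixture bank.  With a seed, discriminations are drawn
    log-uniformly on [0.5, 3.0] and difficulties uniformly on [-2.5, 2.5]
    (sorted), spanning the same easy/hard and low/high-discrimination range.
    """
    if k < 2:
        raise ValueError("an item bank needs at least 2 items")
    if seed is None:
        if k != 20:
            raise ValueError("the fixture bank has k = 20; pass a seed for other sizes")
        return default_item_bank()
    rng = np.random.default_rng(seed)
    a = np.exp(rng.uniform(np.log(0.5), np.log(3.0), size=k))
    b = np.sort(rng.uniform(-2.5, 2.5, size=k))
    return ItemBank(a=a, b=b)


@dataclass(frozen=True)
class AbilitySpec:
    """Distribution of true latent abilities.

    ``family='normal'`` is the standard normal; ``family='skew_normal'`` is
    an Azzalini skew-normal with the given shape parameter, standardized by
    its population moments so the target distribution is exactly mean 0,
    SD 1.
    """

    family: str = "normal"
    shape: float = 10.0
    standardized: bool = True

    def __post_init__(self) -> None:
        if self.family not in TLD_LEVELS:
            raise ValueError(f"family must be one of {TLD_LEVELS}")


@dataclass(frozen=True)
class AbilitySample:
    z: np.ndarray
    spec: AbilitySpec
    seed: int | None = None

    def __post_init__(self) -> None:
        z = np.asarray(self.z, dtype=float)
        if z.ndim != 1 or z.size < 1:
            raise ValueError("ability sample must be a nonempty vector")
        if not np.all(np.isfinite(z)):
            raise ValueError("abilities must be finite")
        object.__setattr__(self, "z", z)

    @property
    def n(self) -> int:
        return int(self.z.size)


def skew_normal_population_moments(shape: float) -> tuple[float, float]:
    """Population mean and SD of the skew-normal(location 0, scale 1, shape)."""
    delta = shape / np.sqrt(1.0 + shape**2)
    mu = delta * np.sqrt(2.0 / np.pi)
    sd = np.sqrt(1.0 - 2.0 * delta**2 / np.pi)
    return float(mu), float(sd)


def skew_normal_population_skewness(shape: float) -> float:
    """Closed-form skewness of the skew-normal; ~0.9556 at shape 10."""
    mu, sd = skew_normal_population_moments(shape)
    return float((4.0 - np.pi) / 2.0 * mu**3 / sd**3)


def sample_abilities(n: int, spec: AbilitySpec, seed) -> AbilitySample:
    """Draw n latent abilities.

    ``seed`` may be an integer or a ``numpy.random.Generator``.  Skew-normal
    draws are standardized by the POPULATION mean and SD of the skew-normal
    (not per-sample moments), so the generating distribution itself has mean
    0 and SD 1.
    """
    if n < 1:
        raise ValueError("need at least one testee")
    rng = np.random.default_rng(seed)
    if spec.family == "normal":
        z = rng.standard_normal(n)
    else:
        z = stats.skewnorm.rvs(spec.shape, size=n, random_state=rng)
        if spec.standardized:
            mu, sd = skew_normal_population_moments(spec.shape)
            z = (z - mu) / sd
    seed_val = seed if isinstance(seed, (int, np.integer)) else None
    return AbilitySample(z=z, spec=spec, seed=seed_val)


@dataclass(frozen=True)
class ResponseMatrix:
    """n x k binary scored responses."""

    x: np.ndarray

    def __post_init__(self) -> None:
        x = np.asarray(self.x)
        if x.ndim != 2:
            raise ValueError("responses must be a 2-d array")
        if not np.isin(x, (0, 1)).all():
            raise ValueError("responses must be binary")
        object.__setattr__(self, "x", x.astype(np.int8))

    @property
    def n(self) -> int:
        return int(self.x.shape[0])

    @property
    def k(self) -> int:
        return int(self.x.shape[1])


def generate_responses(bank: ItemBank, abilities: AbilitySample, seed) -> ResponseMatrix:
    """Simulate binary responses under the 2PL.

    For every testee-item pair the correct-response probability pi is
    computed and compared to an independent Uniform(0, 1) draw; the item is
    scored correct iff pi exceeds the draw.
    """
    rng = np.random.default_rng(seed)
    p = response_probability(bank.a[None, :], bank.b[None, :], abilities.z[:, None])
    u = rng.random((abilities.n, bank.k))
    return ResponseMatrix(x=(p > u).astype(np.int8))


def condition_seed(tld: str, n: int, rep: int, master_seed: int = 0) -> int:
    """Injective deterministic seed for a (true-distribution, n, rep) cell.

    Every estimation-side condition (initial values, convergence criterion,
    method) within one cell reuses this seed and therefore sees the
    identical response matrix; cells differing in true latent distribution,
    sample size, or replication get distinct seeds.
    """
    if rep < 1:
        raise ValueError("replication index starts at 1")
    if not (0 < n < 2**21 and rep < 2**21):
        raise ValueError("n and rep must fit in 21 bits")
    tld_idx = TLD_LEVELS.index(tld)  # raises for unknown level
    return (((master_seed << 1) | tld_idx) << 21 | n) << 21 | rep
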