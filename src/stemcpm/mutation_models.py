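"""Mutation processes of the tumor model.

Two kinds of heritable change are simulated at every cell division:

* a neutral molecular clock — copying errors on a 64-CpG methylation
  pattern, applied independently to mother and daughter at rate ``mu``
  per site per division, in every cell regardless of stemness;
* a non-neutral random walk on a one-dimensional phenotype axis
  ``x in [-24, +25]`` (50 states, solid boundaries), applied with
  probability ``mu_f`` per division, where each phenotype maps to a
  division rate through a named fitness landscape ``f(x)``.

Methylation patterns are stored as 64-bit unsigned integers (bit ``k``
set = CpG site ``k`` methylated); helpers convert to/from explicit bit
vectors. The founder pattern is 0 (fully unmethylated).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "N_CPG_SITES",
    "PHENOTYPE_MIN",
    "PHENOTYPE_MAX",
    "MethylationPattern",
    "FitnessLandscape",
    "get_landscape",
    "landscape_from_table",
    "mutate_methylation",
    "mutate_methylation_array",
    "mutate_phenotype",
    "mutate_phenotype_array",
    "pattern_to_bits",
    "bits_to_pattern",
    "pattern_label",
]

N_CPG_SITES = 64
PHENOTYPE_MIN = -24
PHENOTYPE_MAX = 25

_U64_ONE = np.uint64(1)


@dataclass(frozen=True)
class MethylationPattern:
    """A 64-site CpG methylation state, one bit per site.

    Thin value wrapper around the packed ``uint64`` representation used
    throughout the simulator. Mostly useful at API boundaries and in
    tests; the hot paths work on raw integers/arrays.
    """

    bits: int = 0

    def __post_init__(self) -> None:
        if not 0 <= int(self.bits) < (1 << N_CPG_SITES):
            raise ValueError("methylation pattern must fit in 64 bits")

    @property
    def n_methylated(self) -> int:
        return int(self.bits).bit_count()

    def to_bit_vector(self) -> np.ndarray:
        return pattern_to_bits(self.bits)

    @classmethod
    def from_bit_vector(cls, sites: np.ndarray) -> "MethylationPattern":
        return cls(bits_to_pattern(sites))

    def label(self) -> str:
        return pattern_label(self.bits)


def pattern_to_bits(pattern: int | np.uint64) -> np.ndarray:
    """Unpack a 64-bit pattern into an int8 vector of length 64."""
    p = int(pattern)
    return np.array([(p >> k) & 1 for k in range(N_CPG_SITES)], dtype=np.int8)


def bits_to_pattern(sites: np.ndarray) -> int:
    """Pack an ordered 64-site 0/1 vector into an integer pattern."""
    sites = np.asarray(sites)
    if sites.shape != (N_CPG_SITES,):
        raise ValueError(f"expected {N_CPG_SITES} sites, got {sites.shape}")
    out = 0
    for k in range(N_CPG_SITES):
        if sites[k]:
            out |= 1 << k
    return out


def pattern_label(pattern: int | np.uint64) -> str:
    """Canonical clone label: 16-digit hexadecimal rendering."""
    return f"{int(pattern):016x}"


def mutate_methylation(pattern, mu: float, rng: np.random.Generator):
    """Copy a methylation pattern with independent per-site errors.

    Each of the 64 sites flips (0<->1, covering both methylation and
    demethylation) independently with probability ``mu``. Called once
    for the mother and once for the daughter at every division, for
    every cell type.
    """
    if not 0.0 <= mu <= 1.0:
        raise ValueError(f"mu must lie in [0, 1], got {mu}")
    wrap = isinstance(pattern, MethylationPattern)
    p = np.uint64(pattern.bits if wrap else pattern)
    n_flips = rng.binomial(N_CPG_SITES, mu)
    if n_flips:
        sites = rng.choice(N_CPG_SITES, size=n_flips, replace=False)
        for k in sites:
            p ^= _U64_ONE << np.uint64(k)
    return MethylationPattern(int(p)) if wrap else p


def mutate_methylation_array(
    patterns: np.ndarray, mu: float, rng: np.random.Generator
) -> np.ndarray:
    """Vectorized :func:`mutate_methylation` over a uint64 array."""
    if not 0.0 <= mu <= 1.0:
        raise ValueError(f"mu must lie in [0, 1], got {mu}")
    out = patterns.astype(np.uint64, copy=True)
    n_flips = rng.binomial(N_CPG_SITES, mu, size=out.shape)
    for idx in np.flatnonzero(n_flips):
        sites = rng.choice(N_CPG_SITES, size=n_flips.flat[idx], replace=False)
        for k in sites:
            out.flat[idx] ^= _U64_ONE << np.uint64(k)
    return out


def mutate_phenotype(
    x: int,
    mu_f: float,
    rng: np.random.Generator,
    lo: int = PHENOTYPE_MIN,
    hi: int = PHENOTYPE_MAX,
) -> int:
    """One division's worth of the non-neutral phenotype walk.

    With probability ``1 - mu_f`` the phenotype is copied unchanged;
    with probability ``mu_f`` it takes a unit step, +1 or -1 with equal
    probability. A step that would leave ``[lo, hi]`` is cancelled
    (solid boundary: the phenotype stays put).
    """
    if not 0.0 <= mu_f <= 1.0:
        raise ValueError(f"mu_f must lie in [0, 1], got {mu_f}")
    x = int(x)
    if not lo <= x <= hi:
        raise ValueError(f"phenotype {x} outside domain [{lo}, {hi}]")
    if rng.random() >= mu_f:
        return x
    step = 1 if rng.random() < 0.5 else -1
    y = x + step
    if y < lo or y > hi:
        return x
    return y


def mutate_phenotype_array(
    xs: np.ndarray,
    mu_f: float,
    rng: np.random.Generator,
    lo: int = PHENOTYPE_MIN,
    hi: int = PHENOTYPE_MAX,
) -> np.ndarray:
    """Vectorized phenotype walk (same semantics as the scalar form)."""
    if not 0.0 <= mu_f <= 1.0:
        raise ValueError(f"mu_f must lie in [0, 1], got {mu_f}")
    xs = np.asarray(xs, dtype=np.int64)
    if xs.size and (xs.min() < lo or xs.max() > hi):
        raise ValueError("phenotype outside domain")
    mutate = rng.random(xs.shape) < mu_f
    steps = np.where(rng.random(xs.shape) < 0.5, 1, -1)
    out = xs + np.where(mutate, steps, 0)
    # solid boundaries: cancelled, not clipped into range from outside
    out = np.where((out < lo) | (out > hi), xs, out)
    return out


# --- fitness landscapes -------------------------------------------------

_DOMAIN = np.arange(PHENOTYPE_MIN, PHENOTYPE_MAX + 1)


def _f_linear(x: np.ndarray) -> np.ndarray:
    # f_L(x) = x + 8, defined as 1 for negative x (not merely clamped:
    # f_L would still exceed 1 on -7..-1, the definition overrides it)
    return np.where(x < 0, 1.0, x + 8.0)


def _f_sin(x: np.ndarray) -> np.ndarray:
    return 3.0 - x * np.sin(x / 2.0)


def _f_sin_prime(x: np.ndarray) -> np.ndarray:
    return x * np.sin(x) + 2.0


def _f_cos(x: np.ndarray) -> np.ndarray:
    return x * np.cos(x / 2.0) + 2.0


_LANDSCAPE_FUNCS = {
    "neutral": lambda x: np.ones_like(x, dtype=float),
    "linear": _f_linear,
    "sinusoidal_S": _f_sin,
    "sinusoidal_Sprime": _f_sin_prime,
    "asymmetric_C": _f_cos,
}


@dataclass(frozen=True)
class FitnessLandscape:
    """A named map phenotype -> division rate, tabulated on the domain.

    ``table[i]`` holds ``f(domain_min + i)`` clamped below at ``floor``
    (negative or sub-floor raw values become ``floor``); the linear
    landscape additionally returns the floor for every negative ``x``
    by its printed definition. The reference fitness used to anchor the
    cell-cycle duration is ``f(0)``.
    """

    name: str
    table: np.ndarray
    floor: float = 1.0
    domain_min: int = PHENOTYPE_MIN
    domain_max: int = PHENOTYPE_MAX

    def __post_init__(self) -> None:
        n = self.domain_max - self.domain_min + 1
        if self.table.shape != (n,):
            raise ValueError("landscape table does not cover the domain")
        if np.any(self.table < self.floor):
            raise ValueError("landscape table below floor")

    def __call__(self, x) -> float | np.ndarray:
        return self.fitness(x)

    def fitness(self, x):
        xs = np.asarray(x)
        if np.any(xs < self.domain_min) or np.any(xs > self.domain_max):
            raise ValueError(f"phenotype {x} outside [{self.domain_min}, {self.domain_max}]")
        vals = self.table[xs - self.domain_min]
        return float(vals) if np.isscalar(x) or xs.ndim == 0 else vals

    @property
    def reference_fitness(self) -> float:
        """Fitness of the founder phenotype x0 = 0."""
        return float(self.table[-self.domain_min])


def get_landscape(name: str, floor: float = 1.0) -> FitnessLandscape:
    """Build one of the named landscapes, precomputed on the 50-state domain."""
    try:
        func = _LANDSCAPE_FUNCS[name]
    except KeyError:
        known = ", ".join(sorted(_LANDSCAPE_FUNCS))
        raise ValueError(f"unknown landscape {name!r}; known: {known}") from None
    raw = np.asarray(func(_DOMAIN.astype(float)), dtype=float)
    table = np.maximum(raw, floor)
    return FitnessLandscape(name=name, table=table, floor=floor)


def landscape_from_table(path, name: str = "custom", floor: float = 1.0) -> FitnessLandscape:
    """Load a custom landscape from a two-column (x, f) text table."""
    data = np.loadtxt(path)
    if data.ndim != 2 or data.shape[1] != 2:
        raise ValueError("expected a two-column (x, f) table")
    xs = data[:, 0].astype(int)
    order = np.argsort(xs)
    xs, fs = xs[order], data[order, 1]
    expect = np.arange(PHENOTYPE_MIN, PHENOTYPE_MAX + 1)
    if not np.array_equal(xs, expect):
        raise ValueError("table must define every integer phenotype in the domain")
    return FitnessLandscape(name=name, table=np.maximum(fs, floor), floor=floor)
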