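"""Fecundity trade-off fitness model for CI-induced egg mortality.

A foundress lays N eggs, N_c fertilised by conspecific males and N_h by
heterospecific males (proportions pi_c, pi_h).  Offspring survival to
adulthood is omega_c for conspecific and omega_h for heterospecific
matings.  Oviposition sites inside the syconium form concentric layers of
decreasing quality (survival coefficient per layer, reflecting rising
parasitism risk towards the fig wall), each with a finite egg capacity.

* Without CI ("random" oviposition) conspecific and heterospecific eggs
  are interleaved in their population proportions, so every layer holds
  the same conspecific fraction and low-quality eggs occupy premium
  central sites:

      W_r = sum_l (pi_c omega_c + pi_h omega_h) * eggs_l * coeff_l.

* With CI, incompatible (heterospecific) eggs die before oviposition and
  never consume sites, so the N_c conspecific eggs fill the best layers
  first:

      W_p = omega_c * sum_l eggs_l * coeff_l     (over conspecific fill).

With two layers A (central) and B (boundary), capacities n_A, n_B and
coefficients omega_A > omega_B, these reduce to the closed forms

    W_r = omega_c (N_c/N) n_A omega_A + omega_c (N_c - (N_c/N) n_A) omega_B
        + omega_h (N_h/N) n_A omega_A + omega_h (N_h - (N_h/N) n_A) omega_B
    W_p = omega_c N_c omega_A                       if N_c <= n_A
        = omega_c n_A omega_A
          + omega_c (N_c - n_A) omega_B             otherwise,

and whenever omega_h = 0, omega_A > omega_B and n_A < N, preferential
oviposition strictly wins (W_p > W_r): CI converts fecundity loss into an
oviposition-site advantage.

Egg counts are continuous (expected values); integer inputs reproduce
toy layouts exactly because the layer fill is the same arithmetic.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

#: Five-layer survival coefficients from centre outward (clinal
#: parasitism risk, from empirical fig-parasitism gradients).
DEFAULT_LAYER_COEFFS: tuple[float, ...] = (1.0, 0.75, 0.5, 0.25, 0.0)

#: Default brood size for grid computations.
DEFAULT_N_EGGS: float = 100.0


@dataclass(frozen=True)
class OvipositionLayer:
    capacity: float
    survival: float


@dataclass(frozen=True)
class FecundityScenario:
    """One foundress scenario: brood composition, survivals and layers."""

    n_eggs: float
    n_conspecific: float
    omega_c: float
    omega_h: float
    layers: tuple[OvipositionLayer, ...]

    def __post_init__(self) -> None:
        if not 0 <= self.n_conspecific <= self.n_eggs:
            raise ValueError("need 0 <= N_c <= N")
        for w in (self.omega_c, self.omega_h):
            if not 0 <= w <= 1:
                raise ValueError("survival probabilities must lie in [0, 1]")
        if any(l.capacity <= 0 for l in self.layers):
            raise ValueError("layer capacities must be positive")
        coeffs = [l.survival for l in self.layers]
        if any(a < b for a, b in zip(coeffs, coeffs[1:])):
            raise ValueError("layer coefficients must be non-increasing outward")
        if sum(l.capacity for l in self.layers) < self.n_eggs:
            raise ValueError("layer capacities cannot hold the whole brood")

    @property
    def n_heterospecific(self) -> float:
        return self.n_eggs - self.n_conspecific

    @property
    def pi_c(self) -> float:
        return self.n_conspecific / self.n_eggs if self.n_eggs else 0.0

    @property
    def pi_h(self) -> float:
        return 1.0 - self.pi_c


def two_patch(
    n_eggs: float,
    n_conspecific: float,
    omega_c: float,
    omega_h: float,
    n_a: float,
    n_b: float,
    omega_a: float,
    omega_b: float,
) -> FecundityScenario:
    """Convenience constructor for the two-patch (central A / boundary B) case."""
    return FecundityScenario(
        n_eggs=n_eggs,
        n_conspecific=n_conspecific,
        omega_c=omega_c,
        omega_h=omega_h,
        layers=(
            OvipositionLayer(n_a, omega_a),
            OvipositionLayer(n_b, omega_b),
        ),
    )


def default_layers(
    n_eggs: float = DEFAULT_N_EGGS,
    coeffs: Sequence[float] = DEFAULT_LAYER_COEFFS,
) -> tuple[OvipositionLayer, ...]:
    """Equal-capacity layers (N / n_layers each) with the given coefficients."""
    cap = n_eggs / len(coeffs)
    return tuple(OvipositionLayer(cap, c) for c in coeffs)


def _fill(n_eggs: float, layers: Sequence[OvipositionLayer]) -> list[float]:
    """Centre-outward greedy fill: eggs placed per layer."""
    placed = []
    remaining = n_eggs
    for layer in layers:
        take = min(remaining, layer.capacity)
        placed.append(take)
        remaining -= take
    if remaining > 1e-9:
        raise ValueError("layer capacities cannot hold the whole brood")
    return placed


def fitness_random(scenario: FecundityScenario) -> float:
    """Inclusive fitness W_r without CI (random oviposition order).

    All N eggs fill the layers centre-outward with conspecific and
    heterospecific eggs mixed in proportions pi_c / pi_h in every layer.
    """
    s = scenario
    per_egg = s.pi_c * s.omega_c + s.pi_h * s.omega_h
    placed = _fill(s.n_eggs, s.layers)
    return sum(per_egg * eggs * layer.survival for eggs, layer in zip(placed, s.layers))


def fitness_preferential(scenario: FecundityScenario) -> float:
    """Inclusive fitness W_p under CI (preferential oviposition).

    Heterospecific eggs are lost before oviposition and consume no sites;
    the N_c conspecific eggs fill the highest-coefficient layers first.
    """
    s = scenario
    placed = _fill(s.n_conspecific, s.layers)
    return sum(
        s.omega_c * eggs * layer.survival for eggs, layer in zip(placed, s.layers)
    )


def omega_axis(grid_size: int) -> np.ndarray:
    """Cell-centred survival grid over (0, 1)."""
    if grid_size < 1:
        raise ValueError("grid_size must be >= 1")
    return (np.arange(grid_size) + 0.5) / grid_size


def ci_advantage_grid(
    pi_c: float,
    grid_size: int = 100,
    layers: Sequence[OvipositionLayer] | None = None,
    n_eggs: float = DEFAULT_N_EGGS,
) -> pd.DataFrame:
    """Delta-fitness matrix W_p(CI) - W_r(no CI) over (omega_c, omega_h).

    Rows are indexed by omega_c, columns by omega_h, both on the
    cell-centred grid.  Both fitness functions are linear in the survival
    probabilities, so the layer sums are computed once and broadcast.
    """
    if not 0 < pi_c < 1:
        raise ValueError("pi_c must lie strictly between 0 and 1")
    if layers is None:
        layers = default_layers(n_eggs)
    coeffs = np.array([l.survival for l in layers])
    s_random = float(np.dot(_fill(n_eggs, layers), coeffs))
    s_pref = float(np.dot(_fill(pi_c * n_eggs, layers), coeffs))
    axis = omega_axis(grid_size)
    wc = axis[:, None]
    wh = axis[None, :]
    delta = wc * s_pref - (pi_c * wc + (1 - pi_c) * wh) * s_random
    return pd.DataFrame(delta, index=axis, columns=axis)


def fraction_ci_favored(grid: pd.DataFrame) -> float:
    """Percentage of grid cells where CI strictly beats no-CI.

    Ties count as not favored; deltas within a small relative tolerance of
    zero are treated as ties so exact analytic ties (e.g. the omega_c =
    omega_h diagonal once the conspecific brood saturates the non-zero
    layers) are not split by floating-point round-off.
    """
    values = np.asarray(grid)
    if values.size == 0:
        raise ValueError("empty fitness grid")
    tol = 1e-9 * max(1.0, float(np.abs(values).max()))
    return 100.0 * float((values > tol).mean())


def ci_favored_table(
    pi_values: Sequence[float] | None = None,
    grid_size: int = 100,
    layers: Sequence[OvipositionLayer] | None = None,
    n_eggs: float = DEFAULT_N_EGGS,
) -> pd.DataFrame:
    """Percent of fitness space favouring CI per conspecific-mating level.

    Default sweep pi_c = 0.05, 0.10, ..., 0.95.
    """
    if pi_values is None:
        pi_values = [round(0.05 * k, 2) for k in range(1, 20)]
    rows = []
    for pi_c in pi_values:
        grid = ci_advantage_grid(pi_c, grid_size=grid_size, layers=layers, n_eggs=n_eggs)
        rows.append(
            {"pi_c": pi_c, "pct_ci_favored": fraction_ci_favored(grid)}
        )
    return pd.DataFrame(rows)


def grid_long_format(
    pi_c: float,
    grid_size: int = 100,
    layers: Sequence[OvipositionLayer] | None = None,
    n_eggs: float = DEFAULT_N_EGGS,
) -> pd.DataFrame:
    """Long-format table (pi_c, omega_c, omega_h, w_ci, w_noci, delta)."""
    if layers is None:
        layers = default_layers(n_eggs)
    coeffs = np.array([l.survival for l in layers])
    s_random = float(np.dot(_fill(n_eggs, layers), coeffs))
    s_pref = float(np.dot(_fill(pi_c * n_eggs, layers), coeffs))
    axis = omega_axis(grid_size)
    wc, wh = np.meshgrid(axis, axis, indexing="ij")
    w_ci = wc * s_pref
    w_noci = (pi_c * wc + (1 - pi_c) * wh) * s_random
    return pd.DataFrame(
        {
            "pi_c": pi_c,
            "omega_c": wc.ravel(),
            "omega_h": wh.ravel(),
            "w_ci": w_ci.ravel(),
            "w_noci": w_noci.ravel(),
            "delta": (w_ci - w_noci).ravel(),
        }
    )
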