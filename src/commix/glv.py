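"""Generalized Lotka-Volterra serial-dilution simulator.

The synthetic-data generator at the heart of the package.  Community dynamics
within each 24 h batch-growth cycle follow the GLV ODE

    dN_i/dt = N_i * (r_i + sum_j a_ij N_j),

with strictly negative self-limitation a_ii < 0 (single-isolate carrying
capacity K_i = -r_i / a_ii).  Serial passaging dilutes the end-of-cycle state
by a fixed factor into fresh medium; densities falling below an extinction
floor (less than one cell in the transferred volume) are set to zero and stay
zero — the floor is absorbing.

Ground-truth interaction matrices are drawn from a genus-structured prior:
off-diagonal coefficients are negative with a configurable probability, and
pairs of isolates from the same genus receive an additional negative shift
(congeneric isolates compete for more similar resources).
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import solve_ivp

from .catalog import IsolateCatalog
from .design import CommunityDesign, PassageProtocol, initial_state

__all__ = [
    "GLVParameters",
    "GLVPriorConfig",
    "TrueStateTrajectory",
    "sample_glv_parameters",
    "run_cycle",
    "serial_passage",
    "child_seed",
]

# Below one cell per transferred volume (6 uL at 1:100 from 600 uL), a
# lineage cannot survive dilution; treating it as extinct prevents
# pseudo-persistence of vanishingly small densities.
DEFAULT_EXTINCTION_FLOOR = 1e-3  # cells/uL
DEFAULT_CULTURE_VOLUME = 600.0  # uL


@dataclass
class GLVParameters:
    """Ground-truth growth rates and pairwise interaction coefficients.

    ``r[i]`` is the intrinsic growth rate of isolate i (1/h); ``A[i, j]`` is
    the per-cell effect of isolate j on the growth of isolate i
    (1/(cells/uL * h)).  The diagonal must be strictly negative.
    """

    isolate_ids: list[str]
    r: np.ndarray
    A: np.ndarray

    def __post_init__(self) -> None:
        self.r = np.asarray(self.r, dtype=float)
        self.A = np.asarray(self.A, dtype=float)
        n = len(self.isolate_ids)
        if self.r.shape != (n,) or self.A.shape != (n, n):
            raise ValueError(
                f"parameter shapes {self.r.shape}/{self.A.shape} do not match "
                f"{n} isolates"
            )
        if not np.all(np.isfinite(self.r)) or not np.all(np.isfinite(self.A)):
            raise ValueError("non-finite GLV parameters")
        if np.any(np.diag(self.A) >= 0):
            raise ValueError("self-limitation a_ii must be strictly negative")

    @property
    def carrying_capacity(self) -> np.ndarray:
        """Single-isolate equilibrium K_i = -r_i / a_ii."""
        return -self.r / np.diag(self.A)


@dataclass
class GLVPriorConfig:
    """Prior for sampling ground-truth GLV parameter sets.

    Units: growth rates 1/h, carrying capacities CFU/uL.  Off-diagonal
    magnitudes are expressed relative to the focal row's self-limitation
    |a_ii| so that ``interaction_scale`` ~ 1 means interspecific effects as
    strong as intraspecific ones.
    """

    r_mean: float = 0.5
    r_sd: float = 0.1
    capacity_mean: float = 1e5  # lognormal median of K_i
    capacity_sd_log: float = 0.3
    interaction_scale: float = 0.5  # |a_ij| ~ HalfNormal(scale * |a_ii|)
    negative_fraction: float = 0.67
    same_genus_shift: float = 0.5  # extra negative shift, units of scale*|a_ii|
    sparsity: float = 0.0  # fraction of off-diagonals set to exactly 0
    # Positive a_ij are capped at this fraction of sqrt(a_ii * a_jj) so no
    # mutualistic pair satisfies a_ij * a_ji >= a_ii * a_jj (which would make
    # the two-species equilibrium diverge).
    positive_cap: float = 0.5

    def __post_init__(self) -> None:
        if self.capacity_mean <= 0 or self.r_mean <= 0:
            raise ValueError("growth rate and capacity means must be positive")
        if not (0 <= self.negative_fraction <= 1):
            raise ValueError("negative_fraction must be in [0, 1]")


@dataclass
class TrueStateTrajectory:
    """End-of-cycle density vectors (cells/uL, catalog order) for one run."""

    design: CommunityDesign
    protocol: PassageProtocol
    states: np.ndarray  # (n_cycles, n_isolates)

    @property
    def final_state(self) -> np.ndarray:
        return self.states[-1]


def child_seed(master_seed: int, *key: object) -> int:
    """Derive a stable per-(design, replicate, observation) seed < 2^31.

    Uses a CRC of the stringified key as a spawn key so any single community
    is re-simulable in isolation from the master seed alone.
    """
    tag = zlib.crc32("|".join(str(k) for k in key).encode())
    ss = np.random.SeedSequence(master_seed, spawn_key=(tag,))
    return int(ss.generate_state(1, dtype=np.uint32)[0] % (2**31))


def sample_glv_parameters(
    catalog: IsolateCatalog, config: GLVPriorConfig, seed: int
) -> GLVParameters:
    """Draw a ground-truth parameter set from the genus-structured prior.

    Off-diagonal a_ij magnitudes are half-normal with scale
    ``interaction_scale * |a_ii|``; the sign is negative with probability
    ``negative_fraction``.  Same-genus pairs get an additional negative shift
    of ``same_genus_shift * interaction_scale * |a_ii|``.
    """
    rng = np.random.default_rng(seed)
    n = len(catalog)
    r = np.clip(rng.normal(config.r_mean, config.r_sd, n), 0.05, None)
    K = config.capacity_mean * np.exp(
        rng.normal(0.0, config.capacity_sd_log, n)
    )
    a_ii = -r / K
    A = np.zeros((n, n))
    np.fill_diagonal(A, a_ii)

    scale = config.interaction_scale * np.abs(a_ii)  # per focal row
    genera = np.array(catalog.genera)
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            if config.sparsity > 0 and rng.random() < config.sparsity:
                continue
            mag = np.abs(rng.normal(0.0, scale[i])) if scale[i] > 0 else 0.0
            sign = -1.0 if rng.random() < config.negative_fraction else 1.0
            val = sign * mag
            if genera[i] == genera[j]:
                val -= config.same_genus_shift * scale[i]
            if val > 0:
                val = min(
                    val, config.positive_cap * np.sqrt(a_ii[i] * a_ii[j])
                )
            A[i, j] = val
    return GLVParameters(list(catalog.isolate_ids), r, A)


def run_cycle(
    state: np.ndarray,
    params: GLVParameters,
    hours: float,
    extinction_floor: float = DEFAULT_EXTINCTION_FLOOR,
    rtol: float = 1e-8,
) -> np.ndarray:
    """Integrate one batch-growth cycle of ``hours`` from ``state``.

    Isolates absent (zero) at cycle start stay absent; densities below the
    extinction floor at cycle end are zeroed.
    """
    state = np.asarray(state, dtype=float)
    if np.any(state < 0):
        raise ValueError("negative densities in initial state")
    present = state > 0
    if not present.any():
        return np.zeros_like(state)

    idx = np.flatnonzero(present)
    r = params.r[idx]
    A = params.A[np.ix_(idx, idx)]

    def rhs(_t, y):
        y = np.maximum(y, 0.0)
        return y * (r + A @ y)

    def jac(_t, y):
        y = np.maximum(y, 0.0)
        return np.diag(r + A @ y) + y[:, None] * A

    sol = solve_ivp(
        rhs,
        (0.0, hours),
        state[idx],
        method="LSODA",
        jac=jac,
        rtol=rtol,
        atol=extinction_floor * 1e-3,
    )
    if not sol.success:
        raise RuntimeError(
            f"GLV integration failed: {sol.message}; state={state[idx]!r}"
        )
    if not np.all(np.isfinite(sol.y[:, -1])):
        raise RuntimeError(
            "GLV integration diverged (non-finite densities); "
            f"initial state={state[idx]!r}"
        )
    out = np.zeros_like(state)
    end = np.maximum(sol.y[:, -1], 0.0)
    end[end < extinction_floor] = 0.0
    out[idx] = end
    return out


def serial_passage(
    design: CommunityDesign,
    params: GLVParameters,
    protocol: PassageProtocol,
    catalog: IsolateCatalog,
    culture_volume: float = DEFAULT_CULTURE_VOLUME,
    extinction_floor: float = DEFAULT_EXTINCTION_FLOOR,
) -> TrueStateTrajectory:
    """Run the full serial-passage protocol for one community design.

    Cycle 1 starts from the equal-titer inoculum converted to cells/uL in the
    culture volume; each subsequent cycle starts from ``dilution_factor`` times
    the previous end state.  Dynamics are deterministic — all measurement noise
    lives in the observation models.
    """
    state = initial_state(design, catalog) / culture_volume
    state[state < extinction_floor] = 0.0
    states = np.empty((protocol.n_cycles, len(catalog)))
    for c in range(protocol.n_cycles):
        if c > 0:
            state = state * protocol.dilution_factor
            state[state < extinction_floor] = 0.0
        state = run_cycle(
            state, params, protocol.cycle_hours, extinction_floor=extinction_floor
        )
        states[c] = state
    return TrueStateTrajectory(design=design, protocol=protocol, states=states)
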