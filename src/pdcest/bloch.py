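"""Multi-pool Bloch-McConnell simulation of pulsed off-resonance saturation.

The simulator propagates the coupled Bloch-McConnell equations for a water
pool, an arbitrary number of chemically shifted exchanging solute pools
(three magnetization components each), and optional semisolid
magnetization-transfer pools treated as longitudinal-only with a Lorentzian
absorption lineshape.  Irradiation is pseudo-continuous-wave: a train of
``n_pulses`` rectangular pulses of ``pulse_duration`` seconds separated by
``interpulse_delay`` of free evolution.  Because the RF amplitude is
piecewise constant, each segment is propagated exactly with a matrix
exponential of the augmented (affine) evolution matrix — no step-size
tuning is involved.

The observable is the water longitudinal magnetization at the end of the
train, normalized by its thermal-equilibrium value: the Z-spectrum value
``Ssat/S0`` at the scheduled offset.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
from scipy.linalg import expm

from .schedule import OffsetSchedule

__all__ = ["PoolParams", "SaturationParams", "simulate_zspectrum", "zspectrum_values"]

#: 1H reduced gyromagnetic ratio, Hz per microtesla (= 42.577 MHz/T).
GAMMA_H_HZ_PER_UT = 42.577


@dataclass(frozen=True)
class PoolParams:
    """One magnetization pool.

    Parameters
    ----------
    name:
        Unique label; the reference pool must be named ``"water"``.
    pool_fraction:
        Equilibrium proton fraction relative to water (water = 1).
    chemical_shift:
        Resonance offset from water in ppm (water = 0).
    exchange_rate:
        Pool-to-water exchange rate, 1/s.  The reverse (water-to-pool) rate
        is ``exchange_rate * pool_fraction`` so equilibrium is preserved.
    t1, t2:
        Longitudinal / transverse relaxation times, s.
    semisolid:
        If True the pool is a macromolecular MT compartment: only its
        longitudinal component is tracked and RF saturation enters through a
        Lorentzian absorption rate ``pi * w1^2 * g(dw)`` with
        ``g(dw) = (T2/pi) / (1 + (dw*T2)^2)``.
    """

    name: str
    pool_fraction: float
    chemical_shift: float
    exchange_rate: float
    t1: float
    t2: float
    semisolid: bool = False

    def __post_init__(self) -> None:
        if self.pool_fraction <= 0:
            raise ValueError(f"pool {self.name!r}: pool_fraction must be > 0")
        if self.t1 <= 0 or self.t2 <= 0:
            raise ValueError(f"pool {self.name!r}: relaxation times must be > 0")
        if self.exchange_rate < 0:
            raise ValueError(f"pool {self.name!r}: exchange_rate must be >= 0")

    def scaled(self, fraction_multiplier: float) -> "PoolParams":
        """Copy with the pool fraction scaled (disease-effect hook)."""
        return replace(self, pool_fraction=self.pool_fraction * fraction_multiplier)


@dataclass(frozen=True)
class SaturationParams:
    """Pseudo-CW irradiation scheme and field constants.

    ``b1_amplitude`` is in microtesla; durations in seconds.  ``field_strength``
    (tesla) with the 1H gyromagnetic ratio converts ppm offsets to Hz.
    """

    b1_amplitude: float = 2.0
    pulse_duration: float = 0.2
    n_pulses: int = 4
    interpulse_delay: float = 0.010
    gyromagnetic_ratio: float = GAMMA_H_HZ_PER_UT
    field_strength: float = 3.0

    def __post_init__(self) -> None:
        if self.b1_amplitude < 0:
            raise ValueError("b1_amplitude must be >= 0")
        if self.n_pulses < 1:
            raise ValueError("n_pulses must be >= 1")
        if self.pulse_duration <= 0:
            raise ValueError("pulse_duration must be > 0")
        if self.interpulse_delay < 0:
            raise ValueError("interpulse_delay must be >= 0")

    @property
    def hz_per_ppm(self) -> float:
        return self.gyromagnetic_ratio * self.field_strength

    @property
    def omega1(self) -> float:
        """RF nutation rate, rad/s."""
        return 2.0 * np.pi * self.gyromagnetic_ratio * self.b1_amplitude


def _check_pools(pools: Sequence[PoolParams]) -> tuple[PoolParams, list[PoolParams], list[PoolParams]]:
    names = [p.name for p in pools]
    if len(set(names)) != len(names):
        raise ValueError("two pools share a name")
    waters = [p for p in pools if p.name == "water"]
    if len(waters) != 1:
        raise ValueError("pools must include exactly one pool named 'water'")
    water = waters[0]
    if water.chemical_shift != 0:
        raise ValueError("water pool must have chemical_shift = 0")
    if water.semisolid:
        raise ValueError("water pool cannot be semisolid")
    solutes = [p for p in pools if p is not water and not p.semisolid]
    mts = [p for p in pools if p.semisolid]
    return water, solutes, mts


def _evolution_matrix(
    water: PoolParams,
    solutes: list[PoolParams],
    mts: list[PoolParams],
    sat: SaturationParams,
    offset_ppm: float,
    omega1: float,
) -> np.ndarray:
    """Augmented affine evolution matrix for one constant-RF segment.

    State layout: (Mx, My, Mz) for water then each solute, then Mz for each
    semisolid pool, then the constant 1 carrying the relaxation drive.
    """
    full = [water] + solutes
    n_full = len(full)
    dim = 3 * n_full + len(mts) + 1
    A = np.zeros((dim, dim))

    def z_idx(i: int) -> int:
        return 3 * i + 2

    two_pi = 2.0 * np.pi
    for i, p in enumerate(full):
        dw = two_pi * sat.hz_per_ppm * (p.chemical_shift - offset_ppm)
        r1, r2 = 1.0 / p.t1, 1.0 / p.t2
        ix, iy, iz = 3 * i, 3 * i + 1, 3 * i + 2
        A[ix, ix] += -r2
        A[ix, iy] += dw
        A[iy, ix] += -dw
        A[iy, iy] += -r2
        A[iy, iz] += omega1
        A[iz, iy] += -omega1
        A[iz, iz] += -r1
        A[iz, -1] += r1 * p.pool_fraction

    wz = z_idx(0)
    # exchange: solute <-> water on all three components
    for i, p in enumerate(solutes, start=1):
        k, krev = p.exchange_rate, p.exchange_rate * p.pool_fraction
        for c in range(3):
            si, wi = 3 * i + c, c
            A[si, si] += -k
            A[si, wi] += krev
            A[wi, si] += k
            A[wi, wi] += -krev

    for j, p in enumerate(mts):
        mi = 3 * n_full + j
        r1 = 1.0 / p.t1
        # Lorentzian absorption rate of the semisolid line
        dw = two_pi * sat.hz_per_ppm * (p.chemical_shift - offset_ppm)
        g = (p.t2 / np.pi) / (1.0 + (dw * p.t2) ** 2)
        rrf = np.pi * omega1**2 * g
        k, krev = p.exchange_rate, p.exchange_rate * p.pool_fraction
        A[mi, mi] += -r1 - rrf - k
        A[mi, wz] += krev
        A[wz, mi] += k
        A[wz, wz] += -krev
        A[mi, -1] += r1 * p.pool_fraction
    return A


def _equilibrium(water: PoolParams, solutes: list[PoolParams], mts: list[PoolParams]) -> np.ndarray:
    n_full = 1 + len(solutes)
    m = np.zeros(3 * n_full + len(mts) + 1)
    for i, p in enumerate([water] + solutes):
        m[3 * i + 2] = p.pool_fraction
    for j, p in enumerate(mts):
        m[3 * n_full + j] = p.pool_fraction
    m[-1] = 1.0
    return m


def zspectrum_values(
    pools: Sequence[PoolParams],
    sat: SaturationParams,
    offsets_ppm: Sequence[float],
) -> np.ndarray:
    """``Ssat/S0`` of the water pool at each requested offset (ppm).

    Each offset is propagated independently from thermal equilibrium through
    ``n_pulses`` blocks of (pulse, interpulse delay); the block propagator is
    built from two matrix exponentials and raised to the pulse count.
    """
    water, solutes, mts = _check_pools(pools)
    m0 = _equilibrium(water, solutes, mts)
    s0 = water.pool_fraction  # = 1 by convention
    out = np.empty(len(offsets_ppm))
    for k, off in enumerate(offsets_ppm):
        a_rf = _evolution_matrix(water, solutes, mts, sat, off, sat.omega1)
        e_pulse = expm(a_rf * sat.pulse_duration)
        if sat.interpulse_delay > 0:
            a_free = _evolution_matrix(water, solutes, mts, sat, off, 0.0)
            e_block = expm(a_free * sat.interpulse_delay) @ e_pulse
        else:
            e_block = e_pulse
        m = np.linalg.matrix_power(e_block, sat.n_pulses) @ m0
        out[k] = m[2] / s0
    return out


def simulate_zspectrum(
    pools: Sequence[PoolParams],
    sat: SaturationParams,
    schedule: OffsetSchedule,
):
    """Simulate a Z-spectrum on a saturation schedule.

    Returns a :class:`pdcest.cest.ZSpectrum` with offsets in ascending order.
    """
    from .cest import ZSpectrum

    if schedule.n_offsets == 0:
        raise ValueError("schedule is empty")
    offs = np.array(sorted(schedule.offsets), dtype=float)
    vals = zspectrum_values(pools, sat, offs)
    return ZSpectrum(offsets=offs, values=vals)
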