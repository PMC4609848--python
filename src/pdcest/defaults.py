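"""Default tissue, acquisition and cohort calibration constants.

Nothing in this module is a measured literature value for a specific tissue;
the pool parameters are generic 3 T gray-matter figures chosen so the
healthy phantom produces APT-weighted values in the 0.5-3 percent regime,
with per-region amide fractions calibrated (see
:func:`pdcest.cohort.amide_fraction_for_apt`) so each region's baseline
APT-weighted value matches the magnitude of healthy deep gray matter.
All constants live here, not in code paths, so a study configuration can
override any of them.
"""

from __future__ import annotations

from .bloch import PoolParams, SaturationParams

__all__ = [
    "WATER_POOL",
    "NOE_POOL",
    "MT_POOL",
    "AMIDE_POOL_TEMPLATE",
    "DEFAULT_SATURATION",
    "REGION_APT_BASELINE",
    "REGION_FA_MD_BASELINE",
    "REGION_APT_STAGE",
    "DTI_EFFECTS",
    "make_pools",
]

#: free water, generic 3 T gray matter
WATER_POOL = PoolParams("water", 1.0, 0.0, 0.0, t1=1.3, t2=0.080)

#: aliphatic protons 3.5 ppm upfield, relayed-NOE contaminant of the asymmetry
NOE_POOL = PoolParams("noe", 0.004, -3.5, 20.0, t1=1.0, t2=0.005)

#: broad semisolid macromolecular line centered on water (Lorentzian shape)
MT_POOL = PoolParams("mt", 0.08, 0.0, 25.0, t1=1.0, t2=1.0e-5, semisolid=True)

#: backbone amide protons 3.5 ppm downfield; the pool_fraction here is a
#: template — regions override it with their calibrated baseline fraction
AMIDE_POOL_TEMPLATE = PoolParams("amide", 2.0e-3, 3.5, 30.0, t1=1.0, t2=0.030)

#: 2 uT pseudo-CW train: 4 x 200 ms pulses, 10 ms gaps, 3 T
DEFAULT_SATURATION = SaturationParams(
    b1_amplitude=2.0, pulse_duration=0.2, n_pulses=4, interpulse_delay=0.010,
    field_strength=3.0,
)

#: healthy-control APT-weighted baseline (percent) per region; the phantom's
#: amide fraction in each region is calibrated to reproduce these magnitudes
REGION_APT_BASELINE: dict[str, float] = {
    "substantia_nigra": 1.25,
    "globus_pallidus": 0.68,
    "putamen": 0.83,
    "caudate": 0.84,
    "background": 1.00,
}

#: healthy-control (FA, MD) per region, MD in 1e-3 mm^2/s
REGION_FA_MD_BASELINE: dict[str, tuple[float, float]] = {
    "substantia_nigra": (0.36, 0.68),
    "globus_pallidus": (0.25, 0.70),
    "putamen": (0.14, 0.72),
    "caudate": (0.16, 0.74),
    "background": (0.20, 0.80),
}

#: stage-wise APT-weighted group means (percent) the disease effects aim
#: for: nigral amide signal falls progressively with stage, striatal amide
#: peaks at the early stage and partially renormalizes later.  The amide
#: fraction multiplier per stage is derived from these by inverting the
#: simulator's APT response curve (APTw is offset-linear in the amide
#: fraction — the NOE pool subtracts a near-constant — so fraction ratios
#: are NOT APTw ratios).
REGION_APT_STAGE: dict[str, dict[str, float]] = {
    "substantia_nigra": {"early": 0.96, "advanced": 0.81},
    "globus_pallidus": {"early": 0.89, "advanced": 0.78},
    "putamen": {"early": 1.12, "advanced": 0.99},
    "caudate": {"early": 1.35, "advanced": 0.91},
}

#: diffusion effect multipliers per region and stage: ``aniso`` scales the
#: anisotropic part of the ground-truth tensor, ``md`` its mean; controls
#: are implicitly 1.  Nigral anisotropy falls with stage; striatal
#: diffusion changes are kept small.
DTI_EFFECTS: dict[str, dict[str, dict[str, float]]] = {
    "substantia_nigra": {
        "early": {"aniso": 0.94, "md": 1.015},
        "advanced": {"aniso": 0.86, "md": 1.03},
    },
    "globus_pallidus": {
        "early": {"aniso": 0.92, "md": 1.015},
        "advanced": {"aniso": 0.96, "md": 1.04},
    },
    "putamen": {
        "early": {"aniso": 1.0, "md": 1.0},
        "advanced": {"aniso": 1.0, "md": 1.03},
    },
    "caudate": {
        "early": {"aniso": 1.0, "md": 1.015},
        "advanced": {"aniso": 0.94, "md": 1.0},
    },
}


def make_pools(amide_fraction: float) -> list[PoolParams]:
    """Standard 4-pool system (water, amide, NOE, semisolid MT) with the
    given amide proton fraction."""
    return [
        WATER_POOL,
        AMIDE_POOL_TEMPLATE.scaled(amide_fraction / AMIDE_POOL_TEMPLATE.pool_fraction),
        NOE_POOL,
        MT_POOL,
    ]
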