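"""Two-group / three-stage cohort generation.

A cohort is ``n_control`` healthy subjects plus patients split into an
early and an advanced stage.  Disease enters as multiplicative effects on
the amide pool fraction (protein/peptide content proxy) and on the
diffusion-tensor eigenvalues of each region; between-subject biology is a
lognormal deviate with configurable coefficient of variation, drawn per
subject and region.

Two generation paths share this parameter structure:

* :func:`generate_cohort` — full image-domain simulation (one phantom and
  DWI set per subject), feeding the voxelwise quantification pipeline;
* :func:`generate_cohort_table` — draws ROI metric values directly through
  the Bloch-McConnell APT-weighted response curve (computed once from the
  simulator and spline-interpolated), for statistical calibration studies
  that need hundreds of replicate cohorts.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy.interpolate import CubicSpline

from . import defaults
from .bloch import PoolParams, SaturationParams, zspectrum_values
from .cest import MtrAsymCurve, total_cest
from .dti import fa_md, tensor_from_eigs, _tensor_matrix
from .phantom import (
    PhantomData,
    PhantomSpec,
    REGIONS,
    HEMISPHERES,
    default_dwi_scheme,
    default_phantom_spec,
    generate_dwi,
    generate_phantom,
)
from .schedule import OffsetSchedule

__all__ = [
    "CohortConfig",
    "SubjectRecord",
    "generate_cohort",
    "generate_cohort_table",
    "calibrated_amide_fractions",
    "calibrated_effects",
    "apt_response",
    "null_config",
]

METRICS = ("apt_weighted", "total_cest", "fa", "md")

#: ROI-level measurement noise per metric (absolute SD of one hemisphere
#: sample), emulating residual voxel noise after ROI averaging
DEFAULT_MEASUREMENT_NOISE = {
    "apt_weighted": 0.06,   # percent
    "total_cest": 0.20,     # percent*ppm
    "fa": 0.008,
    "md": 0.010,            # 1e-3 mm^2/s
}


@dataclass(frozen=True)
class CohortConfig:
    """Study design and disease-effect parameters.

    ``effects[region][stage]`` holds multipliers ``amide`` (on the amide
    pool fraction), ``aniso`` (on the anisotropic part of the diffusion
    tensor) and ``md`` (on its mean); controls are implicitly 1.  When
    ``effects`` is None it resolves to :func:`calibrated_effects`, whose
    amide multipliers are derived by inverting the simulator's APT
    response so stage group means land on
    :data:`pdcest.defaults.REGION_APT_STAGE`.  ``subject_cv`` is the
    lognormal coefficient of variation of the amide fraction across
    subjects (the tensor deviates use a third of it); because APTw is
    offset-linear in the amide fraction, the resulting APTw dispersion is
    roughly 3x larger.
    """

    n_control: int = 23
    n_early_pd: int = 12
    n_advanced_pd: int = 11
    effects: dict | None = None
    subject_cv: float = 0.04
    measurement_noise: dict = field(
        default_factory=lambda: dict(DEFAULT_MEASUREMENT_NOISE)
    )
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_control, self.n_early_pd, self.n_advanced_pd) < 1:
            raise ValueError("every group needs at least one subject")
        if self.effects is None:
            object.__setattr__(self, "effects", calibrated_effects())
        for region, stages in self.effects.items():
            for stage, mults in stages.items():
                if any(v <= 0 for v in mults.values()):
                    raise ValueError(f"non-positive effect multiplier in {region}/{stage}")
        if self.subject_cv < 0:
            raise ValueError("subject_cv must be >= 0")

    def stages(self) -> list[tuple[str, str, int]]:
        """(stage, group, n) triples in generation order."""
        return [
            ("control", "control", self.n_control),
            ("early", "pd", self.n_early_pd),
            ("advanced", "pd", self.n_advanced_pd),
        ]

    def multiplier(self, region: str, stage: str, key: str) -> float:
        if stage == "control":
            return 1.0
        return self.effects.get(region, {}).get(stage, {}).get(key, 1.0)


def null_config(**kwargs) -> CohortConfig:
    """Null cohort: all effect multipliers 1 and zero between-subject CV,
    leaving measurement noise as the only source of variation."""
    effects = {
        r: {s: {"amide": 1.0, "aniso": 1.0, "md": 1.0} for s in ("early", "advanced")}
        for r in REGIONS
    }
    return CohortConfig(effects=effects, subject_cv=0.0, **kwargs)


# ---------------------------------------------------------------------------
# Bloch-McConnell response curves and amide calibration

_FRACTION_GRID = np.linspace(5e-5, 1.2e-2, 48)


@lru_cache(maxsize=8)
def _response_splines(sat: SaturationParams) -> tuple[CubicSpline, CubicSpline]:
    """APT-weighted (percent) and total-CEST (percent*ppm) as smooth
    functions of the amide pool fraction, from full simulations on a grid."""
    sched_offsets = sorted(o for o in OffsetSchedule.default().offsets if abs(o) <= 4.0)
    pos = np.unique(np.abs(sched_offsets))
    apt_vals, tot_vals = [], []
    for f in _FRACTION_GRID:
        pools = defaults.make_pools(f)
        z = zspectrum_values(pools, sat, np.array(sched_offsets))
        z_neg = z[np.searchsorted(sched_offsets, -pos)]
        z_pos = z[np.searchsorted(sched_offsets, pos)]
        asym = 100.0 * (z_neg - z_pos)
        asym[pos == 0] = 0.0
        curve = MtrAsymCurve(pos, asym)
        apt_vals.append(curve.interp(3.5))
        tot_vals.append(total_cest(curve))
    return (
        CubicSpline(_FRACTION_GRID, np.asarray(apt_vals)),
        CubicSpline(_FRACTION_GRID, np.asarray(tot_vals)),
    )


def apt_response(sat: SaturationParams | None = None):
    """Spline mapping amide pool fraction -> APT-weighted value (percent)."""
    return _response_splines(sat or defaults.DEFAULT_SATURATION)[0]


@lru_cache(maxsize=8)
def _calibrated_fractions(sat: SaturationParams) -> dict[str, float]:
    spline = _response_splines(sat)[0]
    dense = np.linspace(_FRACTION_GRID[0], _FRACTION_GRID[-1], 4000)
    vals = spline(dense)
    out = {}
    for region, target in defaults.REGION_APT_BASELINE.items():
        out[region] = float(dense[np.argmin(np.abs(vals - target))])
    return out


def calibrated_amide_fractions(sat: SaturationParams | None = None) -> dict[str, float]:
    """Amide fraction per region whose simulated baseline APT-weighted value
    matches :data:`pdcest.defaults.REGION_APT_BASELINE`."""
    return dict(_calibrated_fractions(sat or defaults.DEFAULT_SATURATION))


@lru_cache(maxsize=8)
def _calibrated_effects(sat: SaturationParams) -> dict:
    spline = _response_splines(sat)[0]
    dense = np.linspace(_FRACTION_GRID[0], _FRACTION_GRID[-1], 4000)
    vals = spline(dense)

    def f_for(apt: float) -> float:
        return float(dense[np.argmin(np.abs(vals - apt))])

    base = _calibrated_fractions(sat)
    effects: dict = {}
    for region, stage_apt in defaults.REGION_APT_STAGE.items():
        effects[region] = {}
        for stage, target in stage_apt.items():
            amide = f_for(target) / base[region]
            dti = defaults.DTI_EFFECTS[region][stage]
            effects[region][stage] = {"amide": amide, **dti}
    effects["background"] = {
        s: {"amide": 1.0, "aniso": 1.0, "md": 1.0} for s in ("early", "advanced")
    }
    return effects


def calibrated_effects(sat: SaturationParams | None = None) -> dict:
    """Default disease-effect table: amide multipliers inverted from the
    APT response curve so stage group means land on the configured
    stage-wise targets; diffusion multipliers from
    :data:`pdcest.defaults.DTI_EFFECTS`."""
    import copy

    return copy.deepcopy(_calibrated_effects(sat or defaults.DEFAULT_SATURATION))


# ---------------------------------------------------------------------------
# subject-level parameter draws

def _lognormal_deviate(rng: np.random.Generator, cv: float) -> float:
    """Unit-mean lognormal multiplier with coefficient of variation ``cv``."""
    if cv == 0:
        return 1.0
    sigma = np.sqrt(np.log1p(cv * cv))
    return float(rng.lognormal(mean=-0.5 * sigma * sigma, sigma=sigma))


def _scaled_tensor(base_six: np.ndarray, md_mult: float, aniso_mult: float) -> np.ndarray:
    """Scale the mean and the anisotropic deviation of a tensor separately,
    preserving its eigenvectors."""
    w, v = np.linalg.eigh(_tensor_matrix(np.asarray(base_six, dtype=float)))
    md = w.mean()
    w_new = md * md_mult + (w - md) * aniso_mult
    d = np.einsum("ij,j,kj->ik", v, w_new, v)
    return np.array([d[0, 0], d[1, 1], d[2, 2], d[0, 1], d[0, 2], d[1, 2]])


@dataclass
class SubjectRecord:
    """One simulated subject: identity plus image-domain data."""

    subject_id: str
    group: str
    stage: str
    phantom: PhantomData
    dwi: np.ndarray
    bvals: np.ndarray
    bvecs: np.ndarray
    spec: PhantomSpec


def _subject_params(
    config: CohortConfig,
    base_fractions: dict[str, float],
    base_tensors: dict[str, np.ndarray],
    stage: str,
    rng: np.random.Generator,
):
    """Per-region (amide fraction, tensor) for one subject."""
    cv = config.subject_cv
    fractions, tensors = {}, {}
    for region in list(base_fractions):
        dev = _lognormal_deviate(rng, cv)
        fractions[region] = base_fractions[region] * config.multiplier(region, stage, "amide") * dev
    for region in list(base_tensors):
        dev_md = _lognormal_deviate(rng, cv / 3.0)
        dev_an = _lognormal_deviate(rng, cv / 3.0)
        tensors[region] = _scaled_tensor(
            base_tensors[region],
            config.multiplier(region, stage, "md") * dev_md,
            config.multiplier(region, stage, "aniso") * dev_an,
        )
    return fractions, tensors


def generate_cohort(
    config: CohortConfig,
    spec: PhantomSpec | None = None,
    sat: SaturationParams | None = None,
    schedule: OffsetSchedule | None = None,
    dwi_snr: float = 30.0,
) -> list[SubjectRecord]:
    """Simulate the full image-domain cohort.

    Each subject gets a phantom whose region amide fractions and diffusion
    tensors are the spec baseline times the stage's effect multiplier times
    a per-subject lognormal deviate, then a saturation stack and DWI set
    with subject-specific noise.  Fully deterministic in ``config.rng_seed``.
    """
    sat = sat or defaults.DEFAULT_SATURATION
    schedule = schedule or OffsetSchedule.default()
    spec = spec or default_phantom_spec()
    base_fracs = {
        r: spec.region_pools[r][_amide_index(spec.region_pools[r])].pool_fraction
        for r in spec.region_geometries
    }
    base_fracs["background"] = spec.background_pools[
        _amide_index(spec.background_pools)
    ].pool_fraction
    base_tensors = {r: spec.dwi_truth[r] for r in spec.dwi_truth}
    base_tensors["background"] = spec.background_tensor

    bvals, bvecs = default_dwi_scheme()
    root = np.random.SeedSequence(config.rng_seed)
    subjects: list[SubjectRecord] = []
    idx = 0
    for stage, group, n in config.stages():
        for _ in range(n):
            ss_param, ss_phantom, ss_dwi = root.spawn(3)
            prng = np.random.default_rng(ss_param)
            fracs, tensors = _subject_params(config, base_fracs, base_tensors, stage, prng)
            subj_spec = replace(
                spec,
                region_pools={
                    r: _with_amide(spec.region_pools[r], fracs[r])
                    for r in spec.region_geometries
                },
                background_pools=_with_amide(spec.background_pools, fracs["background"]),
                dwi_truth={r: tensors[r] for r in spec.dwi_truth},
                background_tensor=tensors["background"],
            )
            phantom = generate_phantom(
                subj_spec, sat, schedule, seed=int(ss_phantom.generate_state(1)[0] % 2**31)
            )
            dwi = generate_dwi(
                subj_spec, bvals, bvecs, dwi_snr,
                seed=int(ss_dwi.generate_state(1)[0] % 2**31),
            )
            subjects.append(
                SubjectRecord(f"sub-{idx:03d}", group, stage, phantom, dwi, bvals, bvecs, subj_spec)
            )
            idx += 1
    return subjects


def _amide_index(pools: list[PoolParams]) -> int:
    for i, p in enumerate(pools):
        if p.name == "amide":
            return i
    raise ValueError("pool set has no amide pool")


def _with_amide(pools: list[PoolParams], fraction: float) -> list[PoolParams]:
    i = _amide_index(pools)
    out = list(pools)
    out[i] = out[i].scaled(fraction / out[i].pool_fraction)
    return out


def generate_cohort_table(
    config: CohortConfig,
    sat: SaturationParams | None = None,
    seed: int | None = None,
) -> pd.DataFrame:
    """ROI sample table drawn through the simulator's response curves.

    For each subject and region the amide fraction is drawn exactly as in
    :func:`generate_cohort` and mapped to APT-weighted / total-CEST values
    through the Bloch-McConnell response splines; FA and MD come from the
    scaled ground-truth tensor.  Each hemisphere sample receives independent
    Gaussian measurement noise (``config.measurement_noise``).  Columns
    match :data:`pdcest.stats.REQUIRED_COLUMNS`.
    """
    sat = sat or defaults.DEFAULT_SATURATION
    apt_spline, tot_spline = _response_splines(sat)
    base_fracs = calibrated_amide_fractions(sat)
    base_tensors = {
        r: tensor_from_eigs(
            _eigs_for_region(r), axis=(0.0, 0.0, 1.0)
        )
        for r in REGIONS
    }
    rng = np.random.default_rng(config.rng_seed if seed is None else seed)
    rows = []
    idx = 0
    noise = config.measurement_noise
    for stage, group, n in config.stages():
        for _ in range(n):
            sid = f"sub-{idx:03d}"
            for region in REGIONS:
                dev = _lognormal_deviate(rng, config.subject_cv)
                frac = base_fracs[region] * config.multiplier(region, stage, "amide") * dev
                apt = float(apt_spline(frac))
                tot = float(tot_spline(frac))
                dev_md = _lognormal_deviate(rng, config.subject_cv / 3.0)
                dev_an = _lognormal_deviate(rng, config.subject_cv / 3.0)
                tensor = _scaled_tensor(
                    base_tensors[region],
                    config.multiplier(region, stage, "md") * dev_md,
                    config.multiplier(region, stage, "aniso") * dev_an,
                )
                fa, md = fa_md(tensor)
                truth = {"apt_weighted": apt, "total_cest": tot, "fa": float(fa), "md": float(md)}
                for hemi in HEMISPHERES:
                    for metric in METRICS:
                        rows.append(
                            dict(
                                subject_id=sid, group=group, stage=stage,
                                region=region, hemisphere=hemi, metric=metric,
                                value=truth[metric] + rng.normal(0.0, noise[metric]),
                            )
                        )
            idx += 1
    return pd.DataFrame(rows)


def _eigs_for_region(region: str) -> tuple[float, float, float]:
    from .phantom import eigenvalues_from_fa_md

    fa, md = defaults.REGION_FA_MD_BASELINE[region]
    return eigenvalues_from_fa_md(fa, md)
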