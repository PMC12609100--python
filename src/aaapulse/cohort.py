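"""Synthetic cohort sampling and waveform dataset generation.

A synthetic patient is built in four stages:

1. *Age-adjusted nominals* — the nominal 55-artery tree is scaled by
   monotone age multipliers (older age: lower stroke volume, longer proximal
   aorta, larger diameters, lower terminal compliance, higher peripheral
   resistance and wall stiffness). Multipliers equal 1 at the reference age.
2. *Inter-individual variability (IIV)* — eight per-category coefficients
   drawn from uniform distributions (0.8–1.2 for heart rate, stroke volume,
   lengths, radii, thicknesses, terminal resistances and compliances;
   0.7–1.6 for wall stiffness) multiply the nominal parameters.
3. *Aneurysm severity* — a volumetric severity index (VSI) is drawn uniform
   on [0, 100]%, the bump extent ``l_aaa`` uniform on [max(0.4, vsi/100), 1]
   (the lower bound keeps the area parameter within its admissible range),
   the area parameter follows by inversion, and the wall-stiffness scaling
   ``K_E`` is drawn uniform on [1.25, 2.45] independently of geometry.
4. *Sample-to-sample variability (SSV)* — each recording multiplies every
   circulation parameter by an independent N(1, 0.01) coefficient and
   re-draws the five viscoelastic cuff constants from lognormals centred at
   the subject values with a 1% coefficient of variation.

Subject height is tied to the anatomical length axis
(``height = 170 cm * length IIV``), making it a genuine waveform-affecting
confounder for the adversarial training targets.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass, field, asdict

import h5py
import numpy as np

from . import pvr as pvrmod
from .hemodynamics import (
    AneurysmSpec,
    ArterialTree,
    BloodProperties,
    CompiledTree,
    SimulationSettings,
    Waveform,
    aortic_inflow,
    insert_aneurysm,
    nominal_tree,
    solve_asl,
)
from .pvr import ViscoelasticParams

__all__ = [
    "CohortConfig",
    "SubjectParameters",
    "RealizedSample",
    "WaveDataset",
    "age_adjusted_nominals",
    "sample_subject",
    "perturb_sample",
    "simulate_sample",
    "generate_dataset",
]

IIV_CATEGORIES = (
    "hr",
    "sv",
    "length",
    "radius",
    "thickness",
    "terminal_resistance",
    "terminal_compliance",
    "stiffness",
)

#: sites simulated for every record
RECORD_SITES = ("carotid", "brachial", "femoral", "tibial")


@dataclass
class CohortConfig:
    """Distributions and nominal values defining the synthetic population."""

    age_range: tuple[float, float] = (40.0, 80.0)
    iiv_default: tuple[float, float] = (0.8, 1.2)
    iiv_stiffness: tuple[float, float] = (0.7, 1.6)
    hr_nominal: float = 75.0  # bpm; 0.8-1.2 IIV spans 60-90
    sv_nominal: float = 70e-6  # m^3 at the reference age
    vsi_range: tuple[float, float] = (0.0, 100.0)
    l_aaa_range: tuple[float, float] = (0.4, 1.0)
    k_e_range: tuple[float, float] = (1.25, 2.45)
    n_subsegments: int = 16
    ssv_cv: float = 0.01
    reference_age: float = 50.0
    # linear slopes per year relative to the reference age; stiffness is
    # exponential so the cohort spans the stated wave-speed band
    age_trends: dict = field(
        default_factory=lambda: {
            "sv": -0.004,
            "proximal_aorta_length": 0.004,
            "radius": 0.002,
            "terminal_compliance": -0.008,
            "terminal_resistance": 0.004,
            "stiffness_log": 0.022,
        }
    )
    # subject-level lognormal medians and dispersion of the cuff constants
    viscoelastic_medians: tuple[float, float, float, float, float] = (1.0, 4.0, 0.2, 1.0, 0.1)
    viscoelastic_sigma: float = 0.2
    height_nominal_cm: float = 170.0

    def __post_init__(self) -> None:
        for rng_ in (self.age_range, self.iiv_default, self.iiv_stiffness,
                     self.vsi_range, self.l_aaa_range, self.k_e_range):
            if rng_[0] > rng_[1]:
                raise ValueError(f"range {rng_} is not ordered")
        if self.ssv_cv < 0:
            raise ValueError("ssv_cv must be nonnegative")

    def to_json(self) -> str:
        d = asdict(self)
        return json.dumps(d, sort_keys=True)

    def config_hash(self) -> str:
        return hashlib.sha256(self.to_json().encode()).hexdigest()[:16]


@dataclass
class SubjectParameters:
    """One synthetic patient: demographics, IIV coefficients, AAA, cuff model."""

    subject_id: int
    age: float
    iiv: dict[str, float]
    hr: float
    sv: float
    aneurysm: AneurysmSpec
    viscoelastic: ViscoelasticParams
    height: float  # cm


# the proximal aorta (root to the arch) lengthens preferentially with age
PROXIMAL_AORTA = ("ascending_aorta", "aortic_arch_a", "aortic_arch_b")


def age_adjusted_nominals(age: float, config: CohortConfig | None = None) -> dict[str, float]:
    """Monotone nominal-parameter multipliers at a given age (1 at reference).

    Directions: stroke volume decreases; proximal-aorta length, arterial
    diameters, peripheral resistance and wall stiffness increase; terminal
    compliance decreases.
    """
    config = config or CohortConfig()
    if not 30.0 <= age <= 80.0:
        raise ValueError("age must lie in [30, 80] years")
    da = age - config.reference_age
    tr = config.age_trends
    out = {
        "sv": 1.0 + tr["sv"] * da,
        "proximal_aorta_length": 1.0 + tr["proximal_aorta_length"] * da,
        "radius": 1.0 + tr["radius"] * da,
        "terminal_compliance": 1.0 + tr["terminal_compliance"] * da,
        "terminal_resistance": 1.0 + tr["terminal_resistance"] * da,
        "stiffness": math.exp(tr["stiffness_log"] * da),
    }
    if min(out.values()) <= 0:
        raise ValueError("age trends produced a non-positive multiplier")
    return out


def sample_subject(config: CohortConfig, rng: np.random.Generator,
                   subject_id: int = 0) -> SubjectParameters:
    """Draw one patient: age, the eight IIV coefficients, AAA severity, cuff model."""
    age = rng.uniform(*config.age_range)
    iiv = {}
    for cat in IIV_CATEGORIES:
        lo, hi = config.iiv_stiffness if cat == "stiffness" else config.iiv_default
        iiv[cat] = float(rng.uniform(lo, hi))
    hr = config.hr_nominal * iiv["hr"]
    sv = config.sv_nominal * age_adjusted_nominals(age, config)["sv"] * iiv["sv"]

    vsi = float(rng.uniform(*config.vsi_range))
    lo = max(config.l_aaa_range[0], vsi / 100.0)
    l_aaa = float(rng.uniform(lo, config.l_aaa_range[1]))
    a_sl = solve_asl(vsi, l_aaa)
    k_e = float(rng.uniform(*config.k_e_range))
    aneurysm = AneurysmSpec(
        l_aaa=l_aaa, a_sl=a_sl, k_e=k_e, vsi=vsi, n_subsegments=config.n_subsegments
    )

    med = np.asarray(config.viscoelastic_medians)
    ve = ViscoelasticParams.from_array(
        med * np.exp(config.viscoelastic_sigma * rng.standard_normal(5))
    )
    height = config.height_nominal_cm * iiv["length"]
    return SubjectParameters(
        subject_id=subject_id, age=age, iiv=iiv, hr=hr, sv=sv,
        aneurysm=aneurysm, viscoelastic=ve, height=height,
    )


def _subject_tree(subject: SubjectParameters, config: CohortConfig,
                  base: ArterialTree | None = None) -> ArterialTree:
    """Nominal tree scaled by the subject's age multipliers and IIV coefficients."""
    tree = (base or nominal_tree()).copy()
    mult = age_adjusted_nominals(subject.age, config)
    iiv = subject.iiv
    for seg in tree.segments.values():
        lm = mult["proximal_aorta_length"] if seg.name in PROXIMAL_AORTA else 1.0
        seg.length *= lm * iiv["length"]
        seg.radius *= mult["radius"] * iiv["radius"]
        seg.thickness *= iiv["thickness"]
        seg.youngs_modulus *= mult["stiffness"] * iiv["stiffness"]
    for load in tree.loads.values():
        load.r_total *= mult["terminal_resistance"] * iiv["terminal_resistance"]
        load.compliance *= mult["terminal_compliance"] * iiv["terminal_compliance"]
    return tree


@dataclass
class RealizedSample:
    """One recording: the SSV-perturbed tree (with AAA), drive and cuff model."""

    subject: SubjectParameters
    tree: ArterialTree
    hr: float
    sv: float
    viscoelastic: ViscoelasticParams


def perturb_sample(subject: SubjectParameters, rng: np.random.Generator,
                   config: CohortConfig | None = None,
                   base: ArterialTree | None = None,
                   max_retries: int = 5) -> RealizedSample:
    """Apply sample-to-sample variability and carve in the aneurysm.

    Circulation parameters are multiplied by independent N(1, ssv_cv) draws
    (redrawn in the vanishingly rare case of a non-positive multiplier); the
    cuff viscoelastic constants are re-drawn from lognormals with median at
    the subject value and a coefficient of variation ``ssv_cv``.
    """
    config = config or CohortConfig()
    tree = _subject_tree(subject, config, base)
    cv = config.ssv_cv

    def draw() -> float:
        for _ in range(max_retries):
            m = 1.0 + cv * rng.standard_normal()
            if m > 0:
                return m
        raise RuntimeError("could not draw a positive SSV multiplier")

    if cv > 0:
        for seg in tree.segments.values():
            seg.length *= draw()
            seg.radius *= draw()
            seg.thickness *= draw()
            seg.youngs_modulus *= draw()
        for load in tree.loads.values():
            load.r_total *= draw()
            load.compliance *= draw()
    hr = min(90.0, max(60.0, subject.hr * (draw() if cv > 0 else 1.0)))
    sv = subject.sv * (draw() if cv > 0 else 1.0)

    if cv > 0:
        sigma = math.sqrt(math.log(1.0 + cv * cv))
        ve = ViscoelasticParams.from_array(
            subject.viscoelastic.as_array() * np.exp(sigma * rng.standard_normal(5))
        )
    else:
        ve = subject.viscoelastic

    tree = insert_aneurysm(tree, subject.aneurysm)
    return RealizedSample(subject=subject, tree=tree, hr=hr, sv=sv, viscoelastic=ve)


def simulate_sample(sample: RealizedSample, settings: SimulationSettings | None = None,
                    blood: BloodProperties | None = None,
                    sites: tuple[str, ...] = RECORD_SITES) -> dict[str, Waveform]:
    """Steady-state BP at the named sites plus brachial/tibial PVR."""
    settings = settings or SimulationSettings()
    inflow = aortic_inflow(sample.hr, sample.sv, settings)
    sol = CompiledTree(sample.tree, blood).solve(inflow.periodic)
    out = {f"bp_{s}": sol.site_waveform(s, settings) for s in sites}
    if "brachial" in sites:
        out["pvr_brachial"] = pvrmod.brachial_pvr(out["bp_brachial"], sample.viscoelastic)
    if "tibial" in sites:
        out["pvr_tibial"] = pvrmod.tibial_pvr(out["bp_tibial"], sample.viscoelastic)
    return out


# ---------------------------------------------------------------------------
# datasets
# ---------------------------------------------------------------------------

_WAVE_KEYS = ("bp_carotid", "bp_brachial", "bp_femoral", "bp_tibial",
              "pvr_brachial", "pvr_tibial")


@dataclass
class WaveDataset:
    """Column-oriented waveform dataset (one row per recording)."""

    waveforms: dict[str, np.ndarray]  # each (n_records, n_samples)
    subject_id: np.ndarray
    sample_id: np.ndarray
    height: np.ndarray  # cm
    age: np.ndarray  # years
    hr: np.ndarray  # bpm
    vsi: np.ndarray | None  # % or None for unlabeled datasets
    max_diameter_increase: np.ndarray | None  # %
    fs: float = 128.0
    labeled: bool = True
    meta: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.subject_id)

    # -- persistence (HDF5 layout: /records, /labels, /demographics, /meta) --
    def to_hdf5(self, path) -> None:
        with h5py.File(path, "w") as f:
            rec = f.create_group("records")
            for k, v in self.waveforms.items():
                rec.create_dataset(k, data=v)
            dem = f.create_group("demographics")
            dem.create_dataset("height", data=self.height)
            dem.create_dataset("age", data=self.age)
            dem.create_dataset("hr", data=self.hr)
            dem.create_dataset("subject_id", data=self.subject_id)
            dem.create_dataset("sample_id", data=self.sample_id)
            if self.labeled:
                lab = f.create_group("labels")
                lab.create_dataset("vsi", data=self.vsi)
                lab.create_dataset("max_diameter_increase", data=self.max_diameter_increase)
            meta = f.create_group("meta")
            meta.attrs["fs"] = self.fs
            meta.attrs["labeled"] = self.labeled
            for k, v in self.meta.items():
                meta.attrs[k] = v

    @classmethod
    def from_hdf5(cls, path) -> "WaveDataset":
        with h5py.File(path, "r") as f:
            waveforms = {k: f["records"][k][()] for k in f["records"]}
            dem = f["demographics"]
            labeled = bool(f["meta"].attrs["labeled"])
            return cls(
                waveforms=waveforms,
                subject_id=dem["subject_id"][()],
                sample_id=dem["sample_id"][()],
                height=dem["height"][()],
                age=dem["age"][()],
                hr=dem["hr"][()],
                vsi=f["labels"]["vsi"][()] if labeled else None,
                max_diameter_increase=(
                    f["labels"]["max_diameter_increase"][()] if labeled else None
                ),
                fs=float(f["meta"].attrs["fs"]),
                labeled=labeled,
                meta={k: f["meta"].attrs[k] for k in f["meta"].attrs
                      if k not in ("fs", "labeled")},
            )


def generate_dataset(
    n_subjects: int,
    n_samples_per_subject: int,
    labeled: bool = True,
    config: CohortConfig | None = None,
    rng: np.random.Generator | int | None = None,
    settings: SimulationSettings | None = None,
    progress: bool = False,
    max_retries: int = 3,
) -> WaveDataset:
    """Simulate ``n_subjects x n_samples_per_subject`` recordings.

    Unlabeled datasets keep demographics (height, age) but omit severity
    labels. A failed realisation (numerical failure in the solve) is logged
    and re-perturbed up to ``max_retries`` times.
    """
    if n_subjects < 1 or n_samples_per_subject < 1:
        raise ValueError("dataset dimensions must be >= 1")
    config = config or CohortConfig()
    settings = settings or SimulationSettings()
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    base = nominal_tree()

    n = n_subjects * n_samples_per_subject
    waves = {k: np.empty((n, settings.n_samples)) for k in _WAVE_KEYS}
    subject_id = np.empty(n, dtype=np.int64)
    sample_id = np.empty(n, dtype=np.int64)
    height = np.empty(n)
    age = np.empty(n)
    hr = np.empty(n)
    vsi = np.empty(n)
    mdi = np.empty(n)

    iterator = range(n_subjects)
    if progress:
        from tqdm import tqdm

        iterator = tqdm(iterator, desc="subjects")

    row = 0
    for si in iterator:
        subject = sample_subject(config, rng, subject_id=si)
        for qi in range(n_samples_per_subject):
            for attempt in range(max_retries + 1):
                try:
                    sample = perturb_sample(subject, rng, config, base)
                    rec = simulate_sample(sample, settings)
                    break
                except Exception:
                    if attempt == max_retries:
                        raise
            for k in _WAVE_KEYS:
                waves[k][row] = rec[k].samples
            subject_id[row] = si
            sample_id[row] = qi
            height[row] = subject.height
            age[row] = subject.age
            hr[row] = sample.hr
            vsi[row] = subject.aneurysm.vsi
            mdi[row] = subject.aneurysm.max_diameter_increase_pct
            row += 1

    return WaveDataset(
        waveforms=waves,
        subject_id=subject_id,
        sample_id=sample_id,
        height=height,
        age=age,
        hr=hr,
        vsi=vsi if labeled else None,
        max_diameter_increase=mdi if labeled else None,
        fs=settings.fs,
        labeled=labeled,
        meta={"config_hash": config.config_hash(), "config": config.to_json()},
    )
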