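"""Aneurysm-sensitive pulse-wave features and plausibility analyses.

Four features quantify the imprint of an abdominal aortic aneurysm on
arterial pressure waveforms:

* **cf-PWV** — carotid–femoral pulse wave velocity: the tree path length
  between the two sites divided by the foot-to-foot transit time, feet
  located with the intersecting-tangent method. Decreases with aneurysm
  severity (the dilated segment is locally more compliant).
* **CUI** — carotid upstroke index: the foot-to-peak upstroke is split at the
  point minimising the total RMS error of two least-squares line fits; CUI is
  the peak-to-intersection amplitude over pulse pressure. Increases with
  severity (negative reflections blunt early systole).
* **CAR** — carotid area ratio: diastolic area divided by systolic area under
  the beat (baseline at the diastolic minimum, split at the systolic peak).
* **COR** — carotid oscillatory ratio: spectral energy of the mean-subtracted
  record in 3–8x the fundamental over energy in (0, 3x); the 3x boundary bin
  counts toward the high band.

CUI, CAR and COR are invariant to uniform amplitude scaling; all four are
invariant to time shifts. Features are averaged over all complete beats of a
record. Beats are Fourier-upsampled before sub-sample foot/peak localisation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import find_peaks, resample
from scipy.stats import pearsonr

from .cohort import (
    IIV_CATEGORIES,
    CohortConfig,
    WaveDataset,
    age_adjusted_nominals,
    perturb_sample,
    simulate_sample,
)
from .hemodynamics import ArterialTree, SimulationSettings, Waveform, nominal_tree

__all__ = [
    "FeatureFailure",
    "FeatureVector",
    "BeatSegment",
    "detect_beats",
    "foot_intersecting_tangent",
    "cf_pwv",
    "cui",
    "car",
    "cor",
    "compute_features",
    "feature_table",
    "age_sweep_statistics",
    "feature_severity_correlations",
]


class FeatureFailure(ValueError):
    """Raised when a waveform is degenerate for a given feature."""


@dataclass
class FeatureVector:
    pwv: float  # m/s
    cui: float  # dimensionless in (0, 1)
    car: float  # dimensionless > 0
    cor: float  # dimensionless >= 0


@dataclass
class BeatSegment:
    """One complete beat: samples from onset (diastolic minimum) to next onset."""

    samples: np.ndarray
    fs: float
    onset: int  # index into the parent record
    peak: int  # index of the systolic peak within ``samples``
    end: int  # exclusive end index into the parent record

    def __post_init__(self) -> None:
        if not 0 < self.peak < len(self.samples):
            raise FeatureFailure("beat peak must lie strictly inside the beat")


def detect_beats(w: Waveform | np.ndarray, fs: float | None = None,
                 hr_hint: float | None = None) -> list[BeatSegment]:
    """Segment a record into complete beats at diastolic minima.

    ``hr_hint`` (bpm) sets the minimum onset spacing; without it the spacing
    is inferred from the dominant spectral peak.
    """
    if isinstance(w, Waveform):
        x, fs = w.samples, w.fs
    else:
        x = np.asarray(w, dtype=float)
        if fs is None:
            raise ValueError("fs required for raw arrays")
    if np.ptp(x) < 1e-12 * max(1.0, abs(float(np.mean(x)))) or np.ptp(x) == 0.0:
        raise FeatureFailure("constant record has no beats")
    if hr_hint is None:
        spec = np.abs(np.fft.rfft(x - x.mean()))
        k = int(np.argmax(spec[1:]) + 1)
        f0 = k * fs / len(x)
        hr_hint = 60.0 * f0
    period = fs * 60.0 / hr_hint
    onsets, _ = find_peaks(-x, distance=max(2, int(0.7 * period)))
    onsets = list(onsets)
    # find_peaks cannot flag the record edges; accept them when they are the
    # minimum of the adjacent half-period
    half = max(2, int(0.5 * period))
    if (not onsets or onsets[0] >= half) and x[0] <= x[1:half].min():
        onsets.insert(0, 0)
    n = len(x)
    if (not onsets or onsets[-1] <= n - 1 - half) and x[-1] <= x[n - half : n - 1].min():
        onsets.append(n - 1)
    if len(onsets) < 2:
        raise FeatureFailure("fewer than two diastolic onsets found")
    beats = []
    for a, b in zip(onsets[:-1], onsets[1:]):
        seg = x[a:b + 1]
        peak = int(np.argmax(seg))
        if 0 < peak < len(seg) - 1:
            beats.append(BeatSegment(samples=seg, fs=fs, onset=int(a), peak=peak, end=int(b)))
    if not beats:
        raise FeatureFailure("no complete beat found")
    return beats


def _upsample_beat(beat: BeatSegment, factor: int) -> BeatSegment:
    """Fourier-resample a beat for sub-sample landmark localisation."""
    if factor <= 1:
        return beat
    n = len(beat.samples)
    y = resample(beat.samples, n * factor)
    return BeatSegment(samples=y, fs=beat.fs * factor, onset=beat.onset * factor,
                       peak=int(np.argmax(y)), end=beat.end * factor)


def foot_intersecting_tangent(beat: BeatSegment) -> float:
    """Foot time (s, relative to the record start) by the intersecting-tangent method.

    The horizontal line through the diastolic minimum is intersected with the
    tangent at the maximum-slope point of the systolic upstroke.
    """
    up = beat.samples[: beat.peak + 1]
    if len(up) < 3:
        raise FeatureFailure("upstroke too short for tangent construction")
    slopes = np.gradient(up)
    i = int(np.argmax(slopes))
    m = slopes[i] * beat.fs  # units per second
    if m <= 0:
        raise FeatureFailure("non-positive maximum upstroke slope")
    base = float(np.min(up))
    imin = int(np.argmin(up))
    t_i = i / beat.fs
    t_foot = t_i - (up[i] - base) / m
    t_foot = max(t_foot, imin / beat.fs)  # tangent cannot cross before the minimum
    return beat.onset / beat.fs + t_foot


def cf_pwv(carotid: Waveform, femoral: Waveform, path_length_m: float,
           fs: float | None = None, hr_hint: float | None = None,
           upsample: int = 8) -> float:
    """Carotid–femoral pulse wave velocity (m/s), feet averaged over beats."""
    bc = [_upsample_beat(b, upsample) for b in detect_beats(carotid, fs, hr_hint)]
    bf = [_upsample_beat(b, upsample) for b in detect_beats(femoral, fs, hr_hint)]
    feet_c = np.array([foot_intersecting_tangent(b) for b in bc])
    feet_f = np.array([foot_intersecting_tangent(b) for b in bf])
    # pair each carotid foot with the first femoral foot that follows it
    transits = []
    for tc in feet_c:
        later = feet_f[feet_f > tc]
        if later.size:
            transits.append(later[0] - tc)
    if not transits:
        raise FeatureFailure("no carotid-femoral foot pair found")
    dt = float(np.mean(transits))
    if dt <= 0:
        raise FeatureFailure("non-positive transit time")
    return path_length_m / dt


def cui(beat: BeatSegment, upsample: int = 8) -> float:
    """Carotid upstroke index from a two-line fit of the foot-to-peak upstroke.

    The split index is found by exhaustive search (minimum total RMS error of
    the two least-squares fits, ties broken toward the earlier index); the
    index is the peak-to-intersection amplitude over pulse pressure.
    """
    beat = _upsample_beat(beat, upsample)
    up = beat.samples[: beat.peak + 1]
    start = int(np.argmin(up))
    up = up[start:]
    n = len(up)
    if n < 6:
        raise FeatureFailure("upstroke has fewer than 6 samples")
    t = np.arange(n, dtype=float)

    splits = np.arange(2, n - 2)
    e1 = _prefix_line_sse(t, up)  # SSE of fit to up[:s+1], indexed by s
    e2 = _prefix_line_sse(t, up[::-1])[::-1]  # SSE of fit to up[s:]
    err = (np.sqrt(np.maximum(e1[splits], 0.0) / (splits + 1))
           + np.sqrt(np.maximum(e2[splits], 0.0) / (n - splits)))
    s = int(splits[np.argmin(err)])  # argmin takes the earliest index on ties
    c1 = np.polyfit(t[: s + 1], up[: s + 1], 1)
    c2 = np.polyfit(t[s:], up[s:], 1)
    dm = c1[0] - c2[0]
    if abs(dm) < 1e-12 * max(abs(c1[0]), abs(c2[0]), 1e-30):
        # collinear fits: intersection amplitude at the split is the line value
        p_int = np.polyval(c1, t[-1])
    else:
        t_int = (c2[1] - c1[1]) / dm
        p_int = np.polyval(c1, t_int)
    pp = up[-1] - up[0]
    if pp <= 0:
        raise FeatureFailure("non-positive pulse pressure")
    val = float((up[-1] - p_int) / pp)
    return val


def _prefix_line_sse(t: np.ndarray, y: np.ndarray) -> np.ndarray:
    """SSE of the least-squares line through (t[:k+1], y[:k+1]) for every k.

    Closed-form via running sums; element k < 1 is 0 by convention. This is
    the same brute force as fitting each prefix separately, just vectorised.
    """
    k = np.arange(1, len(t) + 1, dtype=float)
    s1 = np.cumsum(t)
    s2 = np.cumsum(t * t)
    sy = np.cumsum(y)
    sty = np.cumsum(t * y)
    syy = np.cumsum(y * y)
    det = k * s2 - s1 * s1
    with np.errstate(invalid="ignore", divide="ignore"):
        a = (k * sty - s1 * sy) / det
        b = (sy - a * s1) / k
        sse = syy - a * sty - b * sy
    sse[:2] = 0.0
    return sse


def car(beat: BeatSegment) -> float:
    """Carotid area ratio: diastolic over systolic area above the diastolic minimum."""
    x = beat.samples
    base = float(np.min(x))
    sys_area = np.trapezoid(x[: beat.peak + 1] - base)
    dia_area = np.trapezoid(x[beat.peak:] - base)
    if sys_area <= 0:
        raise FeatureFailure("zero systolic area")
    return float(dia_area / sys_area)


def cor(record: Waveform | np.ndarray, hr: float, fs: float | None = None) -> float:
    """Carotid oscillatory ratio: high-band (3-8 f0) over low-band (0-3 f0) energy.

    The record is mean-subtracted before the transform; the DC bin is
    excluded and the 3 f0 boundary bin counts toward the high band.
    """
    if isinstance(record, Waveform):
        x, fs = record.samples, record.fs
    else:
        x = np.asarray(record, dtype=float)
        if fs is None:
            raise ValueError("fs required for raw arrays")
    f0 = hr / 60.0
    spec = np.abs(np.fft.rfft(x - np.mean(x))) ** 2
    freqs = np.fft.rfftfreq(len(x), d=1.0 / fs)
    lo = (freqs > 0) & (freqs < 3.0 * f0 - 1e-12)
    hi = (freqs >= 3.0 * f0 - 1e-12) & (freqs <= 8.0 * f0 + 1e-12)
    e_lo = float(np.sum(spec[lo]))
    e_hi = float(np.sum(spec[hi]))
    if e_lo <= 0:
        raise FeatureFailure("zero low-band energy")
    return e_hi / e_lo


# ---------------------------------------------------------------------------
# record- and dataset-level drivers
# ---------------------------------------------------------------------------


def compute_features(carotid: Waveform | np.ndarray, femoral: Waveform | np.ndarray,
                     path_length_m: float, hr: float, fs: float = 128.0,
                     upsample: int = 8) -> FeatureVector:
    """All four features for one recording (carotid + femoral pressure)."""
    beats = detect_beats(carotid, fs, hr_hint=hr)
    cuis = [cui(b, upsample) for b in beats]
    cars = [car(b) for b in beats]
    return FeatureVector(
        pwv=cf_pwv(carotid, femoral, path_length_m, fs, hr_hint=hr, upsample=upsample),
        cui=float(np.mean(cuis)),
        car=float(np.mean(cars)),
        cor=cor(carotid, hr, fs),
    )


def carotid_femoral_path_length(tree: ArterialTree | None = None) -> float:
    """Path-length difference root->femoral minus root->carotid along the tree."""
    tree = tree or nominal_tree()
    return tree.path_length_to_site("femoral") - tree.path_length_to_site("carotid")


def feature_table(dataset: WaveDataset, path_length_m: float | None = None,
                  upsample: int = 8, progress: bool = False) -> pd.DataFrame:
    """Per-record feature table (pwv, cui, car, cor) with labels when present.

    Records for which a feature is degenerate get NaN in that column. The
    carotid-femoral path length defaults to the nominal anatomy; per-record
    anatomical scaling is not reconstructed from the stored waveforms.
    """
    if path_length_m is None:
        path_length_m = carotid_femoral_path_length()
    rows = []
    n = len(dataset)
    it = range(n)
    if progress:
        from tqdm import tqdm

        it = tqdm(it, desc="features")
    for i in it:
        rec: dict[str, float] = {
            "subject_id": dataset.subject_id[i],
            "sample_id": dataset.sample_id[i],
        }
        try:
            fv = compute_features(
                dataset.waveforms["bp_carotid"][i],
                dataset.waveforms["bp_femoral"][i],
                path_length_m,
                hr=float(dataset.hr[i]),
                fs=dataset.fs,
                upsample=upsample,
            )
            rec.update(pwv=fv.pwv, cui=fv.cui, car=fv.car, cor=fv.cor)
        except FeatureFailure:
            rec.update(pwv=np.nan, cui=np.nan, car=np.nan, cor=np.nan)
        if dataset.labeled:
            rec["vsi"] = dataset.vsi[i]
            rec["max_diameter_increase"] = dataset.max_diameter_increase[i]
        rows.append(rec)
    return pd.DataFrame(rows)


def feature_severity_correlations(table: pd.DataFrame) -> pd.DataFrame:
    """Pearson correlations (with p-values) of each feature vs the severity metrics.

    Returns a table indexed by severity metric with one (rho, p) pair per
    feature. Constant columns yield NaN and are flagged via the p-value.
    """
    feats = ["pwv", "cui", "car", "cor"]
    metrics = [m for m in ("vsi", "max_diameter_increase") if m in table]
    out = {}
    for m in metrics:
        row = {}
        for f in feats:
            sub = table[[m, f]].dropna()
            if sub[f].nunique() <= 1 or sub[m].nunique() <= 1:
                row[f"{f}_rho"], row[f"{f}_p"] = np.nan, np.nan
            else:
                r, p = pearsonr(sub[m], sub[f])
                row[f"{f}_rho"], row[f"{f}_p"] = float(r), float(p)
        out[m] = row
    return pd.DataFrame(out).T


# ---------------------------------------------------------------------------
# age-sweep plausibility analysis
# ---------------------------------------------------------------------------


def _iiv_grid(n_levels: int, rng: np.random.Generator | None, n_subsample: int | None,
              config: CohortConfig):
    """IIV combinations: the full n_levels^8 grid or a random subsample of it."""
    levels = {}
    for cat in IIV_CATEGORIES:
        lo, hi = config.iiv_stiffness if cat == "stiffness" else config.iiv_default
        levels[cat] = np.linspace(lo, hi, n_levels)
    if n_subsample is None:
        grids = np.meshgrid(*[levels[c] for c in IIV_CATEGORIES], indexing="ij")
        combos = np.stack([g.ravel() for g in grids], axis=1)
    else:
        if rng is None:
            rng = np.random.default_rng(0)
        idx = rng.integers(0, n_levels, size=(n_subsample, len(IIV_CATEGORIES)))
        combos = np.stack(
            [levels[c][idx[:, j]] for j, c in enumerate(IIV_CATEGORIES)], axis=1
        )
    return combos


def age_sweep_statistics(config: CohortConfig | None = None,
                         ages: np.ndarray | None = None,
                         n_levels: int = 5,
                         n_subsample: int | None = 200,
                         rng: np.random.Generator | int | None = 0,
                         settings: SimulationSettings | None = None,
                         upsample: int = 8) -> pd.DataFrame:
    """Descriptive statistics of central hemodynamics across age.

    For each age, subjects are built on a grid of equally spaced IIV levels
    (``n_levels`` per coefficient; the full ``n_levels**8`` product or a
    random subsample of it), healthy (no aneurysm), without recording noise.
    Reported per age: mean and SD of aortic systolic pressure, aortic pulse
    pressure, aortic-brachial pulse-pressure amplification, and cf-PWV.
    """
    from .hemodynamics import AneurysmSpec
    from .pvr import ViscoelasticParams
    from .cohort import SubjectParameters

    config = config or CohortConfig()
    settings = settings or SimulationSettings()
    if ages is None:
        ages = np.arange(30, 81, 5, dtype=float)
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    combos = _iiv_grid(n_levels, rng, n_subsample, config)
    base = nominal_tree()
    rows = []
    healthy = AneurysmSpec(l_aaa=1.0, a_sl=0.0, k_e=1.0, vsi=0.0)
    ve = ViscoelasticParams()
    for age_v in ages:
        sbp, pp, ppa, pwv_v = [], [], [], []
        for combo in combos:
            iiv = dict(zip(IIV_CATEGORIES, (float(c) for c in combo)))
            hr = config.hr_nominal * iiv["hr"]
            sv = config.sv_nominal * age_adjusted_nominals(age_v, config)["sv"] * iiv["sv"]
            subject = SubjectParameters(
                subject_id=0, age=age_v, iiv=iiv, hr=hr, sv=sv,
                aneurysm=healthy, viscoelastic=ve,
                height=config.height_nominal_cm * iiv["length"],
            )
            cfg0 = _zero_ssv(config)
            sample = perturb_sample(subject, rng, cfg0, base)
            rec = simulate_sample(
                sample, settings, sites=("ascending_aorta", "carotid", "brachial", "femoral")
            )
            ao = rec["bp_ascending_aorta"].samples
            br = rec["bp_brachial"].samples
            sbp.append(ao.max())
            pp.append(np.ptp(ao))
            ppa.append(np.ptp(br) / np.ptp(ao))
            path = (sample.tree.path_length_to_site("femoral")
                    - sample.tree.path_length_to_site("carotid"))
            try:
                pwv_v.append(cf_pwv(rec["bp_carotid"], rec["bp_femoral"], path,
                                    hr_hint=hr, upsample=upsample))
            except FeatureFailure:
                pwv_v.append(np.nan)
        rows.append({
            "age": age_v,
            "aortic_sbp_mean": np.mean(sbp), "aortic_sbp_sd": np.std(sbp),
            "aortic_pp_mean": np.mean(pp), "aortic_pp_sd": np.std(pp),
            "pp_amplification_mean": np.mean(ppa), "pp_amplification_sd": np.std(ppa),
            "cf_pwv_mean": np.nanmean(pwv_v), "cf_pwv_sd": np.nanstd(pwv_v),
        })
    return pd.DataFrame(rows)


def _zero_ssv(config: CohortConfig) -> CohortConfig:
    import copy as _copy

    cfg = _copy.deepcopy(config)
    cfg.ssv_cv = 0.0
    return cfg
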