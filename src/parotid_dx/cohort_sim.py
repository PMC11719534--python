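"""Synthetic parotid-tumor cohort simulation.

No per-patient data from parotid MRI studies of this kind are public, so the
package ships a generator that emulates the published group-level statistics:
normalized T2 and late post-contrast T1 signal-intensity ratios, ADC values,
prevalences of qualitative findings (ghosting sign, protein-rich cysts,
capsule, calcifications, hemorrhage, homogeneity), and the DCE curve-type
mixtures with their washout-ratio distributions.  Every downstream stage --
curve typing, the decision tree, the performance evaluation -- can therefore
be exercised end-to-end from a seed.

The four histopathological groups are:

* **PA** - pleomorphic adenoma: high normalized T2 SI (5.3 +/- 1.1), high ADC
  (2.0 +/- 0.3), curve types A and C in equal measure.
* **WT** - Warthin tumor: low late T1 SI (1.5 +/- 0.2), low ADC (0.8 +/- 0.1),
  universal ghosting sign, exclusively type-B curves with washout 64 +/- 9%.
* **OBT** - other benign tumors: a small heterogeneous remainder group; its
  quantitative distributions are not constrained by published data and the
  defaults here are deliberate, documented choices.
* **MT** - malignant tumor: low T2 SI (2.3 +/- 0.7), intermediate ADC
  (1.1 +/- 0.4), curve types B (washout 54 +/- 6%) and C.

Continuous features are sampled from normal distributions truncated at a
small positive floor (ratios and diffusivities are positive quantities);
qualitative findings are independent Bernoulli draws at the group prevalence,
except that a complete capsule is only drawn among lesions with a capsule.
DCE curves are generated from a canonical piecewise-linear enhancement model
whose extracted time-to-peak and washout reproduce the requested values
exactly in the noise-free case.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
from scipy import special

from .dce_analysis import SignalTimeCurve

__all__ = [
    "DceTiming",
    "GroupParams",
    "CohortConfig",
    "PhantomSpec",
    "LesionRecord",
    "GROUPS",
    "FEATURE_COLUMNS",
    "default_group_params",
    "sample_lesion_record",
    "generate_cohort",
    "generate_dce_series",
    "generate_phantom_slice",
]

GROUPS = ("PA", "WT", "OBT", "MT")

FINDINGS = (
    "ghosting", "protein_cysts", "capsule", "complete_capsule",
    "calcifications", "hemorrhage", "homog_t2", "homog_t1gd",
)

#: column order of the lesion feature table (CSV schema)
FEATURE_COLUMNS = (
    "lesion_id", "group",
    *FINDINGS,
    "norm_t2_si", "norm_t1_si", "adc",
    "curve_type", "peak_time_s", "washout_pct",
)


@dataclass(frozen=True)
class DceTiming:
    """Frame timing of the dynamic series.

    The default mirrors a 51-repetition acquisition at 6.6 s per frame with
    contrast injected after the first four frames, i.e. a post-injection
    observation window of about 5 minutes.
    """

    n_frames: int = 51
    frame_interval_s: float = 6.6
    n_baseline_frames: int = 4

    def __post_init__(self) -> None:
        if self.n_frames < self.n_baseline_frames + 2:
            raise ValueError("n_frames must be >= n_baseline_frames + 2")
        if self.frame_interval_s <= 0:
            raise ValueError("frame_interval_s must be > 0")
        if self.n_baseline_frames < 1:
            raise ValueError("n_baseline_frames must be >= 1")

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_frames) * self.frame_interval_s

    @property
    def injection_time_s(self) -> float:
        return self.n_baseline_frames * self.frame_interval_s

    @property
    def post_injection_window_s(self) -> float:
        """Seconds from injection to the final frame."""
        return (self.n_frames - 1 - self.n_baseline_frames) * self.frame_interval_s


@dataclass(frozen=True)
class GroupParams:
    """Sampling distribution of one histopathological group.

    SI ratios are dimensionless (lesion / masseter muscle); ADC is in units
    of 1e-3 mm^2/s; washout is in percent; peak times in seconds after
    injection.  ``prevalence`` maps each qualitative finding to its Bernoulli
    probability; ``curve_type_probs`` is a probability vector over curve
    types (A, B, C, D).
    """

    group: str
    t2_si_mean: float
    t2_si_sd: float
    t1_si_mean: float
    t1_si_sd: float
    adc_mean: float
    adc_sd: float
    prevalence: dict[str, float]
    curve_type_probs: tuple[float, float, float, float]
    washout_mean: float
    washout_sd: float
    peak_time_range: tuple[float, float] = (30.0, 120.0)

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ValueError(f"unknown group {self.group!r}")
        for name in ("t2_si_mean", "t1_si_mean", "adc_mean",
                     "t2_si_sd", "t1_si_sd", "adc_sd",
                     "washout_mean", "washout_sd"):
            v = getattr(self, name)
            if not np.isfinite(v):
                raise ValueError(f"{name} must be finite, got {v!r}")
        for name in ("t2_si_sd", "t1_si_sd", "adc_sd", "washout_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        missing = set(FINDINGS) - set(self.prevalence)
        if missing:
            raise ValueError(f"prevalence missing findings: {sorted(missing)}")
        for k, p in self.prevalence.items():
            if not (0.0 <= p <= 1.0):
                raise ValueError(f"prevalence[{k!r}]={p} outside [0, 1]")
        probs = np.asarray(self.curve_type_probs, dtype=float)
        if probs.size != 4 or np.any(probs < 0) or abs(probs.sum() - 1.0) > 1e-9:
            raise ValueError("curve_type_probs must be 4 non-negative values summing to 1")
        lo, hi = self.peak_time_range
        if not (0 < lo < hi):
            raise ValueError("peak_time_range must satisfy 0 < lo < hi")


def default_group_params() -> dict[str, GroupParams]:
    """Default group parameters reproducing the published cohort statistics.

    PA/WT/MT means, SDs, prevalences and curve-type mixtures follow the
    published group summaries (n = 14 / 10 / 8).  The OBT group (n = 4:
    canalicular adenoma, myoepithelioma, oncocytoma, reactive lymph node) has
    no published quantitative summaries; its defaults are loosely constrained
    stand-ins chosen to sit between the benign groups, with the curve-type
    mixture (one A, two B, one C) taken from the reported per-lesion typing.
    """
    return {
        "PA": GroupParams(
            group="PA",
            t2_si_mean=5.3, t2_si_sd=1.1,
            t1_si_mean=2.6, t1_si_sd=0.2,
            adc_mean=2.0, adc_sd=0.3,
            prevalence={
                "ghosting": 0.0,
                "protein_cysts": 5 / 14,
                "capsule": 13 / 14,
                "complete_capsule": 10 / 14,
                "calcifications": 6 / 14,
                "hemorrhage": 8 / 14,
                "homog_t2": 11 / 14,
                "homog_t1gd": 8 / 14,
            },
            curve_type_probs=(0.5, 0.0, 0.5, 0.0),  # 7 A + 7 C of 14
            washout_mean=15.0, washout_sd=8.0,  # type-C washouts; unreported
        ),
        "WT": GroupParams(
            group="WT",
            t2_si_mean=2.4, t2_si_sd=0.4,
            t1_si_mean=1.5, t1_si_sd=0.2,
            adc_mean=0.8, adc_sd=0.1,
            prevalence={
                "ghosting": 1.0,
                "protein_cysts": 1.0,
                "capsule": 9 / 10,
                "complete_capsule": 0.0,
                "calcifications": 1.0,
                "hemorrhage": 7 / 10,
                "homog_t2": 0.0,
                "homog_t1gd": 1.0,
            },
            curve_type_probs=(0.0, 1.0, 0.0, 0.0),  # all 10 type B
            washout_mean=64.0, washout_sd=9.0,
        ),
        "OBT": GroupParams(
            group="OBT",
            t2_si_mean=3.5, t2_si_sd=1.2,
            t1_si_mean=2.2, t1_si_sd=0.5,
            adc_mean=1.4, adc_sd=0.4,
            prevalence={
                "ghosting": 0.0,
                "protein_cysts": 0.25,
                "capsule": 0.5,
                "complete_capsule": 0.25,
                "calcifications": 0.25,
                "hemorrhage": 0.25,
                "homog_t2": 0.5,
                "homog_t1gd": 0.5,
            },
            curve_type_probs=(0.25, 0.5, 0.25, 0.0),  # 1 A + 2 B + 1 C of 4
            washout_mean=45.0, washout_sd=15.0,
        ),
        "MT": GroupParams(
            group="MT",
            t2_si_mean=2.3, t2_si_sd=0.7,
            t1_si_mean=2.5, t1_si_sd=0.4,
            adc_mean=1.1, adc_sd=0.4,
            prevalence={
                "ghosting": 0.0,
                "protein_cysts": 3 / 8,
                "capsule": 3 / 8,
                "complete_capsule": 1 / 8,
                "calcifications": 6 / 8,
                "hemorrhage": 5 / 8,
                "homog_t2": 2 / 8,
                "homog_t1gd": 1 / 8,
            },
            curve_type_probs=(0.0, 0.25, 0.75, 0.0),  # 2 B + 6 C of 8
            washout_mean=54.0, washout_sd=6.0,
        ),
    }


@dataclass(frozen=True)
class CohortConfig:
    """Full configuration of a synthetic cohort draw."""

    n_per_group: dict[str, int] = field(
        default_factory=lambda: {"PA": 14, "WT": 10, "OBT": 4, "MT": 8})
    seed: int = 0
    group_params: dict[str, GroupParams] = field(default_factory=default_group_params)
    dce_timing: DceTiming = field(default_factory=DceTiming)
    noise_sd: float = 0.0  # per-frame DCE signal noise, arbitrary units
    ratio_floor: float = 0.1  # truncation floor for SI ratios and ADC

    def __post_init__(self) -> None:
        for g, n in self.n_per_group.items():
            if g not in GROUPS:
                raise ValueError(f"unknown group {g!r}")
            if n < 0:
                raise ValueError(f"negative count for group {g!r}")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.ratio_floor <= 0:
            raise ValueError("ratio_floor must be > 0")


@dataclass(frozen=True)
class LesionRecord:
    """One simulated patient-lesion with its ground-truth group."""

    lesion_id: str
    group: str
    ghosting: bool
    protein_cysts: bool
    capsule: bool
    complete_capsule: bool
    calcifications: bool
    hemorrhage: bool
    homog_t2: bool
    homog_t1gd: bool
    norm_t2_si: float
    norm_t1_si: float
    adc: float
    curve_type: str
    peak_time_s: float   # NaN for type D
    washout_pct: float   # NaN for types A is defined, D undefined


def _truncnorm(mean: float, sd: float, lo: float, hi: float,
               rng: np.random.Generator, size=None):
    """Normal(mean, sd) truncated to [lo, hi]; degenerate sd=0 -> mean.

    Sampled by inverse-CDF transform (exact, and cheap per scalar draw,
    which matters when cohorts are drawn record by record).
    """
    if sd == 0:
        value = min(max(mean, lo), hi)
        return value if size is None else np.full(size, value)
    a = special.ndtr((lo - mean) / sd)
    b = special.ndtr((hi - mean) / sd)
    u = rng.uniform(a, b, size=size)
    return mean + sd * special.ndtri(u)


# washout-ratio interval compatible with each generated curve type, so that
# a noise-free curve always round-trips to its configured type
_WASHOUT_BOUNDS = {"A": (0.0, 100.0), "B": (30.0, 100.0), "C": (0.0, 30.0)}


def sample_lesion_record(
    params: GroupParams,
    rng: np.random.Generator,
    *,
    lesion_id: str = "L0",
    ratio_floor: float = 0.1,
    timing: DceTiming = DceTiming(),
) -> LesionRecord:
    """Draw one lesion from a group's configured distributions.

    Quantitative ratios come from truncated normals (floor ``ratio_floor``);
    findings are independent Bernoulli draws except that a complete capsule
    is drawn conditionally among capsule-positive lesions.  The curve type is
    drawn from ``curve_type_probs``; the washout ratio is drawn from the
    group washout distribution truncated to the interval compatible with the
    drawn type (>= 30% for B, < 30% for C).
    """
    t2 = float(_truncnorm(params.t2_si_mean, params.t2_si_sd, ratio_floor, np.inf, rng))
    t1 = float(_truncnorm(params.t1_si_mean, params.t1_si_sd, ratio_floor, np.inf, rng))
    adc = float(_truncnorm(params.adc_mean, params.adc_sd, ratio_floor, np.inf, rng))

    prev = params.prevalence
    draws = {f: bool(rng.random() < prev[f]) for f in FINDINGS
             if f != "complete_capsule"}
    # a complete capsule implies a capsule; condition the draw accordingly
    if draws["capsule"] and prev["capsule"] > 0:
        p_complete = min(prev["complete_capsule"] / prev["capsule"], 1.0)
        draws["complete_capsule"] = bool(rng.random() < p_complete)
    else:
        draws["complete_capsule"] = False

    curve_type = str(rng.choice(CURVE_TYPE_LABELS, p=params.curve_type_probs))
    if curve_type == "D":
        peak_time = float("nan")
        washout = float("nan")
    else:
        if curve_type == "A":
            lo = max(120.0, params.peak_time_range[0])
            hi = timing.post_injection_window_s - timing.frame_interval_s
            if hi <= lo:
                raise ValueError("acquisition window too short for a type-A peak")
            peak_time = float(rng.uniform(lo, hi))
        else:
            lo, hi = params.peak_time_range
            peak_time = float(rng.uniform(lo, min(hi, 120.0)))
        w_lo, w_hi = _WASHOUT_BOUNDS[curve_type]
        washout = float(_truncnorm(params.washout_mean, params.washout_sd,
                                   w_lo, w_hi, rng))

    return LesionRecord(
        lesion_id=lesion_id, group=params.group,
        norm_t2_si=t2, norm_t1_si=t1, adc=adc,
        curve_type=curve_type, peak_time_s=peak_time, washout_pct=washout,
        **draws,
    )


CURVE_TYPE_LABELS = ("A", "B", "C", "D")


def generate_cohort(config: CohortConfig) -> "pandas.DataFrame":
    """Generate a lesion feature table with the requested per-group counts.

    Returns a DataFrame in the fixed :data:`FEATURE_COLUMNS` order, with the
    ground-truth group label retained.  Fixed seed implies an identical
    table.  Each group draws from its own seeded substream, so adding a
    group never perturbs the others.
    """
    import pandas as pd

    root = np.random.SeedSequence(config.seed)
    records: list[LesionRecord] = []
    idx = 0
    for gi, group in enumerate(GROUPS):
        n = config.n_per_group.get(group, 0)
        if n == 0:
            continue
        params = config.group_params[group]
        rng = np.random.Generator(np.random.PCG64(root.spawn(gi + 1)[0]))
        for _ in range(n):
            records.append(sample_lesion_record(
                params, rng, lesion_id=f"{group}-{idx:04d}",
                ratio_floor=config.ratio_floor, timing=config.dce_timing))
            idx += 1
    df = pd.DataFrame([dataclasses.asdict(r) for r in records],
                      columns=list(FEATURE_COLUMNS))
    return df


def generate_dce_series(
    curve_type: str,
    peak_time_s: float,
    washout_pct: float,
    baseline_si: float,
    amplitude: float,
    timing: DceTiming = DceTiming(),
    noise_sd: float = 0.0,
    rng: np.random.Generator | None = None,
) -> SignalTimeCurve:
    """Generate a canonical piecewise-linear S(t) curve of a given type.

    The model is flat at ``baseline_si`` before injection, rises linearly to
    ``baseline_si + amplitude`` at the peak, then decays linearly so that the
    washout ratio at the final frame equals ``washout_pct``.  The requested
    peak time is snapped to the nearest acquisition frame (the signal only
    exists at frame times), adjusted if necessary so the snapped peak stays
    on the correct side of the 120 s type boundary; noise-free curves
    therefore round-trip exactly through feature extraction.  Type D emits
    baseline-only signal.  Gaussian noise of ``noise_sd`` is added per frame.
    """
    times = timing.times
    n0 = timing.n_baseline_frames
    if curve_type not in CURVE_TYPE_LABELS:
        raise ValueError(f"unknown curve type {curve_type!r}")
    if baseline_si <= 0:
        raise ValueError("baseline_si must be > 0")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")

    if curve_type == "D":
        signal = np.full(timing.n_frames, float(baseline_si))
    else:
        if amplitude <= 0:
            raise ValueError("amplitude must be > 0 for curve types A-C")
        if not np.isfinite(peak_time_s) or peak_time_s <= 0:
            raise ValueError("peak_time_s must be > 0 for curve types A-C")
        if not (0.0 <= washout_pct <= 100.0):
            raise ValueError("washout_pct must lie in [0, 100]")
        if peak_time_s >= timing.post_injection_window_s:
            raise ValueError(
                "peak_time_s must fall inside the post-injection window "
                f"(< {timing.post_injection_window_s:g} s)"
            )
        inj = timing.injection_time_s
        # snap the peak to the frame grid, keeping >= 1 decay frame after it
        peak_idx = int(round((inj + peak_time_s) / timing.frame_interval_s))
        peak_idx = min(max(peak_idx, n0 + 1), timing.n_frames - 2)
        # keep the snapped peak on the requested side of the A/B-C boundary
        if curve_type == "A":
            while times[peak_idx] - inj <= 120.0:
                peak_idx += 1
            if peak_idx > timing.n_frames - 2:
                raise ValueError("acquisition window too short for a type-A peak")
        else:
            while times[peak_idx] - inj > 120.0 and peak_idx > n0 + 1:
                peak_idx -= 1
        t_peak = times[peak_idx]
        peak_si = baseline_si + amplitude
        end_si = peak_si - washout_pct / 100.0 * amplitude
        signal = np.interp(
            times,
            [inj, t_peak, times[-1]],
            [baseline_si, peak_si, end_si],
            left=baseline_si,
        )
    if noise_sd > 0:
        if rng is None:
            raise ValueError("rng is required when noise_sd > 0")
        signal = signal + rng.normal(0.0, noise_sd, size=signal.size)
    return SignalTimeCurve(times, signal, n0)


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry of a synthetic 2-D image slice for ROI measurement.

    A uniform "gland" background contains an elliptical lesion and a
    rectangular masseter-muscle patch.  This is artifact plumbing, a
    synthetic stand-in for ROI measurement on real images; it models no MR
    physics.  Intensities are arbitrary units; geometry in pixels.
    """

    shape: tuple[int, int] = (128, 128)
    pixel_spacing_mm: float = 0.5
    lesion_center: tuple[float, float] = (48.0, 48.0)
    lesion_axes: tuple[float, float] = (18.0, 14.0)
    lesion_intensity: float = 450.0
    masseter_corner: tuple[int, int] = (88, 80)
    masseter_size: tuple[int, int] = (24, 32)
    masseter_intensity: float = 180.0
    background_intensity: float = 250.0
    noise_sd: float = 0.0

    def __post_init__(self) -> None:
        if self.pixel_spacing_mm <= 0:
            raise ValueError("pixel_spacing_mm must be > 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        r, c = self.lesion_center
        ar, ac = self.lesion_axes
        if ar <= 0 or ac <= 0:
            raise ValueError("lesion axes must be > 0")
        if (r - ar < 0 or r + ar >= self.shape[0]
                or c - ac < 0 or c + ac >= self.shape[1]):
            raise ValueError("lesion ellipse exceeds image bounds")
        mr, mc = self.masseter_corner
        mh, mw = self.masseter_size
        if mh <= 0 or mw <= 0:
            raise ValueError("masseter size must be > 0")
        if mr < 0 or mc < 0 or mr + mh > self.shape[0] or mc + mw > self.shape[1]:
            raise ValueError("masseter rectangle exceeds image bounds")


def generate_phantom_slice(
    spec: PhantomSpec,
    rng: np.random.Generator | None = None,
) -> tuple[np.ndarray, dict[str, np.ndarray]]:
    """Render a phantom slice and return (image, region masks).

    Pixels inside the lesion ellipse are N(lesion_intensity, noise_sd);
    the masseter rectangle and background likewise with their intensities.
    Raises if the two regions overlap.
    """
    from skimage.draw import ellipse

    lesion_mask = np.zeros(spec.shape, dtype=bool)
    rr, cc = ellipse(*spec.lesion_center, *spec.lesion_axes, shape=spec.shape)
    lesion_mask[rr, cc] = True

    masseter_mask = np.zeros(spec.shape, dtype=bool)
    mr, mc = spec.masseter_corner
    mh, mw = spec.masseter_size
    masseter_mask[mr:mr + mh, mc:mc + mw] = True

    if np.any(lesion_mask & masseter_mask):
        raise ValueError("lesion and masseter regions overlap")

    image = np.full(spec.shape, float(spec.background_intensity))
    image[lesion_mask] = spec.lesion_intensity
    image[masseter_mask] = spec.masseter_intensity
    if spec.noise_sd > 0:
        if rng is None:
            raise ValueError("rng is required when noise_sd > 0")
        image = image + rng.normal(0.0, spec.noise_sd, size=spec.shape)
    return image, {"lesion": lesion_mask, "masseter": masseter_mask}
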