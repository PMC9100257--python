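"""Synthetic paired insole-pressure / center-of-gravity gait data.

Real insole recordings with optical-motion-capture ground truth are not
publicly available, so this module generates surrogate gait cycles with the
structure the estimation protocol assumes:

* a gait-event schedule (right heel strike, left toe-off, right mid-stance,
  left heel strike, left mid-stance) on the 100-frame normalized cycle;
* an 18-channel plantar-pressure trace (9 sensors per foot) built from
  smooth per-sensor activation bumps sequenced rear -> mid -> forefoot over
  each stance phase, scaled so the summed peak force is ~1.1 x body weight;
* a 3-axis CG trajectory phase-locked to the events: a double-bump vertical
  (proximal/distal) curve peaking at the two mid-stance events, a single
  medial/lateral oscillation with a subject-specific peak-to-valley range,
  and a monotone anterior/posterior advance;
* young vs. old group structure in the medial/lateral and proximal/distal
  sway amplitudes, with the old group swaying more on both axes.

Group amplitude defaults are the reference (motion-capture) values reported
for healthy young and elderly male cohorts: medial/lateral peak-to-valley
45.25 +/- 2.53 mm (young) and 64.32 +/- 2.87 mm (old); proximal/distal
41.36 +/- 2.11 mm (young) and 46.84 +/- 2.72 mm (old).

Raw trials are sampled at 100 samples/s with natural cycle durations of
~1.0-1.2 s and then go through the ordinary preprocessing path (filtering,
time normalization, amplitude normalization).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict, replace
from pathlib import Path
from typing import Sequence

import numpy as np

__all__ = [
    "GaitEventSchedule",
    "SubjectProfile",
    "SyntheticTrial",
    "GeneratorConfig",
    "GROUP_DEFAULTS",
    "generate_trial",
    "generate_cohort",
    "write_trials",
    "read_trials",
]

#: Default gait-event frames on the 100-frame cycle (standard gait
#: proportions: ~12% double support, mid-stance near 30%/80%).
DEFAULT_EVENTS = dict(lto_frame=12, r_midstance_frame=30, lhs_frame=50,
                      l_midstance_frame=80)

#: Per-group generator defaults: CG sway amplitudes (mm, mean and sd of the
#: subject-level draw), body weight (kg), height (cm, used for leg length)
#: and walking speed (m/s).
GROUP_DEFAULTS = {
    "young": dict(ml_pv_mean=45.25, ml_pv_sd=2.53,
                  pd_pv_mean=41.36, pd_pv_sd=2.11,
                  weight_mean=69.59, weight_sd=6.13,
                  height_mean=172.28, height_sd=6.71,
                  speed_mean=1.41, speed_sd=0.05),
    "old": dict(ml_pv_mean=64.32, ml_pv_sd=2.87,
                pd_pv_mean=46.84, pd_pv_sd=2.72,
                weight_mean=65.76, weight_sd=5.86,
                height_mean=168.24, height_sd=5.59,
                speed_mean=1.41, speed_sd=0.05),
}

GRAVITY = 9.81  # m/s^2

# Per-sensor stance-time activation: (center, width, amplitude) in
# stance-normalized time. Ordering is sensor 1..9 = two heel sensors, two
# midfoot sensors, four metatarsal-head sensors, hallux: heel sensors fire
# earliest, the hallux last (heel strike -> mid stance -> push-off).
_SENSOR_BUMPS = (
    (0.15, 0.16, 1.00),  # s1 medial heel
    (0.18, 0.16, 0.90),  # s2 lateral heel
    (0.38, 0.18, 0.45),  # s3 medial midfoot
    (0.42, 0.18, 0.40),  # s4 lateral midfoot
    (0.62, 0.16, 0.75),  # s5 metatarsal I
    (0.66, 0.16, 0.85),  # s6 metatarsal II
    (0.70, 0.16, 0.80),  # s7 metatarsal III
    (0.72, 0.16, 0.60),  # s8 metatarsal IV-V
    (0.84, 0.13, 0.70),  # s9 hallux
)


@dataclass(frozen=True)
class GaitEventSchedule:
    """Gait-event frames on the 100-frame normalized cycle.

    Frame 0 is right heel strike (RHS) and frame 100 the next RHS. Left
    toe-off (LTO) ends the first double support; right and left mid-stance
    coincide with the two vertical-CG peaks; left heel strike (LHS) starts
    the second double support. Right toe-off (RTO) is not stored: it is
    derived as ``lhs_frame + lto_frame`` (symmetric double support).
    """

    lto_frame: int = DEFAULT_EVENTS["lto_frame"]
    r_midstance_frame: int = DEFAULT_EVENTS["r_midstance_frame"]
    lhs_frame: int = DEFAULT_EVENTS["lhs_frame"]
    l_midstance_frame: int = DEFAULT_EVENTS["l_midstance_frame"]
    rhs_frame: int = 0
    cycle_end: int = 100

    def __post_init__(self) -> None:
        ok = (self.rhs_frame == 0 and self.cycle_end == 100
              and 0 < self.lto_frame < self.r_midstance_frame
              < self.lhs_frame < self.l_midstance_frame < 100)
        if not ok:
            raise ValueError(f"invalid gait event schedule: {self}")

    @property
    def rto_frame(self) -> int:
        """Right toe-off, assuming both double supports last equally long."""
        return self.lhs_frame + self.lto_frame


@dataclass(frozen=True)
class SubjectProfile:
    """Anthropometrics and sway amplitudes of one simulated subject."""

    subject_id: str
    group: str  # "young" | "old"
    weight: float  # kg
    leg_length: float  # mm
    ml_pv_amplitude: float  # medial/lateral peak-to-valley, mm
    pd_pv_amplitude: float  # proximal/distal peak-to-valley, mm
    walking_speed: float = 1.41  # m/s
    seed: int = 0

    def __post_init__(self) -> None:
        if self.group not in ("young", "old"):
            raise ValueError(f"unknown group {self.group!r}")
        if min(self.weight, self.leg_length, self.ml_pv_amplitude,
               self.pd_pv_amplitude, self.walking_speed) <= 0:
            raise ValueError(f"non-positive anthropometric in {self}")


@dataclass(frozen=True)
class GeneratorConfig:
    """Noise and timing knobs of the synthetic-gait generator."""

    pressure_noise_frac: float = 0.02  # Gaussian sd as fraction of peak force
    cg_noise_mm: float = 0.3  # white measurement noise on CG markers
    event_jitter: int = 3  # per-trial integer jitter on event frames
    min_raw_frames: int = 90  # clip for ~0.9 s cycles at 100 samples/s
    max_raw_frames: int = 130  # clip for ~1.3 s cycles
    peak_load_factor: float = 1.1  # summed peak force / body-weight force
    sample_rate_hz: float = 100.0


@dataclass(frozen=True)
class SyntheticTrial:
    """One raw gait cycle: pressures (N), global-frame CG (mm), metadata."""

    pressures: np.ndarray  # (n_raw, 18); columns = left s1..s9, right s1..s9
    cg_global: np.ndarray  # (n_raw, 3) in lab frame, mm
    events: GaitEventSchedule  # on the normalized 100-frame cycle
    profile: SubjectProfile
    heading_deg: float = 0.0  # walking direction in the lab x-y plane
    trial_id: str = ""


def _jittered_schedule(rng: np.random.Generator, jitter: int) -> GaitEventSchedule:
    """Default schedule with bounded integer jitter on the contact events.

    Left toe-off and left heel strike jitter independently; the mid-stance
    events are derived as the midpoint of each foot's single support, so
    both fall at stance fraction 1/2 of the respective foot. Mid-stance is
    thereby a deterministic function of the contact timing the pressures
    encode — without this coupling the phase boundaries (and the CG curve
    anchored to them) would not be recoverable from pressure input.
    """
    lto = int(DEFAULT_EVENTS["lto_frame"] + rng.integers(-jitter, jitter + 1))
    lhs = int(DEFAULT_EVENTS["lhs_frame"] + rng.integers(-jitter, jitter + 1))
    r_mid = int(round((lto + lhs) / 2.0))
    l_mid = int(round((lhs + (100 + lto)) / 2.0))  # rto = lhs + lto
    return GaitEventSchedule(lto_frame=lto, r_midstance_frame=r_mid,
                             lhs_frame=lhs, l_midstance_frame=l_mid)


def _anchored_cosine(phi: np.ndarray, anchors: Sequence[tuple[float, float]]) -> np.ndarray:
    """Piecewise-cosine interpolation through (frame, value) anchors.

    The derivative vanishes at every anchor, so interior anchors are the
    exact local extrema of the curve.
    """
    out = np.empty_like(phi)
    for (fa, va), (fb, vb) in zip(anchors[:-1], anchors[1:]):
        sel = (phi >= fa) & (phi <= fb)
        s = (phi[sel] - fa) / (fb - fa)
        out[sel] = va + (vb - va) * 0.5 * (1.0 - np.cos(np.pi * s))
    return out


def _stance_fraction(phi: np.ndarray, start: float, end: float) -> np.ndarray:
    """Stance-normalized time in [0, 1]; NaN outside stance.

    ``start``/``end`` are normalized frames; ``end`` may exceed 100 to
    describe the left stance wrapping around the cycle boundary.
    """
    length = end - start
    rel = np.mod(phi - start, 100.0)
    s = rel / length
    s[rel > length] = np.nan
    return s


def _foot_pressures(s: np.ndarray, amp_scale: np.ndarray) -> np.ndarray:
    """Per-sensor activation over stance-normalized time ``s`` (9 columns)."""
    out = np.zeros((s.size, 9))
    active = ~np.isnan(s)
    sa = s[active]
    envelope = np.sqrt(np.sin(np.pi * np.clip(sa, 0.0, 1.0)))
    for k, (c, w, a) in enumerate(_SENSOR_BUMPS):
        bump = a * amp_scale[k] * np.exp(-0.5 * ((sa - c) / w) ** 2)
        out[active, k] = bump * envelope
    return out


def generate_trial(
    profile: SubjectProfile,
    trial_seed: int,
    n_raw_frames: int | None = None,
    config: GeneratorConfig = GeneratorConfig(),
) -> SyntheticTrial:
    """Generate one raw gait cycle for ``profile``.

    The trial is sampled on ``n_raw_frames`` points spanning the normalized
    cycle (frame 0 = right heel strike), so that time normalization to 100
    frames places the gait events at their scheduled frames. Pressures and
    CG are deterministic functions of the profile and the event schedule;
    configured noise is added on top.
    """
    # Stride length follows the subject: a leg-length multiple with a mild
    # vertical-sway component (more vaulting, longer step). Cycle duration
    # is stride / speed. Keeping stride a deterministic function of
    # quantities the pressures encode makes the leg-length-normalized CG a
    # well-defined function of the pressure input (the learnability
    # invariant); independent per-trial durations would put irreducible
    # noise on the anterior/posterior target.
    pd_norm = profile.pd_pv_amplitude / profile.leg_length
    stride_mm = (1.55 + 2.0 * pd_norm) * profile.leg_length
    if n_raw_frames is None:
        duration_s = stride_mm / (1000.0 * profile.walking_speed)
        n_raw_frames = int(np.clip(round(config.sample_rate_hz * duration_s),
                                   config.min_raw_frames,
                                   config.max_raw_frames))
    if n_raw_frames < 50:
        raise ValueError("n_raw_frames must be >= 50 (half a second of gait)")
    rng = np.random.default_rng(trial_seed + 1)
    events = _jittered_schedule(rng, config.event_jitter)

    # The raw recording spans the same continuous interval as the 100
    # normalized samples ([0, 99] in normalized-frame units), so linear
    # resampling maps raw sample j to phi = 99 j / (n_raw - 1).
    phi = np.linspace(0.0, 99.0, n_raw_frames)

    # --- CG trajectory (lab frame aligned with gait axes, mm) -------------
    ap = stride_mm * phi / 100.0
    ap = ap + 0.0033 * profile.leg_length * np.sin(2.0 * np.pi * phi / 50.0)
    ml = 0.5 * profile.ml_pv_amplitude * np.cos(
        2.0 * np.pi * (phi - events.r_midstance_frame) / 100.0
    )
    z0 = 0.55 * profile.leg_length  # nominal CG height above ground
    half = 0.5 * profile.pd_pv_amplitude
    pd = _anchored_cosine(phi, [
        (0.0, z0 - half),
        (float(events.r_midstance_frame), z0 + half),
        (float(events.lhs_frame), z0 - half),
        (float(events.l_midstance_frame), z0 + half),
        (99.0 + 1e-9, z0 - half),
    ])
    cg_gait = np.column_stack([ap, ml, pd])

    # --- plantar pressures (N) -------------------------------------------
    # Subject-specific loading pattern: medial/lateral sensor balance and
    # forefoot emphasis are deterministic functions of the leg-length-
    # normalized sway amplitudes, so the normalized-CG targets the model
    # learns are a well-defined function of the pressure input.
    ml_dev = profile.ml_pv_amplitude / profile.leg_length / 0.055 - 1.0
    pd_dev = pd_norm / 0.048 - 1.0
    medial = np.array([1, 0, 1, 0, 1, 1, 0, 0, 1], dtype=float)
    fore = np.array([0, 0, 0, 0, 1, 1, 1, 1, 1], dtype=float)
    right_scale = (1.0 + 0.5 * ml_dev * (medial - 0.5)) * (1.0 + 0.6 * pd_dev * (fore - 0.5))
    left_scale = (1.0 - 0.5 * ml_dev * (medial - 0.5)) * (1.0 + 0.6 * pd_dev * (fore - 0.5))

    s_right = _stance_fraction(phi, 0.0, float(events.rto_frame))
    # Left stance spans LHS -> next LTO, i.e. length (100 - lhs) + lto.
    s_left = _stance_fraction(phi, float(events.lhs_frame),
                              100.0 + float(events.lto_frame))
    right = _foot_pressures(s_right, right_scale)
    left = _foot_pressures(s_left, left_scale)
    pressures = np.hstack([left, right])

    body_force = profile.weight * GRAVITY
    peak = pressures.sum(axis=1).max()
    pressures *= config.peak_load_factor * body_force / peak

    # --- measurement noise -----------------------------------------------
    if config.pressure_noise_frac > 0:
        sigma = config.pressure_noise_frac * pressures.max()
        pressures = pressures + rng.normal(0.0, sigma, size=pressures.shape)
        np.clip(pressures, 0.0, None, out=pressures)
    if config.cg_noise_mm > 0:
        cg_gait = cg_gait + rng.normal(0.0, config.cg_noise_mm,
                                       size=cg_gait.shape)

    # --- place in the lab frame ------------------------------------------
    heading = float(rng.uniform(-10.0, 10.0))
    th = np.radians(heading)
    rot = np.array([[np.cos(th), -np.sin(th), 0.0],
                    [np.sin(th), np.cos(th), 0.0],
                    [0.0, 0.0, 1.0]])
    offset = np.array([1000.0, 500.0, 0.0])
    cg_global = cg_gait @ rot.T + offset

    return SyntheticTrial(pressures=pressures, cg_global=cg_global,
                          events=events, profile=profile,
                          heading_deg=heading,
                          trial_id=f"{profile.subject_id}_t{trial_seed}")


def _draw_profile(rng: np.random.Generator, group: str, subject_id: str,
                  seed: int) -> SubjectProfile:
    d = GROUP_DEFAULTS[group]
    weight = max(40.0, rng.normal(d["weight_mean"], d["weight_sd"]))
    height_cm = rng.normal(d["height_mean"], d["height_sd"])
    leg_length = max(600.0, 0.53 * height_cm * 10.0)  # mm, standard ratio
    return SubjectProfile(
        subject_id=subject_id,
        group=group,
        weight=weight,
        leg_length=leg_length,
        ml_pv_amplitude=max(5.0, rng.normal(d["ml_pv_mean"], d["ml_pv_sd"])),
        pd_pv_amplitude=max(5.0, rng.normal(d["pd_pv_mean"], d["pd_pv_sd"])),
        walking_speed=max(0.5, rng.normal(d["speed_mean"], d["speed_sd"])),
        seed=seed,
    )


def generate_cohort(
    n_young: int,
    n_old: int,
    trials_per_subject: int,
    seed: int,
    config: GeneratorConfig = GeneratorConfig(),
) -> list[SyntheticTrial]:
    """Generate a two-group cohort of raw gait trials, deterministically.

    Subject amplitudes are drawn from the group defaults; each subject
    contributes ``trials_per_subject`` cycles with independent event jitter
    and noise. Trials are ordered subject-major, young group first.
    """
    if min(n_young, n_old, trials_per_subject) < 1:
        raise ValueError("cohort counts must all be >= 1")
    ss = np.random.SeedSequence(seed)
    subj_seeds = ss.spawn(n_young + n_old)
    trials: list[SyntheticTrial] = []
    groups = ["young"] * n_young + ["old"] * n_old
    for i, (group, sseq) in enumerate(zip(groups, subj_seeds)):
        rng = np.random.default_rng(sseq)
        subject_seed = int(rng.integers(0, 2**31 - 1))
        profile = _draw_profile(rng, group, f"{group}{i:02d}", subject_seed)
        for j in range(trials_per_subject):
            trial_seed = int(rng.integers(0, 2**31 - 1))
            trial = generate_trial(profile, trial_seed, config=config)
            trials.append(replace(trial,
                                  trial_id=f"{profile.subject_id}_t{j}"))
    return trials


# --- on-disk trial format ------------------------------------------------

_PRESSURE_COLS = [f"{foot}_s{k}" for foot in ("L", "R") for k in range(1, 10)]
_CG_COLS = ["cg_x_mm", "cg_y_mm", "cg_z_mm"]


def write_trials(trials: Sequence[SyntheticTrial], outdir: str | Path) -> Path:
    """Write trials as per-trial CSV files plus a JSON manifest.

    Floats are written with repr-exact precision so that
    :func:`read_trials` round-trips bit-identically.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = []
    for trial in trials:
        fname = f"{trial.trial_id}.csv"
        data = np.hstack([trial.pressures, trial.cg_global])
        header = "frame," + ",".join(_PRESSURE_COLS + _CG_COLS)
        rows = np.column_stack([np.arange(len(data)), data])
        fmt = ["%d"] + ["%.17g"] * data.shape[1]
        np.savetxt(outdir / fname, rows, fmt=fmt, delimiter=",",
                   header=header, comments="")
        entry = {
            "file": fname,
            "trial_id": trial.trial_id,
            "heading_deg": trial.heading_deg,
            "events": asdict(trial.events),
            "profile": asdict(trial.profile),
        }
        manifest.append(entry)
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return outdir


def read_trials(indir: str | Path) -> list[SyntheticTrial]:
    """Read back a trial directory written by :func:`write_trials`."""
    indir = Path(indir)
    manifest = json.loads((indir / "manifest.json").read_text())
    trials = []
    for entry in manifest:
        raw = np.loadtxt(indir / entry["file"], delimiter=",", skiprows=1)
        trials.append(SyntheticTrial(
            pressures=raw[:, 1:19],
            cg_global=raw[:, 19:22],
            events=GaitEventSchedule(**entry["events"]),
            profile=SubjectProfile(**entry["profile"]),
            heading_deg=entry["heading_deg"],
            trial_id=entry["trial_id"],
        ))
    return trials
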