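"""Ground-truth synthetic data: full-body IMU recordings and cohort tables.

Every stochastic component draws from its own named random sub-stream
derived from the scenario seed, so changing one component's amplitude never
perturbs another component's draws — recordings are additive across
components under a fixed seed, and all outputs are deterministic.

Signal components:

* voluntary movement — minimum-jerk velocity bursts on the arm sensors plus
  low-pass (< 1.5 Hz) smoothed noise everywhere;
* tremor — a slowly amplitude-modulated tone at a configurable frequency in
  3.5–7.5 Hz on the hand gyroscopes;
* dyskinesia — 0.5–4 Hz band-passed Gaussian gyro noise per sensor, with an
  AR(1)-coupled 1 s amplitude envelope travelling across adjacent body
  segments to emulate the flowing character of chorea;
* gait — a locomotor tone (~2 Hz) riding on gravity on the gait sensors'
  accelerometers, replaced inside freeze episodes by 3–8 Hz narrow-band
  trembling with no forward locomotion;
* white sensor noise on every channel.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal as sps

from .core import Recording, SensorLayout, default_layout

GRAVITY = 9.81

#: AR(1) coefficient coupling segment envelopes across 1 s steps (emulation
#: choice for choreic "flow", not a measured quantity).
LID_FLOW_AR = 0.6

_SEGMENT_CHAIN = ("head", "trunk", "arm_l", "arm_r", "leg_l", "leg_r")


def component_rng(seed: int, name: str) -> np.random.Generator:
    """Deterministic, platform-stable RNG for a named component stream."""
    digest = hashlib.sha256(name.encode()).digest()
    key = int.from_bytes(digest[:8], "big")
    return np.random.default_rng(np.random.SeedSequence([int(seed), key]))


# ---------------------------------------------------------------------------
# Scenarios
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RecordingScenario:
    seed: int = 0
    duration_s: float = 30.0
    rate_hz: float = 32.0
    voluntary_amp: float = 0.0      # deg/s RMS of low-frequency movement
    n_reach_bursts: int = 0
    tremor_amp: float = 0.0         # deg/s tone amplitude on each hand
    tremor_freq_hz: float = 5.0
    lid_rms: float = 0.0            # deg/s RMS of dyskinetic noise per sensor
    locomotor_amp: float = 0.0      # m/s^2 amplitude of the gait tone
    locomotor_freq_hz: float = 2.0
    freeze_amp: float = 0.0         # m/s^2 RMS of freeze trembling
    fog_episodes: tuple[tuple[float, float], ...] = ()
    noise_sd: float = 0.02

    def __post_init__(self) -> None:
        if self.rate_hz < 2.0 * max(8.0, self.tremor_freq_hz):
            raise ValueError("sampling rate below twice the highest component frequency")
        for lo, hi in self.fog_episodes:
            if not 0 <= lo < hi <= self.duration_s:
                raise ValueError(f"freeze episode ({lo}, {hi}) outside recording")


@dataclass(frozen=True)
class CohortScenario:
    seed: int = 0
    n_controls: int = 30
    n_patients: int = 60
    tasks: tuple[str, ...] = ("eating_soup", "TUG")
    #: symptom -> (control mean, control sd, patient mean, patient sd)
    symptoms: dict = field(default_factory=lambda: {
        "lid_level": (0.1, 0.05, 3.0, 1.5),
        "tremor_level": (0.05, 0.02, 1.0, 0.8),
        "bradykinesia_level": (250.0, 30.0, 160.0, 40.0),
        "rigidity": (0.0, 0.0, 1.5, 0.8),
        "postural_instability": (0.0, 0.0, 1.2, 0.9),
        "fog_pct": (0.0, 0.0, 3.0, 4.0),
        "age": (68.0, 8.0, 67.0, 9.0),
        "mmse": (28.5, 1.5, 27.0, 2.5),
    })
    #: logistic success model: intercept + per-symptom coefficients
    success_intercept: float = 0.0
    success_betas: dict = field(default_factory=dict)
    #: linear time model (base, per-symptom coefs, noise sd)
    time_base_s: float = 10.0
    time_betas: dict = field(default_factory=dict)
    time_sd: float = 1.0
    #: Poisson error model: log-rate = base + sum(coef * symptom)
    error_log_rate: float = -2.0
    error_betas: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# Signal building blocks
# ---------------------------------------------------------------------------

def _lowpass_noise(rng: np.random.Generator, n: int, rate: float,
                   cutoff: float, rms: float) -> np.ndarray:
    """Gaussian noise low-passed below ``cutoff`` and scaled to ``rms``."""
    raw = rng.normal(0.0, 1.0, n)
    sos = sps.butter(4, cutoff, btype="lowpass", fs=rate, output="sos")
    x = sps.sosfiltfilt(sos, raw)
    sd = np.std(x)
    return x * (rms / sd) if sd > 0 else x


def _bandpass_noise(rng: np.random.Generator, n: int, rate: float,
                    band: tuple[float, float], rms: float) -> np.ndarray:
    raw = rng.normal(0.0, 1.0, n)
    sos = sps.butter(4, band, btype="bandpass", fs=rate, output="sos")
    x = sps.sosfiltfilt(sos, raw)
    sd = np.std(x)
    return x * (rms / sd) if sd > 0 else x


def minimum_jerk_velocity(t: np.ndarray, t0: float, dur: float, peak: float) -> np.ndarray:
    """Minimum-jerk speed profile: 30 τ²(1−τ)² over [t0, t0+dur], scaled so
    the maximum equals ``peak``."""
    tau = np.clip((t - t0) / dur, 0.0, 1.0)
    profile = 30.0 * tau**2 * (1.0 - tau) ** 2
    return profile * (peak / (30.0 * 0.0625))  # max of tau^2(1-tau)^2 is 1/16


def _tremor_tone(rng: np.random.Generator, t: np.ndarray, amp: float,
                 freq: float) -> np.ndarray:
    phase = rng.uniform(0, 2 * np.pi)
    mod_phase = rng.uniform(0, 2 * np.pi)
    envelope = 1.0 + 0.3 * np.sin(2 * np.pi * 0.1 * t + mod_phase)
    return amp * envelope * np.sin(2 * np.pi * freq * t + phase)


def _lid_envelopes(rng: np.random.Generator, n_blocks: int) -> dict[str, np.ndarray]:
    """AR(1)-coupled positive 1 s-block amplitude envelopes per segment."""
    z = {seg: rng.normal(0.0, 1.0, n_blocks) for seg in _SEGMENT_CHAIN}
    latent = {seg: np.zeros(n_blocks) for seg in _SEGMENT_CHAIN}
    for k in range(n_blocks):
        for i, seg in enumerate(_SEGMENT_CHAIN):
            prev_seg = _SEGMENT_CHAIN[i - 1] if i > 0 else _SEGMENT_CHAIN[-1]
            parent = latent[prev_seg][k - 1] if k > 0 else 0.0
            latent[seg][k] = LID_FLOW_AR * parent + np.sqrt(1 - LID_FLOW_AR**2) * z[seg][k]
    # map to positive envelopes with unit mean square
    env = {}
    for seg, x in latent.items():
        e = np.exp(0.5 * x)
        env[seg] = e / np.sqrt(np.mean(e**2))
    return env


def _smooth_env(env_blocks: np.ndarray, n: int, rate: float) -> np.ndarray:
    """Linear interpolation of 1 s block envelope values onto the sample grid."""
    block_t = (np.arange(len(env_blocks)) + 0.5)
    t = np.arange(n) / rate
    return np.interp(t, block_t, env_blocks)


# ---------------------------------------------------------------------------
# Recording simulators
# ---------------------------------------------------------------------------

def _empty_channels(layout: SensorLayout, n: int):
    gyro = {s: np.zeros((n, 3)) for s in layout.placements}
    accel = {s: np.zeros((n, 3)) for s in layout.placements}
    return gyro, accel


def _add_noise(scenario, layout, gyro, accel) -> None:
    if scenario.noise_sd <= 0:
        return
    for s in layout.placements:
        rg = component_rng(scenario.seed, f"noise:gyro:{s}")
        gyro[s] += rg.normal(0.0, scenario.noise_sd, gyro[s].shape)
        ra = component_rng(scenario.seed, f"noise:acc:{s}")
        accel[s] += ra.normal(0.0, scenario.noise_sd, accel[s].shape)


def _add_voluntary(scenario, layout, t, gyro) -> None:
    if scenario.voluntary_amp <= 0:
        return
    n, rate = len(t), scenario.rate_hz
    for s in layout.placements:
        rg = component_rng(scenario.seed, f"vol:{s}")
        for ax in range(3):
            gyro[s][:, ax] += _lowpass_noise(rg, n, rate, 1.5, scenario.voluntary_amp)
    if scenario.n_reach_bursts > 0:
        rb = component_rng(scenario.seed, "vol:bursts")
        arm = list(layout.arm_sensors)
        for _ in range(scenario.n_reach_bursts):
            sensor = arm[rb.integers(len(arm))]
            axis = int(rb.integers(3))
            t0 = rb.uniform(0.0, max(scenario.duration_s - 1.5, 0.1))
            gyro[sensor][:, axis] += minimum_jerk_velocity(
                t, t0, 1.5, 3.0 * scenario.voluntary_amp
            )


def _add_tremor(scenario, layout, t, gyro, truth) -> None:
    if scenario.tremor_amp <= 0:
        return
    for hand in layout.hand_sensors:
        rg = component_rng(scenario.seed, f"tremor:{hand}")
        direction = rg.normal(0.0, 1.0, 3)
        direction /= np.linalg.norm(direction)
        tone = _tremor_tone(rg, t, scenario.tremor_amp, scenario.tremor_freq_hz)
        gyro[hand] += tone[:, None] * direction[None, :]
        truth["tremor"][hand] = {
            "freq_hz": scenario.tremor_freq_hz,
            "amp": scenario.tremor_amp,
        }


def _add_lid(scenario, layout, gyro, truth) -> None:
    if scenario.lid_rms <= 0:
        return
    n = gyro[layout.placements[0]].shape[0]
    rate = scenario.rate_hz
    n_blocks = max(1, int(scenario.duration_s))
    env = _lid_envelopes(component_rng(scenario.seed, "lid:flow"), n_blocks)
    for seg, members in layout.segment_groups.items():
        e = _smooth_env(env[seg], n, rate)
        for sensor in members:
            rg = component_rng(scenario.seed, f"lid:{sensor}")
            for ax in range(3):
                base = _bandpass_noise(rg, n, rate, (0.5, 4.0), scenario.lid_rms)
                gyro[sensor][:, ax] += base * e
        truth["lid_rms"][seg] = float(scenario.lid_rms * np.sqrt(np.mean(env[seg] ** 2)))


def simulate_recording(
    scenario: RecordingScenario, layout: SensorLayout | None = None
) -> tuple[Recording, dict]:
    """Simulate a (sitting-style) full-body recording with ground truth.

    Returns the recording and a truth dictionary holding, per component,
    what was injected where.
    """
    layout = layout or default_layout()
    n = int(round(scenario.duration_s * scenario.rate_hz))
    t = np.arange(n) / scenario.rate_hz
    gyro, accel = _empty_channels(layout, n)
    truth: dict = {"tremor": {}, "lid_rms": {}, "fog_intervals": [], "fog_mask": None}

    _add_voluntary(scenario, layout, t, gyro)
    _add_tremor(scenario, layout, t, gyro, truth)
    _add_lid(scenario, layout, gyro, truth)
    _add_noise(scenario, layout, gyro, accel)
    for s in layout.placements:
        accel[s][:, 2] += GRAVITY

    rec = Recording(sampling_rate=scenario.rate_hz, timestamps=t, gyro=gyro, accel=accel)
    return rec, truth


def _merge_intervals(episodes) -> list[tuple[float, float]]:
    merged: list[list[float]] = []
    for lo, hi in sorted(episodes):
        if merged and lo <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], hi)
        else:
            merged.append([lo, hi])
    return [(a, b) for a, b in merged]


def simulate_walk(
    scenario: RecordingScenario, layout: SensorLayout | None = None
) -> tuple[Recording, dict]:
    """Simulate a walking recording with optional freeze-of-gait episodes.

    Outside episodes the gait sensors carry a locomotor tone riding on
    gravity; inside episodes forward locomotion stops and 3–8 Hz narrow-band
    trembling appears.  The truth dictionary holds merged episode intervals
    and a per-sample frozen mask.
    """
    layout = layout or default_layout()
    rec, truth = simulate_recording(scenario, layout)
    n = rec.n_samples
    t = rec.timestamps
    rate = scenario.rate_hz

    episodes = _merge_intervals(scenario.fog_episodes)
    frozen = np.zeros(n, dtype=bool)
    for lo, hi in episodes:
        frozen[(t >= lo) & (t < hi)] = True
    truth["fog_intervals"] = episodes
    truth["fog_mask"] = frozen
    truth["frozen_fraction"] = float(np.mean(frozen))

    for sensor in layout.fog_sensors:
        rg = component_rng(scenario.seed, f"walk:{sensor}")
        phase = rg.uniform(0, 2 * np.pi)
        loco = scenario.locomotor_amp * np.sin(
            2 * np.pi * scenario.locomotor_freq_hz * t + phase
        )
        loco[frozen] = 0.0  # no forward locomotion during a freeze
        tremble = _bandpass_noise(rg, n, rate, (3.5, 7.0), scenario.freeze_amp) \
            if scenario.freeze_amp > 0 else np.zeros(n)
        tremble[~frozen] = 0.0
        # vertical axis rides on gravity so magnitude responds linearly
        rec.accel[sensor][:, 2] += loco + tremble
        rec.accel[sensor][:, 0] += 0.2 * loco
    return rec, truth


# ---------------------------------------------------------------------------
# Cohort simulator
# ---------------------------------------------------------------------------

def _expit(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(x, -35, 35)))


def simulate_ram(
    seed: int, amp: float, duration_s: float = 10.0, rate_hz: float = 32.0,
    freq_hz: float = 2.0, noise_sd: float = 0.02,
    layout: SensorLayout | None = None,
) -> Recording:
    """A 10 s pronation–supination trial: a sinusoidal angular velocity of
    amplitude ``amp`` on the right forearm's dominant axis plus noise."""
    layout = layout or default_layout()
    n = int(round(duration_s * rate_hz))
    t = np.arange(n) / rate_hz
    gyro, accel = _empty_channels(layout, n)
    gyro["forearm_r"][:, 0] += amp * np.sin(2 * np.pi * freq_hz * t)
    rng = component_rng(seed, "ram:noise")
    for s in layout.placements:
        gyro[s] += rng.normal(0.0, noise_sd, gyro[s].shape)
        accel[s][:, 2] += GRAVITY
    return Recording(sampling_rate=rate_hz, timestamps=t, gyro=gyro, accel=accel)


def simulate_cohort(scenario: CohortScenario) -> tuple[pd.DataFrame, dict]:
    """Simulate a participant × task cohort table with known ground truth.

    Symptom levels are drawn per group from the scenario distributions
    (clipped to their natural ranges); a latent task success is Bernoulli
    with logit equal to the scenario's linear model; task time and error
    counts follow the linear/Poisson performance models so that
    control-referenced success criteria can be derived downstream.
    """
    rng = component_rng(scenario.seed, "cohort")
    rows = []
    truth = {
        "intercept": scenario.success_intercept,
        "betas": dict(scenario.success_betas),
    }
    participants = [("control", f"C{i:03d}") for i in range(scenario.n_controls)] + [
        ("patient", f"P{i:03d}") for i in range(scenario.n_patients)
    ]
    for group, pid in participants:
        symptoms = {}
        for name, (c_mu, c_sd, p_mu, p_sd) in scenario.symptoms.items():
            mu, sd = (c_mu, c_sd) if group == "control" else (p_mu, p_sd)
            val = float(rng.normal(mu, sd)) if sd > 0 else float(mu)
            if name == "mmse":
                val = float(np.clip(round(val), 0, 30))
            elif name != "age":
                val = max(val, 0.0)
            symptoms[name] = val
        for task in scenario.tasks:
            eta = scenario.success_intercept + sum(
                beta * symptoms.get(sym, 0.0)
                for sym, beta in scenario.success_betas.items()
            )
            success_latent = bool(rng.uniform() < _expit(np.array(eta)))
            time_shift = sum(
                beta * symptoms.get(sym, 0.0)
                for sym, beta in scenario.time_betas.items()
            ) if group == "patient" else 0.0
            time_s = max(0.5, scenario.time_base_s + time_shift
                         + float(rng.normal(0.0, scenario.time_sd)))
            log_rate = scenario.error_log_rate + (
                sum(beta * symptoms.get(sym, 0.0)
                    for sym, beta in scenario.error_betas.items())
                if group == "patient" else 0.0
            )
            errors = int(rng.poisson(np.exp(np.clip(log_rate, -20, 5))))
            rows.append({
                "participant_id": pid, "group": group, "task_id": task,
                **symptoms, "time_s": time_s, "error_count": errors,
                "success_latent": success_latent,
            })
    df = pd.DataFrame(rows)
    return df, truth


# ---------------------------------------------------------------------------
# Whole-study simulator (recordings on disk + covariate table)
# ---------------------------------------------------------------------------

STUDY_DEFAULTS: dict = {
    "seed": 0,
    "rate_hz": 32.0,
    "n_controls": 10,
    "n_patients": 20,
    "tasks": [
        {"task_id": "eating_soup", "posture": "sitting", "duration_s": 12.0},
        {"task_id": "TUG", "posture": "walking", "duration_s": 12.0},
    ],
    "include_ram": True,
    # per-patient signal amplitude ranges (uniform draws); controls get none
    "patient_signal": {
        "tremor_amp": [0.0, 40.0],
        "lid_rms": [0.2, 2.0],
        "ram_amp": [120.0, 220.0],
    },
    "control_signal": {"ram_amp": [220.0, 300.0]},
    # clinical covariates: (control mean, sd, patient mean, sd)
    "covariates": {
        "age": [68.0, 8.0, 67.0, 9.0],
        "mmse": [28.5, 1.5, 27.0, 2.5],
        "rigidity": [0.0, 0.0, 1.2, 0.8],
        "postural_instability": [0.0, 0.0, 1.5, 1.0],
    },
    # performance models (patients only get the symptom-driven shifts)
    "time_base_s": 10.0,
    "time_betas": {},
    "time_sd": 1.0,
    "error_log_rate": -2.5,
    "error_betas": {},
    "noise_sd": 0.02,
    "locomotor_amp": 1.0,
}


def simulate_study(config: dict, out_dir) -> dict:
    """Simulate a whole study to disk: one recording CSV per participant ×
    task, a run manifest, and a covariate table.

    ``config`` overrides :data:`STUDY_DEFAULTS`.  Returns the paths of the
    written artifacts.  Deterministic given the seed.
    """
    from pathlib import Path

    from .core import write_recording

    cfg = {**STUDY_DEFAULTS, **config}
    out = Path(out_dir)
    rec_dir = out / "recordings"
    rec_dir.mkdir(parents=True, exist_ok=True)
    layout = default_layout()
    seed = int(cfg["seed"])
    rate = float(cfg["rate_hz"])

    participants = [("control", f"C{i:03d}") for i in range(int(cfg["n_controls"]))] + [
        ("patient", f"P{i:03d}") for i in range(int(cfg["n_patients"]))
    ]
    manifest_rows = []
    cov_rows = []
    for p_index, (group, pid) in enumerate(participants):
        p_seed = seed * 100003 + p_index
        rng = component_rng(p_seed, "study:participant")
        signal_cfg = cfg["patient_signal"] if group == "patient" else cfg["control_signal"]
        amplitudes = {k: float(rng.uniform(lo, hi)) for k, (lo, hi) in signal_cfg.items()}
        covariates = {}
        for name, (c_mu, c_sd, p_mu, p_sd) in cfg["covariates"].items():
            mu, sd = (c_mu, c_sd) if group == "control" else (p_mu, p_sd)
            val = float(rng.normal(mu, sd)) if sd > 0 else float(mu)
            if name == "mmse":
                val = float(np.clip(round(val), 0, 30))
            elif name != "age":
                val = max(val, 0.0)
            covariates[name] = val

        tasks = list(cfg["tasks"])
        if cfg["include_ram"]:
            tasks = tasks + [{"task_id": "RAM", "posture": "sitting", "duration_s": 10.0}]
        for t_index, task in enumerate(tasks):
            task_id = task["task_id"]
            duration = float(task["duration_s"])
            t_seed = p_seed * 131 + t_index
            if task_id == "RAM":
                rec = simulate_ram(
                    t_seed, amplitudes.get("ram_amp", 200.0), duration, rate,
                    noise_sd=float(cfg["noise_sd"]), layout=layout,
                )
            else:
                scenario = RecordingScenario(
                    seed=t_seed, duration_s=duration, rate_hz=rate,
                    voluntary_amp=5.0,
                    tremor_amp=amplitudes.get("tremor_amp", 0.0),
                    lid_rms=amplitudes.get("lid_rms", 0.0),
                    locomotor_amp=float(cfg["locomotor_amp"])
                    if task["posture"] == "walking" else 0.0,
                    noise_sd=float(cfg["noise_sd"]),
                )
                if task["posture"] == "walking":
                    rec, _ = simulate_walk(scenario, layout)
                else:
                    rec, _ = simulate_recording(scenario, layout)
            fname = f"{pid}_{task_id}.csv"
            write_recording(rec, rec_dir / fname)
            manifest_rows.append({
                "participant_id": pid, "task_id": task_id,
                "posture": task["posture"], "start_s": 0.0, "end_s": duration,
                "cue_time_s": 0.0, "recording": f"recordings/{fname}",
            })
            if task_id == "RAM":
                continue
            shift = sum(beta * covariates.get(sym, amplitudes.get(sym, 0.0))
                        for sym, beta in cfg["time_betas"].items()) \
                if group == "patient" else 0.0
            time_s = max(0.5, float(cfg["time_base_s"]) + shift
                         + float(rng.normal(0.0, float(cfg["time_sd"]))))
            log_rate = float(cfg["error_log_rate"]) + (
                sum(beta * covariates.get(sym, amplitudes.get(sym, 0.0))
                    for sym, beta in cfg["error_betas"].items())
                if group == "patient" else 0.0
            )
            errors = int(rng.poisson(np.exp(np.clip(log_rate, -20, 5))))
            cov_rows.append({
                "participant_id": pid, "group": group, "task_id": task_id,
                **covariates, "time_s": time_s, "error_count": errors,
            })

    manifest_path = out / "manifest.csv"
    pd.DataFrame(manifest_rows).to_csv(manifest_path, index=False)
    cov_path = out / "covariates.csv"
    pd.DataFrame(cov_rows).to_csv(cov_path, index=False)
    return {"manifest": str(manifest_path), "covariates": str(cov_path),
            "recordings_dir": str(rec_dir)}
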