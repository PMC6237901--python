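"""Synthetic observer cohorts emulating the phoneme-categorization study design.

Each virtual participant has a continuous reading score (standardized scale,
mean 100, SD 15) that drives the shape of their true psychometric function:
slope increases with reading score (0.023 probability/step per score unit by
default) and lapse rate decreases (−0.0004 per unit, with a +0.010 offset on
the static-cue continuum).  Every subject completes the full design — two
ABX blocks plus one single-interval block per continuum, 10 trials at each
of 7 steps, 70 trials per block, 6 blocks — and reaction times follow a
right-skewed shifted-gamma noise model around an inverted-U profile over
steps whose depth grows with reading score.  Ground-truth parameters are
retained so fitting and regression stages can be checked by parameter
recovery.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Iterator

import numpy as np
import pandas as pd
from scipy import stats

from .psychometric import LN19, BlockData, PsychometricParams, predict_prob

CONTINUA = ("dynamic_ba_da", "static_sha_sa")

#: (paradigm, continuum) for the six blocks, in administration order
BLOCK_LAYOUT = (
    ("abx", "dynamic_ba_da"),
    ("abx", "static_sha_sa"),
    ("abx", "dynamic_ba_da"),
    ("abx", "static_sha_sa"),
    ("single", "dynamic_ba_da"),
    ("single", "static_sha_sa"),
)


@dataclass
class SimConfig:
    """Generative parameters of a synthetic cohort.

    The slope and lapse links carry the study's fitted effect sizes as
    defaults; noise terms and clip bounds keep every subject's psychometric
    valid.  All randomness descends from ``seed`` through named substreams,
    so identical seeds give byte-identical cohorts.
    """

    n_subjects: int = 44
    seed: int = 0

    # reading score distribution (standardized composite)
    reading_mean: float = 100.0
    reading_sd: float = 15.0
    reading_bounds: tuple[float, float] = (55.0, 145.0)

    # slope link: slope = a0 + a1 * reading + noise, in probability/step
    slope_intercept: float = -1.6
    slope_per_reading: float = 0.023
    slope_noise_sd: float = 0.15
    slope_clip: tuple[float, float] = (0.02, 2.0)

    # lapse link: lapse = b0 + b1 * reading (+ static offset) + noise
    lapse_intercept: float = 0.08
    lapse_per_reading: float = -0.0004
    lapse_static_offset: float = 0.010
    lapse_noise_sd: float = 0.010
    lapse_clip: tuple[float, float] = (0.0, 0.3)
    lapse_asymmetry: float = 0.0       # gamma - lambda offset; 0 = symmetric lapses
    paradigm_lapse_increment: float = 0.0  # extra lapse on ABX blocks, off by default

    # category boundary
    threshold_mean: float = 4.0
    threshold_sd: float = 0.5

    # design
    n_per_step: int = 10
    steps: tuple[int, ...] = (1, 2, 3, 4, 5, 6, 7)

    # reaction-time model
    rt_baseline_ms: float = 500.0
    rt_quad_depth_ms: float = 180.0
    rt_reading_coupling: float = 0.01  # curvature multiplier per reading unit
    rt_noise_df: float = 4.0           # chi-square df of the skewed noise
    rt_noise_scale_ms: float = 60.0
    rt_spurious_rate: float = 0.09     # accidental presses below the 200 ms cutoff
    rt_long_pause_rate: float = 0.06   # disengaged trials beyond the 2 s cutoff

    # covariates (no direct effect on outcomes by default)
    adhd_base_rate: float = 0.16
    adhd_per_reading: float = -0.004
    iq_intercept: float = 50.0
    iq_per_reading: float = 0.25
    iq_noise_sd: float = 8.0
    age_range: tuple[float, float] = (8.0, 12.0)

    max_clip_fraction: float = 0.10

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "SimConfig":
        raw = json.loads(Path(path).read_text())
        for key in ("reading_bounds", "slope_clip", "lapse_clip", "age_range", "steps"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)


@dataclass
class Cohort:
    """Subject covariates, trial records and generative ground truth."""

    subjects: pd.DataFrame
    trials: pd.DataFrame
    truth: pd.DataFrame
    config: SimConfig = field(repr=False, default=None)

    def blocks(self) -> Iterator[BlockData]:
        """Yield one BlockData per subject × block, with trial-level records."""
        for (sid, bidx), grp in self.trials.groupby(["subject_id", "block_index"], sort=True):
            yield BlockData.from_trials(
                grp[["trial_number", "step", "response", "rt_ms"]],
                subject_id=sid,
                continuum=grp["continuum"].iloc[0],
                paradigm=grp["paradigm"].iloc[0],
                block_index=int(bidx),
            )

    def to_csv(self, out_dir: str | Path) -> dict[str, Path]:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {}
        for name, frame in (("subjects", self.subjects), ("trials", self.trials), ("truth", self.truth)):
            p = out / f"{name}.csv"
            frame.to_csv(p, index=False, float_format="%.6f")
            paths[name] = p
        return paths


def reading_group(score: float) -> str:
    """Reading group from the standardized score, by the ±1 SD recruitment rule."""
    if score <= 85.0:
        return "Dyslexic"
    if score > 100.0:
        return "Above Average"
    return "Below Average"


def simulate_block_responses(
    params: PsychometricParams,
    n_per_step: int,
    seed: int | np.random.Generator,
    steps: tuple[int, ...] = (1, 2, 3, 4, 5, 6, 7),
) -> pd.DataFrame:
    """Draw one block of binary responses under a true psychometric.

    Each step contributes ``n_per_step`` Bernoulli draws at its predicted
    probability; trial order is a seeded permutation of the full block.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    step_col = np.repeat(np.asarray(steps, dtype=int), n_per_step)
    step_col = rng.permutation(step_col)
    psi = predict_prob(params, step_col.astype(float))
    responses = rng.binomial(1, psi)
    return pd.DataFrame(
        {
            "trial_number": np.arange(1, step_col.size + 1),
            "step": step_col,
            "response": responses,
        }
    )


def simulate_reaction_times(
    trials: pd.DataFrame,
    reading_score: float,
    config: SimConfig,
    rng: np.random.Generator,
) -> np.ndarray:
    """Reaction times for one block's trials, in ms.

    rt = baseline + depth * q(step) * g(reading) + skewed noise, where
    q is an inverted-U peaking at the continuum center (step 4) and g scales
    the curvature up with reading score.  Spurious presses (< 200 ms) and
    long pauses (> 2 s) are injected at their configured rates.
    """
    step = trials["step"].to_numpy(dtype=float)
    q = 1.0 - ((step - 4.0) / 3.0) ** 2
    g = np.clip(1.0 + config.rt_reading_coupling * (reading_score - 100.0), 0.0, 2.5)
    noise = rng.chisquare(config.rt_noise_df, size=step.size) * config.rt_noise_scale_ms
    rt = config.rt_baseline_ms + config.rt_quad_depth_ms * q * g + noise

    u = rng.random(step.size)
    spurious = u < config.rt_spurious_rate
    long_pause = (u >= config.rt_spurious_rate) & (
        u < config.rt_spurious_rate + config.rt_long_pause_rate
    )
    rt[spurious] = rng.uniform(50.0, 199.0, spurious.sum())
    rt[long_pause] = rng.uniform(2001.0, 6000.0, long_pause.sum())
    return rt


def simulate_cohort(config: SimConfig | None = None) -> Cohort:
    """Generate a full synthetic cohort under ``config`` (deterministic per seed)."""
    cfg = config or SimConfig()
    root = np.random.SeedSequence(cfg.seed)
    ss_subjects, ss_trials, ss_rts = root.spawn(3)
    rng_sub = np.random.default_rng(ss_subjects)
    rng_trials = np.random.default_rng(ss_trials)
    rng_rt = np.random.default_rng(ss_rts)

    lo, hi = cfg.reading_bounds
    a = (lo - cfg.reading_mean) / cfg.reading_sd
    b = (hi - cfg.reading_mean) / cfg.reading_sd
    scores = stats.truncnorm.rvs(
        a, b, loc=cfg.reading_mean, scale=cfg.reading_sd,
        size=cfg.n_subjects, random_state=rng_sub,
    )

    subj_rows, truth_rows, trial_frames = [], [], []
    n_clipped = 0
    for i, wj in enumerate(scores):
        sid = f"S{i + 1:03d}"
        age = rng_sub.uniform(*cfg.age_range)
        adhd = int(rng_sub.random() < np.clip(
            cfg.adhd_base_rate + cfg.adhd_per_reading * (wj - 100.0), 0.01, 0.9))
        iq = cfg.iq_intercept + cfg.iq_per_reading * (wj - 100.0) + rng_sub.normal(0, cfg.iq_noise_sd)
        subj_rows.append(
            {
                "subject_id": sid, "wj_brs": wj, "group": reading_group(wj),
                "age": age, "adhd": adhd, "nonverbal_iq": iq,
            }
        )

        true_params: dict[str, PsychometricParams] = {}
        clipped = False
        for continuum in CONTINUA:
            slope_raw = (
                cfg.slope_intercept + cfg.slope_per_reading * wj
                + rng_sub.normal(0, cfg.slope_noise_sd)
            )
            slope = float(np.clip(slope_raw, *cfg.slope_clip))
            lapse_raw = (
                cfg.lapse_intercept + cfg.lapse_per_reading * wj
                + (cfg.lapse_static_offset if continuum == "static_sha_sa" else 0.0)
                + rng_sub.normal(0, cfg.lapse_noise_sd)
            )
            lapse = float(np.clip(lapse_raw, *cfg.lapse_clip))
            # the slope floor/ceiling is a structural part of the link (a
            # floored-linear law: real observers bottom out near chance);
            # only lapse clips signal a config generating invalid probabilities
            clipped = clipped or (lapse != lapse_raw)
            gamma = float(np.clip(lapse + cfg.lapse_asymmetry / 2.0, 0.0, 0.5))
            lam = float(np.clip(lapse - cfg.lapse_asymmetry / 2.0, 0.0, 0.5))
            threshold = rng_sub.normal(cfg.threshold_mean, cfg.threshold_sd)
            width = (1.0 - gamma - lam) * LN19 / (2.0 * slope)
            width = float(np.clip(width, 0.55, 17.0))
            true_params[continuum] = PsychometricParams(threshold, width, gamma, lam)
            truth_rows.append(
                {
                    "subject_id": sid, "continuum": continuum,
                    "threshold": threshold, "width": width,
                    "slope": (1.0 - gamma - lam) * LN19 / (2.0 * width),
                    "lower_asym": gamma, "upper_asym_dev": lam,
                    "lapse": (gamma + lam) / 2.0,
                }
            )
        n_clipped += int(clipped)

        for block_index, (paradigm, continuum) in enumerate(BLOCK_LAYOUT, start=1):
            params = true_params[continuum]
            if cfg.paradigm_lapse_increment and paradigm == "abx":
                g2 = min(params.lower_asym + cfg.paradigm_lapse_increment, 0.5)
                l2 = min(params.upper_asym_dev + cfg.paradigm_lapse_increment, 0.5)
                params = PsychometricParams(params.threshold, params.width, g2, l2)
            block = simulate_block_responses(params, cfg.n_per_step, rng_trials, cfg.steps)
            block["rt_ms"] = simulate_reaction_times(block, wj, cfg, rng_rt)
            block.insert(0, "subject_id", sid)
            block.insert(1, "continuum", continuum)
            block.insert(2, "paradigm", paradigm)
            block.insert(3, "block_index", block_index)
            trial_frames.append(block)

    if n_clipped > cfg.max_clip_fraction * cfg.n_subjects:
        raise ValueError(
            f"config clips slope/lapse for {n_clipped}/{cfg.n_subjects} subjects "
            f"(> {cfg.max_clip_fraction:.0%}); generative links would be distorted"
        )

    return Cohort(
        subjects=pd.DataFrame(subj_rows),
        trials=pd.concat(trial_frames, ignore_index=True),
        truth=pd.DataFrame(truth_rows),
        config=cfg,
    )
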