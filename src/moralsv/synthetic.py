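"""Synthetic cohorts: task designs, agents, choices, RTs and BOLD volumes.

The generator emulates the study conditions the analysis pipeline assumes:
25 subjects, a financial task (20 CHF now vs 20–120 CHF at one of six delays
between 1 and 180 days) and a structurally isomorphic moral task (sacrifice
one person with one of six criminal records vs save 1–10 lives).  Choices
are generated from the hyperbolic subjective-value model with logistic
noise; reaction times decrease with the absolute SV difference (easy trials
are fast); BOLD fixtures inject SV-modulated responses into designated voxel
clusters on top of white noise.

Everything is deterministic given its seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import glm as _glm
from .behavior import _hyperbolic_sv
from .data import (
    FINANCIAL,
    FINANCIAL_AMOUNTS,
    FINANCIAL_DELAYS,
    K_F_RANGE,
    K_M_RANGE,
    MORAL,
    MORAL_LIVES,
    MORAL_RANKS,
    ChoiceDataset,
    PerceptionRatings,
    TaskDesign,
    default_deservingness_rating,
    default_delay_rating,
    reference_value,
)
from .errors import ValidationError

__all__ = [
    "AgentParams",
    "PopulationConfig",
    "SyntheticBold",
    "TruthCluster",
    "BoldTruthConfig",
    "build_design",
    "sample_agent",
    "sample_cohort",
    "simulate_choices",
    "build_events",
    "simulate_bold",
    "matched_slope_cohort",
]

#: Floor applied to simulated reaction times (ms).
RT_FLOOR_MS = 200.0


def build_design(
    task: str,
    amount_grid=None,
    level_grid=None,
    repeats: int = 1,
) -> TaskDesign:
    """Full-factorial trial list: every (magnitude, level) cell ``repeats`` times.

    Grids default to the study ranges; values outside the printed ranges
    raise :class:`ValidationError`.
    """
    if repeats < 1:
        raise ValidationError("repeats must be >= 1")
    if task == FINANCIAL:
        amounts = np.asarray(amount_grid if amount_grid is not None else FINANCIAL_AMOUNTS, float)
        levels = np.asarray(level_grid if level_grid is not None else FINANCIAL_DELAYS, int)
        if amounts.min() < 20.0 or amounts.max() > 120.0:
            raise ValidationError("financial amounts must lie in [20, 120] CHF")
        if levels.min() < 1 or levels.max() > 180:
            raise ValidationError("delays must lie in [1, 180] days")
    elif task == MORAL:
        amounts = np.asarray(amount_grid if amount_grid is not None else MORAL_LIVES, float)
        levels = np.asarray(level_grid if level_grid is not None else MORAL_RANKS, int)
        if amounts.min() < 1 or amounts.max() > 10:
            raise ValidationError("group sizes must lie in [1, 10] lives")
        if levels.min() < 1 or levels.max() > 6:
            raise ValidationError("deservingness ranks must lie in 1..6")
    else:
        raise ValidationError(f"unknown task {task!r}")
    if len(np.unique(levels)) != len(levels):
        raise ValidationError("discounter levels must be distinct")

    mag, lev = np.meshgrid(amounts, levels, indexing="ij")
    trials = pd.DataFrame({"magnitude": mag.ravel(), "level": lev.ravel()})
    trials = pd.concat([trials] * repeats, ignore_index=True)
    return TaskDesign(task=task, trials=trials)


@dataclass
class PopulationConfig:
    """Distributional assumptions of the simulated cohort.

    Discount constants are log-uniform within range (defaults are the
    printed across-participant ranges); choice temperatures log-uniform;
    perception curves are the package defaults with monotonicity-preserving
    log-normal jitter on the increments (sd ``perception_jitter``).
    """

    k_f_range: tuple[float, float] = K_F_RANGE
    k_m_range: tuple[float, float] = K_M_RANGE
    beta_f_range: tuple[float, float] = (0.5, 3.0)  # 1/CHF
    beta_m_range: tuple[float, float] = (1.0, 5.0)  # 1/life
    # RT model: intercept minus slope * |dSV| plus noise.  The slope ranges
    # are calibrated so both tasks have the same expected RT reduction
    # (mean |dSV| is ~27 CHF financial vs ~1.4 lives moral, a ~19:1 scale
    # ratio), keeping the two tasks RT-matched at the group level with
    # grand-mean RTs near 1.2 s.
    rt_intercept_mean: float = 1380.0
    rt_intercept_sd: float = 100.0
    rt_slope_f_range: tuple[float, float] = (2.0, 6.0)  # ms per CHF of |dSV|
    rt_slope_m_range: tuple[float, float] = (38.0, 115.0)  # ms per life of |dSV|
    rt_sd: float = 150.0
    perception_jitter: float = 0.1
    delays: tuple[int, ...] = FINANCIAL_DELAYS
    ranks: tuple[int, ...] = MORAL_RANKS

    def __post_init__(self) -> None:
        for name in ("k_f_range", "k_m_range", "beta_f_range", "beta_m_range",
                     "rt_slope_f_range", "rt_slope_m_range"):
            lo, hi = getattr(self, name)
            if not lo < hi:
                raise ValidationError(f"{name} must satisfy min < max, got ({lo}, {hi})")
        if self.k_f_range[0] <= 0 or self.k_m_range[0] <= 0:
            raise ValidationError("discount constants must be positive")
        if self.rt_sd <= 0:
            raise ValidationError("rt_sd must be positive")

    @classmethod
    def strong_discounting(cls) -> "PopulationConfig":
        """Cohort of uniformly steep financial discounters.

        K_f is drawn from the top of the printed range and choice noise is
        moderate.  For these agents the 20 and 22 CHF larger-later offers
        are rejected at every delay with a larger SV margin than any other
        type's acceptance margin, reproducing the extreme-certainty choice
        pattern that motivates the matching stage.  (Flatter discounters
        are near-indifferent about those offers, so mixed cohorts do not
        show the pattern; see the methods note.)
        """
        return cls(k_f_range=(0.038, 0.043), beta_f_range=(0.5, 1.2))


@dataclass
class AgentParams:
    """Generative parameters of one simulated subject."""

    subject_id: str
    k_f: float
    k_m: float
    beta_f: float
    beta_m: float
    perception: PerceptionRatings
    rt_intercept: float
    rt_slope_financial: float
    rt_slope_moral: float
    rt_sd: float
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.k_f <= 0 or self.k_m <= 0:
            raise ValidationError("discount constants must be positive")
        if self.beta_f < 0 or self.beta_m < 0:
            raise ValidationError("choice temperatures must be non-negative")
        if self.rt_sd <= 0:
            raise ValidationError("rt_sd must be positive")

    def k(self, task: str) -> float:
        return self.k_f if task == FINANCIAL else self.k_m

    def beta(self, task: str) -> float:
        return self.beta_f if task == FINANCIAL else self.beta_m

    def rt_slope(self, task: str) -> float:
        return self.rt_slope_financial if task == FINANCIAL else self.rt_slope_moral

    def to_record(self) -> dict:
        rec = {
            "subject_id": self.subject_id,
            "k_f": self.k_f,
            "k_m": self.k_m,
            "beta_f": self.beta_f,
            "beta_m": self.beta_m,
            "rt_intercept": self.rt_intercept,
            "rt_slope_financial": self.rt_slope_financial,
            "rt_slope_moral": self.rt_slope_moral,
            "rt_sd": self.rt_sd,
            "seed": self.seed,
        }
        return rec


def _log_uniform(rng, lo, hi):
    return float(np.exp(rng.uniform(np.log(lo), np.log(hi))))


def _jittered_curve(rng, base: np.ndarray, jitter: float) -> np.ndarray:
    """Monotone jitter: perturb the increments multiplicatively, keep endpoints."""
    if jitter <= 0 or len(base) < 2:
        return base.copy()
    inc = np.diff(np.concatenate([[0.0], base]))
    inc = inc * np.exp(rng.normal(0.0, jitter, size=inc.shape))
    curve = np.cumsum(inc)
    # rescale so the top level keeps its base rating (100 for the defaults)
    return curve * (base[-1] / curve[-1])


def sample_agent(
    config: PopulationConfig,
    seed: int,
    subject_id: str | None = None,
) -> AgentParams:
    """Draw one agent from the population; bit-identical for equal seeds."""
    rng = np.random.default_rng(seed)
    delays = np.asarray(config.delays, int)
    ranks = np.asarray(config.ranks, int)
    t_curve = _jittered_curve(rng, np.asarray(default_delay_rating(delays), float),
                              config.perception_jitter)
    d_curve = _jittered_curve(rng, np.asarray(default_deservingness_rating(ranks), float),
                              config.perception_jitter)
    perception = PerceptionRatings(
        delay={int(d): float(np.clip(v, 0.0, 100.0)) for d, v in zip(delays, t_curve)},
        deservingness={int(r): float(np.clip(v, 0.0, 100.0)) for r, v in zip(ranks, d_curve)},
    )
    return AgentParams(
        subject_id=subject_id if subject_id is not None else f"sub-{seed:04d}",
        k_f=_log_uniform(rng, *config.k_f_range),
        k_m=_log_uniform(rng, *config.k_m_range),
        beta_f=_log_uniform(rng, *config.beta_f_range),
        beta_m=_log_uniform(rng, *config.beta_m_range),
        perception=perception,
        rt_intercept=float(rng.normal(config.rt_intercept_mean, config.rt_intercept_sd)),
        rt_slope_financial=float(rng.uniform(*config.rt_slope_f_range)),
        rt_slope_moral=float(rng.uniform(*config.rt_slope_m_range)),
        rt_sd=config.rt_sd,
        seed=seed,
    )


def sample_cohort(config: PopulationConfig, n_subjects: int, seed: int) -> list[AgentParams]:
    """Sample ``n_subjects`` agents with independent per-subject streams."""
    children = np.random.SeedSequence(seed).spawn(n_subjects)
    return [
        sample_agent(config, seed=int(child.generate_state(1)[0] % (2**31)),
                     subject_id=f"sub-{i + 1:02d}")
        for i, child in enumerate(children)
    ]


def simulate_choices(agent: AgentParams, design: TaskDesign, seed: int) -> ChoiceDataset:
    """Simulate one subject's choices and RTs on a task design.

    P(choose target) = logistic(beta * (SV_target − SV_reference)); RT =
    intercept − slope·|ΔSV| + Gaussian noise, floored at 200 ms.
    """
    rng = np.random.default_rng(seed)
    task = design.task
    trials = design.trials
    perceived = np.array(
        [agent.perception.rating(task, int(level)) for level in trials["level"]]
    )
    sv = _hyperbolic_sv(trials["magnitude"].to_numpy(float), agent.k(task), perceived)
    dsv = sv - reference_value(task)
    from scipy.special import expit

    p = expit(agent.beta(task) * dsv)
    chose = rng.random(len(p)) < p
    rt = (
        agent.rt_intercept
        - agent.rt_slope(task) * np.abs(dsv)
        + rng.normal(0.0, agent.rt_sd, size=len(p))
    )
    rt = np.maximum(rt, RT_FLOOR_MS)
    out = trials.copy().reset_index(drop=True)
    out["perceived"] = perceived
    out["sv_target"] = sv
    out["chose_target"] = chose
    out["rt_ms"] = rt
    return ChoiceDataset(subject_id=agent.subject_id, task=task, trials=out)


def matched_slope_cohort(
    config: PopulationConfig,
    n_subjects: int,
    seed: int,
    design_financial: TaskDesign | None = None,
    design_moral: TaskDesign | None = None,
    excluded_amounts: tuple[float, ...] = (20.0, 22.0),
    choice_slope_range: tuple[float, float] = (0.8, 1.5),
    rt_slope_target_sd: float = 40.0,
) -> list[AgentParams]:
    """Cohort constructed so both tasks share the same expected slope structure.

    The logistic-SV choice rule is, on the standardized-SV scale, a
    correctly specified logistic regression with slope beta * sd(SV); the
    expected RT slope is -rt_slope * cov(|SV - ref|, SV) / sd(SV).  Both
    quantities are computable analytically per agent from the design and
    the agent's perception (the financial task taken after the certainty
    exclusion, as in the matching procedure).  For each agent a common
    target choice slope (log-uniform in ``choice_slope_range``) and a
    common target RT slope (half-normal, sd ``rt_slope_target_sd`` ms) are
    drawn and the per-task temperatures and RT slopes are set to hit the
    targets exactly, so the cross-task slope differences are zero in
    expectation.  Used for type-I-error checks of the slope comparison.
    """
    design_financial = design_financial or build_design(FINANCIAL)
    design_moral = design_moral or build_design(MORAL)
    fin_trials = design_financial.trials
    fin_trials = fin_trials[~fin_trials["magnitude"].isin(excluded_amounts)]
    agents = sample_cohort(config, n_subjects, seed)
    rng = np.random.default_rng(np.random.SeedSequence([seed, 2**20]).generate_state(1)[0])
    out = []
    for agent in agents:
        stats = {}
        for task, trials, k in (
            (FINANCIAL, fin_trials, agent.k_f),
            (MORAL, design_moral.trials, agent.k_m),
        ):
            ratings = np.array(
                [agent.perception.rating(task, int(x)) for x in trials["level"]]
            )
            sv = _hyperbolic_sv(trials["magnitude"].to_numpy(float), k, ratings)
            sd = sv.std()
            diff = np.abs(sv - reference_value(task))
            c = float(np.mean((diff - diff.mean()) * (sv - sv.mean())) / sd)
            stats[task] = (sd, c)
        target_choice = _log_uniform(rng, *choice_slope_range)
        target_rt = abs(rng.normal(0.0, rt_slope_target_sd))
        # avoid huge RT slopes when |dSV| is nearly uncorrelated with SV
        c_f, c_m = stats[FINANCIAL][1], stats[MORAL][1]
        if min(abs(c_f), abs(c_m)) < 0.05:
            target_rt = 0.0
        out.append(
            AgentParams(
                subject_id=agent.subject_id,
                k_f=agent.k_f,
                k_m=agent.k_m,
                beta_f=target_choice / stats[FINANCIAL][0],
                beta_m=target_choice / stats[MORAL][0],
                perception=agent.perception,
                rt_intercept=agent.rt_intercept,
                rt_slope_financial=0.0 if c_f == 0 else -target_rt / c_f,
                rt_slope_moral=0.0 if c_m == 0 else -target_rt / c_m,
                rt_sd=agent.rt_sd,
                seed=agent.seed,
            )
        )
    return out


# ---------------------------------------------------------------------------
# BOLD fixtures


@dataclass
class TruthCluster:
    """One injected signal cluster: a voxel sphere tied to a modulator."""

    name: str
    center: tuple[int, int, int]
    radius_vox: float
    regressor: str  # e.g. "financial_sv", "moral_sv", "-moral_sv"
    amplitude: float

    def voxels(self, shape: tuple[int, int, int]) -> list[tuple[int, int, int]]:
        cx, cy, cz = self.center
        out = []
        r = int(np.ceil(self.radius_vox))
        for i in range(max(0, cx - r), min(shape[0], cx + r + 1)):
            for j in range(max(0, cy - r), min(shape[1], cy + r + 1)):
                for k in range(max(0, cz - r), min(shape[2], cz + r + 1)):
                    if (i - cx) ** 2 + (j - cy) ** 2 + (k - cz) ** 2 <= self.radius_vox**2:
                        out.append((i, j, k))
        return out


@dataclass
class BoldTruthConfig:
    """Ground truth of a synthetic BOLD volume."""

    clusters: list[TruthCluster] = field(default_factory=list)
    noise_sd: float = 1.0
    baseline: float = 100.0

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2, sort_keys=True))

    @classmethod
    def from_json(cls, path: str | Path) -> "BoldTruthConfig":
        raw = json.loads(Path(path).read_text())
        clusters = [TruthCluster(**{**c, "center": tuple(c["center"])}) for c in raw["clusters"]]
        return cls(clusters=clusters, noise_sd=raw["noise_sd"], baseline=raw["baseline"])


@dataclass
class SyntheticBold:
    """4D synthetic BOLD data plus the events and truth that generated it."""

    data: np.ndarray  # (x, y, z, t)
    affine: np.ndarray
    tr: float
    events: pd.DataFrame
    truth: BoldTruthConfig

    @property
    def n_scans(self) -> int:
        return self.data.shape[-1]

    def to_nifti(self):
        import nibabel as nib

        return nib.Nifti1Image(self.data.astype(np.float32), self.affine)


def build_events(
    datasets: list[ChoiceDataset],
    seed: int,
    start_s: float = 10.0,
    iti_range_s: tuple[float, float] = (3.0, 7.0),
    duration_s: float = 0.0,
) -> pd.DataFrame:
    """Serialize trials of one or more datasets into an events table.

    Trials are laid out sequentially with uniformly jittered inter-trial
    intervals.  Columns: ``onset``, ``duration``, ``trial_type`` (the task)
    and ``sv`` (the trial's target subjective value, the parametric
    modulator).
    """
    rng = np.random.default_rng(seed)
    rows = []
    t = start_s
    for ds in datasets:
        for rec in ds.trials.itertuples():
            rows.append(
                {"onset": t, "duration": duration_s, "trial_type": ds.task, "sv": rec.sv_target}
            )
            t += duration_s + rng.uniform(*iti_range_s)
    return pd.DataFrame(rows)


def simulate_bold(
    datasets: list[ChoiceDataset],
    truth: BoldTruthConfig,
    seed: int,
    shape: tuple[int, int, int] = (12, 12, 12),
    tr: float = 2.0,
    voxel_size_mm: float = 3.0,
    pad_s: float = 30.0,
    events: pd.DataFrame | None = None,
) -> SyntheticBold:
    """Generate a small 4D volume with SV-modulated responses in truth clusters.

    Each cluster's timeseries is baseline + amplitude × (HRF ⊛ mean-centered
    modulator stick function) + white noise; all other voxels are baseline +
    noise.  The modulator regressor is built by the same design-matrix code
    the GLM uses, so an injected amplitude is, in expectation, exactly the
    modulator beta the GLM recovers.
    """
    rng = np.random.default_rng(seed)
    if events is None:
        events = build_events(datasets, seed=int(rng.integers(2**31)))
    n_scans = int(np.ceil((events["onset"].max() + pad_s) / tr))
    design = _glm.build_design(events, tr=tr, n_scans=n_scans, drift_order=0)

    occupied: set[tuple[int, int, int]] = set()
    for cluster in truth.clusters:
        vox = set(cluster.voxels(shape))
        if not vox:
            raise ValidationError(f"truth cluster {cluster.name!r} is empty within {shape}")
        if occupied & vox:
            raise ValidationError(f"truth cluster {cluster.name!r} overlaps another cluster")
        occupied |= vox

    data = truth.baseline + rng.normal(0.0, truth.noise_sd, size=(*shape, n_scans))
    for cluster in truth.clusters:
        name = cluster.regressor
        sign = 1.0
        if name.startswith("-"):
            sign, name = -1.0, name[1:]
        if name not in design.frame.columns:
            raise ValidationError(f"truth cluster regressor {name!r} not in design")
        course = sign * cluster.amplitude * design.frame[name].to_numpy()
        for i, j, k in cluster.voxels(shape):
            data[i, j, k, :] += course

    affine = np.diag([voxel_size_mm, voxel_size_mm, voxel_size_mm, 1.0])
    return SyntheticBold(data=data, affine=affine, tr=tr, events=events, truth=truth)
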