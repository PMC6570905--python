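"""Synthetic inputs for the pipeline: trajectories, snapshots, SSA fluorescence.

Everything downstream can be exercised without external data:

* :func:`gen_trajectories` draws single-cell log10-fluorescence time series from
  a two-state Gaussian HMM (defaults: the fitted switching probabilities
  0.963/0.037/0.023 and emission parameters 2.690/2.933, 0.085/0.080), sampled
  every 5 minutes, with division marks at 40-60 min intervals.  Ground-truth
  state paths are returned so estimators can be scored.
* :func:`gen_snapshots` draws steady-state population snapshots whose
  distribution moves from unimodal-low through unimodal-high to bimodal as the
  inducer rises, with the low-state weight increasing across the top of the
  grid; components are log-normal in linear intensity.
* :func:`ssa_to_fluorescence` converts an exact simulation of the reaction
  network into a fluorescence trajectory (total TetR-Venus: free + complexed +
  DNA-bound monomers, times a scale, with multiplicative log-normal noise).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from autorep.expression_stats import PopulationSnapshot
from autorep.hmm_analysis import FluorescenceTrajectory, TwoStateHMM
from autorep.stochastic_model import SSATrajectory

#: aTc concentrations beyond this are cytotoxic; snapshot grids must stay below.
ATC_TOXICITY_NG_PER_ML = 1900.0


def paper_hmm() -> TwoStateHMM:
    """The fitted two-state HMM used as the trajectory-generator default.

    State order (low, high); start probabilities are the chain's stationary
    distribution.
    """
    transmat = np.array([[0.977, 0.023], [0.037, 0.963]])
    p_low = 0.037 / (0.023 + 0.037)
    return TwoStateHMM(
        transmat=transmat,
        means=np.array([2.690, 2.933]),
        variances=np.array([0.085, 0.080]),
        startprob=np.array([p_low, 1.0 - p_low]),
    )


@dataclass
class TrajectoryGenConfig:
    """Generator settings for HMM-structured single-cell trajectories.

    Defaults emulate the reference time-lapse data set: 163 trajectories of
    40-60 frames at 5-minute sampling (about 8150 pooled points), divisions
    every 40-60 minutes.
    """

    n_trajectories: int = 163
    min_frames: int = 40
    max_frames: int = 60
    exact_frames: int | None = None  # set for homogeneous lengths
    dt: float = 5.0
    hmm: TwoStateHMM = field(default_factory=paper_hmm)
    division_interval: tuple[float, float] = (40.0, 60.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_trajectories < 1 or self.min_frames < 2 or self.max_frames < self.min_frames:
            raise ValueError("invalid trajectory counts")
        if self.dt <= 0:
            raise ValueError("dt must be positive")


def gen_trajectories(cfg: TrajectoryGenConfig):
    """Markov state paths + Gaussian log10 emissions; returns (trajectories, truth).

    ``truth`` is the list of hidden state paths (0 = low, 1 = high), frame for
    frame, for recovery scoring.
    """
    rng = np.random.default_rng(cfg.seed)
    trajectories, truth = [], []
    for k in range(cfg.n_trajectories):
        n = cfg.exact_frames or int(rng.integers(cfg.min_frames, cfg.max_frames + 1))
        x, states = cfg.hmm.sample(n, rng)
        t = np.arange(n) * cfg.dt
        flags = np.zeros(n, dtype=bool)
        lo, hi = cfg.division_interval
        next_div = rng.uniform(lo, hi)
        for j in range(1, n):
            if t[j] >= next_div:
                flags[j] = True
                next_div += rng.uniform(lo, hi)
        trajectories.append(
            FluorescenceTrajectory(
                cell_id=f"cell{k:04d}", t_min=t, log10_fluorescence=x, division_flags=flags
            )
        )
        truth.append(states)
    return trajectories, truth


#: default snapshot schedule: per level (aTc ng/mL) the low-component weight and
#: the component positions on log10 intensity.  Qualitative calibration only:
#: the single peak shifts upward with inducer, the top two levels are bimodal
#: and the low-state weight grows across them.
DEFAULT_SNAPSHOT_SCHEDULE = (
    {"atc": 300.0, "w_low": 1.0, "mu_low": 2.00, "mu_high": 3.00},
    {"atc": 500.0, "w_low": 1.0, "mu_low": 2.20, "mu_high": 3.00},
    {"atc": 700.0, "w_low": 1.0, "mu_low": 2.45, "mu_high": 3.00},
    {"atc": 900.0, "w_low": 1.0, "mu_low": 2.70, "mu_high": 3.00},
    {"atc": 1100.0, "w_low": 0.0, "mu_low": 2.10, "mu_high": 2.95},
    {"atc": 1300.0, "w_low": 0.20, "mu_low": 2.10, "mu_high": 3.00},
    {"atc": 1500.0, "w_low": 0.35, "mu_low": 2.10, "mu_high": 3.00},
)


@dataclass
class SnapshotGenConfig:
    """Generator settings for steady-state population snapshots."""

    schedule: tuple = DEFAULT_SNAPSHOT_SCHEDULE
    cells_per_level: int = 3000
    sigma_log10: float = 0.15
    mechanism: str = "hmm_mixture"  # or "ssa"
    seed: int = 0
    # ssa-mechanism settings
    rate_params: object = None
    fluorescence_scale: float = 3.0
    t_end: float = 30000.0
    burn_in: float = 2000.0

    def __post_init__(self) -> None:
        if self.cells_per_level < 1:
            raise ValueError("cells_per_level must be >= 1")
        if self.mechanism not in ("hmm_mixture", "ssa"):
            raise ValueError(f"unknown snapshot mechanism {self.mechanism!r}")
        for lv in self.schedule:
            if lv["atc"] > ATC_TOXICITY_NG_PER_ML:
                raise ValueError(
                    f"aTc {lv['atc']} ng/mL exceeds the cytotoxicity bound "
                    f"({ATC_TOXICITY_NG_PER_ML} ng/mL)"
                )
            if not 0.0 <= lv["w_low"] <= 1.0:
                raise ValueError("w_low must be in [0, 1]")


def gen_snapshots(cfg: SnapshotGenConfig) -> list[PopulationSnapshot]:
    """One PopulationSnapshot per inducer level of the schedule."""
    rng = np.random.default_rng(cfg.seed)
    if cfg.mechanism == "hmm_mixture":
        out = []
        for lv in cfg.schedule:
            z_low = rng.random(cfg.cells_per_level) < lv["w_low"]
            mu = np.where(z_low, lv["mu_low"], lv["mu_high"])
            logx = rng.normal(mu, cfg.sigma_log10)
            out.append(PopulationSnapshot(10.0 ** logx, atc_ng_per_ml=lv["atc"]))
        return out
    # ssa mechanism: stationary distributions of the reaction network mapped to
    # fluorescence by a per-molecule scale
    from autorep.params import RateParameters
    from autorep.stochastic_model import sweep_inducer

    params = cfg.rate_params or RateParameters()
    grid = [lv["atc"] for lv in cfg.schedule]
    sweep = sweep_inducer(
        params, grid, replicates=2, seed=cfg.seed, t_end=cfg.t_end, burn_in=cfg.burn_in
    )
    out = []
    for lv in sweep.levels:
        n = rng.choice(
            lv.distribution.support, size=cfg.cells_per_level, p=lv.distribution.pmf
        )
        values = np.maximum(n.astype(float), 1.0) * cfg.fluorescence_scale
        sigma_ln = np.sqrt(np.log(1.0 + cfg.sigma_log10**2))
        values = values * rng.lognormal(-0.5 * sigma_ln**2, sigma_ln, size=values.size)
        out.append(PopulationSnapshot(values, atc_ng_per_ml=lv.atc_ng_per_ml))
    return out


def ssa_to_fluorescence(
    traj: SSATrajectory,
    frame_dt: float = 5.0,
    scale: float = 1.0,
    noise_cv: float = 0.05,
    seed: int = 0,
    cell_id: str = "ssa",
) -> FluorescenceTrajectory:
    """Sample total TetR-Venus at frame boundaries and map to log10 fluorescence.

    Total fluorescent monomers = free TetR + Ta complexes + DNA-bound TetR.
    Multiplicative log-normal noise with the given coefficient of variation is
    applied (mean-preserving).  Totals are floored at one molecule before the
    log so dark frames stay finite.
    """
    if scale <= 0:
        raise ValueError("scale must be positive")
    if frame_dt <= 0:
        raise ValueError("frame_dt must be positive")
    rng = np.random.default_rng(seed)
    t_lo, t_hi = traj.times[0], traj.times[-1]
    frames = np.arange(t_lo, t_hi + 1e-9, frame_dt)
    if frames.size < 2:
        raise ValueError("trajectory too short for the requested frame spacing")
    totals = traj.total_venus_at(frames).astype(float)
    values = np.maximum(totals, 1.0) * scale
    if noise_cv > 0:
        sigma = np.sqrt(np.log(1.0 + noise_cv**2))
        values = values * rng.lognormal(-0.5 * sigma**2, sigma, size=values.size)
    return FluorescenceTrajectory(
        cell_id=cell_id,
        t_min=frames,
        log10_fluorescence=np.log10(values),
    )


def write_snapshots_tsv(snapshots, path) -> None:
    rows = []
    for snap in snapshots:
        for k, v in enumerate(snap.values):
            rows.append((f"cell{k:05d}", v, snap.atc_ng_per_ml))
    pd.DataFrame(rows, columns=["cell_id", "fluorescence", "aTc_ng_per_ml"]).to_csv(
        path, sep="\t", index=False
    )


def write_truth_tsv(trajectories, truth, path) -> None:
    """Ground-truth hidden states in a sidecar table (cell_id, t_min, state)."""
    rows = []
    for traj, states in zip(trajectories, truth):
        for t, s in zip(traj.t_min, states):
            rows.append((traj.cell_id, t, int(s)))
    pd.DataFrame(rows, columns=["cell_id", "t_min", "state"]).to_csv(path, sep="\t", index=False)
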