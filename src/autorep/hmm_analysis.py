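"""Two-state hidden-Markov analysis of single-cell fluorescence trajectories.

Cells switch between a low- and a high-expression state; on log10 fluorescence
each state emits Gaussian noise around its own mean.  Baum-Welch EM (via
hmmlearn) fits the shared transition matrix and emission parameters across all
trajectories jointly; Viterbi decoding segments each trajectory into dwell
intervals, from which switching probabilities, state occupancies and mean
residence times follow.

Residence times: the average residence time of a state is the total time spent
in it divided by the number of exits from it.  Because trajectories are finite,
the first and last dwell segments are censored (their true start/end is
unobserved); estimates are bracketed by computing them both with and without
the censored segments.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from hmmlearn.hmm import GaussianHMM
from hmmlearn.base import ConvergenceMonitor
from sklearn.cluster import KMeans

LOW, HIGH = 0, 1


@dataclass
class FluorescenceTrajectory:
    """Evenly sampled single-cell log10-fluorescence series with division marks."""

    cell_id: str
    t_min: np.ndarray
    log10_fluorescence: np.ndarray
    division_flags: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.t_min = np.asarray(self.t_min, dtype=float)
        self.log10_fluorescence = np.asarray(self.log10_fluorescence, dtype=float)
        if self.t_min.size < 2:
            raise ValueError("trajectory needs at least 2 frames")
        if self.t_min.size != self.log10_fluorescence.size:
            raise ValueError("times and values must have equal length")
        steps = np.diff(self.t_min)
        if not np.allclose(steps, steps[0], rtol=1e-6, atol=1e-9) or steps[0] <= 0:
            raise ValueError("frame times must be uniformly spaced and increasing")
        if not np.all(np.isfinite(self.log10_fluorescence)):
            raise ValueError("fluorescence values must be finite")
        if self.division_flags is None:
            self.division_flags = np.zeros(self.t_min.size, dtype=bool)
        else:
            self.division_flags = np.asarray(self.division_flags, dtype=bool)
            if self.division_flags.size != self.t_min.size:
                raise ValueError("division flags must match frame count")

    @property
    def dt(self) -> float:
        return float(self.t_min[1] - self.t_min[0])

    @property
    def n_frames(self) -> int:
        return int(self.t_min.size)


@dataclass
class TwoStateHMM:
    """Two-state Gaussian-emission HMM on log10 fluorescence.

    State 0 is the low-expression state, state 1 the high-expression state
    (mu_low < mu_high by convention).  ``transmat[i, j]`` is the per-frame
    probability of moving from state i to state j.
    """

    transmat: np.ndarray
    means: np.ndarray      # (mu_low, mu_high)
    variances: np.ndarray  # (var_low, var_high)
    startprob: np.ndarray

    def __post_init__(self) -> None:
        self.transmat = np.asarray(self.transmat, dtype=float)
        self.means = np.asarray(self.means, dtype=float)
        self.variances = np.asarray(self.variances, dtype=float)
        self.startprob = np.asarray(self.startprob, dtype=float)
        if self.transmat.shape != (2, 2):
            raise ValueError("transmat must be 2x2")
        if not np.allclose(self.transmat.sum(axis=1), 1.0, atol=1e-12):
            raise ValueError("transmat rows must sum to 1")
        if np.any(self.variances <= 0):
            raise ValueError("emission variances must be positive")
        if not self.means[0] < self.means[1]:
            raise ValueError("state 0 must have the lower emission mean")
        if not np.isclose(self.startprob.sum(), 1.0):
            raise ValueError("startprob must sum to 1")

    def stationary(self) -> np.ndarray | None:
        """Stationary distribution of the transition matrix; None if reducible."""
        p01, p10 = self.transmat[0, 1], self.transmat[1, 0]
        if p01 + p10 <= 0:
            return None
        p_low = p10 / (p01 + p10)
        return np.array([p_low, 1.0 - p_low])

    def sample(self, n_frames: int, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
        """One trajectory of emissions and hidden states."""
        states = np.empty(n_frames, dtype=int)
        states[0] = rng.choice(2, p=self.startprob)
        for t in range(1, n_frames):
            states[t] = rng.choice(2, p=self.transmat[states[t - 1]])
        x = rng.normal(self.means[states], np.sqrt(self.variances[states]))
        return x, states

    def mixture_density(self, x: np.ndarray, weights: np.ndarray | None = None) -> np.ndarray:
        """Two-Gaussian mixture density (stationary weights by default)."""
        if weights is None:
            weights = self.stationary()
            if weights is None:
                weights = np.array([0.5, 0.5])
        x = np.asarray(x, dtype=float)
        out = np.zeros_like(x)
        for k in range(2):
            s2 = self.variances[k]
            out += weights[k] * np.exp(-((x - self.means[k]) ** 2) / (2 * s2)) / np.sqrt(2 * np.pi * s2)
        return out

    def to_dict(self) -> dict:
        return {
            "transmat": self.transmat.tolist(),
            "means": self.means.tolist(),
            "variances": self.variances.tolist(),
            "startprob": self.startprob.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "TwoStateHMM":
        return cls(
            transmat=np.array(d["transmat"]),
            means=np.array(d["means"]),
            variances=np.array(d["variances"]),
            startprob=np.array(d["startprob"]),
        )


class DegenerateFitError(RuntimeError):
    """All EM restarts collapsed onto a degenerate state assignment."""


class _FullHistoryMonitor(ConvergenceMonitor):
    """ConvergenceMonitor that keeps the whole log-likelihood history."""

    def __init__(self, tol, n_iter, verbose=False):
        super().__init__(tol, n_iter, verbose)
        self.full_history: list[float] = []

    def report(self, log_prob):
        self.full_history.append(float(log_prob))
        super().report(log_prob)


@dataclass
class FitResult:
    model: TwoStateHMM
    log_likelihood: float
    per_trajectory_ll: np.ndarray
    ll_history: list = field(default_factory=list)
    n_restarts_used: int = 0


def _pool(trajectories) -> tuple[np.ndarray, np.ndarray]:
    X = np.concatenate([t.log10_fluorescence for t in trajectories])[:, None]
    lengths = np.array([t.n_frames for t in trajectories])
    return X, lengths


def fit_hmm(
    trajectories,
    restarts: int = 10,
    seed: int = 0,
    max_iter: int = 500,
    rtol: float = 1e-8,
) -> FitResult:
    """Baum-Welch fit of a shared two-state HMM over all trajectories.

    Initialisation is 2-means clustering of the pooled emissions plus a sticky
    transition matrix [[0.9, 0.1], [0.1, 0.9]]; further restarts jitter the
    initial means.  The best (highest log-likelihood) non-degenerate restart
    wins; states are relabelled so that mu_low < mu_high.  EM log-likelihood
    is asserted non-decreasing on every restart.  Convergence: relative
    log-likelihood change below ``rtol`` or ``max_iter`` iterations.
    """
    import logging

    logging.getLogger("hmmlearn.base").setLevel(logging.ERROR)
    X, lengths = _pool(trajectories)
    if X.size < 50:
        raise ValueError("need at least 50 pooled frames to fit")
    rng = np.random.default_rng(seed)
    km = KMeans(n_clusters=2, n_init=5, random_state=int(rng.integers(2**31)))
    labels = km.fit_predict(X)
    base_means = np.sort(km.cluster_centers_.ravel())
    base_vars = np.array(
        [max(X[labels == k].var(), 1e-6) if (labels == k).sum() >= 2 else X.var() for k in (0, 1)]
    )
    pooled_sd = X.std()

    best: tuple[float, GaussianHMM, list] | None = None
    for r in range(restarts):
        means0 = base_means.copy()
        if r > 0:
            means0 = means0 + rng.normal(0.0, 0.25 * pooled_sd, size=2)
        tol_abs = rtol * X.shape[0]  # per-frame scale: relative convergence
        m = GaussianHMM(
            n_components=2,
            covariance_type="diag",
            n_iter=max_iter,
            tol=tol_abs,
            init_params="",
            params="stmc",
            random_state=int(rng.integers(2**31)),
        )
        m.startprob_ = np.array([0.5, 0.5])
        m.transmat_ = np.array([[0.9, 0.1], [0.1, 0.9]])
        m.means_ = means0[:, None]
        m.covars_ = np.maximum(base_vars, 1e-6)[:, None]
        m.monitor_ = _FullHistoryMonitor(tol_abs, max_iter)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            m.fit(X, lengths)
        hist = m.monitor_.full_history
        diffs = np.diff(hist)
        if np.any(diffs < -1e-6 * np.maximum(np.abs(hist[:-1]), 1.0)):
            raise RuntimeError("EM log-likelihood decreased during fitting")
        counts = np.bincount(m.predict(X, lengths), minlength=2)
        if counts.min() < 2:
            continue  # degenerate restart: one state captured < 2 frames
        ll = hist[-1]
        if best is None or ll > best[0]:
            best = (ll, m, hist)
    if best is None:
        raise DegenerateFitError(
            f"all {restarts} restarts degenerate (a state captured < 2 frames)"
        )
    ll, m, hist = best
    order = np.argsort(m.means_.ravel())
    model = TwoStateHMM(
        transmat=m.transmat_[np.ix_(order, order)],
        means=m.means_.ravel()[order],
        variances=m.covars_.ravel()[order],
        startprob=m.startprob_[order],
    )
    per_ll = np.array(
        [m.score(t.log10_fluorescence[:, None]) for t in trajectories]
    )
    return FitResult(
        model=model,
        log_likelihood=float(ll),
        per_trajectory_ll=per_ll,
        ll_history=hist,
        n_restarts_used=restarts,
    )


def _as_hmmlearn(model: TwoStateHMM) -> GaussianHMM:
    m = GaussianHMM(n_components=2, covariance_type="diag", init_params="", params="")
    m.startprob_ = model.startprob
    m.transmat_ = model.transmat
    m.means_ = model.means[:, None]
    m.covars_ = model.variances[:, None]
    return m


@dataclass
class Segment:
    state: int
    start: int
    length: int
    censored: bool


@dataclass
class Segmentation:
    """Viterbi path of one trajectory, as per-frame labels and dwell segments."""

    cell_id: str
    states: np.ndarray
    segments: list
    dt: float

    def __post_init__(self) -> None:
        total = sum(s.length for s in self.segments)
        if total != self.states.size:
            raise ValueError("segments must tile the trajectory")


def decode(traj: FluorescenceTrajectory, model: TwoStateHMM) -> Segmentation:
    """Viterbi most-likely state path; first and last segments flagged censored."""
    m = _as_hmmlearn(model)
    states = m.predict(traj.log10_fluorescence[:, None])
    segments = []
    start = 0
    for k in range(1, states.size + 1):
        if k == states.size or states[k] != states[start]:
            segments.append(Segment(int(states[start]), start, k - start, False))
            start = k
    segments[0].censored = True
    segments[-1].censored = True
    return Segmentation(cell_id=traj.cell_id, states=states, segments=segments, dt=traj.dt)


@dataclass
class ResidenceTimeEstimate:
    """Mean residence time of one state, with finite-length bracketing bounds.

    ``point`` is total observed time in the state divided by the number of
    observed exits; ``lower``/``upper`` bracket it by excluding/including the
    censored (first/last) segments of each trajectory.  ``lower_bound_only``
    marks states that were never observed to exit.
    """

    state: int
    point: float
    lower: float
    upper: float
    n_exits: int
    total_time: float
    lower_bound_only: bool = False


def _residence_one_convention(segs, state: int, dt: float, include_censored: bool):
    time = 0.0
    exits = 0
    for seg in segs:
        for s in seg.segments:
            if s.state != state:
                continue
            if not include_censored and s.censored:
                continue
            time += s.length * dt
            is_last = s.start + s.length == seg.states.size
            if not is_last:
                exits += 1
    return time, exits


def residence_times(segmentations, dt: float | None = None) -> dict[int, ResidenceTimeEstimate]:
    """Per-state mean residence times pooled over decoded trajectories."""
    segs = list(segmentations)
    if not segs:
        raise ValueError("need at least one segmentation")
    if dt is None:
        dt = segs[0].dt
    if not any(not s.censored for seg in segs for s in seg.segments):
        if all(len(seg.segments) == 1 for seg in segs):
            pass  # single-state trajectories: lower-bound-only estimates below
    out = {}
    for state in (LOW, HIGH):
        t_inc, x_inc = _residence_one_convention(segs, state, dt, include_censored=True)
        t_exc, x_exc = _residence_one_convention(segs, state, dt, include_censored=False)
        if t_inc == 0.0:
            continue  # state never visited
        if x_inc == 0:
            out[state] = ResidenceTimeEstimate(
                state=state,
                point=t_inc,
                lower=t_inc,
                upper=float("inf"),
                n_exits=0,
                total_time=t_inc,
                lower_bound_only=True,
            )
            continue
        point = t_inc / x_inc
        cands = [point]
        if x_exc > 0:
            cands.append(t_exc / x_exc)
        out[state] = ResidenceTimeEstimate(
            state=state,
            point=point,
            lower=min(cands),
            upper=max(cands),
            n_exits=x_inc,
            total_time=t_inc,
        )
    return out


@dataclass
class MixtureWeights:
    """State weights: stationary distribution of T and empirical frame occupancy."""

    stationary: np.ndarray | None   # (p_low, p_high) or None for a reducible chain
    empirical: np.ndarray           # frame-occupancy fractions (p_low, p_high)
    stationary_defined: bool


def mixture_weights(model: TwoStateHMM, segmentations) -> MixtureWeights:
    """Both the chain's stationary weights and the decoded frame occupancies."""
    counts = np.zeros(2)
    for seg in segmentations:
        counts += np.bincount(seg.states, minlength=2)
    empirical = counts / counts.sum() if counts.sum() > 0 else np.array([0.5, 0.5])
    stat = model.stationary()
    return MixtureWeights(
        stationary=stat,
        empirical=empirical,
        stationary_defined=stat is not None,
    )


@dataclass
class FitQuality:
    correlation: float
    density_x: np.ndarray
    density_y: np.ndarray


def hmm_fit_quality(trajectories, model: TwoStateHMM, seed: int = 0) -> FitQuality:
    """Quantile-quantile agreement between data and model-simulated surrogates.

    Simulates one surrogate trajectory per data trajectory (matched length),
    pools and sorts both intensity sets and returns their Pearson correlation,
    plus the model's two-Gaussian mixture density for histogram overlays.
    """
    rng = np.random.default_rng(seed)
    data = np.sort(np.concatenate([t.log10_fluorescence for t in trajectories]))
    # sample surrogates in length-sorted order so the result is invariant to
    # the ordering of the input trajectories
    lengths = sorted(t.n_frames for t in trajectories)
    sim = np.sort(np.concatenate([model.sample(n, rng)[0] for n in lengths]))
    corr = float(np.corrcoef(data, sim)[0, 1])
    lo, hi = data.min() - 0.3, data.max() + 0.3
    x = np.linspace(lo, hi, 512)
    return FitQuality(correlation=corr, density_x=x, density_y=model.mixture_density(x))


# ---------------------------------------------------------------------------
# table I/O

def read_trajectories_tsv(path) -> list[FluorescenceTrajectory]:
    """Read trajectory tables (cell_id, t_min, fluorescence, division_flag).

    ``fluorescence`` is linear mean intensity; it is log10-transformed here.
    """
    df = pd.read_csv(path, sep="\t")
    required = {"cell_id", "t_min", "fluorescence"}
    if not required.issubset(df.columns):
        raise ValueError(f"trajectory table must have columns {sorted(required)}")
    out = []
    for cid, grp in df.groupby("cell_id", sort=False):
        grp = grp.sort_values("t_min")
        flags = grp["division_flag"].to_numpy().astype(bool) if "division_flag" in grp else None
        out.append(
            FluorescenceTrajectory(
                cell_id=str(cid),
                t_min=grp["t_min"].to_numpy(),
                log10_fluorescence=np.log10(grp["fluorescence"].to_numpy()),
                division_flags=flags,
            )
        )
    return out


def write_trajectories_tsv(trajectories, path) -> None:
    rows = []
    for t in trajectories:
        for k in range(t.n_frames):
            rows.append(
                (t.cell_id, t.t_min[k], 10.0 ** t.log10_fluorescence[k], int(t.division_flags[k]))
            )
    pd.DataFrame(rows, columns=["cell_id", "t_min", "fluorescence", "division_flag"]).to_csv(
        path, sep="\t", index=False
    )


def write_model_json(fit: FitResult, path) -> None:
    payload = fit.model.to_dict()
    payload["log_likelihood"] = fit.log_likelihood
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)


def segments_table(segmentations) -> pd.DataFrame:
    rows = []
    for seg in segmentations:
        for s in seg.segments:
            rows.append((seg.cell_id, s.state, s.start, s.length, s.length * seg.dt, int(s.censored)))
    return pd.DataFrame(
        rows, columns=["cell_id", "state", "start_frame", "n_frames", "duration_min", "censored"]
    )


def residence_table(estimates: dict) -> pd.DataFrame:
    rows = []
    names = {LOW: "low", HIGH: "high"}
    for state, e in sorted(estimates.items()):
        rows.append(
            (names[state], e.point, e.lower, e.upper, e.n_exits, e.total_time, int(e.lower_bound_only))
        )
    return pd.DataFrame(
        rows,
        columns=["state", "mean_residence_min", "lower_min", "upper_min", "n_exits", "total_time_min", "lower_bound_only"],
    )
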