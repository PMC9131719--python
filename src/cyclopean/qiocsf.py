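"""Quick interocular-correlation sensitivity estimation (qIOCSF).

A Bayesian adaptive procedure in the quick-CSF family: a discrete joint
posterior over the four truncated log-parabola parameters is updated after
every two-alternative forced-choice trial, and each next stimulus (envelope
frequency fm, modulation M) is chosen to minimize the expected posterior
entropy (equivalently, to maximize the expected information gain).

The response model is a Weibull psychometric function with guess rate 1/2
for the two-alternative orientation judgment:

    p(correct | M, f, theta) = 1/2 + (1/2 - lapse) * (1 - exp(-(M * 10^S(f))^slope))

so that at the threshold modulation M_t = 10^-S(f) performance is about 79%
for the default lapse of 0.04 and slope of 3.5.

The statsmodels-style surface is `QuickIOCSF` (the model: grid, candidate
stimuli, psychometric constants) whose `fit` / `fit_trials` methods return a
`QuickIOCSFResults` carrying estimates, posterior spreads, the trial log and
a `summary()` table.  The lower-level operations (`init_posterior`,
`update_posterior`, `select_stimulus`, `prob_correct`) are exposed as plain
functions for direct use and for oracle comparisons.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .iocsf import KAPPA, IOCSFParams, aulio_csf, log_sensitivity

__all__ = [
    "GridSpec", "PosteriorGrid", "QTrialRecord", "prob_correct",
    "init_posterior", "update_posterior", "select_stimulus",
    "default_candidates", "QuickIOCSF", "QuickIOCSFResults",
    "run_qiocsf_session",
]

def _xlogx(p: np.ndarray) -> np.ndarray:
    """x * log(x) with the 0 log 0 = 0 convention."""
    p = np.asarray(p, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        return np.where(p > 0, p * np.log(np.maximum(p, 1e-300)), 0.0)


DEFAULT_LAPSE = 0.04
DEFAULT_SLOPE = 3.5
_AXIS_NAMES = ("gamma_max", "f_max", "beta_octaves", "trunc_delta")
_TIE_TOL = 1e-12


@dataclass(frozen=True)
class GridSpec:
    """Bounds and sizes of the discrete 4-D parameter lattice.

    gamma_max and f_max are log-spaced; bandwidth and truncation linear.
    """

    gamma_max_bounds: tuple[float, float] = (2.0, 200.0)
    gamma_max_n: int = 12
    f_max_bounds: tuple[float, float] = (0.5, 5.0)
    f_max_n: int = 12
    beta_bounds: tuple[float, float] = (1.0, 6.0)
    beta_n: int = 8
    delta_bounds: tuple[float, float] = (0.0, 1.5)
    delta_n: int = 8

    def axes(self) -> dict[str, np.ndarray]:
        for lo, hi, n in (
            (*self.gamma_max_bounds, self.gamma_max_n),
            (*self.f_max_bounds, self.f_max_n),
            (*self.beta_bounds, self.beta_n),
            (*self.delta_bounds, self.delta_n),
        ):
            if n < 1 or lo >= hi:
                raise ValueError("grid axes need at least one point and lo < hi")
        return {
            "gamma_max": np.geomspace(*self.gamma_max_bounds, self.gamma_max_n),
            "f_max": np.geomspace(*self.f_max_bounds, self.f_max_n),
            "beta_octaves": np.linspace(*self.beta_bounds, self.beta_n),
            "trunc_delta": np.linspace(*self.delta_bounds, self.delta_n),
        }


@dataclass(frozen=True)
class QTrialRecord:
    """One 2AFC orientation-identification trial."""

    trial_index: int
    fm: float
    M: float
    orientation_true: int
    response_correct: bool


class PosteriorGrid:
    """Discrete joint posterior over the four IOCSF parameters."""

    def __init__(self, axes: dict[str, np.ndarray], mass: np.ndarray):
        if tuple(axes) != _AXIS_NAMES:
            axes = {name: np.asarray(axes[name], float) for name in _AXIS_NAMES}
        self.axes = {k: np.asarray(v, dtype=float) for k, v in axes.items()}
        for name, ax in self.axes.items():
            if ax.ndim != 1 or np.any(np.diff(ax) <= 0):
                raise ValueError(f"axis {name} must be 1-D strictly increasing")
        shape = tuple(len(v) for v in self.axes.values())
        mass = np.asarray(mass, dtype=float)
        if mass.shape != shape:
            raise ValueError(f"mass shape {mass.shape} does not match axes {shape}")
        if np.any(mass < 0):
            raise ValueError("posterior mass must be nonnegative")
        total = mass.sum()
        if not np.isclose(total, 1.0, atol=1e-12, rtol=0):
            raise ValueError(f"posterior mass must sum to 1 (got {total!r})")
        self.mass = mass
        self._cells: tuple[np.ndarray, ...] | None = None

    @property
    def shape(self) -> tuple[int, ...]:
        return self.mass.shape

    @property
    def n_cells(self) -> int:
        return self.mass.size

    def cell_params(self) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
        """Flat per-cell parameter arrays (gamma, f_max, beta, delta)."""
        if self._cells is None:
            grids = np.meshgrid(*self.axes.values(), indexing="ij")
            self._cells = tuple(g.ravel() for g in grids)
        return self._cells

    def marginal(self, name: str) -> np.ndarray:
        axis = _AXIS_NAMES.index(name)
        other = tuple(i for i in range(4) if i != axis)
        return self.mass.sum(axis=other)

    def entropy(self) -> float:
        """Shannon entropy of the joint mass, nats."""
        p = self.mass.ravel()
        return float(-np.sum(_xlogx(p)))

    def mean_params(self) -> IOCSFParams:
        """Marginal posterior means; log10 scale for gamma_max and f_max."""
        est = {}
        for name in _AXIS_NAMES:
            ax, m = self.axes[name], self.marginal(name)
            if name in ("gamma_max", "f_max"):
                est[name] = float(10.0 ** np.sum(m * np.log10(ax)))
            else:
                est[name] = float(np.sum(m * ax))
        # keep within the model's admissible region
        est["gamma_max"] = max(est["gamma_max"], np.nextafter(1.0, 2.0))
        return IOCSFParams(est["gamma_max"], est["f_max"],
                           est["beta_octaves"], est["trunc_delta"])

    def map_params(self) -> IOCSFParams:
        idx = np.unravel_index(int(np.argmax(self.mass)), self.shape)
        vals = [float(self.axes[name][i]) for name, i in zip(_AXIS_NAMES, idx)]
        return IOCSFParams(*vals)

    def sd_log10(self, name: str) -> float:
        """Posterior SD of a parameter (log10 scale for gamma_max / f_max)."""
        ax, m = self.axes[name], self.marginal(name)
        x = np.log10(ax) if name in ("gamma_max", "f_max") else ax
        mu = np.sum(m * x)
        return float(np.sqrt(np.sum(m * (x - mu) ** 2)))


def prob_correct(M, f, params: IOCSFParams, lapse: float = DEFAULT_LAPSE,
                 slope: float = DEFAULT_SLOPE):
    """2AFC probability of a correct orientation judgment (Weibull link)."""
    M = np.asarray(M, dtype=float)
    if np.any(M < 0) or np.any(M > 1):
        raise ValueError("modulation M must lie in [0, 1]")
    _check_psychometric(lapse, slope)
    s = np.asarray(log_sensitivity(f, params))
    p = _weibull_2afc(M, s, lapse, slope)
    return float(p) if p.ndim == 0 else p


def _check_psychometric(lapse: float, slope: float) -> None:
    if not 0.0 <= lapse < 0.1:
        raise ValueError("lapse must lie in [0, 0.1)")
    if slope <= 0:
        raise ValueError("psychometric slope must be positive")


def _weibull_2afc(M, log_sens, lapse, slope):
    x = M * 10.0**np.asarray(log_sens)
    return 0.5 + (0.5 - lapse) * (1.0 - np.exp(-(x**slope)))


def _log_sens_cells(f: float, gamma, f_max, beta, delta):
    """Vectorized truncated log-parabola over per-cell parameter arrays."""
    log_gain = np.log10(gamma)
    half_width = beta * KAPPA / 2.0
    sp = log_gain - KAPPA * ((np.log10(f) - np.log10(f_max)) / half_width) ** 2
    floor = log_gain - delta
    return np.where((f < f_max) & (sp < floor), floor, sp)


def _likelihood_matrix(post: PosteriorGrid, candidates: np.ndarray,
                       lapse: float, slope: float) -> np.ndarray:
    """p(correct) for every (candidate, cell): shape (C, n_cells)."""
    gamma, f_max, beta, delta = post.cell_params()
    P = np.empty((len(candidates), post.n_cells))
    # group by frequency: S(f) per cell is shared across modulation levels
    for f in np.unique(candidates[:, 0]):
        rows = np.nonzero(candidates[:, 0] == f)[0]
        sens = 10.0 ** _log_sens_cells(f, gamma, f_max, beta, delta)
        x = candidates[rows, 1][:, None] * sens[None, :]
        P[rows] = 0.5 + (0.5 - lapse) * (1.0 - np.exp(-(x**slope)))
    return P


def init_posterior(
    grid: GridSpec | dict[str, np.ndarray] | None = None,
    priors: dict[str, np.ndarray] | None = None,
) -> PosteriorGrid:
    """Normalized joint prior: independent marginals, uniform by default."""
    if grid is None:
        grid = GridSpec()
    axes = grid.axes() if isinstance(grid, GridSpec) else {
        k: np.asarray(v, float) for k, v in grid.items()
    }
    if any(len(ax) == 0 for ax in axes.values()):
        raise ValueError("empty grid axis")
    marginals = []
    for name in _AXIS_NAMES:
        if priors and name in priors:
            w = np.asarray(priors[name], dtype=float)
            if w.shape != axes[name].shape or np.any(w < 0) or w.sum() <= 0:
                raise ValueError(f"invalid prior weights for {name}")
        else:
            w = np.ones_like(axes[name])
        marginals.append(w / w.sum())
    mass = marginals[0]
    for m in marginals[1:]:
        mass = np.multiply.outer(mass, m)
    return PosteriorGrid(axes, mass / mass.sum())


def update_posterior(
    post: PosteriorGrid, trial: QTrialRecord,
    lapse: float = DEFAULT_LAPSE, slope: float = DEFAULT_SLOPE,
) -> PosteriorGrid:
    """Bayes update of the posterior with one trial's outcome."""
    _check_psychometric(lapse, slope)
    if not 0.0 <= trial.M <= 1.0:
        raise ValueError("trial modulation outside [0, 1]")
    gamma, f_max, beta, delta = post.cell_params()
    s = _log_sens_cells(trial.fm, gamma, f_max, beta, delta)
    p_correct = _weibull_2afc(trial.M, s, lapse, slope)
    like = p_correct if trial.response_correct else 1.0 - p_correct
    w = post.mass.ravel() * like
    total = w.sum()
    if not total > 0 or not np.isfinite(total):
        raise ValueError(
            "posterior update produced zero total mass "
            f"(trial fm={trial.fm}, M={trial.M}, correct={trial.response_correct})"
        )
    return PosteriorGrid(post.axes, (w / total).reshape(post.shape))


def _expected_entropies(p: np.ndarray, P: np.ndarray, PlogP: np.ndarray,
                        QlogQ: np.ndarray) -> np.ndarray:
    """Expected posterior entropy (nats) after one trial, per candidate.

    Uses H(w/s) = log s - sum(w log w)/s with w = p * P decomposed as
    sum(w log w) = P @ (p log p) + (P log P) @ p, which needs only
    matrix-vector products against precomputed P log P tables.
    """
    Q = 1.0 - P
    plogp = _xlogx(p)
    s_c = P @ p
    s_i = Q @ p
    wlog_c = P @ plogp + PlogP @ p
    wlog_i = Q @ plogp + QlogQ @ p
    with np.errstate(divide="ignore", invalid="ignore"):
        h_c = np.where(s_c > 0, np.log(np.maximum(s_c, 1e-300)) - wlog_c / np.maximum(s_c, 1e-300), 0.0)
        h_i = np.where(s_i > 0, np.log(np.maximum(s_i, 1e-300)) - wlog_i / np.maximum(s_i, 1e-300), 0.0)
    return s_c * h_c + s_i * h_i


def _sort_candidates(candidates) -> np.ndarray:
    cand = np.asarray(candidates, dtype=float)
    if cand.ndim != 2 or cand.shape[1] != 2 or len(cand) == 0:
        raise ValueError("candidates must be a nonempty (C, 2) array of (fm, M)")
    order = np.lexsort((cand[:, 1], cand[:, 0]))
    return cand[order]


def select_stimulus(
    post: PosteriorGrid, candidates,
    lapse: float = DEFAULT_LAPSE, slope: float = DEFAULT_SLOPE,
) -> tuple[float, float]:
    """Candidate (fm, M) minimizing expected posterior entropy.

    Ties (within numerical tolerance) are broken toward the lowest fm, then
    the lowest M.
    """
    cand = _sort_candidates(candidates)
    P = _likelihood_matrix(post, cand, lapse, slope)
    eh = _expected_entropies(post.mass.ravel(), P, _xlogx(P), _xlogx(1 - P))
    best = int(np.nonzero(eh <= eh.min() + _TIE_TOL)[0][0])
    return float(cand[best, 0]), float(cand[best, 1])


def default_candidates(
    f_lo: float = 0.94, f_hi: float = 2.54, n_f: int = 12,
    m_lo: float = 0.02, m_hi: float = 1.0, n_m: int = 25,
) -> np.ndarray:
    """Log-spaced candidate stimulus lattice (fm x M), ordered by (fm, M)."""
    fs = np.geomspace(f_lo, f_hi, n_f)
    ms = np.geomspace(m_lo, m_hi, n_m)
    return np.array([(f, m) for f in fs for m in ms])


@dataclass
class QuickIOCSFResults:
    """Estimates and diagnostics from one qIOCSF session."""

    params: IOCSFParams
    params_map: IOCSFParams
    posterior: PosteriorGrid
    trials: pd.DataFrame
    seed: int | None
    presentation_s: float = 1.0  # logged stimulus duration per trial

    @property
    def n_trials(self) -> int:
        return len(self.trials)

    def aulio(self, f_lo: float = 0.94, f_hi: float = 2.54, n_grid: int = 100) -> float:
        return aulio_csf(self.params, f_lo, f_hi, n_grid)

    def sd_log10(self, name: str) -> float:
        return self.posterior.sd_log10(name)

    def summary(self) -> str:
        buf = io.StringIO()
        buf.write("Quick IOC sensitivity function estimate\n")
        buf.write(f"  trials: {self.n_trials}   seed: {self.seed}\n")
        buf.write(f"  {'parameter':<14}{'estimate':>10}  {'post. SD':>9}  scale\n")
        rows = [
            ("gamma_max", self.params.gamma_max, "log10"),
            ("f_max", self.params.f_max, "log10"),
            ("beta_octaves", self.params.beta_octaves, "linear"),
            ("trunc_delta", self.params.trunc_delta, "linear"),
        ]
        for name, val, scale in rows:
            buf.write(f"  {name:<14}{val:>10.4g}  {self.sd_log10(name):>9.3f}  {scale}\n")
        buf.write(f"  AULIOCSF [0.94, 2.54] c/d: {self.aulio():.4f}\n")
        return buf.getvalue()

    def plot(self, ax=None, f_lo: float = 0.94, f_hi: float = 2.54):
        """Log-log sensitivity curve of the point estimate."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        f = np.geomspace(f_lo, f_hi, 200)
        ax.plot(f, 10.0 ** np.asarray(log_sensitivity(f, self.params)))
        ax.set(xscale="log", yscale="log", xlabel="spatial frequency (c/d)",
               ylabel="IOC sensitivity (1/M)")
        return ax


class QuickIOCSF:
    """The adaptive estimation model: lattice, candidates, psychometric link.

    Likelihood tables over (candidate x cell) are precomputed once, so
    repeated sessions (e.g. a whole simulated cohort) reuse them.
    """

    def __init__(
        self,
        grid: GridSpec | None = None,
        candidates: np.ndarray | None = None,
        lapse: float = DEFAULT_LAPSE,
        slope: float = DEFAULT_SLOPE,
        priors: dict[str, np.ndarray] | None = None,
    ):
        _check_psychometric(lapse, slope)
        self.grid = grid or GridSpec()
        self.lapse = lapse
        self.slope = slope
        self.priors = priors
        self.prior = init_posterior(self.grid, priors)
        self.candidates = _sort_candidates(
            candidates if candidates is not None else default_candidates()
        )
        self._P = _likelihood_matrix(self.prior, self.candidates, lapse, slope)
        self._PlogP = _xlogx(self._P)
        self._QlogQ = _xlogx(1.0 - self._P)

    def _select_index(self, p_flat: np.ndarray) -> int:
        eh = _expected_entropies(p_flat, self._P, self._PlogP, self._QlogQ)
        return int(np.nonzero(eh <= eh.min() + _TIE_TOL)[0][0])

    def fit(
        self,
        observer: IOCSFParams,
        n_trials: int = 100,
        seed: int | np.random.SeedSequence | None = 0,
        observer_lapse: float | None = None,
        observer_slope: float | None = None,
    ) -> QuickIOCSFResults:
        """Run a simulated adaptive session against a generative observer.

        The observer responds by Bernoulli draws from its own psychometric
        function (which may use a different lapse/slope than the fitting
        model).  With ``n_trials=0`` the estimate is the prior mean.
        """
        if n_trials < 0:
            raise ValueError("n_trials must be nonnegative")
        obs_lapse = self.lapse if observer_lapse is None else observer_lapse
        obs_slope = self.slope if observer_slope is None else observer_slope
        rng = np.random.default_rng(seed)

        p = self.prior.mass.ravel().copy()
        records: list[QTrialRecord] = []
        for t in range(n_trials):
            idx = self._select_index(p)
            fm, M = self.candidates[idx]
            orientation = int(rng.choice((45, 135)))
            p_corr = prob_correct(M, fm, observer, obs_lapse, obs_slope)
            correct = bool(rng.random() < p_corr)
            like = self._P[idx] if correct else 1.0 - self._P[idx]
            p = p * like
            total = p.sum()
            if not total > 0:
                raise ValueError("posterior update produced zero total mass")
            p /= total
            records.append(QTrialRecord(t, float(fm), float(M), orientation, correct))
        return self._results(p, records, seed)

    def fit_trials(self, trials) -> QuickIOCSFResults:
        """Posterior from an existing trial log (list of records or DataFrame)."""
        if isinstance(trials, pd.DataFrame):
            trials = [
                QTrialRecord(int(r.trial_index), float(r.fm), float(r.M),
                             int(r.orientation_true), bool(r.response_correct))
                for r in trials.itertuples()
            ]
        post = self.prior
        for tr in trials:
            post = update_posterior(post, tr, self.lapse, self.slope)
        return self._results(post.mass.ravel(), list(trials), None)

    def _results(self, p_flat, records, seed) -> QuickIOCSFResults:
        post = PosteriorGrid(self.prior.axes, p_flat.reshape(self.prior.shape))
        trials = pd.DataFrame(
            [(r.trial_index, r.fm, r.M, r.orientation_true, r.response_correct)
             for r in records],
            columns=["trial_index", "fm", "M", "orientation_true", "response_correct"],
        )
        seed_val = None
        if isinstance(seed, (int, np.integer)):
            seed_val = int(seed)
        return QuickIOCSFResults(
            params=post.mean_params(), params_map=post.map_params(),
            posterior=post, trials=trials, seed=seed_val,
        )


def run_qiocsf_session(
    observer,
    n_trials: int = 100,
    seed: int | np.random.SeedSequence | None = 0,
    engine: QuickIOCSF | None = None,
    **engine_kwargs,
) -> tuple[IOCSFParams, pd.DataFrame]:
    """One simulated session: returns (parameter estimate, trial log).

    ``observer`` is either an :class:`IOCSFParams` or any object exposing
    ``iocsf_true``, ``lapse`` and ``psychometric_slope`` attributes.
    """
    if isinstance(observer, IOCSFParams):
        params, obs_lapse, obs_slope = observer, None, None
    else:
        params = observer.iocsf_true
        obs_lapse = getattr(observer, "lapse", None)
        obs_slope = getattr(observer, "psychometric_slope", None)
    eng = engine or QuickIOCSF(**engine_kwargs)
    res = eng.fit(params, n_trials=n_trials, seed=seed,
                  observer_lapse=obs_lapse, observer_slope=obs_slope)
    return res.params, res.trials
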