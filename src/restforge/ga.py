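"""Genetic-algorithm calibration of the minimal ventricular model to a target APDR.

The calibrator searches the 28-dimensional parameter space for a model
whose dynamic-restitution curve (APD90 against preceding DI) matches a
target logarithmic restitution curve, with fitness expressed as the mean
absolute error in milliseconds plus an optional action-potential
morphology penalty against a base-model template.

Search is performed in log-parameter space with a real-coded GA:
tournament selection, BLX-alpha blend crossover, per-gene Gaussian
mutation, and elitism.  Parameters whose base value is zero cannot be
scaled multiplicatively and stay frozen.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator

from . import _kernels
from .cell import STIM_DURATION, default_stim_amplitude, rescale_voltage, simulate_train
from .cohorts import cohort_table, log_restitution_coefficients
from .params import BOFCParams, PARAM_NAMES, make_base_params, resting_state

__all__ = [
    "FitnessProtocol",
    "GATarget",
    "GAConfig",
    "GAResult",
    "GACalibrator",
    "apdr_fitness",
    "run_ga",
    "make_cohort_target",
    "desk_config",
    "full_scale_config",
    "default_bounds",
    "PENALTY_FITNESS",
]

PENALTY_FITNESS = 1000.0  # ms; non-capturing / blown-up parameter sets

#: parameters searched on the wide multiplicative range
_WIDE_FACTOR = 20.0
#: thresholds & gate midpoints: narrower range, clipped for model sanity
_NARROW_FACTOR = 2.0
_NARROW_CLIP = 1.6
_NARROW_NAMES = frozenset(
    {
        "u_u",
        "theta_v",
        "theta_w",
        "theta_v_minus",
        "theta_o",
        "u_w_minus",
        "u_so",
        "u_s",
        "w_inf_star",
    }
)
#: fast-inward / excitability-recovery time constants: the fitted cohort
#: models keep the depolarization phase near base (near-base Vmax, dV/dt
#: and time-to-peak; fast-inward current similar between cohorts), so
#: these are searched on the narrow multiplicative range as well
_DEPOL_TAUS = frozenset({"tau_fi", "tau_v1_minus", "tau_v2_minus", "tau_v_plus"})


def default_bounds(base: BOFCParams | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Per-parameter (lo, hi) search bounds around the base set.

    Repolarization time constants and slope factors span
    [base/20, base*20] (the reported best-fit populations contain
    fold-changes up to ~17, all in the slow-current parameters);
    thresholds and gate midpoints span [base/2, base*2] clipped at 1.6;
    the depolarization-phase time constants span [base/2, base*2]
    unclipped.  Zero-valued base entries are frozen.
    """
    base = base or make_base_params()
    b = base.to_vector()
    lo = np.empty_like(b)
    hi = np.empty_like(b)
    for i, name in enumerate(PARAM_NAMES):
        if b[i] == 0.0:
            lo[i] = hi[i] = 0.0
        elif name in _NARROW_NAMES:
            lo[i] = b[i] / _NARROW_FACTOR
            hi[i] = min(b[i] * _NARROW_FACTOR, _NARROW_CLIP)
        elif name in _DEPOL_TAUS:
            lo[i] = b[i] / _NARROW_FACTOR
            hi[i] = b[i] * _NARROW_FACTOR
        else:
            lo[i] = b[i] / _WIDE_FACTOR
            hi[i] = b[i] * _WIDE_FACTOR
    return lo, hi


#: clinical pacing protocol (matches the electrogram acquisition bursts)
CLINICAL_CLS = (600.0, 550.0, 500.0, 450.0, 400.0, 350.0)
#: cell-scan-range protocol: calibrates the model over the full DI range
#: on which the alternans scan operates (620 -> 260 ms, coarsened to 20 ms)
SCAN_RANGE_CLS = tuple(float(c) for c in range(620, 259, -20))


@dataclass(frozen=True)
class FitnessProtocol:
    """Dynamic-restitution protocol used inside the fitness function.

    The default calibrates over the cell-scan cycle-length range so the
    fitted model is constrained on the full DI support where alternans
    predictions are made; the clinical burst protocol is available as
    ``FitnessProtocol(cls=CLINICAL_CLS, beats_per_cl=20)``.
    """

    cls: tuple = SCAN_RANGE_CLS
    beats_per_cl: int = 10
    # keep the post-step transient beats: steady beats alone pin the target
    # curve's values but not its slope (they all satisfy APD + DI = CL)
    exclude_first: int = 1
    exclude_last: int = 0
    dt_min: float = 0.02  # ms; upstroke resolution of the adaptive stepper
    dt_max: float = 0.1
    err_tol: float = 0.002
    stim_dur: float = STIM_DURATION


@dataclass
class GATarget:
    """Calibration target: a logarithmic restitution curve plus morphology template.

    ``alpha`` and ``beta`` define ARI(DI) = alpha + beta ln(DI) over
    [di_min, di_max] ms.  ``lambda_morph`` weights the mean absolute mV
    deviation of a cycle-length-600 beat from the base-model template;
    zero disables the term.
    """

    alpha: float
    beta: float
    di_min: float
    di_max: float
    lambda_morph: float = 1.0
    template_mv: np.ndarray | None = field(default=None, repr=False)
    label: str = ""
    #: optional explicit (DI, ARI) points; when set the target evaluates by
    #: linear interpolation through them instead of the log curve
    points_di: np.ndarray | None = field(default=None, repr=False)
    points_ari: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self):
        if self.di_min <= 0 or self.di_max <= self.di_min:
            raise ValueError("DI range must be positive and ordered")
        if self.lambda_morph < 0:
            raise ValueError("lambda_morph must be >= 0")

    def __call__(self, di):
        if self.points_di is not None:
            return np.interp(di, self.points_di, self.points_ari)
        return self.alpha + self.beta * np.log(di)

    @classmethod
    def from_points(
        cls,
        di,
        ari,
        lambda_morph: float = 1.0,
        label: str = "",
        interpolate: bool = False,
    ) -> "GATarget":
        """Target from explicit (DI, ARI) points.

        By default a log curve is fitted (OLS) and used for evaluation;
        with ``interpolate=True`` the target passes exactly through the
        points (used e.g. for self-target recovery experiments).
        """
        di = np.asarray(di, dtype=float)
        ari = np.asarray(ari, dtype=float)
        if np.any(di <= 0):
            raise ValueError("all DI must be positive")
        beta, alpha = np.polyfit(np.log(di), ari, 1)
        order = np.argsort(di)
        return cls(
            alpha=float(alpha),
            beta=float(beta),
            di_min=float(di.min()),
            di_max=float(di.max()),
            lambda_morph=lambda_morph,
            label=label,
            points_di=di[order] if interpolate else None,
            points_ari=ari[order] if interpolate else None,
        )


_MORPH_CL = 600.0
_MORPH_DT = 0.05  # ms; fixed-step trace for the morphology comparison
#: comparison grid: 0.1 ms over the first 10 ms so the ~1 ms upstroke and
#: peak actually register in the mean absolute deviation, 1 ms elsewhere
_MORPH_GRID = np.concatenate([np.arange(0.0, 10.0, 0.1), np.arange(10.0, _MORPH_CL, 1.0)])
_template_cache: dict[float, np.ndarray] = {}


def _morphology_trace(params: BOFCParams) -> np.ndarray:
    """Rested cycle-length-600 beat on the morphology comparison grid, in mV."""
    tr = simulate_train(params, _MORPH_CL, 1, dt=_MORPH_DT)
    return np.interp(_MORPH_GRID, tr.time, tr.voltage)


def base_morphology_template() -> np.ndarray:
    if _MORPH_CL not in _template_cache:
        _template_cache[_MORPH_CL] = _morphology_trace(make_base_params())
    return _template_cache[_MORPH_CL]


def make_cohort_target(cohort: str, lambda_morph: float = 1.0) -> GATarget:
    """GA target from a cohort's published per-CL mean (DI, ARI) anchors.

    The target's DI validity range is the span of the clinical anchors;
    simulated beats with shorter diastolic intervals are not scored
    against the (extrapolated) curve.
    """
    tab = cohort_table(cohort)
    alpha, beta = log_restitution_coefficients(cohort)
    target = GATarget(
        alpha=alpha,
        beta=beta,
        di_min=float(tab["di_mean"].min()),
        di_max=float(tab["di_mean"].max()),
        lambda_morph=lambda_morph,
        label=cohort.lower(),
    )
    if lambda_morph > 0:
        target.template_mv = base_morphology_template()
    return target


@dataclass
class GAConfig:
    """Genetic-algorithm settings.  ``seed`` is mandatory."""

    seed: int
    population_size: int = 1512
    max_generations: int = 300
    tournament_size: int = 3
    crossover_prob: float = 0.9
    blx_alpha: float = 0.5
    mutation_prob: float = 2.0 / 28.0
    mutation_sigma: float = 0.1  # log-space
    elitism: int = 2
    convergence_window: int = 25
    convergence_tol: float = 0.01  # ms
    init: str = "log"  # initial sampling: 'log' (log-uniform) or 'linear'
    protocol: FitnessProtocol = field(default_factory=FitnessProtocol)

    def __post_init__(self):
        if self.population_size < 4:
            raise ValueError("population must be >= 4")
        if self.seed is None:
            raise ValueError("seed is mandatory")


def desk_config(seed: int, population_size: int = 100, max_generations: int = 60) -> GAConfig:
    """Scaled settings for desk-scale runs (minutes on one CPU)."""
    return GAConfig(seed=seed, population_size=population_size, max_generations=max_generations)


def full_scale_config(seed: int) -> GAConfig:
    """Full-scale settings (population 1512; hours on one CPU)."""
    return GAConfig(seed=seed, population_size=1512, max_generations=300)


def _protocol_stims(protocol: FitnessProtocol):
    stim_times = []
    included = []
    t = 0.0
    for cl in protocol.cls:
        for b in range(protocol.beats_per_cl):
            stim_times.append(t)
            included.append(
                protocol.exclude_first <= b < protocol.beats_per_cl - protocol.exclude_last
            )
            t += cl
    return np.asarray(stim_times), np.asarray(included, dtype=bool), t + protocol.cls[-1]


def _restitution_error(vec, target: GATarget, protocol: FitnessProtocol, stim_amp, cache):
    stim_times, included, total = cache
    state = np.array([vec[0], 1.0, 1.0, 0.5 * (1.0 + np.tanh(vec[23] * (vec[0] - vec[24])))])
    t_act, t_end, apd, cap, _, ok = _kernels.paced_beats_adaptive(
        vec,
        _kernels.make_gate_table(vec),
        state,
        stim_times,
        total,
        protocol.stim_dur,
        stim_amp,
        protocol.dt_min,
        protocol.dt_max,
        protocol.err_tol,
    )
    if not ok or np.any(cap == 0.0):
        return PENALTY_FITNESS
    di = np.empty_like(apd)
    di[0] = np.nan
    di[1:] = t_act[1:] - t_end[:-1]
    m = included & np.isfinite(di) & np.isfinite(apd)
    m &= (di >= target.di_min) & (di <= target.di_max)
    if m.sum() < 5:
        return PENALTY_FITNESS
    return float(np.mean(np.abs(apd[m] - target(di[m]))))


def apdr_fitness(
    params: BOFCParams | np.ndarray,
    target: GATarget,
    protocol: FitnessProtocol | None = None,
    stim_amp: float | None = None,
) -> float:
    """Fitness (ms) of a parameter set against a restitution target.

    Mean absolute APD90 deviation from the target curve over the retained
    dynamic-restitution points whose DI lies in the target's validity
    range, plus ``lambda_morph`` times the mean absolute voltage deviation
    (mV) from the morphology template.  Simulation failures and loss of
    1:1 capture return a large finite penalty so the GA can continue.
    """
    protocol = protocol or FitnessProtocol()
    if stim_amp is None:
        stim_amp = default_stim_amplitude()
    vec = params.to_vector() if isinstance(params, BOFCParams) else np.asarray(params, float)
    cache = _protocol_stims(protocol)
    err = _restitution_error(vec, target, protocol, stim_amp, cache)
    if err >= PENALTY_FITNESS:
        return err
    if target.lambda_morph > 0 and target.template_mv is not None:
        try:
            morph = _morphology_trace(BOFCParams.from_vector(vec))
        except Exception:
            return PENALTY_FITNESS
        err += target.lambda_morph * float(np.mean(np.abs(morph - target.template_mv)))
    return err


@dataclass
class GAResult:
    """Final state of a GA run."""

    population: np.ndarray  # (n, 28) raw parameter values
    fitness: np.ndarray  # (n,)
    best_params: BOFCParams
    best_fitness: float
    history: np.ndarray  # best fitness per generation (non-increasing)
    generations: int
    config: GAConfig
    target_label: str = ""


class GACalibrator(BaseEstimator):
    """Scikit-learn style wrapper around the GA search.

    Parameters mirror :class:`GAConfig`.  ``fit`` accepts either a
    :class:`GATarget` or explicit restitution points ``(di, ari)`` and
    exposes the fitted population through trailing-underscore attributes.
    """

    def __init__(
        self,
        seed: int = 0,
        population_size: int = 100,
        max_generations: int = 60,
        tournament_size: int = 3,
        crossover_prob: float = 0.9,
        blx_alpha: float = 0.5,
        mutation_prob: float = 2.0 / 28.0,
        mutation_sigma: float = 0.1,
        elitism: int = 2,
        convergence_window: int = 25,
        convergence_tol: float = 0.01,
        lambda_morph: float = 1.0,
    ):
        self.seed = seed
        self.population_size = population_size
        self.max_generations = max_generations
        self.tournament_size = tournament_size
        self.crossover_prob = crossover_prob
        self.blx_alpha = blx_alpha
        self.mutation_prob = mutation_prob
        self.mutation_sigma = mutation_sigma
        self.elitism = elitism
        self.convergence_window = convergence_window
        self.convergence_tol = convergence_tol
        self.lambda_morph = lambda_morph

    def _config(self) -> GAConfig:
        return GAConfig(
            seed=self.seed,
            population_size=self.population_size,
            max_generations=self.max_generations,
            tournament_size=self.tournament_size,
            crossover_prob=self.crossover_prob,
            blx_alpha=self.blx_alpha,
            mutation_prob=self.mutation_prob,
            mutation_sigma=self.mutation_sigma,
            elitism=self.elitism,
            convergence_window=self.convergence_window,
            convergence_tol=self.convergence_tol,
        )

    def fit(self, X, y=None):
        """Calibrate to a target.

        ``X`` may be a :class:`GATarget`, a cohort name ('snlv'/'icmp'),
        or an array of DI values with ``y`` the matching ARI values.
        """
        if isinstance(X, GATarget):
            target = X
        elif isinstance(X, str):
            target = make_cohort_target(X, lambda_morph=self.lambda_morph)
        else:
            target = GATarget.from_points(X, y, lambda_morph=self.lambda_morph)
            if self.lambda_morph > 0:
                target.template_mv = base_morphology_template()
        result = run_ga(self._config(), target)
        self.result_ = result
        self.population_ = result.population
        self.fitness_ = result.fitness
        self.best_params_ = result.best_params
        self.best_fitness_ = result.best_fitness
        self.history_ = result.history
        self.n_generations_ = result.generations
        return self


def run_ga(config: GAConfig, target: GATarget) -> GAResult:
    """Run the genetic algorithm; fully reproducible under ``config.seed``."""
    rng = np.random.default_rng(config.seed)
    base = make_base_params()
    b = base.to_vector()
    lo, hi = default_bounds(base)
    free = hi > lo
    d = int(free.sum())
    xlo = np.log(lo[free])
    xhi = np.log(hi[free])
    n = config.population_size
    stim_amp = default_stim_amplitude()
    cache = _protocol_stims(config.protocol)

    def to_vec(x):
        vec = b.copy()
        vec[free] = np.exp(x)
        return vec

    def evaluate(x):
        vec = to_vec(x)
        err = _restitution_error(vec, target, config.protocol, stim_amp, cache)
        if err >= PENALTY_FITNESS:
            return PENALTY_FITNESS
        if target.lambda_morph > 0 and target.template_mv is not None:
            try:
                morph = _morphology_trace(BOFCParams.from_vector(vec))
            except Exception:
                return PENALTY_FITNESS
            err += target.lambda_morph * float(np.mean(np.abs(morph - target.template_mv)))
        return err

    if config.init == "linear":
        # uniform in raw parameter space: large multiples of the base value
        # are as likely as small ones, favoring slow-time-constant regions
        pop = np.log(rng.uniform(lo[free], hi[free], size=(n, d)))
    else:
        pop = rng.uniform(xlo, xhi, size=(n, d))
    pop[0] = np.log(b[free])  # inject the base individual once
    fit = np.array([evaluate(x) for x in pop])
    if np.all(fit >= PENALTY_FITNESS):
        raise RuntimeError("entire initial population penalized; check target/protocol")

    history = []
    best_fit = float(fit.min())
    stall = 0
    gens_run = 0

    for gen in range(config.max_generations):
        order = np.argsort(fit, kind="stable")
        elites = pop[order[: config.elitism]].copy()
        elite_fit = fit[order[: config.elitism]].copy()

        children = []
        while len(children) < n - config.elitism:
            ia = _tournament(rng, fit, config.tournament_size)
            ib = _tournament(rng, fit, config.tournament_size)
            pa, pb = pop[ia], pop[ib]
            if rng.random() < config.crossover_prob:
                c1, c2 = _blx(rng, pa, pb, config.blx_alpha)
            else:
                c1, c2 = pa.copy(), pb.copy()
            for c in (c1, c2):
                mask = rng.random(d) < config.mutation_prob
                c[mask] += rng.normal(0.0, config.mutation_sigma, size=int(mask.sum()))
                np.clip(c, xlo, xhi, out=c)
                children.append(c)
        children = np.asarray(children[: n - config.elitism])
        child_fit = np.array([evaluate(x) for x in children])

        pop = np.vstack([elites, children])
        fit = np.concatenate([elite_fit, child_fit])
        gens_run = gen + 1

        new_best = float(fit.min())
        if best_fit - new_best > config.convergence_tol:
            stall = 0
        else:
            stall += 1
        best_fit = min(best_fit, new_best)
        history.append(best_fit)
        if stall >= config.convergence_window:
            break

    i_best = int(np.argmin(fit))
    population = np.array([to_vec(x) for x in pop])
    return GAResult(
        population=population,
        fitness=fit,
        best_params=BOFCParams.from_vector(population[i_best]),
        best_fitness=float(fit[i_best]),
        history=np.asarray(history),
        generations=gens_run,
        config=config,
        target_label=target.label,
    )


def _tournament(rng, fit, k):
    idx = rng.integers(0, fit.shape[0], size=k)
    return idx[np.argmin(fit[idx])]


def _blx(rng, pa, pb, alpha):
    lo = np.minimum(pa, pb)
    hi = np.maximum(pa, pb)
    span = hi - lo
    a = lo - alpha * span
    bnd = hi + alpha * span
    return rng.uniform(a, bnd), rng.uniform(a, bnd)
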