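"""Synthetic gradCPT behaviour and brain-network co-simulation.

Real gradCPT-with-fMRI datasets of the kind this package analyses are not
freely downloadable, so this module generates data with the statistical
structure the analysis assumes, with full ground truth recorded:

* trial streams with 90% city / 10% mountain scenes, no immediate scene
  repeats, and constant stimulus spacing;
* binarized 8-network activity sampled from a planted two-minimum pairwise
  maximum-entropy model via single-flip Metropolis (``dwell_control`` steps
  per recorded volume interpolates between persistent states and i.i.d.
  draws), plus a continuous BOLD-like observation (+/-a offset with N(0,1)
  noise);
* state-dependent ex-Gaussian RTs with omission/commission error structure,
  ambiguous and multiple presses, and trial-to-state alignment defined
  through the same hemodynamic-lag shift the analysis pipeline removes, so
  generator -> pipeline round trips are exact;
* cross-participant parameter populations with planted parameter-error rank
  correlations.

All randomness derives from ``numpy.random.SeedSequence`` spawns of a single
seed, so every participant/run is reproducible in isolation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .behavior import CITY, MOUNTAIN, TrialStream, UNAMBIG_HI, UNAMBIG_LO
from .exgauss import ExGaussParams, exgauss_rvs
from .mem import (
    DEFAULT_NETWORKS,
    MEMModel,
    all_energies,
    build_landscape,
    lag_to_shift,
    pattern_probabilities,
    spin_to_binary,
)

__all__ = [
    "StateBehavior",
    "SimConfig",
    "GroundTruth",
    "gen_trial_stream",
    "gen_network_series",
    "sample_boltzmann",
    "gen_behavior",
    "gen_population",
    "planted_two_state_model",
    "write_events_table",
]

N_SCENE_IDS = 10   # 10 city and 10 mountain photographs


@dataclass
class StateBehavior:
    """Behavioural regime while the brain occupies one state."""

    params: ExGaussParams
    omission_rate: float = 0.0
    commission_rate: float = 0.0

    def __post_init__(self) -> None:
        for r in (self.omission_rate, self.commission_rate):
            if not 0.0 <= r <= 1.0:
                raise ValueError("rates must be probabilities")


@dataclass
class SimConfig:
    """Ground-truth world for a simulated gradCPT-with-fMRI experiment."""

    n_participants: int = 25
    n_trials_per_run: int = 300
    n_runs: int = 1
    isi: float = 0.8
    p_mountain: float = 0.10
    tr: float = 2.0
    hemodynamic_lag: float = 5.0
    seed: int = 0
    mem_truth: MEMModel | None = None
    state_params: dict[int, StateBehavior] = field(default_factory=dict)
    dwell_control: int = 8
    ambiguous_press_rate: float = 0.0
    multipress_rate: float = 0.0
    bold_amplitude: float = 1.0

    def __post_init__(self) -> None:
        if self.n_participants < 1 or self.n_trials_per_run < 2 or self.n_runs < 1:
            raise ValueError("participant/trial/run counts must be positive")
        if self.isi <= 0 or self.tr <= 0:
            raise ValueError("isi and tr must be positive")
        if self.dwell_control < 1:
            raise ValueError("dwell_control must be >= 1")
        for p in (self.p_mountain, self.ambiguous_press_rate, self.multipress_rate):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")
        if self.mem_truth is not None and self.state_params:
            minima = set(build_landscape(self.mem_truth).minima.tolist())
            if set(self.state_params) != minima:
                raise ValueError(
                    "state_params keys must match the planted minima "
                    f"(minima={sorted(minima)}, keys={sorted(self.state_params)})"
                )

    @property
    def run_duration(self) -> float:
        return self.n_trials_per_run * self.isi

    @property
    def volumes_per_run(self) -> int:
        # enough volumes that every trial onset + lag falls inside the run
        return int(np.ceil(self.run_duration / self.tr)) + lag_to_shift(
            self.hemodynamic_lag, self.tr
        ) + 1


@dataclass
class GroundTruth:
    """Everything the generator knew: for round-trip testing downstream."""

    state_series: np.ndarray           # per-volume pattern index of the basin truth
    trial_states: np.ndarray           # generating state per trial
    trial_rts: np.ndarray              # intended RT per trial (NaN = no press)
    trial_classes: np.ndarray          # intended classification per trial
    model: MEMModel | None = None


def gen_trial_stream(
    n_trials: int,
    isi: float,
    p_mountain: float = 0.10,
    seed: int | np.random.Generator = 0,
) -> TrialStream:
    """Random gradCPT trial stream: 90/10 city/mountain, no scene repeats."""
    if n_trials < 2:
        raise ValueError("need at least 2 trials")
    if isi <= 0:
        raise ValueError("isi must be positive")
    if not 0.0 <= p_mountain <= 1.0:
        raise ValueError("p_mountain must be a probability")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    categories = np.where(rng.random(n_trials) < p_mountain, MOUNTAIN, CITY)
    scene_ids = np.empty(n_trials, dtype=object)
    prev = None
    for i, cat in enumerate(categories):
        while True:
            sid = f"{cat}{rng.integers(N_SCENE_IDS)}"
            if sid != prev:
                break
        scene_ids[i] = sid
        prev = sid
    onsets = np.arange(n_trials) * isi
    return TrialStream(onsets=onsets, categories=categories,
                       scene_ids=scene_ids, isi=isi)


def sample_boltzmann(
    model: MEMModel, n: int, rng: np.random.Generator
) -> np.ndarray:
    """``n`` exact independent draws (pattern indices) from the Boltzmann law."""
    probs = pattern_probabilities(model)
    return rng.choice(probs.size, size=n, p=probs)


def _metropolis_chain_py(energies, flip_bits, log_u, volumes, dwell, n, state):
    # lazy single-flip Metropolis kernel; flip_bits == n means stay put
    recorded = np.empty(volumes, dtype=np.int64)
    step = 0
    for v in range(volumes):
        for _ in range(dwell):
            bit = flip_bits[step]
            if bit < n:
                proposal = state ^ (1 << bit)
                if log_u[step] < energies[state] - energies[proposal]:
                    state = proposal
            step += 1
        recorded[v] = state
    return recorded


try:  # numba shaves the kernel from microseconds to nanoseconds per step
    from numba import njit

    _metropolis_chain = njit(cache=True)(_metropolis_chain_py)
except ImportError:  # pragma: no cover - numba is normally available
    _metropolis_chain = _metropolis_chain_py


def gen_network_series(
    model: MEMModel,
    volumes: int,
    dwell_control: int = 8,
    seed: int | np.random.Generator = 0,
    amplitude: float = 1.0,
    start: int | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Sample binarized + continuous network activity from the model.

    Runs a lazy single-flip Metropolis chain whose stationary law is
    P(V_k) proportional to exp(-E(V_k)), recording one pattern every
    ``dwell_control`` steps (larger values approach independent draws,
    smaller values give temporally persistent states).  Each step stays put
    with probability 1/(N+1), which breaks the bit-flip parity periodicity
    that would otherwise make the zero-energy chain non-ergodic on the
    recorded subsequence.  The continuous
    matrix observes each binary state as ``+/-amplitude`` plus unit-variance
    Gaussian noise, mimicking a noisy BOLD readout whose time-mean
    binarization recovers the truth with high probability.

    Returns ``(binary, values)`` with shapes (volumes, N).
    """
    if volumes < 1:
        raise ValueError("volumes must be >= 1")
    if dwell_control < 1:
        raise ValueError("dwell_control must be >= 1")
    n = model.n_networks
    if n > 16:
        raise ValueError("N <= 16 required for exhaustive energies")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    energies = all_energies(model)
    state = int(sample_boltzmann(model, 1, rng)[0]) if start is None else int(start)

    total_steps = volumes * dwell_control
    flip_bits = rng.integers(n + 1, size=total_steps).astype(np.int64)
    log_u = np.log(rng.random(total_steps))
    recorded = _metropolis_chain(
        energies, flip_bits, log_u, volumes, dwell_control, n, state
    )

    binary = ((recorded[:, None] >> np.arange(n)[None, :]) & 1).astype(np.int8)
    values = amplitude * (2.0 * binary - 1.0) + rng.normal(size=(volumes, n))
    return binary, values


def gen_behavior(
    stream: TrialStream,
    state_series: np.ndarray,
    cfg: SimConfig,
    seed: int | np.random.Generator = 0,
) -> tuple[np.ndarray, GroundTruth]:
    """Generate raw press timestamps for one run, driven by brain state.

    The generating state of a trial is the label of the volume the pipeline
    will consult after its backward hemodynamic shift — volume
    floor(onset/tr) + round(lag/tr) — so state-resolved RT pools reconstruct
    the generator's pools exactly.  City trials emit a press at
    onset + RT with probability 1 - omission_rate(state), RT drawn from the
    state's ex-Gaussian; mountain trials emit a press with probability
    commission_rate(state).  RTs are not truncated: draws beyond 1.4*isi
    land in the next trial's window and get misassigned as fast responses,
    the same slow-to-fast leakage a real gradCPT shows.  With probability
    ``ambiguous_press_rate`` a press is displaced into the ambiguous window,
    and with probability ``multipress_rate`` an extra press is duplicated
    onto the same trial.
    """
    state_series = np.asarray(state_series)
    if state_series.size == 0:
        raise ValueError("state_series must be nonempty")
    if not cfg.state_params:
        raise ValueError("cfg.state_params must define behaviour per state")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    shift = lag_to_shift(cfg.hemodynamic_lag, cfg.tr)
    isi = stream.isi

    n = stream.n_trials
    trial_states = np.empty(n, dtype=np.int64)
    trial_rts = np.full(n, np.nan)
    trial_classes = np.empty(n, dtype=object)
    presses: list[float] = []

    for t in range(n):
        vol = int(stream.onsets[t] // cfg.tr) + shift
        if vol >= state_series.size:
            raise ValueError("state_series does not cover the run duration")
        s = int(state_series[vol])
        trial_states[t] = s
        beh = cfg.state_params[s]
        city = stream.categories[t] == CITY
        press_prob = (1.0 - beh.omission_rate) if city else beh.commission_rate
        if rng.random() >= press_prob:
            trial_classes[t] = "omission_error" if city else "correct_omission"
            continue
        rt = float(exgauss_rvs(beh.params, 1, rng)[0])
        trial_rts[t] = rt
        trial_classes[t] = "correct_commission" if city else "commission_error"
        press = stream.onsets[t] + rt
        if rng.random() < cfg.ambiguous_press_rate:
            # displace into the ambiguous zone: before 70% coherence of this
            # scene or after 40% coherence of the next
            if rng.random() < 0.5:
                press = stream.onsets[t] + rng.uniform(0.41 * isi, 0.69 * isi)
            else:
                press = stream.onsets[t] + rng.uniform(1.41 * isi, 1.69 * isi)
        presses.append(press)
        if rng.random() < cfg.multipress_rate:
            presses.append(
                stream.onsets[t] + rng.uniform(UNAMBIG_LO * isi, UNAMBIG_HI * isi)
            )

    truth = GroundTruth(
        state_series=state_series,
        trial_states=trial_states,
        trial_rts=trial_rts,
        trial_classes=trial_classes,
        model=cfg.mem_truth,
    )
    return np.sort(np.asarray(presses, dtype=float)), truth


def gen_population(
    n_participants: int,
    population_means: tuple[float, float, float] = (0.80, 0.08, 0.05),
    population_sds: tuple[float, float, float] = (0.06, 0.03, 0.02),
    error_link: float = 0.5,
    seed: int | np.random.Generator = 0,
) -> pd.DataFrame:
    """Participant-level ex-Gaussian parameters and error rates.

    ``mu`` is drawn truncated-normal (positive), ``sigma`` and ``tau``
    lognormal with matched mean/SD so they stay positive.  Omission and
    commission rates are monotone (logistic) functions of the Gaussian
    latent behind ``sigma`` plus independent noise; ``error_link`` is the
    planted Spearman correlation between sigma and each error rate
    (converted internally to the latent Pearson correlation via
    rho = 2 sin(pi rho_s / 6), exact for bivariate normal latents).
    """
    if any(sd < 0 for sd in population_sds):
        raise ValueError("population SDs must be nonnegative")
    if not -1.0 <= error_link <= 1.0:
        raise ValueError("error_link must be a correlation")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    means = np.asarray(population_means, dtype=float)
    sds = np.asarray(population_sds, dtype=float)
    rho = 2.0 * np.sin(np.pi * error_link / 6.0)

    def lognormal(mean: float, sd: float, size: int) -> np.ndarray:
        if sd == 0:
            return np.full(size, mean)
        s2 = np.log1p((sd / mean) ** 2)
        return rng.lognormal(np.log(mean) - s2 / 2.0, np.sqrt(s2), size)

    mu = means[0] + sds[0] * rng.standard_normal(n_participants)
    mu = np.abs(mu)   # fold the (negligible) negative mass back
    sigma = lognormal(means[1], sds[1], n_participants)
    tau = lognormal(means[2], sds[2], n_participants)

    # Gaussian latent behind the lognormal sigma; rank-preserving transform
    log_sigma = np.log(sigma)
    z = (
        (log_sigma - log_sigma.mean()) / log_sigma.std()
        if log_sigma.std() > 0
        else np.zeros(n_participants)
    )
    noise_scale = np.sqrt(max(1.0 - rho**2, 0.0))
    lin_om = rho * z + noise_scale * rng.standard_normal(n_participants)
    lin_co = rho * z + noise_scale * rng.standard_normal(n_participants)
    omission = 1.0 / (1.0 + np.exp(-(lin_om - 2.0)))
    commission = 1.0 / (1.0 + np.exp(-(lin_co - 1.0)))

    return pd.DataFrame({
        "participant": np.arange(n_participants),
        "mu": mu, "sigma": sigma, "tau": tau,
        "omission_rate": omission, "commission_rate": commission,
    })


def planted_two_state_model(
    depth: float = 0.55,
    networks: tuple[str, ...] = DEFAULT_NETWORKS,
    state1_networks: frozenset[str] | set[str] | None = None,
) -> MEMModel:
    """Hopfield-style model whose two minima are State1 and its complement.

    In the +/-1 spin convention a single stored pattern x with couplings
    (depth/(N-1)) x x^T makes both x and -x energy minima; converted to the
    0/1 convention this plants State1 (FPN_A + DMN + limbic active) and
    State2 (the complementary five networks active) as the only two local
    minima.  ``depth`` sets the barrier height: the default gives strongly
    dominant but still inter-switching states under Metropolis sampling.
    """
    from .mem import STATE1_NETWORKS

    if state1_networks is None:
        state1_networks = STATE1_NETWORKS
    n = len(networks)
    x = np.array([1.0 if net in state1_networks else -1.0 for net in networks])
    j_spin = (depth / (n - 1)) * np.outer(x, x)
    np.fill_diagonal(j_spin, 0.0)
    h01, j01 = spin_to_binary(np.zeros(n), j_spin)
    return MEMModel(h=h01, J=j01, networks=networks)


def write_events_table(stream: TrialStream, rts: np.ndarray, path) -> pd.DataFrame:
    """Write a BIDS-style events table (tab-delimited) for one run."""
    df = pd.DataFrame({
        "onset": stream.onsets,
        "duration": np.full(stream.n_trials, stream.isi),
        "trial_type": stream.categories,
        "scene_id": stream.scene_ids,
        "response_time": rts,
    })
    df.to_csv(path, sep="\t", index=False, na_rep="n/a")
    return df
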