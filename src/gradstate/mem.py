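"""Pairwise maximum-entropy model and energy-landscape brain states.

Binarized activity of N brain networks (active/inactive per fMRI volume) is
modelled with the pairwise maximum-entropy (Boltzmann / Ising) distribution

    P(V_k) = exp(-E(V_k)) / Z,
    E(V_k) = - sum_i h_i s_i(V_k) - 1/2 sum_{i != j} J_ij s_i(V_k) s_j(V_k),

where s_i in {0, 1}, h_i is a per-network bias and J the symmetric coupling
matrix (zero diagonal).  For small N (<= 16) everything is computed by
exhaustive enumeration of the 2^N activity patterns: maximum-likelihood
fitting reduces to gradient ascent that matches model moments <s_i> and
<s_i s_j> to their empirical counterparts, and the energy landscape — local
minima over the Hamming-1 neighbour graph and their steepest-descent basins —
defines the discrete brain states.  A hemodynamic-lag shift aligns the
per-volume state labels with behaviour.

Pattern encoding: pattern index k has bit i equal to s_i(V_k), i.e.
``(k >> i) & 1`` is the activity of network i.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import special

__all__ = [
    "DEFAULT_NETWORKS",
    "STATE1_NETWORKS",
    "STATE2_NETWORKS",
    "NetworkActivity",
    "MEMModel",
    "EnergyLandscape",
    "StateSeries",
    "all_patterns",
    "pattern_index",
    "clean_and_average",
    "binarize",
    "empirical_moments",
    "energy",
    "all_energies",
    "pattern_probabilities",
    "fit_mem",
    "fit_quality",
    "find_minima",
    "basin_assign",
    "build_landscape",
    "state_series",
    "label_named_states",
    "lag_to_shift",
    "spin_to_binary",
]

#: Canonical 8-network parcellation order used throughout.
DEFAULT_NETWORKS = ("DMN", "Limbic", "FPN_A", "FPN_B", "DAN", "SN", "SMN", "Visual")
#: Networks whose joint activation characterises the behaviourally optimal state.
STATE1_NETWORKS = frozenset({"FPN_A", "DMN", "Limbic"})
#: Networks whose joint activation characterises the suboptimal state.
STATE2_NETWORKS = frozenset({"FPN_B", "DAN", "SN", "SMN", "Visual"})


@dataclass
class NetworkActivity:
    """Cleaned, standardized per-volume activity of N networks.

    ``values`` is T x N (volumes by networks); ``run_ids`` labels each row
    with its run so that downstream stages can map concatenated volumes back
    to individual runs.
    """

    values: np.ndarray
    tr: float
    networks: tuple[str, ...] = DEFAULT_NETWORKS
    run_ids: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a T x N matrix")
        n = self.values.shape[1]
        if not 2 <= n <= 16:
            raise ValueError("between 2 and 16 networks supported")
        if len(self.networks) != n:
            raise ValueError("network name count must match columns")
        if self.run_ids is None:
            self.run_ids = np.zeros(self.values.shape[0], dtype=int)
        else:
            self.run_ids = np.asarray(self.run_ids)
            if self.run_ids.shape[0] != self.values.shape[0]:
                raise ValueError("run_ids must label every volume")

    @property
    def n_networks(self) -> int:
        return self.values.shape[1]


@dataclass
class MEMModel:
    """Pairwise maximum-entropy model: biases ``h`` and couplings ``J``."""

    h: np.ndarray
    J: np.ndarray
    networks: tuple[str, ...] = DEFAULT_NETWORKS
    n_iter: int = 0
    max_moment_mismatch: float = float("nan")
    converged: bool = True

    def __post_init__(self) -> None:
        self.h = np.asarray(self.h, dtype=float)
        self.J = np.asarray(self.J, dtype=float)
        n = self.h.shape[0]
        if self.J.shape != (n, n):
            raise ValueError("J must be N x N matching h")
        if not np.allclose(self.J, self.J.T):
            raise ValueError("J must be symmetric")
        if not np.allclose(np.diag(self.J), 0.0):
            raise ValueError("J must have zero diagonal")
        if len(self.networks) != n:
            self.networks = tuple(f"net{i}" for i in range(n))

    @property
    def n_networks(self) -> int:
        return self.h.shape[0]


@dataclass
class EnergyLandscape:
    """Exhaustive energy landscape over all 2^N activity patterns."""

    energies: np.ndarray
    probabilities: np.ndarray
    minima: np.ndarray            # sorted pattern indices of local minima
    basin: np.ndarray             # basin[k] = index of the minimum reached from k
    networks: tuple[str, ...] = DEFAULT_NETWORKS

    @property
    def n_networks(self) -> int:
        return int(np.log2(self.energies.shape[0]) + 0.5)


@dataclass
class StateSeries:
    """Per-volume brain-state labels after the hemodynamic-lag shift.

    ``labels[v]`` is the basin minimum (pattern index) aligned with behaviour
    at volume ``v``; the series is ``shift_volumes`` shorter than the run.
    """

    labels: np.ndarray
    tr: float
    shift_volumes: int
    run_ids: np.ndarray | None = None

    def __len__(self) -> int:
        return self.labels.shape[0]


# ---------------------------------------------------------------------------
# pattern enumeration helpers


def all_patterns(n: int) -> np.ndarray:
    """(2^n, n) matrix of binary patterns; row k, column i = bit i of k."""
    if not 1 <= n <= 16:
        raise ValueError("n must be between 1 and 16")
    k = np.arange(2**n, dtype=np.int64)
    return ((k[:, None] >> np.arange(n)[None, :]) & 1).astype(float)


def pattern_index(binary: np.ndarray) -> np.ndarray:
    """Map rows of a T x N binary matrix to pattern indices (bit i = column i)."""
    binary = np.asarray(binary)
    n = binary.shape[-1]
    weights = (1 << np.arange(n)).astype(np.int64)
    return (binary.astype(np.int64) @ weights).astype(np.int64)


# ---------------------------------------------------------------------------
# preprocessing


def clean_and_average(
    roi_series: np.ndarray,
    roi_to_network: dict[int, str] | list[str],
    confounds: np.ndarray | None = None,
    tr: float = 2.0,
    networks: tuple[str, ...] = DEFAULT_NETWORKS,
    run_ids: np.ndarray | None = None,
) -> NetworkActivity:
    """Residualize ROI series against confounds, standardize, average to networks.

    Each ROI column is OLS-residualized against the supplied confound matrix
    (an intercept is always appended), then standardized to mean 0 / variance 1
    within each run, and finally averaged over the ROIs belonging to each
    network.  Confound construction itself (motion, aCompCor, task regressors)
    is up to the caller.
    """
    X = np.asarray(roi_series, dtype=float)
    if X.ndim != 2:
        raise ValueError("roi_series must be T x R")
    t, r = X.shape
    if isinstance(roi_to_network, dict):
        labels = [roi_to_network[i] for i in range(r)]
    else:
        labels = list(roi_to_network)
    if len(labels) != r:
        raise ValueError("roi_to_network must label every ROI column")
    for net in networks:
        if net not in labels:
            raise ValueError(f"network {net!r} has no member ROIs")

    if confounds is None:
        C = np.ones((t, 1))
    else:
        C = np.asarray(confounds, dtype=float)
        if C.ndim == 1:
            C = C[:, None]
        C = np.column_stack([C, np.ones(t)])
    rank = np.linalg.matrix_rank(C)
    if rank < C.shape[1]:
        warnings.warn("rank-deficient confound matrix; using pseudo-inverse")
    beta, *_ = np.linalg.lstsq(C, X, rcond=None)
    resid = X - C @ beta

    if run_ids is None:
        run_ids = np.zeros(t, dtype=int)
    run_ids = np.asarray(run_ids)
    std = np.empty_like(resid)
    for run in np.unique(run_ids):
        rows = run_ids == run
        block = resid[rows]
        sd = block.std(axis=0)
        scale = np.maximum(X[rows].std(axis=0), 1.0)
        if np.any(sd <= 1e-10 * scale):
            raise ValueError("zero-variance ROI after residualization")
        std[rows] = (block - block.mean(axis=0)) / sd

    net_vals = np.column_stack(
        [std[:, [j for j, lab in enumerate(labels) if lab == net]].mean(axis=1)
         for net in networks]
    )
    return NetworkActivity(values=net_vals, tr=tr, networks=networks, run_ids=run_ids)


def binarize(activity: NetworkActivity | np.ndarray) -> np.ndarray:
    """Binarize each network series at its time-averaged activity.

    Entry is 1 iff the value strictly exceeds the column mean computed over
    the full (concatenated) series supplied; exact ties map to 0.
    """
    values = activity.values if isinstance(activity, NetworkActivity) else np.asarray(activity, dtype=float)
    return (values > values.mean(axis=0, keepdims=True)).astype(np.int8)


def empirical_moments(binary: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """First and second empirical moments <s_i> and <s_i s_j> of binary data."""
    b = np.asarray(binary, dtype=float)
    if b.ndim != 2 or b.shape[0] < 1:
        raise ValueError("binary must be a nonempty T x N matrix")
    first = b.mean(axis=0)
    second = (b.T @ b) / b.shape[0]
    return first, second


# ---------------------------------------------------------------------------
# model, energies, fitting


def energy(pattern: np.ndarray, model: MEMModel) -> float:
    """Energy of one activity pattern under the model."""
    s = np.asarray(pattern, dtype=float)
    if s.shape != (model.n_networks,):
        raise ValueError("pattern length must match the model")
    return float(-model.h @ s - 0.5 * s @ model.J @ s)


def all_energies(model: MEMModel) -> np.ndarray:
    """Energies of all 2^N patterns, in pattern-index order."""
    P = all_patterns(model.n_networks)
    return -(P @ model.h) - 0.5 * np.einsum("ki,ij,kj->k", P, model.J, P)


def pattern_probabilities(model: MEMModel) -> np.ndarray:
    """Boltzmann probabilities P(V_k) = exp(-E_k)/Z over all 2^N patterns.

    Lower energy means higher probability, so the landscape's local minima
    are the dominant patterns.  Computed with log-sum-exp for stability.
    """
    e = all_energies(model)
    log_p = -e - special.logsumexp(-e)
    return np.exp(log_p)


def _model_moments(model: MEMModel, probs: np.ndarray | None = None) -> tuple[np.ndarray, np.ndarray]:
    P = all_patterns(model.n_networks)
    if probs is None:
        probs = pattern_probabilities(model)
    first = probs @ P
    second = P.T @ (probs[:, None] * P)
    return first, second


def fit_mem(
    binary: np.ndarray,
    eta: float = 0.2,
    tol: float = 1e-5,
    max_iter: int = 100_000,
    networks: tuple[str, ...] | None = None,
    track_loglik: bool = False,
) -> MEMModel:
    """Fit h and J by gradient-ascent moment matching (maximum likelihood).

    Iterates h_i += eta (<s_i>_emp - <s_i>_model) and the analogous update for
    J_ij, with model moments from exhaustive enumeration, until the largest
    absolute moment mismatch drops below ``tol``.  This is exactly gradient
    ascent on the exponential-family log-likelihood, so the log-likelihood is
    non-decreasing for a stable step size (optionally recorded via
    ``track_loglik``).  Empirical moments at the 0/1 boundary (a network
    always on or always off) are clamped to [eps, 1-eps] with eps = 1/(2T).
    """
    b = np.asarray(binary, dtype=float)
    if b.ndim != 2:
        raise ValueError("binary must be T x N")
    t, n = b.shape
    if not 2 <= n <= 16:
        raise ValueError("between 2 and 16 networks supported")
    emp1, emp2 = empirical_moments(b)
    eps = 1.0 / (2.0 * t)
    if np.any(emp1 <= 0) or np.any(emp1 >= 1):
        warnings.warn("network always on/off in data; clamping empirical moments")
    emp1 = np.clip(emp1, eps, 1.0 - eps)
    offdiag = ~np.eye(n, dtype=bool)
    emp2 = emp2.copy()
    emp2[offdiag] = np.clip(emp2[offdiag], 0.0, 1.0)

    names = networks if networks is not None else (
        DEFAULT_NETWORKS if n == len(DEFAULT_NETWORKS) else tuple(f"net{i}" for i in range(n))
    )
    h = np.zeros(n)
    J = np.zeros((n, n))
    P = all_patterns(n)
    logliks: list[float] = []
    mismatch = np.inf
    it = 0
    for it in range(1, max_iter + 1):
        e = -(P @ h) - 0.5 * np.einsum("ki,ij,kj->k", P, J, P)
        log_z = special.logsumexp(-e)
        probs = np.exp(-e - log_z)
        if track_loglik:
            # mean log-likelihood per volume under current parameters
            ll = float(h @ emp1 + 0.5 * np.sum(J * emp2) - log_z)
            logliks.append(ll)
        mod1 = probs @ P
        mod2 = P.T @ (probs[:, None] * P)
        g1 = emp1 - mod1
        g2 = emp2 - mod2
        g2[np.eye(n, dtype=bool)] = 0.0
        mismatch = max(float(np.max(np.abs(g1))), float(np.max(np.abs(g2))))
        if mismatch < tol:
            break
        h = h + eta * g1
        J = J + eta * g2
        J = 0.5 * (J + J.T)
        np.fill_diagonal(J, 0.0)

    model = MEMModel(
        h=h, J=J, networks=names, n_iter=it,
        max_moment_mismatch=mismatch, converged=mismatch < tol,
    )
    if track_loglik:
        model.loglik_trace = np.asarray(logliks)  # type: ignore[attr-defined]
    if not model.converged:
        warnings.warn(
            f"MEM fit did not reach tol={tol} in {max_iter} iterations "
            f"(mismatch {mismatch:.2e})"
        )
    return model


def fit_quality(binary: np.ndarray, model: MEMModel) -> float:
    """Pearson correlation between empirical and model pattern probabilities.

    The empirical appearance probability of pattern k is the fraction of
    volumes whose 1-of-K indicator selects k.  Returns NaN (with a warning)
    when either probability vector has zero variance.
    """
    idx = pattern_index(np.asarray(binary))
    k = 2**model.n_networks
    emp = np.bincount(idx, minlength=k) / idx.shape[0]
    mod = pattern_probabilities(model)
    if np.ptp(emp) == 0 or np.ptp(mod) == 0:
        warnings.warn("zero-variance appearance probabilities; correlation undefined")
        return float("nan")
    return float(np.corrcoef(emp, mod)[0, 1])


# ---------------------------------------------------------------------------
# energy landscape


def _neighbor_indices(n: int) -> np.ndarray:
    """(2^n, n) matrix: column i is the Hamming-1 neighbour with bit i flipped."""
    k = np.arange(2**n, dtype=np.int64)
    return k[:, None] ^ (1 << np.arange(n, dtype=np.int64))[None, :]


def find_minima(energies: np.ndarray) -> np.ndarray:
    """Local minima: patterns strictly below all N Hamming-1 neighbours."""
    e = np.asarray(energies, dtype=float)
    n = int(np.log2(e.shape[0]) + 0.5)
    if 2**n != e.shape[0]:
        raise ValueError("energies length must be a power of two")
    nbr = _neighbor_indices(n)
    is_min = np.all(e[:, None] < e[nbr], axis=1)
    return np.flatnonzero(is_min)


def basin_assign(energies: np.ndarray) -> np.ndarray:
    """Steepest-descent basin of every pattern.

    From each pattern, repeatedly move to the strictly lower neighbour of
    smallest energy (ties broken toward the lowest pattern index) until a
    local minimum is reached.  Returns ``basin`` with ``basin[k]`` the
    minimum's pattern index; ``basin[m] == m`` for every minimum.
    """
    e = np.asarray(energies, dtype=float)
    n = int(np.log2(e.shape[0]) + 0.5)
    nbr = _neighbor_indices(n)
    # order neighbours by ascending pattern index so argmin tie-breaks low
    order = np.argsort(nbr, axis=1)
    nbr_sorted = np.take_along_axis(nbr, order, axis=1)
    nbr_e = e[nbr_sorted]
    best = np.argmin(nbr_e, axis=1)
    best_idx = nbr_sorted[np.arange(e.shape[0]), best]
    lower = e[best_idx] < e
    step = np.where(lower, best_idx, np.arange(e.shape[0]))
    # pointer jumping: strict descent guarantees convergence in <= 2^n hops
    basin = step
    for _ in range(n * 64):
        nxt = basin[basin]
        if np.array_equal(nxt, basin):
            break
        basin = nxt
    else:  # pragma: no cover - cannot happen with strict descent
        raise AssertionError("steepest descent failed to converge")
    return basin


def build_landscape(model: MEMModel) -> EnergyLandscape:
    """Energies, Boltzmann probabilities, minima and basins for a model."""
    e = all_energies(model)
    return EnergyLandscape(
        energies=e,
        probabilities=pattern_probabilities(model),
        minima=find_minima(e),
        basin=basin_assign(e),
        networks=model.networks,
    )


def lag_to_shift(lag: float, tr: float) -> int:
    """Volumes corresponding to the hemodynamic lag: round(lag/tr), .5 down."""
    if tr <= 0:
        raise ValueError("tr must be positive")
    return int(np.ceil(lag / tr - 0.5))


def state_series(
    binary: np.ndarray,
    landscape: EnergyLandscape,
    tr: float,
    lag: float = 5.0,
    run_ids: np.ndarray | None = None,
) -> StateSeries:
    """Per-volume brain states aligned to behaviour by the hemodynamic lag.

    Each volume's state is the basin of its observed activity pattern; state
    labels are then shifted backwards by round(lag/tr) volumes (ties rounded
    down), so the state at behavioural time t is read from the volume
    acquired ~lag seconds later.  With per-run ``run_ids`` the shift is
    applied within each run independently.
    """
    shift = lag_to_shift(lag, tr)
    idx = pattern_index(np.asarray(binary))
    states = landscape.basin[idx]
    if run_ids is None:
        if states.shape[0] <= shift:
            raise ValueError("run shorter than the hemodynamic shift")
        return StateSeries(labels=states[shift:], tr=tr, shift_volumes=shift)
    run_ids = np.asarray(run_ids)
    out_labels = []
    out_runs = []
    for run in np.unique(run_ids):
        rows = states[run_ids == run]
        if rows.shape[0] <= shift:
            raise ValueError(f"run {run} shorter than the hemodynamic shift")
        out_labels.append(rows[shift:])
        out_runs.append(np.full(rows.shape[0] - shift, run))
    return StateSeries(
        labels=np.concatenate(out_labels),
        tr=tr,
        shift_volumes=shift,
        run_ids=np.concatenate(out_runs),
    )


def label_named_states(
    minima: np.ndarray, networks: tuple[str, ...] = DEFAULT_NETWORKS
) -> dict[int, str]:
    """Name each minimum State1 / State2 / other by its active networks.

    State1 is the pattern dominated by joint activation of FPN_A, DMN and the
    limbic network (the behaviourally optimal profile); State2 by FPN_B, DAN,
    SN, SMN and visual (suboptimal).  A minimum is labelled with a state when
    a strict majority of that state's template networks are active and a
    strict majority of the opposing template's networks are inactive;
    anything else (including the all-off pattern) is "other".
    """
    n = len(networks)
    labels: dict[int, str] = {}
    templates = (
        ("State1", STATE1_NETWORKS & set(networks), STATE2_NETWORKS & set(networks)),
        ("State2", STATE2_NETWORKS & set(networks), STATE1_NETWORKS & set(networks)),
    )
    for m in np.asarray(minima, dtype=int):
        active = {networks[i] for i in range(n) if (int(m) >> i) & 1}
        name = "other"
        for state, own, other in templates:
            if not own:
                continue
            on = len(own & active)
            off = len(other) - len(other & active)
            if on > len(own) / 2 and (not other or off > len(other) / 2):
                name = state
                break
        labels[int(m)] = name
    return labels


def spin_to_binary(h_spin: np.ndarray, J_spin: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Convert Ising parameters from the +/-1 spin convention to 0/1.

    With x = 2s - 1, the spin Hamiltonian maps onto the 0/1 one (up to an
    irrelevant constant) via J01 = 4 J_spin and h01 = 2 (h_spin - J_spin @ 1).
    Handy for planting Hopfield-style two-state models.
    """
    h_spin = np.asarray(h_spin, dtype=float)
    J_spin = np.asarray(J_spin, dtype=float)
    return 2.0 * (h_spin - J_spin.sum(axis=1)), 4.0 * J_spin
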