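"""End-to-end orchestration: simulate -> behaviour -> states -> comparison.

One config drives the whole chain: a planted two-minimum pairwise
maximum-entropy model generates per-run network activity and state-dependent
ex-Gaussian behaviour; presses are assigned back to trials; the model is
re-fitted from the binarized concatenated series; the energy landscape
yields named brain states; correct-commission RTs are pooled by state and
the three ex-Gaussian parameters are compared across states.  A manifest
records config hash, seeds, per-stage timings and output checksums.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import behavior as beh
from . import mem, simulate, stats
from .exgauss import ExGaussParams

__all__ = ["PipelineConfig", "ConfigError", "run_pipeline", "make_report"]


class ConfigError(ValueError):
    """Invalid pipeline configuration; the message names the field."""


@dataclass
class StateSpec:
    """Behavioural regime of one named state in the config schema."""

    mu: float = 0.80
    sigma: float = 0.08
    tau: float = 0.05
    omission_rate: float = 0.05
    commission_rate: float = 0.30


@dataclass
class PipelineConfig:
    """Schema for a simulated gradCPT-with-fMRI experiment."""

    n_participants: int = 25
    n_trials_per_run: int = 300
    n_runs: int = 1
    isi: float = 0.8
    p_mountain: float = 0.10
    tr: float = 2.0
    hemodynamic_lag: float = 5.0
    seed: int = 0
    dwell_control: int = 8
    depth: float = 0.55
    ambiguous_press_rate: float = 0.01
    multipress_rate: float = 0.01
    state1: StateSpec = field(default_factory=StateSpec)
    state2: StateSpec = field(default_factory=lambda: StateSpec(sigma=0.12))
    skew_policy: str = "exclude"
    min_pool_trials: int = 10

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        known = {f for f in cls.__dataclass_fields__}
        for key in raw:
            if key not in known:
                raise ConfigError(f"unknown config field: {key}")
        kwargs = dict(raw)
        for state_key in ("state1", "state2"):
            if state_key in kwargs and isinstance(kwargs[state_key], dict):
                extra = set(kwargs[state_key]) - set(StateSpec.__dataclass_fields__)
                if extra:
                    raise ConfigError(f"{state_key}: unknown fields {sorted(extra)}")
                kwargs[state_key] = StateSpec(**kwargs[state_key])
        cfg = cls(**kwargs)
        cfg.validate()
        return cfg

    def validate(self) -> None:
        if self.n_participants < 1:
            raise ConfigError("n_participants: must be >= 1")
        if self.n_trials_per_run < 2:
            raise ConfigError("n_trials_per_run: must be >= 2")
        if self.n_runs < 1:
            raise ConfigError("n_runs: must be >= 1")
        if self.isi <= 0:
            raise ConfigError("isi: must be positive")
        if self.tr <= 0:
            raise ConfigError("tr: must be positive")
        if self.dwell_control < 1:
            raise ConfigError("dwell_control: must be >= 1")
        for name in ("p_mountain", "ambiguous_press_rate", "multipress_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name}: must be a probability")
        for state_key in ("state1", "state2"):
            spec = getattr(self, state_key)
            if spec.sigma <= 0 or spec.tau <= 0:
                raise ConfigError(f"{state_key}: sigma and tau must be positive")
            for rate in ("omission_rate", "commission_rate"):
                if not 0.0 <= getattr(spec, rate) <= 1.0:
                    raise ConfigError(f"{state_key}.{rate}: must be a probability")
        if self.skew_policy not in ("flip", "exclude"):
            raise ConfigError("skew_policy: must be 'flip' or 'exclude'")


def _state_behavior(spec: StateSpec) -> simulate.StateBehavior:
    return simulate.StateBehavior(
        params=ExGaussParams(mu=spec.mu, sigma=spec.sigma, tau=spec.tau),
        omission_rate=spec.omission_rate,
        commission_rate=spec.commission_rate,
    )


def run_pipeline(
    config: PipelineConfig | str | Path,
    out_dir: str | Path | None = None,
    seed: int | None = None,
) -> dict:
    """Execute the full chain and (optionally) write a report directory.

    Returns the machine-readable report dict; when ``out_dir`` is given,
    writes ``report.json``, ``comparison.tsv`` and ``manifest.json`` there.
    ``seed`` overrides the config seed (convenience for replicate studies).
    """
    if not isinstance(config, PipelineConfig):
        config = PipelineConfig.from_file(config)
    config.validate()
    if seed is not None:
        config.seed = int(seed)

    timings: dict[str, float] = {}
    t0 = time.perf_counter()

    # --- stage 1: ground-truth world ------------------------------------
    truth_model = simulate.planted_two_state_model(depth=config.depth)
    truth_scape = mem.build_landscape(truth_model)
    named_truth = mem.label_named_states(truth_scape.minima)
    by_name = {v: k for k, v in named_truth.items()}
    if "State1" not in by_name or "State2" not in by_name:
        raise RuntimeError("planted model lost its two named minima")
    state_params = {
        by_name["State1"]: _state_behavior(config.state1),
        by_name["State2"]: _state_behavior(config.state2),
    }
    # any stray minima behave like State2 (robustness; none at default depth)
    for m in truth_scape.minima:
        state_params.setdefault(int(m), _state_behavior(config.state2))

    sim_cfg = simulate.SimConfig(
        n_participants=config.n_participants,
        n_trials_per_run=config.n_trials_per_run,
        n_runs=config.n_runs,
        isi=config.isi,
        p_mountain=config.p_mountain,
        tr=config.tr,
        hemodynamic_lag=config.hemodynamic_lag,
        seed=config.seed,
        mem_truth=truth_model,
        state_params=state_params,
        dwell_control=config.dwell_control,
        ambiguous_press_rate=config.ambiguous_press_rate,
        multipress_rate=config.multipress_rate,
    )
    timings["setup"] = time.perf_counter() - t0

    # --- stage 2: simulate + press assignment ----------------------------
    t0 = time.perf_counter()
    root = np.random.SeedSequence(config.seed)
    part_seeds = root.spawn(config.n_participants)
    volumes = sim_cfg.volumes_per_run

    all_binary = []
    run_records = []   # (participant, run, RTSeries, truth_labels)
    for p in range(config.n_participants):
        run_seeds = part_seeds[p].spawn(config.n_runs)
        for r in range(config.n_runs):
            rng = np.random.default_rng(run_seeds[r])
            stream = simulate.gen_trial_stream(
                config.n_trials_per_run, config.isi, config.p_mountain, rng
            )
            binary, _values = simulate.gen_network_series(
                truth_model, volumes, config.dwell_control, rng
            )
            pattern_idx = mem.pattern_index(binary)
            true_states = truth_scape.basin[pattern_idx]
            presses, truth = simulate.gen_behavior(stream, true_states, sim_cfg, rng)
            series = beh.assign_presses(stream, presses)
            all_binary.append(binary)
            run_records.append((p, r, series, truth))
    binary_cat = np.concatenate(all_binary, axis=0)
    timings["simulate_behavior"] = time.perf_counter() - t0

    # --- stage 3: MEM fit + landscape on the concatenated series ---------
    t0 = time.perf_counter()
    model = mem.fit_mem(binary_cat)
    quality = mem.fit_quality(binary_cat, model)
    scape = mem.build_landscape(model)
    named = mem.label_named_states(scape.minima)
    timings["mem_landscape"] = time.perf_counter() - t0

    # --- stage 4: state series + pooling + comparison --------------------
    t0 = time.perf_counter()
    name_by_min = dict(named)
    target = {v: k for k, v in name_by_min.items()}
    if "State1" not in target or "State2" not in target:
        raise RuntimeError(
            "fitted landscape has no State1/State2 minima; "
            f"minima labels: {sorted(name_by_min.values())}"
        )
    pools_by_participant: dict[int, dict[int, list[float]]] = {}
    offset = 0
    for p, r, series, truth in run_records:
        run_binary = all_binary[offset]
        offset += 1
        sseries = mem.state_series(
            run_binary, scape, tr=config.tr, lag=config.hemodynamic_lag
        )
        pools = stats.pool_rts(series, sseries, participant=p)
        acc = pools_by_participant.setdefault(p, {})
        for state, vals in pools.pools.items():
            acc.setdefault(state, []).extend(vals.tolist())
    pools_list = [
        stats.StateRTPools(
            pools={k: np.asarray(v) for k, v in acc.items()}, participant=p
        )
        for p, acc in sorted(pools_by_participant.items())
    ]
    comparison = stats.compare_states(
        pools_list,
        state_a=target["State1"],
        state_b=target["State2"],
        skew_policy=config.skew_policy,
        min_trials=config.min_pool_trials,
    )
    timings["states_comparison"] = time.perf_counter() - t0

    report = make_report(
        config=config,
        model=model,
        quality=quality,
        landscape=scape,
        named_states=name_by_min,
        comparison=comparison,
    )
    report["timings_s"] = {k: round(v, 3) for k, v in timings.items()}

    if out_dir is not None:
        _write_outputs(Path(out_dir), config, report, comparison, timings)
    return report


def make_report(
    config: PipelineConfig,
    model: mem.MEMModel,
    quality: float,
    landscape: mem.EnergyLandscape,
    named_states: dict[int, str],
    comparison: stats.ComparisonResult | None,
) -> dict:
    """Machine-readable summary mirroring the per-parameter reporting style."""
    minima_table = [
        {
            "pattern": int(m),
            "label": named_states.get(int(m), "other"),
            "energy": float(landscape.energies[m]),
            "probability": float(landscape.probabilities[m]),
            "active_networks": [
                landscape.networks[i]
                for i in range(len(landscape.networks))
                if (int(m) >> i) & 1
            ],
        }
        for m in landscape.minima
    ]
    report: dict = {
        "config": asdict(config),
        "mem_fit": {
            "n_iter": model.n_iter,
            "max_moment_mismatch": model.max_moment_mismatch,
            "converged": model.converged,
            "appearance_probability_r": quality,
        },
        "minima": minima_table,
    }
    if not minima_table:
        report["states"] = "no states found"
    if comparison is None:
        report["comparison"] = "missing"
    else:
        report["comparison"] = {
            "n_included": comparison.n_included,
            "n_excluded": comparison.n_excluded,
            "exclusions": {str(k): v for k, v in comparison.exclusions.items()},
            "parameters": comparison.table.to_dict(orient="records"),
        }
    return report


def _config_hash(config: PipelineConfig) -> str:
    blob = json.dumps(asdict(config), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def _write_outputs(
    out: Path,
    config: PipelineConfig,
    report: dict,
    comparison: stats.ComparisonResult,
    timings: dict[str, float],
) -> None:
    out.mkdir(parents=True, exist_ok=True)
    report_clean = {k: v for k, v in report.items() if k != "timings_s"}
    (out / "report.json").write_text(json.dumps(report_clean, indent=2, sort_keys=True))
    comparison.table.to_csv(out / "comparison.tsv", sep="\t", index=False)
    checksums = {
        name: hashlib.sha256((out / name).read_bytes()).hexdigest()
        for name in ("report.json", "comparison.tsv")
    }
    manifest = {
        "config_hash": _config_hash(config),
        "seed": config.seed,
        "outputs": checksums,
        "stage_timings_s": {k: round(v, 3) for k, v in timings.items()},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
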