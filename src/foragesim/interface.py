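"""Configuration, seeded end-to-end experiment runs, and fixture cohorts.

Everything downstream of a :class:`RunConfig` is reproducible from the
config alone: one master seed feeds named counter-based substreams for
dataset generation, strategy draws, replicate draws and fixture records.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import yaml

from .behavior_metrics import ParticipantRecord
from .hypothesis_fit import CoverageSpec
from .simulation import (
    ErrorDistribution,
    execute_strategy,
    parse_strategy_spec,
    strategy_error_distribution,
)
from .strategies import (
    SamplingStrategy,
    StrategyStep,
    average_interval_discrepancy,
    evenly_spaced_strategy,
)
from .synthetic_data import (
    GradientModel,
    GroundTruthDataset,
    InvalidParameterError,
    NoiseModel,
    TransectGrid,
    build_gradient_model,
    generate_dataset,
)

__all__ = [
    "RunConfig",
    "substream_seed",
    "build_hypothesis_datasets",
    "run_figure6_experiment",
    "make_fixture_cohort",
]

logger = logging.getLogger("foragesim")

DEFAULT_STRATEGIES = ("even:8x3", "even:11x3", "random:8x3", "random:11x3")


def substream_seed(master_seed: int, *key: int) -> int:
    """Derive a named integer substream seed (< 2^31) from the master seed."""
    state = np.random.SeedSequence([int(master_seed), *map(int, key)]).generate_state(1)
    return int(state[0] % (2**31))


@dataclass(frozen=True)
class RunConfig:
    """Fully serializable description of one end-to-end run."""

    master_seed: int = 0
    grid_size: int = 22
    model: dict = field(default_factory=dict)      # GradientModel field overrides
    noise: dict = field(default_factory=dict)      # NoiseModel field overrides
    strategies: tuple[str, ...] = DEFAULT_STRATEGIES
    n_iter: int = 100
    coverage_intervals: int = 10
    out_dir: str = "results"

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict:
        d = asdict(self)
        d["strategies"] = list(self.strategies)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "strategies" in d:
            d["strategies"] = tuple(d["strategies"])
        return cls(**d)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    def config_hash(self) -> str:
        canonical = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(canonical.encode()).hexdigest()[:12]

    # -- derived pieces -----------------------------------------------------

    def make_grid(self) -> TransectGrid:
        return TransectGrid.regular(self.grid_size)

    def make_noise(self) -> NoiseModel:
        return NoiseModel(**self.noise)

    def make_model(self, hypothesis_id: str) -> GradientModel:
        params = dict(self.model)
        if hypothesis_id == "given":
            params.pop("dip_depth", None)
        return build_gradient_model(hypothesis_id, **params)

    def coverage_spec(self) -> CoverageSpec:
        return CoverageSpec(n_intervals=self.coverage_intervals)


def build_hypothesis_datasets(config: RunConfig) -> dict[str, GroundTruthDataset]:
    """One seeded ground-truth dataset per hypothesis."""
    grid, noise = config.make_grid(), config.make_noise()
    out = {}
    for h_idx, hyp in enumerate(("given", "alternative")):
        seed = substream_seed(config.master_seed, 1, h_idx)
        out[hyp] = generate_dataset(config.make_model(hyp), noise, grid, seed=seed)
        logger.info(
            "stage=dataset hypothesis=%s seed=%d config=%s", hyp, seed,
            config.config_hash(),
        )
    return out


def run_figure6_experiment(config: RunConfig) -> dict[str, ErrorDistribution]:
    """Monte-Carlo heuristic-versus-random comparison, written to disk.

    Runs every configured strategy family against both hypothesis datasets
    for ``n_iter`` iterations each, writing one ``iteration,final_rmse``
    CSV per (hypothesis, strategy) pair and a JSON summary with the
    representative errors.  Rerunning with an identical config reproduces
    the files byte for byte.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    datasets = build_hypothesis_datasets(config)
    results: dict[str, ErrorDistribution] = {}
    summary: dict = {"config": config.to_dict(), "config_hash": config.config_hash(),
                     "distributions": []}
    for h_idx, (hyp, dataset) in enumerate(datasets.items()):
        for s_idx, spec_text in enumerate(config.strategies):
            spec = parse_strategy_spec(spec_text)
            seed = substream_seed(config.master_seed, 2, h_idx, s_idx)
            dist = strategy_error_distribution(
                spec, dataset, n_iter=config.n_iter, seed=seed
            )
            key = f"{hyp}_{spec_text.replace(':', '_')}"
            csv_path = out_dir / f"{key}.csv"
            dist.to_frame().to_csv(csv_path, index=False)
            entry = dist.sidecar() | {"file": csv_path.name, "seed": seed}
            summary["distributions"].append(entry)
            results[key] = dist
            logger.info(
                "stage=distribution hypothesis=%s strategy=%s seed=%d out=%s",
                hyp, spec_text, seed, csv_path,
            )
    (out_dir / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True))
    return results


# ---------------------------------------------------------------------------
# synthetic participant cohorts with analytically known composition
# ---------------------------------------------------------------------------

def _exact_count(fraction: float, n: int) -> int:
    return int(np.floor(fraction * n + 0.5))


def _flags(n_true: int, n: int, rng: np.random.Generator) -> np.ndarray:
    flags = np.zeros(n, dtype=bool)
    flags[:n_true] = True
    rng.shuffle(flags)
    return flags


def _nonuniform_locations(
    grid: TransectGrid, n_locations: int, threshold: float, rng: np.random.Generator
) -> tuple[int, ...]:
    """Distinct locations whose interval discrepancy exceeds the threshold."""
    for _ in range(100):
        locs = tuple(
            int(l) for l in
            sorted(rng.choice(grid.n_locations, size=n_locations, replace=False) + 1)
        )
        strategy = SamplingStrategy(grid, tuple(StrategyStep(l, 1) for l in locs))
        if average_interval_discrepancy(strategy) > threshold:
            return locs
    # clustered fallback: a tight run plus far-flung points is always non-uniform
    base = list(range(1, n_locations)) + [grid.n_locations]
    return tuple(base)


def make_fixture_cohort(
    n_records: int,
    seed: int,
    *,
    grid: TransectGrid | None = None,
    equal_spacing_fraction: float = 34 / 39,
    magic_number_probs: dict[int, float] | None = None,
    anchored_fraction: float = 9 / 39,
    deviated_fraction_of_adjusted: float = 7 / 30,
    magic_change_fraction_of_adjusted: float = 10 / 30,
    conclusion_accuracy: dict[str, float] | None = None,
    threshold: float = 1.0,
) -> list[ParticipantRecord]:
    """Generate a synthetic expert cohort with analytically known composition.

    Mixture weights are honored *exactly* (counts are rounded once, then
    assigned by shuffling), so cohort summaries are predictable by
    counting: ``equal_spacing_fraction`` of records use evenly spaced
    locations, all records use a magic number drawn from
    ``magic_number_probs`` (default uniform over {3, 4, 5}),
    ``anchored_fraction`` execute their plan unchanged, and the remainder
    adjust — a ``deviated_fraction_of_adjusted`` share before completing
    the plan, the rest afterwards; ``magic_change_fraction_of_adjusted``
    of the adjusters revisit a planned location (changing its total count
    away from the magic number) while the others add a fresh location at
    the magic count.  Conclusions are correct for a
    ``conclusion_accuracy`` share of each hypothesis arm.  Defaults mirror
    the expert cohort composition reported in the behavioral results.
    """
    if n_records < 1:
        raise InvalidParameterError("n_records must be >= 1")
    grid = grid or TransectGrid()
    magic_probs = magic_number_probs or {3: 1 / 3, 4: 1 / 3, 5: 1 / 3}
    accuracy = {"given": 1.0, "alternative": 1.0} | (conclusion_accuracy or {})
    if any(m < 1 or m > 9 for m in magic_probs):
        raise InvalidParameterError("fixture magic numbers must be in 1..9")

    rng = np.random.default_rng(
        np.random.SeedSequence([int(seed), 4])
    )
    noise, cfg = NoiseModel(), RunConfig(master_seed=int(seed))
    datasets = {
        hyp: generate_dataset(
            cfg.make_model(hyp), noise, grid,
            seed=substream_seed(seed, 4, h_idx),
        )
        for h_idx, hyp in enumerate(("given", "alternative"))
    }

    equal_flags = _flags(_exact_count(equal_spacing_fraction, n_records), n_records, rng)
    anchored_flags = _flags(_exact_count(anchored_fraction, n_records), n_records, rng)
    adjusted_idx = np.flatnonzero(~anchored_flags)
    n_adj = len(adjusted_idx)
    dev_flags_adj = _flags(_exact_count(deviated_fraction_of_adjusted, n_adj), n_adj, rng)
    chg_flags_adj = _flags(_exact_count(magic_change_fraction_of_adjusted, n_adj), n_adj, rng)
    deviated_flags = np.zeros(n_records, dtype=bool)
    deviated_flags[adjusted_idx] = dev_flags_adj
    change_flags = np.zeros(n_records, dtype=bool)
    change_flags[adjusted_idx] = chg_flags_adj

    hypotheses = np.array(
        ["given" if i % 2 == 0 else "alternative" for i in range(n_records)]
    )
    correct_flags = np.zeros(n_records, dtype=bool)
    for hyp in ("given", "alternative"):
        arm = np.flatnonzero(hypotheses == hyp)
        correct_flags[arm] = _flags(
            _exact_count(accuracy[hyp], len(arm)), len(arm), rng
        )

    magic_values = np.array(sorted(magic_probs))
    magic_p = np.array([magic_probs[m] for m in magic_values], dtype=float)
    magic_p = magic_p / magic_p.sum()

    records: list[ParticipantRecord] = []
    for i in range(n_records):
        hyp = str(hypotheses[i])
        magic = int(rng.choice(magic_values, p=magic_p))
        n_loc = int(rng.integers(6, 12))
        if equal_flags[i]:
            strategy = evenly_spaced_strategy(grid, n_loc, magic)
        else:
            locs = _nonuniform_locations(grid, n_loc, threshold, rng)
            strategy = SamplingStrategy(
                grid, tuple(StrategyStep(l, magic) for l in locs)
            )
        executed = strategy
        if not anchored_flags[i]:
            plan_locs = strategy.initial_locations()
            if change_flags[i]:
                # revisit a planned location: its total leaves the magic number
                extra_loc = plan_locs[0]
                extra_n = min(magic, 10 - magic)
            else:
                # add a fresh location at the magic count: no change
                free = sorted(set(range(1, grid.n_locations + 1)) - set(plan_locs))
                extra_loc = free[0]
                extra_n = magic
            at = len(strategy.steps) - 1 if deviated_flags[i] else None
            executed = strategy.with_step(extra_loc, extra_n, phase="added", at=at)
        log = execute_strategy(
            datasets[hyp], executed, substream_seed(seed, 5, i),
            track_cumulative=False,
        )
        if hyp == "given":
            conclusion = "accept" if correct_flags[i] else "reject"
        else:
            conclusion = "reject" if correct_flags[i] else "accept"
        records.append(
            ParticipantRecord(
                participant_id=f"fixture-{i + 1:03d}",
                expertise="expert",
                assigned_hypothesis=hyp,
                initial_strategy=strategy,
                executed_log=log,
                conclusion=conclusion,
                confidence="moderately",
            )
        )
    logger.info(
        "stage=fixture n_records=%d seed=%d", n_records, seed
    )
    return records
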