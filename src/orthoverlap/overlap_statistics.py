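"""Null models for the number of genes hit by two or more independent screens.

This is an explicit extension of the integrative analysis: it quantifies
whether an observed cross-study overlap count exceeds what uniform, independent
per-study draws from a shared gene universe would produce. It is OFF by
default in the main pipeline report.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .errors import ValidationError
from .integration import OverlapEntry, RegulatorCatalog

DEFAULT_SEED = 17


@dataclass(frozen=True)
class NullModelConfig:
    """Sampling frame for the overlap null: uniform draws without replacement."""

    universe_size: int
    study_sizes: tuple[int, ...]
    n_perm: int = 10_000
    seed: int = DEFAULT_SEED

    def __post_init__(self) -> None:
        if self.universe_size <= 0:
            raise ValidationError("universe_size must be positive")
        if any(s <= 0 for s in self.study_sizes):
            raise ValidationError("study sizes must be positive")
        if any(s > self.universe_size for s in self.study_sizes):
            raise ValidationError("every study size must be <= universe_size")


@dataclass
class NullSummary:
    observed: int
    null_counts: np.ndarray
    mean_null: float
    p_value: float
    expectation_closed_form: float
    config: NullModelConfig | None = field(default=None, repr=False)

    def quantiles(self, qs=(0.025, 0.5, 0.975)) -> dict[str, float]:
        if len(self.null_counts) == 0:
            return {f"q{q}": 0.0 for q in qs}
        return {f"q{q}": float(np.quantile(self.null_counts, q)) for q in qs}

    def to_json(self) -> str:
        payload = {
            "observed": self.observed,
            "mean_null": self.mean_null,
            "p_value": self.p_value,
            "expectation_closed_form": self.expectation_closed_form,
            "n_perm": int(len(self.null_counts)),
            **self.quantiles(),
        }
        if self.config is not None:
            payload["universe_size"] = self.config.universe_size
            payload["study_sizes"] = list(self.config.study_sizes)
            payload["seed"] = self.config.seed
        return json.dumps(payload, indent=2, sort_keys=True)


def expected_overlap_closed_form(config: NullModelConfig) -> float:
    """Exact expected number of genes hit by >= 2 studies.

    With p_i = n_i / U the marginal inclusion probability of any fixed gene in
    study i, E[#genes in >=2 studies] = U * [1 - prod(1-p_i) - sum_i p_i *
    prod_{j!=i} (1-p_j)]; inclusion events are independent across studies.
    """
    u = config.universe_size
    p = np.asarray(config.study_sizes, dtype=float) / u
    if np.any(p > 1):
        raise ValidationError("study size exceeds universe")
    q = 1.0 - p
    prod_q = np.prod(q)
    none = prod_q
    # P(exactly one study hits the gene), guarding the p_i = 1 division case
    exactly_one = 0.0
    for i in range(len(p)):
        exactly_one += p[i] * np.prod(np.delete(q, i))
    return float(u * (1.0 - none - exactly_one))


def sample_null_counts(config: NullModelConfig, rng: np.random.Generator) -> np.ndarray:
    """Draw n_perm replicates of the >= 2-study overlap count under the null."""
    u = config.universe_size
    counts = np.empty(config.n_perm, dtype=np.int64)
    for r in range(config.n_perm):
        hits = np.zeros(u, dtype=np.int16)
        for size in config.study_sizes:
            picked = rng.choice(u, size=size, replace=False)
            hits[picked] += 1
        counts[r] = int(np.count_nonzero(hits >= 2))
    return counts


def permutation_null(config: NullModelConfig, observed: int) -> NullSummary:
    """Seeded permutation null with the add-one p-value (never exactly 0)."""
    if observed < 0:
        raise ValidationError("observed must be >= 0")
    if config.n_perm <= 0:
        raise ValidationError("n_perm must be positive")
    rng = np.random.default_rng(config.seed)
    null_counts = sample_null_counts(config, rng)
    p_value = (1.0 + np.count_nonzero(null_counts >= observed)) / (1.0 + config.n_perm)
    return NullSummary(
        observed=observed,
        null_counts=null_counts,
        mean_null=float(null_counts.mean()),
        p_value=float(p_value),
        expectation_closed_form=expected_overlap_closed_form(config),
        config=config,
    )


def overlap_report(
    catalog: RegulatorCatalog,
    overlaps: list[OverlapEntry],
    config: NullModelConfig,
    out_path=None,
) -> NullSummary:
    """Bind the pipeline's observed overlap count to the null machinery."""
    observed = len(overlaps)
    if len(catalog) == 0 and observed == 0:
        summary = NullSummary(
            observed=0,
            null_counts=np.zeros(0, dtype=np.int64),
            mean_null=0.0,
            p_value=1.0,
            expectation_closed_form=0.0,
            config=config,
        )
    else:
        summary = permutation_null(config, observed)
    if out_path is not None:
        with open(out_path, "w", encoding="utf-8") as handle:
            handle.write(summary.to_json() + "\n")
    return summary


def default_universe_size(omap) -> int:
    """Map-reachable worm genes: the default sampling frame for the null."""
    return len(omap.reference_universe())
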