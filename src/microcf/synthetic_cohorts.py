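"""Multi-cohort zero-inflated compositional abundance simulator.

Generates species-level relative-abundance tables for several cohorts
(countries) with obese/healthy groups, planted biomarkers whose log-scale
mean differs between groups, cohort (geography) effects, and Bernoulli
zero-inflation — the sparse, heterogeneous character of real gut-metagenome
profiles — so that every downstream selection stage can be scored against a
known ground truth.

Generative model (per sample, per species):

    log lambda = base + cohort_shift + direction * effect/2 * group_sign + noise
    intensity  = exp(log lambda), zeroed with probability ``zero_inflation``
    abundance  = intensity / sum(intensity)          (compositional closure)

``group_sign`` is +1 for obese, -1 for healthy; ``direction`` is +-1 drawn
once per planted species, so the obese-vs-healthy log-mean shift of a planted
species is exactly ``effect_size`` in the cohorts where it is planted.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .abundance_io import HEALTHY, OBESE, AbundanceTable, write_merged_profile, write_metadata
from .errors import ConfigurationError

UP = "up_in_obese"
DOWN = "down_in_obese"

#: SD of per-species baseline log intensities (controls abundance skew).
BASE_LOG_SD = 2.0
#: SD of per-sample log-normal noise.
NOISE_LOG_SD = 1.0


@dataclass(frozen=True)
class SimulationSpec:
    """Configuration of the synthetic multi-cohort study design."""

    n_cohorts: int = 5
    n_per_group: int = 100
    n_species: int = 200
    n_planted_shared: int = 20
    n_planted_private: int = 0
    effect_size: float = 1.0
    cohort_effect_size: float = 1.0
    zero_inflation: float = 0.3
    seed: int = 0

    def validate(self) -> None:
        for name in ("n_cohorts", "n_per_group", "n_species",
                     "n_planted_shared", "n_planted_private"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0")
        if self.n_cohorts < 1:
            raise ConfigurationError("n_cohorts must be >= 1")
        if self.n_planted_shared + self.n_planted_private > self.n_species:
            raise ConfigurationError(
                "n_planted_shared + n_planted_private exceeds n_species")
        if not 0.0 <= self.zero_inflation <= 1.0:
            raise ConfigurationError("zero_inflation must be in [0, 1]")


@dataclass
class GroundTruth:
    """Planted biomarkers and their group-effect directions."""

    shared_biomarkers: set[str]
    private_biomarkers: dict[str, set[str]]
    effect_directions: dict[str, str]

    def __post_init__(self) -> None:
        private_all = set().union(*self.private_biomarkers.values()) \
            if self.private_biomarkers else set()
        if self.shared_biomarkers & private_all:
            raise ConfigurationError("shared and private biomarker sets overlap")

    def to_json(self, path: str | Path) -> None:
        payload = {
            "shared_biomarkers": sorted(self.shared_biomarkers),
            "private_biomarkers": {c: sorted(v) for c, v in self.private_biomarkers.items()},
            "effect_directions": dict(sorted(self.effect_directions.items())),
        }
        Path(path).write_text(json.dumps(payload, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        payload = json.loads(Path(path).read_text())
        return cls(
            shared_biomarkers=set(payload["shared_biomarkers"]),
            private_biomarkers={c: set(v) for c, v in payload["private_biomarkers"].items()},
            effect_directions=payload["effect_directions"],
        )


def simulate_multicohort(spec: SimulationSpec) -> tuple[AbundanceTable, GroundTruth]:
    """Generate a multi-cohort abundance table with planted biomarkers."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    p = spec.n_species
    species = [f"sp_{j:04d}" for j in range(p)]
    cohort_names = [f"cohort_{i}" for i in range(spec.n_cohorts)]

    base = rng.normal(0.0, BASE_LOG_SD, size=p)
    cohort_shift = rng.normal(0.0, spec.cohort_effect_size,
                              size=(spec.n_cohorts, p))

    planted = rng.choice(p, size=spec.n_planted_shared + spec.n_planted_private,
                         replace=False)
    shared_idx = planted[: spec.n_planted_shared]
    private_idx = planted[spec.n_planted_shared:]
    private_cohort = rng.integers(0, spec.n_cohorts, size=len(private_idx))
    directions = rng.choice([1.0, -1.0], size=p)  # only planted entries matter

    # effect mask per cohort x species: 1 where the species is planted there
    effect_mask = np.zeros((spec.n_cohorts, p))
    effect_mask[:, shared_idx] = 1.0
    for j, c in zip(private_idx, private_cohort):
        effect_mask[c, j] = 1.0

    n = spec.n_cohorts * 2 * spec.n_per_group
    sample_ids, cohorts, groups = [], [], []
    rows = np.empty((n, p))
    i = 0
    for c, cname in enumerate(cohort_names):
        for group, sign in ((OBESE, 1.0), (HEALTHY, -1.0)):
            for k in range(spec.n_per_group):
                sample_ids.append(f"{cname}_{group}_{k:03d}")
                cohorts.append(cname)
                groups.append(group)
                mean = (base + cohort_shift[c]
                        + directions * effect_mask[c] * spec.effect_size / 2.0 * sign)
                log_lam = mean + rng.normal(0.0, NOISE_LOG_SD, size=p)
                intensity = np.exp(log_lam)
                zero = rng.random(p) < spec.zero_inflation
                # never zero out a whole sample: the top species stays
                zero[np.argmax(intensity)] = False
                intensity[zero] = 0.0
                rows[i] = intensity / intensity.sum()
                i += 1

    values = pd.DataFrame(rows, index=sample_ids, columns=species)
    table = AbundanceTable(values,
                           pd.Series(cohorts, index=sample_ids),
                           pd.Series(groups, index=sample_ids))
    truth = GroundTruth(
        shared_biomarkers={species[j] for j in shared_idx},
        private_biomarkers={
            cohort_names[c]: {species[j] for j, cc in zip(private_idx, private_cohort) if cc == c}
            for c in range(spec.n_cohorts)
        },
        effect_directions={
            species[j]: (UP if directions[j] > 0 else DOWN)
            for j in planted
        },
    )
    return table, truth


def recovery_metrics(selected: set[str], truth: GroundTruth) -> tuple[float, float]:
    """Precision and recall of a selected set against the planted shared set.

    Precision is 0 by convention when ``selected`` is empty.
    """
    shared = truth.shared_biomarkers
    hits = len(set(selected) & shared)
    precision = hits / len(selected) if selected else 0.0
    recall = hits / len(shared) if shared else 0.0
    return precision, recall


def write_simulation(table: AbundanceTable, truth: GroundTruth,
                     out_dir: str | Path) -> None:
    """Write the simulated study to disk (merged TSV, metadata TSV, truth JSON)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_merged_profile(table, out / "abundance.tsv")
    write_metadata(table, out / "metadata.tsv")
    truth.to_json(out / "ground_truth.json")
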