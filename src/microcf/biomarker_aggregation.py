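"""Set algebra combining the three selection families into final biomarkers.

Per-cohort selections are intersected across cohorts ("regional"), the
filter and embedded regional sets are unioned, and the union is intersected
with the wrapper pool:  final = (F ∪ E₁ ∪ … ∪ Eₘ) ∩ W.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .errors import DataError

logger = logging.getLogger(__name__)


@dataclass
class SelectionOutcome:
    """One selection event with provenance, for the audit trail."""

    family: str  # filter | embedded | wrapper
    method: str
    cohort: str  # cohort label or "regional"
    species: set[str]
    provenance: str = ""

    def to_record(self) -> dict:
        return {"family": self.family, "method": self.method,
                "cohort": self.cohort, "species": sorted(self.species),
                "provenance": self.provenance}


def regional_intersection(per_cohort: Mapping[str, Iterable[str]]) -> set[str]:
    """Intersection of per-cohort selected sets (order-invariant)."""
    if not per_cohort:
        raise DataError("need at least one cohort")
    sets = [set(v) for v in per_cohort.values()]
    return set.intersection(*sets)


def aggregate_final(filter_regional: Iterable[str],
                    embedded_regionals: Sequence[Iterable[str]],
                    wrapper_pool: Iterable[str]) -> tuple[set[str], set[str]]:
    """Union the filter/embedded families, intersect with the wrapper pool."""
    union_set = set(filter_regional)
    for e in embedded_regionals:
        union_set |= set(e)
    final = union_set & set(wrapper_pool)
    if union_set and not final:
        logger.warning("wrapper pool shares no species with the filter/embedded "
                       "union; final biomarker set is empty")
    return union_set, final


def outcomes_to_frame(outcomes: Sequence[SelectionOutcome],
                      universe: Sequence[str]) -> pd.DataFrame:
    """One row per species, one boolean column per (family, method, cohort)."""
    frame = pd.DataFrame(index=list(universe))
    frame.index.name = "species"
    for o in outcomes:
        frame[f"{o.family}.{o.method}.{o.cohort}"] = [
            s in o.species for s in frame.index]
    return frame


def write_manifest(path: str | Path, **entries) -> None:
    """Run manifest: seeds, thresholds and set sizes, as JSON."""
    def _default(o):
        if isinstance(o, set):
            return sorted(o)
        raise TypeError(f"not serialisable: {type(o)}")
    Path(path).write_text(json.dumps(entries, indent=2, default=_default,
                                     sort_keys=True))
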