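"""Pooling counterfactuals into modulation calls and co-abundance networks.

For each biomarker and cohort the shift between the median abundance of the
original samples and of their counterfactual instances is classified as
``up`` / ``down`` / ``unchanged`` using a dead band (default 0.1 on the
table's native abundance scale).  A biomarker is a broad-spectrum target
when every cohort calls the same non-unchanged direction.

Co-abundance networks connect biomarkers whose pairwise Pearson correlation
exceeds a threshold in absolute value (default 0.3); comparing the edge sets
of the counterfactual-sample network and the healthy-sample network counts
their common associations.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .errors import ContractError, DataError

logger = logging.getLogger(__name__)

UP, DOWN, UNCHANGED, NONE = "up", "down", "unchanged", "none"

#: dead band for a median shift to count as a direction call
DEFAULT_SHIFT_THRESHOLD = 0.1
#: minimum |Pearson r| for a co-abundance edge
DEFAULT_EDGE_THRESHOLD = 0.3


def _to_frame(m, columns=None) -> pd.DataFrame:
    if isinstance(m, pd.DataFrame):
        return m
    return pd.DataFrame(np.atleast_2d(np.asarray(m, dtype=float)),
                        columns=columns)


def median_shift_directions(originals, counterfactuals,
                            threshold: float = DEFAULT_SHIFT_THRESHOLD
                            ) -> pd.DataFrame:
    """Per-species median shift and direction call.

    shift = median(counterfactual) - median(original); ``up`` when
    shift >= threshold, ``down`` when shift <= -threshold, else
    ``unchanged`` (so unchanged <=> |shift| < threshold).
    """
    orig = _to_frame(originals)
    cf = _to_frame(counterfactuals, columns=orig.columns)
    if list(orig.columns) != list(cf.columns):
        raise ContractError("originals and counterfactuals disagree on species")
    if orig.shape[0] < 1 or cf.shape[0] < 1:
        raise DataError("need at least one sample on each side")
    shift = cf.median(axis=0) - orig.median(axis=0)
    direction = pd.Series(UNCHANGED, index=shift.index, dtype=object)
    direction[shift >= threshold] = UP
    direction[shift <= -threshold] = DOWN
    return pd.DataFrame({
        "original_median": orig.median(axis=0),
        "counterfactual_median": cf.median(axis=0),
        "shift": shift,
        "direction": direction,
    })


def broad_spectrum_call(per_cohort_directions: Mapping[str, Mapping[str, str]],
                        mode: str = "unanimous") -> dict[str, str]:
    """Cross-cohort consensus on modulation direction.

    ``unanimous`` (default): a species is broad-spectrum up/down only when
    every cohort calls that same direction.  ``majority``: the direction with
    most calls wins provided no cohort calls the opposite direction.
    """
    if len(per_cohort_directions) < 2:
        raise DataError("broad-spectrum calls need >=2 cohorts")
    if mode not in ("unanimous", "majority"):
        raise DataError(f"unknown mode: {mode!r}")
    species: set[str] = set()
    for calls in per_cohort_directions.values():
        species |= set(calls)
    out: dict[str, str] = {}
    for sp in sorted(species):
        calls = [per_cohort_directions[c].get(sp, UNCHANGED)
                 for c in per_cohort_directions]
        n_up, n_down = calls.count(UP), calls.count(DOWN)
        if mode == "unanimous":
            if n_up == len(calls):
                out[sp] = UP
            elif n_down == len(calls):
                out[sp] = DOWN
            else:
                out[sp] = NONE
        else:
            if n_up > 0 and n_down == 0 and n_up > len(calls) / 2:
                out[sp] = UP
            elif n_down > 0 and n_up == 0 and n_down > len(calls) / 2:
                out[sp] = DOWN
            else:
                out[sp] = NONE
    return out


@dataclass
class ModulationSummary:
    """Per-(species, cohort) direction calls plus broad-spectrum verdicts."""

    table: pd.DataFrame  # species, cohort, medians, shift, direction
    broad_spectrum: dict[str, str]
    threshold: float

    def to_tsv(self, path: str | Path) -> None:
        out = self.table.copy()
        out["broad_spectrum"] = out["species"].map(self.broad_spectrum)
        out.to_csv(path, sep="\t", index=False, float_format="%.10g")


def summarize_modulation(per_cohort_originals: Mapping[str, pd.DataFrame],
                         per_cohort_counterfactuals: Mapping[str, pd.DataFrame],
                         threshold: float = DEFAULT_SHIFT_THRESHOLD,
                         mode: str = "unanimous") -> ModulationSummary:
    """Direction calls per cohort plus the cross-cohort broad-spectrum call."""
    if set(per_cohort_originals) != set(per_cohort_counterfactuals):
        raise ContractError("cohort sets of originals and counterfactuals differ")
    rows = []
    per_cohort_calls: dict[str, dict[str, str]] = {}
    for cohort in per_cohort_originals:
        calls = median_shift_directions(per_cohort_originals[cohort],
                                        per_cohort_counterfactuals[cohort],
                                        threshold=threshold)
        per_cohort_calls[cohort] = calls["direction"].to_dict()
        for sp, row in calls.iterrows():
            rows.append((sp, cohort, row["original_median"],
                         row["counterfactual_median"], row["shift"],
                         row["direction"]))
    broad = broad_spectrum_call(per_cohort_calls, mode=mode) \
        if len(per_cohort_calls) >= 2 else \
        {sp: NONE for sp in next(iter(per_cohort_calls.values()))}
    table = pd.DataFrame(rows, columns=["species", "cohort", "original_median",
                                        "counterfactual_median", "shift",
                                        "direction"])
    return ModulationSummary(table=table, broad_spectrum=broad,
                             threshold=threshold)


@dataclass
class CoabundanceNetwork:
    """Thresholded Pearson co-abundance graph over biomarkers."""

    nodes: list[str]
    edges: dict[tuple[str, str], float]  # key = sorted species pair
    threshold: float

    def __post_init__(self) -> None:
        for (a, b), w in self.edges.items():
            if a == b:
                raise ContractError("self-loops are not allowed")
            if abs(w) <= self.threshold:
                raise ContractError("edge weight inside the threshold band")

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self.nodes)
        for (a, b), w in self.edges.items():
            g.add_edge(a, b, weight=float(w))
        return g

    def to_edgelist_tsv(self, path: str | Path) -> None:
        rows = [(a, b, w) for (a, b), w in sorted(self.edges.items())]
        pd.DataFrame(rows, columns=["species_a", "species_b", "weight"]) \
            .to_csv(path, sep="\t", index=False, float_format="%.10g")

    def to_graphml(self, path: str | Path) -> None:
        nx.write_graphml(self.to_networkx(), path)


def coabundance_network(abundances, threshold: float = DEFAULT_EDGE_THRESHOLD
                        ) -> CoabundanceNetwork:
    """Build the co-abundance network of a samples x biomarkers matrix.

    Edges keep pairs with |Pearson r| strictly above ``threshold``;
    constant species cannot be correlated and are dropped from the node set
    with a warning.
    """
    frame = _to_frame(abundances)
    if frame.shape[0] < 3:
        raise DataError("need >=3 samples to correlate")
    constant = [c for c in frame.columns if frame[c].nunique() <= 1]
    if constant:
        logger.warning("excluding %d constant species from the network: %s",
                       len(constant), constant[:5])
        frame = frame.drop(columns=constant)
    cols = list(frame.columns)
    corr = np.corrcoef(frame.to_numpy(dtype=float), rowvar=False)
    edges: dict[tuple[str, str], float] = {}
    for i in range(len(cols)):
        for j in range(i + 1, len(cols)):
            r = corr[i, j]
            if np.isfinite(r) and abs(r) > threshold:
                a, b = sorted((cols[i], cols[j]))
                edges[(a, b)] = float(r)
    return CoabundanceNetwork(nodes=cols, edges=edges, threshold=threshold)


def common_associations(net_a: CoabundanceNetwork, net_b: CoabundanceNetwork,
                        require_same_sign: bool = False) -> int:
    """Number of unordered pairs that are edges in both networks."""
    shared = set(net_a.edges) & set(net_b.edges)
    if require_same_sign:
        shared = {e for e in shared
                  if np.sign(net_a.edges[e]) == np.sign(net_b.edges[e])}
    return len(shared)
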