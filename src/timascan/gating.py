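"""Hierarchical gating of leukocyte events and rare-marker positivity calls.

The gate tree reproduces the consecutive manual gating strategy of the
monocyte assay: singlet selection (FSC-A vs FSC-H band), debris exclusion
(FSC-A vs SSC-A), a leukocyte/monocyte scatter region, CD45+ selection,
a lymphocyte branch (CD45-high / SSC-low, HLA-DR and CD300e negative),
monocyte identification via HLA-DR and CD300e (HLA-DR+CD300e- events are
dendritic cells), a CD300e vs CD14 confirmation region, and finally the
CD14 vs CD16 monocyte subset split into classical (CD14+CD16-), intermediate
(CD14+CD16+) and non-classical (CD14-CD16+) monocytes.

GFAP/PLP1 positivity is a rare-event call made per sample against the
fluorescent background of that sample's own gated lymphocytes: the threshold
is an upper quantile (default 0.995) of the lymphocyte marker intensities and
events strictly above it are positive.

All rectangular bounds are half-open ``[low, high)``; gate coordinates live on
the analysis scale (see :mod:`timascan.io`).
"""

from __future__ import annotations

import copy
import hashlib
import json
from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator

from .io import EventTable

__all__ = [
    "Gate2D",
    "GateTree",
    "GatingResult",
    "PositivityCall",
    "GatingError",
    "ConfigError",
    "default_timascan_tree",
    "apply_gate_tree",
    "lymphocyte_background_threshold",
    "label_marker_positive",
    "call_positivity",
    "GateTreeClassifier",
    "DEFAULT_GATE_CONFIG",
    "TERMINAL_POPULATIONS",
]


class ConfigError(ValueError):
    """Invalid or incomplete gate-tree configuration."""


class GatingError(RuntimeError):
    """A sample cannot be gated or thresholded as requested."""


TERMINAL_POPULATIONS = (
    "debris_doublets_excluded",
    "lymphocyte",
    "monocyte",
    "classical_mono",
    "intermediate_mono",
    "nonclassical_mono",
    "dendritic",
)

#: Stage keys, in gating order, with the channel shown in error messages.
_STAGES = {
    "singlets": "FSC-H",
    "debris": "FSC-A",
    "leukocyte_region": "SSC-A",
    "cd45": "CD45",
    "lymphocyte": "CD45/SSC-A",
    "cd300e": "CD300e",
    "cd14_confirm": "CD14",
    "subsets": "CD16",
}

DEFAULT_GATE_CONFIG: dict[str, dict[str, float | list[float]]] = {
    # FSC-H within +-tol of slope * FSC-A (doublets have ~half the ratio)
    "singlets": {"slope": 0.95, "tol": 180.0, "fsc_a_max": 1400.0},
    "debris": {"fsc_a_min": 200.0, "ssc_a_min": 0.0},
    "leukocyte_region": {"fsc_a": [250.0, 900.0], "ssc_a": [0.0, 550.0]},
    "cd45": {"cd45_min": 3.0},
    "lymphocyte": {"cd45_min": 5.0, "ssc_a_max": 260.0,
                   "hladr_max": 3.0, "cd300e_max": 3.0},
    "cd300e": {"hladr_min": 3.5, "cd300e_min": 3.0},
    "cd14_confirm": {"cd300e": [3.0, 9.0], "cd14": [-1.0, 9.0]},
    "subsets": {"cd14_split": 3.5, "cd16_split": 3.0},
}


@dataclass(frozen=True)
class Gate2D:
    """A named 2-D gate region (rectangle or convex polygon) with a parent."""

    name: str
    channel_x: str
    channel_y: str
    region: dict
    parent: str = "root"


@dataclass
class GateTree:
    """Ordered gate definitions rooted at "all events" plus their parameters."""

    config: dict
    gates: list[Gate2D] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.gates:
            self.gates = _build_gates(self.config)
        names = {"root"}
        for g in self.gates:
            if g.parent not in names:
                raise ConfigError(f"gate {g.name} precedes its parent {g.parent}")
            names.add(g.name)

    @property
    def terminal_populations(self) -> tuple[str, ...]:
        return TERMINAL_POPULATIONS

    def tree_hash(self) -> str:
        payload = json.dumps(self.config, sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]

    def to_dict(self) -> dict:
        return copy.deepcopy(self.config)


def _build_gates(config: dict) -> list[Gate2D]:
    c = config
    s = c["singlets"]
    xm, a, b = s["fsc_a_max"], s["slope"], s["tol"]
    gates = [
        Gate2D("singlets", "FSC-A", "FSC-H",
               {"kind": "polygon",
                "vertices": [[0.0, -b], [xm, a * xm - b], [xm, a * xm + b], [0.0, b]]}),
        Gate2D("non_debris", "FSC-A", "SSC-A",
               {"kind": "rect", "x": [c["debris"]["fsc_a_min"], np.inf],
                "y": [c["debris"]["ssc_a_min"], np.inf]}, parent="singlets"),
        Gate2D("leukocyte_region", "FSC-A", "SSC-A",
               {"kind": "rect", "x": list(c["leukocyte_region"]["fsc_a"]),
                "y": list(c["leukocyte_region"]["ssc_a"])}, parent="non_debris"),
        Gate2D("cd45_pos", "SSC-A", "CD45",
               {"kind": "rect", "x": [-np.inf, np.inf],
                "y": [c["cd45"]["cd45_min"], np.inf]}, parent="leukocyte_region"),
        Gate2D("lymph_scatter", "SSC-A", "CD45",
               {"kind": "rect", "x": [-np.inf, c["lymphocyte"]["ssc_a_max"]],
                "y": [c["lymphocyte"]["cd45_min"], np.inf]}, parent="cd45_pos"),
        Gate2D("lymphocyte", "HLA-DR", "CD300e",
               {"kind": "rect", "x": [-np.inf, c["lymphocyte"]["hladr_max"]],
                "y": [-np.inf, c["lymphocyte"]["cd300e_max"]]}, parent="lymph_scatter"),
        Gate2D("hladr_pos", "HLA-DR", "CD300e",
               {"kind": "rect", "x": [c["cd300e"]["hladr_min"], np.inf],
                "y": [-np.inf, np.inf]}, parent="cd45_pos"),
        Gate2D("dendritic", "HLA-DR", "CD300e",
               {"kind": "rect", "x": [c["cd300e"]["hladr_min"], np.inf],
                "y": [-np.inf, c["cd300e"]["cd300e_min"]]}, parent="hladr_pos"),
        Gate2D("monocyte", "HLA-DR", "CD300e",
               {"kind": "rect", "x": [c["cd300e"]["hladr_min"], np.inf],
                "y": [c["cd300e"]["cd300e_min"], np.inf]}, parent="hladr_pos"),
        Gate2D("cd14_confirm", "CD300e", "CD14",
               {"kind": "rect", "x": list(c["cd14_confirm"]["cd300e"]),
                "y": list(c["cd14_confirm"]["cd14"])}, parent="monocyte"),
        Gate2D("classical_mono", "CD14", "CD16",
               {"kind": "rect", "x": [c["subsets"]["cd14_split"], np.inf],
                "y": [-np.inf, c["subsets"]["cd16_split"]]}, parent="cd14_confirm"),
        Gate2D("intermediate_mono", "CD14", "CD16",
               {"kind": "rect", "x": [c["subsets"]["cd14_split"], np.inf],
                "y": [c["subsets"]["cd16_split"], np.inf]}, parent="cd14_confirm"),
        Gate2D("nonclassical_mono", "CD14", "CD16",
               {"kind": "rect", "x": [-np.inf, c["subsets"]["cd14_split"]],
                "y": [c["subsets"]["cd16_split"], np.inf]}, parent="cd14_confirm"),
    ]
    return gates


def default_timascan_tree(config: dict | None = None) -> GateTree:
    """Build the default consecutive gating tree.

    ``config`` may override per-stage parameters but, when given, must name
    every stage (a missing stage is a configuration error naming its gate).
    """
    if config is None:
        merged = copy.deepcopy(DEFAULT_GATE_CONFIG)
    else:
        missing = [k for k in _STAGES if k not in config]
        if missing:
            raise ConfigError(f"missing gate: {_STAGES[missing[0]]}")
        unknown = [k for k in config if k not in _STAGES]
        if unknown:
            raise ConfigError(f"unknown gate stage: {unknown[0]}")
        merged = copy.deepcopy(DEFAULT_GATE_CONFIG)
        for stage, params in config.items():
            merged[stage].update(params)
    return GateTree(merged)


@dataclass
class GatingResult:
    """Per-event terminal population assignment for one sample."""

    sample_id: str
    labels: np.ndarray  # terminal population, "ungated", or debris/doublet
    population_counts: dict[str, int]
    stage_counts: dict[str, int]
    provenance: dict

    @property
    def n_events(self) -> int:
        return int(self.labels.shape[0])

    def mask(self, *populations: str) -> np.ndarray:
        out = np.zeros(self.n_events, dtype=bool)
        for p in populations:
            out |= self.labels == p
        return out


def _in_rect(x: np.ndarray, y: np.ndarray, region: dict) -> np.ndarray:
    (xl, xh), (yl, yh) = region["x"], region["y"]
    return (x >= xl) & (x < xh) & (y >= yl) & (y < yh)


def _in_convex_polygon(x: np.ndarray, y: np.ndarray, vertices: list) -> np.ndarray:
    v = np.asarray(vertices, dtype=float)
    inside = np.ones(x.shape[0], dtype=bool)
    n = len(v)
    # CCW convex polygon: inside iff left of (or on) every directed edge
    for i in range(n):
        x0, y0 = v[i]
        x1, y1 = v[(i + 1) % n]
        inside &= (x1 - x0) * (y - y0) - (y1 - y0) * (x - x0) >= 0
    return inside


def _gate_mask(table: EventTable, gate: Gate2D) -> np.ndarray:
    x = table.column(gate.channel_x)
    y = table.column(gate.channel_y)
    if gate.region["kind"] == "rect":
        return _in_rect(x, y, gate.region)
    return _in_convex_polygon(x, y, gate.region["vertices"])


def apply_gate_tree(table: EventTable, tree: GateTree) -> GatingResult:
    """Assign every event to exactly one terminal population or "ungated".

    Events rejected by the singlet or debris gates are labelled
    ``debris_doublets_excluded``. Terminal assignments follow tree order and
    the terminal gates are disjoint by construction; the reported ``monocyte``
    count is the sum of the three subset counts.
    """
    for ch in ("FSC-A", "FSC-H", "SSC-A", "CD45", "HLA-DR", "CD300e", "CD14", "CD16"):
        if ch not in table.channels:
            raise GatingError(f"missing channel {ch}")

    n = table.n_events
    masks: dict[str, np.ndarray] = {"root": np.ones(n, dtype=bool)}
    for gate in tree.gates:
        masks[gate.name] = masks[gate.parent] & _gate_mask(table, gate)

    labels = np.full(n, "ungated", dtype=object)
    labels[~masks["non_debris"]] = "debris_doublets_excluded"
    for terminal in ("lymphocyte", "dendritic", "classical_mono",
                     "intermediate_mono", "nonclassical_mono"):
        labels[masks[terminal]] = terminal

    counts = {p: int(np.sum(labels == p)) for p in TERMINAL_POPULATIONS
              if p != "monocyte"}
    counts["monocyte"] = (counts["classical_mono"] + counts["intermediate_mono"]
                          + counts["nonclassical_mono"])
    counts["ungated"] = int(np.sum(labels == "ungated"))
    stage_counts = {name: int(m.sum()) for name, m in masks.items() if name != "root"}
    stage_counts["leukocytes"] = stage_counts["non_debris"]

    assert (counts["debris_doublets_excluded"] + counts["lymphocyte"]
            + counts["dendritic"] + counts["monocyte"] + counts["ungated"]) == n

    return GatingResult(
        sample_id=table.sample_id,
        labels=labels,
        population_counts=counts,
        stage_counts=stage_counts,
        provenance={"gate_tree_hash": tree.tree_hash()},
    )


@dataclass
class PositivityCall:
    """A per-sample marker positivity threshold and the per-event flags."""

    marker: str
    threshold: float
    quantile: float
    background_population: str = "lymphocyte"
    flags: np.ndarray | None = None

    @property
    def n_positive(self) -> int:
        return int(self.flags.sum()) if self.flags is not None else 0


def lymphocyte_background_threshold(
    table: EventTable,
    gating: GatingResult,
    marker: str,
    quantile: float = 0.995,
    background_population: str = "lymphocyte",
    min_background_events: int = 500,
) -> float:
    """Empirical background quantile (type-7) of the marker in gated lymphocytes."""
    if not 0 < quantile < 1:
        raise ValueError("quantile must be in (0, 1)")
    bg = table.column(marker)[gating.mask(background_population)]
    if bg.size < min_background_events:
        raise GatingError(
            f"only {bg.size} {background_population} events gated "
            f"(< {min_background_events}); flag sample instead of thresholding"
        )
    return float(np.quantile(bg, quantile))  # numpy default = type-7 interpolation


def label_marker_positive(
    table: EventTable,
    gating: GatingResult,
    marker: str,
    threshold: float,
    populations: tuple[str, ...] | None = None,
) -> np.ndarray:
    """Flag events strictly above the threshold (boundary events are negative).

    When ``populations`` is given, flags outside those gated populations are
    forced False.
    """
    if not np.isfinite(threshold):
        raise ValueError("threshold must be finite")
    flags = table.column(marker) > threshold
    if populations is not None:
        flags &= gating.mask(*populations)
    return flags


def call_positivity(
    table: EventTable,
    gating: GatingResult,
    marker: str,
    quantile: float = 0.995,
    populations: tuple[str, ...] | None = None,
    min_background_events: int = 500,
) -> PositivityCall:
    """Convenience: derive the background threshold and label events."""
    thr = lymphocyte_background_threshold(
        table, gating, marker, quantile, min_background_events=min_background_events)
    flags = label_marker_positive(table, gating, marker, thr, populations)
    return PositivityCall(marker=marker, threshold=thr, quantile=quantile, flags=flags)


class GateTreeClassifier(BaseEstimator):
    """Scikit-learn-style wrapper assigning events to leukocyte populations.

    The gates are fixed configuration, so ``fit`` only materializes the tree;
    ``predict`` maps an :class:`EventTable` (or an events x channels array with
    ``channels``) to per-event population labels.
    """

    def __init__(self, config: dict | None = None):
        self.config = config

    def fit(self, X=None, y=None) -> "GateTreeClassifier":
        self.tree_ = default_timascan_tree(self.config)
        return self

    def _as_table(self, X, channels) -> EventTable:
        if isinstance(X, EventTable):
            return X
        if channels is None:
            raise ValueError("channels required when X is an array")
        return EventTable("sample", list(channels), np.asarray(X, dtype=float))

    def predict(self, X, channels: list[str] | None = None) -> np.ndarray:
        if not hasattr(self, "tree_"):
            self.fit()
        return apply_gate_tree(self._as_table(X, channels), self.tree_).labels

    def gate(self, X, channels: list[str] | None = None) -> GatingResult:
        if not hasattr(self, "tree_"):
            self.fit()
        return apply_gate_tree(self._as_table(X, channels), self.tree_)
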