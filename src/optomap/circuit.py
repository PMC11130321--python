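"""Circuit-map assembly: layer assignment, activation criteria, layer ×
cell-type input matrices, normalization, and dual-input convergence stats.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Callable

import numpy as np
import pandas as pd

__all__ = [
    "LayerTable",
    "DEFAULT_LAYER_TABLE",
    "NeuronRecord",
    "InputMatrix",
    "ConvergenceSummary",
    "assign_layer",
    "classify_activation",
    "assemble_input_matrix",
    "normalize_strengths",
    "convergence_stats",
    "ACTIVATION_THRESHOLD_MV",
    "STRONG_ACTIVATION_THRESHOLD_MV",
]

# evoked-EPSP criteria: mean amplitude >3 mV = activated, >7 mV = strong
ACTIVATION_THRESHOLD_MV = 3.0
STRONG_ACTIVATION_THRESHOLD_MV = 7.0

CELL_CLASSES = ("Pyr", "L1-IN", "PV", "SST", "VIP")


@dataclass(frozen=True)
class LayerTable:
    """Ordered cortical-layer boundaries, µm from the pia.

    ``bounds`` lists the depth at the *top* of each layer plus a final
    deepest bound; layer i occupies the half-open interval
    [bounds[i], bounds[i+1]).
    """

    names: tuple[str, ...] = ("L1", "L2/3", "L4", "L5", "L6")
    bounds: tuple[float, ...] = (0.0, 100.0, 310.0, 430.0, 600.0, 850.0)

    def __post_init__(self) -> None:
        if len(self.bounds) != len(self.names) + 1:
            raise ValueError("need len(names)+1 boundary depths")
        if any(b >= a for a, b in zip(self.bounds[1:], self.bounds)):
            raise ValueError("boundaries must be strictly increasing")
        if self.bounds[0] != 0.0:
            raise ValueError("coverage must start at the pia (0 µm)")

    @property
    def max_depth(self) -> float:
        return self.bounds[-1]

    def interval(self, name: str) -> tuple[float, float]:
        i = self.names.index(name)
        return self.bounds[i], self.bounds[i + 1]


DEFAULT_LAYER_TABLE = LayerTable()


def assign_layer(depth: float, table: LayerTable = DEFAULT_LAYER_TABLE) -> str:
    """Map a soma depth (µm from pia) to its layer, half-open intervals."""
    if not (0.0 <= depth < table.max_depth):
        raise ValueError(
            f"depth {depth} µm outside [0, {table.max_depth}) µm")
    idx = int(np.searchsorted(table.bounds, depth, side="right")) - 1
    return table.names[idx]


def classify_activation(mean_amplitude: float) -> str:
    """Activation class from the trial-averaged EPSP amplitude (mV)."""
    if not np.isfinite(mean_amplitude):
        raise ValueError("amplitude must be finite")
    if mean_amplitude > STRONG_ACTIVATION_THRESHOLD_MV:
        return "strong"
    if mean_amplitude > ACTIVATION_THRESHOLD_MV:
        return "activated"
    return "none"


@dataclass
class NeuronRecord:
    """One recorded (or simulated) neuron and its evoked responses.

    ``responses`` maps input source name → a PSP or PSC measurement from
    :mod:`optomap.ephys`.
    """

    cell_id: str
    depth_from_pia: float                  # µm
    layer: str | None = None               # derived from depth if omitted
    cell_class: str = "Pyr"
    responses: dict[str, Any] = field(default_factory=dict)
    ih_slope: float | None = None          # pA/s
    predicted_type: str | None = None      # "Pyr_LP" | "Pyr_ORBvl"
    layer_table: LayerTable = DEFAULT_LAYER_TABLE

    def __post_init__(self) -> None:
        derived = assign_layer(self.depth_from_pia, self.layer_table)
        if self.layer is None:
            self.layer = derived
        elif self.layer != derived:
            raise ValueError(
                f"layer {self.layer} inconsistent with depth "
                f"{self.depth_from_pia} µm (table says {derived})")
        if self.layer == "L1" and self.cell_class == "Pyr":
            raise ValueError("L1 cells cannot be pyramidal")


def _response_amplitude(measurement: Any) -> float:
    amp = getattr(measurement, "amplitude", None)
    if amp is None:
        amp = getattr(measurement, "peak_amplitude", None)
    if amp is None:
        raise TypeError("measurement carries no amplitude")
    return float(amp)


@dataclass
class InputMatrix:
    """Per (layer, cell_class) mean response amplitude for one input source.

    ``table`` has columns mean_amplitude, n, activation_class; cells never
    recorded are absent from the table (missing, not 0 mV).
    """

    input_source: str
    table: pd.DataFrame
    normalized_to: str | None = None


def assemble_input_matrix(records: list[NeuronRecord],
                          input_source: str) -> InputMatrix:
    """Group responses to one input source by (layer, cell_class)."""
    rows = []
    for rec in records:
        if input_source in rec.responses:
            rows.append((rec.layer, rec.cell_class,
                         _response_amplitude(rec.responses[input_source])))
    if not rows:
        raise ValueError(f"no record has a response to {input_source!r}")
    df = pd.DataFrame(rows, columns=["layer", "cell_class", "amplitude"])
    # canonical row order so group means are exactly record-order invariant
    df = df.sort_values(["layer", "cell_class", "amplitude"],
                        kind="stable", ignore_index=True)
    grouped = df.groupby(["layer", "cell_class"], sort=True)["amplitude"]
    out = grouped.agg(mean_amplitude="mean", n="count")
    out["activation_class"] = out["mean_amplitude"].map(classify_activation)
    return InputMatrix(input_source=input_source, table=out)


def normalize_strengths(matrix: InputMatrix,
                        reference_cell: tuple[str, str]) -> InputMatrix:
    """Divide every group mean by the reference group's mean.

    The reference (layer, cell_class) maps to exactly 1.0; activation
    classes are re-derived from the *unnormalized* means and kept.
    """
    if reference_cell not in matrix.table.index:
        raise ValueError(f"reference {reference_cell} not in matrix")
    ref = matrix.table.loc[reference_cell, "mean_amplitude"]
    if matrix.normalized_to is not None:
        ref_label = f"{reference_cell[0]}/{reference_cell[1]}"
        if matrix.normalized_to == ref_label and np.isclose(ref, 1.0):
            return matrix  # idempotent re-normalization
    if not ref > 0:
        raise ValueError("reference mean must be positive")
    table = matrix.table.copy()
    table["mean_amplitude"] = table["mean_amplitude"] / ref
    return InputMatrix(
        input_source=matrix.input_source,
        table=table,
        normalized_to=f"{reference_cell[0]}/{reference_cell[1]}",
    )


@dataclass
class ConvergenceSummary:
    """Dual-input convergence tallies for one population of neurons."""

    source_a: str
    source_b: str
    counts: dict[str, int]          # both / only_a / only_b / neither
    percentages: dict[str, float]   # same keys, sum to 100
    charge_pairs: pd.DataFrame      # per neuron: |charge| to A and to B

    @property
    def n(self) -> int:
        return sum(self.counts.values())


def _default_responder(measurement: Any, sd_multiplier: float) -> bool:
    """Default response criterion: evoked charge exceeding
    ``sd_multiplier`` × the baseline-window charge SD."""
    charge = abs(getattr(measurement, "charge"))
    base_sd = getattr(measurement, "baseline_charge_sd", None)
    if base_sd is None or base_sd == 0:
        return charge > 0
    return charge > sd_multiplier * base_sd


def convergence_stats(
    records: list[NeuronRecord],
    source_a: str,
    source_b: str,
    response_criterion: Callable[[Any], bool] | None = None,
    sd_multiplier: float = 5.0,
) -> ConvergenceSummary:
    """Bin neurons into both / only-A / only-B / neither responders.

    Every record must carry a measured response to both sources; the
    criterion defaults to evoked charge > ``sd_multiplier`` × its
    baseline-window charge SD.
    """
    if response_criterion is None:
        def response_criterion(m):  # noqa: F811 - deliberate default
            return _default_responder(m, sd_multiplier)
    counts = {"both": 0, "only_a": 0, "only_b": 0, "neither": 0}
    pairs = []
    for rec in records:
        for src in (source_a, source_b):
            if src not in rec.responses:
                raise ValueError(
                    f"record {rec.cell_id} lacks a response to {src!r}")
        ra = response_criterion(rec.responses[source_a])
        rb = response_criterion(rec.responses[source_b])
        key = ("both" if ra and rb else "only_a" if ra
               else "only_b" if rb else "neither")
        counts[key] += 1
        pairs.append((rec.cell_id,
                      abs(getattr(rec.responses[source_a], "charge", np.nan)),
                      abs(getattr(rec.responses[source_b], "charge", np.nan))))
    n = sum(counts.values())
    if n == 0:
        raise ValueError("no records")
    percentages = {k: round(100.0 * v / n, 1) for k, v in counts.items()}
    charge_pairs = pd.DataFrame(
        pairs, columns=["cell_id", f"charge_{source_a}", f"charge_{source_b}"]
    ).set_index("cell_id")
    return ConvergenceSummary(source_a=source_a, source_b=source_b,
                              counts=counts, percentages=percentages,
                              charge_pairs=charge_pairs)
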