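"""File I/O: delimited-text and HDF5 trace containers, Matrix Market and
dense count matrices, two-column axon profiles, and model/report tables.

Trace text format: one ``#``-prefixed header line of key=value protocol
fields, one ``#``-prefixed JSON metadata line, then CSV columns
(time_ms, value). Count matrices are Matrix Market with sidecar
genes/cells name files, or dense tab-delimited text.
"""
from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

from .circuit import LayerTable
from .classifier import ClassifierModel
from .patchseq import CountMatrix
from .profiles import AxonProfile
from .traces import CurrentClampTrace, VoltageClampTrace

__all__ = [
    "write_trace", "read_trace",
    "write_trace_hdf5", "read_trace_hdf5",
    "write_count_matrix_mtx", "read_count_matrix_mtx",
    "write_count_matrix_tsv", "read_count_matrix_tsv",
    "write_profile", "read_profile",
    "write_classifier_model", "read_classifier_model",
]


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")


# ---------------------------------------------------------------------------
# Traces: delimited text
# ---------------------------------------------------------------------------

def write_trace(trace: VoltageClampTrace | CurrentClampTrace,
                path: str | Path) -> None:
    path = Path(path)
    if isinstance(trace, VoltageClampTrace):
        header = (f"# type=voltage_clamp sampling_rate_khz={trace.sampling_rate} "
                  f"units=pA step_onset_ms={trace.step_onset} "
                  f"step_delta_v_mv={trace.step_delta_v} "
                  f"step_duration_ms={trace.step_duration} "
                  f"holding_mv={trace.holding_potential}")
        cols = {"time_ms": trace.time, "current_pa": trace.current}
    else:
        header = (f"# type=current_clamp sampling_rate_khz={trace.sampling_rate} "
                  f"units=mV")
        cols = {"time_ms": trace.time, "voltage_mv": trace.voltage,
                "injected_pa": trace.injected_current}
    meta = "# metadata=" + json.dumps(trace.metadata, default=_json_default)
    body = pd.DataFrame(cols).to_csv(index=False)
    path.write_text(header + "\n" + meta + "\n" + body)


def _parse_header(line: str) -> dict[str, str]:
    fields = {}
    for tok in line.lstrip("# ").split():
        if "=" in tok:
            k, v = tok.split("=", 1)
            fields[k] = v
    return fields


def read_trace(path: str | Path) -> VoltageClampTrace | CurrentClampTrace:
    path = Path(path)
    with path.open() as fh:
        header = _parse_header(fh.readline())
        meta_line = fh.readline().strip()
        metadata = json.loads(meta_line.split("metadata=", 1)[1]) \
            if "metadata=" in meta_line else {}
        df = pd.read_csv(fh)
    rate = float(header["sampling_rate_khz"])
    if header.get("type") == "voltage_clamp":
        dur = header.get("step_duration_ms")
        return VoltageClampTrace(
            time=df["time_ms"].to_numpy(),
            current=df["current_pa"].to_numpy(),
            step_onset=float(header["step_onset_ms"]),
            step_delta_v=float(header["step_delta_v_mv"]),
            step_duration=None if dur in (None, "None") else float(dur),
            holding_potential=float(header.get("holding_mv", -70.0)),
            sampling_rate=rate,
            metadata=metadata,
        )
    return CurrentClampTrace(
        time=df["time_ms"].to_numpy(),
        voltage=df["voltage_mv"].to_numpy(),
        injected_current=df["injected_pa"].to_numpy(),
        sampling_rate=rate,
        metadata=metadata,
    )


# ---------------------------------------------------------------------------
# Traces: HDF5
# ---------------------------------------------------------------------------

def write_trace_hdf5(trace: VoltageClampTrace | CurrentClampTrace,
                     path: str | Path) -> None:
    import h5py

    with h5py.File(path, "w") as f:
        f.create_dataset("time_ms", data=trace.time)
        f.attrs["sampling_rate_khz"] = trace.sampling_rate
        f.attrs["metadata_json"] = json.dumps(trace.metadata,
                                              default=_json_default)
        if isinstance(trace, VoltageClampTrace):
            f.attrs["type"] = "voltage_clamp"
            f.create_dataset("current_pa", data=trace.current)
            f.attrs["step_onset_ms"] = trace.step_onset
            f.attrs["step_delta_v_mv"] = trace.step_delta_v
            f.attrs["holding_mv"] = trace.holding_potential
            if trace.step_duration is not None:
                f.attrs["step_duration_ms"] = trace.step_duration
        else:
            f.attrs["type"] = "current_clamp"
            f.create_dataset("voltage_mv", data=trace.voltage)
            f.create_dataset("injected_pa", data=trace.injected_current)


def read_trace_hdf5(path: str | Path):
    import h5py

    with h5py.File(path, "r") as f:
        metadata = json.loads(f.attrs.get("metadata_json", "{}"))
        time = f["time_ms"][:]
        rate = float(f.attrs["sampling_rate_khz"])
        if f.attrs["type"] == "voltage_clamp":
            return VoltageClampTrace(
                time=time, current=f["current_pa"][:],
                step_onset=float(f.attrs["step_onset_ms"]),
                step_delta_v=float(f.attrs["step_delta_v_mv"]),
                step_duration=float(f.attrs["step_duration_ms"])
                if "step_duration_ms" in f.attrs else None,
                holding_potential=float(f.attrs["holding_mv"]),
                sampling_rate=rate, metadata=metadata)
        return CurrentClampTrace(
            time=time, voltage=f["voltage_mv"][:],
            injected_current=f["injected_pa"][:],
            sampling_rate=rate, metadata=metadata)


# ---------------------------------------------------------------------------
# Count matrices
# ---------------------------------------------------------------------------

def write_count_matrix_mtx(matrix: CountMatrix, prefix: str | Path) -> None:
    """Write Matrix Market + sidecar genes/cells (and labels) files."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    scipy.io.mmwrite(str(prefix) + ".mtx",
                     scipy.sparse.csr_matrix(matrix.counts.to_numpy()))
    Path(str(prefix) + ".genes.txt").write_text(
        "\n".join(matrix.genes) + "\n")
    Path(str(prefix) + ".cells.txt").write_text(
        "\n".join(matrix.cells) + "\n")
    if matrix.labels is not None:
        matrix.labels.to_csv(str(prefix) + ".labels.tsv", sep="\t",
                             header=["cell_class"])


def read_count_matrix_mtx(prefix: str | Path) -> CountMatrix:
    prefix = str(prefix)
    mat = scipy.io.mmread(prefix + ".mtx").toarray().astype(np.int64)
    genes = Path(prefix + ".genes.txt").read_text().split()
    cells = Path(prefix + ".cells.txt").read_text().split()
    labels = None
    if Path(prefix + ".labels.tsv").exists():
        labels = pd.read_csv(prefix + ".labels.tsv", sep="\t",
                             index_col=0)["cell_class"]
    return CountMatrix(pd.DataFrame(mat, index=genes, columns=cells), labels)


def write_count_matrix_tsv(matrix: CountMatrix, path: str | Path) -> None:
    matrix.counts.to_csv(path, sep="\t")


def read_count_matrix_tsv(path: str | Path,
                          labels: pd.Series | None = None) -> CountMatrix:
    return CountMatrix(pd.read_csv(path, sep="\t", index_col=0), labels)


# ---------------------------------------------------------------------------
# Axon profiles
# ---------------------------------------------------------------------------

def write_profile(profile: AxonProfile, path: str | Path) -> None:
    pd.DataFrame({"depth_um": profile.depth,
                  "intensity_au": profile.intensity}).to_csv(
        path, sep="\t", index=False)


def read_profile(path: str | Path,
                 layer_table: LayerTable | None = None) -> AxonProfile:
    df = pd.read_csv(path, sep="\t")
    kwargs = {} if layer_table is None else {"layer_table": layer_table}
    return AxonProfile(depth=df["depth_um"].to_numpy(),
                       intensity=df["intensity_au"].to_numpy(), **kwargs)


# ---------------------------------------------------------------------------
# Classifier model
# ---------------------------------------------------------------------------

def write_classifier_model(model: ClassifierModel, path: str | Path) -> None:
    Path(path).write_text(json.dumps({
        "boundary": model.boundary,
        "class_above": model.class_above,
        "class_below": model.class_below,
        "margin": model.margin,
        "regularization_c": model.regularization_c,
        "training_counts": model.training_counts,
        "degenerate": model.degenerate,
    }, indent=2, default=_json_default) + "\n")


def read_classifier_model(path: str | Path) -> ClassifierModel:
    d = json.loads(Path(path).read_text())
    return ClassifierModel(**d)
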