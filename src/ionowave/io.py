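"""Trace and configuration I/O.

Traces travel as two-column delimited text (time_s, volts) with a header line
carrying the sampling rate and trigger index, or — for batches — as a portable
``.npz`` array container.  Scenario/chain presets live in hierarchical YAML
(see :func:`ionowave.scenarios.load_preset`); user configs in the same shape
can be loaded and dumped here.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml

from .errors import ConfigurationError
from .scenarios import AcquisitionChain, Scenario, SignalTrace
from .wtda import WaveletDecomposition

__all__ = [
    "save_trace_txt",
    "load_trace_txt",
    "save_traces_npz",
    "load_traces_npz",
    "save_config_yaml",
    "load_config_yaml",
    "decomposition_table_txt",
]

_HEADER = "# ionowave-trace sampling_rate_hz={fs!r} trigger_index={ti} units={units}"


def save_trace_txt(trace: SignalTrace, path: str | Path) -> None:
    """Write a trace as two-column text: time relative to trigger, volts."""
    path = Path(path)
    header = _HEADER.format(
        fs=trace.sampling_rate_hz, ti=trace.trigger_index, units=trace.units
    )
    data = np.column_stack([trace.times_s, trace.samples])
    with path.open("w") as fh:
        fh.write(header + "\n")
        np.savetxt(fh, data, fmt="%.17e", delimiter="\t")


def load_trace_txt(path: str | Path) -> SignalTrace:
    path = Path(path)
    with path.open() as fh:
        header = fh.readline().strip()
        if not header.startswith("# ionowave-trace"):
            raise ConfigurationError(f"{path} is not an ionowave trace file")
        fields = dict(item.split("=", 1) for item in header.split()[2:])
        data = np.loadtxt(fh, delimiter="\t")
    return SignalTrace(
        samples=data[:, 1],
        sampling_rate_hz=float(fields["sampling_rate_hz"]),
        trigger_index=int(fields["trigger_index"]),
        units=fields.get("units", "V"),
    )


def save_traces_npz(traces: Sequence[SignalTrace], path: str | Path) -> None:
    """Batch container: one stacked array plus shared geometry (binary, for
    scratch/interchange use)."""
    if len(traces) == 0:
        raise ConfigurationError("no traces to save")
    fs = traces[0].sampling_rate_hz
    ti = traces[0].trigger_index
    for t in traces[1:]:
        if t.sampling_rate_hz != fs or t.trigger_index != ti or len(t) != len(traces[0]):
            raise ConfigurationError("batch traces must share geometry")
    np.savez_compressed(
        Path(path),
        samples=np.vstack([t.samples for t in traces]),
        sampling_rate_hz=fs,
        trigger_index=ti,
    )


def load_traces_npz(path: str | Path) -> list[SignalTrace]:
    with np.load(Path(path)) as data:
        samples = data["samples"]
        fs = float(data["sampling_rate_hz"])
        ti = int(data["trigger_index"])
    return [SignalTrace(samples=row.copy(), sampling_rate_hz=fs, trigger_index=ti) for row in samples]


def save_config_yaml(
    scenario: Scenario, chain: AcquisitionChain, path: str | Path, acquisition: dict | None = None
) -> None:
    entry = {
        "scenario": dataclasses.asdict(scenario),
        "chain": dataclasses.asdict(chain),
    }
    if acquisition:
        entry["acquisition"] = dict(acquisition)
    Path(path).write_text(yaml.safe_dump({scenario.name: entry}, sort_keys=False))


def load_config_yaml(path: str | Path, name: str | None = None):
    """Load a (scenario, chain, acquisition) triple from a YAML config file."""
    doc = yaml.safe_load(Path(path).read_text())
    if name is None:
        if len(doc) != 1:
            raise ConfigurationError("config holds several presets; pass name=")
        name = next(iter(doc))
    entry = doc[name]
    scenario = Scenario(**entry["scenario"])
    chain = AcquisitionChain(**entry["chain"])
    return scenario, chain, dict(entry.get("acquisition", {}))


def decomposition_table_txt(dec: WaveletDecomposition, path: str | Path) -> None:
    """Per-level diagnostic table as tab-delimited text."""
    dec.to_table().to_csv(Path(path), sep="\t", index=False)
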