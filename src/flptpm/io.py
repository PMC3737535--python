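"""Trace file format: TSV body plus JSON metadata sidecar.

The body holds one row per frame with columns ``frame``, ``time_s``, ``x_nm``,
``y_nm``; coordinates are serialized with ``repr`` round-trip precision so
``read_trace(write_trace(t))`` reproduces ``t`` exactly.  Metadata (protocol,
substrate, molecule id, hidden ground truth) lives in ``<path>.meta.json``.
"""

from __future__ import annotations

import json
import os

import numpy as np

from .simulate import RawTrace, TRACE_FORMAT_VERSION

__all__ = ["write_trace", "read_trace", "write_cohort", "read_cohort"]

_COLUMNS = ("frame", "time_s", "x_nm", "y_nm")
_REQUIRED_META = ("format_version", "molecule_id", "protocol")


def _sidecar(path: str) -> str:
    return str(path) + ".meta.json"


def write_trace(trace: RawTrace, path: str) -> None:
    """Write one trace as TSV plus its JSON metadata sidecar."""
    meta = dict(trace.metadata)
    meta.setdefault("format_version", TRACE_FORMAT_VERSION)
    with open(path, "w") as fh:
        fh.write("\t".join(_COLUMNS) + "\n")
        for f, t, x, y in zip(trace.frames, trace.times, trace.x, trace.y):
            fh.write(f"{int(f)}\t{float(t)!r}\t{float(x)!r}\t{float(y)!r}\n")
    with open(_sidecar(path), "w") as fh:
        json.dump(meta, fh, indent=1)
        fh.write("\n")


def read_trace(path: str) -> RawTrace:
    """Read a trace written by :func:`write_trace`.

    Malformed rows and missing metadata keys raise ``ValueError`` with the
    offending row number / key name.
    """
    sidecar = _sidecar(path)
    if not os.path.exists(sidecar):
        raise ValueError(f"missing metadata sidecar {sidecar}")
    with open(sidecar) as fh:
        meta = json.load(fh)
    for key in _REQUIRED_META:
        if key not in meta:
            raise ValueError(f"metadata sidecar {sidecar} lacks required key {key!r}")

    frames, times, xs, ys = [], [], [], []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if tuple(header) != _COLUMNS:
            missing = set(_COLUMNS) - set(header)
            raise ValueError(
                f"{path}: header row 1 has columns {header}, missing {sorted(missing)}"
            )
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != len(_COLUMNS):
                raise ValueError(
                    f"{path}: row {lineno} has {len(parts)} fields, expected {len(_COLUMNS)}"
                )
            try:
                frames.append(int(parts[0]))
                times.append(float(parts[1]))
                xs.append(float(parts[2]))
                ys.append(float(parts[3]))
            except ValueError as exc:
                raise ValueError(f"{path}: row {lineno}: {exc}") from None
    return RawTrace(
        np.asarray(frames, dtype=int),
        np.asarray(times, dtype=float),
        np.asarray(xs, dtype=float),
        np.asarray(ys, dtype=float),
        meta,
    )


def write_cohort(traces, truth, outdir: str, prefix: str = "trace") -> str:
    """Write a cohort of traces plus a manifest TSV with the truth table.

    Returns the manifest path.  The manifest lists one row per molecule:
    trace file, molecule id, true class, post-SDS state, artifact count.
    """
    os.makedirs(outdir, exist_ok=True)
    manifest = os.path.join(outdir, "manifest.tsv")
    with open(manifest, "w") as fh:
        fh.write("file\tmolecule_id\ttrue_class\tpost_sds_state\tn_artifacts\n")
        for i, (trace, rec) in enumerate(zip(traces, truth)):
            fname = f"{prefix}{i:04d}.tsv"
            write_trace(trace, os.path.join(outdir, fname))
            fh.write(
                f"{fname}\t{rec['molecule_id']}\t{rec['class']}\t"
                f"{rec['post_sds_state']}\t{len(rec['artifacts'])}\n"
            )
    return manifest


def read_cohort(manifest: str):
    """Read back a cohort manifest; returns (traces, truth_records)."""
    outdir = os.path.dirname(os.path.abspath(manifest))
    traces, truth = [], []
    with open(manifest) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        for line in fh:
            rec = dict(zip(header, line.rstrip("\n").split("\t")))
            traces.append(read_trace(os.path.join(outdir, rec["file"])))
            truth.append(rec)
    return traces, truth
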