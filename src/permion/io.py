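"""File formats: XVG-like numeric traces, multi-model PDB rings, JSON results.

The trace dialect is the whitespace-separated numeric text emitted by
common MD analysis tools: '#' lines are free comments, '@' lines carry
plot/units metadata, everything else is a fixed-width numeric table.
Hexamer trajectories travel as multi-model PDB (MODEL/ENDMDL, six chains,
one CA per residue per protomer); coordinates are Angstrom on disk and nm
in memory, converted only at this boundary.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import biotite.structure as struc
from biotite.structure.io.pdb import PDBFile

from .constants import ANG_TO_NM, NM_TO_ANG
from .hexgeometry import HexFrameSeries
from .pmf import PMFProfile, SMDLog
from .pull import PullTraceSet


class TraceParseError(ValueError):
    """Raised on malformed trace files; message names file and line."""


# ---------------------------------------------------------------------------
# XVG-like numeric traces
# ---------------------------------------------------------------------------

def read_trace_table(path) -> tuple[np.ndarray, list[str]]:
    """Read a whitespace-separated numeric table, returning (data, header).

    '#' and '@' lines are collected as header metadata.  Ragged rows,
    non-numeric fields and an empty data section raise
    :class:`TraceParseError` naming the offending line.
    """
    path = Path(path)
    header: list[str] = []
    rows: list[list[float]] = []
    ncols = None
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            s = line.strip()
            if not s:
                continue
            if s.startswith("#") or s.startswith("@"):
                header.append(s)
                continue
            fields = s.split()
            if ncols is None:
                ncols = len(fields)
            elif len(fields) != ncols:
                raise TraceParseError(
                    f"{path}:{lineno}: expected {ncols} columns, got {len(fields)}"
                )
            try:
                rows.append([float(x) for x in fields])
            except ValueError as exc:
                raise TraceParseError(f"{path}:{lineno}: non-numeric field ({exc})") from None
    if not rows:
        raise TraceParseError(f"{path}: no data rows")
    return np.asarray(rows, dtype=float), header


def _parse_meta(header: list[str]) -> dict:
    meta = {}
    for line in header:
        if line.startswith("@") and "=" in line:
            key, _, val = line.lstrip("@ ").partition("=")
            meta[key.strip()] = val.strip()
    return meta


def _write_table(path, columns: list[np.ndarray], header: list[str]) -> None:
    path = Path(path)
    data = np.column_stack(columns)
    with open(path, "w") as fh:
        for line in header:
            fh.write(line.rstrip("\n") + "\n")
        for row in data:
            fh.write(" ".join(f"{x:.10g}" for x in row) + "\n")


def write_smd_log(path, log: SMDLog) -> None:
    header = [
        "# steered-pulling force log",
        "@ columns = t z_trap z_ion f_spring",
        "@ units = ns nm nm kJ/mol/nm",
        f"@ k = {log.k:.10g}",
        f"@ v = {log.v:.10g}",
    ]
    _write_table(path, [log.t, log.z_trap, log.z_ion, log.f_spring], header)


def read_smd_log(path, k: float | None = None, v: float | None = None) -> SMDLog:
    """Read a 4-column (t, z_trap, z_ion, f_spring) steered-pulling log.

    Spring constant and velocity are taken from '@' metadata unless given
    explicitly.
    """
    data, header = read_trace_table(path)
    if data.shape[1] < 4:
        raise TraceParseError(f"{path}: SMD log needs 4 columns (t z_trap z_ion f)")
    meta = _parse_meta(header)
    if k is None:
        k = float(meta.get("k", "nan"))
    if v is None:
        v = float(meta.get("v", "nan"))
    if not np.isfinite(k) or not np.isfinite(v):
        raise TraceParseError(f"{path}: spring constant/velocity missing (pass k=, v=)")
    return SMDLog(
        t=data[:, 0], z_trap=data[:, 1], z_ion=data[:, 2], f_spring=data[:, 3],
        k=k, v=v, meta={"header": header},
    )


def write_pmf(path, profile: PMFProfile) -> None:
    header = [
        "# potential of mean force",
        "@ columns = z W",
        "@ units = nm kJ/mol",
        f"@ tag = {profile.tag}",
    ]
    _write_table(path, [profile.z, profile.w], header)


def read_pmf(path, tag: str | None = None) -> PMFProfile:
    """Read a two-column (z, W) profile; tag from '@' metadata by default."""
    data, header = read_trace_table(path)
    if data.shape[1] < 2:
        raise TraceParseError(f"{path}: PMF needs 2 columns (z W)")
    meta = _parse_meta(header)
    resolved = tag or meta.get("tag", "hemichannel")
    return PMFProfile(z=data[:, 0], w=data[:, 1], tag=resolved, meta={"header": header})


def write_pull_traces(path, trace_set: PullTraceSet) -> None:
    """Write traces as one multi-column file: t, F_1 ... F_n (common grid
    required; traces are interpolated to the first trace's grid)."""
    t0 = trace_set.traces[0][0]
    cols = [t0] + [np.interp(t0, t, f) for t, f in trace_set.traces]
    header = [
        "# pull-force traces, one column per helix",
        "@ columns = t " + " ".join(f"F_{i+1}" for i in range(len(trace_set.traces))),
        "@ units = ns " + " ".join(["kJ/mol/nm"] * len(trace_set.traces)),
        f"@ k = {trace_set.k:.10g}",
        f"@ v = {trace_set.v:.10g}",
        f"@ condition = {trace_set.condition}",
    ]
    _write_table(path, cols, header)


def read_pull_traces(path, k: float | None = None, v: float | None = None) -> PullTraceSet:
    data, header = read_trace_table(path)
    if data.shape[1] < 2:
        raise TraceParseError(f"{path}: pull trace file needs >= 2 columns")
    meta = _parse_meta(header)
    if k is None:
        k = float(meta.get("k", "nan"))
    if v is None:
        v = float(meta.get("v", "nan"))
    t = data[:, 0]
    traces = [(t.copy(), data[:, i]) for i in range(1, data.shape[1])]
    return PullTraceSet(
        traces=traces, k=k, v=v,
        condition=meta.get("condition", ""), meta={"header": header},
    )


# ---------------------------------------------------------------------------
# Multi-model PDB hexamer trajectories
# ---------------------------------------------------------------------------

def write_hex_pdb(path, traj: HexFrameSeries) -> None:
    """Write a ring trajectory as multi-model PDB, six chains, CA atoms."""
    n_frames, _, n_res, _ = traj.coords.shape
    n_atoms = 6 * n_res
    template = struc.AtomArray(n_atoms)
    chain_ids, res_ids = [], []
    for p in range(6):
        for r in traj.residue_ids:
            chain_ids.append(traj.protomer_labels[p])
            res_ids.append(r)
    template.chain_id = np.array(chain_ids)
    template.res_id = np.array(res_ids)
    template.res_name = np.array(["GLY"] * n_atoms)
    template.atom_name = np.array(["CA"] * n_atoms)
    template.element = np.array(["C"] * n_atoms)
    template.hetero = np.zeros(n_atoms, dtype=bool)
    stack = struc.AtomArrayStack(n_frames, n_atoms)
    for cat in template.get_annotation_categories():
        stack.set_annotation(cat, template.get_annotation(cat))
    stack.coord = traj.coords.reshape(n_frames, n_atoms, 3) * NM_TO_ANG
    pdb = PDBFile()
    pdb.set_structure(stack)
    pdb.write(str(path))


def read_hex_pdb(path, residue_ids=None, chain_order: list[str] | None = None) -> HexFrameSeries:
    """Read a multi-model PDB into a ring trajectory.

    Exactly six chains are required; frames follow MODEL order and the
    cyclic protomer order follows sorted chain IDs unless ``chain_order``
    overrides it.  A missing CA raises an error naming model, chain and
    residue.
    """
    pdb = PDBFile.read(str(path))
    n_frames = pdb.get_model_count()
    models = [pdb.get_structure(model=m + 1) for m in range(n_frames)]
    cas = [m[m.atom_name == "CA"] for m in models]
    found_chains = sorted({c for ca in cas for c in set(ca.chain_id)})
    if len(found_chains) != 6:
        raise ValueError(
            f"{path}: expected 6 chains, found {len(found_chains)} ({found_chains})"
        )
    chains = found_chains if chain_order is None else list(chain_order)
    if residue_ids is None:
        residue_ids = sorted({int(r) for ca in cas for r in ca.res_id})
    residue_ids = list(residue_ids)
    coords = np.empty((n_frames, 6, len(residue_ids), 3))
    for m, ca in enumerate(cas):
        for ci, chain in enumerate(chains):
            for ri, rid in enumerate(residue_ids):
                sel = (ca.chain_id == chain) & (ca.res_id == rid)
                n_hit = int(sel.sum())
                if n_hit != 1:
                    raise ValueError(
                        f"{path}: model {m + 1}: chain {chain} residue {rid}: "
                        f"expected 1 CA, found {n_hit}"
                    )
                coords[m, ci, ri, :] = ca.coord[sel][0]
    return HexFrameSeries(
        coords=coords * ANG_TO_NM,
        residue_ids=residue_ids,
        protomer_labels=list(chains),
        meta={"path": str(path)},
    )


# ---------------------------------------------------------------------------
# JSON results / ground-truth sidecars
# ---------------------------------------------------------------------------

def write_json(path, obj) -> None:
    def _default(o):
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.floating, np.integer)):
            return o.item()
        if hasattr(o, "as_dict"):
            return o.as_dict()
        raise TypeError(f"not JSON-serializable: {type(o)}")

    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, default=_default)
        fh.write("\n")


def read_json(path):
    with open(path) as fh:
        return json.load(fh)
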