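"""Readers and writers for the on-disk formats the pipeline touches.

Spectral surfaces are plain CSV matrices (first row the wavelength axis,
first column the delay axis) with '#'-prefixed ``key=value`` header comments
carrying units and metadata.  Decays, chromatograms and titrations are
two-column CSV with the same comment convention.  Trajectories are
multi-MODEL PDB files (read and written through biotite).  Readers reject
malformed input rather than silently coercing it.
"""

from __future__ import annotations

import warnings

import numpy as np

from .global_kinetics import TimeResolvedSpectra
from .lifetime import DecayTrace, InstrumentResponse
from .structure import Trajectory

__all__ = [
    "read_metadata",
    "write_matrix_csv",
    "read_matrix_csv",
    "write_xy_csv",
    "read_xy_csv",
    "write_pdb_trajectory",
    "read_pdb_trajectory",
]

TIME_UNIT_TO_PS = {"fs": 1e-3, "ps": 1.0, "ns": 1e3, "us": 1e6}


def read_metadata(path) -> dict:
    """Parse '#'-prefixed key=value comment lines from a CSV file."""
    meta = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            body = line[1:].strip()
            if "=" in body:
                key, _, value = body.partition("=")
                meta[key.strip()] = value.strip()
    return meta


def _write_meta(fh, meta):
    for key, value in meta.items():
        fh.write(f"# {key}={value}\n")


# ---------------------------------------------------------------------------
# matrix CSV (time-resolved spectra)
# ---------------------------------------------------------------------------

def write_matrix_csv(path, data: TimeResolvedSpectra, extra_meta=None) -> None:
    with open(path, "w") as fh:
        meta = {"time_unit": data.time_unit}
        meta.update(extra_meta or {})
        _write_meta(fh, meta)
        fh.write("," + ",".join(f"{w:.12g}" for w in data.wavelengths) + "\n")
        for t, row in zip(data.delays, data.delta_a):
            fh.write(f"{t:.12g}," + ",".join(f"{v:.12g}" for v in row) + "\n")


def read_matrix_csv(path) -> TimeResolvedSpectra:
    """Read a wavelength x delay matrix; delays are normalised to ps.

    Round-trips through :func:`write_matrix_csv` losslessly to 1e-12.
    A missing ``time_unit`` comment defaults to ps with a warning; ragged
    rows raise with the offending line number.
    """
    meta = read_metadata(path)
    unit = meta.get("time_unit")
    if unit is None:
        warnings.warn(f"{path}: no time_unit declared; assuming ps",
                      RuntimeWarning)
        unit = "ps"
    if unit not in TIME_UNIT_TO_PS:
        raise ValueError(f"{path}: unknown time unit {unit!r}")

    rows = []
    header = None
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            cells = line.split(",")
            if header is None:
                if cells[0] != "":
                    raise ValueError(
                        f"{path}:{lineno}: header row must start with an "
                        "empty cell before the wavelength axis"
                    )
                header = np.array([float(c) for c in cells[1:]])
                continue
            if len(cells) != header.size + 1:
                raise ValueError(
                    f"{path}:{lineno}: ragged row ({len(cells)} cells, "
                    f"expected {header.size + 1})"
                )
            rows.append([float(c) for c in cells])
    if header is None or not rows:
        raise ValueError(f"{path}: no data rows")
    body = np.asarray(rows)
    scale = TIME_UNIT_TO_PS[unit]
    return TimeResolvedSpectra(
        wavelengths=header,
        delays=body[:, 0] * scale,
        delta_a=body[:, 1:],
        time_unit="ps",
        meta=meta,
    )


# ---------------------------------------------------------------------------
# two-column CSV (decays, chromatograms, titrations, traces)
# ---------------------------------------------------------------------------

def write_xy_csv(path, x, y, meta=None, columns=("x", "y")) -> None:
    with open(path, "w") as fh:
        _write_meta(fh, meta or {})
        fh.write(",".join(columns) + "\n")
        for xi, yi in zip(np.asarray(x), np.asarray(y)):
            fh.write(f"{xi:.12g},{yi:.12g}\n")


def read_xy_csv(path):
    """Read a two-column CSV; returns (x, y, meta)."""
    meta = read_metadata(path)
    x, y = [], []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            cells = line.split(",")
            if len(cells) != 2:
                raise ValueError(f"{path}:{lineno}: expected two columns")
            try:
                x.append(float(cells[0]))
                y.append(float(cells[1]))
            except ValueError:
                if lineno <= 2 and not x:   # header row
                    continue
                raise ValueError(f"{path}:{lineno}: non-numeric cell")
    return np.asarray(x), np.asarray(y), meta


def read_decay_csv(path) -> DecayTrace:
    t, c, meta = read_xy_csv(path)
    return DecayTrace(channel_times=t, counts=c, meta=meta)


def read_irf_csv(path) -> InstrumentResponse:
    t, c, meta = read_xy_csv(path)
    return InstrumentResponse(channel_times=t, counts=c, meta=meta)


# ---------------------------------------------------------------------------
# multi-MODEL PDB trajectories
# ---------------------------------------------------------------------------

def write_pdb_trajectory(path, traj: Trajectory) -> None:
    """Write a Trajectory as a multi-MODEL PDB file.

    The frame spacing is preserved in a ``REMARK 250 FRAME_DT_NS`` record
    (PDB has no native time axis).
    """
    import biotite.structure as struc
    from biotite.structure.io.pdb import PDBFile

    n_frames, n_atoms = traj.coords.shape[:2]
    stack = struc.AtomArrayStack(n_frames, n_atoms)
    stack.coord = traj.coords
    stack.set_annotation("atom_name", traj.name.astype("U6"))
    stack.set_annotation("res_name", traj.resname.astype("U5"))
    stack.set_annotation("res_id", traj.resid.astype(int))
    stack.set_annotation("chain_id", traj.chain.astype("U4"))
    stack.set_annotation(
        "hetero", np.isin(traj.resname, ["HOH", "WAT", "SOL"])
    )
    stack.set_annotation("element", np.array([n[0] for n in traj.name], dtype="U2"))
    pdb = PDBFile()
    pdb.set_structure(stack)
    dt = traj.times[1] - traj.times[0] if traj.times.size > 1 else 1.0
    with open(path, "w") as fh:
        fh.write(f"REMARK 250 FRAME_DT_NS {dt:.9g}\n")
        fh.write(f"REMARK 250 T0_NS {traj.times[0]:.9g}\n")
        pdb.write(fh)


def _diagnose_roster_mismatch(path):
    """Per-MODEL roster scan used to name the first differing atom."""
    rosters = []
    current = None
    with open(path) as fh:
        for line in fh:
            if line.startswith("MODEL"):
                current = []
            elif line.startswith("ENDMDL"):
                rosters.append(current)
                current = None
            elif line.startswith(("ATOM", "HETATM")) and current is not None:
                current.append(
                    (line[12:16].strip(), line[17:20].strip(),
                     line[21].strip(), line[22:26].strip())
                )
    ref = rosters[0]
    for m, roster in enumerate(rosters[1:], start=2):
        if roster != ref:
            missing = [a for a in ref if a not in roster]
            extra = [a for a in roster if a not in ref]
            detail = missing[0] if missing else extra[0]
            name, resname, chain, resid = detail
            return (f"MODEL {m} atom roster differs from MODEL 1 near "
                    f"{chain}:{resid}:{name} ({resname})")
    return "atom roster differs between models"


def read_pdb_trajectory(path) -> Trajectory:
    """Read a multi-MODEL PDB file into a Trajectory (frames in MODEL order)."""
    from biotite.structure.io.pdb import PDBFile

    pdb = PDBFile.read(path)
    try:
        stack = pdb.get_structure(model=None)
    except Exception as err:
        raise ValueError(
            f"{path}: {_diagnose_roster_mismatch(path)}"
        ) from err
    coords = stack.coord
    if coords.ndim == 2:    # single model
        coords = coords[None]
    dt, t0 = 1.0, 0.0
    with open(path) as fh:
        for line in fh:
            if line.startswith("REMARK 250 FRAME_DT_NS"):
                dt = float(line.split()[-1])
            elif line.startswith("REMARK 250 T0_NS"):
                t0 = float(line.split()[-1])
            elif line.startswith(("ATOM", "MODEL")):
                break
    n_frames = coords.shape[0]
    return Trajectory(
        serial=np.arange(1, stack.array_length() + 1),
        name=np.asarray(stack.atom_name),
        resname=np.asarray(stack.res_name),
        resid=np.asarray(stack.res_id),
        chain=np.asarray(stack.chain_id),
        coords=coords,
        times=t0 + np.arange(n_frames) * dt,
        meta={"source": str(path)},
    )
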