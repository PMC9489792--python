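"""Geometric post-processing of MD coordinate trajectories.

Implements the analysis criteria used for voltage-clamped rhodopsin
simulations: hydrogen-bond detection (donor-acceptor distance <= 3 A and
donor-hydrogen-acceptor angle >= 150 deg, with redundant bonds to the two
carboxyl oxygens of one Asp/Glu counted once), inward/outward side-chain
classification by minimal distances to reference atom sets, distance-angle
distributions of the Schiff-base/counterion geometry, pocket water counting,
and selection of the equilibrated trajectory tail.

Coordinates are in Angstrom, frame times in ns, frames 0-indexed.  Hydrogens
must be explicit; no periodic-boundary minimum-image handling is applied, so
real MD output must be pre-wrapped with the molecule whole.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Trajectory",
    "HBondCriteria",
    "HBondStats",
    "OrientationSeries",
    "atom_spec",
    "detect_hbonds_frame",
    "hbond_probability",
    "classify_side_chain_orientation",
    "distance_angle_distribution",
    "count_pocket_waters",
    "trajectory_tail",
]

CARBOXYL_OXYGENS = {
    ("ASP", "OD1"), ("ASP", "OD2"),
    ("GLU", "OE1"), ("GLU", "OE2"),
}


@dataclass
class Trajectory:
    """Multi-frame coordinate set with a fixed atom roster.

    ``coords`` has shape (n_frames, n_atoms, 3) in Angstrom; the annotation
    arrays have length n_atoms and are identical across frames.
    """

    serial: np.ndarray
    name: np.ndarray
    resname: np.ndarray
    resid: np.ndarray
    chain: np.ndarray
    coords: np.ndarray
    times: np.ndarray      # ns, one per frame
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise ValueError("coords must have shape (n_frames, n_atoms, 3)")
        if self.coords.shape[0] != self.times.size:
            raise ValueError("one frame time per frame required")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("coordinates must be finite")
        if self.times.size > 1 and np.any(np.diff(self.times) <= 0):
            raise ValueError("frame times must be strictly increasing")
        n_atoms = self.coords.shape[1]
        for arr in (self.serial, self.name, self.resname, self.resid, self.chain):
            if len(arr) != n_atoms:
                raise ValueError("annotation length does not match atom count")

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[1]

    def index_of(self, spec: str) -> int:
        """Resolve a 'chain:resid:atomname' spec to an atom index."""
        chain, resid, name = atom_spec(spec)
        mask = (
            (self.chain == chain)
            & (self.resid == int(resid))
            & (self.name == name)
        )
        idx = np.flatnonzero(mask)
        if idx.size == 0:
            raise KeyError(f"no atom matching {spec!r}")
        if idx.size > 1:
            raise KeyError(f"ambiguous atom spec {spec!r}")
        return int(idx[0])


def atom_spec(spec: str) -> tuple:
    parts = spec.split(":")
    if len(parts) != 3:
        raise ValueError(f"atom spec must be 'chain:resid:atomname', got {spec!r}")
    return parts[0], int(parts[1]), parts[2]


@dataclass
class HBondCriteria:
    """Geometric hydrogen-bond criteria (defaults per the analysis protocol)."""

    max_donor_acceptor_distance: float = 3.0   # A
    min_dha_angle: float = 150.0               # deg, 180 = linear
    carboxylate_dedup: bool = True

    def __post_init__(self):
        if self.max_donor_acceptor_distance < 0:
            raise ValueError("distance cutoff must be non-negative")
        if not 0.0 < self.min_dha_angle <= 180.0:
            raise ValueError("angle cutoff must lie in (0, 180]")


@dataclass
class HBondStats:
    pair: tuple
    series: np.ndarray       # bool per frame
    n_frames: int

    @property
    def probability(self) -> float:
        return float(np.mean(self.series))


@dataclass
class OrientationSeries:
    probe: str
    classes: np.ndarray      # 'inward' / 'outward' per frame

    @property
    def fractions(self) -> dict:
        n = self.classes.size
        inward = float(np.sum(self.classes == "inward")) / n
        return {"inward": inward, "outward": 1.0 - inward}


# ---------------------------------------------------------------------------
# geometry primitives
# ---------------------------------------------------------------------------

def _dha_angle(donor, hydrogen, acceptor):
    """Donor-hydrogen-acceptor interior angle in degrees (180 = linear)."""
    v1 = donor - hydrogen
    v2 = acceptor - hydrogen
    n1 = np.linalg.norm(v1, axis=-1)
    n2 = np.linalg.norm(v2, axis=-1)
    cosang = np.sum(v1 * v2, axis=-1) / (n1 * n2)
    return np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))


def _is_bonded(frame, donor_idx, hydrogen_idx, acceptor_idx, criteria):
    d = np.linalg.norm(frame[donor_idx] - frame[acceptor_idx])
    if d > criteria.max_donor_acceptor_distance:
        return False, d
    ang = _dha_angle(frame[donor_idx], frame[hydrogen_idx], frame[acceptor_idx])
    return bool(ang >= criteria.min_dha_angle), d


def detect_hbonds_frame(
    traj: Trajectory,
    frame_index: int,
    donors: list,
    acceptors: list,
    criteria: HBondCriteria | None = None,
) -> list:
    """Hydrogen bonds in one frame.

    ``donors`` is a list of (donor_index, hydrogen_index) pairs, ``acceptors``
    a list of acceptor atom indices.  A pair is reported iff the
    donor-acceptor distance is within the cutoff (inclusive) and the D-H-A
    angle is at or above the angle cutoff.  With ``carboxylate_dedup`` on,
    bonds from one donor to both carboxyl oxygens of the same Asp/Glu count
    once (the closer oxygen is reported).
    """
    criteria = criteria or HBondCriteria()
    frame = traj.coords[frame_index]
    hits = []  # (donor_idx, acceptor_idx, distance)
    for d_idx, h_idx in donors:
        if traj.name[h_idx][0] not in ("H", "1", "2", "3"):
            raise ValueError(
                f"atom {traj.name[h_idx]!r} does not look like a hydrogen"
            )
        for a_idx in acceptors:
            bonded, dist = _is_bonded(frame, d_idx, h_idx, a_idx, criteria)
            if bonded:
                hits.append((d_idx, a_idx, dist))
    if not criteria.carboxylate_dedup:
        return [(d, a) for d, a, _ in hits]

    best: dict = {}
    order = []
    for d_idx, a_idx, dist in hits:
        key_res = (traj.chain[a_idx], traj.resid[a_idx])
        if (traj.resname[a_idx], traj.name[a_idx]) in CARBOXYL_OXYGENS:
            key = (d_idx, "carboxylate", key_res)
        else:
            key = (d_idx, "atom", a_idx)
        if key not in best:
            best[key] = (a_idx, dist)
            order.append(key)
        elif dist < best[key][1]:
            best[key] = (a_idx, dist)
    return [(key[0], best[key][0]) for key in order]


def hbond_probability(
    traj: Trajectory,
    donor: str,
    hydrogen: str,
    acceptors: list,
    criteria: HBondCriteria | None = None,
) -> HBondStats:
    """Per-frame hydrogen-bond occupancy of one donor/acceptor-group pair.

    ``acceptors`` is a list of atom specs (both carboxyl oxygens may be given;
    the dedup rule makes the pair count once per frame).  The probability is
    the bonded-frame count over all frames of ``traj``.
    """
    if traj.n_frames == 0:
        raise ValueError("empty frame selection")
    criteria = criteria or HBondCriteria()
    d_idx = traj.index_of(donor)
    h_idx = traj.index_of(hydrogen)
    a_idx = [traj.index_of(a) for a in acceptors]
    series = np.zeros(traj.n_frames, dtype=bool)
    for f in range(traj.n_frames):
        bonds = detect_hbonds_frame(traj, f, [(d_idx, h_idx)], a_idx, criteria)
        series[f] = len(bonds) > 0
    return HBondStats(pair=(donor, tuple(acceptors)), series=series,
                      n_frames=traj.n_frames)


def classify_side_chain_orientation(
    traj: Trajectory,
    probe: str,
    inward_refs: list,
    outward_refs: list,
) -> OrientationSeries:
    """Inward/outward classification of a probe atom per frame.

    A frame is 'inward' iff the minimal probe distance to the inward reference
    set is strictly smaller than to the outward set; ties are 'outward'
    (deterministic, documented convention).
    """
    if not inward_refs or not outward_refs:
        raise ValueError("reference sets must be non-empty")
    p = traj.index_of(probe)
    i_idx = [traj.index_of(a) for a in inward_refs]
    o_idx = [traj.index_of(a) for a in outward_refs]
    d_in = np.min(
        np.linalg.norm(traj.coords[:, i_idx] - traj.coords[:, [p]], axis=-1), axis=1
    )
    d_out = np.min(
        np.linalg.norm(traj.coords[:, o_idx] - traj.coords[:, [p]], axis=-1), axis=1
    )
    classes = np.where(d_in < d_out, "inward", "outward")
    return OrientationSeries(probe=probe, classes=classes)


def distance_angle_distribution(
    traj: Trajectory,
    donor: str,
    hydrogen: str,
    acceptor: str,
    distance_bins=20,
    angle_bins=18,
    distance_range=None,
    angle_range=(0.0, 180.0),
):
    """2-D histogram of (donor-acceptor distance, D-H-A angle) over frames.

    Returns (hist, distance_edges, angle_edges); the histogram sums to the
    frame count.
    """
    d_idx = traj.index_of(donor)
    h_idx = traj.index_of(hydrogen)
    a_idx = traj.index_of(acceptor)
    dist = np.linalg.norm(traj.coords[:, d_idx] - traj.coords[:, a_idx], axis=-1)
    ang = _dha_angle(
        traj.coords[:, d_idx], traj.coords[:, h_idx], traj.coords[:, a_idx]
    )
    if np.isscalar(distance_bins) and distance_bins <= 0:
        raise ValueError("need at least one distance bin")
    if np.isscalar(angle_bins) and angle_bins <= 0:
        raise ValueError("need at least one angle bin")
    if distance_range is None:
        lo, hi = dist.min(), dist.max()
        pad = max(1e-6, 0.05 * (hi - lo))
        distance_range = (lo - pad, hi + pad)
    hist, d_edges, a_edges = np.histogram2d(
        dist, ang, bins=[distance_bins, angle_bins],
        range=[distance_range, angle_range],
    )
    if np.any(np.diff(d_edges) <= 0) or np.any(np.diff(a_edges) <= 0):
        raise ValueError("zero-width histogram bins")
    return hist, d_edges, a_edges


def count_pocket_waters(
    traj: Trajectory,
    center,
    radius: float,
    water_resnames=("HOH", "SOL", "WAT"),
    water_atom="O",
) -> np.ndarray:
    """Number of water oxygens within ``radius`` of a pocket centre, per frame.

    ``center`` is either a fixed (x, y, z) point or a list of atom specs whose
    per-frame midpoint defines the centre.  Counts are inclusive of the
    boundary; radius 0 therefore only counts exact coincidences.
    """
    if radius < 0:
        raise ValueError("radius must be non-negative")
    wmask = np.isin(traj.resname, water_resnames) & (traj.name == water_atom)
    if not np.any(wmask):
        warnings.warn("no water records found; returning zeros", RuntimeWarning)
        return np.zeros(traj.n_frames, dtype=int)
    waters = traj.coords[:, wmask]          # (F, W, 3)
    if isinstance(center, (list, tuple)) and center and isinstance(center[0], str):
        c_idx = [traj.index_of(a) for a in center]
        ctr = traj.coords[:, c_idx].mean(axis=1)   # per-frame midpoint
    else:
        ctr = np.broadcast_to(np.asarray(center, dtype=float), (traj.n_frames, 3))
    d = np.linalg.norm(waters - ctr[:, None, :], axis=-1)
    return np.sum(d <= radius, axis=1).astype(int)


def trajectory_tail(traj: Trajectory, window: float) -> Trajectory:
    """Frames with t >= t_end - window (closed interval), order preserved."""
    duration = traj.times[-1] - traj.times[0]
    if window > duration:
        raise ValueError(
            f"window {window} ns exceeds trajectory duration {duration} ns"
        )
    keep = traj.times >= traj.times[-1] - window
    return Trajectory(
        serial=traj.serial,
        name=traj.name,
        resname=traj.resname,
        resid=traj.resid,
        chain=traj.chain,
        coords=traj.coords[keep],
        times=traj.times[keep],
        meta=dict(traj.meta),
    )
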