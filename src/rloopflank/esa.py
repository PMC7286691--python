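"""Envelope surface area (ESA): a base-stacking metric for trajectory frames.

At an interhelical junction, the terminal base of the RNA strand and the DNA
base stacked upon it jointly occupy a volume whose solvent-exposed surface
area is small when the two bases are stacked (their faces are buried against
each other) and large when they unstack.  Tracking this *envelope surface
area* over molecular-dynamics frames therefore reports on coaxial-stacking
dynamics without choosing a stacking geometry a priori.

The surface is the solvent-accessible surface of the union of probe-inflated
atomic spheres, evaluated by deterministic equal-area point sampling
(a Fibonacci lattice on every sphere; a point counts as exposed when it lies
outside all other inflated spheres).  Sphere points are generated in a
canonical molecular frame — the principal axes of the selected atoms with a
deterministic sign convention — so the result is exactly invariant under
rigid-body motion of the selection (for degenerate, highly symmetric
configurations the lab frame is used and invariance is only statistical).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.sparse.csgraph import connected_components

from .reactivity import ValidationError

#: Element-based radii (Å), conventional van der Waals values.
DEFAULT_RADII: Mapping[str, float] = {
    "C": 1.70,
    "N": 1.55,
    "O": 1.52,
    "P": 1.80,
    "H": 1.10,
    "S": 1.80,
}

DEFAULT_PROBE_RADIUS = 1.4  # Å, water
DEFAULT_SPHERE_POINTS = 960

#: Backbone atom names excluded by the default nucleobase selection: sugar
#: atoms carry a prime in their name; the rest is the phosphate group.
_BACKBONE_NAMES = frozenset(
    {"P", "OP1", "OP2", "OP3", "O1P", "O2P", "O3P", "HP", "H5T", "H3T"}
)


@dataclass(frozen=True)
class AtomRecord:
    """One atom of a frame selection."""

    name: str
    residue: tuple[str, int]  # (chain/segment id, residue number)
    element: str
    coords: tuple[float, float, float]
    radius: float

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ValidationError(f"atom {self.name}: radius must be > 0")
        if not all(math.isfinite(c) for c in self.coords):
            raise ValidationError(f"atom {self.name}: non-finite coordinate")


@dataclass(frozen=True)
class BasePairSelection:
    """The two nucleobases whose joint envelope is measured.

    ``residues`` identifies the RNA-terminal base and the DNA base stacked on
    it from the displaced strand, as ``(chain_id, residue_number)`` pairs.
    By default all base atoms (ring plus exocyclic substituents, hydrogens
    included) are kept and sugar/phosphate atoms are dropped; explicit
    per-residue atom-name lists override this.
    """

    residues: tuple[tuple[str, int], tuple[str, int]]
    atom_names: Mapping[tuple[str, int], frozenset[str]] | None = None
    include_hydrogens: bool = True

    def wants(self, residue: tuple[str, int], name: str, element: str) -> bool:
        if residue not in self.residues:
            return False
        if not self.include_hydrogens and element == "H":
            return False
        if self.atom_names is not None:
            allowed = self.atom_names.get(residue)
            return allowed is not None and name in allowed
        return is_base_atom(name)


@dataclass(frozen=True)
class ESASeries:
    """Per-frame ESA trace with its sliding-window smoothed companion."""

    times_ps: tuple[float, ...]
    esa: tuple[float, ...]
    smoothed: tuple[float, ...] | None = None
    window_ps: float | None = None

    def __post_init__(self) -> None:
        if any(e < 0 for e in self.esa):
            raise ValidationError("ESA values must be >= 0")
        if self.smoothed is not None and len(self.smoothed) != len(self.esa):
            raise ValidationError("smoothed series must match raw length")


def is_base_atom(name: str) -> bool:
    """True for nucleobase atoms: no sugar prime, not phosphate backbone."""
    return "'" not in name and "*" not in name and name.upper() not in _BACKBONE_NAMES


def guess_element(name: str) -> str:
    """Element from a PDB-style atom name (leading letter, H variants)."""
    stripped = name.strip().lstrip("0123456789")
    if not stripped:
        raise ValidationError(f"cannot infer element from atom name {name!r}")
    if stripped[0] in "Hh":
        return "H"
    return stripped[0].upper()


def radius_for(element: str, radii: Mapping[str, float] | None = None) -> float:
    table = DEFAULT_RADII if radii is None else radii
    try:
        return table[element.upper()]
    except KeyError:
        raise ValidationError(f"no radius for element {element!r}") from None


# ---------------------------------------------------------------------------
# frame reading / writing
# ---------------------------------------------------------------------------


def read_frames(
    path: str | Path,
    selection: BasePairSelection | None = None,
    radii: Mapping[str, float] | None = None,
    dt_ps: float = 1.0,
) -> tuple[list[list[AtomRecord]], np.ndarray]:
    """Read a multi-model PDB or plain xyz file into per-frame atom sets.

    Only atoms matched by ``selection`` are retained (xyz frames carry no
    residue metadata, so the whole frame is taken and ``selection`` must be
    ``None``).  Returns ``(frames, times_ps)`` with frame times spaced
    ``dt_ps`` apart, matching the trajectory sampling interval.
    """
    path = Path(path)
    if path.suffix.lower() == ".xyz":
        if selection is not None:
            raise ValidationError("xyz frames carry no residue ids; selection unsupported")
        frames = _read_xyz(path, radii)
    else:
        frames = _read_pdb(path, selection, radii)
    counts = {len(f) for f in frames}
    if len(counts) > 1:
        raise ValidationError(f"{path}: inconsistent atom counts across frames: {sorted(counts)}")
    times = np.arange(len(frames), dtype=float) * dt_ps
    return frames, times


def _read_pdb(
    path: Path,
    selection: BasePairSelection | None,
    radii: Mapping[str, float] | None,
) -> list[list[AtomRecord]]:
    import MDAnalysis as mda

    u = mda.Universe(str(path))
    atoms = u.atoms
    try:
        elements = [str(e) for e in atoms.elements]
    except Exception:
        elements = [guess_element(n) for n in atoms.names]
    chains = atoms.chainIDs if hasattr(atoms, "chainIDs") else atoms.segids
    meta = [
        (str(n), (str(c).strip() or str(s).strip(), int(r)), (el.strip() or guess_element(n)).upper())
        for n, c, s, r, el in zip(atoms.names, chains, atoms.segids, atoms.resids, elements)
    ]
    keep = []
    for i, (name, residue, element) in enumerate(meta):
        if selection is None or selection.wants(residue, name, element):
            keep.append(i)
    frames: list[list[AtomRecord]] = []
    for ts in u.trajectory:
        recs = []
        for i in keep:
            name, residue, element = meta[i]
            xyz = ts.positions[i]
            recs.append(
                AtomRecord(
                    name=name,
                    residue=residue,
                    element=element,
                    coords=(float(xyz[0]), float(xyz[1]), float(xyz[2])),
                    radius=radius_for(element, radii),
                )
            )
        if not recs:
            raise ValidationError(f"{path}: selection matches zero atoms in frame {ts.frame}")
        frames.append(recs)
    if selection is not None:
        present = {r for rec in frames[0] for r in [rec.residue]}
        missing = [r for r in selection.residues if r not in present]
        if missing:
            raise ValidationError(f"{path}: selection names missing residue(s) {missing}")
    return frames


def _read_xyz(path: Path, radii: Mapping[str, float] | None) -> list[list[AtomRecord]]:
    frames: list[list[AtomRecord]] = []
    with open(path) as fh:
        lines = fh.read().splitlines()
    i = 0
    frame_no = 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        try:
            natoms = int(lines[i].strip())
        except ValueError:
            raise ValidationError(f"{path} line {i + 1}: expected atom count") from None
        block = lines[i + 2 : i + 2 + natoms]
        if len(block) < natoms:
            raise ValidationError(f"{path}: truncated frame {frame_no}")
        recs = []
        for j, line in enumerate(block):
            parts = line.split()
            if len(parts) < 4:
                raise ValidationError(f"{path} line {i + 3 + j}: expected 'name x y z'")
            name = parts[0]
            element = guess_element(name)
            recs.append(
                AtomRecord(
                    name=name,
                    residue=("", frame_no),
                    element=element,
                    coords=(float(parts[1]), float(parts[2]), float(parts[3])),
                    radius=radius_for(element, radii),
                )
            )
        frames.append(recs)
        i += 2 + natoms
        frame_no += 1
    if not frames:
        raise ValidationError(f"{path}: no frames found")
    return frames


def write_xyz_frames(frames: Sequence[Sequence[AtomRecord]], path: str | Path) -> None:
    """Write frames as plain xyz-with-names (round-trips with the reader)."""
    with open(path, "w") as fh:
        for recs in frames:
            fh.write(f"{len(recs)}\nframe\n")
            for a in recs:
                x, y, z = a.coords
                fh.write(f"{a.name} {x:.3f} {y:.3f} {z:.3f}\n")


# ---------------------------------------------------------------------------
# the surface itself
# ---------------------------------------------------------------------------


def fibonacci_sphere(n: int) -> np.ndarray:
    """Deterministic, near-equal-area unit-sphere point set (n x 3)."""
    k = np.arange(n, dtype=float)
    z = 1.0 - (2.0 * k + 1.0) / n
    phi = k * math.pi * (3.0 - math.sqrt(5.0))  # golden angle
    r = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


def _canonical_axes(coords: np.ndarray) -> np.ndarray:
    """Principal axes of the point cloud with deterministic sign choice.

    Returns a 3x3 rotation (rows = axes).  Falls back to the identity when
    the spectrum is (near-)degenerate or a sign convention cannot be fixed,
    in which case rigid-motion invariance is only statistical.
    """
    centered = coords - coords.mean(axis=0)
    cov = centered.T @ centered / len(coords)
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    scale = evals.max() if evals.max() > 0 else 1.0
    gaps = np.diff(evals) / scale
    if np.any(np.abs(gaps) < 1e-6):
        return np.eye(3)
    axes = []
    for j in range(3):
        v = evecs[:, j]
        proj = centered @ v
        skew = float(np.sum(proj**3))
        if abs(skew) < 1e-9 * scale ** 1.5 * len(coords):
            return np.eye(3)
        axes.append(v if skew > 0 else -v)
    R = np.array(axes)
    if np.linalg.det(R) < 0:  # keep a proper rotation
        R[2] = -R[2]
    return R


def esa_per_frame(
    atoms: Sequence[AtomRecord],
    probe_radius: float = DEFAULT_PROBE_RADIUS,
    sphere_points: int = DEFAULT_SPHERE_POINTS,
) -> float:
    """Solvent-exposed surface area (Å²) of one frame's atom set.

    Every atomic sphere is inflated by ``probe_radius`` and covered with a
    Fibonacci lattice of ``sphere_points`` points (oriented in the canonical
    molecular frame); points outside all other inflated spheres are exposed,
    and each atom contributes ``4 pi R² * exposed_fraction``.
    """
    if not atoms:
        raise ValidationError("empty atom set")
    if probe_radius < 0:
        raise ValidationError("probe radius must be >= 0")
    centers = np.array([a.coords for a in atoms], dtype=float)
    if not np.all(np.isfinite(centers)):
        raise ValidationError("non-finite coordinate in frame")
    radii = np.array([a.radius for a in atoms], dtype=float) + probe_radius
    base_unit = fibonacci_sphere(sphere_points)
    n = len(atoms)
    # canonicalize the point orientation per connected cluster of overlapping
    # spheres: rigid motion then maps clusters onto themselves exactly, and
    # non-overlapping groups stay strictly additive
    d = np.linalg.norm(centers[:, None, :] - centers[None, :, :], axis=2)
    overlap = d < (radii[:, None] + radii[None, :])
    _, labels = connected_components(overlap, directed=False)
    unit_by_cluster = {}
    for c in np.unique(labels):
        members = np.where(labels == c)[0]
        if members.size >= 3:
            unit_by_cluster[c] = base_unit @ _canonical_axes(centers[members])
        else:
            unit_by_cluster[c] = base_unit
    area = 0.0
    for i in range(n):
        neighbors = np.where(overlap[i] & (np.arange(n) != i))[0]
        if neighbors.size:
            pts = centers[i] + radii[i] * unit_by_cluster[labels[i]]
            diff = pts[:, None, :] - centers[neighbors][None, :, :]
            inside = (np.einsum("ijk,ijk->ij", diff, diff) < radii[neighbors] ** 2).any(axis=1)
            exposed = int((~inside).sum())
        else:
            exposed = sphere_points
        area += 4.0 * math.pi * radii[i] ** 2 * exposed / sphere_points
    return area


def esa_series(
    frames: Sequence[Sequence[AtomRecord]],
    times_ps: Sequence[float] | None = None,
    probe_radius: float = DEFAULT_PROBE_RADIUS,
    sphere_points: int = DEFAULT_SPHERE_POINTS,
    window_ps: float | None = 1000.0,
) -> ESASeries:
    """ESA of every frame, optionally smoothed with a sliding window."""
    if times_ps is None:
        times_ps = np.arange(len(frames), dtype=float)
    esa = tuple(esa_per_frame(f, probe_radius, sphere_points) for f in frames)
    series = ESASeries(times_ps=tuple(float(t) for t in times_ps), esa=esa)
    if window_ps is not None:
        series = smooth_series(series, window_ps)
    return series


def smooth_series(series: ESASeries, window_ps: float) -> ESASeries:
    """Centered moving average over ``window_ps``; edges use the available window."""
    times = np.asarray(series.times_ps, dtype=float)
    if len(times) > 1:
        dt = float(np.min(np.diff(times)))
    else:
        dt = window_ps
    if window_ps < dt:
        raise ValidationError(
            f"window ({window_ps} ps) is shorter than the sampling interval ({dt} ps)"
        )
    half = window_ps / 2.0
    x = np.asarray(series.esa, dtype=float)
    smoothed = np.empty_like(x)
    for i, t in enumerate(times):
        mask = (times >= t - half) & (times <= t + half)
        smoothed[i] = x[mask].mean()
    return replace(series, smoothed=tuple(smoothed), window_ps=window_ps)


def classify_stacking(
    series: ESASeries,
    low_threshold: float,
    high_threshold: float,
) -> tuple[tuple[str, ...], Mapping[str, float]]:
    """Label each smoothed frame stacked / intermediate / unstacked.

    Low ESA reflects a stacked architecture, high ESA unstacked bases; frames
    between the thresholds are intermediate.  Returns the per-frame states and
    the fraction of time in each state.
    """
    if not low_threshold < high_threshold:
        raise ValidationError("low_threshold must be < high_threshold")
    trace = series.smoothed if series.smoothed is not None else series.esa
    states = tuple(
        "stacked" if v <= low_threshold else "unstacked" if v >= high_threshold else "intermediate"
        for v in trace
    )
    n = len(states)
    fractions = {
        s: states.count(s) / n for s in ("stacked", "intermediate", "unstacked")
    }
    return states, fractions
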