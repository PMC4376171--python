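"""Topology / trajectory readers and analysis-output writers.

Topology comes from PSF (X-PLOR/CHARMM dialects) with a PDB fallback,
coordinates from DCD; both are parsed with MDAnalysis.  The module also
carries the minimal PSF/DCD *writers* needed by the synthetic-trajectory
generator, and the TSV/JSON writers for event tables and pathway summaries.

Coordinates are Å throughout.  Residue numbering is taken verbatim from the
source files (1-based, never renumbered).  Chains are identified by segment
identifier first, chain identifier second.
"""

from __future__ import annotations

import json
import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import TopologyError, TrajectoryError

__all__ = [
    "AtomTable",
    "Trajectory",
    "SimulationMetadata",
    "read_topology",
    "read_trajectory",
    "write_psf",
    "write_dcd",
    "write_event_table",
    "ROLE_PROTEIN",
    "ROLE_WATER",
    "ROLE_LIGAND",
    "ROLE_HEME",
    "ROLE_ION",
]

ROLE_PROTEIN = "protein"
ROLE_WATER = "water"
ROLE_LIGAND = "ligand"
ROLE_HEME = "heme"
ROLE_ION = "ion"
_ROLES = (ROLE_PROTEIN, ROLE_WATER, ROLE_LIGAND, ROLE_HEME, ROLE_ION)

#: default residue-name pattern for O2 ligand copies (overridable everywhere)
DEFAULT_LIGAND_PATTERN = r"OXY|O2|OXS|OX2"

_WATER_RESNAMES = {"TIP3", "TIP3P", "TIP4", "TP3", "HOH", "WAT", "SPC", "SPCE", "SOL"}
_HEME_RESNAMES = {"HEM", "HEME", "HEMO"}
_ION_RESNAMES = {"SOD", "CLA", "POT", "CAL", "MG", "ZN2", "NA", "CL", "K", "CES"}

# mass -> element, for PSF topologies (no element column)
_MASS_ELEMENTS = [(1.008, "H"), (12.011, "C"), (14.007, "N"), (15.999, "O"),
                  (22.990, "NA"), (30.974, "P"), (32.06, "S"), (35.45, "CL"),
                  (39.098, "K"), (55.845, "FE")]


def _element_from(name: str, mass: float | None) -> str:
    if mass is not None and mass > 0:
        best = min(_MASS_ELEMENTS, key=lambda me: abs(me[0] - mass))
        if abs(best[0] - mass) < 1.5:
            return best[1]
    stripped = re.sub(r"[^A-Za-z]", "", name)
    if not stripped:
        return "X"
    if stripped[0].upper() == "H":
        return "H"
    return stripped[0].upper()


@dataclass
class AtomTable:
    """Static per-atom description of a system.

    ``copy_index`` is 0 for non-ligand atoms and 1..N for atoms of ligand
    copy k; copy indices are assigned deterministically in file order.
    """

    serial: np.ndarray        # (n,) int, 1-based, contiguous
    name: np.ndarray          # (n,) str
    element: np.ndarray       # (n,) str
    resname: np.ndarray       # (n,) str
    resid: np.ndarray         # (n,) int, file numbering
    chain: np.ndarray         # (n,) str (segid first, chainID fallback)
    role: np.ndarray          # (n,) str, one of _ROLES
    copy_index: np.ndarray    # (n,) int, 0 = not a ligand atom
    mass: np.ndarray | None = None

    def __post_init__(self):
        self.serial = np.asarray(self.serial, dtype=int)
        self.resid = np.asarray(self.resid, dtype=int)
        self.copy_index = np.asarray(self.copy_index, dtype=int)
        for attr in ("name", "element", "resname", "chain", "role"):
            setattr(self, attr, np.asarray(getattr(self, attr), dtype=object))

    # -- invariants ---------------------------------------------------------
    def validate(self) -> None:
        n = self.n_atoms
        if not np.array_equal(np.sort(self.serial), np.arange(1, n + 1)):
            raise TopologyError("atom serials are not unique and contiguous 1..n")
        bad = set(self.role) - set(_ROLES)
        if bad:
            raise TopologyError(f"unknown role flags: {sorted(bad)}")
        lig = self.role == ROLE_LIGAND
        if np.any(self.copy_index[lig] < 1):
            raise TopologyError("ligand atom without a copy index")
        if np.any(self.copy_index[~lig] != 0):
            raise TopologyError("copy index set on a non-ligand atom")

    # -- views --------------------------------------------------------------
    @property
    def n_atoms(self) -> int:
        return len(self.serial)

    @property
    def protein_heavy(self) -> np.ndarray:
        """Indices of protein heavy atoms (the operational 'protein surface')."""
        return np.flatnonzero((self.role == ROLE_PROTEIN) & (self.element != "H"))

    @property
    def protein_chains(self) -> list[str]:
        return sorted(set(self.chain[self.role == ROLE_PROTEIN]))

    @property
    def ligand_copies(self) -> list[int]:
        return sorted(int(k) for k in set(self.copy_index[self.copy_index > 0]))

    def copy_atoms(self, k: int) -> np.ndarray:
        idx = np.flatnonzero(self.copy_index == k)
        if idx.size == 0:
            raise KeyError(f"no atoms for ligand copy {k}")
        return idx

    def copy_chain(self, k: int) -> str:
        return str(self.chain[self.copy_atoms(k)[0]])

    def copies_by_chain(self) -> dict[str, list[int]]:
        out: dict[str, list[int]] = {}
        for k in self.ligand_copies:
            out.setdefault(self.copy_chain(k), []).append(k)
        return out

    def residue_atoms(self, chain: str, resid: int, heavy_only: bool = True) -> np.ndarray:
        mask = (self.chain == chain) & (self.resid == resid)
        if heavy_only:
            mask &= self.element != "H"
        return np.flatnonzero(mask)

    @property
    def water_oxygens(self) -> np.ndarray:
        return np.flatnonzero((self.role == ROLE_WATER) & (self.element == "O"))

    def __eq__(self, other) -> bool:
        if not isinstance(other, AtomTable):
            return NotImplemented
        return all(
            np.array_equal(getattr(self, a), getattr(other, a))
            for a in ("serial", "name", "resname", "resid", "chain", "role", "copy_index")
        )


@dataclass
class Trajectory:
    """Ordered coordinate frames aligned to an :class:`AtomTable`."""

    coords: np.ndarray            # (n_frames, n_atoms, 3) float32, Å
    dt: float                     # ps between stored frames
    times: np.ndarray | None = None   # (n_frames,) ps
    box: np.ndarray | None = None     # (n_frames, 3) orthorhombic lengths, or None

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=np.float32)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise TrajectoryError("coords must have shape (frames, atoms, 3)")
        if self.times is None:
            self.times = np.arange(self.n_frames, dtype=float) * self.dt
        self.times = np.asarray(self.times, dtype=float)

    def validate(self) -> None:
        if not np.all(np.isfinite(self.coords)):
            frame = int(np.argwhere(~np.isfinite(self.coords))[0, 0])
            raise TrajectoryError(f"non-finite coordinates at frame {frame}")
        if self.n_frames > 1 and not np.all(np.diff(self.times) > 0):
            raise TrajectoryError("frame times are not strictly increasing")

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[1]

    @property
    def span_ns(self) -> float:
        """Total simulated span covered by the stored frames (ns)."""
        return self.n_frames * self.dt / 1000.0

    def frame_box(self, i: int) -> np.ndarray | None:
        return None if self.box is None else self.box[i]


@dataclass
class SimulationMetadata:
    """Provenance-only record; never consumed by numerical operations."""

    label: str = ""
    source_structure: str = ""
    temperature_K: float = 310.0
    pressure_atm: float = 1.0
    salt_M: float = 0.15
    nonbond_cutoff_A: float = 12.0
    switch_distance_A: float = 10.0
    extra: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------

def _classify_roles(resnames, ligand_re) -> np.ndarray:
    roles = np.empty(len(resnames), dtype=object)
    for i, rn in enumerate(resnames):
        rn_up = str(rn).upper()
        if ligand_re.fullmatch(rn_up):
            roles[i] = ROLE_LIGAND
        elif rn_up in _WATER_RESNAMES:
            roles[i] = ROLE_WATER
        elif rn_up in _HEME_RESNAMES:
            roles[i] = ROLE_HEME
        elif rn_up in _ION_RESNAMES:
            roles[i] = ROLE_ION
        else:
            roles[i] = ROLE_PROTEIN
    return roles


def read_topology(path, ligand_spec: str = DEFAULT_LIGAND_PATTERN) -> AtomTable:
    """Read a PSF (or PDB) topology and classify every atom.

    Ligand copies are the residues whose name matches ``ligand_spec``
    (full regex match, case-insensitive); they are numbered 1..N in file
    order, which groups them by chain for chain-sorted inputs.
    """
    import MDAnalysis as mda

    path = Path(path)
    if not path.exists():
        raise TopologyError(f"topology file not found: {path}")
    try:
        ligand_re = re.compile(ligand_spec, re.IGNORECASE)
    except re.error as exc:
        raise TopologyError(f"invalid ligand residue pattern {ligand_spec!r}: {exc}") from exc
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            u = mda.Universe(str(path), to_guess=())
    except Exception as exc:
        raise TopologyError(f"cannot parse topology {path}: {exc}") from exc

    n = len(u.atoms)
    if n == 0:
        raise TopologyError(f"topology {path} contains no atoms")
    names = np.array([str(a) for a in u.atoms.names], dtype=object)
    resnames = np.array([str(r) for r in u.atoms.resnames], dtype=object)
    resids = np.asarray(u.atoms.resids, dtype=int)
    try:
        masses = np.asarray(u.atoms.masses, dtype=float)
    except Exception:
        masses = None

    # segid first, chainID second
    chains = np.empty(n, dtype=object)
    segids = getattr(u.atoms, "segids", None)
    chainids = getattr(u.atoms, "chainIDs", None)
    for i in range(n):
        seg = str(segids[i]).strip() if segids is not None else ""
        cid = str(chainids[i]).strip() if chainids is not None else ""
        chains[i] = seg or cid or "A"

    elements = np.array(
        [_element_from(names[i], None if masses is None else masses[i]) for i in range(n)],
        dtype=object,
    )
    roles = _classify_roles(resnames, ligand_re)
    if not np.any(roles == ROLE_PROTEIN):
        raise TopologyError(f"topology {path} contains zero protein atoms")

    # copy indices: one per ligand residue, file order
    copy_index = np.zeros(n, dtype=int)
    k = 0
    seen: dict[tuple, int] = {}
    for i in np.flatnonzero(roles == ROLE_LIGAND):
        key = (chains[i], resids[i], resnames[i])
        if key not in seen:
            k += 1
            seen[key] = k
        copy_index[i] = seen[key]

    table = AtomTable(
        serial=np.arange(1, n + 1),
        name=names,
        element=elements,
        resname=resnames,
        resid=resids,
        chain=chains,
        role=roles,
        copy_index=copy_index,
        mass=masses,
    )
    table.validate()
    return table


def read_trajectory(path, atoms: AtomTable) -> Trajectory:
    """Read a DCD coordinate file, keeping frames strictly in file order."""
    from MDAnalysis.coordinates.DCD import DCDReader

    path = Path(path)
    if not path.exists():
        raise TrajectoryError(f"trajectory file not found: {path}")
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            reader = DCDReader(str(path))
    except Exception as exc:
        raise TrajectoryError(f"cannot open trajectory {path}: {exc}") from exc

    if reader.n_atoms != atoms.n_atoms:
        raise TrajectoryError(
            f"atom-count mismatch: trajectory {path} has {reader.n_atoms} atoms, "
            f"topology has {atoms.n_atoms}"
        )
    frames, times, boxes = [], [], []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for i, ts in enumerate(reader):
            xyz = np.asarray(ts.positions, dtype=np.float32)
            if not np.all(np.isfinite(xyz)):
                raise TrajectoryError(f"corrupt frame {i} in {path}: non-finite coordinates")
            frames.append(xyz.copy())
            times.append(float(ts.time))
            dims = ts.dimensions
            boxes.append(None if dims is None or not np.any(dims[:3]) else np.array(dims[:3]))
    reader.close()
    if not frames:
        raise TrajectoryError(f"trajectory {path} contains no frames")
    dt = float(times[1] - times[0]) if len(times) > 1 else float(getattr(reader, "dt", 1.0))
    box = None
    if all(b is not None for b in boxes):
        box = np.stack(boxes)
    traj = Trajectory(coords=np.stack(frames), dt=dt, times=np.asarray(times), box=box)
    traj.validate()
    return traj


# ---------------------------------------------------------------------------
# writers (synthetic-generator + report plumbing)
# ---------------------------------------------------------------------------

def write_psf(atoms: AtomTable, path) -> Path:
    """Write a minimal whitespace-delimited X-PLOR-style PSF."""
    path = Path(path)
    masses = atoms.mass
    lines = ["PSF", "", "       1 !NTITLE", " REMARKS oxypath synthetic topology", ""]
    lines.append(f"{atoms.n_atoms:8d} !NATOM")
    for i in range(atoms.n_atoms):
        m = 12.011 if masses is None else float(masses[i])
        lines.append(
            f"{int(atoms.serial[i]):8d} {str(atoms.chain[i]):<4s} "
            f"{int(atoms.resid[i]):<6d} {str(atoms.resname[i]):<6s} "
            f"{str(atoms.name[i]):<6s} {str(atoms.element[i]):<4s} "
            f"{0.0:10.6f} {m:13.4f} {0:11d}"
        )
    lines += ["", "       0 !NBOND: bonds", ""]
    path.write_text("\n".join(lines))
    return path


def write_dcd(coords: np.ndarray, path, dt: float = 1.0) -> Path:
    """Write frames (F, N, 3) to a DCD file."""
    import MDAnalysis as mda
    from MDAnalysis.coordinates.DCD import DCDWriter

    coords = np.asarray(coords, dtype=np.float32)
    path = Path(path)
    n_atoms = coords.shape[1]
    u = mda.Universe.empty(n_atoms, trajectory=True)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        with DCDWriter(str(path), n_atoms=n_atoms, dt=dt) as w:
            for frame in coords:
                u.atoms.positions = frame
                w.write(u.atoms)
    return path


def write_event_table(events, summary, outdir) -> tuple[Path, Path]:
    """Write the TSV event table and the JSON pathway summary.

    ``events`` may mix escape and crossing events (duck-typed on their
    fields).  The summary's counts are cross-checked against the rows
    actually written; a mismatch raises ``ValueError``.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    tsv = outdir / "events.tsv"
    js = outdir / "summary.json"

    header = ["copy", "frame", "event", "portal", "last_cavity",
              "origin", "destination", "returned"]
    rows = []
    portal_counts: dict[str, int] = {}
    n_crossings = 0
    for ev in events:
        if hasattr(ev, "portal"):  # escape
            portal = ev.portal or "unclassified"
            portal_counts[portal] = portal_counts.get(portal, 0) + 1
            rows.append([ev.copy, ev.frame, "escape", portal,
                         ev.last_cavity or "-", "-", "-", "-"])
        else:  # crossing
            n_crossings += 1
            rows.append([ev.copy, ev.departure_frame, "crossing", "-", "-",
                         ev.origin, ev.destination, str(bool(ev.returned)).lower()])

    if summary is not None:
        if dict(summary.portal_counts) != portal_counts:
            raise ValueError(
                f"summary portal counts {dict(summary.portal_counts)} do not match "
                f"event table counts {portal_counts}"
            )
        if len(summary.crossings) != n_crossings:
            raise ValueError("summary crossing count does not match event table")

    with tsv.open("w") as fh:
        fh.write("\t".join(header) + "\n")
        for row in rows:
            fh.write("\t".join(str(x) for x in row) + "\n")
    payload = summary.to_dict() if summary is not None else {}
    js.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
    return tsv, js
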