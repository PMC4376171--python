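"""Per-copy ligand tracks, escape/portal/cavity/crossing analysis.

The operational definitions:

* ligand position  = geometric center of the copy's atoms;
* protein surface  = the set of protein heavy atoms, so the surface
  distance of a copy is the minimum Euclidean (minimum-image when box
  vectors are present) distance from its center to any protein heavy atom;
* escape           = first frame where the surface distance exceeds the
  threshold (default 5.0 Å) and stays above it for at least ``persistence``
  stored frames or to the trajectory end;
* portal           = the two nearest helices of the copy's chain at the
  last interior frame preceding the escape, alphabetized ("B-G");
  corner pseudo-regions win when nearest, exits whose nearest protein
  atoms belong to the opposite chain are "interface", and exits farther
  than ``classify_bound`` from every helix are "unclassified";
* subunit          = chain of the nearest protein heavy atom, or
  "interface" when the two chains' nearest-atom distances differ by less
  than the ambiguity margin;
* crossing         = subunit assignment changes chain and the new chain
  persists for at least ``dwell`` frames.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from ._geometry import min_dist_to_set, nearest_in_set
from .annotation import CavityDefinition, HelixTable
from .errors import ParameterError, TopologyError
from .trajio import AtomTable, Trajectory

__all__ = [
    "TrackingParams",
    "LigandTrack",
    "EscapeEvent",
    "CrossingEvent",
    "PathwaySummary",
    "min_surface_distance",
    "detect_escape",
    "classify_portal",
    "cavity_occupancy",
    "detect_crossings",
    "is_interface_resident",
    "summarize_pathways",
    "build_tracks",
    "analyze_run",
]

INTERFACE = "interface"
UNCLASSIFIED = "unclassified"


@dataclass
class TrackingParams:
    """Analysis defaults; every value is overridable from the CLI."""

    threshold: float = 5.0        # Å, surface-escape criterion
    persistence: int = 10         # stored frames the distance must stay above threshold
    window: int = 100             # frames searched backwards for the last interior frame
    classify_bound: float = 15.0  # Å, beyond which a portal is "unclassified"
    interface_margin: float = 1.5 # Å, |dA - dB| below which a copy is "interface"
    dwell: int = 25               # frames a new chain must persist to confirm a crossing

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in
                ("threshold", "persistence", "window", "classify_bound",
                 "interface_margin", "dwell")}


@dataclass
class LigandTrack:
    """Per-frame state of one ligand copy."""

    copy: int
    positions: np.ndarray       # (F, 3) copy geometric center
    surface_dist: np.ndarray    # (F,) min distance to protein heavy atoms
    nearest_chain: np.ndarray   # (F,) chain of the nearest protein heavy atom
    subunit: np.ndarray         # (F,) chain label or "interface"
    cavity: np.ndarray | None = None  # (F,) cavity name or None

    @property
    def n_frames(self) -> int:
        return len(self.surface_dist)


@dataclass
class EscapeEvent:
    copy: int
    frame: int
    portal: str | None = None
    last_cavity: str | None = None


@dataclass
class CrossingEvent:
    copy: int
    departure_frame: int
    arrival_frame: int
    origin: str
    destination: str
    returned: bool = False

    def __post_init__(self):
        if self.departure_frame >= self.arrival_frame:
            raise ValueError("crossing must have departure_frame < arrival_frame")
        if self.origin == self.destination and not self.returned:
            raise ValueError("origin == destination only allowed for returned crossings")


@dataclass
class PathwaySummary:
    """Per-simulation accounting of all ligand copies."""

    label: str
    n_copies: int
    portal_counts: dict[str, int] = field(default_factory=dict)
    non_escaped: int = 0
    interface_resident: int = 0
    crossings: list[CrossingEvent] = field(default_factory=list)

    def validate(self) -> None:
        total = sum(self.portal_counts.values()) + self.non_escaped + self.interface_resident
        if total != self.n_copies:
            raise ValueError(
                f"accounting identity violated: {sum(self.portal_counts.values())} escaped "
                f"+ {self.interface_resident} interface + {self.non_escaped} non-escaped "
                f"!= {self.n_copies} copies"
            )

    def to_dict(self) -> dict:
        return {
            "label": self.label,
            "n_copies": self.n_copies,
            "portal_counts": dict(sorted(self.portal_counts.items())),
            "non_escaped": self.non_escaped,
            "interface_resident": self.interface_resident,
            "crossings": [
                {"copy": int(c.copy), "departure_frame": int(c.departure_frame),
                 "arrival_frame": int(c.arrival_frame), "origin": str(c.origin),
                 "destination": str(c.destination), "returned": bool(c.returned)}
                for c in self.crossings
            ],
        }


# ---------------------------------------------------------------------------
# elementary operations
# ---------------------------------------------------------------------------

def min_surface_distance(ligand_coords: np.ndarray, protein_coords: np.ndarray,
                         box: np.ndarray | None = None) -> float:
    """Minimum distance (Å) from the ligand geometric center to any protein atom.

    ``ligand_coords`` may be a single point (3,) or the copy's atoms (k, 3),
    in which case their geometric center is used.
    """
    lig = np.asarray(ligand_coords, dtype=float)
    center = lig if lig.ndim == 1 else lig.mean(axis=0)
    protein_coords = np.asarray(protein_coords, dtype=float)
    if protein_coords.ndim != 2 or len(protein_coords) == 0:
        raise ValueError("need at least one protein atom")
    return float(min_dist_to_set(center[None, :], protein_coords, box)[0])


def detect_escape(track, threshold: float = 5.0, persistence: int = 10) -> EscapeEvent | None:
    """First durable excursion beyond ``threshold``, or None (non-escaper).

    ``track`` is a :class:`LigandTrack` or a raw surface-distance series.
    The event sits at the first frame of the first run of
    above-threshold frames that lasts >= ``persistence`` frames or
    reaches the trajectory end.
    """
    if persistence < 1:
        raise ParameterError(f"persistence must be >= 1, got {persistence}")
    if isinstance(track, LigandTrack):
        series, copy = track.surface_dist, track.copy
    else:
        series, copy = np.asarray(track, dtype=float), -1
    above = series > threshold
    n = len(above)
    i = 0
    while i < n:
        if above[i]:
            j = i
            while j < n and above[j]:
                j += 1
            if (j - i) >= persistence or j == n:
                return EscapeEvent(copy=copy, frame=i)
            i = j
        else:
            i += 1
    return None


def _last_interior_frame(track: LigandTrack, event: EscapeEvent,
                         threshold: float, window: int) -> int:
    lo = max(0, event.frame - window)
    for j in range(event.frame - 1, lo - 1, -1):
        if track.surface_dist[j] <= threshold:
            return j
    return max(0, event.frame - 1)


def _current_chain(track: LigandTrack, frame: int) -> str:
    for j in range(frame, -1, -1):
        if track.subunit[j] != INTERFACE:
            return str(track.subunit[j])
    return str(track.nearest_chain[frame])


def region_distances(point: np.ndarray, chain: str, helices: HelixTable,
                     atoms: AtomTable, frame_coords: np.ndarray,
                     box: np.ndarray | None = None) -> list[tuple[float, str, str]]:
    """Sorted (distance, label, kind) of every helix/corner region of a chain."""
    out = []
    fc = np.asarray(frame_coords, dtype=float)
    for kind, label, (lo, hi) in helices.chain_regions(chain):
        mask = ((atoms.chain == chain) & (atoms.resid >= lo) & (atoms.resid <= hi)
                & (atoms.role == "protein") & (atoms.element != "H"))
        idx = np.flatnonzero(mask)
        if idx.size == 0:
            continue
        d = float(min_dist_to_set(point[None, :], fc[idx], box)[0])
        out.append((d, label, kind))
    out.sort(key=lambda t: (t[0], t[1]))
    return out


def classify_portal(track: LigandTrack, event: EscapeEvent, helices: HelixTable,
                    atoms: AtomTable, trajectory: Trajectory,
                    params: TrackingParams | None = None) -> str:
    """Portal label for an escape: helix pair, corner, interface, or unclassified."""
    if event is None:
        raise ValueError("classify_portal requires an escape event")
    params = params or TrackingParams()
    if params.window < 1:
        raise ParameterError("window must be >= 1")
    j = _last_interior_frame(track, event, params.threshold, params.window)
    point = np.asarray(track.positions[j], dtype=float)
    chain = _current_chain(track, j)
    if str(track.nearest_chain[j]) != chain:
        return INTERFACE
    box = trajectory.frame_box(j) if trajectory is not None else None
    frame_coords = trajectory.coords[j] if trajectory is not None else None
    regs = region_distances(point, chain, helices, atoms, frame_coords, box)
    return label_from_regions(regs, params.classify_bound)


def label_from_regions(regs: list[tuple[float, str, str]], classify_bound: float) -> str:
    """Portal label from sorted (distance, label, kind) region distances."""
    if not regs:
        return UNCLASSIFIED
    if regs[0][2] == "corner":
        return f"corner:{regs[0][1]}"
    helix_regs = [r for r in regs if r[2] == "helix"]
    if len(helix_regs) < 2 or helix_regs[0][0] > classify_bound:
        return UNCLASSIFIED
    pair = sorted([helix_regs[0][1], helix_regs[1][1]])
    return f"{pair[0]}-{pair[1]}"


def cavity_occupancy(track: LigandTrack, cavities: list[CavityDefinition],
                     trajectory: Trajectory, atoms: AtomTable,
                     escape_frame: int | None = None):
    """Per-frame cavity labels (nearest-wins, alphabetical tie-break) and
    the last cavity occupied strictly before ``escape_frame``."""
    F = track.n_frames
    labels = np.full(F, None, dtype=object)
    if cavities:
        best_d = np.full(F, np.inf)
        # alphabetical iteration + strict improvement = alphabetical tie-break
        for cav in sorted(cavities, key=lambda c: c.name):
            idx = cav.resolve(atoms)
            centroids = np.asarray(trajectory.coords[:F, idx, :], dtype=float).mean(axis=1)
            d = np.linalg.norm(track.positions - centroids, axis=1)
            hit = (d <= cav.cutoff) & (d < best_d)
            labels[hit] = cav.name
            best_d = np.minimum(best_d, np.where(d <= cav.cutoff, d, np.inf))
    last_cavity = None
    if escape_frame is not None:
        for f in range(min(escape_frame, F) - 1, -1, -1):
            if labels[f] is not None:
                last_cavity = labels[f]
                break
    return labels, last_cavity


def detect_crossings(track: LigandTrack, dwell: int = 25,
                     atoms: AtomTable | None = None) -> list[CrossingEvent]:
    """Confirmed subunit crossings (new chain persists >= ``dwell`` frames).

    An A->B->A round trip with both dwells satisfied collapses into a single
    event with ``returned=True`` (origin == destination == A).  Interface
    frames never break a chain run; they are skipped.
    """
    if dwell < 1:
        raise ParameterError(f"dwell must be >= 1, got {dwell}")
    if atoms is not None and len(atoms.protein_chains) < 2:
        raise TopologyError("crossing detection is undefined for a single-chain topology")
    sub = track.subunit
    # runs of same-chain assignment; interface frames excluded and merged over
    runs: list[list] = []  # [chain, start, end]
    for f, s in enumerate(sub):
        s = str(s)
        if s == INTERFACE:
            continue
        if runs and runs[-1][0] == s:
            runs[-1][2] = f
        else:
            runs.append([s, f, f])
    transitions = []
    for r1, r2 in zip(runs, runs[1:]):
        # both the origin and the new chain must persist: a sub-dwell flicker
        # into the other chain is neither a departure nor an arrival
        if r2[0] != r1[0] and (r2[2] - r2[1] + 1) >= dwell \
                and (r1[2] - r1[1] + 1) >= dwell:
            transitions.append((r1[2], r2[1], r1[0], r2[0]))
    events: list[CrossingEvent] = []
    i = 0
    while i < len(transitions):
        dep, arr, frm, to = transitions[i]
        if i + 1 < len(transitions) and transitions[i + 1][2] == to and transitions[i + 1][3] == frm:
            events.append(CrossingEvent(track.copy, dep, transitions[i + 1][1],
                                        frm, frm, returned=True))
            i += 2
        else:
            events.append(CrossingEvent(track.copy, dep, arr, frm, to, returned=False))
            i += 1
    return events


def is_interface_resident(track: LigandTrack, escaped: bool, dwell: int = 25) -> bool:
    """True for copies that end the run parked in the subunit interface.

    Majority vote over the trailing ``2 * dwell`` frames, so boundary
    flicker of the nearest-chain assignment does not break residency.
    """
    if escaped or track.n_frames == 0:
        return False
    tail = track.subunit[-max(2 * dwell, 1):]
    return float(np.mean(tail == INTERFACE)) > 0.5


def summarize_pathways(events: list[EscapeEvent], crossings: list[CrossingEvent],
                       n_copies: int, interface_resident: set[int] = frozenset(),
                       label: str = "") -> PathwaySummary:
    """Fold escapes + crossings into the per-simulation accounting record."""
    copies = [e.copy for e in events]
    dup = [c for c, cnt in Counter(copies).items() if cnt > 1]
    if dup:
        raise ValueError(f"duplicate escape events for copies {dup}")
    overlap = set(copies) & set(interface_resident)
    if overlap:
        raise ValueError(f"copies {sorted(overlap)} both escaped and interface-resident")
    portal_counts = dict(Counter((e.portal or UNCLASSIFIED) for e in events))
    summary = PathwaySummary(
        label=label,
        n_copies=n_copies,
        portal_counts=portal_counts,
        non_escaped=n_copies - len(events) - len(interface_resident),
        interface_resident=len(interface_resident),
        crossings=list(crossings),
    )
    summary.validate()
    return summary


# ---------------------------------------------------------------------------
# drivers
# ---------------------------------------------------------------------------

def build_tracks(trajectory: Trajectory, atoms: AtomTable,
                 params: TrackingParams | None = None) -> list[LigandTrack]:
    """Compute position / surface-distance / subunit series for every copy."""
    params = params or TrackingParams()
    copies = atoms.ligand_copies
    if not copies:
        raise TopologyError("topology contains no ligand copies")
    prot = atoms.protein_heavy
    if prot.size == 0:
        raise TopologyError("topology contains no protein heavy atoms")
    chains = atoms.protein_chains
    chain_idx = {c: prot[np.array([atoms.chain[i] == c for i in prot])] for c in chains}
    copy_idx = {k: atoms.copy_atoms(k) for k in copies}

    F = trajectory.n_frames
    pos = {k: np.empty((F, 3)) for k in copies}
    sdist = {k: np.empty(F) for k in copies}
    nchain = {k: np.empty(F, dtype=object) for k in copies}
    sub = {k: np.empty(F, dtype=object) for k in copies}

    use_pbc = trajectory.box is not None
    for f in range(F):
        fc = np.asarray(trajectory.coords[f], dtype=float)
        centers = np.stack([fc[copy_idx[k]].mean(axis=0) for k in copies])
        box = trajectory.frame_box(f)
        if use_pbc:
            dmins, chain_d = {}, {}
            for c in chains:
                dc = min_dist_to_set(centers, fc[chain_idx[c]], box)
                chain_d[c] = dc
            dall = np.min(np.stack([chain_d[c] for c in chains]), axis=0)
            nearest_c = [chains[int(a)] for a in
                         np.argmin(np.stack([chain_d[c] for c in chains]), axis=0)]
        else:
            chain_trees = {c: cKDTree(fc[chain_idx[c]]) for c in chains}
            chain_d = {c: chain_trees[c].query(centers)[0] for c in chains}
            stacked = np.stack([chain_d[c] for c in chains])
            dall = stacked.min(axis=0)
            nearest_c = [chains[int(a)] for a in stacked.argmin(axis=0)]
        for ki, k in enumerate(copies):
            pos[k][f] = centers[ki]
            sdist[k][f] = dall[ki]
            nchain[k][f] = nearest_c[ki]
            if len(chains) >= 2:
                ds = sorted(chain_d[c][ki] for c in chains)
                sub[k][f] = INTERFACE if (ds[1] - ds[0]) < params.interface_margin \
                    else nearest_c[ki]
            else:
                sub[k][f] = nearest_c[ki]

    return [LigandTrack(copy=k, positions=pos[k], surface_dist=sdist[k],
                        nearest_chain=nchain[k], subunit=sub[k]) for k in copies]


@dataclass
class AnalysisResult:
    tracks: list[LigandTrack]
    escapes: list[EscapeEvent]
    crossings: list[CrossingEvent]
    residents: set[int]
    summary: PathwaySummary

    def __iter__(self):  # backward-compatible tuple unpacking
        return iter((self.tracks, self.escapes, self.crossings, self.summary))


def analyze_run(trajectory: Trajectory, atoms: AtomTable, helices: HelixTable,
                cavities: list[CavityDefinition] | None = None,
                params: TrackingParams | None = None, label: str = "") -> AnalysisResult:
    """Full per-simulation analysis of every ligand copy."""
    params = params or TrackingParams()
    cavities = cavities or []
    tracks = build_tracks(trajectory, atoms, params)
    escapes: list[EscapeEvent] = []
    crossings: list[CrossingEvent] = []
    residents: set[int] = set()
    for tr in tracks:
        ev = detect_escape(tr, params.threshold, params.persistence)
        if ev is not None:
            ev.copy = tr.copy
            ev.portal = classify_portal(tr, ev, helices, atoms, trajectory, params)
            tr.cavity, ev.last_cavity = cavity_occupancy(tr, cavities, trajectory,
                                                         atoms, escape_frame=ev.frame)
            escapes.append(ev)
        else:
            tr.cavity, _ = cavity_occupancy(tr, cavities, trajectory, atoms)
        if len(atoms.protein_chains) >= 2:
            end = ev.frame if ev is not None else tr.n_frames
            clipped = LigandTrack(tr.copy, tr.positions[:end], tr.surface_dist[:end],
                                  tr.nearest_chain[:end], tr.subunit[:end])
            crossings.extend(detect_crossings(clipped, params.dwell))
            if is_interface_resident(tr, escaped=ev is not None, dwell=params.dwell):
                residents.add(tr.copy)
    summary = summarize_pathways(escapes, crossings, len(tracks), residents, label)
    return AnalysisResult(tracks, escapes, crossings, residents, summary)
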