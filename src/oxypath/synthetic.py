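"""Scripted two-chain toy systems with exact ground truth.

The toy "protein" is a pair of mirror-image pseudo-atom shells (chains A
and B) whose surfaces carry eight labelled helix arcs, an FG-corner patch
and an interface patch, and whose interiors hold four lined cavities
(B, Xe1, Xe2, Xe4) plus a coarse scaffold grid that keeps every interior
point within the surface-escape threshold of some heavy atom.  Ligand
copies (7 O2 pseudo-diatomics per chain), interfacial water beads and the
annotation config are generated together with a machine-readable
ground-truth record, so every analysis stage can be verified end to end
without external data.

Scripted copies follow piecewise-linear itineraries through cavity centers
and then escape through a chosen portal, cross the subunit interface,
park in the interface, or never leave.  Escaping copies exceed the 5 Å
surface criterion exactly from their scripted frame onward (verified
numerically at build time on the noise-free coordinates).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.spatial import cKDTree

from ._geometry import fibonacci_sphere
from .annotation import CavityDefinition, HelixTable, save_annotation
from .errors import ScriptError
from .trajio import AtomTable, Trajectory, write_dcd, write_psf
from .tracking import TrackingParams, label_from_regions

__all__ = [
    "ToyProteinSpec",
    "ToyProtein",
    "CopyScript",
    "EventScript",
    "Escape",
    "Cross",
    "InterfaceStay",
    "NoEscape",
    "build_toy_system",
    "script_trajectory",
    "feasible_portals",
    "random_script",
    "wt_like_script",
    "benchmark_run",
    "write_toy_bundle",
    "score_recovery",
]

HELIX_LABELS = tuple("ABCDEFGH")
CAVITY_NAMES = ("B", "Xe1", "Xe2", "Xe4")


def _dir(polar_deg: float, azim_deg: float) -> np.ndarray:
    """Unit vector; polar angle measured from the +x axis (the interface axis)."""
    p, a = np.radians(polar_deg), np.radians(azim_deg)
    return np.array([np.cos(p), np.sin(p) * np.cos(a), np.sin(p) * np.sin(a)])


@dataclass
class ToyProteinSpec:
    """Geometry of the toy two-chain pseudo-protein."""

    shell_radius: float = 15.0
    gap: float = 5.0                       # closest approach of the two shells
    residues_per_helix: int = 12
    helix_span_deg: float = 26.0
    # (polar, azim) of each helix arc center, degrees; polar from the +x pole
    helix_placement: dict = field(default_factory=lambda: {
        "A": (90.0, 288.0), "B": (90.0, 0.0), "C": (90.0, 144.0),
        "D": (90.0, 216.0), "E": (45.0, 0.0), "F": (45.0, 72.0),
        "G": (90.0, 72.0), "H": (135.0, 252.0),
    })
    corners: dict = field(default_factory=lambda: {"FG": (67.5, 72.0)})
    residues_per_corner: int = 5
    cavity_placement: dict = field(default_factory=lambda: {
        "B": (90.0, 180.0), "Xe1": (50.0, 90.0),
        "Xe2": (140.0, 0.0), "Xe4": (90.0, 270.0),
    })
    cavity_radius: float = 6.5             # distance of cavity centers from chain center
    cavity_cutoff: float = 4.5
    lining_offset: float = 2.2             # lining atoms sit at center +- offset
    scaffold_spacing: float = 5.0
    scaffold_radius: float = 12.5
    n_loop: int = 260
    n_waters_permanent: int = 12
    n_waters_transient: int = 5
    n_copies: int = 14
    o2_bond: float = 1.2

    def validate(self) -> None:
        for name, (p, a) in self.helix_placement.items():
            for other, (p2, a2) in self.helix_placement.items():
                if name >= other:
                    continue
                ang = np.degrees(np.arccos(np.clip(np.dot(_dir(p, a), _dir(p2, a2)), -1, 1)))
                if ang < self.helix_span_deg:
                    raise ScriptError(f"helix arcs {name} and {other} overlap ({ang:.1f} deg)")
        if self.cavity_radius + self.cavity_cutoff >= self.shell_radius:
            raise ScriptError("cavities must lie inside the shell")
        if self.n_copies % 2:
            raise ScriptError("n_copies must split evenly over the two chains")


def _arc_points(center_dir: np.ndarray, n: int, span_deg: float, radius: float) -> np.ndarray:
    """n points along a great-circle arc centered on center_dir."""
    ref = np.array([0.0, 0.0, 1.0])
    if abs(np.dot(ref, center_dir)) > 0.95:
        ref = np.array([0.0, 1.0, 0.0])
    tangent = np.cross(center_dir, ref)
    tangent /= np.linalg.norm(tangent)
    angles = np.radians(np.linspace(-span_deg / 2, span_deg / 2, n))
    pts = (np.cos(angles)[:, None] * center_dir[None, :]
           + np.sin(angles)[:, None] * tangent[None, :])
    return radius * pts


@dataclass
class ToyProtein:
    """Built toy system: topology, template coordinates and ground truth."""

    spec: ToyProteinSpec
    atoms: AtomTable
    template: np.ndarray                   # (n_atoms, 3) frame-0 coordinates
    helices: HelixTable
    cavities: list[CavityDefinition]
    chain_centers: dict                    # chain -> (3,)
    cavity_centers: dict                   # (chain, name) -> (3,)
    water_keys: list                       # [(chain, resid)] in WAT segment
    build_record: dict
    _portal_table: dict = field(default_factory=dict, repr=False)

    def mirror(self, local: np.ndarray) -> np.ndarray:
        out = np.array(local, dtype=float)
        out[..., 0] *= -1
        return out

    def to_global(self, chain: str, local: np.ndarray) -> np.ndarray:
        local = np.asarray(local, dtype=float)
        if chain == "B":
            local = self.mirror(local)
        return local + self.chain_centers[chain]


def build_toy_system(spec: ToyProteinSpec | None = None, seed: int = 0) -> ToyProtein:
    """Deterministically build the two-chain toy topology + annotation."""
    spec = spec or ToyProteinSpec()
    spec.validate()
    rng = np.random.default_rng(seed)
    R = spec.shell_radius
    half = R + spec.gap / 2.0
    chain_centers = {"A": np.array([-half, 0.0, 0.0]), "B": np.array([half, 0.0, 0.0])}

    # ---- chain-local layout (chain A; chain B is the x-mirror) -------------
    local_pos: list[np.ndarray] = []
    resids: list[int] = []
    region_ranges: dict[str, tuple[int, int]] = {}
    rid = 0

    def add_residues(points, tag=None):
        nonlocal rid
        start = rid + 1
        for p in points:
            rid += 1
            local_pos.append(np.asarray(p, dtype=float))
            resids.append(rid)
        if tag is not None:
            region_ranges[tag] = (start, rid)

    for label in HELIX_LABELS:
        polar, azim = spec.helix_placement[label]
        add_residues(_arc_points(_dir(polar, azim), spec.residues_per_helix,
                                 spec.helix_span_deg, R), tag=f"helix:{label}")
    for cname, (polar, azim) in sorted(spec.corners.items()):
        add_residues(_arc_points(_dir(polar, azim), spec.residues_per_corner,
                                 spec.helix_span_deg * 0.6, R), tag=f"corner:{cname}")

    cavity_local = {name: spec.cavity_radius * _dir(*spec.cavity_placement[name])
                    for name in CAVITY_NAMES}
    lining_ranges: dict[str, tuple[int, int]] = {}
    axes = np.eye(3)
    for name in sorted(cavity_local):
        c = cavity_local[name]
        pts = [c + s * spec.lining_offset * ax for ax in axes for s in (+1.0, -1.0)]
        start = rid + 1
        add_residues(pts)
        lining_ranges[name] = (start, rid)

    # interface patch: pole atom + ring, keeps the inter-shell gap "coated"
    pole = _dir(0, 0) * R
    ring = [_dir(15.0, a) * R for a in np.linspace(0, 360, 8, endpoint=False)]
    add_residues([pole] + ring, tag="patch")

    # interior scaffold grid: guarantees interior points stay within the
    # escape threshold of some heavy atom (spacing 5 A -> max gap ~4.33 A)
    g = np.arange(-spec.scaffold_radius, spec.scaffold_radius + 1e-9, spec.scaffold_spacing)
    grid = np.array([[x, y, z] for x in g for y in g for z in g])
    keep = np.linalg.norm(grid, axis=1) <= spec.scaffold_radius
    for c in cavity_local.values():
        keep &= np.linalg.norm(grid - c, axis=1) > 2.0
    add_residues(grid[keep], tag="scaffold")

    # loop shell (uniform points; padding for surface-distance realism)
    add_residues(fibonacci_sphere(spec.n_loop) * R, tag="loops")

    n_per_chain = len(local_pos)
    local_arr = np.asarray(local_pos)

    # ---- assemble both chains + ligands + waters --------------------------
    pos, name, element, resname, resid, chain, role, copyi, mass = \
        [], [], [], [], [], [], [], [], []

    def add_atom(p, nm, el, rn, ri, ch, rl, k, m):
        pos.append(np.asarray(p, dtype=float))
        name.append(nm); element.append(el); resname.append(rn)
        resid.append(ri); chain.append(ch); role.append(rl)
        copyi.append(k); mass.append(m)

    for ch in ("A", "B"):
        coords = local_arr if ch == "A" else local_arr * np.array([-1.0, 1.0, 1.0])
        for i in range(n_per_chain):
            add_atom(coords[i] + chain_centers[ch], "CA", "C", "GLY",
                     resids[i], ch, "protein", 0, 12.011)

    n_half = spec.n_copies // 2
    bond = spec.o2_bond / 2.0
    k = 0
    cavity_centers = {(ch, nm): (local if ch == "A" else local * np.array([-1.0, 1.0, 1.0]))
                      + chain_centers[ch]
                      for nm, local in cavity_local.items() for ch in ("A", "B")}
    for ch in ("A", "B"):
        for j in range(n_half):
            k += 1
            start = cavity_centers[(ch, "B")]
            for off, nm in ((-bond, "O1"), (+bond, "O2")):
                add_atom(start + np.array([0.0, 0.0, off]), nm, "O", "OXY",
                         2000 + j + 1, ch, "ligand", k, 15.999)

    water_keys = []
    n_w = spec.n_waters_permanent + spec.n_waters_transient
    wring = np.linspace(0, 2 * np.pi, max(n_w, 1), endpoint=False)
    for w in range(n_w):
        rho = 2.2 if w < spec.n_waters_permanent else 2.8
        home = np.array([0.0, rho * np.cos(wring[w]), rho * np.sin(wring[w])])
        wid = w + 1
        water_keys.append(("WAT", wid))
        add_atom(home, "OH2", "O", "TIP3", wid, "WAT", "water", 0, 15.999)
        add_atom(home + np.array([0.76, 0.59, 0.0]), "H1", "H", "TIP3", wid, "WAT", "water", 0, 1.008)
        add_atom(home + np.array([-0.76, 0.59, 0.0]), "H2", "H", "TIP3", wid, "WAT", "water", 0, 1.008)

    n = len(pos)
    atoms = AtomTable(
        serial=np.arange(1, n + 1), name=np.array(name, dtype=object),
        element=np.array(element, dtype=object), resname=np.array(resname, dtype=object),
        resid=np.array(resid, dtype=int), chain=np.array(chain, dtype=object),
        role=np.array(role, dtype=object), copy_index=np.array(copyi, dtype=int),
        mass=np.array(mass, dtype=float),
    )
    atoms.validate()

    # ---- annotation -------------------------------------------------------
    helices = HelixTable()
    for ch in ("A", "B"):
        for label in HELIX_LABELS:
            helices.helices[(ch, label)] = region_ranges[f"helix:{label}"]
        for cname in spec.corners:
            helices.corners[(ch, cname)] = region_ranges[f"corner:{cname}"]
    helices.validate()
    cavities = []
    for nm in sorted(CAVITY_NAMES):
        lo, hi = lining_ranges[nm]
        for ch in ("A", "B"):
            cav = CavityDefinition(name=nm, cutoff=spec.cavity_cutoff,
                                   residues=[(ch, r) for r in range(lo, hi + 1)])
            cav.validate()
            cav.resolve(atoms)
            cavities.append(cav)

    build_record = {
        "seed": seed,
        "n_atoms": n,
        "n_per_chain_protein": n_per_chain,
        "n_copies": spec.n_copies,
        "cavity_centers": {f"{ch}:{nm}": list(map(float, cavity_centers[(ch, nm)]))
                           for (ch, nm) in cavity_centers},
        "helix_ranges": {f"{ch}:{lab}": list(helices.helices[(ch, lab)])
                         for ch in ("A", "B") for lab in HELIX_LABELS},
        "rng": "numpy.default_rng",
    }

    return ToyProtein(
        spec=spec, atoms=atoms, template=np.asarray(pos), helices=helices,
        cavities=cavities, chain_centers=chain_centers,
        cavity_centers=cavity_centers, water_keys=water_keys,
        build_record=build_record,
    )


# ---------------------------------------------------------------------------
# portal feasibility (which exit directions classify as which portal)
# ---------------------------------------------------------------------------

def _region_atom_sets(protein: ToyProtein, chain: str):
    atoms = protein.atoms
    out = []
    for kind, label, (lo, hi) in protein.helices.chain_regions(chain):
        mask = ((atoms.chain == chain) & (atoms.resid >= lo) & (atoms.resid <= hi)
                & (atoms.role == "protein"))
        out.append((kind, label, protein.template[np.flatnonzero(mask)]))
    return out


def _portal_scan(protein: ToyProtein, chain: str, threshold: float = 5.0,
                 n_dirs: int = 800) -> dict:
    """Map portal label -> (best unit direction, exit radius r5, margin)."""
    key = ("scan", chain, threshold)
    if key in protein._portal_table:
        return protein._portal_table[key]
    R = protein.spec.shell_radius
    center = protein.chain_centers[chain]
    prot_idx = protein.atoms.protein_heavy
    tree = cKDTree(protein.template[prot_idx])
    prot_chain = protein.atoms.chain[prot_idx]
    dirs = fibonacci_sphere(n_dirs)
    if chain == "B":
        dirs = dirs * np.array([-1.0, 1.0, 1.0])
    radii = np.arange(R, R + 25.0, 0.5)
    pts = center[None, None, :] + radii[None, :, None] * dirs[:, None, :]
    d, _ = tree.query(pts.reshape(-1, 3))
    d = d.reshape(len(dirs), len(radii))
    regions = _region_atom_sets(protein, chain)

    best: dict[str, tuple] = {}
    for i, u in enumerate(dirs):
        above = np.flatnonzero(d[i] >= threshold)
        if above.size == 0 or above[0] == 0:
            continue
        j = above[0]
        # refine r5 by bisection on the true min distance
        lo_r, hi_r = radii[j - 1], radii[j]
        for _ in range(30):
            mid = 0.5 * (lo_r + hi_r)
            if tree.query(center + mid * u)[0] >= threshold:
                hi_r = mid
            else:
                lo_r = mid
        r5 = hi_r
        p_star = center + (r5 - 0.7) * u           # the scripted last-interior point
        dd, ii = tree.query(p_star)
        if prot_chain[ii] != chain:
            continue
        regs = sorted(
            [(float(np.min(np.linalg.norm(rpts - p_star, axis=1))), label, kind)
             for kind, label, rpts in regions],
            key=lambda t: (t[0], t[1]),
        )
        label = label_from_regions(regs, classify_bound=TrackingParams().classify_bound)
        if label.startswith("corner:"):
            margin = regs[1][0] - regs[0][0]
        else:
            hx = [r for r in regs if r[2] == "helix"]
            margin = (hx[2][0] - hx[1][0]) if len(hx) > 2 else np.inf
            # a corner closer than the 2nd helix makes the label noise-fragile
            if regs[0][2] == "corner" or (len(regs) > 1 and regs[1][2] == "corner"
                                          and regs[1][0] < hx[1][0]):
                margin = min(margin, hx[0][0] - regs[0][0])
        # outward path must stay beyond the threshold once escaped
        out_r = r5 + 0.2 + 0.9 * np.arange(0, 40)
        dout, _ = tree.query(center[None, :] + out_r[:, None] * u[None, :])
        if np.any(dout <= threshold):
            continue
        if label not in best or margin > best[label][2]:
            best[label] = (u, r5, margin)
    protein._portal_table[key] = best
    return best


def feasible_portals(protein: ToyProtein, chain: str = "A",
                     min_margin: float = 1.2) -> list[str]:
    """Portal labels that admit a robust scripted exit direction."""
    scan = _portal_scan(protein, chain)
    return sorted(lbl for lbl, (_, _, m) in scan.items()
                  if m >= min_margin and lbl != "unclassified")


def exit_geometry(protein: ToyProtein, chain: str, portal: str,
                  min_margin: float = 1.2):
    scan = _portal_scan(protein, chain)
    if portal not in scan or scan[portal][2] < min_margin:
        raise ScriptError(
            f"portal {portal!r} is not scriptable on chain {chain}; "
            f"feasible: {feasible_portals(protein, chain)}"
        )
    u, r5, _ = scan[portal]
    return u, r5


# ---------------------------------------------------------------------------
# event scripts
# ---------------------------------------------------------------------------

@dataclass
class Escape:
    portal: str
    frame: int


@dataclass
class Cross:
    dest: str
    arrive_frame: int
    returned: bool = False
    return_frame: int | None = None


@dataclass
class InterfaceStay:
    frame: int


@dataclass
class NoEscape:
    pass


@dataclass
class CopyScript:
    copy: int
    chain: str
    itinerary: list            # [(cavity name, dwell frames)]
    outcome: object


@dataclass
class EventScript:
    copies: list
    n_frames: int = 600
    sigma: float = 0.0
    seed: int = 0
    jitter_shell: float = 0.0
    transit_frames: int = 15


def _copy_waypoints(protein: ToyProtein, cs: CopyScript, script: EventScript):
    """(frame, xyz) waypoints for one copy; raises ScriptError on bad scripts."""
    T = script.transit_frames
    F = script.n_frames
    declared = {nm for (_, nm) in protein.cavity_centers}
    if not cs.itinerary:
        raise ScriptError(f"copy {cs.copy}: empty itinerary")
    wps: list[tuple[int, np.ndarray]] = []
    t = 0
    for i, (cav, dwell) in enumerate(cs.itinerary):
        if cav not in declared:
            raise ScriptError(f"copy {cs.copy}: undeclared cavity {cav!r}")
        p = protein.cavity_centers[(cs.chain, cav)]
        if i == 0:
            wps.append((0, p))
        else:
            wps.append((t, p))
        t += int(dwell)
        wps.append((t, p))
        t += T
    t_last = wps[-1][0]
    last_cav = cs.itinerary[-1][0]
    out = cs.outcome

    if isinstance(out, NoEscape):
        wps.append((F - 1, wps[-1][1]))
    elif isinstance(out, Escape):
        if out.frame < t_last + 20 or out.frame > F - 2:
            raise ScriptError(
                f"copy {cs.copy}: escape frame {out.frame} incompatible with "
                f"itinerary end {t_last} and length {F}"
            )
        u, r5 = exit_geometry(protein, cs.chain, out.portal)
        center = protein.chain_centers[cs.chain]
        # clearance-safe approach: radially out of the cavity to r_mid, then a
        # constant-radius arc to the exit direction (always >= r_mid - r_cav
        # from every cavity center), then outward along the exit ray
        r_mid = protein.spec.cavity_radius + protein.spec.cavity_cutoff + 0.8
        local_cav = protein.cavity_centers[(cs.chain, last_cav)] - center
        v = local_cav / np.linalg.norm(local_cav)
        avail = out.frame - 1 - t_last
        wps.append((t_last + max(2, int(0.2 * avail)), center + r_mid * v))
        ang = float(np.arccos(np.clip(np.dot(v, u), -1.0, 1.0)))
        if np.sin(ang) > 1e-6:
            for lam in (0.25, 0.5, 0.75):
                w = (np.sin((1 - lam) * ang) * v + np.sin(lam * ang) * u) / np.sin(ang)
                t_w = t_last + max(3, int((0.2 + 0.5 * lam) * avail))
                wps.append((t_w, center + r_mid * w))
        elif ang > 1.0:  # antipodal: detour through a perpendicular direction
            perp = np.cross(v, [0.0, 0.0, 1.0])
            if np.linalg.norm(perp) < 1e-6:
                perp = np.cross(v, [0.0, 1.0, 0.0])
            perp /= np.linalg.norm(perp)
            wps.append((t_last + max(3, int(0.45 * avail)), center + r_mid * perp))
        wps.append((out.frame - 1, center + (r5 - 0.7) * u))
        wps.append((out.frame, center + (r5 + 0.2) * u))
        wps.append((F - 1, center + (r5 + 0.2 + 0.9 * (F - 1 - out.frame)) * u))
    elif isinstance(out, Cross):
        if out.dest == cs.chain:
            raise ScriptError(f"copy {cs.copy}: crossing destination equals origin")
        mid = np.array([0.0, 1.0, 0.5])
        if out.arrive_frame < t_last + 2 * T + 5:
            raise ScriptError(f"copy {cs.copy}: arrive_frame too early")
        wps.append((t_last + T, mid))
        wps.append((t_last + T + 5, mid))
        dest_cav = protein.cavity_centers[(out.dest, last_cav)]
        wps.append((out.arrive_frame, dest_cav))
        if out.returned:
            rf = out.return_frame
            if rf is None or rf < out.arrive_frame + 30 or rf > F - 1:
                raise ScriptError(f"copy {cs.copy}: bad return_frame {rf}")
            wps.append((rf - 2 * T - 5, dest_cav))
            wps.append((rf - T - 5, mid))
            wps.append((rf - T, mid))
            wps.append((rf, protein.cavity_centers[(cs.chain, last_cav)]))
            wps.append((F - 1, protein.cavity_centers[(cs.chain, last_cav)]))
        else:
            wps.append((F - 1, dest_cav))
    elif isinstance(out, InterfaceStay):
        mid = np.array([0.0, 0.8, 0.4])
        arrive = max(out.frame, t_last + T)
        if arrive > F - 30:
            raise ScriptError(f"copy {cs.copy}: interface arrival too late")
        wps.append((arrive, mid))
        wps.append((F - 1, mid))
    else:
        raise ScriptError(f"copy {cs.copy}: unknown outcome {out!r}")

    # drop duplicate times, require strictly increasing
    clean = []
    for t_i, p_i in wps:
        if clean and t_i == clean[-1][0]:
            clean[-1] = (t_i, p_i)
            continue
        if clean and t_i < clean[-1][0]:
            raise ScriptError(f"copy {cs.copy}: waypoint times not increasing")
        clean.append((int(t_i), np.asarray(p_i, dtype=float)))
    _check_cavity_clearance(protein, cs, clean, F, T)
    return clean


def _check_cavity_clearance(protein: ToyProtein, cs: CopyScript, wps,
                            n_frames: int, transit: int) -> None:
    """Reject scripts whose paths stray into cavities they never declared.

    Keeps the itinerary the single source of truth for cavity occupancy
    (in particular for the last cavity before escape).
    """
    path = _interp_path(wps, n_frames)
    keys = sorted(protein.cavity_centers)
    dists = np.stack([np.linalg.norm(path - protein.cavity_centers[k], axis=1)
                      for k in keys], axis=1)          # (F, n_cavities)
    # tiny epsilon above the cutoff: enough to absorb float32 storage noise
    clearance = protein.spec.cavity_cutoff + 0.02
    last_cav = cs.itinerary[-1][0]

    # timeline of cavity visits
    t = 0
    bounds = []                                        # (arrive, depart, name)
    for cav, dwell in cs.itinerary:
        bounds.append((t, t + int(dwell), cav))
        t += int(dwell) + transit
    t_last = bounds[-1][1]

    def allowed_at(f: int) -> set:
        for i, (a, d, cav) in enumerate(bounds):
            if a <= f <= d:
                return {(cs.chain, cav)}
            if f < a:
                prev = bounds[i - 1][2] if i else cav
                return {(cs.chain, prev), (cs.chain, cav)}
        out = {(cs.chain, last_cav)}
        if isinstance(cs.outcome, Cross):
            out.add((cs.outcome.dest, last_cav))
        return out

    for f in range(n_frames):
        ok = allowed_at(f)
        for j, key in enumerate(keys):
            if key in ok:
                continue
            if dists[f, j] <= clearance:
                raise ScriptError(
                    f"copy {cs.copy}: path enters undeclared cavity "
                    f"{key[0]}:{key[1]} at frame {f} (d={dists[f, j]:.2f})"
                )


def _interp_path(wps, n_frames: int) -> np.ndarray:
    t = np.array([w[0] for w in wps], dtype=float)
    p = np.stack([w[1] for w in wps])
    frames = np.arange(n_frames, dtype=float)
    return np.column_stack([np.interp(frames, t, p[:, d]) for d in range(3)])


def script_trajectory(protein: ToyProtein, script: EventScript):
    """Render an :class:`EventScript` into a Trajectory + ground-truth log."""
    spec = protein.spec
    F = script.n_frames
    atoms = protein.atoms
    rng = np.random.default_rng(script.seed)

    seen = [cs.copy for cs in script.copies]
    if len(set(seen)) != len(seen):
        raise ScriptError("duplicate copy index in script")
    valid = set(atoms.ligand_copies)
    for cs in script.copies:
        if cs.copy not in valid:
            raise ScriptError(f"script references unknown copy {cs.copy}")
        if atoms.copy_chain(cs.copy) != cs.chain:
            raise ScriptError(f"copy {cs.copy} lives on chain "
                              f"{atoms.copy_chain(cs.copy)}, script says {cs.chain}")

    coords = np.repeat(protein.template[None, :, :], F, axis=0).astype(np.float64)

    # protein jitter (optional; exercises per-frame cavity centroids)
    prot_idx = np.flatnonzero(atoms.role == "protein")
    if script.jitter_shell > 0:
        coords[:, prot_idx, :] += rng.normal(0.0, script.jitter_shell,
                                             size=(F, prot_idx.size, 3))

    # ligand paths
    centers_noise_free: dict[int, np.ndarray] = {}
    bond = spec.o2_bond / 2.0
    for cs in script.copies:
        path = _interp_path(_copy_waypoints(protein, cs, script), F)
        centers_noise_free[cs.copy] = path
        idx = atoms.copy_atoms(cs.copy)
        for off, ai in zip((-bond, +bond), idx):
            coords[:, ai, :] = path + np.array([0.0, 0.0, off])
            if script.sigma > 0:
                coords[:, ai, :] += rng.normal(0.0, script.sigma, size=(F, 3))

    # waters: permanent stay home; transient leave for bulk at 60% of the run
    widx = {}
    for i in np.flatnonzero(atoms.role == "water"):
        widx.setdefault((str(atoms.chain[i]), int(atoms.resid[i])), []).append(i)
    water_truth = {}
    t_leave = int(round(0.6 * F))
    for w, key in enumerate(protein.water_keys):
        permanent = w < spec.n_waters_permanent
        if not permanent:
            bulk = np.array([0.0, 26.0 + 2.0 * w, 0.0])
            home = protein.template[widx[key][0]]
            for ai in widx[key]:
                off = protein.template[ai] - home
                coords[t_leave + 2:, ai, :] = bulk + off
                # two transition frames interpolate home -> bulk
                for j, lam in enumerate((0.4, 0.8)):
                    coords[t_leave + j, ai, :] = (1 - lam) * (home + off) + lam * (bulk + off)
        if script.sigma > 0:
            for ai in widx[key]:
                coords[:, ai, :] += rng.normal(0.0, min(script.sigma, 0.15), size=(F, 3))
        water_truth[f"{key[0]}:{key[1]}"] = 1.0 if permanent else t_leave / F

    traj = Trajectory(coords=coords.astype(np.float32), dt=10000.0 / F)
    truth = _ground_truth(protein, script, water_truth)
    if script.jitter_shell == 0:
        _verify_script(protein, script, centers_noise_free)
    return traj, truth


def _verify_script(protein: ToyProtein, script: EventScript, centers, threshold=5.0):
    """Assert the noise-free paths honour the escape criterion exactly."""
    tree = cKDTree(protein.template[protein.atoms.protein_heavy])
    for cs in script.copies:
        d, _ = tree.query(centers[cs.copy])
        if isinstance(cs.outcome, Escape):
            f = cs.outcome.frame
            if not np.all(d[:f] <= threshold - 0.1):
                bad = int(np.argmax(d[:f] > threshold - 0.1))
                raise ScriptError(
                    f"copy {cs.copy}: interior frame {bad} too close to the "
                    f"surface criterion (d={d[bad]:.2f})"
                )
            if not np.all(d[f:] > threshold + 0.05):
                raise ScriptError(f"copy {cs.copy}: escaped path dips back under threshold")
        else:
            if not np.all(d <= threshold - 0.1):
                bad = int(np.argmax(d > threshold - 0.1))
                raise ScriptError(
                    f"copy {cs.copy}: non-escaping path leaves the surface "
                    f"at frame {bad} (d={d[bad]:.2f})"
                )


def _ground_truth(protein: ToyProtein, script: EventScript, water_truth) -> dict:
    copies = {}
    portal_counts: dict[str, int] = {}
    crossings = []
    n_res = 0
    n_non = 0
    scripted = {cs.copy for cs in script.copies}
    for k in protein.atoms.ligand_copies:
        if k not in scripted:
            n_non += 1  # unscripted copies sit at their seed cavity: non-escapers
            copies[str(k)] = {"chain": protein.atoms.copy_chain(k),
                              "outcome": "non_escape", "last_cavity": "B"}
    for cs in script.copies:
        rec = {"chain": cs.chain, "itinerary": [[c, int(d)] for c, d in cs.itinerary]}
        out = cs.outcome
        last_cav = cs.itinerary[-1][0] if cs.itinerary else None
        if isinstance(out, Escape):
            rec.update(outcome="escape", portal=out.portal, frame=int(out.frame),
                       last_cavity=last_cav)
            portal_counts[out.portal] = portal_counts.get(out.portal, 0) + 1
        elif isinstance(out, Cross):
            dest = cs.chain if out.returned else out.dest
            rec.update(outcome="crossing", origin=cs.chain, destination=dest,
                       returned=out.returned, last_cavity=last_cav)
            crossings.append({"copy": cs.copy, "origin": cs.chain,
                              "destination": dest, "returned": out.returned})
            n_non += 1
        elif isinstance(out, InterfaceStay):
            rec.update(outcome="interface_resident", last_cavity=last_cav)
            n_res += 1
        else:
            rec.update(outcome="non_escape", last_cavity=last_cav)
            n_non += 1
        copies[str(cs.copy)] = rec
    return {
        "seed": script.seed,
        "sigma": script.sigma,
        "n_frames": script.n_frames,
        "copies": copies,
        "waters": water_truth,
        "expected": {
            "portal_counts": portal_counts,
            "non_escaped": n_non,
            "interface_resident": n_res,
            "crossings": crossings,
            "n_copies": len(protein.atoms.ligand_copies),
        },
    }


# ---------------------------------------------------------------------------
# canned scripts
# ---------------------------------------------------------------------------

def random_script(protein: ToyProtein, seed: int, n_frames: int = 600,
                  sigma: float = 0.0) -> EventScript:
    """A randomized 14-copy script covering every event class."""
    rng = np.random.default_rng(seed)
    portals = feasible_portals(protein)
    if not portals:
        raise ScriptError("toy system admits no scriptable portals")
    by_chain = protein.atoms.copies_by_chain()
    copies = []
    all_copies = [(ch, k) for ch in sorted(by_chain) for k in by_chain[ch]]
    outcomes = (["escape"] * 9 + ["cross", "cross_back", "interface", "stay", "stay"])
    outcomes = list(rng.permutation(np.array(outcomes, dtype=object)))[:len(all_copies)]
    probe = EventScript(copies=[], n_frames=n_frames, sigma=0.0, seed=seed)
    for (ch, k), kind in zip(all_copies, outcomes):
        other = "B" if ch == "A" else "A"
        cs = None
        dwell_hi = max(45, min(110, (n_frames - 150) // 2))
        for _attempt in range(80):
            n_cav = int(rng.integers(1, 3))
            itin = [(str(rng.choice(CAVITY_NAMES)), int(rng.integers(40, dwell_hi)))
                    for _ in range(n_cav)]
            t_last = sum(d for _, d in itin) + 15 * (len(itin) - 1)
            if t_last > n_frames - 130:
                continue  # itinerary leaves no room for the outcome
            if kind == "escape":
                f = int(rng.integers(t_last + 60, n_frames - 20))
                out = Escape(portal=str(rng.choice(portals)), frame=f)
            elif kind == "cross":
                out = Cross(dest=other, arrive_frame=t_last + 50)
            elif kind == "cross_back":
                out = Cross(dest=other, arrive_frame=t_last + 50, returned=True,
                            return_frame=min(t_last + 200, n_frames - 60))
            elif kind == "interface":
                out = InterfaceStay(frame=t_last + 30)
            else:
                out = NoEscape()
            candidate = CopyScript(copy=k, chain=ch, itinerary=itin, outcome=out)
            try:
                _copy_waypoints(protein, candidate, probe)
            except ScriptError:
                continue  # e.g. exit leg grazes an undeclared cavity; resample
            cs = candidate
            break
        if cs is None:
            raise ScriptError(f"could not script copy {k} as {kind!r} after 80 attempts")
        copies.append(cs)
    return EventScript(copies=copies, n_frames=n_frames, sigma=sigma, seed=seed)


def wt_like_script(protein: ToyProtein, n_frames: int = 600, sigma: float = 0.0,
                   seed: int = 0) -> EventScript:
    """The wild-type-like mix: 5 B-G, 4 E-F, 2 B-E, 1 C-G escapes plus two
    copies entering the interface (one crossing, one staying)."""
    plan_a = [("B-G", 80), ("B-G", 150), ("B-G", 220), ("E-F", 120), ("E-F", 200),
              ("B-E", 90), ("cross", None)]
    plan_b = [("B-G", 110), ("B-G", 180), ("E-F", 140), ("E-F", 260),
              ("B-E", 160), ("C-G", 130), ("stay_interface", None)]
    copies = []
    k = 0
    for ch, plan in (("A", plan_a), ("B", plan_b)):
        for portal, dwell in plan:
            k += 1
            if portal == "cross":
                itin = [("Xe4", 60)]
                out = Cross(dest="B" if ch == "A" else "A", arrive_frame=150)
            elif portal == "stay_interface":
                itin = [("Xe2", 60)]
                out = InterfaceStay(frame=120)
            else:
                itin = [("Xe4", dwell // 2), ("Xe2", dwell // 2)]
                t_last = dwell + 15
                out = Escape(portal=portal, frame=t_last + 120)
                # spread escape frames so the mix is not synchronous
                out.frame = min(out.frame + 30 * (k % 5), n_frames - 20)
            copies.append(CopyScript(copy=k, chain=ch, itinerary=itin, outcome=out))
    return EventScript(copies=copies, n_frames=n_frames, sigma=sigma, seed=seed)


def benchmark_run(seed: int, sigma: float = 0.0, n_frames: int = 600,
                  spec: ToyProteinSpec | None = None):
    """Build a toy system, script it randomly, and render the trajectory."""
    protein = build_toy_system(spec, seed=seed)
    script = random_script(protein, seed=seed, n_frames=n_frames, sigma=sigma)
    traj, truth = script_trajectory(protein, script)
    return protein, traj, truth


# ---------------------------------------------------------------------------
# serialization + scoring
# ---------------------------------------------------------------------------

def write_toy_bundle(protein: ToyProtein, traj: Trajectory, truth: dict, outdir) -> dict:
    """Write toy.psf / toy.dcd / annotation.txt / ground_truth.json."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "psf": write_psf(protein.atoms, outdir / "toy.psf"),
        "dcd": write_dcd(traj.coords, outdir / "toy.dcd", dt=traj.dt),
        "annotation": save_annotation(protein.helices, protein.cavities,
                                      outdir / "annotation.txt"),
    }
    gt = outdir / "ground_truth.json"

    def _np_safe(o):
        if isinstance(o, np.integer):
            return int(o)
        if isinstance(o, np.floating):
            return float(o)
        raise TypeError(f"not JSON serializable: {type(o)}")

    gt.write_text(json.dumps(truth, indent=2, sort_keys=True, default=_np_safe) + "\n")
    paths["ground_truth"] = gt
    return {k: str(v) for k, v in paths.items()}


def score_recovery(truth: dict, result, frame_tolerance: int = 10) -> dict:
    """Compare an :class:`~oxypath.tracking.AnalysisResult` with ground truth.

    Returns per-category (n_true, n_recovered) counts; portals must match
    exactly, escape frames within ``frame_tolerance``.
    """
    escapes = {e.copy: e for e in result.escapes}
    crossings = {c.copy: c for c in result.crossings}
    score = {cat: [0, 0] for cat in
             ("portal", "frame", "last_cavity", "crossing", "interface_resident",
              "non_escape")}
    for kstr, rec in truth["copies"].items():
        k = int(kstr)
        if rec["outcome"] == "escape":
            ev = escapes.get(k)
            for cat, ok in (
                ("portal", ev is not None and ev.portal == rec["portal"]),
                ("frame", ev is not None and abs(ev.frame - rec["frame"]) <= frame_tolerance),
                ("last_cavity", ev is not None and ev.last_cavity == rec["last_cavity"]),
            ):
                score[cat][0] += 1
                score[cat][1] += bool(ok)
        elif rec["outcome"] == "crossing":
            cr = crossings.get(k)
            ok = (cr is not None and cr.origin == rec["origin"]
                  and cr.destination == rec["destination"]
                  and cr.returned == rec["returned"] and k not in escapes)
            score["crossing"][0] += 1
            score["crossing"][1] += bool(ok)
        elif rec["outcome"] == "interface_resident":
            score["interface_resident"][0] += 1
            score["interface_resident"][1] += bool(k in result.residents)
        else:
            ok = k not in escapes and k not in result.residents
            score["non_escape"][0] += 1
            score["non_escape"][1] += bool(ok)
    return score
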