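"""Interfacial-water identification, hydrogen-bond graphs, and persistence.

Interface membership uses a dual-proximity rule: a water belongs to the
subunit interface in a frame when its oxygen lies within ``d_int`` (default
4.0 Å) of protein heavy atoms of *both* chains.  Hydrogen bonds use the
conventional geometric criteria (donor-acceptor heavy-atom distance <=
3.5 Å, donor-H...acceptor angle >= 150°); when the topology carries no
hydrogens the graph falls back to distance-only edges and says so in its
metadata.  Waters are tracked by residue identity, so exchange events count
against persistence.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._geometry import min_dist_to_set
from .errors import ParameterError, TopologyError
from .trajio import ROLE_PROTEIN, ROLE_WATER, AtomTable, Trajectory

__all__ = [
    "WaterParams",
    "HBondCandidate",
    "interfacial_waters",
    "water_candidates",
    "hydrogen_bonds",
    "persistent_water_count",
]


@dataclass
class WaterParams:
    d_int: float = 4.0        # Å, dual-proximity interface cutoff
    d_hb: float = 3.5         # Å, donor-acceptor heavy-atom distance
    angle_min: float = 150.0  # degrees, donor-H...acceptor angle
    residence_min: float = 1.0

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in ("d_int", "d_hb", "angle_min", "residence_min")}


def _water_index(atoms: AtomTable) -> dict[tuple[str, int], dict]:
    """(chain, resid) -> {'O': oxygen atom index, 'H': [hydrogen indices]}."""
    out: dict[tuple[str, int], dict] = {}
    for i in np.flatnonzero(atoms.role == ROLE_WATER):
        key = (str(atoms.chain[i]), int(atoms.resid[i]))
        rec = out.setdefault(key, {"O": None, "H": []})
        if atoms.element[i] == "O":
            rec["O"] = i
        elif atoms.element[i] == "H":
            rec["H"].append(i)
    return {k: v for k, v in out.items() if v["O"] is not None}


def interfacial_waters(frame_coords: np.ndarray, atoms: AtomTable,
                       d_int: float = 4.0,
                       box: np.ndarray | None = None) -> set[tuple[str, int]]:
    """Waters whose oxygen is within ``d_int`` of both chains' protein heavy atoms."""
    chains = atoms.protein_chains
    if len(chains) < 2:
        raise TopologyError("interfacial waters are undefined without two protein chains")
    widx = _water_index(atoms)
    if not widx:
        warnings.warn("topology contains no water molecules; empty interfacial set")
        return set()
    fc = np.asarray(frame_coords, dtype=float)
    keys = list(widx)
    opos = fc[[widx[k]["O"] for k in keys]]
    prot = atoms.protein_heavy
    members = np.ones(len(keys), dtype=bool)
    for c in chains[:2]:
        cidx = prot[np.array([atoms.chain[i] == c for i in prot])]
        members &= min_dist_to_set(opos, fc[cidx], box) <= d_int
    return {keys[i] for i in np.flatnonzero(members)}


@dataclass
class HBondCandidate:
    """A donor/acceptor heavy atom with its attached hydrogens."""

    heavy: int
    hydrogens: tuple[int, ...] = ()
    is_donor: bool = True
    is_acceptor: bool = True
    tag: str = ""


def water_candidates(atoms: AtomTable, restrict: set[tuple[str, int]] | None = None
                     ) -> list[HBondCandidate]:
    """Hydrogen-bond candidates for every (optionally restricted) water."""
    out = []
    for key, rec in _water_index(atoms).items():
        if restrict is not None and key not in restrict:
            continue
        out.append(HBondCandidate(heavy=int(rec["O"]), hydrogens=tuple(rec["H"]),
                                  tag=f"{key[0]}:{key[1]}"))
    return out


def interface_protein_candidates(atoms: AtomTable, frame_coords: np.ndarray,
                                 d_int: float = 4.0) -> list[HBondCandidate]:
    """Interface-facing protein N/O atoms, as acceptor-only candidates.

    Donor hydrogens are not resolvable without connectivity, so protein
    sites participate through distance+angle tests on the water side only.
    """
    fc = np.asarray(frame_coords, dtype=float)
    chains = atoms.protein_chains
    prot = atoms.protein_heavy
    out = []
    polar = np.array([atoms.element[i] in ("N", "O") for i in prot])
    for i in prot[polar]:
        other = [c for c in chains if c != atoms.chain[i]]
        if not other:
            continue
        oidx = prot[np.array([atoms.chain[j] == other[0] for j in prot])]
        if float(min_dist_to_set(fc[i][None, :], fc[oidx])[0]) <= d_int:
            out.append(HBondCandidate(heavy=int(i), hydrogens=(), is_donor=False,
                                      tag=f"prot:{atoms.chain[i]}:{atoms.resid[i]}"))
    return out


def _angle_deg(a: np.ndarray, b: np.ndarray, c: np.ndarray) -> float:
    """Angle a-b-c at vertex b, degrees."""
    v1, v2 = a - b, c - b
    cosv = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
    return float(np.degrees(np.arccos(np.clip(cosv, -1.0, 1.0))))


def hydrogen_bonds(frame_coords: np.ndarray, candidates: list[HBondCandidate],
                   d_hb: float = 3.5, angle_min: float = 150.0):
    """Per-frame hydrogen-bond graph over ``candidates``.

    Edge iff the heavy-atom distance is <= ``d_hb`` and some donor
    hydrogen (on either partner) makes a D-H...A angle >= ``angle_min``.
    Returns a :class:`networkx.Graph` whose graph attributes record the
    criteria and whether the distance-only fallback was used.
    """
    import networkx as nx

    fc = np.asarray(frame_coords, dtype=float)
    any_h = any(c.hydrogens for c in candidates)
    g = nx.Graph(d_hb=d_hb, angle_min=angle_min, distance_only=not any_h)
    for c in candidates:
        g.add_node(c.heavy, tag=c.tag)
    for i, ci in enumerate(candidates):
        for cj in candidates[i + 1:]:
            d = float(np.linalg.norm(fc[ci.heavy] - fc[cj.heavy]))
            if d > d_hb:
                continue
            if not any_h:
                g.add_edge(ci.heavy, cj.heavy, distance=d)
                continue
            ok = False
            for donor, acceptor in ((ci, cj), (cj, ci)):
                if not (donor.is_donor and acceptor.is_acceptor):
                    continue
                for h in donor.hydrogens:
                    ang = _angle_deg(fc[donor.heavy], fc[h], fc[acceptor.heavy])
                    if ang >= angle_min:
                        ok = True
                        break
                if ok:
                    break
            if ok:
                g.add_edge(ci.heavy, cj.heavy, distance=d)
    return g


def persistent_water_count(trajectory: Trajectory, atoms: AtomTable,
                           d_int: float = 4.0, residence_min: float = 1.0
                           ) -> tuple[int, pd.DataFrame]:
    """Number of waters resident in the interface for >= ``residence_min``
    of the frames, plus the per-water residence table."""
    if not (0.0 < residence_min <= 1.0):
        raise ParameterError(f"residence_min must be in (0, 1], got {residence_min}")
    if trajectory.n_frames < 2:
        raise ParameterError("persistence needs at least 2 frames")
    widx = _water_index(atoms)
    keys = sorted(widx)
    flagged = {k: 0 for k in keys}
    F = trajectory.n_frames
    for f in range(F):
        members = interfacial_waters(trajectory.coords[f], atoms, d_int,
                                     trajectory.frame_box(f))
        for k in members:
            flagged[k] += 1
    records = pd.DataFrame(
        {
            "chain": [k[0] for k in keys],
            "resid": [k[1] for k in keys],
            "frames_interfacial": [flagged[k] for k in keys],
            "residence_fraction": [flagged[k] / F for k in keys],
        }
    )
    records["persistent"] = records["residence_fraction"] >= residence_min
    return int(records["persistent"].sum()), records
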