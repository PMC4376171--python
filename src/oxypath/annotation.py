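"""Helix/corner region tables and internal-cavity definitions.

The annotation config is flat text::

    helix  <chain> <label> <start> <end>
    corner <chain> <name>  <start> <end>
    cavity <name> <cutoff>
      <chain> <resid>
      ...
    end

Helix labels are single letters A..H; corner pseudo-regions (e.g. the FG
corner) carry free-form names.  Cavities are declared, never discovered:
a cavity is the set of residues lining it plus a membership cutoff, and
its per-frame center is the unweighted centroid of the lining residues'
heavy atoms, so cavities track protein deformation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np

from .errors import AnnotationError
from .trajio import AtomTable

__all__ = [
    "HelixTable",
    "CavityDefinition",
    "load_annotation",
    "parse_annotation",
    "save_annotation",
    "assign_helix",
    "cavity_centroid",
    "default_hbi_annotation",
]

HELIX_LABELS = tuple("ABCDEFGH")


@dataclass
class HelixTable:
    """(chain, label) -> inclusive residue range, for helices and corners."""

    helices: dict[tuple[str, str], tuple[int, int]] = field(default_factory=dict)
    corners: dict[tuple[str, str], tuple[int, int]] = field(default_factory=dict)

    def validate(self) -> None:
        for (chain, label), (lo, hi) in {**self.helices, **self.corners}.items():
            if lo > hi:
                raise AnnotationError(f"empty range for {label} on chain {chain}: {lo}..{hi}")
        by_chain: dict[str, list] = {}
        for (chain, label), rng in self.helices.items():
            by_chain.setdefault(chain, []).append((rng, label))
        for chain, ranges in by_chain.items():
            ranges.sort()
            for (r1, l1), (r2, l2) in zip(ranges, ranges[1:]):
                if r2[0] <= r1[1]:
                    raise AnnotationError(
                        f"overlapping helix ranges on chain {chain}: "
                        f"{l1} {r1} and {l2} {r2}"
                    )

    @property
    def chains(self) -> list[str]:
        return sorted({c for c, _ in list(self.helices) + list(self.corners)})

    def assign(self, chain: str, resid: int) -> str | None:
        """Helix label containing ``resid``, or None (loops/corners)."""
        if chain not in self.chains:
            raise AnnotationError(f"unknown chain {chain!r}; annotated chains: {self.chains}")
        for (c, label), (lo, hi) in self.helices.items():
            if c == chain and lo <= resid <= hi:
                return label
        return None

    def chain_regions(self, chain: str) -> list[tuple[str, str, tuple[int, int]]]:
        """All (kind, label, range) regions of a chain; kind is 'helix' or 'corner'."""
        out = [("helix", lab, rng) for (c, lab), rng in self.helices.items() if c == chain]
        out += [("corner", lab, rng) for (c, lab), rng in self.corners.items() if c == chain]
        return sorted(out, key=lambda t: (t[0], t[1]))


@dataclass
class CavityDefinition:
    """A named internal cavity declared by its lining residues."""

    name: str
    cutoff: float
    residues: list[tuple[str, int]]  # (chain, resid)
    _atom_idx: np.ndarray | None = field(default=None, repr=False, compare=False)

    def validate(self) -> None:
        if self.cutoff <= 0:
            raise AnnotationError(f"cavity {self.name}: cutoff must be > 0")
        if len(self.residues) < 3:
            raise AnnotationError(
                f"cavity {self.name}: needs >= 3 lining residues, got {len(self.residues)}"
            )

    @property
    def chain(self) -> str:
        chains = {c for c, _ in self.residues}
        if len(chains) != 1:
            return "*"  # cavities may straddle the interface in principle
        return next(iter(chains))

    def resolve(self, atoms: AtomTable) -> np.ndarray:
        """Heavy-atom indices of the lining residues (cached)."""
        if self._atom_idx is None:
            idx = []
            for chain, resid in self.residues:
                ai = atoms.residue_atoms(chain, resid, heavy_only=True)
                if ai.size == 0:
                    raise AnnotationError(
                        f"cavity {self.name}: residue {chain}:{resid} absent from topology"
                    )
                idx.append(ai)
            self._atom_idx = np.concatenate(idx)
        return self._atom_idx


def assign_helix(chain: str, resid: int, table: HelixTable) -> str | None:
    """Deterministic helix lookup; residues outside all ranges map to None."""
    return table.assign(chain, resid)


def cavity_centroid(frame_coords: np.ndarray, cavity: CavityDefinition, atoms: AtomTable) -> np.ndarray:
    """Unweighted mean of the lining residues' heavy-atom coordinates in a frame."""
    idx = cavity.resolve(atoms)
    return np.asarray(frame_coords, dtype=float)[idx].mean(axis=0)


# ---------------------------------------------------------------------------
# config parsing
# ---------------------------------------------------------------------------

def parse_annotation(text: str) -> tuple[HelixTable, list[CavityDefinition]]:
    table = HelixTable()
    cavities: list[CavityDefinition] = []
    current: CavityDefinition | None = None
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        tok = line.split()
        try:
            if current is not None:
                if tok[0].lower() == "end":
                    current.validate()
                    cavities.append(current)
                    current = None
                else:
                    current.residues.append((tok[0], int(tok[1])))
                continue
            kind = tok[0].lower()
            if kind == "helix":
                chain, label, lo, hi = tok[1], tok[2], int(tok[3]), int(tok[4])
                key = (chain, label)
                if key in table.helices:
                    raise AnnotationError(f"duplicate helix {label} on chain {chain}")
                table.helices[key] = (lo, hi)
            elif kind == "corner":
                chain, label, lo, hi = tok[1], tok[2], int(tok[3]), int(tok[4])
                table.corners[(chain, label)] = (lo, hi)
            elif kind == "cavity":
                current = CavityDefinition(name=tok[1], cutoff=float(tok[2]), residues=[])
            else:
                raise AnnotationError(f"unknown directive {tok[0]!r}")
        except AnnotationError:
            raise
        except Exception as exc:
            raise AnnotationError(f"annotation parse error at line {lineno}: {raw!r} ({exc})") from exc
    if current is not None:
        raise AnnotationError(f"unterminated cavity block {current.name!r} (missing 'end')")
    table.validate()
    return table, cavities


def load_annotation(path, atoms: AtomTable | None = None) -> tuple[HelixTable, list[CavityDefinition]]:
    """Parse an annotation file and optionally validate it against a topology."""
    path = Path(path)
    if not path.exists():
        raise AnnotationError(f"annotation file not found: {path}")
    table, cavities = parse_annotation(path.read_text())
    if atoms is not None:
        for cav in cavities:
            cav.resolve(atoms)  # raises naming the missing residue
    return table, cavities


def save_annotation(table: HelixTable, cavities: list[CavityDefinition], path) -> Path:
    path = Path(path)
    lines = []
    for (chain, label), (lo, hi) in sorted(table.helices.items()):
        lines.append(f"helix {chain} {label} {lo} {hi}")
    for (chain, label), (lo, hi) in sorted(table.corners.items()):
        lines.append(f"corner {chain} {label} {lo} {hi}")
    for cav in cavities:
        lines.append(f"cavity {cav.name} {cav.cutoff:g}")
        for chain, resid in cav.residues:
            lines.append(f"  {chain} {resid}")
        lines.append("end")
    path.write_text("\n".join(lines) + "\n")
    return path


def default_hbi_annotation() -> tuple[HelixTable, list[CavityDefinition]]:
    """The shipped default HbI helix/cavity table (chains A and B).

    Helix boundaries follow the 3SDH globin fold; xenon-cavity linings
    follow the xenon-binding crystallography on this protein.  Both are
    explicitly replaceable via ``load_annotation``.
    """
    text = resources.files("oxypath.data").joinpath("hbi_annotation.txt").read_text()
    return parse_annotation(text)
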