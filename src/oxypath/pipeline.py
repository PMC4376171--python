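"""End-to-end per-simulation analysis driver used by the CLI."""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

from .annotation import default_hbi_annotation, load_annotation
from .errors import OxypathError
from .tracking import TrackingParams, analyze_run
from .trajio import DEFAULT_LIGAND_PATTERN, read_topology, read_trajectory, write_event_table
from .water import WaterParams, persistent_water_count

log = logging.getLogger("oxypath")

__all__ = ["RunConfig", "run_analysis"]


@dataclass
class RunConfig:
    """Fully resolved analysis configuration; serialized into every output."""

    topology: str
    trajectory: str
    annotation: str | None = None       # None -> shipped HbI default
    outdir: str = "oxypath_out"
    label: str = ""
    ligand_pattern: str = DEFAULT_LIGAND_PATTERN
    tracking: TrackingParams = field(default_factory=TrackingParams)
    water: WaterParams = field(default_factory=WaterParams)
    analyze_waters: bool = True
    seed: int = 0

    def to_dict(self) -> dict:
        d = asdict(self)
        d["tracking"] = self.tracking.to_dict()
        d["water"] = self.water.to_dict()
        return d


def _cavity_segments(track) -> list[tuple[str, int, int]]:
    segs = []
    cur = None
    for f, lab in enumerate(track.cavity if track.cavity is not None else []):
        if lab is None:
            cur = None
            continue
        if cur is not None and cur[0] == lab and cur[2] == f - 1:
            cur[2] = f
        else:
            cur = [lab, f, f]
            segs.append(cur)
    return [(s[0], s[1], s[2]) for s in segs]


def _report_text(summary, n_persistent: int | None, config: RunConfig) -> str:
    parts = [f"Simulation {summary.label or config.topology}:"]
    total_esc = sum(summary.portal_counts.values())
    if total_esc:
        portals = ", ".join(f"{v} via {k}" for k, v in
                            sorted(summary.portal_counts.items(), key=lambda kv: -kv[1]))
        parts.append(f"{total_esc} of {summary.n_copies} ligand copies escaped ({portals}).")
    else:
        parts.append(f"No ligand copies escaped out of {summary.n_copies}.")
    parts.append(f"{summary.non_escaped} copies never escaped; "
                 f"{summary.interface_resident} finished resident in the subunit interface.")
    if summary.crossings:
        descr = "; ".join(
            f"copy {c.copy} {c.origin}->{c.destination}"
            + (" (returned)" if c.returned else "")
            for c in summary.crossings
        )
        parts.append(f"Subunit crossings: {descr}.")
    else:
        parts.append("No subunit crossings detected.")
    if n_persistent is not None:
        parts.append(f"{n_persistent} interfacial waters stayed resident for "
                     f">= {config.water.residence_min:.0%} of the run.")
    return " ".join(parts) + "\n"


def run_analysis(config: RunConfig) -> dict:
    """Run every analysis stage and write the report bundle.

    Returns a dict with the output paths and the in-memory summary.
    Raises ``OxypathError`` subclasses naming the failing stage.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    log.info("stage: topology (%s)", config.topology)
    atoms = read_topology(config.topology, config.ligand_pattern)
    log.info("stage: trajectory (%s)", config.trajectory)
    traj = read_trajectory(config.trajectory, atoms)
    log.info("stage: annotation")
    if config.annotation:
        helices, cavities = load_annotation(config.annotation, atoms)
    else:
        helices, cavities = default_hbi_annotation()
        for cav in cavities:
            cav.resolve(atoms)

    log.info("stage: ligand tracking (%d frames, %d copies)",
             traj.n_frames, len(atoms.ligand_copies))
    result = analyze_run(traj, atoms, helices, cavities,
                         config.tracking, label=config.label)
    result.summary.validate()

    n_persistent = None
    water_records = None
    if config.analyze_waters and atoms.water_oxygens.size \
            and len(atoms.protein_chains) >= 2:
        log.info("stage: water network")
        n_persistent, water_records = persistent_water_count(
            traj, atoms, config.water.d_int, config.water.residence_min)

    log.info("stage: reports")
    events = list(result.escapes) + list(result.crossings)
    tsv, js = write_event_table(events, result.summary, outdir)

    # embed full provenance in the summary JSON
    payload = result.summary.to_dict()
    payload["config"] = config.to_dict()
    if n_persistent is not None:
        payload["persistent_interfacial_waters"] = n_persistent
    js.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")

    cav_path = outdir / "cavity_itinerary.tsv"
    with cav_path.open("w") as fh:
        fh.write("copy\tcavity\tstart_frame\tend_frame\n")
        for tr in result.tracks:
            for cav, lo, hi in _cavity_segments(tr):
                fh.write(f"{tr.copy}\t{cav}\t{lo}\t{hi}\n")

    water_path = None
    if water_records is not None:
        water_path = outdir / "water_residence.tsv"
        water_records.to_csv(water_path, sep="\t", index=False)

    report_path = outdir / "report.txt"
    report_path.write_text(_report_text(result.summary, n_persistent, config))

    return {
        "events_tsv": str(tsv),
        "summary_json": str(js),
        "cavity_tsv": str(cav_path),
        "water_tsv": None if water_path is None else str(water_path),
        "report_txt": str(report_path),
        "summary": result.summary,
        "result": result,
        "persistent_waters": n_persistent,
    }
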