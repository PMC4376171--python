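"""Locating and analyzing the deposited HbI LESMD dataset, when present.

The deposited trajectories (PSF + DCD per simulation, coded by source PDB
id) are not redistributable inside this repository; place them under
``data/deposited/`` (any nesting) to enable the full-data analyses.  File
names must contain the PDB code, e.g. ``3sdh*.psf`` / ``3sdh*.dcd``.
"""

from __future__ import annotations

from pathlib import Path

from .pipeline import RunConfig, run_analysis

#: simulation label -> PDB code used in the deposited file names
DATASET_CODES = {
    "WT": "3sdh",
    "F97L": "2av0",
    "F97V": "2auq",
    "M37V": "2grh",
    "M37F": "2r4w",
    "I114F": "1jwn",
    "I25W": "2r4z",
}


def find_deposited(label: str, root: str | Path = "data/deposited"):
    """(psf, dcd) paths for a simulation label, or None if not present."""
    code = DATASET_CODES[label].lower()
    root = Path(root)
    if not root.is_dir():
        return None
    psfs = sorted(p for p in root.rglob("*.psf") if code in p.name.lower())
    dcds = sorted(p for p in root.rglob("*.dcd") if code in p.name.lower())
    if not psfs or not dcds:
        return None
    return psfs[0], dcds[0]


def analyze_deposited(label: str, root: str | Path = "data/deposited",
                      outdir: str | Path = "scratch/deposited_out", **config_kw):
    """Default-parameter analysis of one deposited simulation.

    Returns the ``run_analysis`` output dict, or None when the dataset is
    not available locally.
    """
    found = find_deposited(label, root)
    if found is None:
        return None
    psf, dcd = found
    config = RunConfig(topology=str(psf), trajectory=str(dcd),
                       outdir=str(Path(outdir) / label), label=label, **config_kw)
    return run_analysis(config)
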