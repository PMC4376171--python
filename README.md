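# oxypath

Analysis toolkit for multi-copy ligand escape in dimeric globin MD
trajectories. Given a PSF/PDB topology and a DCD trajectory carrying
several non-interacting O₂ copies (the locally-enhanced-sampling setup:
14 copies, 7 per subunit), it reconstructs, per copy:

- the **surface-escape event** (first durable excursion > 5 Å from the
  protein surface, operationalized as minimum distance to any protein
  heavy atom);
- the **escape portal**, labelled by the two nearest globin-fold helices
  at the last interior frame (`B-G`, `E-F`, …), with corner pseudo-regions
  (`corner:FG`), `interface`, and `unclassified` fallbacks;
- the **cavity itinerary** through declared internal cavities
  (B / Xe1 / Xe2 / Xe4 by default) and the last cavity visited before escape;
- **subunit crossings** (with return detection) and interface residency;
- the per-simulation **pathway summary** (portal counts + non-escapers +
  interface residents, which always sum to the copy count).

A second stage measures the **interfacial water network**: dual-proximity
interfacial waters, per-frame hydrogen-bond graphs, and residence
persistence across the run.

Two generators make every stage testable without external data:

- `oxypath.synthetic` — scripted two-chain toy systems with exact
  ground truth (cavity itineraries, portal exits, crossings, interfacial
  waters), written in the same PSF/DCD formats the readers consume;
- `oxypath.les` — a minimal BAOAB-Langevin implementation of the LES
  copy-scaling contract (N copies, mutual interaction zero, environment
  coupling exactly 1/N) on a cage potential with portal depressions.

## CLI

```bash
# analyze one simulation (annotation defaults to the shipped HbI table)
oxypath analyze --topology wt.psf --trajectory wt.dcd --out out/ --label WT

# generate a scripted synthetic bundle with ground truth
oxypath simulate-toy --seed 1 --preset wt-like --out toy/

# analyze it back (recovers the script exactly at sigma = 0)
oxypath analyze --topology toy/toy.psf --trajectory toy/toy.dcd \
    --annotation toy/annotation.txt --out toy_out/

# LES sampling-enhancement demonstration (N=14 vs N=1 first passage)
oxypath les-demo --seed 1 --out les.json

# annotation sanity check
oxypath validate-annotation --annotation toy/annotation.txt --topology toy/toy.psf
```

`analyze` writes `events.tsv`, `summary.json` (with the full resolved
parameter set embedded), `cavity_itinerary.tsv`, `water_residence.tsv`
and a human-readable `report.txt`. All thresholds (escape distance,
persistence, crossing dwell, interface margin, water cutoffs) are flags;
identical inputs and parameters give byte-identical reports.

## Annotation format

Flat text, shipped default in `src/oxypath/data/hbi_annotation.txt`:

```
helix  A E 55 76          # chain, helix label, inclusive residue range
corner A FG 97 100        # corner pseudo-region
cavity Xe4 4.5            # cavity name, membership cutoff (Å)
  A 25
  A 32
  ...
end
```

Cavity centers are recomputed per frame as the centroid of the lining
residues' heavy atoms, so cavities follow protein deformation. The
shipped helix boundaries and xenon-cavity linings are defaults derived
from the 3SDH globin fold and the xenon-binding literature; override them
with `--annotation` for other numbering conventions.
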