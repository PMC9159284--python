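# dockmap

FFT-correlation rigid-body protein–protein docking, whole-surface solvent
mapping with ligand-probe hotspots and druggability classification, and
interface model-selection utilities — in one Python package with a CLI.

## What it does

**Docking** (`dockmap dock`): sweeps a quasi-uniform rotation set, scores
every translation of the ligand against the receptor with multi-channel FFT
correlation (repulsive core, attractive surface shell, electrostatics, an
atom-type contact term), retains the 1000 lowest-energy poses, clusters them
greedily by ligand RMSD, refines cluster members by rigid-body energy
minimization, and writes up to 10 models ranked by cluster population.
Pairwise distance restraints with k-of-n group semantics can restrict the
search.

**Mapping** (`dockmap ftmap`): sweeps each of 16 small organic probe
molecules (ethanol … N,N-dimethylformamide) over the entire surface, keeps
and minimizes the best poses per probe, clusters them and ranks clusters by
average minimized energy, merges cross-probe clusters into consensus sites
(hotspots), classifies site strength (strong at ≥ 16 probe clusters) and
overall druggability, and combines nearby hotspots into predicted binding
sites (`dockmap ftsite`). Per-domain mapping is supported via `--domains`.

**Interface scoring** (`dockmap afscore`): average predicted-aligned-error
over interface residue pairs (10 Å heavy-atom cutoff) to rank candidate
complex models; `dockmap metrics` reports ligand RMSD and interface
backbone RMSD (iRMSD) of a model against a reference.

**Synthetic ground truth** (`dockmap fixtures`): a planted-pose
receptor/ligand complex and a designed-cavity receptor, used throughout the
test suite — no downloads required anywhere.

## Quick start

```sh
# make a ground-truth system and dock it
dockmap fixtures complex --seed 1 --out toy/
dockmap dock toy/REC.pdb toy/LIG.pdb --rotations 500 --seed 17 --out dock_out/

# map a pocketed receptor and report hotspots / binding sites
dockmap fixtures pocket --seed 1 --out pocket/
dockmap ftmap pocket/POCKET.pdb --seed 1 --out map_out/
dockmap ftsite map_out/

# restraints and interface-PAE scoring
dockmap restraints generate --pair A.85:C.119 --dmin 2 --dmax 10 --required 1 > R.json
dockmap afscore MODEL.pdb PAE.json --chains-a A --chains-b B
```

Key–value config files (`key = value`) are accepted via `--config`;
CLI flags take precedence over config values, which take precedence over
defaults. Outputs include TSV reports, PDB models and a JSON run manifest
(version, input checksums, full parameters, seed, timings).

## Layout

| module | role |
|---|---|
| `dockmap.structio` | PDB read/write, selections, per-atom radius/charge/type assignment |
| `dockmap.gridcore` | multi-channel grids, FFT correlation engine + brute-force oracle |
| `dockmap.dock` | rotation sampling, rigid docking sweep, pose refinement |
| `dockmap.restraints` | restraint JSON dialect, k-of-n evaluation, pose filtering |
| `dockmap.cluster` | greedy RMSD clustering, ligand RMSD, iRMSD |
| `dockmap.ftmap` | probe library, surface mapping, hotspots, druggability, sites |
| `dockmap.afutils` | interface residues and average interface-PAE scoring |
| `dockmap.fixtures` | self-validating synthetic test systems |
| `dockmap.pipeline` | end-to-end workflows, manifests, TSV/PDB outputs |
| `dockmap.cli` | `dockmap` command group |
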