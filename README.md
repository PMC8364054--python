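# aevnet

Protein–ligand binding-affinity scoring built on atomic environment
vectors (AEVs): every atom of a binding site is featurized with
translation/rotation/permutation-invariant atom-centred symmetry
functions, fed through a per-element feed-forward network, and the
per-atom outputs are summed to a pK prediction. The package also
implements a Δ-learning mode (converted docking baseline + learned
correction), consensus ensembles with per-prediction uncertainty,
CASF-style scoring/ranking/docking/screening metrics with bootstrap
confidence intervals, and gradient/contribution-based interpretability.
A synthetic-data module generates toy complexes, decoy poses, and
screening pools so everything is testable offline at desk scale.

The neural networks (forward, backward, dropout, Adam) are implemented
directly on NumPy — no deep-learning framework is required — which keeps
training runs bit-reproducible from a single integer seed.

## Layout

| module | contents |
| --- | --- |
| `aevnet.aev` | symmetry functions, AEV layout/computation, analytic backward pass |
| `aevnet.chem_io` | PDB/SDF/MOL2 reading, binding-site selection, species/metal/hydrogen policies, dataset splits, manifests |
| `aevnet.model` | per-element networks, training loop, ensembles, checkpoints |
| `aevnet.delta` | docking-score → pK conversion and Δ-learning combiner |
| `aevnet.metrics` | scoring/ranking/docking/screening power, bootstrap CIs |
| `aevnet.interpret` | coordinate gradients, per-atom contributions, annotated PDB output |
| `aevnet.fixtures` | synthetic complexes, linear-in-AEV ground truth, decoys, screening pools |
| `aevnet.cli` | `aevnet` command-line interface |

## CLI

```bash
# synthetic benchmark data (PDB/SDF files + manifest.csv with labels)
aevnet make-fixtures --out fx/ --n 200 --seed 1

# binding-site AEVs for one complex
aevnet featurize --protein prot.pdb --ligand lig.sdf --out aevs.csv

# train an ensemble (90/10 split, best-validation checkpointing)
aevnet train --manifest fx/manifest.csv --out-dir model/ \
    --species C,N,O --epochs 300 --learning-rate 1e-3 \
    --ensemble-size 5 --standardize

# predict (mean pK and ensemble std)
aevnet predict --model model/ --protein prot.pdb --ligand lig.sdf --species C,N,O

# Δ-learning prediction on top of an external docking score (kcal/mol)
aevnet delta-predict --model model/ --protein prot.pdb --ligand lig.sdf \
    --species C,N,O --baseline-score -7.5

# score a whole manifest, then CASF-style evaluation
aevnet predict-manifest --model model/ --manifest fx/manifest.csv \
    --species C,N,O --out preds.csv
aevnet evaluate scoring --scores scores.csv --out report.json
aevnet evaluate ranking --scores scores.csv --out ranking.json
aevnet evaluate docking --decoys decoys.csv --out docking.json
aevnet evaluate screening --candidates cands.csv --out screening.json

# per-atom contributions / coordinate gradients (B-factor annotated PDB)
aevnet attribute --model model/ --protein prot.pdb --ligand lig.sdf \
    --species C,N,O --out-pdb attr.pdb --out-csv attr.csv
```

Structural policies: water is always removed; element symbols come from
explicit element fields only (files without them are rejected); metals
are discarded or mapped to the dummy species `X` (`--metal-policy`);
hydrogens can be stripped (`--no-hydrogens`); binding sites keep whole
protein residues with any atom within `--d` Å of the ligand (default
3.5; `--d 0` gives a ligand-only model).

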