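# helixbridge

Analysis of salt-bridge networks and helix geometry in molecular-dynamics
ensembles of α-helical protein domains — built around the kind of question
asked of nuclear-receptor ligand-binding domains (LBDs): does a point
mutation or phospho-mimetic substitution (e.g. S371E in the RARγ LBD)
rewire the electrostatic network and shift the packing of helices far from
the mutated site?

The package is aimed at computational structural biologists who already
have MD trajectories (or deposited crystal structures) and want the
ensemble observables that make such allosteric arguments quantitative:

- **Electrostatic contact probabilities.** A residue pair (Asp/Glu vs
  Arg/Lys) is *in contact* in a frame when the minimum distance between
  any side-chain oxygen (Oδ1/Oδ2, Oε1/Oε2) and any side-chain nitrogen
  (Nε/Nη1/Nη2, Nζ) is ≤ 3.5 Å. The contact probability is the fraction
  of analysed frames in contact, pooled over replicas after an
  equilibration discard (default 30 ns). Network totals sum the
  probabilities over a set of pairs.
- **Distance pools.** All O–N atom-pair distances of a pair, pooled over
  frames, with histograms and the fractions of distances below 4 Å and
  within [2, 4) Å.
- **Helix axes and angles.** Cylinder-style axis fits from Cα traces
  (bisector local-center construction + least-squares refinement),
  inter-helix angles on N→C-oriented axes in [0°, 180°], and per-frame
  maximum intra-helix bending from local axis points over sliding
  4-residue windows.
- **Statistics.** Bootstrap standard errors of ensemble means (1000
  replicates, seeded) and two-sample Student's t-tests between
  conditions, with the conventional `< 2.2e-16` reporting floor.
- **Cα superposition.** Closed-form Kabsch least-squares fit (reflection
  corrected) of two structures paired by author residue numbering, with
  RMSD — the standard check that two crystal forms are isomorphous.
- **Synthetic ensembles with ground truth.** A generator that emulates
  the statistical structure of a replica MD study: ideal α-helices at
  controlled mutual angles with a controlled kink, plus salt-bridge
  pseudo-atoms whose O–N distance follows a two-state (closed/open)
  Markov chain with state-conditional Gaussian distances. Every analysis
  stage is validated by parameter recovery against the generator's
  manifest.

## Worked example

Generate a synthetic "wild-type-like" ensemble (4 replicas × 100 frames;
two helices at 47.6° with a 17.2° kink in H9; one salt bridge with
stationary closed probability 0.6) and analyse it:

```sh
helixbridge simulate --out sim --seed 7 --n-frames 100 --n-replicas 4
helixbridge saltbridge --config sim/analysis.yaml --topology sim/topology.pdb \
    --traj sim/replica_00.pdb --traj sim/replica_01.pdb \
    --traj sim/replica_02.pdb --traj sim/replica_03.pdb \
    --frame-dt 0.2 --out saltbridge_wt
helixbridge helixgeom --config sim/analysis.yaml --topology sim/topology.pdb \
    --traj sim/replica_00.pdb --traj sim/replica_01.pdb \
    --traj sim/replica_02.pdb --traj sim/replica_03.pdb \
    --frame-dt 0.2 --out helixgeom_wt
```

The two commands print:

```
pair,n_frames,n_contacts,probability
R2-D1,400,239,0.5975
TOTAL,,,0.5975

observable,mean,bootstrap_se,n
angle_H9-H10,47.59693798335152,0.018993430308141535,400
bend_H9,17.607014743471574,0.05085049639531706,400
bend_H10,1.8191570337209344,0.03647085084684664,400
```

Reading: the R2–D1 pseudo-pair was in contact in 239 of 400 frames
(0.5975, vs the configured stationary closed probability 0.60); the
fitted H9–H10 angle averages 47.60° (configured 47.6°) with a bootstrap
SE of 0.019°; the maximum bend within H9 averages 17.6° (configured kink
17.2°; the small upward offset is the noise bias of a per-frame maximum);
the unkinked H10 bends < 2°. A second condition directory (e.g. generated
at 49.0°) can be compared with `helixbridge report --a helixgeom_wt --b
helixgeom_mut --out comparison.csv`, which adds mean differences, t
statistics and p-values per observable, and `helixbridge compare ref.pdb
mobile.pdb` prints the Kabsch RMSD and transform of two structures.

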