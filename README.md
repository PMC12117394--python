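# tmdimer

Trajectory and free-energy analysis for transmembrane (TM) helix dimers
represented as coarse-grained (CG) bead models — the kind of data produced
by CG simulations of receptor TM domains (e.g. the neurotrophin receptors
TrkA, TrkB and p75, whose dimers start from structures such as PDB 2N90,
2MIC and 2MJO).  It is aimed at simulators who need to turn raw two-helix
bead trajectories into quantitative statements about dimer arrangement,
interface contacts, conformational states, and dimerization free energy.

## What it computes

**Arrangement descriptors** (per frame, from backbone-bead centres of
geometry, COGs):

- *d* — distance between the backbone COGs of the two helices (Å);
- *Ω* — crossing angle: the signed dihedral over (N-half COG₁, COG₁,
  COG₂, N-half COG₂); Ω > 0 means a left-handed dimer, Ω < 0 right-handed;
- *phase* / *position* — rotation of each helix about its own long axis,
  measured as the dihedral (partner COG, own COG, own upper-half COG,
  reference-residue bead); an angle near 0° puts the reference residue at
  the dimer interface;
- *dN* / *dC* — distances between the first- and last-residue backbone
  beads (N- and C-termini separation, Å).

**Contact maps** — residue *i* (helix 1) and residue *j* (helix 2) are in
contact in a frame when any bead of *i* is strictly closer than 6 Å to any
bead of *j*; occupancy is the fraction of pooled frames in contact, and
difference maps compare mutant against wild-type occupancies.

**Configurational landscapes** — 2D Gaussian-kernel density maps over
descriptor pairs (Scott bandwidth × adjust, default 1.0), ranked density
maxima, and rectangular state regions (e.g. the TrkA "active" box with both
rotation angles in [100°, 150°)) that classify frames and report state
populations and per-state C-termini distance modes.

**Well-tempered metadynamics** on toy Langevin systems with the hill rule

    W = W₀ · exp( −V(s, t) / ((f − 1) k_B T) )

(defaults W₀ = 0.05 kJ/mol, bias factor f = 10, Gaussian width σ = 0.05 CV
units, one hill per 5000 steps, T = 310 K), free-energy reconstruction
F(s) = −f/(f−1)·V(s) (minimum pinned to 0), Boltzmann reweighting with the
time-dependent offset c(t), dimerization free energy ΔG_bind between
explicit bound/unbound windows, and the standard convergence diagnostics:
CV diffusion, hill-height decay, ΔG(t), and block-analysis error curves
evaluated every 10 blocks from 1 to 1000.

A synthetic-dimer generator builds ideal CG helices (1.5 Å rise, 100°
twist, 2.3 Å radius) and places two copies at any prescribed arrangement,
so every stage can be validated against exactly known ground truth.

## Worked example

```sh
tmdimer simulate \
    --segment "d=8,omega=25,phase=120,position=120:60" \
    --segment "d=8,omega=-30,phase=0,position=0:40" \
    --jitter 0.3 --seed 11 --output-dir sim
tmdimer descriptors sim/trajectory.txt --topology sim/structure.pdb --output-dir .
tmdimer classify descriptors.tsv --regions regions.txt --output-dir .
```

with `regions.txt` containing `active phase position 100 150 100 150 0`.
The descriptor table starts

```
frame  time  d      omega   phase    position  dN      dC      undefined
0      0.0   8.066  24.550  119.729  117.092   10.858  14.254  False
1      1.0   8.050  24.452  112.890  127.732   10.237  14.401  False
```

— each row is one frame: the dimer sits at d ≈ 8 Å with a left-handed
crossing of ≈ +25° and both rotation angles near 120° (inside the active
box), with 0.3 Å of bead jitter scattering the angles by a few degrees.
`classify` prints

```
{"active": 0.59, "other": 0.41}
```

: 59% of frames fall in the active region — one jittered frame of the 60%
ground-truth active segment fluctuated across the box edge.

A toy metadynamics run and its convergence report:

```sh
tmdimer toy-metad --a 5 --b 1 --n-steps 10000000 --seed 3 --output-dir metad
tmdimer report metad/HILLS metad/COLVAR --bound "-1.4:-0.6" --unbound "0.6:1.4" \
    --output-dir metad
```

```
INFO tmdimer: 2000 hills deposited; final height 0.04223 kJ/mol
{"delta_g_kJ_mol": -2.49, "n_hills": 2000, "bound": "-1.4:-0.6", "unbound": "0.6:1.4"}
```

The double well U(x) = 5(x²−1)² + x has its deeper basin at x ≈ −1; the
hill heights have tempered from 0.05 toward 0.042 kJ/mol and the
bound-minus-unbound free energy is ≈ −2.5 kJ/mol (association favourable).
`metad/blocks.tsv` and `metad/delta_g_t.tsv` hold the block-error curve and
the time evolution of ΔG.

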