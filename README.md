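# hemelock

Tools for quantifying how firmly a heme cofactor is locked into its protein
pocket, and for turning that census into a thermostability predictor for
heme enzymes such as the lignin peroxidase of *Phanerochaete chrysosporium*
(PcLiP01).

Heme enzymes often unfold at the temperatures where they would be most
useful industrially. For PcLiP-family peroxidases, stability is strongly
influenced by the residue packed against heme propionate A (position 181 in
the mature-protein numbering, propeptide residues −7..−1). `hemelock`
provides the computational side of engineering that interaction:

* **Interaction census** — detects hydrogen bonds, carbon hydrogen bonds and
  salt bridges between the heme propionate carboxylates (groups A and D)
  and amino-acid donors across a structural ensemble, using heavy-atom
  criteria: donor–acceptor distance *d* ≤ 3.4 Å for N/O donors, ≤ 3.8 Å
  for C/S donors, with both the X–D–A and D–A–Y angles in [90°, 180°];
  Arg/Lys contacts count as salt bridges at *d* ≤ 5.6 Å.
* **HemeLock index** — per-category interaction frequencies *I* and mean
  distances *D* (Å) are combined with the sidechain volume *V* (Å³) of the
  residue at the key position:

  ```
  interaction score = w1·BBCHI/BBCHD + w2·SCHI/SCHD + w3·SCCHI/SCCHD + w4·SCSBI/SCSBD
  size score        = w5 / V
  HemeLock index    = interaction score + size score
  Tm (°C)           = a · index + b
  ```

  The packaged model fitted on the PcLiP01 V181X saturation panel is
  w1 = 2.974, w2 = 0.9201, w3 = w4 = 0, w5 = 282.3, a = 4.995, b = 42.86,
  with per-isozyme refinements of the size weight (w5 = 233.1 for PcLiP05,
  223.3 for PcLiP09) available through `refit_w5`.
* **Trajectory observables** — multi-model PDB ensembles, Kabsch
  superposition, RMSD with the flexible termini (−7..−1, 329..344)
  excluded, and per-frame atom–atom distance traces.
* **Kinetics** — specific activity via Beer–Lambert (ε310 = 9.3 mM⁻¹cm⁻¹),
  enzyme concentration from the heme Soret band (ε409 = 168 mM⁻¹cm⁻¹),
  first-order thermal-inactivation constants from ln(residual activity)
  regression with t½ = ln 2/kd, and Michaelis–Menten fits for kcat and KM.
* **Synthetic data** — generators for heme-pocket ensembles with programmed
  interaction occupancy, variant panels obeying a known linear Tm law, and
  kinetics series, each returning its ground truth so every analysis stage
  is testable without an MD engine.

## Worked example

Generate a synthetic heme-pocket ensemble with 80% programmed interaction
occupancy, census it, and score residue 181:

```python
from hemelock.synthetic import default_pocket_spec, make_pocket_trajectory
from hemelock.interactions import scan_trajectory, aggregate
from hemelock.model import index_from_summary, predict_tm

spec = default_pocket_spec(occupancy=0.8, n_frames=200, seed=7,
                           jitter_d=0.05, jitter_angle=3.0)
traj, truth = make_pocket_trajectory(spec)
summary = aggregate(scan_trajectory(traj), traj.n_frames)
print(summary.table.to_string(index=False))
```

```
chain  residue_seq residue_name category    I        D  n_events  n_frames
    A           39          LYS    SC_SB 0.78 4.993062       156       200
    A           82          SER     SC_H 0.78 2.993871       156       200
    A          181          ALA    BB_CH 0.80 3.491590       160       200
```

Each site is recovered at a frame-fraction frequency binomially scattered
around the programmed 0.8 and at its programmed mean distance (3.5, 3.0 and
5.0 Å). Scoring the alanine at position 181:

```python
bd = index_from_summary(summary, 181, "ALA")
print(f"{bd.bb_ch_term:.4f} {bd.size_score:.4f} "
      f"{bd.hemelock_index:.4f} {float(predict_tm(bd.hemelock_index)):.2f}")
```

```
0.6814 3.1862 3.8676 62.18
```

The backbone carbon-hydrogen-bond term contributes 2.974 × 0.80/3.4916 =
0.6814; alanine's small sidechain (88.6 Å³) gives the maximal size score
282.3/88.6 = 3.1862; the index 3.8676 maps to a predicted melting
temperature of 62.18 °C. (The Lys salt bridge is censused but carries zero
weight in the published model.)

The same pipeline is available from the shell:

```sh
hemelock simulate pocket -o sim --occupancy 0.8 --n-frames 200 --seed 7
hemelock scan sim/pocket.pdb -o scan_out
hemelock score scan_out/summary.tsv --residue 181 --aa ALA
hemelock predict panel.csv            # observed / predicted / difference table
```

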