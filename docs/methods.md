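# Methods

This note records what `hemelock` computes, the parameters it uses, and the
numerical and design choices behind them.

## Interaction census

Interactions are detected between heme propionate carboxylate acceptors
(atoms O1A/O2A of propionate group A and O1D/O2D of group D, antecedent
carbons CGA/CGD) and amino-acid donor heavy atoms, using heavy-atom
geometric criteria evaluated per frame of a structural ensemble:

| Parameter | Default | Units | Rationale |
|---|---|---|---|
| d_max, N/O donors | 3.4 | Å | conventional heavy-atom hydrogen-bond cutoff |
| d_max, C/S donors | 3.8 | Å | longer cutoff for weak carbon/sulfur donors |
| d_max, salt bridge | 5.6 | Å | Arg/Lys charged-nitrogen to carboxylate span |
| X–D–A angle | [90°, 180°] | — | donor-antecedent geometry consistent with a donated hydrogen pointing at the acceptor |
| D–A–Y angle | [90°, 180°] | — | acceptor lone-pair orientation |

A donor qualifies if the distance criterion holds and **any** combination
of its antecedent X and the acceptor's antecedent Y satisfies both angular
windows. Events are classified as backbone carbon hydrogen bonds (Cα
donors, BB_CH), sidechain hydrogen bonds (polar N/O donors, SC_H),
sidechain carbon hydrogen bonds (Cβ/Sγ donors, SC_CH) and salt bridges
(Arg NE/NH1/NH2, Lys NZ, SC_SB). An Arg/Lys contact that satisfies both
the hydrogen-bond and salt-bridge criteria is recorded as both events by
default (`salt_bridge_priority` collapses it to the salt bridge only).
Donor atoms missing from a frame are skipped with a logged count; a frame
without a heme residue is a contract violation, not a silent zero.

Per category and residue, the census yields a frequency *I* and a mean
donor–acceptor distance *D* (Å). The default frequency is the fraction of
frames with at least one event ("frame_fraction"); "events_per_frame"
counts multiple simultaneous events. Frame fraction is the default because
it is bounded on [0, 1] and maps directly to an occupancy probability,
which is what the synthetic generator programs and what the index
interprets.

## HemeLock index and Tm model

```
interaction score = w1·BBCHI/BBCHD + w2·SCHI/SCHD + w3·SCCHI/SCCHD + w4·SCSBI/SCSBD
size score        = w5 / V
index             = interaction score + size score
Tm                = a · index + b
```

*V* is the sidechain (Zamyatnin) volume of the residue at the key
heme-contacting position, from the packaged `residue_volumes.csv`
(88.6 Å³ for Ala to 227.8 Å³ for Trp). A category with zero frequency
contributes zero regardless of its undefined mean distance.

Packaged parameters: w1 = 2.974, w2 = 0.9201, w3 = w4 = 0, w5 = 282.3;
a = 4.995 °C per index unit, b = 42.86 °C. With these, the size score
spans 1.239 (Trp) to 3.186 (Ala), the backbone term 0–0.750 and the
sidechain hydrogen-bond term 0–0.348.

### Fitting

The Tm law is degenerate under joint rescaling: multiplying all weights by
c and dividing the slope by c leaves predictions unchanged. `fit_model`
therefore anchors w5 at its published value and optimizes the remaining
weights (non-negative bounds, multi-start `scipy.optimize.least_squares`
with tolerances 1e-14); only the ratios w1/w5, w2/w5 (etc.) and the
products a·wk are identifiable, and the tests assert exactly those.
With `fixed_weights` the problem reduces to ordinary least squares of Tm
on the index. R² and MSE use an n denominator (MSE is the quantity being
minimized); slope/intercept standard errors and 95% confidence intervals
use the usual t-based OLS formulas with n − 2 degrees of freedom.

`refit_w5` re-estimates only the size weight for a new isozyme, holding
everything else fixed. The MSE is quadratic in w5, so the minimizer is
computed in closed form (and clipped at zero) rather than by iteration;
a grid-scan oracle in the tests confirms the closed form.

## Kinetics

* Specific activity: U/mg from an absorbance slope at 310 nm via
  Beer–Lambert with ε = 9.3 mM⁻¹ cm⁻¹ and 1 cm path length.
* Enzyme concentration: heme Soret absorbance at 409 nm,
  ε = 168 mM⁻¹ cm⁻¹.
* Thermal inactivation: activities are normalized to t = 0, non-positive
  values excluded with a log message (they have no logarithm and indicate
  the signal floor), and ln(activity) regressed on time
  (`scipy.stats.linregress`); kd is the negated slope, t½ = ln 2/kd, and
  the kd confidence interval comes from the slope's standard error.
* Michaelis–Menten: `scipy.optimize.curve_fit` with positivity bounds and
  tolerances 1e-12; a fitted KM at or below 1% of the smallest assayed
  concentration sets `km_at_boundary`, since such values are not resolved
  by the data.

## Synthetic generators

`make_pocket_trajectory` builds multi-model PDB ensembles of a heme
fragment plus donor residues. Each site is placed per frame by a Bernoulli
draw at the programmed occupancy; when placed, the donor position is
solved explicitly from the target distance and angles (with jitter clipped
inside the detection window), and when not placed it sits beyond 8 Å.
The second propionate oxygen is positioned trans to the first across the
carboxylate carbon, so its acceptor angle rejects every programmed donor —
each site produces exactly one event category per placed frame and the
ground truth (per-frame placements, realized frame fractions and mean
distances) is exact, not approximate. The generator emulates occupancy and
geometry statistics only; it does not emulate physical dynamics,
correlated motions, solvent, or forcefield energetics, and its ensembles
carry no kinetic meaning.

`make_variant_panel` draws per-variant census statistics uniformly within
the component spans above and produces Tm = a·index + b + N(0, σ²), so
regression-recovery tests know the generating law exactly.
`make_decay_series` and `make_saturation_series` produce exponential-decay
and Michaelis–Menten data with optional lognormal/Gaussian noise. All
generators take integer seeds (`numpy.random.default_rng`) and are
byte-reproducible.

## Structural I/O choices

The PDB reader is a small fixed-column parser rather than a general
library wrapper so that it can report line-numbered parse errors, enforce
topology identity across models (same atoms, same order), count and log
dropped altloc records, and accept negative residue numbers for the
propeptide (−7..−1). RMSD uses Kabsch superposition via
`scipy.spatial.transform.Rotation.align_vectors` on Cα atoms with the
flexible termini (−7..−1 and 329..344) excluded by default; a collinear or
too-small selection is rejected as degenerate rather than silently fitted.
Sample statistics use the n − 1 denominator.

## Limitations

* The Tm model is a two-parameter linear law calibrated on single-position
  variant panels; it does not extrapolate to multi-site designs beyond the
  additive index.
* Census criteria are heavy-atom geometric proxies; no hydrogens, energies
  or electronic effects are evaluated.
* The per-isozyme `refit_w5` adjusts one parameter and inherits all other
  weights; it cannot correct for qualitatively different pocket chemistry.
* Synthetic ensembles validate the analysis chain, not any physical
  sampling claim; statistics quoted in the documentation are those the
  test suite and acceptance script actually compute.
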