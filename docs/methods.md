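# Methods

`cgbind` implements a coarse-grained, multiple-basin structure-based model
of an enzyme whose catalytic cleft opens and closes by a hinge motion, with
explicit rigid ligands whose binding landscape can be made rugged through a
single non-native interaction strength.  The package is built around the
question of how repeated open/close transitions rescue incorrectly bound
substrates, and provides the sampling (Langevin dynamics, PaCS-MD, umbrella
sampling + MBAR) and analysis (reaction coordinates, first-passage
statistics, cycle counting) machinery needed to pose it quantitatively.

## Energy model

Each protein residue is one bead at the C-alpha position; ligands are small
rigid bead sets (5 beads for the AMP-like ligand, 7 for the ATP-like one).
The apo potential is

    V = V_shared + sum_i V_MB,i ,   i in {LID-CORE, NMP-CORE, LID-NMP},

where `V_shared` collects bonded terms (harmonic bonds, harmonic angles,
cosine dihedrals referenced to the closed conformation) plus single-basin
12-10 contacts within each domain and generic excluded volume, and each
interface component is mixed from its closed- and open-basin parts by the
lower eigenvalue of the two-state secular problem

    V_MB = ((V1 + V2) - sqrt((V1 - V2)^2 + 4 Delta^2)) / 2,
    V1 = V_closed,  V2 = V_open + dV.

Each basin's interface component contains its own 12-10 contacts (detected
at a 6.5-A heavy-atom threshold in that reference, |i-j| >= 3), its own
copies of hinge-spanning angle/dihedral terms (terms whose reference values
differ between the conformers, softened to 2.0 kcal/mol/rad^2 and
0.5 kcal/mol), and soft harmonic "tether" springs on every interface
contact pair referenced to that conformer's distances
(`k_tether = 0.03 kcal/mol/A^2`).  The tethers give each basin a funnel over
the whole interdomain range - bare 12-10 contacts are too short-ranged to
steer re-closing - and play the role of the long-range part of a
structure-based basin potential.  Forces are exact analytic gradients,
including the chain-rule mixing weights; finite-difference agreement to
better than 1e-5 relative is enforced in the test suite.

Protein-ligand terms use the standard parameterization of this model family: 12-10 native
contacts of depth `eps_nat = 0.15 kcal/mol`, Gaussian non-native wells
`-eps_nnat exp(-r^2 / (2 sigma^2))` with `sigma_nnat = 6.0 A` on pairs that
(i) are not native, (ii) involve a residue within 6 A of a
native-contact-forming residue, and (iii) are closer than 10 A in the
closed reference, and excluded volume `eps_exv (sigma/r)^12` with
`sigma = 5.0 A` (protein-ligand) and `3.5 A` (ligand-ligand),
`eps_exv = 1.0 kcal/mol`.  `eps_nnat` is the ruggedness dial and the scan
variable of the binding experiments.  Ligands are kept rigid by stiff
internal bond/angle/dihedral restraints (100 / 50 / 50 in kcal/mol units)
referenced to the native pose.  No interaction cutoff is applied: systems
are small enough that every listed pair is evaluated exactly, so all terms
and derivatives are continuous on (0, inf).

Intra-domain contacts use `eps_intra = 1.0 kcal/mol` so the domains are
rigid bodies at 300 K; interface contacts use `eps_protein = 0.3 kcal/mol`.
This separation matters: marginally folded walls wash out the
conformational coordinate, while over-stiff interfaces freeze the closed
state's vibrational entropy and unbalance the two basins.

## Units, dynamics

Internal units are kcal/mol, Angstrom, Kelvin; `k_B = 0.0019872`.  All
beads carry mass 100 in these units, which approximates the residue-mass
scale of C-alpha models and puts the stiffest bonded mode at
omega*dt ~ 0.1 for the default time step `dt = 0.1 tau` - the stability
margin standard coarse-grained engines operate at.  Dynamics are BAOAB
Langevin with friction `gamma = 0.25 / tau` at `T = 300 K`; with the
thermostat off the scheme reduces to velocity Verlet (no secular energy
drift).  Trajectories are deterministic per seed, and a serialized state
resumes bit-identically.

## Reaction coordinates

* `xi = (RMSD_C - RMSD_O) / RMSD_CO` over protein beads, with best-fit
  (Kabsch) superpositions: -1 at the closed reference, +1 at the open.
  Its analytic gradient (through the superposition, via the envelope
  theorem) drives the umbrella bias.
* `Q`: fraction of native contacts formed, a sharp cutoff at 1.2 r0 by
  default (a logistic switching variant is available behind the same
  interface).
* Pose coordinates `(R, theta)`: after superposing the CORE domain onto the
  closed reference, `R` is the displacement of the terminal-phosphate bead
  and `theta` the angle between instantaneous and reference
  base-to-terminal-phosphate vectors.  Both vanish at the native pose.
* Interdomain distances are unweighted bead-centroid distances; open/close
  segmentation uses two-threshold hysteresis at 30% / 70% of the
  closed-open gap to suppress chatter.

## Enhanced sampling

PaCS-MD runs short unbiased replica bursts, ranks all sampled snapshots
(plus the incumbent seeds, so the best-RMSD series is monotone) by RMSD to
the target structure, and reseeds from the best; a stalled cycle triggers a
plain relaxation segment.  The potential is never modified, so every
snapshot is a valid equilibrium state.

Umbrella sampling biases xi with (k/2)(xi - c)^2 on an evenly spaced grid
(41 windows at spacing 0.05 across [-1, 1] by default); the first quarter
of each window is discarded as equilibration.  Profiles are recovered by
MBAR, solved by self-consistent iteration of the standard equations to
1e-7, with block-bootstrap uncertainties.  The window force constant must
make the biased ξ fluctuation (sqrt(kT/k)) comparable to the window
spacing; with too soft a bias the windows lose overlap at steep parts of
the profile and the cross-gap free-energy offset becomes meaningless - the
reweighting code warns when adjacent windows share no overlap.  2D
landscapes are minus-log histograms of unbiased runs; 2D barriers are
bottleneck (minimax) levels on the bin adjacency graph, found by a
threshold sweep with connected-component labeling.

## First-passage statistics

Binding success uses the standard criteria of this model family: `Q >= 0.7` for every
ligand simultaneously (CG rule), or `R < 3 A` and `theta < 0.4 rad`
sustained for a dwell of 10 frames (pose rule; theta is treated as
radians).  MFPTs use the censored-exponential maximum-likelihood estimator,

    MFPT = (sum of all durations, censored included) / (number of events),

with percentile-bootstrap confidence intervals over trajectories.  This
estimator is scale-equivariant and never decreases when censored
observations are added.

## The synthetic two-state system

The toy enzyme is a 60-bead "clamshell" on a 3.8-A lattice (small seeded
jitter breaks the symmetry): a 4x5 floor, an NMP-like side wall, a 5x2
LID plate roofing the ligand groove, an end wall, and two static cage
rails at ligand height that seal the groove's sides.  The open conformer
is generated by a crankshaft rotation of the LID segment (default 40
degrees) about the axis through its two anchor beads, which preserves both
junction bond lengths exactly.  Domain labels follow the chain layout
(CORE = floor + anchors + end wall + rails, NMP = side wall, LID = plate);
xi endpoints are exact by construction.

The ligand is a 14-A five-bead rod (base = 2 beads, ribose with a 1.5-A
dip, two phosphate beads) lying in the groove, forming ~45 native contacts
with floor, rails, side wall and lid, every one of them at 5.4 A or more
so that excluded volume leaves room for non-native poses.  Three design
features carry the full-size enzyme's mechanism down to desk scale:

1. **Caging.**  With the lid closed the rod is buried: sideways escape is
   blocked by the rails and wall, upward escape by the lid.
2. **Orientational frustration.**  The rod is longer than the closed
   cleft's free height, so flipping it end over end (the non-native pose,
   theta = pi) is sterically impossible while closed but easy when open.
   `perturb_pose(mode="flip180")` generates exactly this pose; it
   destabilizes the closed state through excluded volume, mirroring the
   downhill-opening effect of incorrectly bound substrate.
3. **Small mobile domain.**  The LID is 10 beads so the open state's
   conformational entropy stays comparable to the closed state's; a wide
   lid makes the open state win by tens of kT and the hinge stops cycling.

Calibration of the double basin follows the usual logic for multiple-basin
models: the energy-gap offsets `dV_i` and couplings `Delta_i` are not
physical observables and are tuned so that (a) the apo enzyme populates
the closed state at roughly the experimental ~0.3 level and (b)
transitions occur on simulation-accessible timescales.  The shipped
defaults are `dV = -2.0 kcal/mol` and `Delta = 1.0 kcal/mol` per interface
with `k_tether = 0.03 kcal/mol/A^2`.  The closed-restrained control (the
"C model") raises the open basin far above thermal reach
(`dV = +25 kcal/mol`) and additionally pins the protein with a harmonic
RMSD restraint to the closed structure (239 kcal/mol/A^2, the targeted-MD
constant of 23 900 kcal/mol/nm^2): the basin shift alone still permits
partial lid openings large enough to defeat the control, the pin does not.

What the toy does *not* emulate: a realistic fold or sequence, solvent and
electrostatics, the separation between closing time and binding-search
time of the real enzyme (see below), and the absolute timescale mapping of
tau.  Passing trend tests therefore demonstrates that the *mechanisms* -
caging, orientational frustration, ruggedness-controlled rescue - operate
in the model, not that the toy is quantitatively AdK.

## The three experiments

* **Binding MFPT vs ruggedness.**  Encounter poses are drawn by lifting
  the native pose ~5 A above the open cleft and applying random rotations
  and bounded translations (clash-checked), so the encounter ensemble is
  genuinely orientation-diverse.  Each encounter state is then driven to
  its first closure under the C model with the targeted-MD pin - closing
  this fast preserves the encounter orientation, so the first-closure
  snapshot ensemble stays pose-diverse - and from that common snapshot
  both the WT variant (free to reopen) and the pinned C variant are
  propagated to correct binding.  Measuring both variants from the shared
  first-closure state isolates the role of repeated cycling: in the real
  system closing is fast compared to the binding search, a separation the
  toy cannot afford, so timing the WT from the open start would merely
  measure its closing time.  A flat-bottom restraint
  (K = 0.239 kcal/mol/A^2, i.e. 23.9 kcal/mol/nm^2) keeps the ligand
  inside the binding area, as such protocols commonly do.  Open/close
  cycles are counted with 25%/50%-of-gap hysteresis thresholds (matched to
  the toy's partial-opening rescue amplitude), the success frame completes
  a terminal closing sweep (a correctly bound state is conformationally
  closed by definition of Q), and the reported count is averaged over
  successful trajectories.
* **Opening MFPT vs ligand state.**  Closed starts (apo, native pose,
  flipped pose) are first relaxed under the pinned C model, then
  propagated with the WT model until the LID-CORE distance crosses the
  open threshold.
* **Free-energy profiles.**  Umbrella sampling along xi with the ligand
  position-restrained in the native or flipped pose (the profile compares
  enzyme conformations at a fixed binding state, mirroring the pre-bound
  substrate restraints such studies employ).  Windows are seeded from
  PaCS-MD transition sweeps run in both directions - closed-to-open seeds
  for xi < -0.1, open-to-closed seeds for xi > 0.1, the pooled sweeps for
  the middle - which supplies relaxed initial structures and avoids the
  hysteresis of geometric-morph seeding.  Unbiased 2D (R_LID-CORE, Q)
  landscapes accompany the profiles.  The ruggedness showcase value for
  the profile comparison is eps_nnat = 0.5.

Problem sizes in the shipped tests (10-16 trajectories, 1e5-step horizons,
21-41 umbrella windows of a few thousand steps) are chosen so the full
suite runs on one CPU in well under half an hour; all drivers accept
larger budgets through their config dicts.

## Numerical choices and limitations

* Contact detection prunes candidate pairs with a KD-tree; tests compare
  against a brute-force all-pairs scan.
* theta is computed via arccos of a clamped normalized dot product.
* MBAR bootstrap uses blocks of 50 frames to respect autocorrelation.
* The censored-exponential MFPT model assumes memoryless passage times; for
  strongly non-exponential processes it estimates the mean under
  exponential weighting of the censored mass.
* Statistical acceptance bands in the tests are derived from effective
  sample sizes (e.g. the number of double-well round trips), not from raw
  frame counts.
* The real-PDB input path (C-alpha extraction, AMP/ATP bead mapping by
  chemical moiety) is exercised against synthetic PDB fixtures; reproducing
  AdK's full free-energy landscape requires cluster-scale sampling
  and is out of desk scope.
* Two trend limitations of the miniature system are worth stating plainly.
  First, with `sigma_nnat = 6 A` spanning most of the toy pocket the
  non-native term acts as smooth adhesion rather than position-resolved
  ruggedness; frustration enters through orientationally trapped poses
  (the flip) rather than through competing spatial minima, and the
  binding-rescue and cycle-count trends are carried by that mechanism.
  Second, the toy's conformational barrier is dominated by the intrinsic
  interface-mixing crossing (~4 kT) that the calibration needs for
  two-state apo behavior.  A flipped ligand destabilizes the closed basin
  (the open state becomes the global minimum and opening accelerates
  ~5-fold), but it cannot erase that intrinsic crossing barrier, so the
  flipped-pose profile is tilted toward open rather than strictly
  downhill.  In the full-size enzyme the opening barrier is dominated by
  substrate-mediated contacts, which a non-native pose removes entirely -
  a separation of scales the 60-bead model does not reach.
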