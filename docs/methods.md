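# Methods

## The problem

Unbinding a high-affinity ligand from its protein is far too slow to observe
in plain molecular dynamics, and the intermediate states along the pathway —
partially disengaged complexes held together by a few anchoring and many
transient contacts — are exactly the species one wants to characterize.
`ratchetpath` implements, at a scale where every stage can be tested against
planted ground truth, the standard search strategy for such intermediates:

1. **Ratchet-biased unbinding (BMD).** A half-quadratic penalty
   `E = ½·α·(ρ_max − ρ)²` acts on one reaction-coordinate distance ρ (a
   ligand anchor atom to a protein anchor atom), and only while ρ sits below
   its running maximum ρ_max; whenever ρ exceeds ρ_max the bias vanishes and
   the maximum advances. The ratchet never pulls — it converts spontaneous
   outward fluctuations into irreversible progress, which is why it perturbs
   the system far less than steered pulling.
2. **Adaptive force schedule.** The initial bias constant α₁ = 300 pN/Å is
   strong enough to unbind within the run limit. Metastable pauses found on
   the way out are then *extended* by restarting from the last stable
   structure with α lowered in steps of 25 pN/Å within 50–250 pN/Å, with
   branch logic: a pause that lasts beyond 150 ps is pooled; a ligand that
   returns to the bound state means α was too low (discarded as a rebound);
   unbinding with no pause means α was too high (retry lower); an exhausted
   schedule discards the restart.
3. **Metastable-plateau detection.** An intermediate announces itself as an
   interval during which *all* monitored channels — ρ (d_RC), the four
   pocket-to-moiety centre-of-mass distances (d_CM), and the RMSD traces —
   hold constant means. Lifetimes above 150 ps qualify for the pool.
4. **Cluster-based acceptance.** Pooled segments are clustered
   (average-linkage on the per-moiety d_CM/RMSD feature vector) and a
   cluster is accepted only if (i) every member is internally stable,
   (ii) the protein core is not significantly distorted, (iii) the cluster
   is tight across independent runs, and (iv) it sits near the bound state.
5. **Contact and geometry analysis** of the accepted state: candidate
   contacts (< 4 Å in more than half the frames of at least one run),
   permanent/transient classification (permanent = every frame of every run
   and pooled SD < 0.25 Å), moiety-by-residue contact maps with a
   bridging-water layer, hydrogen-bond geometry, RMSF, and the A1/A2
   alignment RMSDs (A1 fits all Cα atoms; A2 fits all except a group G, so
   the RMSD of G measures its displacement relative to the rest).

## The toy complex and what it emulates

The simulator is a bead-scale Langevin model, not a force field. The
"protein" is four anchor beads arranged symmetrically about the z axis
(tethered, k = 20 kcal·mol⁻¹·Å⁻²) forming a binding pocket, plus one weakly
tethered bead (k = 1.5) standing in for a mobile loop. The "ligand" is a
core bead carrying three peripheral moiety beads (iBu/Tol/Ethe analogues)
held by lab-frame vector springs (k = 10), so the ligand translates as a
semi-rigid unit and does not tumble; a transverse funnel (k = 2 on the
core) confines unbinding to the z axis. The unbinding landscape along the
core-to-anchor distance is two negative Gaussian wells plus an inner wall:

* bound well at ρ = 5 Å, depth 6.0 kcal/mol (≈ 10 kT at 300 K) — deep
  enough that no unbiased escape occurs on the nanosecond scale, shallow
  enough that the α₁ = 300 pN/Å ratchet unbinds within the 2 ns run limit
  (the same calibration logic by which α₁ is defined);
* metastable intermediate at ρ = 9 Å, depth 4.0 kcal/mol (≈ 6.7 kT) —
  deep enough to hold the ligand for hundreds of picoseconds under a weak
  ratchet, so that >150 ps plateaus actually occur;
* a flat unbound region (both Gaussians decayed), so barrier tops sit at
  zero by construction.

Well width is 0.6 Å for both wells; beads weigh 30–70 amu; the friction is
60 ps⁻¹ and the temperature 300 K. Masses and well curvatures admit a
0.02 ps time step for protocol-scale runs (the BAOAB scheme is stable and
accurate in this strongly damped regime); closed-form checks use 0.002 ps.

What the toy does *not* emulate: chemistry (no force field, no explicit or
implicit solvent energetics), ligand internal flexibility and tumbling,
protein conformational change beyond one mobile bead, and solvent granularity
(bridging-water analysis is exercised on synthetic fixtures with explicit
water beads). A passing suite therefore demonstrates that the *search and
analysis machinery* is correct — ratchet mechanics, plateau detection,
branch logic, clustering criteria, contact statistics — not that any real
complex has a particular intermediate.

Two direct fixture generators bypass the dynamics entirely:
`synth_series` plants plateaus of known position, level and noise in
multichannel traces (ramps connect the levels, and the series drifts away
outside the planted intervals so only they are stable), and
`synth_contact_trajectory` plants atom pairs with Bernoulli contact
frequencies and Gaussian in-contact distance distributions on separated
lanes, giving exact ground truth for the census.

## Parameters that matter

| parameter | default | units | note |
|---|---|---|---|
| α₁ | 300 | pN/Å | initial bias; 1 pN/Å = 1.4393×10⁻² kcal·mol⁻¹·Å⁻² |
| α schedule | −25 within [50, 250] | pN/Å | lifetime-extension stage |
| run limit (step 1 / step 2) | 2000 / 600 | ps | per biased run |
| unbound threshold | bound ρ + 8 | Å | ratchet run stops here |
| min lifetime | 150 | ps | pooling requires strictly more |
| restart stretch | 25 | ps | shortest stable stretch that seeds a step-2 restart |
| detector window | 50 | ps | running-mean window; boundary resolution |
| drift_tol / fluct_tol | 0.5 / 1.0 | Å | per-channel plateau qualification |
| contact cutoff | 4 (strict <) | Å | heavy atoms only |
| candidate frequency | 0.5 (strict >) | fraction, in ≥ 1 run | |
| permanent SD | 0.25 (strict <) | Å | plus contact in every frame |
| tight-cluster threshold | 1.0 | Å | per-feature ensemble SD |
| integrity threshold | 2.0 | Å | non-loop protein RMSD |
| proximity window | bound d_CM(core) + 5 | Å | acceptance criterion (iv) |
| rebound rule | within 1 Å of bound ρ for ≥ 50 ps | | discard branch |
| friction / temperature | 60 / 300 | ps⁻¹ / K | |
| k_B | 1.987204×10⁻³ | kcal·mol⁻¹·K⁻¹ | |

The detector tolerances are inferred from the statistics that accepted
states exhibit (within-run fluctuations below 1 Å, less for the ligand
core; ensemble SDs below ~0.7 Å, versus above 2 Å for rejected sets) — the
1 Å tight-cluster threshold separates those two regimes. All are config
values on `DetectorParams`/`ProtocolConfig`, never hard-coded.

## Numerical choices

* **Integrator**: BAOAB splitting; the noise is drawn once per step in a
  fixed order, so runs are bit-reproducible for a given seed. A
  numba-compiled kernel specialized to the toy complex handles
  protocol-scale ensembles; it consumes the identical noise stream and
  performs the identical step algebra as the generic term-based integrator
  (which remains the path for arbitrary potentials and the fallback when
  numba is absent). Biased and unbiased runs share the kernel, so the
  zero-bias equivalence invariant (α = 0 ⇒ bit-identical to unbiased) holds
  exactly on the path actually used.
* **Ratchet update order**: ρ_max is frozen during a step's force
  evaluations and advanced once from the post-step coordinates.
* **Time step**: the underlying description of the reference protocol
  prints an implausible integration step for an all-atom system; here dt is
  always a parameter. Toy default 0.002 ps; protocol-scale runs use
  0.02 ps (stiffest mode ω·dt ≈ 0.3, safely inside BAOAB stability).
* **Plateau detection**: greedy maximal-run growth under the joint
  drift/SD criterion on the window-smoothed series, followed by a boundary
  refinement that trims/extends edges against a robust per-channel level
  (gate = 4× segment SD, clipped to [0.25, 1]×drift_tol; extension capped
  at one window per side). Noiseless change-points resolve to the exact
  frame; boundary error is bounded by the window. Runs shorter than the
  window are treated as fragments that cannot block a full-sized
  neighbour's refinement. Near-adjacent runs are merged only when the
  union still qualifies.
* **Superposition**: Kabsch via `scipy.spatial.transform.Rotation.align_vectors`
  on centred coordinates (proper rotation guaranteed); degenerate
  (collinear) fit sets are rejected. RMSDs over ligand moieties use heavy
  atoms, protein RMSDs use the Cα set; sample (n−1) SDs throughout because
  the ensembles are small.
* **COM distances** are mass-weighted (a geometric-centroid flag exists).
* **Strict inequalities** at every contact boundary (4 Å, 50 %, 0.25 Å)
  are deliberate and tested at the boundary values.
* **Reactant exclusion**: a detected segment whose mean d_RC lies within
  the rebound tolerance of the bound-state value is the reactant, not an
  intermediate candidate; it is excluded from the pool (the same logic as
  the rebound discard branch). Without this rule the bound state itself
  passes all four acceptance criteria trivially.
* **Clustering**: average-linkage with Euclidean distance on the feature
  vector (per-moiety d_CM means and per-moiety A1-RMSD means), cut at
  tight-threshold × √(n_features), which makes the cutoff commensurate with
  the per-feature SD criterion. When several clusters pass all four
  criteria the best-populated one is reported as accepted (the report
  flags every passing cluster, and the recovery acceptance check requires
  exactly one).

## Problem sizes used in tests and the acceptance script

The bead complex has 9 atoms. The recovery study uses 10 master seeds ×
(6 starts × ≤ 2 ns step-1 runs + step-2 schedule walks at 0.02 ps), plus 10
barrierless controls; closed-form checks integrate 10⁶ steps at 0.002 ps;
the contact oracle uses 20 × 100-frame synthetic trajectories; the
superposition oracle 50 random 10-atom pairs against a 12³ Euler grid with
simplex polish. These sizes keep each stage's sampling error comfortably
inside the asserted tolerances.

## Known limitations

* The protocol's recovery statistics are properties of this landscape and
  schedule; the toy cannot say anything about force-field accuracy or real
  solvent effects.
* Plateau boundaries on slowly ramping series are ambiguous at the level of
  the drift tolerance divided by the ramp slope; the refinement cap bounds
  the error at one window.
* The ligand is orientationally rigid by construction, so the monitored
  RMSD channels are strongly correlated with d_RC; in real data they carry
  independent information.
* Bridging-water analysis counts any water atom within the cutoff
  (oxygen-only available as a flag); with no solvent present it returns an
  all-zero layer with a warning rather than failing.
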