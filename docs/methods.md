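# Methods

This note records the models behind each analysis, the defaults and why
they were chosen, what the synthetic generator does and does not emulate,
and the numerical conventions a careful user should know.

## Static interaction model

Crystal structures of proteins at typical resolution carry no hydrogens,
so all static hydrogen-bond logic is heavy-atom based: a bond is a pair of
H-bond-capable polar atoms within a distance cutoff.  Capability follows
common contact-map practice — backbone N donates and carbonyl O accepts;
side-chain N/O per residue type (Asn/Gln split into amide O acceptor and N
donor, carboxylates accept, Lys/Arg/Trp donate, His ND1/NE2 and all
hydroxyls ambivalent); waters ambivalent; Cys/Met sulfur is available as a
weak acceptor but off by default.  Non-standard residues (the chromophore)
use a CRO-style name table, with any other hetero N/O treated as
ambivalent.  There is **no donor-angle term in static mode** — with no
hydrogens an angle criterion would be guesswork; this is a documented
limitation, and borderline pairs near the cutoff should be read as
"polar contacts" rather than chemically certified bonds.

Pairs inside one residue, and backbone–backbone pairs of
sequence-adjacent residues (the covalent O=C–N neighbourhood), are
excluded.

Defaults, all configurable per call:

| quantity | default | rationale |
|---|---|---|
| chromophore-shell H-bond cutoff | 3.3 Å | conventional upper bound for heavy-atom N/O···N/O bonds |
| dimer-interface H-bond cutoff | 3.7 Å | interface seams include long polar pairs (~3.6 Å) that a 3.3 Å cutoff would drop |
| hydrophobic contact | apolar C···C ≤ 4.0 Å | van-der-Waals contact distance; "apolar carbon" = carbon not bonded to N/O, by per-residue name table |
| shell census radius | 4.0 Å | nearest-shell convention |

Water-mediated bridges are triples (chromophore polar atom, water O,
residue polar atom) with both legs within the H-bond cutoff; the record
keeps the longer leg as its metric and names the bridging water.

The shell census lists residues (waters excluded) with any heavy atom
within the radius of any chromophore heavy atom.  The chromophore's own
covalent neighbour residues are excluded when only their linking backbone
atoms reach the shell.  Classification into direct-H-bond /
water-mediated / hydrophobic subsets is non-exclusive, and members
matching no detector are reported explicitly as `unclassified` — the
census never forces a class.

## Interface quantification

Per-atom SASA is Shrake–Rupley sphere-point sampling: each atom's
probe-expanded sphere (element radii C 1.70, N 1.55, O 1.52, S 1.80,
H 1.20 Å; probe 1.4 Å) is covered with a golden-spiral lattice (default
960 points) and a point counts as accessible when outside every
neighbour's expanded sphere.  Doubling the point count changes totals by
< 0.5 % on the bundled test systems.  "Contact area" of a dimer interface
is the total ΔSASA summed over both subunits,
S(A) + S(B) − S(A∪B) with waters excluded (≈ 2× the half-interface
convention, which is available via `half=True`).

Interface H-bond *counting* follows the two-fold-symmetry reporting
convention: detection runs once on the coordinates as deposited, symmetry
copies are collapsed to a unique chain-blind bond list, and a bond whose
two partners are the same residue on the two chains counts once while
every other bond counts twice.  Doubling is a reporting convention, not
re-detection — in a real crystal the second copy of a bond deviates from
perfect symmetry and may drift across a distance cutoff, so counting from
the unique list is the stable choice.

## Geometry

Superposition is least-squares rigid-body fitting (Kabsch, via SciPy's
`Rotation.align_vectors`), pairing atoms by (residue number, atom name).
For mutant-vs-precursor comparisons the default fit set is Cα atoms of
residues common to both sequences — mutation sites contribute backbone
only — which isolates side-chain and chromophore displacements from the
fit itself.  Probe displacement (e.g. of the phenolic hydroxyl) is the
Euclidean distance between the probe positions after applying the fitted
transform.  Whole-monomer Cα fitting is the default; a local-site fit can
be requested with an explicit atom list, since which convention a given
publication used is often unstated.

Ring planes are least-squares planes (smallest principal direction);
plane–plane angles use the acute convention [0°, 90°], vector–vector
angles the full [0°, 180°].  The His-side-chain–hydroxyl distance is
operationalized as min over {ND1, NE2} × {OH}.

## Ensemble observables

* **Equilibration trimming** discards the leading 25 % of frames by
  default (keep the final 75 %), matching the common practice of analysing
  only the equilibrated production tail; configurable.
* **RMSF** fits every frame to the iteratively refined ensemble average
  (three fixed-point iterations, batched Kabsch) on Cα by default, then
  averages per-atom RMSF over side-chain heavy atoms (Cα fallback for
  glycine) — side-chain mobility is usually the quantity of interest when
  comparing chromophore pockets.
* **Trajectory H-bond criterion**: with hydrogens present,
  donor–acceptor ≤ 3.5 Å AND H–donor–acceptor angle ≤ 30°; without
  hydrogens, heavy-atom ≤ 3.3 Å.  The angle term only exists where
  hydrogens do.
* **π–π stacking**: ring-centroid distance ≤ 5.5 Å AND inter-plane angle
  ≤ 30°, per frame.  These are conventional geometric bounds; both are
  parameters, and counts should be quoted with the criterion used.
* **Lifetimes** are maximal runs of consecutive presence × dt.  Total
  event length always equals total present frames (mass conservation); a
  contact present in every frame is one event spanning the whole series.
* **Dipole states**: the per-frame fragment moment uses the charge table
  supplied by the caller (protonation state is the caller's choice and
  travels with that table).  Since the fragment may carry net charge, the
  reference point — fragment heavy-atom centroid — is part of the result.
  Frames are classified cis/trans by the angle between the phenolic O–H
  bond vector and the direction from the phenol oxygen to the
  imidazolinone carbonyl oxygen, binarized at 90° (proton toward the
  carbonyl = cis = minor state).  When hydrogens are absent the frames are
  *not* classified — there is no silent heavy-atom proxy.
* **2-D state densities** are normalized histograms over
  (dipole modulus, axis angle); the integral over bins is 1 to machine
  precision regardless of binning.

## Synthetic generator: what a green test establishes

The generator builds a ~20-residue toy pocket around an idealized planar
chromophore with CRO-style atom names, placing each neighbour so that its
*minimum* distance to the chromophore equals a prescribed target
(realized to < 0.01 Å, verified at construction; placement raises rather
than silently approximating, and a no-side-effect search guarantees no
unintended polar or apolar contacts).  The default spec states a pocket
with 19 shell residues: 5 direct H-bond partners, 6 residues bridged by 2
waters, 7 hydrophobic contacts and 1 unclassified neighbour; the default
ensemble is 750 frames at dt = 100 ps (75 ns of analysed trajectory) with
isotropic per-coordinate σ = 0.10 Å.

Ensemble dynamics are deliberately simple so expectations are closed-form:

* positional noise is i.i.d. Gaussian per frame (RMSF → σ√3, no
  autocorrelation);
* switched contacts follow a two-state Markov chain with prescribed
  stationary occupancy and mean on-dwell, realized by pinning the acceptor
  at 2.9 Å (on) or 4.5 Å (off) along the donor→acceptor axis from the
  *noisy* donor position — the toggled acceptor and the hydroxyl proton
  carry no Gaussian noise of their own, so occupancy, dwell and state
  populations equal the recorded random draws exactly rather than
  approximately (adding noise to those atoms would smear the geometric
  toggle across the criterion cutoff and turn exact bookkeeping into a
  seed-dependent approximation);
* hydroxyl states are i.i.d. Bernoulli per frame with the prescribed
  trans fraction, realized by exact trans/cis proton placement.

The manifest records every random draw (per-frame contact booleans, state
labels, realized per-atom fluctuations), so analysis output can be
predicted without rerunning the generator.  Frames are quantized to
10⁻⁶ Å and structure coordinates to 10⁻³ Å so text round-trips are exact.

What the generator does **not** emulate: autocorrelated collective
motion, anharmonic side-chain rotamer jumps, solvent, realistic
chromophore electronic structure, or force-field energetics.  A green
parameter-recovery test therefore establishes that the *estimators* are
correct (counting, fitting, classification, normalization), not that any
particular protein behaves like the toy.  The two shipped charge tables
(`charges_*_synthetic.txt`) are synthetic test sets — a neutral one and a
net −1 phenolate one to exercise origin-dependence — not force-field
parameters; real analyses must supply the force field's own fragment
charges.

## Numerical conventions and edge cases

* Alt-locs: the highest-occupancy conformer is kept (ties: blank/'A'
  first); the number of dropped conformers is recorded in metadata.
* Coordinates are treated as orthogonal Å; CRYST1 is carried through but
  unused; no symmetry expansion is performed.
* Residue numbering follows the input file verbatim.
* Collinear fit/ring atom sets raise degenerate-geometry errors instead
  of returning an arbitrary plane or rotation.
* Ring-plane normals get a deterministic sign (first nonzero component
  positive); angles never depend on it.
* Unknown elements in SASA fall back to the carbon radius with a warning.
* All stochastic paths take an explicit integer seed; identical seeds give
  bitwise-identical ensembles, manifests and report files.

## Known limitations

* Static H-bond detection is distance-only (no hydrogens, no angles, no
  energies); CH···O and halogen bonds are out of scope.
* The interface module classifies nothing as "biological" vs "crystal
  packing"; it measures whatever chain pair it is given.
* Absolute dipole moduli for charged fragments depend on the reference
  point; comparisons across conventions are only meaningful for neutral
  charge sets (verified origin-independent to 10⁻⁹ D in the tests).
* Ensemble readers handle multi-MODEL PDB and the whitespace XYZ dialect
  only; binary MD trajectory formats are out of scope.
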