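# Methods

## Lattice model

The ring is an idealized 13_3 B lattice: `n_pf` = 13 protofilaments, a
3-start helix (`helix_start` = 3), monomer rise h and axial dimer repeat
c = 2h.  The nucleotide state selects the repeat: c = 81.20 Å (GDP) or
83.38 Å (GTP); h may also be set directly.  Dimer k is the template rotated
by (k−1)·2π/13 about the MT axis (z) and raised by (k−1)·3h/13, so one full
lateral turn rises exactly three monomers — the closure identity of a
3-start lattice.  The ring is axially periodic with Lz = c (default box
293.85 × 293.85 × c Å³), so it tiles into an infinitely long MT.

The helical continuation past protofilament 13 would sit at 3h, but the
periodic images of protofilament 1 sit at multiples of c = 2h; the seam
ligand is therefore dimer 1 translated by (helix_start−1)·h = c, exactly one
monomer rise out of register, producing the α–β lateral packing that defines
the seam.  This construction requires `helix_start` odd; an even start is
rejected when a seam subsystem is requested.

Orientation convention: the template dimer is placed with its β-subunit at
low z and α at high z.  Consequently the +c periodic image of a dimer
presents its β to the receptor's α, which matches the standard receptor
conventions for MT energetics: in longitudinal subsystems the receptor is
the dimer whose α-tubulin faces the interface (so Lα and Rβ contribute
essentially nothing there), and in lateral subsystems the receptor is the
dimer whose M-loop faces the interface (receptor k, ligand k+1).  Residues
in a subsystem carry a continuous 1..N numbering in the order receptor-α,
receptor-β, ligand-α, ligand-β, with (role, subunit, residue number) as the
primary key so templates missing a few residues remain well-defined.

Cofactors (GTP/GDP, Mg²⁺, coordinating waters) are ordinary named residues
assigned to their host subunit, so they appear as first-class rows in
per-residue tables and in domain aggregation.

## Energy model

Interaction energies use the single-trajectory MM/GBSA convention: complex
and isolated partners are scored on identical coordinates, so bonded and
intramolecular nonbonded terms cancel exactly and

ΔE = ΔE_vdW + ΔE_ele + ΔE_GB + ΔE_SA (kcal/mol).

* **vdW, ele** — cross-molecular pair sums only: 12-6 Lennard-Jones with
  r_min,ij = r_min,i/2 + r_min,j/2 and ε_ij = √(ε_i ε_j); Coulomb with
  k_e = 332.0636 kcal·Å·mol⁻¹·e⁻² and solute dielectric ε_in (default 1).
  Each pair term is half-assigned to each partner atom, so receptor and
  ligand shares of these components are symmetric by construction.
* **GB** — OBC-II: pairwise HCT descreening integrals with screened reduced
  radii (ρ = R − 0.09 Å), tanh rescaling (α, β, γ) = (1.0, 0.8, 4.85), Still
  pairwise function f_GB = √(r² + B_iB_j·exp(−r²/4B_iB_j)), prefactor
  −½(1/ε_in − 1/ε_out) with ε_out = 80.  Per-atom shares are the rows of
  the ordered double sum (self term plus half of each unordered pair).  The
  interaction contribution of an atom is its complex share minus its
  isolated-partner share — this is the only route (with SASA) by which
  receptor and ligand totals can differ, i.e. any receptor/ligand asymmetry
  of the totals is purely a solvation effect.
* **SA** — Shrake–Rupley solvent-accessible surface area on a deterministic
  golden-spiral point set (default 240 points per atom in pipeline runs; 960
  in high-accuracy checks), probe 1.4 Å, atom radii taken from the intrinsic
  GB radii; E_SA = γ·SASA + β with γ = 0.0072 kcal·mol⁻¹·Å⁻², β = 0.
  Coordinates are first rotated into a deterministic principal-axes frame so
  that SASA is an exact function of internal geometry, making the whole
  interaction energy exactly invariant under rigid motion of a subsystem.

No pair cutoff is applied: subsystems are small after dimer extraction and
a cutoff would only introduce a tolerance knob.  No entropy term is
computed.  Waters and bulk ions are expected to be stripped before scoring;
nucleotide-site Mg²⁺ and its coordinating waters are retained as named
residues.  Ensemble statistics over trajectory frames report per-residue and
total mean ± population SD (ddof = 0), with the SD of any sum computed from
per-frame sums, never by summing per-residue SDs.

The GB flavor and the surface-tension constant are this package's declared
defaults (OBC-II, γ = 0.0072); they are standard choices for MM/GBSA
rescoring, not quantities with a single canonical value.

## Aggregation

Per-ring contributions of any entity x follow the ring-sum convention:
lateral E_x = ϵ_x(seam) + Σ₁²ϵ_x(R_kL_{k+1}); longitudinal
E_x = Σ₁³ϵ_x(R_kL′_k).  The subunit/role matrix is the 2×2 partition of the
per-residue table into (L/R) × (α/β) cells with exact margins.  Domain
aggregation uses an editable YAML map of inclusive residue-number ranges per
subunit (standard tubulin nomenclature: T1–T7 loops, H1–H12 helices, S1–S10
strands, M-loop, termini) plus residue-name overrides for cofactors; the
bundled ranges follow conventional tubulin numbering and are data, not code.
Unmapped residues aggregate under a reserved `unassigned` domain so domain
sums always conserve the total.  Model differences are computed entity-wise
(GTP − GDP by convention) with outer-join zero-fill flagged per entity.
The ring energy diagram orders the 13 per-interface totals around the ring
and reports the weakest interface by |E| (ties reported as a set).

## Spatial profiles

Residue position is the mass-weighted center of mass of the residue's
atoms.  The MT axis is refit per frame by a plane fit (SVD) to the dimer
COMs after removing the known per-step helical rise, since distorted rings
would otherwise bias radii.  Declared conventions, reported in output
headers because no single standard exists:

* **lumen reference** — r_lumen is the 1st percentile of atomic distances
  from the axis over the whole ring (a robust inner-surface estimate;
  configurable, or a fixed value may be supplied).  The radial coordinate is
  x = r_residue − r_lumen, clamped at 0.
* **tangential origin** — the plane through the contact midpoint (midpoint
  of the closest atom pair between the receptor and the designated laterally
  adjacent dimer), normal to the local tangential unit vector t̂ = ẑ × r̂.
  The coordinate is oriented away from the adjacent dimer — it is a distance
  from that neighbor — placing the dimer body at positive x and the tubulin
  COM near x ≈ 30 Å on realistic geometry.  The raw (unoriented) sign
  convention is available for symmetry analyses.

Energies are summed over half-open bins [x, x+w) anchored at 0 (w = 3 Å
default); a value exactly on an edge belongs to the upper bin.  Binning is
exactly conservative per component, and refining the width then re-merging
bins reproduces the coarser profile exactly.  The inner/outer split sums
bins below/above a threshold (bins whose lower edge is at or above the
threshold count as outer) and reports the outer fraction of the total.

## Geometry metrics

Dx is the xy-projected distance between the COM of dimer 4 and the joint
COM of dimers 10 and 11; Dy likewise for dimer 1 against dimers 7 and 8.
On an ideal ring of COM radius R both equal R(1 + cos(π/13)) because the
joint COM of two adjacent vertices sits diametrically opposite the reference
vertex at radius R·cos(π/13).  For an elliptically distorted ring with
semi-axes R ± δ, exact trigonometry gives (Dy − Dx)/2 ≈ 1.94·δ·2/2, so the
half-difference of the diameter series recovers 2δ to within ~3%; the
recovery tests use this estimator at a 5% tolerance.

Backbone RMSD selects atoms named N/CA/C/O (cofactors drop out naturally)
and by default reports the deviation after optimal Kabsch superposition;
the unfitted lab-frame deviation is available via a flag since either
convention is defensible for a periodic ring.

## Synthetic data

The generators are pure functions of (spec, seed) and define the study
conditions for all tests:

* **toy dimers** — two labeled subunits of bead residues (default 8 residues
  × 3 atoms per subunit) arranged as azimuthal bead rings stacked over one
  monomer rise each, with the scaffold radius bulging at the subunit center
  and tapering toward the ends.  The bulge plays the role of the M-loop
  equator: lateral closest contacts track subunit centers, which is what
  makes the seam's one-monomer register flip detectable as an α–β distance
  ordering.  Charges are seeded Gaussian draws (SD 0.3 e) shifted to an
  exact net charge (default −4 e, tubulin-like net negative); LJ and GB
  parameters are a minimal bespoke preset (r_min/2 ∈ [1.7, 2.0] Å,
  ε ∈ [0.05, 0.2] kcal/mol, GB radius 0.9·r_min/2, screen 0.8) chosen to
  exercise every energy term rather than to excerpt any real force field.
  Toy rings in tests use ring radius 36 Å so the beads form real lateral
  contacts; the default spec radius of 115 Å is the realistic MT value for
  full-size templates.
* **ring trajectories** — frame t applies an elliptical distortion with
  semi-axes R·(1 ± u_t), u_t = (δ/R)·sin(2πt/n_frames), plus isotropic
  Gaussian jitter σ; δ = σ = 0 reproduces the ideal ring bit-exactly.
* **mock tables** — 13-subsystem per-residue table sets with planted
  subunit/role cell sums, an optional block (M-loop-like) carrying an exact
  fraction of each cell, or an outer radial group carrying an exact fraction
  of every component, with ground truth returned alongside.  Noise is added
  after planting, so noiseless recovery is exact by construction.

What passing tests show — and do not show — about real data: the synthetic
systems verify the machinery (lattice geometry, energy decomposition
identities, aggregation conservation, coordinate conventions, determinism)
exactly, but their magnitudes are not tubulin's: toy lateral contacts are
net repulsive because compact like-charged beads dominate, whereas real
lateral interfaces are stabilized by shape-complementary vdW contacts the
bead model does not possess.  Conclusions about real MT energetics come
from applying the pipeline to real parameterized templates, not from the
toys.

## Numerical choices

* Tolerances: pairwise terms are validated against brute-force oracles at
  10⁻⁹ relative; per-residue additivity holds to 10⁻⁶ relative (it is exact
  up to floating-point summation order); helical closure to 10⁻⁶ Å.
* Degenerate inputs: zero inter-atomic distances raise singularity errors
  (coincident atoms are also rejected in the descreening sum); atoms missing
  parameters raise an error listing the offending (residue, atom) keys;
  empty selectors and disjoint entity sets in differences raise rather than
  silently returning zeros.
* Tie-breaks: the weakest-interface report returns the full argmin set under
  exact |E| equality.
* Problem sizes: the default test and acceptance runs score 26 subsystems of
  96-atom toy systems with 120-point SASA, chosen so the full suite and the
  acceptance script each complete in seconds while exercising every code
  path; SASA accuracy checks against analytic spheres use 960 points.

## Known limitations

* The ring is ideally symmetric; real MT models carry small per-dimer
  deviations from helical symmetry, which this package deliberately does not
  reproduce.
* Protonation states, explicit solvent, entropy, and dynamics are out of
  scope; His-protonation differences between nucleotide states must be
  encoded in the input template and parameters.
* The lumen reference and tangential origin are declared conventions; any
  profile comparison across tools must state both.
* GB is OBC-II only; other GB flavors would shift absolute solvation terms,
  though interaction differences are less sensitive.
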