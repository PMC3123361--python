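# Methods

## The motif model

The object of study is the six-residue calcium-binding loop with consensus
`D-x-[DN]-x-D-G` (positions numbered 1-6). Its metal interactions are: the
side-chain oxygens of positions 1, 3 and 5; the backbone carbonyl oxygen of
the residue immediately following position 6; and the side chain of at
least one additional acidic (occasionally amide) residue later in the
sequence, at separations from 2 to over 100 residues. Position 6 is
glycine in every metal-bound instance we model, but the search does not
require it; `MotifHit.has_gly6` records it instead.

Two complementary detectors are implemented.

**Structural detector.** A pseudoatom query in the SPASM tradition: each
constrained residue contributes a main-chain pseudoatom (Cα) and a
side-chain pseudoatom (heavy-atom centroid; Cα for Gly). The query
constrains only the three D positions — window offsets 0/2/4 of a
five-residue window — with allowed sets D, [DNST] and [DN] respectively
(Ser/Thr at the middle position ligate through their hydroxyl oxygen, as in
the fungal-lectin site). Candidate windows are sequence-contiguous:
consecutive internal indices and neighbour Cα-Cα below 4.5 Å; discontiguous
multi-segment queries are out of scope. A window is accepted when its six
pseudoatoms superpose on the query's within `pseudo_rmsd_cutoff`. The
cutoff defaults to 1.0 Å; this is a package choice in the range commonly
used for pseudoatom substructure matching, exposed as a flag, not a value
taken from any publication. Accepted windows additionally carry the
30-atom extended-main-chain RMSD against the reference loop (below).

A distance-matrix pre-filter runs before each Kabsch fit: if any
inter-pseudoatom distance differs from the query's by more than
`sqrt(2N) * cutoff` (N = 6 pseudoatoms), the window cannot reach the cutoff
after any rigid superposition, because the residual vectors e_i after an
optimal fit satisfy |Δd_ij| ≤ ‖e_i‖+‖e_j‖ ≤ sqrt(2·Σ‖e‖²) = sqrt(2N)·RMSD.
The bound makes the filter provably inert (the brute-force equivalence test
exercises this) while still discarding most decoy geometry cheaply.

**Sequence detector.** The functional pattern
`D x [DNST] x [DN] [GADN]` + spacer(k) + `[DE]`, scanned with overlaps
reported (PROSITE-style). Position 6 is widened from G to [GADN] and an
explicit acidic tail is required because a sequence match is meant to imply
a *functional* site, where the downstream acidic ligand at the structurally
observed spacing is part of the definition. For separations above 30
residues the tail is dropped — at such distances the spacer is not a
meaningful sequence constraint. `X` and `-` never satisfy a constrained
position; wildcard positions accept any amino-acid letter.

**Metal screening.** Instead of visual inspection of search hits, a window
counts as metal-bound when at least two side-chain oxygen atoms from its D
positions lie within the coordination cutoff of one indexed metal. The
metal element set defaults to {Ca, Mn, Mg, Sr, Na, K, Zn, Cd, Tb, La}:
EF-hand-type sites are routinely crystallized with surrogate cations (the
galactosaminidase site binds Mn in the deposited structure), so restricting
to Ca would miss genuine sites.

## Superposition and the extended main chain

Rigid superposition is the Kabsch least-squares solution (via
`scipy.spatial.transform.Rotation.align_vectors`, reflection branch
corrected); RMSD is reported over the same atoms that are fitted.
Quantitative loop comparisons use the *extended main chain*: N, Cα, C, O
and Cβ per residue — 30 atoms over a six-residue window. A virtual Cβ is
constructed for Gly (and for any residue missing its real Cβ, with a
warning) at 1.522 Å from Cα with N-Cα-Cβ = 110.4° and C-Cα-Cβ = 110.6°, on
the L-amino-acid side of the backbone plane; these are standard ideal
values, and the construction agrees with the widely used fixed-coefficient
virtual-Cβ formula to ~0.02 Å at ideal backbone geometry. Real Cβ atoms are
used whenever present; only Gly gets the virtual atom in normal operation.

## Coordination shells and motif linkage

All protein O/N atoms within the coordination cutoff (default 3.0 Å;
typical Ca-O bonds are ~2.4 Å) are direct ligands: side-chain atoms are
`sidechain_direct`, backbone O is `backbone_carbonyl`, backbone N is
`other` (geometrically present, chemically implausible as a Ca ligand — it
is listed, not hidden). A water oxygen within the cutoff recruits protein
polar atoms within 3.5 Å of itself as `water_mediated` ligands carrying the
bridging-water reference. The coordination number counts direct ligand
atoms plus each bridging water once. A bidentate carboxylate contributes
two listed atoms but one ligand *residue* for residue-level logic (shared
ligands of binuclear pairs, separations).

Additional-ligand separation uses the exclusive convention: the number of
residues strictly between motif position 6 and the ligating residue,
counted on internal sequential indices so that author-numbering gaps and
insertion codes cannot distort it. The published separations we compare
against (2 for the blade sites, 5 for the canonical EF-hand loop, 36 for
the adhesin) are reproduced by this convention; if a future structure
disagrees, the discrepancy should be documented rather than the convention
silently changed. A side-chain ligand from a residue *preceding* the motif
sets `preceding_additional_flag` — across all known structural contexts the
additional ligand follows the motif, so a preceding one is an anomaly worth
surfacing. Binuclear centres are metal pairs sharing at least
`shared_ligand_min` ligand residues (default 1), reported once per
unordered pair.

## The synthetic template

The packaged reference loop and the structure generator are built from
internal coordinates, not from any deposited structure, so the repository
is self-contained. The chain is assembled residue-by-residue with ideal
bond lengths and angles (NeRF placement; Engh-Huber-like values, ω = 180°).
The 12-residue loop DKDGDGTITTKE carries the motif at positions 1-6 and the
canonical downstream Glu at position 12 (separation 5); six-residue
ideal α-helices flank it. The loop's φ/ψ and the ligand χ angles were
determined once by least-squares fitting the canonical coordination
geometry — the three Asp Oδ1, the position-7 backbone O and the bidentate
Glu carboxylate at 2.4-2.6 Å from a free metal position, with steric
hinge penalties — and frozen as the documented table in
`camotif.synthetic`. The resulting site: ligand distances 2.44-2.58 Å,
Thr9 Oγ1 held at 4.15 Å (the geometry a bridging water would occupy in a
real loop; no explicit water is modelled), minimum non-bonded heavy-atom
distance 2.6 Å. Agreement of this idealized loop with any real EF-hand is
checked only by the optional accession-based tests, never assumed.

Configurable aspects: motif-position mutations; the additional-ligand
separation (the Glu is relocated and its χ angles re-aimed at the metal by
a deterministic grid + simplex search; geometrically unreachable
separations raise a configuration error); decoy chains that preserve the
loop's composition but perturb every backbone dihedral by at least 30°,
translated away from the site; iid Gaussian coordinate noise applied to
every atom. Ground truth (planted positions, ligand distances, separation,
decoy chain ids) is returned alongside.

What the generator does *not* emulate: crystallographic artifacts
(alternate conformations, missing atoms, occupancies below 1), solvent,
real side-chain rotamer distributions, and genuinely irregular loop
flanks. Passing the planted-truth tests therefore demonstrates the
correctness of the search and characterization machinery, not recall on
experimental structures; the latter is what the optional accession checks
measure.

The sequence generator samples a background from database-like amino-acid
frequencies (optionally Asp-enriched), plants motif strings drawn from the
pattern's allowed sets, and rejection-samples until no spurious core match
remains outside planted sites (capped; the cap errors out with advice to
lower the enrichment). The slippage operator inserts tandem DG copies at a
marked DG site, shifting recorded motif positions accordingly; matches the
expansion creates are recorded truth, mirroring how a repeat tract can give
birth to the motif once three D positions align.

## Problem sizes and numerical choices

Simulation-based tests use 30-100 replicates per condition with fixed
seeds; the noise-recall curve is measured at σ ∈ {0, 0.1, ..., 0.5} Å and
the σ = 0.2 Å recall (0.97 over 100 replicates, seeds 1000-1099) is pinned
exactly since the generator is deterministic. The motif-frequency check
plants the motif in exactly 74 of 200 rows (prevalence 0.37) so the
binomial interval tests the estimator rather than the carrier draw.
Brute-force equivalence runs over 50 random generator configurations.
Dihedrals are reported in (-180°, 180°]; φ/ψ are undefined at chain
termini. RMSDs print to 2 decimals, distances to 2-3. All randomness flows
through `numpy.random.default_rng` with explicit seeds; identical configs
give byte-identical outputs.

Secondary-structure context is a deliberately simple φ/ψ-region classifier
(helix: φ ∈ [-120°, -30°], ψ ∈ [-80°, 5°]; strand: φ ∈ [-180°, -45°],
ψ ≥ 90° or ≤ -150°; else other) applied to the six residues flanking each
motif side, taking the majority label. It approximates what a full
assignment program would produce and is used only for context reporting,
never for filtering.

## Design choices where the design was open

- The superposition is fitted on, and the RMSD reported over, the same 30
  extended-main-chain atoms; fitting on a subset and scoring another adds a
  convention without improving comparability.
- Real Cβ atoms are preferred over virtual ones for non-Gly residues in
  RMSD windows; an all-virtual variant would change values by well under
  the reported precision at ideal geometry.
- In multi-copy crystals the first chain containing the motif is the
  default reporting copy.
- Only MODEL 1 of multi-model files is read; the targets are crystal
  structures.
- Alternate locations collapse to the highest-occupancy variant (ties by
  altloc character order).
- Frequency scans over alignments are window-restricted (motif columns ± 6
  alignment columns, mirroring the flank width used when excerpting motif
  regions for profile searches); whole-sequence scanning is available by
  calling `scan` on the degapped rows directly.
- `scan_all_spacings` deduplicates by start position, keeping the smallest
  matching spacer.

## Known limitations

- The structural detector only enumerates sequence-contiguous windows; a
  motif assembled from two chain segments would be missed.
- PDB parsing is delegated to gemmi; pathological fixed-column files that
  gemmi cannot read are rejected as a whole rather than record-by-record
  (atoms that parse but violate basic sanity are skipped with a logged
  warning).
- The idealized template is one conformation; recall under noise measures
  robustness around that conformation only.
- The water-mediated ligand class depends on crystallographic waters being
  present in the input; structures solved without modelled solvent will
  under-report it.
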