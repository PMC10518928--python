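# Methods

## The QTY substitution code

Membrane proteins expose hydrophobic helix faces to the lipid bilayer,
which makes them aggregate in water and hard to express, purify and
screen. The QTY code is a deterministic design rule that converts a
membrane protein into a water-soluble analogue by pairwise residue
substitution inside its transmembrane (TM) segments only:

    Leu -> Gln    Val -> Thr    Ile -> Thr    Phe -> Tyr

Each pair swaps a hydrophobic side chain for a hydrophilic one of very
similar size and shape, and none of the four introduced residues is
charged. The designed variant therefore keeps the native length,
register, charged-residue census and (empirically) the native fold,
while losing the hydrophobic helix surface. The map is closed: Trp, Met
and Ala are not substituted, and because Gln, Thr and Tyr lie outside
the map's domain the code is idempotent. Residues outside annotated TM
segments are never touched.

Two variation metrics summarize a design: TM variation, the percentage
of TM residues substituted, and total variation, the percentage of all
residues substituted. Both are exact integer-count ratios kept as
rationals internally and rounded half-up to two decimals only for
reporting, so published-table comparisons are reproducible bit-for-bit.
A protein with no TM segments yields the identity design with both
metrics 0 by convention (avoiding 0/0).

## Coordinates and topology

TM segments use 1-based inclusive residue coordinates, the UniProt
feature-table convention; internal arithmetic converts to 0-based
half-open slices at module boundaries. Topologies are validated against
their sequence (sorted, non-overlapping, within range) before any
design. Three on-disk dialects are read: a TSV (protein_id/start/end), a
JSON map, and UniProt flat-file `FT TRANSMEM s..e` lines; all three
parse to identical objects. Non-standard residue codes (B, J, O, U, X,
Z) are accepted in sequences but never substituted, are excluded from
pI/GRAVY sums, and contribute a configurable 110 Da average mass to MW
with a warning — robustness without inventing chemistry.

## Physicochemical properties

**Molecular weight** is the sum of average residue masses (ExPASy
average-mass table, shipped as JSON) plus one water (18.01524 Da),
stored in Da at full precision and displayed in kDa at 2 decimals.

**Isoelectric point** is the root of the Henderson–Hasselbalch net
charge

Z(pH) = Σ_pos n_g / (1 + 10^(pH − pKa_g)) − Σ_neg n_g / (1 + 10^(pKa_g − pH))

found by bisection on [0, 14] to 1e-4 pH (Z is strictly decreasing, so
the root is unique). The pKa set is Bjellqvist's, as used by the ExPASy
Compute pI/MW tool, including its residue-specific N-/C-terminal
refinements; it ships as an editable JSON constants file and the tests
pin it (cross-checked against both a fine pH-grid scan and Biopython's
`IsoelectricPoint` inside the interior of the latter's clamped search
interval). Cys is treated as reduced (no disulfides), and the canonical
sequence with initiator Met is used as given.

**Hydropathy** (H_γ) is the Kyte–Doolittle mean (GRAVY) over standard
residues. The scale is pluggable; KD is the default because every QTY
pair strictly decreases it (L→Q 3.8→−3.5, V→T 4.2→−0.7, I→T 4.5→−0.7,
F→Y 2.8→−1.3), which gives the design its monotone-solubilization
property. Per-substitution MW deltas are signed (L→Q +14.97, V→T +1.97,
I→T −12.04, F→Y +16.00 Da): the net MW increase seen in practice is an
empirical outcome of composition, not an invariant, so tests assert the
exact Δ from the substitution list rather than naive monotonicity.

## Structure comparison

Native and QTY-variant models are paired by sequential residue order
(the code preserves indexing), so no alignment is used. Superposition
is the closed-form Kabsch solution (SVD with reflection correction;
rotation always proper to 1e-9), validated in tests against an
independent brute-force minimizer over an Euler-angle grid with simplex
refinement. Full RMSD uses all CA atoms; TM-restricted RMSD refits on
TM-segment CAs only, which removes the flexible loops that dominate
full-chain RMSD.

Secondary structure is assigned from CA geometry with P-SEA-style
distance windows: residue window i is helical when |CA(i)−CA(i+3)| ∈
[4.5, 6.0] Å and |CA(i)−CA(i+4)| ∈ [5.7, 6.7] Å (all five residues of a
satisfying window labeled H), extended when |CA(i)−CA(i+2)| ∈
[6.6, 7.7] Å, else coil. Sequential CA–CA gaps above 4.5 Å are chain
breaks that split windows with a warning. A DSSP-format file, when
supplied, overrides the heuristic (full hydrogen-bond DSSP is out of
scope; only helix content R_H = #H/length is needed downstream). The
polar-plot datum for a pair is (radius = full RMSD, angle = min(180°,
|ΔR_H|·180°), hemisphere = upper iff native pI ≥ 7 — the tie at exactly
7 goes upper by convention). The angle normalization treats ΔR_H as a
fraction mapped linearly onto the 180° scale; this is a documented
choice, since only the ordering of angles matters for the plot.

SASA is Shrake–Rupley with a 1.4 Å probe and 960 quasi-uniform test
points per atom from a golden-section spiral (deterministic — no random
sphere sampling), with vdW radii C 1.70, N 1.55, O 1.52, S 1.80 Å and a
1.70 Å default for unknown elements. The 960-point default reproduces
the analytic single-sphere area to better than 0.5 %.

YRB atom classes mark hydrophobic surface: yellow = carbons with no
covalent N/O neighbor (per-residue rule table), red = Asp/Glu
carboxylate and C-terminal oxygens, blue = Lys/Arg side-chain
nitrogens. The hydrophobic-patch fraction is yellow SASA over total
SASA. Because a designed variant has no modeled side chains without an
external predictor, the packaged native/variant patch comparison uses a
reduced representation — backbone + CB, with residue-typed CB radii
approximating side-chain bulk and the CB carrying its side chain's
class (yellow iff the residue's KD hydropathy is positive). Full-atom
models use their own atoms and the full rule table; reduced mode is
auto-detected.

## Function-text embedding and association scoring

Descriptions are lowercased; parenthesized PubMed reference blocks and
bare `PubMed[: ]NNNNNNN` patterns are removed; punctuation is stripped;
tokens are split on whitespace and filtered against a vendored English
stopword list (the classic Glasgow IR list, stored as package data so
results do not drift with library versions). Cleaning is idempotent.

The vocabulary is the top-MF terms by total corpus count (ties broken
alphabetically; MF exposed on the 50–250 grid in steps of 50). Counts
are weighted with the smoothed-idf TF-IDF convention, weight(d,t) =
tf·(ln((1+N)/(1+df))+1), then L2 row normalization — fixed to this
convention so hand oracles are unambiguous; a term present in every
document has idf factor exactly 1. The N×MF matrix is embedded in 3D by
UMAP with n_neighbors=10, n_components=3, min_dist=0.5,
metric='correlation', random_state=16 (all overridable); UMAP is
delegated to umap-learn, since the algorithm is prior art — this module
owns only the contract and defaults. Embeddings are deterministic per
seed. Note that an all-zero TF-IDF row (empty description) has no
defined correlation distance; corpora should carry non-empty texts.

Association scoring formalizes "nearby proteins share pathology": for
protein p and cancer c, score(p,c) is the fraction of p's k nearest
Euclidean neighbors (self excluded; distance ties broken by index
order) annotated with c, and p is flagged `is_novel` for c when it
lacks the label and score ≥ threshold. k=10 and threshold=0.6 are the
defaults — the source workflow is qualitative about both, so they are
exposed as flags. Scores are invariant under rigid motion of the
embedding.

## Synthetic study conditions

The generators define the conditions every test and the acceptance
script run under:

- **Proteins**: alternating polar loop / hydrophobic TM architecture;
  2–7 TM helices of 18–25 residues (typical single-span lengths), loops
  of 4–20 residues. TM composition is drawn from {L,I,V,F,A,M,G,W} with
  hydrophobic-heavy weights (94 % of mass on hydrophobics); loops from
  all 20 residues with polar-heavy weights (20 % hydrophobic mass).
  The 4-residue loop minimum keeps ideal-bundle connectors below the
  4.5 Å chain-break threshold at the default 8 Å bundle radius.
- **Structures**: each TM segment is an ideal α-helix (1.5 Å rise,
  100°/residue, 2.3 Å CA radius) on an antiparallel bundle; loops are
  straight connectors with a small perpendicular bulge; CB atoms sit
  1.53 Å from CA pointing away from the local axis. No side-chain
  packing realism is attempted — sufficient for the SS, RMSD and SASA
  contracts. Perturbations are isotropic Gaussian CA displacements,
  optionally restricted to TM or loop residues.
- **Corpora**: 4 planted classes (receptor/transporter/enzyme/channel)
  with disjoint 8-word keyword pools plus shared background words and a
  fake PubMed token per text; each class's cancer label is attached
  with probability 0.9, leaving ~10 % natural hold-outs for
  association-recovery tests. n = 200 (50 per class) at seed 1 is the
  standard recovery condition.

All generators are pure functions of (spec, seed) using an explicit
numpy Generator — no global state.

What passing these tests shows — and does not: the synthetic corpus has
clean, disjoint keyword structure, so perfect ARI/recall there
demonstrates the pipeline's correctness, not its performance on real
UniProt prose, where vocabularies overlap heavily and descriptions vary
in length. Likewise ideal bundles validate the geometry contracts, not
prediction quality on real structures, which this package deliberately
does not predict.

## Numerical choices and degenerate inputs

- Percentages: exact rationals, half-up rounding at 2 dp in reports.
- pI bisection tolerance 1e-4 pH on [0, 14].
- Kabsch: SVD; near-collinear sets (second singular value < 1e-8 of the
  first) compute with a warning because the rotation is not unique.
- RMSD requires ≥ 3 paired points (≥ 3 TM residues for TM RMSD).
- SASA requires ≥ 50 sphere points; 960 is the accuracy/runtime default.
- k-NN ties: stable argsort on distances, so equal distances resolve to
  the lower index; association output is sorted by score then
  (id, cancer) for byte-stable reports.
- Hemisphere tie at pI exactly 7: upper.
- Empty topology: identity design, metrics 0; empty text: empty token
  stream, all-zero TF-IDF row.

## Known limitations

- The pI/MW/hydropathy constants reproduce the ExPASy-style calculator;
  other tools (including the standalone calculator used for the
  published tables) may differ in the hydrophobicity scale, so absolute
  H_γ values are not comparable across tools — only the guaranteed
  monotone decrease under QTY is.
- The SS heuristic is CA-only; it is a helix-content estimator, not a
  DSSP replacement.
- The reduced CB-proxy patch fraction is a surface *ranking* tool for
  native/variant pairs on a shared backbone; its absolute values are
  representation-dependent.
- Structure prediction, pocket prediction, docking and MD are outside
  this package; it consumes models, it does not make them.
- The regression fixture for the three canonical reference proteins
  (MGAT3/MOGAT3, GPR35, SLC10A1) requires a one-time UniProt fetch; see
  `tests/data/table1/README.md`.
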