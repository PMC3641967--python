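# Methods

`enumol` grows virtual C/H/N/O molecules by stochastic fragment assembly
and profiles the resulting compound sets. This note documents the model,
its tunable parameters, the numerical conventions, and what the shipped
defaults do and do not reproduce.

## The growth model

A molecule starts as a single carbon atom whose four valences seed four
*growth branches* (the branch identity later classifies ring closures).
Growth proceeds in cycles. In each cycle every open valence site, in
creation order, draws one fragment from the library with probability
proportional to its enumeration weight and attaches it; after the sites
are processed, one ring closure is attempted with probability
`ring_closure_probability`. Growth ends when no open site remains, or at
a safety cap of 500 cycles (any leftover sites are hydrogen-capped; the
cap is never reached in practice at the default settings).

### The fragment library

The default library contains ten fragments — a hydrogen cap, two sp3
carbons (one of which may also accept double/aromatic bonds), an amine
nitrogen, hydroxyl/ether/carbonyl oxygens, a C–O diatomic, an acyl
carbon, and benzene — with enumeration weights scaled by the carbon count
of the largest fragment: weight = 6 / max(1, n_carbon), giving 6 for the
one-carbon-or-less fragments, 1 for phenyl, and 3 for the optional
two-carbon olefin. Attachment obeys three eligibility rules:

1. **Heteroatom flag.** Fragments flagged "no" never attach at N/O
   sites; the carbonyl oxygen (flag "NA": it closes with no open valence)
   is treated the same way, so N–N, N–O and O–O bonds never form.
2. **Bond-capability matching.** A fragment that must attach through a
   double bond (the carbonyl oxygen) requires a site whose own fragment
   carried the double-bond marker — in the default library, carbons
   introduced by the P,D,A-marked carbon. This is also why the library
   meaningfully contains two sp3 carbons: they differ in what their open
   sites can later accept.
3. **Geminal-heteroatom stability.** A carbon already bearing one
   single-bonded N/O accepts no second one, removing gem-diol, acetal and
   aminal motifs that no stable compound collection would contain.
   Carbonyl oxygens are exempt, so acids, esters and amides form freely.

### Termination and the size distribution

No molecular-weight constraint is applied — molecules are never rejected
or truncated by size. Termination is purely stochastic, through the
hydrogen cap, whose effective weight at carbon sites rises with the
current heavy-atom count n:

    w_H(n) = 6 · h_weight_multiplier · n^gamma .

A constant H weight would make molecule size a branching-process progeny
count: at a mean of 264 g/mol the SD exceeds 400 and at most about a
quarter of molecules can fall in the 200–500 window — qualitatively wrong
for the bell-shaped target distribution. The power-law damping makes
small partial molecules grow almost freely while large ones cap quickly.
The exponent gamma (default 3.0) is a structural constant setting the
SD/mean ratio (~0.25 at 3.0); it is not part of routine calibration. At
nitrogen/oxygen sites the H cap competes at its base weight instead:
those sites are sparse and carry little growth, and damping them early
would merely strand polar hydroxyl/amine groups, biasing composition
rather than limiting size.

### Ring closure

With probability `ring_closure_probability` per cycle, one eligible pair
of open sites is bonded (single bond): the atoms must be distinct,
non-adjacent (ring size >= 3), not both heteroatoms, must respect the
geminal-heteroatom rule, and the pair must match an active mode — same
branch = intra-chain, different branches = inter-chain. An eligible pair
is drawn uniformly; if none exists the attempt is a silent no-op.
Disabling both modes yields molecules whose only rings are benzene.

### Calibration and frozen defaults

`calibrate_growth` fits `(h_weight_multiplier,
ring_closure_probability)` by an iteratively refined grid search
minimizing the tolerance-normalized squared error of the sample MW mean
and SD against a target (default 264 ± 65 g/mol). The MW statistics
alone cannot identify the ring rate — the loss surface is a flat ridge in
that direction, and an unconstrained search drifts to a ring rate of
zero, i.e. an all-acyclic library that contradicts the whole point of
ring-assembly analysis. The ring rate is therefore fixed structurally at
0.30 per cycle (about 1.4 closures per molecule; ~80 % of molecules carry
at least one closed ring, in line with a natural-product-like scaffold
set), and the H multiplier is calibrated along that slice. Frozen
defaults, from a run with 4,000 molecules per trial on an 8×8 refined
grid:

| parameter                  | default | role                          |
|----------------------------|---------|-------------------------------|
| `h_weight_multiplier`      | 0.00574 | overall growth damping        |
| `ring_closure_probability` | 0.30    | closures per growth cycle     |
| `growth_damping_exponent`  | 3.0     | SD/mean ratio of the MW dist. |
| `max_growth_cycles`        | 500     | safety cap only               |

A 25,000-molecule run at these defaults gives mean MW 263.8, SD 63.3,
99.9–100 % below 500 g/mol and ~85 % between 200 and 500.

### Reproducibility

Randomness uses PCG64. Each molecule's substream derives from
(master seed, molecule index), so record *i* of any run can be
regenerated in isolation and a longer run's prefix is byte-identical to
a shorter one. Output files carry the config hash, seed and library
name.

## Property conventions

MW uses average atomic masses. PSA is Ertl topological PSA; AlogP is
the Crippen atom-contribution logP; HBA/HBD use the original Lipinski
N+O / N–H+O–H counting; rotatable bonds are non-ring single bonds
between non-terminal heavy atoms. Lipinski compliance defaults to the
strict zero-violation reading (a one-violation variant is available);
all rule thresholds are boundary-inclusive. The combined MW/PSA window
uses inclusive MW bounds and a strict PSA window (0 < PSA < 140 Å²).
Fsp3 is sp3 carbons over total carbons, 0 when carbon-free.

## Complexity score

MC = Σ log10(count + 1) over bridgehead atoms, spiro atoms, potential
(unassigned) tetrahedral stereocenters, rings of size >= 8, and
non-aromatic double bonds, plus a size term. The size-term expression is
read as n_heavy · 1.005^(−n_heavy), a slowly saturating reward that
peaks near 200 heavy atoms; the alternative power reading
n_heavy^(1.005 − n_heavy) vanishes for every drug-sized molecule and
cannot produce a usable distribution, but remains selectable for
comparison. The mid/large-ring threshold (8) is configurable.

## Ring assemblies

Rings sharing at least one atom merge into one assembly (fused, spiro and
bridged systems alike); ring systems joined only by acyclic linkers —
including a direct biaryl-type bond — are separate assemblies, each
seeing the other's attachment atom as an alpha atom. Alpha atoms are
retained one bond deep with original element and bond order, then
H-capped; exocyclic double-bond partners (ring C=O) are always kept,
since removing them would change ring-atom hybridization. The canonical
key is the canonical SMILES of the extracted H-capped subgraph.

## Shape descriptors

One conformer per molecule: best-energy pick of five seeded
distance-geometry embeddings, MMFF94-relaxed (UFF fallback), with the
seed derived from the canonical SMILES so results are reproducible
without bookkeeping. PMI uses atomic masses with explicit hydrogens;
NPR1/NPR2 place molecules in the rod–disc–sphere triangle. Shadow areas
are union-of-vdW-disk projections onto the three principal planes,
rasterized at 0.2 Å (halving the pitch changes areas by < 1 %).
Elongation p = small/medium and flatness q = medium/large are computed
from both the PMI and shadow triples; degenerate zero denominators
report p = 0.

Sphericity is psi = π^(1/3)(6V)^(2/3) / SASA. SASA uses Shrake–Rupley
with a deterministic 960-point Fibonacci sphere and a 1.4 Å probe. The
volume V defaults to the union of *probe-inflated* spheres — the volume
enclosed by the same solvent-accessible surface — because only a
consistent volume/surface pair gives psi = 1 at the single-sphere limit,
psi <= 1 (up to voxel discretization, ~0.5 %), monotone decrease under
elongation, and invariance when all lengths (coordinates, radii, probe)
scale together. A bare-vdW-volume variant is available but is not
normalized to 1 at the sphere limit. Volumes are voxel counts at 0.35 Å
pitch.

The shape map standardizes the five descriptors (p and q from both
triples, plus psi), fits a PCA, min–max scales PC1/PC2 over designated
scaling sets (default: the reference itself), and bins scores into a
50×50 frequency grid; out-of-range projections clamp to edge bins so the
grid total always equals the number of mapped items.

## Similarity

Fingerprints are hashed circular substructures of radius 2 (ECFP_4
equivalent), kept as sparse feature-id sets; Tanimoto is computed on the
unfolded sets (folding to 2048 bits changes values negligibly and is not
applied). Two empty fingerprints score 1.0, logged as degenerate.
Property-space distance is the Euclidean norm of standardized
six-property differences, with zero-variance properties dropped with a
warning. Multi-fusion similarity reports min/mean/max Tanimoto and
min/mean Euclidean per query so either fusion statistic can be plotted.
Exact-match hits are identical feature sets (Tanimoto exactly 1).
Internal diversity computes all-pairs Tanimoto distances via a sparse
feature-occurrence matrix, deterministically subsampling sets above
5,000 items.

## What the synthetic conditions do and do not show

The built-in fixtures (ten named molecules with frozen expected values,
and analytic rod/disc/sphere point sets) validate the arithmetic of every
stage independently of the stochastic generator. The enumerated sets
validate distribution-level behavior of the calibrated chemistry. Neither
emulates external reference collections (drug databases, natural-product
dictionaries): comparisons against such sets run through the same API but
require user-supplied SMILES/SDF files.

Problem sizes used by the test suite and the acceptance script — 25,000
molecules per enumerated condition, 10,000-molecule batches for
stationarity, subsampled all-pairs diversity — were chosen so the full
analysis reproduces set-level statistics with sampling noise well below
the stated tolerances while remaining a few minutes of single-core work.

## Known limitations

* The enumeration chemistry retains more carbonyl and ether oxygen than
  the reference statistics for this fragment set imply: at the calibrated
  defaults the mean Fsp3 is ~0.60 (reference 0.71 ± 0.22 per molecule)
  and joint Lipinski+Veber compliance is ~88 % (reference ~95 %), with
  the shortfall concentrated in the rotatable-bond (>10) and PSA (>140)
  tails. The fragment weights are fixed by the library definition and
  are deliberately not tuned to close this gap; the mode-ablation
  *ordering* (intra-chain-only markedly less compliant than
  inter-chain-only, and higher-median MC) reproduces, while the absolute
  ablation levels sit ~9–11 points below the reference values for the
  same reason as the main run.
* Ring closures are single bonds with a ring-size floor of 3;
  three-membered rings are permitted and occur (~0.5 per molecule).
* No stereochemistry is enumerated; stereocenters are counted as
  potential centers only.
* One conformer per molecule; no ensemble averaging.
* The shadow/volume/SASA rasterizations trade ~1 % accuracy for speed;
  pitches and probe radius are arguments, not constants.
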