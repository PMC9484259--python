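# Methods

This note documents the models, conventions and numerical choices
behind each analysis stage, what the synthetic generators do and do not
emulate, and the design decisions taken where more than one sensible
convention exists.

## Structure model

Coordinate files (PDB or mmCIF, via gemmi) are reduced to a
chain/residue/atom hierarchy. Author residue numbering is canonical
throughout: receptor ectodomain 1–174 with the d1/d2 hinge at Gly89,
Fc in EU-style numbering (construct residues 237–447, CH2 ≈ 231–340).
Hydrogens are dropped (the intended inputs are 1.9–3.8 Å X-ray models
with none deposited). For alternate locations the highest-occupancy
conformer is kept, ties resolved toward altloc 'A', so all downstream
geometry sees a single conformer. Waters are flagged and excluded from
interface math by default.

**Glycan trees.** N-linked glycans are detected geometrically rather
than from LINK/struct_conn records, for robustness to legacy files: a
tree roots at any saccharide whose anomeric C1 lies within 2.0 Å of an
Asn ND2, and sugar–sugar edges are O–C pairs within the same cutoff.
A sugar with a damaged ring (no C1) can still root a tree through a
nearest-heavy-atom criterion inside a 1.5× relaxed shell, flagged
low-confidence. Saccharides reachable from no Asn are reported
separately, never silently absorbed.

**Complex roles.** Within one complex copy the receptor is the protein
chain with the shortest ordered length (the ~170-residue ectodomain vs
~210-residue Fc monomers). The two Fc chains are distinguished by the
asymmetry of the interface: the chain whose CH2 BC+DE loop residues
place more heavy atoms within 5 Å of the receptor is chain A (the
BC/DE-binding monomer), the other is chain B (FG-binding). Exact ties
fall back to lexicographic chain order with a warning. Multi-copy
asymmetric units are split by seeding each receptor-like chain with its
two nearest Fc-like chains by centroid distance.

## Sequence mapping

Global Needleman–Wunsch alignment (Biopython PairwiseAligner) with
BLOSUM62, gap open 10, gap extend 0.5; a gap of length L costs
open + (L−1)·extend. For >90%-identity orthologs the result is
insensitive to these choices. X is tolerated and scored 0. Percent
identity defaults to matches over aligned (both-non-gap) columns —
the usual ortholog-identity convention — with shorter-sequence and
alignment-length denominators available because published identity
figures rarely state their convention. Identity is computed from the
full polymer (entity) sequence record when available, since published
figures refer to constructs rather than ordered residues.

Residue correspondence maps for superposition come either from the
alignment (different constructs) or from identical author numbering
(copies/variants of one construct); pairs with either residue
unresolved are dropped, and a <30% identity pairing raises rather than
silently producing a nonsense map. Multi-structure averages use the
intersection of resolved mapped residues across all structures, so
every copy is measured over the same core.

## Superposition and angles

Kabsch superposition via SVD with the determinant correction, so the
returned rotation is always proper (no reflections). "Main chain"
means N, Cα, C, O; Cα-only and N/Cα/C selections are provided since
published RMSD values rarely define the set, and the fit and the score
always use the same atoms (no fit/score split). Pairwise matrices are
full and symmetric; group means over crystal copies are arithmetic
means of per-pair RMSDs.

The interdomain angle is measured between the vectors from the Gly89
Cα to the Cα centroids of d1 (1–88) and d2 (90–174), optionally
restricted to a shared residue set. It is invariant under global rigid
motion; a missing pivot Cα is an error (with a pointer to a
nearest-resolved fallback) rather than a silent substitution.

## Surface area and interfaces

SASA is Shrake–Rupley with a deterministic golden-spiral point set —
results are exactly reproducible for a given point count, with no
random number generator involved. Defaults: probe 1.4 Å, 960 points
per atom, NACCESS-like united-atom radii (C 1.70, N 1.65, O 1.40,
S 1.85 Å) applied to protein and sugar atoms alike, giving magnitudes
comparable to PISA. At 960 points the two-sphere closed form is
reproduced within ~0.2% and a 10-fold finer sampling moves toy-interface
BSA by <2%.

BSA uses the ΔASA-sum convention by default — Σ over components of
[SASA(alone) − SASA(in assembly)], i.e. both sides of each interface —
matching the "total BSA" magnitudes quoted for complexes of this kind;
a half-sum flag gives the PISA-style per-interface area. Components
are receptor, Fc chain A and Fc chain B, each owning the glycans
attached to it. Per-atom ΔASA is retained so the total can be
decomposed exactly: by residue, by Fc region (N-terminus 220–230, BC
267–273, BC vicinity 265–270, DE 294–299, FG 325–332; percentages
relative to the Fc-side buried total), by receptor contact patch, and
by owner type. Glycan-vs-protein attribution assigns each buried
glycan atom to glycan–glycan or glycan–protein according to its
nearest cross-component neighbour within 5 Å; occluded glycan area
with no near neighbour counts as glycan–protein. This attribution is a
heuristic — only aggregate glycan figures should be compared across
programs. Disordered residues contribute nothing; nothing is modelled
in.

Contacts are residue pairs across components with any heavy-atom pair
≤ 5 Å (min distance recorded). Per partner, the chain-position class
is main-chain, side-chain or both according to which atoms participate
within the cutoff; polarity is hydrophobic when every participating
pair is carbon–carbon, hydrophilic when every pair involves N/O/S, and
both otherwise. Hydrogen bonds are distance-only N/O donor–acceptor
pairs ≤ 3.5 Å (donors: any N, hydroxyl O of Ser/Thr/Tyr and sugar
hydroxyls; acceptors: any O, His ring N); no angle term is applied
because the intended inputs do not resolve protons and a geometric
angle criterion would suggest spurious precision. Intra-Fc pairs at
sequence separation ≥ 2 are also scanned, since the BC/DE loop bonds
that stabilise the Fc glycan are intra-chain.

## Glycopeptide profiling

Digestion models chymotrypsin (after F/Y/W/L/M) plus Glu-C with
E-only specificity, reflecting ammonium-carbonate conditions (an E/D
mode is available); cleavage never occurs before proline. All peptides
with ≤ 2 missed cleavages and length ≥ 4 are generated. Masses are
monoisotopic with fixed carbamidomethyl-Cys (+57.02146 Da); glycan
increments are HexNAc 203.07937, Hex 162.05282, dHex 146.05791, NeuAc
291.09542 Da. Matching is precursor-mass only at 10 ppm (Orbitrap-
typical); there is no MS2 scoring, so the log-probability column is an
input from the upstream search engine, not computed here. When the
precursor table carries a site assignment (as tables exported from
MS2-level identification do), candidate matches are restricted to that
sequon; without it, all same-mass candidates are reported and flagged
ambiguous. Isobaric compositions are never distinguished.

The default composition database covers HexNAc 1–6, Hex 0–9, dHex 0–2,
NeuAc 0–4 (requiring Hex ≥ 3 once HexNAc ≥ 2, except explicit truncated
forms) — wide enough to contain every HEK293-type glycoform of
interest. With precursor-only matching a database this size produces
occasional near-isobaric cross-peptide collisions; recovery studies on
generated data therefore use the targeted pool database that the
generator itself samples from, which mirrors curated-database practice.

Profiles aggregate spectral counts per composition after excluding
matches with log probability < 1 or fewer than 2 spectra (each
exclusion audited), classify compositions as truncated (below the
HexNAc₂Hex₃ core), oligomannose (HexNAc₂Hex≥₄, unfucosylated,
unsialylated), hybrid (HexNAc≥₃ with Hex≥₅) or complex (everything
else), and rank a top-N by count with a deterministic lexicographic
tie-break. These class boundaries are standard heuristics exposed as
configuration, not ground truth of any nomenclature. Class fractions
are invariant under uniform scaling of counts.

## Binding kinetics

The 1:1 Langmuir model: during association
R(t) = R_max·C/(C+K_D)·(1−e^−(k_on·C+k_off)t), during dissociation
exponential decay at k_off from the end-of-association level;
K_D ≡ k_off/k_on, asserted on every fit object. Mass transport and
avidity are deliberately not modelled. Fits use trust-region least
squares (lmfit) with log-parameterised rates, which enforces
positivity without box constraints; k_off is initialised from the tail
decay of the top trace. Global fits share k_on, k_off, R_max across
the concentration series. Equilibrium fits average a 5 s window at the
end of association and fit the Langmuir isotherm; a statistically
significant residual slope in the window triggers an under-saturation
warning, because truncated association biases the equilibrium K_D
upward (the low-concentration traces sit furthest from equilibrium).
Rates are scale-invariant in the response units; only R_max carries
them. A single-concentration fit is allowed but warned about. The
instrument schedule default is 300 s association / 300 s dissociation
over a 7-point 3-fold series from 10 µM — the published protocol's
concentration endpoints read as µM (a 10 mM top concentration of a
~50 kDa receptor is not physically plausible and the series endpoint
0.013 matches the µM reading).

## Synthetic data

The generators define the study conditions; every output carries a
sidecar ground-truth record so tests recover plants instead of
re-deriving them, and every generator is deterministic given its seed.

**Toy complexes** place a 174-residue receptor with Cα atoms on two
straight 3.8 Å-spaced arms hinged at residue 89 — the planted
interdomain angle is exact by construction — plus minimal backbones
and Cβ side chains (enough to exercise main-chain/side-chain
classification). Fc chains hold their planted contact residues at the
requested 3.8–4.8 Å Cβ–Cβ distance while the rest of each chain sits
200 Å away, and generation fails loudly (naming the offending pair) if
any unplanned cross-chain pair lands inside 5 Å, so the planted
contact set is exactly the observable one. Glycans are linear
NAG/NAG/BMA/MAN chains at bonding distances from the Asn ND2. These
fixtures are geometric scaffolds, not proteins: tests passing on them
validate bookkeeping, classification rules and plant recovery, not
crystallographic realism.

**Glyco datasets** sample per-site compositions from class-conditional
pools (defaults mirror the observed site profiles: predominantly
complex-type, ~10% hybrid at Asn45, truncated forms at Asn64/Asn162),
attach them to the shortest digest peptide covering each site on a
synthetic 174-residue scaffold with sequons at exactly Asn45/64/162,
and emit masses with Gaussian ppm noise clipped at 3σ (default σ=2
ppm) so every planted mass stays inside the 10 ppm matching window.
Filter plants — a fraction of rows with log probability < 1 and extra
single-spectrum rows — are added so the exclusion rules have known
victims, and the ground truth records the post-filter class fractions.

**Sensorgrams** wrap the 1:1 simulator over the default series with
additive Gaussian noise (default 5% of R_max) on the published phase
schedule.

## Problem sizes

The test suite and acceptance script run entirely on synthetic inputs:
~620-residue toy complexes at 960 SASA points, 500-spectrum glyco
datasets, and 50-seed kinetic recovery studies at 1200 samples per
trace — sizes chosen so each stage's statistical claims (multinomial
fraction error ≤ 3 points, median K_D error < 10%) are meaningful
while a full run stays in the minutes range. The deposited-accession
checks operate on the real asymmetric units (two complex copies,
~10⁴ atoms) when the files are available in the local cache.

## Known limitations

- BSA protein/glycan attribution is nearest-neighbour heuristic;
  per-residue values match PISA only approximately.
- Precursor-only glycopeptide matching cannot resolve isobaric or
  near-isobaric assignments; ambiguity is flagged, not resolved.
- The H-bond detector trades specificity for robustness at low
  resolution (no angle term).
- The kinetics module fits only the 1:1 model; mass-transport-limited
  or avid data will show structured residuals rather than a warning.
- Role assignment assumes the receptor is the shortest protein chain
  of a copy; heavily disordered Fc chains could defeat the length
  profile, in which case roles must be set manually.
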