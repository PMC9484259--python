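# fcgr3kit

Structural and biochemical analysis of FcγRIII–IgG Fc complexes.

FcγRIII (CD16) is the low-affinity Fcγ receptor that triggers
antibody-dependent cellular cytotoxicity when its two-domain ectodomain
engages the Fc of target-bound IgG. Comparative work on this system —
for example contrasting allelic receptor variants, species orthologs, or
glycoform states — leans on a recurring set of quantitative analyses:
rigid-body superposition and main-chain RMSD matrices across crystal
copies, the interdomain "comma" angle of the receptor, buried-surface-
area (BSA) totals decomposed into protein and glycan contributions and
into the Fc CH2 loop regions (BC, DE, FG, N-terminus), 5 Å residue
contact networks with main-chain/side-chain and polarity classes,
site-specific N-glycopeptide composition profiles from spectral counts,
and 1:1 Langmuir fits of biolayer-interferometry sensorgrams.

`fcgr3kit` packages those stages as a composable Python library for
structural immunologists and protein biochemists, with a synthetic-data
module that plants known ground truth for every stage so the whole
pipeline is testable offline.

## Core quantities

- **Superposition/RMSD** — Kabsch least-squares fit; RMSD over the
  main-chain atoms (N, Cα, C, O) of the residues shared between
  structures, reported post-fit on the same atom set.
- **Interdomain angle** — the angle ∠(c₁, p, c₂) between the Cα
  centroids c₁, c₂ of receptor domains d1 (residues 1–88) and d2
  (90–174) with the Gly89 Cα as origin p.
- **SASA / BSA** — Shrake–Rupley sphere sampling (probe 1.4 Å,
  NACCESS-like united-atom radii); BSA = Σ over components of
  [SASA(component alone) − SASA(in assembly)], with per-atom ΔASA
  retained for per-residue, per-region and protein/glycan attribution.
- **Contacts / H-bonds** — residue pairs across components with any
  heavy-atom pair ≤ 5 Å; hydrogen bonds as donor/acceptor N/O pairs
  ≤ 3.5 Å (distance-only, suited to limited-resolution X-ray data).
- **Glycoprofiling** — chymotrypsin + Glu-C in-silico digestion,
  monoisotopic glycopeptide masses (peptide + 203.07937·HexNAc +
  162.05282·Hex + 146.05791·dHex + 291.09542·NeuAc), 10 ppm precursor
  matching, oligomannose/hybrid/complex/truncated classification, and
  top-N tables after the log-probability ≥ 1 and ≥ 2-spectra filters.
- **Kinetics** — R(t) = R_max·C/(C+K_D)·(1−e^−(k_on·C+k_off)t) during
  association, exponential k_off decay during dissociation; global
  kinetic fits and equilibrium Langmuir fits, K_D = k_off/k_on.

## Worked example

`python examples/binding_kinetics.py` simulates the ~0.25 µM
receptor–Fc regime (7-point, 3-fold series from 10 µM, 5% noise) and
fits it back:

```
global kinetic fit:
  k_on  = 9.96e+04 /M/s   (true 1e+05)
  k_off = 0.025 /s     (true 0.025)
  K_D   = 0.251 uM (true 0.25)
  residual RMS = 0.0497 (noise sd 0.05)

equilibrium fit (5 s end-of-association window):
  K_D   = 0.230 uM
```

The global fit recovers the planted rate constants to well under 1%,
and the equilibrium route — which uses only the end-of-association
levels — agrees with the kinetic K_D to within the noise. The other
examples (`structure_compare.py`, `interface_report.py`,
`glyco_profile.py`) do the same for the structural and glycoprofiling
stages; each prints the recovered quantity next to its planted value.

A thin CLI mirrors the library (`fcgr3kit compare|angle|interface|
contacts|glyco|kinetics|synth ...`); every run writes its full
configuration next to its outputs, and deterministic runs are
byte-reproducible from that saved configuration.

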