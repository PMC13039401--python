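# Methods

This note records the models implemented, the parameter choices that
matter, what the synthetic generators do and do not emulate, and the
numerical decisions taken where the design was open.

## Cytosolic loop statistics

A topology is an ordered, contiguous, non-overlapping list of segments
labelled cytosolic (`i`), membrane (`M`) or extracytosolic (`o`) with
1-based inclusive coordinates; two membrane segments may never be
adjacent. Confidence filtering keeps records with *high* orientation
quality, *medium or high* TM-count quality, certain N/C-terminal
localization, and at least `min_tm = 2` membrane segments (multipass).
Unknown grade strings are treated as "low" (hence dropped) and counted
as warnings rather than errors, so a single odd annotation cannot crash
a proteome-scale run.

The per-protein statistic is the longest cytosolic segment.
Terminal tails count by default (`count_termini = True`): tails and
loops act interchangeably as degradation handles, and the quantity of
interest is the longest cytosolic *extension* of any kind. The switch
exists for sensitivity analysis. A protein is "short-loop" when the
longest extension is strictly below `short_threshold = 20` aa — strict,
so a 20-aa tail is not short. Histograms use 10-aa bins to 200 aa plus
an open overflow bin.

## TM hydrophobic stretches

Within an annotated TM column range, gaps are stripped per sequence
before computing the longest run free of the highly polar set
{K, R, N, Q, H, D, E}: a stretch is a property of the residue chain, not
of alignment columns, so inserting gap columns can never split or join a
run (a property the tests enforce). The unknown residue X breaks a run
by default (conservative lower bound; configurable). Ser and Thr are
deliberately *not* in the default polar set — the statistic is defined
by the highly polar residues only — but the set is a parameter.
Sequences fully gapped in a region are recorded with `n_ungapped = 0`
and excluded from medians/IQRs.

The TM1-vs-TM2 comparison uses a two-sided Mann–Whitney test computed
via midranks. With `n1 + n2 ≤ 12` and no ties the two-sided p-value is
exact, by full enumeration of all C(n1+n2, n1) group labelings (p =
fraction of labelings whose U deviates from n1·n2/2 at least as much as
observed). Otherwise the normal approximation with tie correction and a
0.5 continuity correction is used. The method actually applied is always
reported, since the exact and approximate branches can differ at small
n. A single-sequence family is degenerate: p = 1 by construction.

## Insertion ΔG scoring

Segment ΔG is the sum of per-residue apparent insertion free energies on
the biological (translocon-measured) hydrophobicity scale, shipped as a
data file (kcal/mol). This additive form intentionally omits the full
predictor's position-dependent profiles, length correction and
hydrophobic-moment term: the package uses ΔG only for the ordinal
question "does this (mutated) TM still insert", i.e. sign and ordering,
not server-exact values. The window scan enumerates every window of
length 19–23 (bracketing the ~20 residues needed to span the ~30 Å
hydrophobic bilayer core) and reports the global minimum; insertion is
predicted when min ΔG < 0. Window sums use exactly rounded summation
(`math.fsum`), so windows containing the same residue multiset score
bit-identically and ties resolve deterministically to the smallest
start, then the smallest length. Note that under an additive scale a
longer all-hydrophobic window always scores lower, so on homopolymers
the minimum is attained at the maximum window length.

## Atom polarity and lipid exposure

Atom classes follow a surface-chemistry scheme: a carbon is hydrophobic
iff no covalently bonded neighbour is N or O, with covalency formalized
as inter-atomic distance ≤ 1.8 Å between heavy atoms (covers C–N/C–O
bonds without catching 1–3 neighbours; hydrogens are ignored). Sulfur is
not treated as electronegative, so Met/Cys carbons stay hydrophobic.
N/O atoms are classed by group — side-chain carboxylate O of Asp/Glu
negative, side-chain amine/guanidinium N of Lys/Arg positive, backbone
amide/carbonyl and side-chain N/O of Ser/Thr/Asn/Gln/His polar — and a
carbon bonded to a classed N/O inherits the class (charge beats polar).
Tyr OH and Trp NE1 fall outside the scheme ("other"), mirroring the
coloring convention the scheme reproduces; their bonded carbons are
still non-hydrophobic.

Relative lipid exposure is side-chain SASA (Shrake–Rupley rolling probe,
radius 1.4 Å, fixed 1000-point Fibonacci sampling — deterministic)
divided by the SASA of the same side chain computed in isolation (the
residue keeps its own backbone; the rest of the structure is removed).
This same-geometry reference was chosen over an extended Gly-X-Gly
reference table because it guarantees exposure ∈ [0, 1] for *any* atom
representation, including the reduced side chains of the synthetic
bundles, where a full-atom reference maximum would be the wrong
denominator. Glycine falls back to a CA surrogate and is flagged.

Membrane placement is an input: a slab along z with configurable center
(default: coordinate centroid) and half-thickness 15 Å (30 Å hydrophobic
thickness). A residue is flagged as a candidate lipid-facing degron when
its side chain contains polar/charged atoms, its side-chain centroid
lies in the slab, and exposure ≥ `exposure_min = 0.25`. The threshold is
an operational choice — it separates the planted exposed fixture
(exposure ≈ 0.94) cleanly from buried controls (≈ 0.03) — not a value
derived from experiment; treat it as tunable.

## Degradation kinetics

Two models: Y(t) = A·e^(−kt) + C (single-exponential decay of a
degradable fraction A with stable fraction C) and
Y(t) = A₁·e^(−k₁t) + A₂·e^(−k₂t) (biphasic). Curves are normalized to
their t = 0 value inside the reader; replicates are pooled into one
residual vector and fitted jointly. Fitting is bounded least squares
(0 ≤ A, C ≤ 1, 0 < k ≤ 10 min⁻¹) with multi-start: a log-linear
regression start for the plateau model plus five fixed-seed random
starts (seeds 11/23/37/51/73 — documented so runs are reproducible), and
tight tolerances (1e-14) so noiseless inputs are recovered to numerical
precision. Standard errors come from the Gauss–Newton covariance at the
optimum.

Conventions and diagnostics:

* the biphasic fit reports k1 ≥ k2; when the fitted rates do not
  separate (k1/k2 < 1.5) the biphasic claim is marked unsupported and
  the single-plateau alternative fit is attached;
* a flat curve fits with A < 0.01 and is annotated "degradation
  fraction ~0" (k is unidentifiable there — the estimate is not
  meaningful);
* **half-life** of the plateau model is defined on the degradable
  fraction, ln2/k, because the total signal never halves when C ≥ 0.5;
  the time for the *total* signal to reach 0.5 is reported separately
  when reachable. For the biphasic model the half-life solves
  Y(t) = Y(0)/2 by bracketed root finding on [0, 10/k₂];
* half-life is refused (error) when the degradable fraction is < 0.01.

A trivial linear model Y(t) = a + b·t is included for slow early-phase
decays fitted linearly.

## Synthetic data

All generators are pure functions of (config, master seed); each draws
from its own RNG stream `default_rng([seed, stream_index])`, so adding a
generator never perturbs another's output, and identical seeds give
byte-identical results.

* **Topology tables** — TM count 2 + Poisson, loop lengths geometric
  (right-skewed, qualitatively like observed loop-length distributions —
  no claim of matching the real proteome). With planted probability
  `p_short` (default 0.21) every cytosolic extension stays below 20 aa;
  otherwise one extension of ≥ 20 aa is planted. Confidence grades are
  assigned so a configured fraction passes the filters. Ground truth
  (per-protein longest extension and pass/fail) is emitted alongside.
* **Homolog families** — each sequence is linker | polar-cap ·
  hydrophobic core · polar-cap (TM1) | linker | cap · core · cap (TM2) |
  linker; core lengths are rounded normals, defaults TM1 ≈ 15 ± 1.5 and
  TM2 ≈ 20 ± 2 (the observed short-TM1 architecture). Blocks are
  right-padded with gaps, so TM column ranges are exact block boundaries
  and per-sequence gaps occur inside TM regions. Real phylogenetic
  covariance, indel structure and alignment error are *not* emulated: a
  green planted-effect test establishes that the statistic and test
  detect the architecture, not that any particular real family shows it.
* **Helix bundles** — ideal parallel α-helices (1.5 Å rise, 100° twist,
  CA radius 2.3 Å) on a circle, poly-Leu with a reduced representation
  (crude backbone N/CA/C/O plus one side-chain pseudo-atom at the
  side-chain centroid distance). Axis spacing defaults to 8 Å — tighter
  than full-atom helix packing (~9.5–10 Å) because the reduced side
  chains carry less bulk; this reproduces the buried/exposed contrast
  the fixture is defined by. One polar residue (Gln via an N
  pseudo-atom) is planted at mid-slab on the outward or inward face.
  The geometry is adequate for exposure *ranking*; it is explicitly not
  atomically realistic and unsuitable for energetics.
* **Decay curves** — model evaluation plus Gaussian noise (σ = 0.05 by
  default), clipped at 0 and re-normalized at t = 0. Defaults state a
  single-plateau world with A = 0.6, k = ln2/40 min⁻¹, C = 0.4
  (40-min half-life, 40% stable fraction), 7 timepoints over 0–120 min,
  3 replicates — the regime of translation-shutoff densitometry.

## Known limitations

* Topology confidence grades are a three-level categorical reading of
  the upstream predictor's annotations; other encodings must be mapped
  to high/medium/low on input.
* Re-entrant membrane segments and signal peptides are not modelled;
  every membrane-labelled segment counts as a TM.
* The ΔG scan is ordinal; do not compare its absolute values against
  the full position-dependent predictor.
* Automatic membrane positioning is out of scope — the structure must
  be membrane-oriented (z normal), or the centroid-centered default slab
  accepted.
* The exposure score depends on the atom representation; compare scores
  only within one representation.
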