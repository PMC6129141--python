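# Methods

This document records the model implemented by `epsbind`, the parameter
choices with their rationale, and the known limitations. Everything stated
here is either a definition or is verified by the test suite /
`scripts/acceptance.py`; no empirical claims beyond those computations are
made.

## Data model

An **ensemble** is a set of replicate runs, each a sequence of frames with
identical topology (same atoms, same order; positions vary). Topology
constancy is enforced at construction and on file read; violations raise
`TopologyError` naming the offending file. Frames are exchanged as
multi-model PDB files, one file per run, parsed and written through
biotite. Binary trajectory formats and mmCIF are out of scope.

**Replicate statistics.** For any per-frame observable, each run is first
reduced to its mean over the analysis frames; the reported value is the
mean of those run means and the sample standard deviation (ddof = 1) over
run means. With a single run the SD is reported as 0. This treats the run,
not the frame, as the independent unit, which is the correct level for
correlated MD frames. The **equilibration discard** removes the leading
`floor(f·m)` frames of each `m`-frame run for fraction `f ∈ [0, 1)`; floor
semantics guarantee at least one analysis frame remains.

## Hydrogen-bond network

A donor–hydrogen/acceptor triple is a hydrogen bond when

- the H···acceptor distance is ≤ `d_max` = 2.7 Å (inclusive), and
- the deviation from linearity of the D–H···A angle at the hydrogen is
  ≤ `angle_max` = 30°.

An alternative `donor` angle convention (angle at the donor heavy atom
between D→H and D→A, as used by some MD tools) is available via
`HBondCriteria(angle_convention="donor")`; the default is `deviation`.
Donor/acceptor atom names come from a registry (arginine NE/NH1/NH2
donors; glutamate/aspartate carboxylates, ATP phosphate oxygens and water
as acceptors) that callers can extend.

Per-bond energies use the distance-based estimate

E(d) = −A·exp(−B·d), A = 25300 kJ/mol, B = 3.6 Å⁻¹

applied by default to the H···A distance (a D–A option exists). The
constants are the literature values for this exponential form and are
configurable; they are an empirical correlation calibrated on O–H···O
bonds, so absolute energies are estimates — the pipeline uses them
comparatively. E(1.8 Å) ≈ −38.8 and E(2.0 Å) ≈ −18.9 kJ/mol (verified in
tests). The **network energy** is the plain sum over detected bonds (0 for
an empty network). Detection is implemented with a k-d tree neighbour
search and is verified frame-by-frame against an all-pairs brute-force
oracle.

## Repulsive contacts

Like-charge crowding is measured as the per-frame number of **group
pairs** whose minimum inter-atomic distance is ≤ 4.5 Å. Default groups are
the guanidinium nitrogen sets (NE/NH1/NH2) of arginines 92, 99, 103, 115,
122, 126 plus the Mg²⁺ ion. Counting is pair-level, not atom-level: an
arginine–arginine pair contributes at most 1 regardless of how many
nitrogen pairs are close. Groups that resolve to no atoms (e.g. mutated
arginines) are dropped; fewer than two non-empty groups yields 0 with a
warning. The count is monotone in the cutoff and is verified against a
brute-force oracle.

## Mg²⁺ coordination

Exactly one Mg²⁺ is expected (residue/atom name `MG`). Direct
(first-sphere) coordination uses a 2.6 Å Mg–O cutoff; a water-bridged
second sphere requires Mg–O(water) and O(water)–O(phosphate) within
3.5 Å. These two cutoffs are conventional values for Mg–O geometry, not
fitted to any particular dataset. States: `FIRST_SPHERE_OA_OB` (α and β
oxygens, no γ), `FIRST_SPHERE_OB_OG` (β and γ, no α), `OTHER` for any
other direct pattern, `SECOND_SPHERE`, `UNBOUND`. Phosphate oxygen naming
defaults to PDB component conventions (O1A/O2A/O3A etc.) and is
remappable. Per-state occupancies over the analysis frames sum to 1.

## Geometry

- **Helix centre-of-mass distance**: Euclidean distance between centroids
  of two disjoint selections, unit masses by default (element masses
  optional). The helix residue ranges are deliberately not defaulted —
  where to split the C-terminal domain into two helices is a modelling
  choice the caller makes in config.
- **Interaction distance series**: per-frame distance between two
  selections (single-atom, or minimum over pairs in min-distance mode for
  NHx-type groups), histogrammed at configurable bin width, with mean
  deviation from a named crystal reference distance.
- **Superposition RMSD**: optimal proper rigid-body (Kabsch) alignment via
  `scipy.spatial.transform.Rotation.align_vectors`; RMSD = rssd/√n.
  Rigid copies give 0 to numerical precision; the two-atom stretch
  (1 Å vs 3 Å separation) gives exactly 1.0.

## Thermodynamic integration

TI input is a two-column (λ, ⟨∂H/∂λ⟩) text table per direction, λ strictly
increasing in [0, 1]. Any per-window equilibration discard is applied
upstream; the declared fraction is metadata only. Integration uses the
composite trapezoid rule by default (Simpson optional). Forward and
backward legs combine as the mean; the error is the sample SD of the two
leg estimates (|ΔG_f − ΔG_b|/√2) and the hysteresis is |ΔG_f − ΔG_b|.
Placement comparisons propagate errors in quadrature and declare a tie
when the ΔΔG gap does not exceed the combined error. On a noiseless 3λ²
integrand over 85 windows the pipeline recovers ΔG = 1 within 1e-3 with
zero hysteresis; over 100 noisy replicates the estimator is unbiased
within statistical error (both verified).

## Comparative report

Variants are ranked by network energy (most negative first). A variant is
classified `higher-than-reference` only when its energy is more favourable
*and* its repulsive-contact count lower, both separated from the reference
beyond the combined SD (√(sd₁²+sd₂²)); the mirror condition gives
`lower-than-reference`; anything else is `similar`. Experimental Kd values
are carried through as metadata only — the report never converts energies
to affinities. Output formats: markdown, TSV, JSON, all deterministic.

## Sequence-conservation scan

Pairwise identity is matches over mutually non-gap columns. Redundancy
filtering is greedy first-come at threshold 0.95 (idempotent). The
position map pairs the k-th non-gap column of the reference row with PS3
position k+offset. The **binding set** is {E83, R92, R99, R122, R126};
the **modulator positions** are 103 and 115. Hypotheses per sequence:
`baseline` if both modulators are arginine-like (or reference-identical);
`increased-affinity` if a modulator carries a non-basic residue while the
binding set is intact; `indeterminate` when binding-set substitutions
confound the call (listed in the caveat). A histidine at 103 adds a
titratability caveat. Gaps count as substitutions.

Note on residue sets: published descriptions of this site vary in
numbering of the last two arginines (122/126 vs 123/127) and in the
residue at 103 in some homologues; this implementation fixes the binding
set above and treats 103/115 purely as modulators. The choice is
configurable only through code, not config, to keep reports comparable.

## Synthetic-data generator

The generator produces ensembles with **planted ground truth**: each
planted hydrogen bond has a target occupancy, and in event frames the
geometry is placed strictly inside both cutoffs by a margin (0.1 Å, 5°),
in non-event frames strictly outside; likewise for contacts (inside/
outside distances around the 4.5 Å cutoff) and Mg²⁺ coordination states
(precomputed geometries satisfying exactly one classification). Per-
feature random streams come from `numpy.random.SeedSequence.spawn`, so
outputs are pure functions of (spec, seed) and adding a feature does not
shift another feature's stream. Decoy atoms are kept ≥ 8 Å from all
planted geometry.

What it does **not** emulate: physical dynamics, frame-to-frame
correlation (frames are i.i.d. Bernoulli draws, so the binomial error
model used in validation is exact rather than optimistic), force fields,
solvent structure, or realistic protein topology — only the minimal atom
sets the detectors consume. TI tables are an analytic polynomial integrand
plus i.i.d. Gaussian window noise. The alignment fixture plants known
substitutions, duplicates and gap blocks to exercise the scan.

## Numerical choices

- Neighbour searches use `scipy.spatial.cKDTree`; quadrature uses
  `numpy.trapezoid` / `scipy.integrate.simpson`; rotations use
  `scipy.spatial.transform.Rotation`.
- Distance/angle cutoffs are inclusive (≤).
- All iteration orders (atoms, bonds, dict outputs, report rows) are
  sorted or insertion-stable, so every stage is deterministic and
  re-running on identical inputs is byte-identical (verified).
- Energies are kJ/mol; TI tables are kcal/mol (the unit convention of the
  producing MD packages); the report does not mix the two.

## Limitations

- Hydrogen positions must be present in the input; the package does not
  add or guess hydrogens.
- The per-bond energy is a distance-only estimate; it ignores
  angular dependence, cooperativity and the chemical identity of the
  partners beyond the registry.
- Run-level SD with 2–3 replicates is a weak estimator; the report's
  "beyond combined SD" separation rule is intentionally conservative but
  not a significance test.
- The TI module analyses provided ⟨∂H/∂λ⟩ tables; it does not run or
  validate the underlying simulations, and the two-leg error estimate
  (n = 2) is crude by construction.
- The sequence scan's hypotheses are heuristics about site composition,
  not affinity predictions.
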