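# epsbind

Analysis toolkit for quantifying how point mutations in the ε subunit of
bacterial F₁-ATPase change its ATP-binding behaviour, using ensemble data
from molecular-dynamics simulations.

## Scientific problem

The ε subunit of the *Bacillus* PS3 F₁-ATPase binds ATP and acts as an
intracellular ATP-level sensor. Its C-terminal domain carries a cluster of
arginines (R92, R99, R103, R115, R122, R126) around the triphosphate moiety.
Paradoxically, *removing* two of them — the double mutant R103A/R115A — is
known experimentally to *increase* ATP affinity by roughly two orders of
magnitude. The mechanistic hypothesis is that R103 and R115 contribute
little direct binding but crowd the site electrostatically: deleting them
relieves arginine–arginine (and arginine–Mg²⁺) repulsion, letting the
remaining residues form a tighter, more persistent hydrogen-bond network
with the nucleotide.

`epsbind` implements the analysis pipeline needed to test that hypothesis
on simulation ensembles:

- **Hydrogen-bond network analysis** — geometric detection
  (H···acceptor ≤ 2.7 Å, ≤ 30° deviation from linearity) plus a
  distance-based per-bond energy estimate
  `E(d) = −25300·exp(−3.6·d)` kJ/mol, summed into a network energy.
- **Repulsive-contact counting** — per-frame count of basic-group pairs
  (arginine guanidinium NE/NH1/NH2 sets and Mg²⁺) within 4.5 Å of each
  other, as a proxy for like-charge crowding.
- **Mg²⁺ coordination classification** — first-sphere Oα/Oβ, Oβ/Oγ or other
  direct coordination, water-bridged second sphere, or unbound, with
  per-state occupancies.
- **Geometry metrics** — centre-of-mass distance between the two C-terminal
  helices, per-frame interaction distances vs crystal references, and
  Kabsch superposition RMSD.
- **Thermodynamic-integration (TI) analysis** — quadrature of ⟨∂H/∂λ⟩
  tables, forward/backward combination with hysteresis and error estimates,
  and placement comparison with an explicit tie verdict.
- **Comparative affinity report** — ranks variants by network energy and
  classifies each as higher/lower/similar relative to a reference, requiring
  both the energy and the contact count to separate beyond combined SD.
- **Sequence-conservation scan** — redundancy filtering of a multiple
  sequence alignment, PS3↔alignment position mapping, and per-sequence
  hypotheses (baseline / increased-affinity / indeterminate) based on
  whether positions 103/115 carry non-arginine residues while the binding
  set (E83, R92, R99, R122, R126) is intact.
- **Synthetic-data generator** — deterministic ensembles, TI tables and
  alignments with planted ground truth, used for validation throughout.

All replicate statistics are reported as mean ± sample SD over per-run
means, after discarding a configurable leading equilibration fraction of
each run.

## Worked example

Generate a synthetic wild-type vs mutant fixture set and run the full
pipeline on it:

```bash
epsbind simulate --seed 42 --out demo --frames 30
epsbind run --config demo/config.yaml --out demo/results
```

`simulate` writes three multi-model PDB replicates per variant, a pair of
forward/backward TI tables, a FASTA alignment and a ready-to-run
`config.yaml`. `run` executes every stage and writes `report.md`,
`report.json`, `variant_stats.tsv`, `ti_site.json` and `seqscan.tsv`.
The report for this seed reads:

```
| variant | Mg²⁺ coordination | h-bonds | E_HB (kJ/mol) | repulsive contacts | class |
|---|---|---|---|---|---|
| MUT | Oα/Oβ | 10.54 ± 0.11 | -436.80 ± 13.78 | 1.19 ± 0.02 | higher-than-reference |
| WT | Oα/Oβ | 8.69 ± 0.07 | -121.43 ± 0.90 | 2.00 ± 0.00 | reference |

Ranking (most to least favourable network energy): MUT > WT
```

The planted mutant (more, shorter hydrogen bonds; one contact mostly
released) is correctly classified above the wild type. The TI stage on the
bundled noisy 3λ² tables reports

```json
{"dG_forward": 1.0022, "dG_backward": 0.9592, "dG_mean": 0.9807,
 "dG_err": 0.0304, "hysteresis": 0.0430, "n_windows": 85}
```

and the sequence scan flags non-arginine residues at 103/115:

```
id          hypothesis          caveats
PS3         baseline
CTHE_LIKE   increased-affinity
BPUM_LIKE   increased-affinity  histidine at 103: the imidazole ring is titratable near neutral pH, ...
BCAL_LIKE   indeterminate       binding-set substitution(s) R99S confound the 103/115 effect
LSPH_LIKE   increased-affinity
PAIR94      baseline
```

Individual stages are also available as subcommands
(`epsbind hbonds | contacts | coordination | geometry | ti | seqscan |
report`); see `epsbind --help`.

Python API equivalent of the core step:

```python
from epsbind import read_ensemble, ensemble_hbond_stats

ens = read_ensemble([f"demo/mut_run{i}.pdb" for i in (1, 2, 3)],
                    equilibration_fraction=0.2, label="MUT")
count, energy = ensemble_hbond_stats(ens)
print(count, energy)   # 10.51 ± 0.10 -435.22 ± 8.96
```

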