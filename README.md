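# contactfold

A contact-guided coarse-grained ab initio folding toolkit:

- **msa_stats** — FASTA/Stockholm/A3M alignment parsing, HHfilter-style
  redundancy and gap-row filtering, the effective sequence count
  `Nf = (1/√L) Σᵢ 1/[1 + Σ_{j≠i} I(S_ij ≥ 0.8)]`, the augmentation fraction
  `Nff = (Nf_combined − Nf_base)/Nf_combined`, and family triage
  (Nf > 64, Nff > 0.5).
- **contact_consensus** — CASP-RR contact list parsing, four predictor
  accuracy tiers with top `L / L/2 / L/4.5 / L/7.5` truncation, and a
  mean-confidence consensus contact set.
- **contact_potential** — the piecewise sine-well contact restraint
  (flat −U below 8 Å, zero at a length-dependent d2 ∈ [14, 24] Å, flat +U
  beyond 80 Å).
- **folding_engine** — replica-exchange Monte Carlo assembly of Cα/virtual-Cβ
  chains with fragment-substitution, pivot and crankshaft moves, a minimal
  generic force field (harmonic bonds, soft-sphere excluded volume), and
  fragment-derived distance-profile restraints.
- **decoy_analysis** — optimal-superposition RMSD, SPICKER-style
  neighbour-count clustering with an adaptive cutoff, first-model selection,
  and the convergence density `Dc = (M/M_tot)/⟨R⟩`.
- **quality_score** — weighted long-range contact satisfaction `Sr`,
  the confidence score `C = 0.2·ln(Nf) + ln(Sr·Dc)`, the linear TM-score
  calibration `TM = 0.0659·C + 0.477` (residual RMSD 0.084), a true
  TM-score implementation, and calibration checking.
- **toygen** — seeded synthetic fixtures: idealized helix-bundle /
  β-hairpin / mixed folds, true contact maps, precision-controlled corrupted
  predictor lists, fragment libraries with tunable jitter, and MSAs that hit
  a requested Nf.
- **cli / config** — a `contactfold` command orchestrating the pipeline.

## CLI

```sh
contactfold toygen --topology helix_bundle --n-res 60 --seed 7 --out toy/
contactfold nf --msa family.fasta --base-msa base.fasta --format fasta
contactfold consensus --rr respre.rr:very_high --rr ccmpred.rr:low \
    --length 120 --nf 80 --out consensus.rr
contactfold fold --seq target.fasta --contacts consensus.rr \
    --config run.yaml --seed 1 --out decoys.pdb
contactfold cluster --decoys decoys.pdb --out clusters.tsv
contactfold cscore --model model1.pdb --contacts consensus.rr \
    --nf 80 --clusters clusters.tsv --out confidence.json
contactfold pipeline --seed 1 --topology beta_hairpin --n-res 48 --out run/
```

`run.yaml` holds the thresholds (nf_cutoff 64, nff_cutoff 0.5, identity 0.8,
nf_switch 50) and a `simulation:` block mapped onto `SimulationConfig`
(replica count, temperature ladder, steps, term weights, seed).

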