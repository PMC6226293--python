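# Methods

## The model

`polyocc` computes the equilibrium DNA occupancy of a polymerizing
transcription factor — modeled on the Drosophila ETS-family repressor Yan,
whose SAM domains form head-to-tail helical polymers — as the product of two
equilibria:

**On DNA.** The regulatory element is a 1-D lattice of N sites, each either
sequence-specific (ETS, binding free energy α) or non-specific (β). A
microstate σ ∈ {0,1}^N has statistical weight

    W(σ) = Π_{occupied i} w_i · Π_{adjacent occupied pairs} g,
    w_i = (C_eff / c0) · exp(−ε_i / RT),   g = exp(−γ / RT),

where γ is the SAM–SAM self-association free energy and the bond factor g
applies only between occupied sites at adjacent lattice positions (a linear
polymer tracking the DNA; free, non-periodic ends; no skip-bonds or
branching). Fractional occupancy of site j is the Boltzmann average
θ_j = Σ_{σ: σ_j=1} W(σ) / Σ_σ W(σ).

**Off DNA.** Self-association in the nucleoplasm sequesters protein into
polymers that cannot nucleate on DNA. With x = C_total / Kd (Kd the SAM–SAM
dissociation constant), the binding-competent fraction is the truncated
geometric ratio

    f(x) = (Σ_{k=0}^{m−1} x^k) / (Σ_{k=0}^{n} x^k),

with n the polymer cap and m the number of nucleating species sizes
(m = 1 monomers only; 2 adds dimers; 3 adds trimers). The lattice then sees
C_eff = C_total · f(x). The series takes the *total* concentration as given:
there is no self-consistent mass balance between the on-DNA, free, and
polymerized pools, and nucleating dimers/trimers act purely through the
concentration multiplier (they occupy one lattice site and carry no distinct
binding energy). These simplifications define the model, not an
approximation we could refine within it.

A single affinity number γ drives both ends: the on-DNA bond factor
g = exp(−γ/RT) and, by default, the off-DNA Kd = c0·exp(γ/RT). A config
override (`offdna.kd_sam_molar`) decouples them for sensitivity analysis.

## Parameters, units, defaults

| parameter | meaning | default | unit |
|---|---|---|---|
| `thermo.rt_kcal_per_mol` | thermal energy RT | 0.593 (≈298 K) | kcal/mol |
| `thermo.c0_molar` | reference concentration | 1.0 | M |
| `energies.alpha` | specific (ETS) protein–DNA energy | −9.955 | kcal/mol |
| `energies.beta` | non-specific protein–DNA energy | −5.837 | kcal/mol |
| `energies.gamma_sam` | SAM–SAM self-association energy | 0.0 | kcal/mol |
| `element.n_sites` / `ets_positions` | element layout | 24, ETS at 1 | — |
| `offdna.n_max` | polymer cap n | 50 | — |
| `offdna.m_species` | nucleating species count m | 1 | — |
| scan bounds / density | window search | 1e−12–1 M, 25 pts/decade | — |

Favorable energies are negative; Kd = c0·exp(ΔG/RT) throughout. RT and c0
are never printed alongside the published energies, so they are fixed here
by consistency: with RT = 0.593 kcal/mol and c0 = 1 M the measured wildtype
SAM Kd (~7 µM) lands at ≈ −7.0 kcal/mol and the strongest engineered variant
(0.13 nM) at ≈ −13.5, inside the 0 to −14 kcal/mol axis the affinity scan
covers. Both are config-overridable.

The default concentration scan [1e−12, 1] M at 25 log-spaced points per
decade brackets every regime the model produces, including the sub-nanomolar
windows at γ = −14 kcal/mol. The curve presets (`figure1A/B/C`) use
γ = −7.0 (wildtype, anchored to the ~7 µM Kd), −4.0 (weak) and −11.2
(strong, near the 6.7 nM variant); the exact curve affinities were never
published numerically and the presets are flagged as reconstructions.

## Numerical choices

- `occupancy_fast` is a forward/backward transfer recursion over the
  lattice, renormalized at every step, so the partition function never
  over- or underflows (validated for per-site weights from 1e−300 to 1e300).
  Site indexing is 1-based in all I/O; occupancy is reported per site and
  "occupancy at the ETS site" is site 1 of the default layout.
- `occupancy_bruteforce` is the independent oracle: full 2^N enumeration
  with log-sum-exp accumulation, chunked so the 24-site element (2^24
  microstates) is feasible; it is guarded to N ≤ 20 unless explicitly
  unlocked. The two agree to better than 1e−12 per site everywhere tested.
- The competent fraction uses the closed-form geometric ratio while
  x^(n+1) is representable and log-domain evaluation beyond; x = 1 is
  handled by exact term count (m / (n+1)). Extreme sequestration underflows
  `effective_concentration` cleanly to 0.0 rather than raising.
- Window edges: a log-spaced scan locates threshold crossings of
  θ_ETS − target; each crossing is bisected in log-concentration to relative
  tolerance 1e−5 (five significant figures). On ultrasensitive transitions
  the bisection continues until the occupancy residual at the returned edge
  is ≤ 1e−5, so edge concentrations reproduce the target occupancy to
  better than 1e−4. Edges abutting a scan bound are flagged censored.
  Multiple disjoint intervals are supported structurally; the default
  parameters yield a single interval per affinity (asserted as a test, not
  assumed).
- A zero lower scan bound (θ = 0 there, so no window can touch it) is
  floored at c_max·1e−30 for the log grid.
- Everything is deterministic: identical configuration gives byte-identical
  output files.

## Known limitations

- The polymer cap n = 50 is part of the model definition, not a converged
  approximation: below the SAM Kd (x ≤ 0.5) the competent fraction is
  insensitive to the cap to ≤ 1e−12 and the *lower* window edges are
  bit-identical between n = 50 and n = 100, but above Kd the fraction scales
  like x^(m−n), so the *upper* window edge sits at x ≈ (Kd/c*)^(1/(n−1))
  and moves by ~8% when the cap doubles. Quantities quoted at the upper edge
  are therefore specific to n = 50.
- Two site classes only (ETS / non-specific); no competing or heterotypic
  factors; no kinetics, nuclear transport, phosphorylation, or
  phase-separation physics — the model is strictly equilibrium.
- DNA-bound protein is not subtracted from the off-DNA pool (consistent with
  the formula as defined), so predictions near strong depletion regimes
  should be read qualitatively.
- The term x^k of the series is labeled "species of size k+1" in the
  distribution output; whether it denotes a k-mer or a (k+1)-mer is purely a
  labeling convention and does not affect any computed number.

## What the tests demonstrate

There is no external data in this package: the model *is* the object of
study, so tests validate internal consistency (recursion vs enumeration,
closed-form limits, monotonicity and symmetry invariants) and the model's
qualitative regime structure (curve collapse above Kd; windows narrowing and
shifting to lower concentration as affinity strengthens; insensitivity to
the nucleating-species choice within a factor of ~1.03 on edges). Passing
tests show the implementation computes this model correctly — not that the
model captures any particular in-vivo system. Problem sizes used by the test
suite and acceptance script: 200 random lattices at N ≤ 12, one exact 2^24
enumeration of the default 24-site element, 29-point affinity grids
(0 to −14 kcal/mol, step 0.5), 251-point concentration grids.
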