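# privrep

Reputation dynamics and evolutionary stability in the donation game with
**private assessment**.

Every individual holds its own binary opinion ("good"/"bad") of every
other. A strategy is ten bits: an action pair `(a1, a0)` — cooperate with
a recipient deemed good / bad — and two assessment tables `c_ij`, `d_ij`
giving the new opinion of a donor who cooperated / defected, indexed by
the observer's current opinions of donor (`i`) and recipient (`j`).
Execution errors (`mu_e`) flip actions; assessment errors (`mu_a`) flip
judgements.

The package provides:

* **`privrep.strategies`** — the 10-bit strategy space, integer encoding,
  good/bad label mirror, reduction of the 1024 raw strategies to the 258
  canonical ones (256 discriminators + unconditional cooperator and
  defector), and a catalog of named strategies / wildcard rule patterns
  (image scoring, standing, the leading eight, the cooperator ESS
  families).
* **`privrep.mean_field`** — cooperation and assessment probabilities and
  the deterministic dynamics of average reputations (*h-scores*) for
  monomorphic and resident + rare-mutant populations; the monomorphic
  derivative is a cubic polynomial in `h`.
* **`privrep.equilibrium`** — long-run h-scores selected by forward
  dynamics from the shared initial score `h0` (exact directional
  polynomial roots, with an explicit integrator as cross-check), plus
  stability diagnostics (sign of the derivative / Jacobian leading
  eigenvalue).
* **`privrep.ess`** — invasion fitness
  `Δw = p_mr·b − p_rm·c − p_rr·(b−c)` at the dimorphic equilibrium,
  exhaustive ESS scans of all 258 residents × 257 mutants × initial
  h-scores {0.1, 0.5, 0.9}, cooperation classification, exact minimum
  benefit-to-cost thresholds, and mutual-invasion (polymorphism) checks.
  Equilibria are payoff-independent, so each pairing is solved once and
  reused across the whole b/c range, on which `Δw` is affine.
* **`privrep.abm`** — an agent-based Monte-Carlo implementation of the
  exact interaction protocol (N×N opinion matrix, one observer per
  interaction, numba-accelerated) used to validate the mean-field model
  strategy by strategy.
* **`privrep.cli` / `privrep.io`** — a `privrep` command-line tool with
  reproducible CSV/JSON outputs and sidecar manifests.

Headline results reproduced by the analysis (no errors): 15 cooperator
ESSs — exactly the `c1_4`/`c5_11`/`c12_15` pattern families, with minimum
b/c thresholds 1, 2 and 1/(1−h0) respectively — and 38 defector ESSs.
With errors, unconditional defection is the only strategy stable across
the benefit range.

## CLI

```sh
privrep enumerate --out strategies.csv
privrep equilibrium --strategy standing --h0 0.5
privrep equilibrium --strategy 757 --mutant alld --h0 0.9
privrep ess-scan --bc-min 1.25 --bc-max 20 --bc-step 0.25 \
        --h0 0.1,0.5,0.9 --mu-e 0 --mu-a 0 --out ess.csv --plot ess.png
privrep simulate --strategy standing --n 100 --steps 400000 \
        --window 100000 --reps 30 --h0 0.5 --mu-e 1e-4 --mu-a 1e-4 \
        --seed 7 --out sim.csv
privrep compare --all --reps 10 --out compare.csv
```

Strategies are referred to by catalog name (`standing`, `image_scoring`,
`allc`, `alld`) or by their integer code (bit order
`a1 a0 | c11 c10 c01 c00 | d11 d10 d01 d00`, `a1` most significant; e.g.
standing = `1011110101` = 757).

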