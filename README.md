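# slowerx

Population-genetic theory of the **early stages of X-chromosome
evolution**: fixation probabilities and substitution rates at loci on a
young X chromosome that has stopped recombining with the Y while the
Y-linked copy is still functional.

At such a **diploid X locus** a male is permanently heterozygous X/Y, so a
partly recessive X-linked mutation is *sheltered* in males by the
ancestral Y allele. Combined with the X's reduced copy number (1.5N
X chromosomes vs 2N autosome copies at even sex ratio) and its
female-biased transmission (2/3 of X copies pass through females), this
produces a **"slower-X" effect**: selection is less efficient on the young
X, so beneficial mutations fix more slowly and deleterious mutations fix
faster than on an autosome — the opposite of the classical faster-X
behaviour of a hemizygous X. The package is for theoreticians and for
empiricists interpreting divergence data from clades with young or
homomorphic sex chromosomes.

## Model

For a mutant at frequency `x` with sex-specific selection coefficients
`s_f`, `s_m` and dominance `h` (shared between sexes), the expected
frequency change at each locus class has the form `x(1-x)(a + b x)`,
which reduces the class to two compound coefficients, `s̄ = a + b/2`
(sex-averaged selection) and `σ = b/2` (dominance deviation, zero at
`h = 1/2`):

| class          | s̄               | σ                  | Ne     | p0       |
|----------------|------------------|--------------------|--------|----------|
| autosomal      | (s_f + s_m)/4    | (s_f+s_m)(1−2h)/4  | Ne_A   | 1/(2N)   |
| hemizygous X   | (s_f + s_m)/3    | s_f(1−2h)/3        | Ne_X   | 2/(3N)   |
| diploid X      | (s_f + h·s_m)/3  | s_f(1−2h)/3        | Ne_X   | 2/(3N)   |

The diffusion fixation probability is

```
U(p) = ∫₀^p G(y) dy / ∫₀¹ G(y) dy,   G(y) = exp(−4 Ne (s̄ y − σ y(1−y)))
```

and the substitution rate relative to the mutation rate is `U(p0)/p0`
(neutral = 1), so the X/A rate ratio `R` compares classes directly. The
quadratic exponent makes both integrals error-function expressions, which
`slowerx` evaluates in log space and cross-checks by adaptive quadrature;
at `h = 1/2` the rate reduces to Kimura's `4Ne s̄ / (1 − e^{−4Ne s̄})`.
For strongly beneficial mutations a Haldane branching process gives the
dominance-free limit

```
R = (2 s_f + s_m) / (2 s_f + 2 s_m)
```

(1 for female-limited, 1/2 for male-limited, 3/4 for equal effects). A
genotype-resolved two-sex Wright–Fisher simulator verifies the diffusion
results independently.

## Worked example

Relative substitution rates for a beneficial mutation with equal effects
in both sexes (`Ne_A·s = 3`, i.e. `s_f = s_m = 3×10⁻⁶` at
`Ne_A = 10⁶`), partial recessivity `h = 0.2`, `Ne_X = 0.75·Ne_A`:

```
$ slowerx rates --sf 3e-6 --sm 3e-6 --dominance 0.2 --N 1e6
locus_class     relative_rate   R_vs_autosome
autosomal       3.87089065479   1
hemizygous_X    4.8714053773    1.25847145056
diploid_X       2.85289440972   0.737012399506
```

The autosomal locus substitutes this mutation 3.87× faster than a neutral
one. The hemizygous X is faster still (R = 1.26, the classical faster-X
effect for a recessive beneficial), while the diploid X reaches only 74%
of the autosomal rate — the slower-X effect, despite identical selection
parameters. The same quantities are available in the library:

```python
import slowerx as sx
pop = sx.PopulationModel(N=1_000_000)                 # Ne_X = 0.75 Ne_A
reg = sx.SelectionRegime(s_f=3e-6, s_m=3e-6, h=0.2)
sx.relative_substitution_rate(reg, "diploid_X", pop)  # 2.8528944...
sx.R_branching(sx.SelectionRegime(0.0, 0.01, 0.3))    # 0.5 (male-limited)
```

Grid scans over dominance and sex-specific effects (`slowerx scan
--preset fig1|fig2|fig3`) write tab-separated tables with a provenance
header; `slowerx compare` runs the forward-simulation verification grid
against the diffusion predictions.

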