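# inhibkin

Enzyme-inhibition kinetics for fluorogenic microplate assays: simulate
progress curves, extract initial rates, fit Michaelis–Menten and general
inhibitor models, and identify the inhibition mechanism by graphical
discrimination (Dixon and substrate-over-velocity plots) with a
closed-form estimate of the inhibition constant.

The package is written for enzymologists and assay scientists who titrate
an inhibitor against a substrate series in a plate reader — the motivating
system is a cysteine protease (cathepsin B) assayed with a fluorogenic
peptide substrate and a cyclic-depsipeptide inhibitor — and who want the
whole chain from raw fluorescence traces to a mechanism verdict to be
scripted, testable and reproducible.

## The model

Uninhibited velocities follow Michaelis–Menten kinetics,

v = V<sub>max</sub> [S] / (K<sub>M</sub> + [S]),

and inhibited velocities the general (mixed) inhibitor model

v = V<sub>max</sub> [S] / ( K<sub>M</sub> (1 + [I]/K<sub>i</sub>) + [S] (1 + [I]/K<sub>i</sub>′) ),

where K<sub>i</sub> and K<sub>i</sub>′ are the inhibitor's dissociation
constants from free enzyme (EI) and from the enzyme–substrate complex
(ESI). The classical mechanisms are the finiteness patterns of
(K<sub>i</sub>, K<sub>i</sub>′): competitive (K<sub>i</sub>′ → ∞),
uncompetitive (K<sub>i</sub> → ∞), noncompetitive (equal, finite), mixed
(both finite, unequal).

Rearranged as straight lines in [I] at fixed [S]:

* **Dixon plot** (1/v vs [I]): all lines cross at [I] = −K<sub>i</sub>;
  parallel lines mean K<sub>i</sub> is infinite — an uncompetitive
  inhibitor.
* **[S]/v plot** ([S]/v vs [I]): all lines cross at [I] = −K<sub>i</sub>′
  with ordinate K<sub>M</sub>(1 − K<sub>i</sub>′/K<sub>i</sub>)/V<sub>max</sub>;
  parallel lines mean K<sub>i</sub>′ is infinite — a competitive
  inhibitor. For an uncompetitive inhibitor the ordinate is exactly
  K<sub>M</sub>/V<sub>max</sub>, an internal consistency check.

Noisy lines have no single crossing, so the common point is estimated as
the **closest-neighbour intersection**: the (x, y) minimising
Σ<sub>i</sub> (a<sub>i</sub>x + b<sub>i</sub>y + c<sub>i</sub>)² / (a<sub>i</sub>² + b<sub>i</sub>²),
the summed squared perpendicular distances to the fitted lines, solved in
closed form from the 2×2 normal equations. Parallelism is judged by an
extra-sum-of-squares F-test; the verdict rule table and its calibration
are described in `docs/methods.md`.

## Worked example

Simulate an uncompetitive inhibitor (K<sub>i</sub>′ = 44.3 μM) on an
enzyme with K<sub>M</sub> = 93.9 μM, V<sub>max</sub> = 33.02
pmol min⁻¹ μg⁻¹ under the default design (20 ng enzyme per 100 μL well,
[S] up to 200 μM, [I] up to 25 μM, triplicates, reads every 45 s for
1400 s, 2% CV rate noise), then analyse it:

```sh
inhibkin simulate --out run --seed 1 --mechanism uncompetitive --noise-cv 0.02
inhibkin analyze  --input run/plate.csv --out run/analysis
```

or run the scripted version, `python analysis/01_simulate_assay.py` …
`05_benchmark_classifier.py`. The discrimination step prints:

```
Dixon plot parallel: True (p = 0.265)
S/v plot parallel:   False (p = 3.58e-14)
S/v crossing: x* = -41.14 uM, y* = 2948.53 min ug
verdict: uncompetitive  ->  Ki' = 41.14 uM
consistency of y* vs KM/Vmax at I=0: 3.72 %
```

Reading: the Dixon lines are statistically parallel while the [S]/v lines
converge left of the axis — the uncompetitive signature — so
K<sub>i</sub>′ is estimated as the negated crossing abscissa (41.1 μM
here, against a planted 44.3 μM at this noise level). The crossing
ordinate agrees with K<sub>M</sub>/V<sub>max</sub> from the uninhibited
fit (the nM-convention ratio 93 900/33.02 = 2843.73 min μg) to within a
few percent, as the uncompetitive model demands. On a noise-free plate the
pipeline returns K<sub>i</sub>′ = 44.3 μM exactly.

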