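# opscreen

Genetic-interaction profiling of protein-overproduction colony screens in
budding yeast.

Overproducing even a harmless ("gratuitous") protein such as GFP slows
growth by overloading the protein-synthesis machinery — the *protein
burden* — while modified probes (a triple-GFP, or a triple-GFP carrying a
nuclear export signal) overload more specific resources such as the
proteasome or the nuclear export machinery.  Colony-array screens cross an
overproduction plasmid into thousands of deletion and temperature-sensitive
mutants and read growth out as colony size on 1536-format agar plates.
`opscreen` turns those raw per-colony measurements into quantitative
genetic-interaction profiles, expression classes and enriched processes,
and ships a synthetic-screen generator with a planted ground truth so every
stage of the analysis is testable without any external data.

## The model

Fitness of each mutant is its plate-normalized colony size `W` (interior
plate median = 1, the "U" unit), corrected for spatial artifacts by a
fixed three-stage chain (plate median → row/column median polish → moving
2‑D median), with the outer two rows/columns excluded from every median.
The genetic-interaction (GI) score of mutant *A* with overproduction
construct *B* is the deviation from the multiplicative expectation

    ε = W_AB − W_A · W_B ,   with W_B ≡ 1, so ε = W_AB − W_A,

where `W_AB` is the mutant's fitness carrying the overproduction plasmid
and `W_A` its fitness with the empty vector.  Confidence comes from a
variance-floored Welch-type test on the replicate colonies (the floor is
the across-array median per-strain variance, so artificially tight
quadruplicates are still judged against array-typical dispersion).  A
mutant is **called** when both duplicate experiments pass `|ε| > 0.08`
(upper/lower 0.16 / −0.12 for the triple-GFP constructs) with the same
sign and `p < 0.05`; called scores are averaged across duplicates, and
`|ε̄| > 0.2` under high-copy (−Leu/Ura) conditions defines the strong
`op_negative` / `op_positive` sets.

Reporter expression per mutant is the **GFPunit**: colony fluorescence
medians in the GFP channel (F488) and a constitutive E2‑Crimson channel
(F532) are each divided by their plate average, the per-colony ratio
F488/F532 cancels colony size, and two colonies are averaged.  Mutants
below the across-mutant mean are `GFP_L`, the rest `GFP_H`.  Combining the
GI sign with the expression class yields four interpretive quadrants
(sensitive to overproduction / production enhancing / production reducing
/ resistant to overproduction).  Positive calls from marker-pathway
(his/lys/arg) strains whose vector-control colonies are carryover-small
(`W ≤ 0.39`) are filtered out.  GI profiles over the three constructs are
clustered by average-linkage hierarchical clustering (k = 15), and any
strain set can be tested for annotation-set over-representation with a
hypergeometric upper tail and Benjamini–Hochberg FDR.

## Worked example

Simulate a one-plate screen (308 mutants, vector + GFP-op, duplicate
experiments, two conditions) with two planted interactions of ε = ∓0.3 —
the negative interactor also producing less GFP — and run the whole
pipeline:

```python
from opscreen import RunConfig, SimConfig, run_pipeline
from opscreen.simulate import default_strain_ids

ids = default_strain_ids(308)
planted = []
for cond, scale in (("leu_ura_minus", 1.0), ("ura_minus", 0.7)):
    planted += [(ids[5], "GFP", cond, -0.30 * scale),
                (ids[9], "GFP", cond, +0.30 * scale)]
sim = SimConfig(n_strains=308, constructs=("vector", "GFP"),
                planted_interactions=planted,
                planted_expression=[(ids[5], 0.6)],
                noise_sd=0.02, baseline_sd=0.05,
                gradient=(0.1, 0.08, 0.15), edge_factor=1.25, seed=42)
out = run_pipeline(RunConfig(out_dir="example_run", simulate=sim, cluster_k=4))

calls = out["calls"]
print(calls[(calls.call != "none") & (calls.condition == "leu_ura_minus")]
      [["strain_id", "eps_rep1", "eps_rep2", "eps_mean", "call", "strong"]])
```

prints

```
strain_id  eps_rep1  eps_rep2  eps_mean     call  strong
  yfg0006    -0.328    -0.323    -0.326 negative    True
  yfg0010     0.292     0.308     0.300 positive    True
```

— both planted effects are recovered through the plate gradients and edge
artifacts, called in both replicates, and flagged strong.  The quadrant
table combines the calls with the fluorescence classes:

```
strain_id construct     call  gfp_unit level_class              interpretation
  yfg0006       GFP negative     0.600       GFP_L sensitive_to_overproduction
  yfg0010       GFP positive     1.001       GFP_H resistant_to_overproduction
```

The planted 0.6× expression factor is recovered as `gfp_unit = 0.600`
(scanner gains cancel exactly), so the negative interactor is interpreted
as overproduction-sensitive.  `example_run/` contains the full set of TSV
outputs (fitness, GI scores, calls, reproducibility report, GFPunits,
quadrants, carryover rejects, clusters, enrichment, manifest).

The same pipeline runs from the shell:

```sh
opscreen simulate --seed 7 --n-strains 1232 --out screen/
opscreen run --plates screen/plates.tsv --key screen/array_key.tsv \
             --gmt screen/annotations.gmt --out run/
opscreen report --run-dir run/
```

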