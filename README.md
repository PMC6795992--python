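# tdrpclock

Dating virus–host co-speciation events under a power-law
time-dependent-rate clock, with the pre- and post-processing a
recombination-aware analysis of a viral gene alignment needs.

## The problem

Viral evolutionary rates are not constant in the way molecular-clock dating
assumes: rates measured over days-to-years are orders of magnitude higher
than rates inferred over millions of years of virus–host co-divergence (the
*time-dependent rate phenomenon*, TDRP). For viruses such as simian foamy
viruses — which have co-speciated with their primate hosts for tens of
millions of years — this means a strict or relaxed clock calibrated at one
depth badly mis-dates nodes at another. Empirically, the relationship between
a node's age *t* (Myr) and its height *s* (expected substitutions per site
per lineage) follows a simple power law:

    log t = α + β log s

`tdrpclock` calibrates this clock against dated host divergences and uses it
to convert node heights into divergence times. Calibration is repeated in
**every** tree of a Bayesian posterior sample: for each tree, calibration
node heights are extracted (MRCA of a named taxon set; height = mean
root-to-tip path below the node), one date per calibration point is drawn
from a normal distribution (mean = published median, sd = wider 95% interval
half-width / 1.96, truncated to positive times), an unweighted least-squares
line is fitted in log–log space, and the fitted line dates the target clades
of that same tree. Pooling across trees propagates phylogenetic and
calibration-date uncertainty jointly; pooled distributions are summarised by
the median and the 95% highest-posterior-density (shortest-window) interval.

Around the clock, the package implements the supporting pipeline used in
studies of modular viral genome evolution:

- **consensus filtering** of multi-programme recombination-event calls
  (keep events detected by ≥ 4 programmes at P < 0.05) and 1-D clustering of
  breakpoints into hotspot intervals;
- **alignment splitting** into hotspot-bounded regions (1-based inclusive
  coordinates), with per-sequence excision of recombinant segments by gap
  substitution;
- **site-rate summaries**: scaling site-wise rates to mean 1, region means
  with HPDs over posterior samples, and focal/complement rate ratios with
  linear- and log-scale HPDs;
- **codon-usage comparison** on the fixed 61 sense-codon table with a
  Pearson χ² (df = 60 × (groups − 1); stop/gap/ambiguous triplets tallied
  separately);
- **synthetic-data generators** for all of the above with known ground
  truth, including posterior tree samples whose node heights follow the
  inverted power law with multiplicative lognormal noise.

## Worked example

Simulate a 500-tree posterior sample under a known clock
(α = 4.114, β = 1.762, lognormal height noise σ = 0.1) and date three target
clades against three dated host splits:

```python
from tdrpclock import run_dating
from tdrpclock.simulate import (demo_sim_spec, demo_calibrations,
                                demo_targets, simulate_posterior_trees)

trees, truth = simulate_posterior_trees(demo_sim_spec(sigma=0.1, n_trees=500), seed=42)
res = run_dating(trees, demo_calibrations(), demo_targets(), seed=42)
print(res.summary())
```

```
Power-law TDRP clock: log t = alpha + beta log s (natural logs, t in Myr)
  trees used: 500
  alpha: 4.113  (95% HPD 3.829 - 4.433)
  beta:  1.770  (95% HPD 1.429 - 2.059)

                                 median_Myr  hpd95_lower_Myr  hpd95_upper_Myr
clade                                                                        
mandrill N-S split (variant I)        1.065            0.433            1.771
mandrill N-S split (variant II)       0.401            0.135            0.743
env variant origin                   29.774           19.167           43.015
```

The fitted clock recovers the generating parameters, and the pooled medians
sit on the true node times (1.075, 0.415 and 29.892 Myr): the shallow
mandrill North/South splits date to ~1 Myr and ~0.4 Myr, and the deep
origin of the two envelope variants to ~30 Myr, each with its 95% HPD.

The same analysis runs end to end from the shell, producing region
alignments, the dating report, codon-usage and rate-ratio summaries, and a
reproducibility manifest:

```sh
cat > demo.yaml <<EOF
seed: 1
output: runs/demo
simulate: {n_trees: 500, sigma: 0.1}
calibration: {preset: demo}
EOF
tdrpclock run --config demo.yaml
```

Other subcommands (`tdrpclock trees validate`, `calibrate preview`,
`regions consensus|split|rates`, `codons chisq`, `simulate ...`,
`tdrp date`) expose each stage separately; see `tdrpclock --help`.

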