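# specstruct

Do lineages that build more population structure over space also speciate
faster?  `specstruct` is a desk-scale Python toolkit for asking that question
the way it is asked for real radiations — here modeled on a ~23-million-year
island snake radiation with ~93% of extant species sampled — by joining three
analyses that usually live in separate ecosystems:

1. **Macroevolution from the dated tree.**  The lineage-through-time curve
   identifies only *pulled* rates: the pulled speciation rate
   λ<sub>p</sub> = λ(1 − E) (the log-slope of the LTT) and the pulled
   diversification rate r<sub>p</sub> = λ − μ + λ′(τ)/λ (τ = age), which is
   constant across the whole *congruence class* of (λ(t), μ(t), ρ) scenarios
   that fit the tree equally well.  `specstruct.congruence` estimates
   λ<sub>p</sub> by spline-smoothing ln M(t), maps a reference scenario
   through the class (propose an extinction history μ\*(t), solve the
   congruent λ\*(t), and vice versa) under 11 families of alternative
   trajectories (GMRF/HSMRF random walks, linear/exponential twofold changes,
   episodic shifts), and classifies per-time-slice rate trends across
   replicates — so a claim like "speciation declined toward the present"
   can be checked across every scenario the data cannot distinguish.
2. **Tip rates.**  `specstruct.tiprates` computes the DR statistic
   (inverse equal-splits: ES<sub>i</sub> = Σ<sub>j</sub> l<sub>j</sub> 2<sup>−(j−1)</sup>,
   DR<sub>i</sub> = 1/ES<sub>i</sub>) and imports externally estimated tip
   rates (CLaDS, BAMM) from CSV.
3. **Microevolution from per-species SNP + mtDNA data.**
   `specstruct.popgen` computes Hudson-type pairwise Fst between individuals,
   unbiased nucleotide diversity π, allele-sharing and Euclidean genotype
   distances, mtDNA p-distances, and the isolation-by-distance slope
   **β_IBD** — Fst/(1 − Fst) regressed on ln(great-circle km) — with
   Mantel-permutation significance.
4. **The junction.**  `specstruct.comparative` joins per-species metrics to
   tip rates: Spearman correlations, phylogenetic signal (ML Pagel's λ with
   a likelihood-ratio test; Blomberg's K with permutation replicates),
   VIF-based multicollinearity elimination (threshold 10), and PGLS with an
   ML λ transform.  `decoupling_report` runs the whole battery.

Because the real data (GBS VCFs, COI alignments, a dated tree) are large and
archived elsewhere, `specstruct.simulate` generates synthetic studies with
the same statistical structure: birth–death trees with declining speciation
and incomplete sampling, genotype matrices whose β_IBD is calibrated exactly
(in expectation) to a target slope, distance-structured mtDNA alignments,
Brownian tip traits, and whole "worlds" in which β_IBD either is
(**coupled**) or is not (**uncoupled**) a monotone function of the tip
speciation rate — positive and negative controls for the headline analysis.

## A worked example

```python
from specstruct.simulate import SpatialSimParams, simulate_spatial_genotypes
from specstruct.popgen import (pairwise_fst, linearize_fst, geographic_km,
                               ibd_slope, nucleotide_diversity)

g = simulate_spatial_genotypes(SpatialSimParams(
    n_individuals=20, n_sites=5000, beta_target=0.05, missing_rate=0.05,
    species="Liophidium_sp", seed=42))
lin, _ = linearize_fst(pairwise_fst(g))
res = ibd_slope(lin, geographic_km(g.coords), permutations=999, seed=42)
print(f"beta_IBD = {res.beta:.4f} per ln(km)  (generating value 0.05)")
print(f"Mantel p = {res.p_perm:.3f} over {res.n_pairs} pairs")
print(f"pi = {nucleotide_diversity(g):.3f}")
```

prints

```
beta_IBD = 0.0411 per ln(km)  (generating value 0.05)
Mantel p = 0.001 over 190 pairs
pi = 0.257
```

— the estimated slope recovers the generating isolation-by-distance
strength (0.05, here within one seed's sampling noise), the Mantel test
confirms the spatial signal against 999 label permutations, and π is the
per-site nucleotide diversity over variant sites.  The `examples/` directory
has one short script per capability (pulled rates and congruence classes,
DR tip rates, IBD, the coupled/uncoupled decoupling analysis, and the full
pipeline); each prints the numbers it computes with a line on what they
mean.

## Pipeline and CLI

The library is the primary interface.  For shell use, a thin CLI wraps the
configuration-driven pipeline (simulate → tiprates → congruence → popgen →
comparative), with per-stage content hashing so identical reruns are
byte-identical and unchanged stages are skipped:

```bash
specstruct run-all --config config.yaml
specstruct tiprates --tree tree.nwk --method dr
specstruct popgen --species-manifest manifest.csv --tree tree.nwk --seed 1 --out-dir run
```

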