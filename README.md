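# tdbscore

Network-based reaction scoring for genome-scale metabolic reconstructions.

Curated reconstructions annotate each reaction with a discrete confidence
score (4 = direct biochemical proof … 0 = included only because it improves
modelling). Those labels are coarse — five values for over a thousand
reactions — and say nothing about how well a reaction fits the network it
sits in. `tdbscore` complements them with a continuous, probabilistic score
computed purely from the topology of the metabolite–reaction bipartite
graph: how likely is this particular combination of metabolites to
co-occur in a reaction, given the statistical regularities of the whole
network?

## The model in brief

The bipartite network (M metabolites, R reactions, L links) is fitted by a
hierarchical random graph: nodes are the leaves of a binary dendrogram
whose internal nodes t carry connection probabilities ρ_t; a
metabolite–reaction pair whose lowest common ancestor is t links with
probability ρ_t. For a fixed topology the likelihood

  log ℒ = Σ_t [ E_t log ρ_t + (ε_t − E_t) log(1 − ρ_t) ],
  ε_t = Lm_t·Rr_t + Lr_t·Rm_t,  ρ̂_t = E_t/ε_t

is maximized by the observed cross-link fractions; dendrogram space is
sampled by Metropolis–Hastings branch swaps and ρ is averaged over sampled
trees into pairwise ρ_mr (the HRBG probabilities), with tree distance
d_mr = 1 − ρ_mr. Degree correction turns distances into Tree Distance
Bipartite (TDB) connection probabilities

  p_mr = 1 / (1 + d_mr / (μ k_m)),  μ = 1/R,

calibrated so that Σ p_mr tracks L. A reaction with metabolite set ν is
scored by its expected number of co-occurrences

  S_TDB(ν) = Σ_r Π_{m∈ν} p_mr · Π_{m′∉ν} (1 − p_m′r),

and relative to the configuration-model null S_CMB (degree-preserving,
otherwise random) as Σ = S_TDB / S_CMB: Σ > 1 means the reaction's
metabolites aggregate in the fitted hierarchy, Σ < 1 that they avoid each
other. Validation is by ROC/AUC against all absent pairs, link-removal
robustness, and probability calibration. See `docs/methods.md` for the
full account.

## Worked example

Simulate a small network with metabolic degree statistics, fit it, score
its reactions, and validate the probability models:

```sh
tdbscore simulate -M 30 -R 45 --seed 7 -o demo_net.tsv
tdbscore fit      -i demo_net.tsv -o demo_pairs.tsv \
                  --seed 7 --burn-in 500000 --samples 500 --interval 75
tdbscore score    -i demo_net.tsv -p demo_pairs.tsv -o demo_scores.tsv
tdbscore validate -i demo_net.tsv -o demo_report \
                  --seed 7 --burn-in 500000 --samples 500 --interval 75
```

`demo_scores.tsv` ranks the 45 reactions by descending absolute score:

```
# reaction_id  size  s_tdb          s_cmb          sigma       rank
r02            2     2.376933404    2.582861815    0.9202712242  1
r22            2     2.376933404    2.582861815    0.9202712242  2
r37            3     0.5552269076   0.5584566087   0.9942167376  3
...
r38            8     1.262706599e-06 1.297157361e-06 0.9734413401 45
```

Small, hub-dominated metabolite combinations are expected to recur
(S_TDB ≈ 2.4 occurrences), while the largest 8-metabolite combination is
essentially unique (S_TDB ≈ 10⁻⁶) — six orders of magnitude apart even on
a 45-reaction toy; larger networks spread the scores much further. Relative
scores Σ near 1 say this simulated network carries no strong
distance correlations, as expected from a degree-sequence generator.
`demo_report/summary.txt` compares the models' link-discrimination power:

```
# model  AUC
hrbg     0.9711
tdb      0.9022
cmb      0.8561
cn       0.7405
```

The tree-based models dominate the degree-only null (cmb) and the local
common-neighbours baseline (cn). Each run writes a `.manifest` file
echoing its resolved configuration; re-running with the same seed
reproduces every output byte for byte.

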