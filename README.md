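# traitnet

Generative modelling of animal social networks from trait-based social
preferences, with simulation of the structural and functional
consequences: network metrics, disease/information transmission, and
robustness to the loss of individuals.

Across species, individuals preferentially socialise with partners that
have certain trait values — their own sex, a large body size, close kin.
`traitnet` turns such preferences into networks. It is intended for
behavioural ecologists and network scientists who want to ask: *if a
population uses preference X with trait Y, what social structure
follows, and what does that structure do to transmission and to
resilience against fragmentation?*

## The model

Two preference types act on individual traits:

* **similarity** (homophily): pair attraction is a kernel of trait
  distance — 1 at identical values, decreasing with distance;
* **popularity**: higher trait values are preferred by everyone; each
  individual gets a min–max-normalised score s ∈ [0, 1] and a pair's
  attraction is (s_i + s_j)/2.

Each preference k has an importance ω_k ∈ [0, 1], and the pairwise
*social attraction* is

    A_ij = max(ε, Π_k [(1 − ω_k) + ω_k · a_k(i, j)])

ω = 0 recovers a uniform random graph; ω = 1 gives the preference full
control. Networks with n nodes and mean degree d̄ get exactly
m = round(n·d̄/2) edges, drawn sequentially without replacement with
probability ∝ A_ij (weighted mode: edge weight ∝ A_ij, mean weight 1);
only single-component draws are kept. Three trait distributions are
built in — categorical (sex), normal (body size), circular
(relatedness) — and importance sweeps generate network ensembles across
the (ω_popularity, ω_similarity) range. Full model details are in
[docs/methods.md](docs/methods.md).

## Worked example

Compare a random population (ω = 0) against one in which one sex is
universally preferred as a social partner (popularity preference on a
categorical trait at full importance), 25 networks per point:

```python
import traitnet as tn

cfg = tn.SweepConfig(
    popularity_trait=tn.categorical("sex"),
    similarity_trait=tn.normal("size"),
    importance_grid=[(0.0, 0.0), (1.0, 0.0)],
    ensemble_size=25,
    master_seed=42,
    transmission=[tn.TransmissionConfig(mode="simple", beta=0.1)],
    removal=[tn.RemovalStrategy("degree_high_first")],
    weighted_metrics=False,
)
result = tn.run_sweep(cfg)
cols = ["omega_pop", "degree_variation_mean", "clustering_mean",
        "pop_trait_degree_corr_mean", "simple_u_t100_mean",
        "break_degree_high_first_mean"]
print(result.table[cols].round(3).to_string(index=False))
```

```
 omega_pop  degree_variation_mean  clustering_mean  pop_trait_degree_corr_mean  simple_u_t100_mean  break_degree_high_first_mean
       0.0                  0.297            0.100                      -0.008              13.116                         40.92
       1.0                  0.583            0.166                       0.866              20.788                          8.84
```

Reading the rows: at zero importance the ensemble sits at the random
G(n, m) baseline — clustering ≈ edge density 10/99, no trait–degree
correlation. At full popularity importance the preferred sex hoards
connections (trait–degree correlation 0.87), degree variation nearly
doubles (core–periphery structure), simple transmission needs ~21 steps
instead of ~13 to reach everyone (peripheral nodes are hard to reach),
and removing high-degree individuals first fragments the network after
only ~9 removals instead of ~41 — popularity preferences buy
centralisation at the price of robustness.

The same machinery is scriptable from the shell:

```sh
traitnet generate --n 100 --mean-degree 10 \
    --pop-trait sex:categorical --omega-pop 1 --seed 1 --out net.graphml
traitnet metrics net.graphml
traitnet transmit net.graphml --mode simple --beta 0.1 --reps 10
traitnet robustness net.graphml --strategy degree_high_first
traitnet sweep --config sweep.yaml --out results/
```

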