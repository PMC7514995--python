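# oinet

Transfer-entropy network inference for microbiome time series: from
relative-species-abundance (RSA) tables to directed species interaction
networks, species importance indices, diversity macroecology, and
scaling/criticality diagnostics.

## The problem

Gut microbiome studies produce per-individual time series of OTU relative
abundances — short (tens of days), compositional (columns sum to 1), with
dozens to hundreds of species. Who is driving whom? Co-occurrence networks
ignore direction and magnitude; `oinet` instead quantifies directed,
lagged predictive influence between species with **transfer entropy**

    TE(X_i -> X_j; tau) = sum p(x_{j,t}, x_{j,t-tau}, x_{i,t-tau})
                          log2 [ p(x_{j,t} | x_{j,t-tau}, x_{i,t-tau})
                               / p(x_{j,t} | x_{j,t-tau}) ]

estimated by plug-in histograms on quantile-binned symbols, with the lag
chosen to minimize the functional distance `d_f = exp(-MI)`. Edges must
beat a circular-shift permutation null, and conditional transfer entropy
removes indirect links (information *flow* rather than mere transfer).
Because retained TE terms are nonnegative, the surviving edge set
maximizes the total network entropy

    H(N) = sum_i H(x_i) g(x_i) + sum_{i != j} sign(i,j) TE(i -> j) g(x_i)

— the **Maximum Entropy Network** (MENet). Dropping nodes whose incoming
TE is at least their outgoing TE (g = 0) yields the **Optimal Information
Network** (OIN), the minimal non-redundant predictive core. On top of the
networks the package computes Transfer Entropy Indices (sigma_i =
OTE_i/H(OIN), mu_i = H(x_i)/H(OIN)), alpha/beta/gamma diversity tracks
with speciation-event counts, two-regime exceedance fits (exponential
bulk, power-law middle with pdf exponent epsilon, exponential tail),
log-log scaling fits, and stability/resilience metrics (spectral radius,
random attack).

## Worked example

```python
import numpy as np
from oinet import SimSpec, simulate, TransferEntropyNetwork, tei

# a 20-species community with 20 planted directed couplings, 500 days
series, true_edges = simulate(SimSpec(n_species=20, n_time=500,
                                      topology="random",
                                      coupling_strength=0.8, seed=0))
est = TransferEntropyNetwork(random_state=0).fit(series.data)
found = set(est.menet_.graph.edges)
true = {(u, v) for u, v, _ in true_edges}
tp = len(found & true)
print(f"MENet: {len(found)} edges, precision {tp/len(found):.2f}, "
      f"recall {tp/len(true):.2f}")
print(f"OIN: {est.oin_.n_nodes} nodes / {est.oin_.n_edges} edges")
rows = tei(est.oin_)
print(f"most interactive species: {rows[0].species} (sigma={rows[0].sigma:.3f})")
```

prints

```
MENet: 15 edges, precision 0.93, recall 0.70
OIN: 7 nodes / 1 edges
most interactive species: sp006 (sigma=0.020)
```

Fourteen of the fifteen retained edges are planted couplings; the OIN
keeps the seven species that export more information than they receive
(with only the edges among them), and sigma ranks species by their share
of the network's information flow.

The same pipeline runs from the shell on delimited RSA tables:

```sh
oinet simulate --n-species 47 --n-time 30 --out a.tsv
oinet infer a.tsv --group-id demo --outdir out/
oinet run-all --config config.yaml --outdir out/
```

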