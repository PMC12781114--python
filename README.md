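# nqogate

Analysis toolkit for conformationally gated flavoenzymes of the
NADH:quinone oxidoreductase (NQO) type — enzymes in which a flexible loop
and an adjacent extended domain form a *gate* over the active site, and
whose catalysis follows a ping-pong bi-bi mechanism (NADH reduces the
bound FMN cofactor, NAD+ leaves, then a quinone such as CoQ0 reoxidizes
it).  The package is aimed at computational enzymologists who want to
connect gate dynamics in structural ensembles to measured kinetics:

* **synthetic data** — two-state (open/closed) gate ensembles with
  configurable state means, fluctuations and Markov switching, plus
  simulated initial-rate tables and stopped-flow transients;
* **trajectory core** — PDB/DCD/XYZ I/O, an atom-selection
  mini-language, Kabsch superposition, RMSD series, equilibration
  trimming;
* **ensemble PCA** — pooled backbone covariance across systems, scree,
  projections, shared-grid 2D densities, most-probable conformations;
* **contact networks** — heavy-atom residue contacts (4.5 A, sequence
  separation >= 3), occupancy matrices, wild-type -> mutant difference
  networks (df), consensus communities, community-level net df;
* **gate geometry** — residue-pair distance series and statistics;
* **kinetics** — surface fits of the ping-pong law with and without NADH
  substrate inhibition, AICc + F-test model selection, biexponential
  stopped-flow fits, hyperbolic kobs saturation, catalytic efficiencies
  and fold changes.

## The models

Steady-state turnover at NADH concentration *A* and CoQ0 concentration
*B* (rates as v0/e, s^-1; K's in uM):

    v0/e = A B kcat / (A Kb + B Ka + A B)                      (ping-pong)
    v0/e = A B kcat / (Ka B + Kb A (1 + A/Kis) + A B)          (+ NADH inhibition)

Stopped-flow flavin reduction at 461 nm and its saturation:

    A(t)  = B1 exp(-kobs1 t) + B2 exp(-kobs2 t) + C
    kobs1 = kred S / (Kd + S)

Structural stages operate on ensembles: frames are superposed onto a
common reference (Kabsch), the pooled covariance of selected coordinates
is diagonalized for PCA, and residue contacts are counted per frame with
an inclusive 4.5 A heavy-atom cutoff.  The contact-probability difference
df = P(mutant) - P(wild type) per residue pair, summed over community
interfaces, quantifies where a mutation rewires the structure.

## Worked example

`examples/05_stopped_flow_transients.py` simulates a reductive
half-reaction series at the mutant-like conditions (kred 4.8 s^-1,
Kd 450 uM, a 0.1 s^-1 slow phase carrying 8% of the amplitude) and fits
it back:

```
per-trace biexponential fits:
  [NADH] =    90 uM: kobs1 =  0.80 s^-1, kobs2 =  0.06 s^-1, fast phase 93% of amplitude
  [NADH] =   150 uM: kobs1 =  1.17 s^-1, kobs2 =  0.08 s^-1, fast phase 93% of amplitude
  [NADH] =   250 uM: kobs1 =  1.73 s^-1, kobs2 =  0.15 s^-1, fast phase 92% of amplitude
  [NADH] =   350 uM: kobs1 =  2.15 s^-1, kobs2 =  0.13 s^-1, fast phase 92% of amplitude
  [NADH] =   500 uM: kobs1 =  2.45 s^-1, kobs2 =  0.08 s^-1, fast phase 92% of amplitude
saturation fit: kred = 4.59 +/- 0.32 s^-1, Kd = 419 +/- 51 uM
```

The fast-phase rate rises hyperbolically toward the limiting reduction
rate kred and half-saturates at Kd; both recover the generating truth
within their standard errors, and the substrate-independent slow phase
stays below 10% of the amplitude.  The other examples walk through the
gate ensemble generator (01), pooled PCA of closed vs open ensembles
(02), difference contact networks and communities (03), and steady-state
surface fitting with model selection (04); each prints the numbers it
computes and a line on what they mean.

## Selection mini-language

`select_atoms(structure, expr)` accepts:

| expression            | selects                                        |
|-----------------------|------------------------------------------------|
| `all`                 | every atom                                     |
| `backbone`            | atoms named N, CA, C, O                        |
| `heavy`               | element != H                                   |
| `sidechain`           | not backbone                                   |
| `name CA CB`          | by atom name(s)                                |
| `resid 80`, `resid 75 : 86` | residue number or range (`to` also works) |
| `element C N`         | by element                                     |
| `chain A`             | by chain id                                    |
| `not`, `and`, `or`    | boolean combinations (that precedence order)   |

Example: `resid 80 and name CA` resolves the gate marker atom.

## Pipeline and CLI

The config-driven pipeline (`nqogate.pipeline`) chains
simulate/ingest -> trim -> superpose -> PCA + contacts + distances ->
kinetic fits, writes all artifacts (CSV/JSON, PDB/DCD) under one output
directory with a config hash in the run report, and is deterministic for
a fixed config + seed.  A thin CLI wraps it:

```sh
nqogate run-all --demo --outdir demo_out --seed 1
nqogate fit-steadystate --rates-csv rates.csv --model both
nqogate validate -c config.yaml
```

Subcommands: `simulate`, `distances`, `pca`, `contacts`, `dcna`,
`fit-steadystate`, `fit-transient`, `run-all`, `validate`.  The YAML
config schema is documented in `nqogate/pipeline.py`.

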