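# edupulse

Cell-cycle kinetics from EdU/BrdU pulse-chase flow cytometry.

In vivo pulse-chase labelling with thymidine analogues (EdU, BrdU) marks
every cell that passes through S phase while label is bioavailable.  A
single endpoint snapshot — the bivariate DNA-content × EdU dot plot — then
encodes the population's cycling kinetics in three gated percentages:
unlabelled G0/G1 cells, unlabelled G2/M cells, and EdU⁺ cells.  `edupulse`
turns those three numbers into proliferation rates and cell-cycle phase
durations, for immunologists quantifying lymphocyte turnover (thymocyte
differentiation stages, naïve/effector splenocytes, Tregs, …) and for
anyone analysing comparable labelling designs.

## Model

Cells occupy six compartments — G0/G1, S and G2/M, each unlabelled
(G, S, M) or labelled (G′, S′, M′) — coupled by linear ODEs:

```
dG/dt  = 2 a_M M + 2 α a_M′ M′ − (a_G + d_G) G
dS/dt  = a_G G − (a_S + d_S) S − [0, β] S
dM/dt  = a_S S − (a_M + d_M) M
dG′/dt = 2 (1 − α) a_M′ M′ − (a_G′ + d_G′) G′
dS′/dt = a_G′ G′ − (a_S′ + d_S′) S′ + [0, β] S
dM′/dt = a_S′ S′ − (a_M′ + d_M′) M′
```

`a_X` are phase-exit rates, `d_X` population-exit rates (death,
differentiation, migration), `β` the labelling rate during pulses and `α`
the label-shedding proportion at division.  The standard hypotheses —
kinetically neutral labelling, instantaneous uptake (β = ∞, implemented as
a discrete S → S′ transfer at each pulse start), no shedding (α = 0),
steady state (which forces d_G = a_G), no exit during S or G2/M, and a
fixed 6.5-h S phase — reduce the system to two free parameters (a_G, a_M).
The steady-state phase occupancy is closed-form, the proliferation rate is

```
p = 200 a_M a_G / (2 a_M + 13 a_M a_G + 2 a_G)    [% of cells dividing per hour]
```

and phase durations are reciprocal rates (G0/G1 = 1/a_G, G2/M = 1/a_M),
with inter-mitotic time 100/p.  Fitting minimises the Euclidean distance
between the observed triplet and the triplet simulated through the
labelling protocol (RK4, dt = 0.01 h) over a log-spaced (a_G, a_M) grid,
then polishes with Nelder–Mead.  Confidence intervals come from the
Hessian of a multinomially weighted least-squares objective at the
optimum (Wald intervals; delta method for p).

The package also ships a synthetic flow-cytometry generator — per-group
kinetic "signatures" spanning the observed 1–45 %/day range, multinomial
counting noise, event-level DNA × EdU draws with sub-G0/G1 apoptotic and
>4N engulfed dead-cell populations — and the gating that converts events
back into triplets, so the whole pipeline is testable end to end without
instrument data.

## Worked example

```python
from edupulse import DotPlotModel

# gated percentages at sacrifice: %G0/G1 unlabelled, %G2/M unlabelled, %EdU+
res = DotPlotModel((79.37, 2.26, 18.37), n_events=20_000).fit()
print(res.summary())
```

```
EdU pulse-chase dot-plot fit
==============================================
target (%G, %M, %EdU+)   : (79.37, 2.26, 18.37)
a_G (entry into S, /h)   : 0.0100015
a_M (entry into div, /h) : 0.250389
Euclidean distance (%)   : 5.187e-10
proliferation rate       : 21.724 %/day (0.9052 %/h)
G0/G1 duration           : 99.98 h
S duration (fixed)       : 6.50 h
G2/M duration            : 3.99 h
inter-mitotic time       : 4.60 days
95% CI p (%/day)         : (21.075, 22.373), SE = 0.331
flags                    : none
```

A population showing 18.4% EdU⁺ cells after the default 16.5-h
pulse-chase-pulse design divides at ~22 %/day: cells spend ~100 h in
G0/G1 and ~4 h in G2/M, dividing about every 4.6 days on average.  The
fit distance (≪ 0.05) says the model reproduces the observed triplet
essentially exactly; the CI reflects counting noise at 20,000 gated
events.

The command line mirrors the library
(`edupulse simulate|generate|gate|fit|regress|baron|pipeline`), e.g.:

```bash
edupulse fit --in triplets.csv --out fits.csv
edupulse pipeline --seed 1 --out-dir results/
```

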