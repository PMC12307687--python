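# strucbif

Topology-based bifurcation analysis of chemical reaction networks.

Given only the wiring of a reaction network — species, integer
stoichiometries, and signed regulation arrows — `strucbif` determines where
equilibrium bifurcations can occur, which parameters can induce them, and
which chemicals exhibit them.  A numeric ODE layer verifies the predictions,
including for networks with conserved quantities (where the standard Jacobian
determinant vanishes identically and is uninformative).

## How it works

1. **Augmented matrix** `A = [[dr/dx, C], [D^T, 0]]` — one row per reaction
   plus one per conserved quantity, one column per chemical plus one per flux
   loop.  The rate-derivative entries are abstract symbols whose signs follow
   from the topology (positive for reactants, annotated signs for
   regulators).
2. **Finest block-triangularization** of `A` (maximum bipartite matching +
   strongly connected components) splits the network into *determinant
   structures*; the off-diagonal pattern yields an acyclic *influence graph*.
3. **Buffering structures** — output-complete, index-zero subnetworks — are
   the descendant-closed unions of determinant structures; perturbations
   inside one never propagate outside.
4. Each block's **symbolic determinant** is classified (always positive /
   always negative / can change sign); sign-indefinite blocks carry the
   bifurcation conditions, their influence ancestors the inducing parameters,
   and their minimal enclosing buffering structure the bifurcating chemicals.
5. The numeric layer connects `A` to the modified Jacobian
   `J_g = V^+ J_f V` in reduced coordinates via the exact identity
   `det A = det(D^T D) det(C^T C) / det(Lambda) * det J_g`, giving a
   one-sided stability criterion
   (`sign(det Lambda * det A) != (-1)^(M-L)` ⟹ not stable) and full
   bifurcation-diagram sweeps with branch tracking and threshold bisection.

## CLI

```bash
# kinetics-free six-step analysis -> report.json / report.md / influence.dot
strucbif fixtures export macrophage_socs3d --out-dir work
strucbif analyze work/macrophage_socs3d.json --bases work/macrophage_socs3d.bases.json --out-dir work/out

# numeric sweep of a conserved quantity -> diagram.csv / diagram.json
strucbif simulate work/macrophage_socs3d.json work/macrophage_socs3d.sigmoid.kinetics.json \
    --parameter eta:eta1 --range 6.0 8.5 --eta 8,8,8,8 --bases work/macrophage_socs3d.bases.json \
    --out-dir work/out --plot

# determinant-identity verification on random states
strucbif verify work/macrophage_socs3d.json work/macrophage_socs3d.sigmoid.kinetics.json \
    --bases work/macrophage_socs3d.bases.json --samples 100
```

Networks are plain JSON (`species`, `reactions` with
`reactants`/`products`/`regulators`, `metadata`); a TSV edge-list reader and
an optional SBML importer (needs `python-libsbml`) are also provided.

## Bundled fixtures

`example1` (2 species, a buffering structure confining all bifurcations to
one chemical; pitchfork / transcritical / saddle-node kinetic presets),
`conserved_example` (5 species, one conserved moiety, two loops),
and `macrophage_wt` / `macrophage_socs3d` / `macrophage_socs3d_klf4d`
(an 8-species M1/M2 polarization signalling network and its knockouts).
The macrophage kinetic preset is a qualitative reconstruction calibrated for
bistability over `eta1 ∈ [6, 8.5]` with the M1-like branch terminating at a
fold; it is not a published parameter fit.

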