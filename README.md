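# dimerlink

Dynamical residue-network allostery analysis and dimer-interface
engineering toolkit for homodimeric lectins (and other tightly coupled
homodimers).

## The problem

Prototype galectins such as galectin-7 work as back-to-back homodimers in
which the two glycan-binding sites sit on opposite protomers, ~50 Å apart,
yet communicate: ligand binding on one side changes dynamics on the other.
Engineering the dimer interface (for example the G16C disulfide bridge or
the destabilizing G16S substitution at the galectin-7 protomer interface)
modulates that communication and with it the protein's pro-apoptotic
activity. Characterizing such designs requires a consistent dry-lab stack:
contact-network analysis of conformational ensembles, interface and
surface-area comparison of crystal structures, screening of predicted
mutation energetics, and fitting of the standard biophysical readouts.
`dimerlink` implements that stack as a tested, scriptable library with
seeded synthetic-data generators, so every stage can be validated against
planted ground truth without touching cluster-scale simulation data.

## The model

**Contact network.** Each residue is a node at the per-frame mass-weighted
center of its heavy atoms. Residues i, j are connected when any pair of
their heavy atoms stays within 4.5 Å in ≥ 75% of the frames. The edge
weight is the relative fluctuation of the inter-node distance series
r_ij(t),

    C_ij = ⟨(r_ij − ⟨r_ij⟩)²⟩ / ⟨r_ij⟩

(a sd/mean variant is selectable). Mechanically stable contacts carry low
weight, so the allosteric pathway between two sites is the minimum-weight
(Dijkstra) path, and edge importance is weighted edge betweenness
(Brandes); "critical" edges exceed the betweenness distribution mean by 3σ.

**Structure comparison.** Kabsch Cα superposition with optional iterative
outlier rejection (the protocol molecular-graphics aligners report),
Shrake–Rupley SASA on a deterministic golden-spiral point set expressed in
a molecule-fixed frame (exactly rotation-equivariant), interface residues
as those losing > 10 percentage points of relative accessibility upon
dimerization, buried surface area, and distance-criterion polar contacts.

**Mutation screen.** Point mutations from ΔΔG prediction tables survive
when they lie on the interface, destabilize the dimer fold more than the
monomer fold by ≥ 2 kcal/mol, avoid Gly/Pro/Cys, preserve net charge at
pH 7, and weaken binding by ΔΔG_B ≥ 4 kcal/mol; survivors rank by ΔΔG_B.

**Measurement models.** PFG-NMR diffusion decay
I(g) = I(0)·exp[−D(γgδ)²(Δ − δ/3 − τ/2)], four-parameter logistic EC50
with profile-likelihood CI95 and extra-sum-of-squares F-test curve
comparison, Savitzky–Golay-derivative melting midpoints, and a mass-action
monomer–dimer exchange model for dissociation constants.

## Worked example

Generate a synthetic dimer ensemble with a planted low-fluctuation path
crossing the interface, build the network, and recover the path:

```python
from dimerlink import synthgen, network, biophys

spec = synthgen.PlantedEnsembleSpec(seed=1, n_frames=2000)
ens, truth = synthgen.make_planted_ensemble(spec)
net = network.build_network(ens)
network.edge_betweenness(net)
path = network.shortest_path(net, "A:6", "B:6")
print(" -> ".join(path.labels))
print(f"path weight {path.path_weight:.3f} (planted {truth.expected_weight:.3f})")
```

prints

```
A:6 -> A:8 -> A:10 -> A:12 -> A:14 -> B:14 -> B:12 -> B:10 -> B:8 -> B:6
path weight 0.014 (planted 0.014)
```

— the recovered minimum-weight route runs along chain A, crosses the
interface at the planted column 14, and returns along chain B; its summed
C_ij weight matches the first-order expectation from the planted
fluctuation amplitudes. Fitting a noisy synthetic diffusion decay on the
standard 40-point gradient grid:

```python
series, _ = synthgen.make_curves("decay", truth={"D": 1.0e-10}, noise=0.01, seed=1)
fit = biophys.fit_diffusion(synthgen.to_decay_experiment(series))
print(fit.params["D"])   # 1.004e-10 m²/s, SE 2.8e-13
```

recovers the planted diffusion coefficient to 0.4% at 1% intensity noise.

The same operations are available from the shell:

```sh
dimerlink simulate planted --seed 1 --out sim/
dimerlink network --traj sim/frames.pdb --top sim/topology.pdb --source A:6 --target B:6
dimerlink fit diffusion --data decay.tsv
```

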