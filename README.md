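# filosim

Individual-based, force-based simulation of filopodia-driven cell invasion
into three-dimensional extracellular-matrix (ECM) fiber networks.

Cells invading a collagen gel probe it with filopodia: thin protrusions
that grow along chemotactic gradients, grab fibers through short-lived
focal complexes, and contract by myosin activity to pull the cell body
forward — unless the bond cluster fails first.  Whether a filopodium loads
up or cycles through "load-and-fail" depends on the local stiffness, pore
size and proteolytic degradation of the network.  `filosim` models this
machinery explicitly, for researchers in cell mechanobiology who want a
tested, scriptable sandbox for filopodium–ECM mechanics:

* **ECM networks** — procedurally generated cross-linked fiber graphs with
  controlled pore size (0.5/1.0/1.5 μm presets) and fiber diameter
  (28/34/41 nm), fiber energy
  H = κ_s/2 Σ (L−L0)²/L0 + κ_b/2 Σ (θ−θ0)²/L0 with κ_s = E_f·π r² and
  κ_b = E_f·π r⁴/4, exact virtual-work nodal forces, and integrity-driven
  crosslink detachment N_uf = round((1−I)·N_0f);
* **filopodia** — a seven-state phase machine (outgrowing, tugging,
  contractile, retractile, …) over eight acto-myosin compartments obeying
  the force–velocity law v_m = v_m0 (F_stall − F)/(F_stall + c_m F), with
  stochastic focal-complex kinetics: binding p = 1−e^(−k_on Δt) against a
  300-ligand pool per fiber node and Bell slip-bond rupture
  k_off = k_off0·e^(κ_LR(L_b−λ)x_b/k_BT);
* **cell body** — triple 549-node membranes (cell / transduce / nucleus)
  with cortical Kelvin–Voigt coupling, focal adhesions, contractile stress
  fibers and a 300 pN lamellipodium force;
* **biochemistry** — finite-volume reaction–diffusion of VEGF, MMP-2,
  TIMP-2, MT1-MMP, their ternary complex, free ligand and the ECM field,
  driving chemotaxis and matrix degradation;
* **engine** — adaptive overdamped integration of all of it with exact
  action–reaction couplings, geometric contact handling and deterministic
  seeded replicates.

See `docs/methods.md` for the full model description and numerical choices.

## A worked example

```bash
python examples/build_and_stretch_network.py
```

builds a 6 μm box of 1 μm-pore collagen (34 nm fibers, E_f = 1 MPa),
stretches it quasi-statically and fits the bulk modulus over strain
0.2–0.7.  Typical output:

```
nodes: 5344, segments: 5678, fibers: 912
mean crosslink spacing: 0.89 um (target 1.0 um)
stretch modulus kappa_s = 908 pN, bend modulus kappa_b = 6.56e-02 pN um^2
strain  stress_Pa
 0.00       0.00
 0.05       9.13
 0.10      26.92
 0.20      88.22
 ...
 0.70     525.49
 0.75     575.09
fitted bulk modulus (strain 0.2-0.7): 878.5 Pa
```

The slope is the network-level stiffness; sweeping fiber diameter
28→34→41 nm or E_f 0.25→1 MPa raises it monotonically (the in-silico
rheology study in `filosim.studies.run_rheology_study`).

Other narrative examples:

* `examples/single_filopodium_regimes.py` — one filopodium against a rigid
  vs softly-tethered fiber: sustained ~nN contractile tension vs repeated
  load-and-fail cycles;
* `examples/reaction_diffusion_demo.py` — MMP-2 activation around a
  secreting filopodium root and the resulting ECM integrity loss;
* `examples/invasion_small.py` — quick single-replicate invasion runs
  across the three pore presets.

The full study conditions (N = 5 seeds per preset, 10 simulated minutes,
15×5×5 μm domains) live in `filosim.studies`.

## Command line

```bash
filosim build-network --pore-size 1.0 --fiber-diameter 34 --domain 10 10 10 \
    --seed 7 --out net.json
filosim stretch-test --network net.json --out curve.csv
filosim simulate --preset pore1.5 --replicates 5 --seed 1 --out results/
```

`simulate` writes per-replicate event logs (time, phase, length, bond
count, tip tension), a JSON summary with mean ± SEM tip/root speeds, and a
manifest with the configuration hash and seed.

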