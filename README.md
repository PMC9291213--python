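# dynhb — dynamic hydrogen-bond potentials and molecular interaction fields

Classical molecular-interaction-field (MIF) force fields of the GRID lineage
describe how a target molecule interacts with a chemical probe (an amide NH
donor, a carbonyl O acceptor, ...) on a 3D lattice. Their hydrogen-bond term
is parametrized per *atom type*: every pyridine-type nitrogen gets the same
fixed well depth Emin, no matter what substituents decorate the ring. `dynhb`
implements a *dynamic* parametrization for computational and medicinal
chemists: the well depth of each individual atom (dEmin) is derived from the
electrostatic potential (EP) at its nucleus, and a latent-variable regression
on atom-environment fingerprints makes that parameter predictable for new
molecules without any quantum-mechanical calculation.

## The model

The probe–target energy at each grid point is

```
E = Σ E_LJ + Σ E_EL + Σ E_HB ,          E_HB = Er · Et · Ep
```

with a 12-6 Lennard-Jones term, a Coulomb term with distance-dependent
dielectric ε(r) = 4r, and a hydrogen-bond term factored into a radial part
and two angular parts. The radial part uses the 6-4 form

```
Er(r) = Emin · [ 3 (Rmin/r)⁴ − 2 (Rmin/r)⁶ ]
```

whose minimum is exactly (Rmin, Emin); Et = cos²t falls off with the angle at
the target and Ep = 1 (probe at its optimal orientation). Repulsive clashes
are capped at +5 kcal/mol.

The dynamic well depth replaces the static Emin with an affine function of
the atom's nucleus-centred EP (atomic units), fitted per (atom type, role):

```
acceptors:  dEmin =  m · EP + q          donors:  dEmin = −m · EP − q     (m > 0)
```

Slopes and intercepts are calibrated so the training EP window (1st–99th
percentile) maps onto the band [Emin·(1+δ), Emin·(1−δ)] around the static
value (δ = 0.5 by default), keeping every emitted dEmin inside a
force-field-acceptable range, with the window midpoint anchored at the static
Emin. dEmin is then regressed on tree-structured count fingerprints (counts
of atom categories at topological distances 1..10 from the root atom) with a
natively implemented NIPALS partial-least-squares (PLS), validated by
random-groups cross-validation (5 groups, 20 partitionings) and summarised by
R², Q², SDEC and SDEP. The same EP→energy transform extended to non-HB heavy
atoms gives a per-atom reactivity descriptor (GRID charge, GC) used to rank
aromatic CH carbons for electrophilic substitution.

The package ships a transcription of the published statistics of the 22
per-atom-type PLS models, a static Emin/Rmin parameter table (only the
aromatic-nitrogen −5.5 and secondary-amine −4.0 kcal/mol values are public;
the rest are labelled placeholders in an override-able CSV), probe and
Lennard-Jones tables, and a synthetic-data module that generates every
fixture the test-suite needs, including molecules with hand-authored charges
whose EP orderings hold by construction.

## Worked example

Substituent effects on the pyridine nitrogen, end to end: surrogate EP from
point charges, EP→dEmin calibration for the aromatic-nitrogen type, and the
donor-probe ("N1") interaction field with its −4 kcal/mol isovolume.

```python
from dynhb import (gen_fixture_molecules, surrogate_ep, assign_atom_types,
                   fit_linear_map, apply_linear_map, static_emin,
                   compute_mif, build_grid, isovolume, load_probes, MapStore)

mols, charges = gen_fixture_molecules(seed=7)
byname = {m.name: m for m in mols}
series = ["nitropyridine", "pyridine", "aminopyridine"]

ring_ep = {}
for name in series:
    typing = assign_atom_types(byname[name])
    eps = {r.atom_index: r.ep for r in surrogate_ep(byname[name], charges[name])}
    n_idx = next(a.atom_index for a in typing if a.at_code == "N:=")
    ring_ep[name] = eps[n_idx]

lm = fit_linear_map(list(ring_ep.values()), "N:=", "acceptor", static_emin("N:="))
probe = load_probes()["N1"]
print(f"{'molecule':<16}{'EP (a.u.)':>10}{'dEmin (kcal/mol)':>18}{'V(-4) (A^3)':>13}")
for name in series:
    mol = byname[name]
    grid = compute_mif(mol, assign_atom_types(mol),
                       (MapStore([lm]), surrogate_ep(mol, charges[name])),
                       probe, build_grid(mol), charges=charges[name])
    _, vol = isovolume(grid, -4.0)
    print(f"{name:<16}{ring_ep[name]:>10.4f}"
          f"{apply_linear_map(lm, ring_ep[name]):>18.2f}{vol:>13.2f}")
```

prints

```
molecule         EP (a.u.)  dEmin (kcal/mol)  V(-4) (A^3)
nitropyridine       0.0551             -2.75         0.00
pyridine           -0.0172             -7.56        19.50
aminopyridine      -0.0276             -8.25        28.50
```

The electron-withdrawing nitro group raises the ring-nitrogen EP, shallowing
its hydrogen-bond well until the −4 kcal/mol isovolume vanishes; the
electron-donating amino group deepens it and grows the donor-probe field —
the ordering a chemist expects.

A command-line interface mirrors the library (`dynhb type | ep | fingerprint
| calibrate | train | predict | mif | sites | validate | synth`); e.g.
`dynhb validate` prints the packaged model-table aggregates.

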