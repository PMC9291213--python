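# Methods

This note documents the models implemented in `dynhb`, the choices made where
the underlying physics or published description left the design open, and
what the synthetic test data does and does not establish.

## Scope and data flow

The pipeline derives a per-atom hydrogen-bond well depth (dEmin, kcal/mol)
from the electrostatic potential (EP) at the atom's nucleus, learns to
predict dEmin from topological atom-environment fingerprints, and consumes
the result in a GRID-style interaction-field engine:

1. **Atom typing** (`core_chem`) — every atom is assigned one hydrogen-bond
   atom-type code (e.g. `N:=` aromatic nitrogen, `OH` phenolic hydroxyl) with
   its donor/acceptor roles.
2. **EP** (`electrostatics`) — from an external table of QM values, or from a
   point-charge surrogate.
3. **Calibration** (`calibration`) — per (atom type, role) affine EP→dEmin
   maps.
4. **Regression** (`pls_engine`) — PLS from tree fingerprints to dEmin, so
   dEmin can be predicted without any EP calculation.
5. **Consumption** (`mif_engine`, `gc_sites`) — interaction fields and
   isovolumes; reactivity ranking of aromatic carbons.

## Atom typing

The atom-type vocabulary covers the nitrogen and oxygen hydrogen-bonding
classes for which reference model statistics are packaged, plus `C_generic`,
`H_polar` and `other`. The defining rule of each code is a SMARTS pattern
transcribing its chemical description (hybridization, hydrogen count,
neighbour elements); patterns are evaluated in a fixed precedence order,
most specific first (nitro oxygen before generic terminal oxygen, ester
bridging oxygen before the ether codes), and the first match wins. The table
lives in `data/atom_type_patterns.csv` and is deliberately editable — the
rules are this package's reconstruction, not a published specification.
Known coarse spots: `N::` ("sp2 nitrogen with two lone pairs and one double
bond") is interpreted as terminal doubly-bonded or anionic sp2 nitrogen;
pyrrole-type NH falls to `other` (no packaged model class exists for it);
tautomer and protonation states are taken as given in the input. The `OES`
ester oxygen is described in its source as "not accepting H-bonds" yet is
modelled as an acceptor slot; the packaged table follows the acceptor
assignment and this contradiction is noted here rather than resolved.

Structure input is SDF (V2000, 3D, explicit hydrogens) or SMILES; SMILES
inputs are embedded to a single 3D conformer (ETKDGv3, fixed seed). The
embedding stands in for a proper geometry optimisation: typing and
fingerprints are purely topological, so only the interaction fields and the
surrogate EP feel the geometry, and only weakly for rigid aromatics.

## Electrostatic potentials

EP values are stored in atomic units (hartree per unit charge; 1 a.u. =
627.509 kcal/mol·e). The surrogate evaluates the discrete point-charge
analogue of the molecular EP at each nucleus,
`ep(a) = Σ_{b≠a} q_b / |R_b − R_a|` (distances in bohr), excluding the atom's
own site to avoid the singularity — matching the convention of
nucleus-centred QM extractions. The surrogate is linear in the charges and
exactly translation/rotation invariant. It is **not** a stand-in of DFT
quality: point charges have no penetration or polarisation terms, so only
orderings and trends, never absolute values, should be read from it. All
downstream code consumes EP records agnostically; a real QM table can be
dropped in via `load_ep_table`.

## EP → dEmin calibration

For each (atom type, role) the affine map is fitted from the training EP
distribution: the window between the 1st and 99th EP percentiles is mapped
onto the energy band `[Emin·(1+δ), Emin·(1−δ)]` around the static well depth,
with δ = 0.5 by default. Orientation follows the role: for acceptors a more
negative EP (electron-rich site) gives a deeper well, for donors a more
positive EP does. Consequences used as test anchors: the window midpoint maps
exactly to the static Emin; δ → 0 recovers the static force field; the
conventional slope m is positive for both roles while the intercept's sign
depends on the window (the published convention writes acceptor maps as
`m·EP + q` and donor maps as `−m·EP − q`). EP values outside the fitted
window are **clamped** to its edges rather than extrapolated — whether the
original software clamps is unknown; clamping was chosen because it keeps
every emitted dEmin inside the force-field band by construction.

The published slope/intercept coefficients themselves are in supplementary
tables that are not packaged; the calibration rule above reproduces their
stated constraints (signs, range containment, static anchor) rather than
their numeric values. Only two static Emin values are public: −5.5 kcal/mol
for `N:=` and −4.0 for `N1:`. All other codes carry placeholder defaults in
`data/static_params.csv`, marked as such in a provenance column and
overridable through a user CSV of the same dialect (the packaged registry is
never mutated). Rmin values are likewise not published; the packaged defaults
are 1.6 Å for nitrogen codes and 1.5 Å for oxygen codes (target-side
contribution).

## Tree-structured fingerprints

Each atom's environment is a count vector over shells k = 1..10 (topological
bond distance) × 13 atom categories (C/N/O split by aromaticity, S, P, pooled
halogens, H, positively/negatively charged heavy atoms, overflow). Counts are
used instead of bits because the downstream linear model benefits from
magnitude information. The root atom is excluded from its own fingerprint —
its identity is already fixed by the per-atom-type model it feeds. Two atoms
with isomorphic depth-10 neighbourhoods therefore receive identical vectors,
and the vector sums to (atom count − 1) whenever the graph diameter is within
the depth. The category vocabulary is versioned and configurable
(`FingerprintSchema`).

## PLS regression and validation

The regression core is a native NIPALS implementation (`TreePLSRegressor`,
scikit-learn estimator conventions). X and y are mean-centred; unit-variance
scaling is off by default because count features share a natural scale, and
can be switched on. Component extraction deflates X and stops early if the
residual X carries no covariance with y; after extraction the model is
collapsed to an affine predictor (coefficients + intercept), which makes
prediction exactly reproducible and serialisation binary-free (JSON + CSV).
Correctness anchors: at full rank the predictions coincide with ordinary
least squares (checked against explicit normal equations), and at any LV
count they match scikit-learn's PLSRegression to numerical precision — the
sklearn implementation is used only as a cross-check, never as the engine.
One algebraic note: duplicating a feature column changes intermediate-LV
NIPALS scores (the duplicated entry doubles its weight in w ∝ X'y) and only
the full-rank fit is invariant; the tests assert the invariant where it
actually holds.

Cross-validation follows the random-groups protocol: rows are randomly
partitioned into 5 near-equal groups, each group predicted by a model trained
on the rest, repeated over 20 independent partitionings. Q² = 1 − PRESS/TSS
with PRESS pooled over all folds of all partitionings (equivalently, divided
by n_partitionings·TSS); TSS is about the full-data mean. Pooling PRESS
rather than averaging per-partition Q² values was an open choice; pooled
PRESS weighs every held-out residual equally. All CV randomness flows from a
single seed (`CVConfig`). Latent-variable count is selected by maximising Q²
over 1..max_lv (default cap 15; the packaged reference models use 4–12),
with ties broken toward fewer components. Metrics follow chemometrics
conventions: R² and SDEC (root-mean-square residual) on the training fit,
SDEP on an external set, Q² from CV. `train_at_models` trains one model per
(atom type, role) group, skipping groups under a minimum size (default 50
atoms).

## Interaction fields

Grids are axis-aligned boxes: molecular bounding box plus padding (default
4 Å) at spacing 0.5 Å (defaults chosen as the common working resolution for
small-molecule fields). The probe interacts with every atom through:

* **E_LJ** — 12-6 Lennard-Jones with per-element parameters from an editable
  packaged table (Lorentz-Berthelot combination with the probe's parameters).
  The table is an approximation authored for this package, not a published
  parametrization.
* **E_EL** — Coulomb with distance-dependent dielectric ε(r) = 4r, a standard
  implicit-screening choice; active only when partial charges are supplied.
* **E_HB** — `Er·Et·Ep` between the probe and target atoms of the
  complementary role only. `Er` is the 6-4 well (minimum exactly at
  (Rmin, Emin), equivalently `(A/r⁶ − B/r⁴)` with `A = −2·Emin·Rmin⁶`,
  `B = −3·Emin·Rmin⁴`); the 6-4 form is the classical hydrogen-bond radial
  choice of the GRID family. The combined optimum distance is the sum of
  target and probe Rmin contributions (the "half-distance" convention read
  additively). `Et = max(0, cos t)²` with t measured at the target between
  the ideal hydrogen-bond direction and the target→probe vector; `Ep = 1`
  (the probe is taken at its optimal orientation, no orientational
  sampling). Ideal directions: donor targets use each heavy-atom→H bond axis
  (best direction wins per grid point); acceptor targets use the negated,
  normalised sum of covalent bond vectors as a lone-pair proxy.

Well depths come from one of three sources: the static registry, an explicit
per-atom dEmin mapping, or the dynamic path (linear maps + EP records). An
atom whose dynamic value cannot be resolved falls back to its static Emin
with a logged warning. When every dEmin equals the static value, the dynamic
field is bitwise identical to the static one.

Numerical handling: distances are floored at 0.05 Å so grid points falling on
nuclei stay finite; pairwise Lennard-Jones contributions are bounded
internally so the clash cap stays numerically exact; the total energy is
capped at +5 kcal/mol with the excess absorbed into the LJ component, keeping
`total = E_LJ + E_EL + E_HB` an exact identity at every point. An isovolume
at threshold T is the count of points with E ≤ T times spacing³. Fields
export to Gaussian cube (bohr, z-fastest data order); a reader is included
and round-trip tested.

## GRID charges and site ranking

Hydrogen-bonding atoms keep their calibrated dEmin as the descriptor (single
source of truth). Other heavy atoms pass through a generic map fitted with
the same window rule under a generic code (placeholder static anchor
−3.0 kcal/mol), so all values share one kcal/mol-derived scale. Eligibility
for electrophilic-site ranking is restricted to aromatic carbons bearing at
least one hydrogen — the relevant late-stage functionalization reactions are
(het)aromatic C–H substitutions — ordered most electron-rich (most negative
GC) first, ties broken toward the lower atom index. Per-ring mean GC supports
the electron-rich versus electron-poor ring call for radical additions.
Steric control (e.g. iridium-catalysed borylation) is out of scope: the
descriptor is electronic only. One practical caveat encoded in the tests:
the generic map must be calibrated on a *population* of EPs; fitting it on a
single highly symmetric molecule amplifies embedding noise across the whole
energy band.

## Synthetic data: what it emulates and what it does not

`gen_fixture_molecules` provides pyridine, its para-nitro and para-amino
derivatives, phenol, furan, benzene, a phenyl-pyridine biaryl and
N-methylacetamide, with hand-authored partial charges (heavy atoms and
hydrogens authored together in SMILES atom order; any residual against the
formal charge is spread equally so charge conservation is exact). The charges
are constructed — not derived from any charge model — so that three
qualitative orderings hold by construction and remain stable across
dependency versions: ring-nitrogen EP nitro > unsubstituted > amino (less to
more negative), pyridine ortho/para carbons less electron-rich than benzene
carbons, and the biaryl's phenyl ring electron-rich relative to its pyridine
ring. These fixtures validate machinery and qualitative chemistry; they say
nothing about quantitative accuracy against quantum-mechanical EPs.

`gen_synthetic_training` draws sparse non-negative counts with per-shell
decaying Poisson rates (near shells dense, common organic categories more
abundant) and y = X·w + Gaussian noise; it supports exact parameter-recovery
statements (with σ = 0.3 kcal/mol and 2000/500 train/external rows the
external SDEP is expected in [0.25, 0.37], the sampling bracket of an RMSE at
n = 500 around the noise floor). `gen_scale_benchmark` emulates a single-site
hydrogen-bond basicity benchmark: dEmin drawn uniformly over the
[−8.25, −2.75] force-field band, experimental value = slope·dEmin + noise,
with the noise SD set analytically (σ = |slope|·sd·√(1/r²−1)) so the
population correlation is −0.85 at the benchmark size of 279. Passing these
tests demonstrates the estimators and the protocol, not performance on real
laboratory scales.

Problem sizes throughout the suite (≤ 2000 training rows, ≤ 0.5 Å grids on
single-ring molecules, 5 seeds per stochastic check) were chosen as the
smallest sizes at which the statistical brackets above are stable.

## Known limitations

* The packaged atom-typing rules and LJ/probe/static-parameter tables are
  reconstructions; real GRID parameters and the published per-type
  slope/intercepts are not redistributable here.
* Training-set-scale statistics of the packaged 22-model reference table are
  shipped as data, not reproduced by retraining (that would need the original
  ~66k-molecule DFT dataset).
* The point-charge EP surrogate supports trends only; no quantum chemistry is
  performed.
* Single conformer, no conformational ensembles; no entropic field term (it
  is fixed to zero); no probe orientational sampling; protein-scale targets
  are out of scope.
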