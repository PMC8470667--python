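# cypflex

Salt-bridge and structural-flexibility analysis of protein
conformational ensembles, built around the kind of question the CYP450
superfamily poses: enzymes with nearly identical folds span the range
from strict substrate *specialists* (bacterial CYP101, camphor) to broad
*generalists* (human CYP2C9, a large share of drug metabolism).  A
mechanism repeatedly observed in that family is that the **density of
salt bridges** — the number of Asp/Glu–Lys/Arg/His ion pairs per 100
residues — rigidifies the fold, damps the F–G lid over the catalytic
pocket and the B′-helix ligand gate, and thereby narrows the range of
substrates the enzyme can accept.

`cypflex` turns that analysis into a reusable, tested pipeline for
anyone with conformational ensembles (multi-model PDB natively; DCD/XTC
through adapters):

* **Salt bridges** — a bridge exists between a carboxylate oxygen
  (Asp OD1/OD2, Glu OE1/OE2) and a basic nitrogen (Lys NZ, Arg
  NE/NH1/NH2, His ND1/NE2) when the minimum O–N distance is within a
  cutoff (default 3.2 Å).  Per pair the package reports the *lifetime*
  s (fraction of frames formed), the category — short (s < 2%), medium
  (2% ≤ s ≤ 20%), long (s > 20%) — and per-protein densities, both
  distinct-pair and instantaneous per-frame.
* **Flexibility** — least-squares (Kabsch) removal of global motion,
  per-residue RMSF with secondary-structure aggregation,
  time-origin-averaged MSD curves MSD(τ) = ⟨|r(t+τ) − r(t)|²⟩, and
  ligand-gate distance series (e.g. the F/G-loop Ser to B′-helix Pro
  Cα–Cα distance) with sample-s.d. fluctuations.
* **Pocket volume** — a POVME-style grid method: lattice points inside
  user-defined inclusion spheres are deleted within vdW + padding of
  any atom, optionally restricted to the contiguous component holding a
  seed point; volume = surviving points × spacing³.
* **Neutron MSD** — elastic incoherent scans S(q, Δt) are converted to
  mean-squared displacements by the quartic-corrected Gaussian fit
  ln I(q) = a − (MSD/6) q² + c q⁴ over a configurable q window
  (default 0.25–1.75 Å⁻¹).
* **Family correlation** — per-protein descriptor summaries and the
  cross-family Pearson correlation of salt-bridge density with mean
  RMSF, pocket-volume fluctuation and gate fluctuation, grouped by
  biological category (Fungi/Archaea/Bacteria/Protista/Animalia/Plantae).
* **Synthetic data** — generators with exact ground truth (Bernoulli
  bridge occupancy, Gaussian per-residue fluctuation of known σ,
  linearly density-coupled families, model elastic scans) so that every
  stage is verifiable without cluster-scale simulations.

## Worked example

A 100-residue toy chain with two programmed bridges (occupancies 0.40
and 0.95) and per-axis Gaussian fluctuation σ = 0.3 Å:

```python
import cypflex as cf

spec = cf.ToyProteinSpec(
    n_residues=100,
    placements=((1, "ASP"), (2, "LYS"), (9, "GLU"), (10, "ARG")),
    bridges=(cf.BridgeSpec(1, 2, 0.40), cf.BridgeSpec(9, 10, 0.95)),
    sigma=0.3, seed=42,
)
structure, traj, realized = cf.make_toy_trajectory(spec, n_frames=2000, dt=10.0)

summary = cf.compute_records(traj)
for rec in summary.records:
    print(f"{rec.label():<14} lifetime {100*rec.lifetime:5.2f}%  "
          f"({rec.lifetime_ns:.2f} ns)  {rec.category()}")
print(f"distinct density: "
      f"{cf.density_distinct(summary.n_distinct, summary.n_residues):.1f}"
      " per 100 residues")

profile = cf.rmsf(cf.align_trajectory(traj))
print(f"mean RMSF: {profile.mean_rmsf:.3f} A")
```

prints

```
ASP1-LYS2      lifetime 41.40%  (8.28 ns)  long
GLU9-ARG10     lifetime 95.70%  (19.14 ns)  long
distinct density: 2.0 per 100 residues
mean RMSF: 0.514 A
```

The realized lifetimes sit at their programmed Bernoulli occupancies
(41.4% vs 0.40, 95.7% vs 0.95 — binomial noise over 2000 frames), both
above the 20% boundary and hence *long*-lived; two distinct pairs on
100 residues give a density of 2.0; and the mean RMSF recovers
σ√3 = 0.520 Å up to the small shrinkage from the rigid-body fit.

At family scale, the default synthetic family (146 proteins, densities
uniform on 2–8 per 100 residues, mean RMSF linearly and negatively
coupled to density with a programmed population correlation of −0.45):

```python
from cypflex.family import SummaryConfig, summarize_protein, correlate_family

data = cf.make_family(cf.SyntheticFamilySpec(seed=7))
cfg = SummaryConfig(window_ns=data.spec.window_ns)
summaries = [summarize_protein(p.trajectory, cfg, protein_id=p.protein_id,
                               category=p.category) for p in data.proteins]
results, grouped = correlate_family(summaries)
```

yields `density_vs_mean_rmsf: r = -0.471 (n = 146)` for this seed, with
the denser ("Bacteria") half of the family showing the lower mean RMSF
— the specialist/generalist contrast the descriptors are designed to
expose.

## Command line

Each stage is also a subcommand over a validated YAML config
(flags > config > defaults); every output directory receives TSV tables
plus a `provenance.json` recording the tool version, resolved config
and input digests.  Identical config + seed reproduce outputs
byte-for-byte.

```bash
cypflex synth --config family.yaml --seed 1     # write a synthetic family
cypflex summarize --config family.yaml          # per-protein descriptors
cypflex correlate --config family.yaml --plot   # family-wide Pearson r
cypflex saltbridges --config run.yaml --cutoff 3.2
cypflex flexibility --config run.yaml
cypflex pocket --config run.yaml
cypflex gate --config run.yaml
cypflex neutron-msd --config run.yaml scans.tsv
```

## Scope

The package consumes ensembles; it does not run MD, download PDB
entries, assign secondary structure, or classify CYP450 nomenclature.
SSE ranges, gate residues, pocket spheres and biological categories are
user-supplied configuration.
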