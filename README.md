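# epimap

Structural immunoinformatics of allergen isoform polymorphism, built around
plant profilins (the Ole e 2 / Bet v 2 / Hev b 8 / Ara t 8 pan-allergen
family). The package quantifies how micro-heterogeneity among isoforms
reshapes the antibody-visible surface of an allergen: which residues are
exposed, where discontinuous (conformational) B-cell epitopes sit, how
variable each alignment column and each epitope region is across isoforms,
and how linear B- and T-cell epitopes overlap the conformational ones.

It is a library first (`import epimap`), with short narrative scripts under
`examples/` and a thin `epimap` command-line wrapper for file-based use.

## What it computes

- **Solvent accessibility** — Shrake–Rupley per-atom SASA with a
  deterministic golden-spiral point set (probe 1.4 Å), summed per residue
  and normalised by the residue's Gly-X-Gly tripeptide standard-state area:
  `rel = 100 · A_res / A_GXG`. Exposure classes: buried < 20%,
  partially accessible ≥ 20%, surface ≥ 25%, protruding > 75%.
- **Conformational epitopes** — a three-rule structure-based prediction:
  (i) protruding residues (rel. SASA > 75%) seed epitopes and merge when
  closer than 0.5 nm; (ii) every partially accessible residue (> 20%)
  within 1 nm of any center joins (the radius of a typical
  antigen–antibody contact surface); (iii) single sequence gaps between
  members are filled.
- **Variability** — Wu–Kabat per-column variability `V = N·k/n`
  (N non-gap residues, k distinct, n count of the commonest), a
  median-normalised index with low/intermediate/high classes, and
  per-region variant enumeration with suffix labels (0 = template isoform)
  and frequencies.
- **Antigenicity** — Kyte–Doolittle, Welling and Parker sliding-window
  profiles and high-antigenicity region calling gated by accessibility.
- **Structure comparison** — Kabsch least-squares superposition and
  alignment-mapped Cα RMSD, cysteine Cα–Cα disulfide-feasibility screening
  (3.0–7.5 Å window), and formal-charge summaries (Asp/Glu −1, Lys/Arg +1).
- **Epitope overlap** — Hamming-best localisation of linear epitopes on a
  chain and total/partial/none overlap classification against
  conformational member sets.
- **Synthetic data** — seeded generators of globular structures with
  provable exposure/distance ground truth, and of alignments with exact
  planted variant frequencies, so every stage is testable without
  downloading structures.

## Worked example

```python
from epimap import (GlobuleSpec, SasaConfig, EpitopeParams,
                    make_globule, compute_exposures, predict_epitopes)

structure, truth = make_globule(
    GlobuleSpec(n_residues=60, protruding=(8, 25, 47), seed=42))
exposures = compute_exposures(structure, SasaConfig(n_points=480))
table = predict_epitopes(structure, exposures, EpitopeParams())
for row in table:
    print(row.epitope_id, [c.label for c in row.centers], row.n_residues)
```

Running `python examples/01_sasa_and_conformational_epitopes.py` prints:

```
planted protruding residues: [9, 26, 48]
detected protruding residues: [9, 26, 48]
epitope 1: center A9, 5 residues
epitope 2: center A26, 5 residues
epitope 3: center A48, 6 residues
```

The three residues displaced beyond the shell exceed the 75% protrusion
threshold and each seeds one epitope (they are farther apart than the
merge radius); the remaining members are the partially accessible shell
residues within 1 nm of each center. Similarly,
`examples/02_variability_and_region_variants.py` recovers planted region
variants exactly:

```
A1-0 (70.00%) QAYVDD
A1-1 (25.00%) QTYVDD
A1-2 (5.00%) QGYVDD
B1-0 (90.00%) PGHLAP
B1-1 (10.00%) PGSLAP
```

## Layout

- `src/epimap/structio.py` — PDB/alignment I/O, canonical in-memory types
- `src/epimap/sasa.py` — Shrake–Rupley engine, Gly-X-Gly normalisation
- `src/epimap/conf_epitope.py` — three-rule conformational epitope predictor
- `src/epimap/seqvar.py` — Wu–Kabat, region variants, anchor analysis
- `src/epimap/antigenicity.py` — scale profiles and region calling
- `src/epimap/structcomp.py` — superposition, cysteines, charges
- `src/epimap/overlap.py` — linear/conformational overlap classification
- `src/epimap/synthetic_data.py` — seeded ground-truth generators
- `src/epimap/reference.py`, `src/epimap/data/` — curated published inputs
- `docs/methods.md` — models, parameters, numerical choices, limitations
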