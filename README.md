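# whales3d

WHALES (Weighted Holistic Atom Localization and Entity Shape) 3D molecular
descriptors, with the similarity-screening and scaffold-hopping evaluation
stack built around them.

## The problem

Ligand-based virtual screening ranks a compound library by similarity to
known actives. Fragment-based representations (substructure fingerprints)
are excellent at finding close analogs — and for the same reason poor at
*scaffold hopping*, the retrieval of isofunctional compounds whose core
framework differs from the query's. `whales3d` is for medicinal and
computational chemists who want a holistic, "fuzzy" 3D representation that
abstracts away from the molecular graph: it encodes where atoms and partial
charges sit in space, not which fragments are present.

## The descriptor

For each heavy atom *j* of an energy-minimized conformer, a charge-weighted
covariance of the atom distribution is centred on *j*:

S_w(j) = Σᵢ |δᵢ| (xᵢ−xⱼ)(xᵢ−xⱼ)ᵀ / Σᵢ |δᵢ|

and the atom-centred Mahalanobis matrix collects the normalized squared
distances ACM(i,j) = (xᵢ−xⱼ)ᵀ S_w(j)⁻¹ (xᵢ−xⱼ). Per-atom **remoteness**
(ACM row average), **isolation degree** (column minimum) and their ratio —
negated for negatively charged atoms — are reduced to min, nine deciles and
max each, giving a 33-value vector independent of molecular size, atom
order and molecular orientation. Charge schemes: Gasteiger–Marsili, unit
("shape-only"), or externally supplied per-atom charges (e.g.
quantum-derived). Details and numerical conventions: `docs/methods.md`.

Screening ranks by Euclidean distance on Gaussian-normalized descriptors;
multi-query campaigns are fused by the sum of reciprocal ranks. Evaluation
utilities cover Murcko-scaffold diversity of retrieved actives (SD_A%),
enrichment factors, a leave-one-active-out retrospective benchmark and a
Best/Worst-augmented PCA for comparing descriptor sets.

## Worked example

```python
from whales3d import parse_and_sanitize, compute_whales

rec = parse_and_sanitize("CC(=O)Nc1ccc(O)cc1", "paracetamol")
vec = compute_whales(rec, scheme="gasteiger_marsili", seed=0)
for name, v in list(zip(vec.names, vec.values))[:6]:
    print(f"{name:8s} {v: .4f}")
```

prints

```
rem_min  -4.5618
rem_d1   -3.0580
rem_d2   -1.9277
rem_d3    1.1369
rem_d4    1.8147
rem_d5    1.9394
```

— the low remoteness deciles are negative because paracetamol's oxygens and
nitrogen carry negative partial charge, and their (sign-flipped) remoteness
values populate the lower tail of the distribution. The full vector has 33
named entries (`rem_*`, `is_*`, `ir_*`).

From the shell, a complete screening campaign against a synthetic fixture
library:

```sh
whales fixtures --out-dir fix --seed 0 --n-molecules 40 --n-families 4 \
    --n-targets 1 --actives-per-target 8
whales screen --library fix/library.smi --queries fix/library.smi \
    --out ranking.tsv --charges unit --seed 0
```

which logs the resolved configuration and the top fused hits
(`top hit m0024 rrf=6.4817 ...`) and writes `ranking.tsv` with one row per
library molecule: fused rank, molecule id, reciprocal-rank-sum score, and
the per-query ranks. `whales compute` writes the 33-column descriptor table
(with a `.rejects.tsv` sidecar naming any molecule that failed preparation
and why), and `whales benchmark` runs the leave-one-active-out benchmark
from a library and an activity table.

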