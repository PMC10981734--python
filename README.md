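# tautopo

Topological analysis and classification of tau filament structures.

Cryo-EM has resolved distinct tau filament folds for the major tauopathies
(Alzheimer's disease, PART, CTE, Pick's disease, CBD, AGD, PSP, GGT, GPT),
but comparing those folds by eye gives no quantitative measure of how much
— or in what way — they differ. `tautopo` measures filament shape with
tools from open-curve knot theory, treating each protein chain as the open
polygonal curve through its consecutive C-alpha atoms:

* the **Gauss linking integral**
  `Lk(l1,l2) = 1/(4π) ∮∮ ((γ̇1×γ̇2)·(γ1−γ2))/|γ1−γ2|³ dt ds`
  between two curves (repeats of one filament, backbone vs side-chain
  push-off, or stacked fibril rungs);
* the **writhe** `Wr` of one curve (the same integral of a curve with
  itself), whose sign reads out conformational handedness;
* the **second Vassiliev measure** `v2`, the sphere average over projection
  directions of half the sum over alternating interleaved crossing pairs of
  the product of crossing signs — an open-curve knottedness measure that
  detects *knotoid* structure (e.g. the two-crossing knotoid K2₁, whose
  diagram value is 0.5).

On top of these, the package builds repeat-pair linking sign tuples,
residue-resolved linking matrices rendered as *linking fingerprints*,
side-chain push-off ribbon analysis (`Tw = Lk − Wr`), stacked-filament
linking, and K-means classification of the global feature vectors
`(Wr/N, Lk_s/N, |v2|)`. A synthetic-structure generator (helices, closed
knots, knotoids, PDB-format fibrils with construction-known ground truth)
makes the full pipeline testable offline.

## Worked example

Analyze a synthetic three-rung fibril whose side chains wind exactly three
right-handed turns about the backbone:

```sh
tautopo make-fibril fibril.pdb --rungs 3 --turns 3
tautopo analyze fibril.pdb --projections 2000 --seed 1 --out run
```

which prints `analyzed 1/1 structures -> run*` and writes `run_global.csv`:

```
filament,N,Wr,Wr/N,Lk_s,Lk_s/N,v2,|v2|,v2_stderr,seed,n_projections
fibril:A,71,0.0,0.0,0.017346235041459112,0.00024431316959801566,0.0,0.0,0.0,1,2000
```

Reading the row: the C-shaped fold is exactly planar, so its writhe vanishes
identically (`Wr/N = 0`); the −1°/rung twist of the stack gives a small
positive mean linking with the neighboring rungs (`Lk_s/N ≈ 2.4e-4`); and no
projection of this unknotted arc shows knotoid structure (`|v2| = 0`).
The ribbon table `run_ribbon.csv` reports `Lk = 2.949` for the backbone
against its side-chain push-off — recovering the three constructed turns
(the ~0.05 deficit is the open ribbon's end effect).

In Python, the same measures on a library curve:

```python
>>> from tautopo.synthetic import make_knot, make_k21_knotoid, K21_CANONICAL_DIRECTION
>>> from tautopo.topology import diagram_v2, project_diagram
>>> diagram_v2(project_diagram(make_k21_knotoid(), direction=K21_CANONICAL_DIRECTION))
0.5
>>> diagram_v2(project_diagram(make_knot("5_2"), direction=(0.26726124, 0.53452248, 0.80178373)))
2.0
```

0.5 is the second Vassiliev value of the K2₁ knotoid diagram (the knotoid
seen from some perspectives of the PSP filament fold), and 2.0 is the
second Vassiliev invariant of the 5₂ knot — identical in every generic
projection because the curve is closed.

Classification of the published 17-filament global metrics (typed-in
reference data, no downloads):

```sh
python -c "from tautopo.reference import global_metrics; \
           global_metrics()[['wr_per_n','lks_per_n','abs_v2']].to_csv('m.csv')"
tautopo cluster m.csv -k 5 --seed 0
```

prints, among five clusters, `cluster 0: AD-PHF, AD-SF, CTE-I, CTE-II, PART`
— the 3R+4R filaments grouped apart from the 4R and 3R folds.

Analyses of deposited cryo-EM structures run the same way
(`tautopo analyze 7p65.cif ...`) once the mmCIF/PDB files are fetched
(`tautopo.structure_io.fetch_structure` caches them locally); see
`docs/methods.md` for chain-selection caveats.

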