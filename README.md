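# slimdock

Scanning and structural placement tools for the PP2A/B55α substrate
recruitment motif.

The Ser/Thr phosphatase holoenzyme PP2A/B55α recognises substrates such as
the tumor suppressor p107 through a short linear motif (SLiM) in a
disordered region, with consensus

```
p[ST]-P-x(4,10)-[RK]-V-x-x-[VI]-R
```

where the `p`-prefixed `[ST]` is the phosphoacceptor (p107 Ser-615), the
`[RK]` after the variable gap is the basic anchor proposed to contact
B55α D197 (p107 Arg-621), and the spacing between phosphoacceptor and
anchor (5 residues in p107) sets how the phosphosite is presented to the
catalytic subunit's di-Mn²⁺ active site.

`slimdock` implements both halves of this analysis as a tested library:

* **Motif scanning** (`slimdock.motif`) — a PROSITE-style pattern grammar
  with variable gaps, proteome-wide scanning with a deterministic hit
  identity (one hit per distinct phosphoacceptor/anchor pair),
  phospho-to-anchor spacing histograms, and one-sided Fisher exact
  (hypergeometric) enrichment of motif-bearing proteins in interactor
  sets.
* **Fragment mining** (`slimdock.fragments`) — excision of
  pattern-matching peptide fragments (e.g. `xHPRVx`, `xEPxxxPRx`) from
  PDB/mmCIF files, backbone φ/ψ/ω computation, conformer clustering by
  DBSCAN under a max-circular-torsion metric, best-resolution reference
  selection, Glu(OE)–Arg(NH) end-to-end span screening (≥ 20 Å retains
  peptides able to bridge both sites), and a survey of shortest
  Mn²⁺–phosphate-oxygen distances.
* **Model assembly** (`slimdock.assembly`) — construction of the
  "two-fragment" placement target (active-site Glu phosphomimetic from an
  aligned donor structure plus an Arg anchored at D197 in bidentate
  geometry, ~3 Å from the carboxylate), pair-fit superposition of
  candidate peptides onto the anchor atoms, displacement scoring,
  threading of the p107 sequence (`MPM` + `EPLMHPR` + `V` →
  `MPMEPLMHPRV`, numbered from 612), and top-k ranking with final
  selection by distances to the Mn²⁺ pair and D197.
* **Synthetic data** (`slimdock.synthetic`) — seeded generators with
  ground truth for every input class: planted-motif proteomes, interactor
  sets with a controlled enrichment factor, dihedral-cluster conformer
  libraries built by internal-coordinate placement, and mock anchor
  scenes with exact requested spans (default 27.5 Å, the published
  Glu-to-Arg distance of the two-fragment geometry).

## Worked example

```python
import slimdock as sd

strict = sd.parse_pattern(sd.STRICT_PATTERN)
p107 = sd.ProteinRecord(id="RBL1_R1", sequence="MPMSPLMHPRVKEVR")  # M612-R626
(hit,) = sd.scan_sequence(strict, p107, offset=611)
print(f"matched   : {hit.matched_seq}")
print(f"span      : {hit.start}-{hit.end}")
print(f"phospho   : S{hit.phospho_pos}")
print(f"anchor    : R{hit.anchor_pos}")
print(f"spacing   : {hit.spacing}")
scene, _ = sd.gen_anchor_scene(seed=1)
print(f"scene span: {scene.anchor_span:.1f} A")
```

prints

```
matched   : SPLMHPRVKEVR
span      : 615-626
phospho   : S615
anchor    : R621
spacing   : 5
scene span: 27.5 A
```

That is: within the reconstructed p107 fragment M612–R626 the strict
consensus matches exactly once, the phosphoacceptor is Ser-615, the basic
anchor is Arg-621, and 5 residues separate them — the spacer the peptide
must stretch across the ~27.5 Å between the active site and the D197
anchor point.

The same operations are available from a shell:

```sh
slimdock scan --pattern 'p[ST]-P-x(4,10)-[RK]-V-x-x-[VI]-R' \
    --fasta proteome.fasta --out hits.tsv
slimdock enrich --pattern 'p[ST]-P-x(4,10)-[RK]-V-x-x-[VI]-R' \
    --fasta proteome.fasta --targets interactors.txt
slimdock mine --pattern xHPRVx --structs pdb_dir/
slimdock cluster --pattern xHPRVx --structs pdb_dir/ --eps 60 --min-pts 5
slimdock survey --structs mn_po4_dir/
slimdock assemble --holo 3DW8.cif --donor 5HPE.cif --out scene.json
slimdock fit --structs pdb_dir/ --scene scene.json --top-k 20
slimdock simulate proteome --n 500 --plant-rate 0.1 --seed 1 \
    --out syn.fasta --truth-out truth.json
```

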