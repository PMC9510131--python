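# cma-toolkit

Competitive-modelling toolkit for multidomain protein complexes:

* **structio** — PDB/mmCIF reading and writing, domain extraction,
  region erasure (author numbering, inclusive ranges, gaps preserved).
* **energetics** — contact-based interface binding-energy prediction:
  interfacial residue contacts at a 5.5 Å heavy-atom cutoff classified
  by residue character, non-interacting-surface composition from a
  deterministic Shrake–Rupley SASA (NACCESS-style radii, Tien
  theoretical maxima for relative SASA), a published linear ΔG model,
  and a |ΔG| < 3 kcal/mol "no complex" classifier.
* **arbitration** — ensemble arbitration: member scoring (complex /
  no-complex / overlap artifact), geometry clustering by fraction of
  common contacts, frequencies over all runs with a 20% significance
  rule, affinity-based representative selection, and dimer topology
  labelling (cis/trans, closed/crossed).
* **assembly** — C2 symmetry-axis detection from chain superposition,
  axis alignment, shortest clash-free axial separation, common dihedral
  angle feasible for several conformational variants, steric clash
  detection (Bondi radii − 0.4 Å tolerance), hybrid open/closed
  composition.
* **grafting** — cofactor transfer by restricted-domain superposition
  and polypeptide linker-feasibility checks.
* **seqdesign** — motif-anchored sequence edits (delete, insert,
  substitute, chimera splicing) with anchor verification and length
  bookkeeping.
* **fixtures** — synthetic C2 homodimers, topology dimers and planted
  ensembles with exact ground truth; everything is testable offline.

## CLI

All operations are exposed under one `cma` entry point; every
subcommand can write a JSON report (tool version + resolved config +
results), and a YAML `--config` file can hold per-subcommand defaults
(explicit flags win).

```sh
cma extract --in model.pdb --chain A --range 2:458 --out p450d.pdb
cma erase   --in model.pdb --chain A --range 632:651 --out trimmed.pdb
cma dg      --in complex.pdb --groups A:B --report dg.json --contacts contacts.tsv
cma arbitrate --models run0.pdb --models run1.pdb ... --groups A:B \
              --min-freq 0.2 --dg-threshold 3.0 --report arbitration.json
cma assemble --part1 p450d_dimer.pdb --part2 fadd_dimer.pdb \
             [--variant2 alt.pdb] --out full.pdb --report assembly.json
cma graft   --template ref.pdb --cofactor HEM --fit-range A:2:458 \
            --into model.pdb --target-range A:2:458 --out grafted.pdb
cma linker-check --in full.pdb --from C:631 --to C:652 --missing 20
cma edit    --in sequences.fasta --script edits.yaml --out variants.fasta
cma simulate c2-dimer --sigma 0.2 --seed 7 --out fix.pdb --truth truth.json
cma simulate ensemble --n-runs 10 --proportions crossed=0.8,closed=0.2 \
            --out-dir runs/ --truth truth.json
```

Exit codes: 0 success, 1 domain error (no feasible assembly, anchor not
found, empty selection, ...), 2 usage error.

Edit scripts are YAML lists, e.g.

```yaml
- sequence: bacterial
  kind: insert_after
  anchor_motif: VDSAADM
  anchor_position: 648
  after: VDSA
  payload: GSGGSG
  id: bacterial_extended
- kind: splice_chimera
  a: human
  b: bacterial
  segments: [[A, 1, 230], [B, 231, 270], [A, 271, 680]]
  id: chimera
```

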