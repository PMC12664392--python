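# xscan

Specificity and cross-reactivity profiling for binders that target
peptide–MHC (pMHC) complexes — DARPins, TCR-mimetic antibodies, or TCR-based
T cell engagers.

A pMHC-targeted therapeutic recognizes a short peptide (here the 9-mer
NY-ESO-1 epitope `SLLMWITQV` presented on HLA-A\*02:01) in the context of the
MHC groove. Because tens of thousands of self peptides are presented the
same way, the central safety question is: *which other human peptides could
this binder engage?* `xscan` implements the desk side of that campaign:

1. **X-scan profiling** (`xscan.activation`) — positional-scanning
   mutagenesis matrices (% activated CD8⁺ T cells for every single-residue
   variant of the epitope) are averaged across replicates, normalized to
   100% at the wild-type residue of each position, and thresholded: a
   substitution is *tolerated* at position *i* when its normalized
   activation exceeds 30%. Alanine-scan sensitivity calls (with the two MHC
   anchor positions p2/p9 mutated jointly) use the same arithmetic.
2. **Motif scanning** (`xscan.motif`) — each tolerance profile serializes
   to a PROSITE-style pattern, e.g.
   `[FILMT]-W-[FILMV]-…`, which is scanned against a proteome FASTA; every
   matching 9-mer window is a candidate cross-reactive epitope.
3. **Assay arithmetic** (`xscan.assays`) — HTRF specificity ratios
   (target signal over the worst negative control, 25-fold hit threshold),
   the three-parameter log(agonist) vs. response model
   `y = Bottom + (Top − Bottom)/(1 + EC50/x)` with
   `EC_F = EC50·F/(100−F)` (so EC90 = 9·EC50), and chromium-release
   `% specific lysis = (exp − spont)/(max − spont) × 100`.
4. **Structural footprints** (`xscan.structure`) — Shrake–Rupley SASA,
   buried interface area `½(SASA_A + SASA_B − SASA_AB)` (the PISA
   convention), per-residue footprints, distance-typed hydrogen-bond and
   hydrophobic contacts, backbone share of the interface, and Kabsch
   superposition RMSD, for binder/HLA-peptide complexes in PDB or mmCIF.
5. **Synthetic data** (`xscan.simulate`) — seeded generators for every
   input above with known ground truth, so the full pipeline is testable
   without downloads.

## Worked example

```python
from xscan import (ToleranceProfile, average_replicates, normalize_to_wildtype,
                   tolerated_sets, emit_motif, match_peptide, scan_proteome)
from xscan.simulate import XscanSimSpec, ProteomeSimSpec, gen_xscan, gen_proteome
from xscan.motif import parse_motif

# simulate a duplicate X-scan around a designed tolerance structure
target = ToleranceProfile(
    wild_type="SLLMWITQV",
    allowed=parse_motif(
        "[ACFHIMNPQRSTVWY]-[FILMVW]-[ILMQV]-[IM]-W-[FILMPVW]-"
        "[ACFGILMNQRSTV]-[ACDEFGHKLMNPQRSTVWY]-[ACFGILSTV]").classes)
replicates, _ = gen_xscan(XscanSimSpec(profile=target, seed=7))

profile = tolerated_sets(normalize_to_wildtype(average_replicates(replicates)))
motif = profile.to_motif("NY_2")
print(emit_motif(motif))
# [ACFHIMNPQRSTVWY]-[FILMVW]-[ILMQV]-[IM]-W-[FILMPVW]-[ACFGILMNQRSTV]-[ACDEFGHKLMNPQRSTVWY]-[ACFGILSTV]

print(match_peptide("SLLMWLTPL", motif))   # True  — candidate cross-reactive epitope
print(match_peptide("TLLIWLFEV", motif))   # True

# scan a (synthetic) proteome, excluding the target epitope itself
records, _ = gen_proteome(ProteomeSimSpec(
    n_proteins=50, mean_length=300, planted=((3, 40, "SLLMWLTPL"),), seed=1))
hits, summary = scan_proteome(records, [motif], exclude_peptides=["SLLMWITQV"])
print(summary[["peptide", "n_occurrences"]].head(1).to_string(index=False))
#   peptide  n_occurrences
# SLLMWLTPL              1
```

The printed pattern is the binder's recognition motif: at each position it
lists every residue whose variant still triggered >30% of wild-type T-cell
activation. Peptides matching the motif are the candidates carried forward
to experimental cross-reactivity testing; `SLLMWLTPL` is the kind of
near-self sequence such a scan is designed to surface.

The same steps are available from the shell:

```sh
xscan profile --input xscan.tsv --threshold 30 --out profile.json
xscan scan --motif motifs.json --fasta proteome.fasta --exclude SLLMWITQV --out hits.tsv
xscan ec --input dr.tsv --f 90
xscan interface --structure complex.cif --group-a D --group-b A,B,C
xscan rmsd --a free.pdb --b complex.cif --chains A:D
```

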