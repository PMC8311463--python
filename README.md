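# cyclopept

Discovery and characterization workflows for **cyclotides** — head-to-tail
cyclized plant peptides of ~30 residues with six conserved cysteines forming
a cyclic cystine knot — implemented as a tested, reusable Python pipeline.

The package covers the computational side of a cyclotide peptidomics study
of *Allexis* violets (Violaceae), whose peptides alca 1 and alca 2 inhibit
human prolyl oligopeptidase (POP):

1. **Derivatization screening** (`cyclopept.screen`): a peptide with *n*
   cysteines and a cyclic backbone shows up in four MALDI peak lists as a
   chained quadruple — native, +*n*·1.007825 Da after disulfide reduction,
   +*n*·57.021464 Da after iodoacetamide alkylation, +18.010565 Da after
   single-site GluC ring opening. `match_series` chains these shifts within
   a ppm or Dalton tolerance, infers *n*, and flags six-Cys cyclic
   (cyclotide-like) candidates.
2. **In-silico proteolysis of cyclic peptides** (`cyclopept.digest`):
   GluC / trypsin / chymotrypsin digestion with cyclic-coordinate
   fragments, missed cleavages, and ring-opened full-length precursors;
   each cut adds one water.
3. **MS/MS annotation** (`cyclopept.msms`): singly charged b/y ladders with
   −17/−18 Da losses, per-residue coverage, evidence merging across
   differently opened precursors, and Ile/Leu resolution from chymotryptic
   cleavage (cleaves after Leu, hindered by Ile).
4. **Inhibition analytics** (`cyclopept.assay`): percent remaining activity
   I = (v_i/v_o)·100, Michaelis–Menten (K_m, V_max) fits, and 4PL
   dose-response fits
   `Y = Bottom + (Top−Bottom)/(1 + 10^((LogIC50−X)·HillSlope))`.
5. **Sequence analytics** (`cyclopept.seqanalysis`): cystine-loop
   decomposition, Moebius/bracelet classification (Pro in loop 5),
   identity-scored homology ranking (match 1, free gaps ⇒ LCS), and
   frequency matrices for sequence logos.
6. **Synthetic data** (`cyclopept.synthetic`): seeded generators for every
   input the pipeline consumes, with machine-readable ground truth.

## Worked example

```python
from cyclopept.masses import Peptide, peptide_neutral_mass, mz
from cyclopept.digest import GLUC, TRYPSIN, digest_peptide
from cyclopept.seqanalysis import loop_decompose, classify_subtype

alca1 = Peptide("GVIPCGESCVFIPCISAAIGCSCKNKVCYRD",
                topology="cyclic", cys_state="oxidized", n_disulfides=3)
print(round(mz(peptide_neutral_mass(alca1)), 1))   # 3211.4  (native [M+H]+)

cam = Peptide(alca1.sequence, "cyclic", "carbamidomethylated")
ring_opened, = digest_peptide(cam, GLUC)
print(ring_opened.sequence)          # SCVFIPCISAAIGCSCKNKVCYRDGVIPCGE
print(round(ring_opened.mz1, 1))     # 3577.6  (+366 Da vs native: 6x58 + 18)

for f in sorted(digest_peptide(cam, TRYPSIN, max_missed=1), key=lambda f: f.mz1):
    print(f"{f.sequence:32s} {f.mz1:9.2f}  missed={f.missed}")
# NK                                  261.16  missed=0
# VCYR                                597.28  missed=0
# NKVCYR                              839.42  missed=1
# DGVIPCGESCVFIPCISAAIGCSCK          2757.22  missed=0
# ...

d = loop_decompose(alca1.sequence)
print(d.loops[5], classify_subtype(d))   # KNKV bracelet (no Pro in loop 5)
```

The native mass, the single +18 Da GluC product, and the tryptic fragment
masses match the published MALDI values for alca 1 to within 0.2 Da; the
missing Pro in loop 5 places both alca peptides in the bracelet subfamily.

A command-line interface mirrors the library:

```sh
cyclopept screen --native n.csv --reduced r.csv --alkylated a.csv \
                 --linearized l.csv --tol 0.2Da --out report.json
cyclopept digest --fasta alca1.fa --enzyme trypsin --missed 2 --cam
cyclopept fit-ic50 --csv dose_response.csv --normalize max
cyclopept simulate peaklists --seed 7 --n 20 --outdir sim/
```

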