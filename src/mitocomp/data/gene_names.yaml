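# Canonicalization of heterogeneous GenBank gene/product labels to the
# 37 canonical insect mitochondrial gene names used throughout the toolkit.
# Keys are matched case-insensitively after stripping spaces and hyphens.
# Edit or extend this table for taxa whose deposits use other spellings.
protein_coding:
  ND1: nad1
  ND2: nad2
  ND3: nad3
  ND4: nad4
  ND4L: nad4l
  ND5: nad5
  ND6: nad6
  NAD1: nad1
  NAD2: nad2
  NAD3: nad3
  NAD4: nad4
  NAD4L: nad4l
  NAD5: nad5
  NAD6: nad6
  NADH1: nad1
  NADH2: nad2
  NADH3: nad3
  NADH4: nad4
  NADH4L: nad4l
  NADH5: nad5
  NADH6: nad6
  NADHDEHYDROGENASESUBUNIT1: nad1
  NADHDEHYDROGENASESUBUNIT2: nad2
  NADHDEHYDROGENASESUBUNIT3: nad3
  NADHDEHYDROGENASESUBUNIT4: nad4
  NADHDEHYDROGENASESUBUNIT4L: nad4l
  NADHDEHYDROGENASESUBUNIT5: nad5
  NADHDEHYDROGENASESUBUNIT6: nad6
  COI: cox1
  COII: cox2
  COIII: cox3
  CO1: cox1
  CO2: cox2
  CO3: cox3
  COX1: cox1
  COX2: cox2
  COX3: cox3
  COXI: cox1
  COXII: cox2
  COXIII: cox3
  CYTOCHROMECOXIDASESUBUNIT1: cox1
  CYTOCHROMECOXIDASESUBUNIT2: cox2
  CYTOCHROMECOXIDASESUBUNIT3: cox3
  CYTOCHROMECOXIDASESUBUNITI: cox1
  CYTOCHROMECOXIDASESUBUNITII: cox2
  CYTOCHROMECOXIDASESUBUNITIII: cox3
  ATP6: atp6
  ATP8: atp8
  ATPASE6: atp6
  ATPASE8: atp8
  ATPSYNTHASEF0SUBUNIT6: atp6
  ATPSYNTHASEF0SUBUNIT8: atp8
  CYTB: cob
  COB: cob
  CB: cob
  CYTOCHROMEB: cob
rRNA:
  RRNL: rrnL
  RRNS: rrnS
  LRRNA: rrnL
  SRRNA: rrnS
  16S: rrnL
  12S: rrnS
  16SRIBOSOMALRNA: rrnL
  12SRIBOSOMALRNA: rrnS
  LARGESUBUNITRIBOSOMALRNA: rrnL
  SMALLSUBUNITRIBOSOMALRNA: rrnS
# tRNAs are canonicalized from the amino-acid letter of "tRNA-Xxx" products;
# Leu and Ser isoacceptors are split by the recognized codon family
# (L1: CUN, L2: UUR, S1: AGN, S2: UCN) taken from the product parenthetical
# or the anticodon qualifier.
trna_single:
  ALA: trnA
  ARG: trnR
  ASN: trnN
  ASP: trnD
  CYS: trnC
  GLN: trnQ
  GLU: trnE
  GLY: trnG
  HIS: trnH
  ILE: trnI
  LYS: trnK
  MET: trnM
  PHE: trnF
  PRO: trnP
  THR: trnT
  TRP: trnW
  TYR: trnY
  VAL: trnV
control_region:
  CONTROLREGION: CR
  ATRICHREGION: CR
  A+TRICHREGION: CR
  DLOOP: CR
  CR: CR
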