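# Reference-protein regression fixture (not distributed)

`tests/test_acceptance.py::TestReferenceProteinRegression` checks the
toolkit against three canonical human membrane proteins whose printed
properties are known: MGAT3/MOGAT3 (UniProt Q86G97), GPR35 (Q9HC97) and
SLC10A1 (Q14973). The inputs are the canonical sequences and their
TRANSMEM ranges, which require a one-time online fetch that the build
environment of this distribution could not perform, so the fixture is
absent and the test reports that explicitly.

To populate it (machine with network access):

1. `sequences.fasta` — the three canonical sequences with headers
   `>MGAT3`, `>GPR35`, `>SLC10A1`, e.g. from
   `https://rest.uniprot.org/uniprotkb/<accession>.fasta`.
2. `topology.tsv` — TSV columns `protein_id`, `start`, `end`, one
   TRANSMEM segment per row, from each entry's feature table
   (`qtykit.io.read_topology` also accepts the flat-file `FT TRANSMEM`
   lines directly via `dialect="uniprot_ft"`). Pin the ranges that
   reproduce the reference values in case live annotations drift:
   MGAT3 has 3 segments totalling 63 residues (33 of them L/I/V/F over
   a 341-residue chain).

No other files are needed; the expected values are in the test.
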