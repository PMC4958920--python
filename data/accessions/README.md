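Place downloaded GenBank flat files here to enable the accession-backed
acceptance tests (see tests/test_acceptance.py):

    KU833271.gb   Pyrola rotundifolia plastome
    KU878156.gb   Hypopitys monotropa plastome
    KX228067.gb   Monotropa uniflora plastome

plus, for the selection analyses, the published codon alignments:

    orf357_codon_alignment.fasta   rps4-derived ORF, P. rotundifolia vs O. secunda (KU588419)
    accd_codon_alignment.fasta     four-species accD ORF codon alignment
    accd_tree.nwk                  its topology (newick)

No data ships with this repository.
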