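Slot for the real COL4A5 reference CDS (kidney isoform 2).

Place a single-record FASTA named NM_033380.3.fasta here, with record id
NM_033380.3 and the coding sequence only (from the initiator ATG through
the stop codon).  The sequence is fetched from NCBI by the user; it is
not redistributed with this package.  When present, the enumeration
pipeline and the corresponding acceptance checks run against the real
transcript instead of the synthetic stand-in.
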