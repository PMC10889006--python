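# Genomic coordinates (1-based) of the c.840 position of SMN1 and SMN2
# per reference build. The base at the SMN1 position must be 'C' and at
# the SMN2 position 'T'; run `sma-caller validate-reference` against your
# local FASTA before trusting any entry on new data.
#
# T2T-CHM13 coordinates were derived by flank matching from GRCh38 (see
# locus_config.derive_positions_by_flank_match) and should be re-validated
# against a local CHM13v2.0 FASTA.

[GRCh37]
chromosome = 5
smn1_c840_pos = 70247773
smn2_c840_pos = 69372353
smn1_base = C
smn2_base = T

[GRCh38]
chromosome = 5
smn1_c840_pos = 70951946
smn2_c840_pos = 70076526
smn1_base = C
smn2_base = T

[T2T-CHM13]
chromosome = 5
smn1_c840_pos = 71408734
smn2_c840_pos = 70810812
smn1_base = C
smn2_base = T
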