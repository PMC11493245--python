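# Reference sequence data

`sfx_tran_homologs.faa` (not shipped): a protein FASTA of surface-exclusion
factor and adhesin homologs retrieved from public sequence databases, with
record ids `Sfx_94`, `Sfx_AQU1`, `Sfx_RA1`, `TraN_94`, `TraN_AQU1`,
`TraN_Asa4c`, `TraN_AhD4-1`. The test recomputing published pairwise
identities (`tests/test_acceptance.py::test_published_pairwise_identities_recovered_from_homolog_sequences`)
reads it from this directory and fails with a clear message when it is
absent.
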