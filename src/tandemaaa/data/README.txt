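Curated example data for the repertoire module:

parasite_repertoire.tsv  presence/copy-number table of the eight
                         eukaryotic Cdc48-family members across selected
                         parasitic lineages, plus the full Homo sapiens
                         repertoire for comparison (vertebrates carry two
                         Yta7/ATAD2 copies).
eukaryote_tree.nwk       a rooted consensus-style eukaryote lineage tree
                         over the same taxa (root between the
                         Opisthokonta/Amoebozoa side and the rest),
                         for Dollo ancestral-repertoire reconstruction.
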