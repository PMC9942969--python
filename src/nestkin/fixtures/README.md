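# Packaged fixtures

`nc_broods_pairings.csv` — observed pairing table for 20 American black duck
maternal lineages (19 sampled nests plus one clutch laid by an unsampled
parasitizing female) from a 2020–2021 brood study in coastal North
Carolina.  One row per maternal lineage: the inferred maternal species,
whether the hen was sampled, and the inferred paternal lineages with the
number of sampled eggs each explains (`id:eggs:species`, `;`-separated).
Species labels use ABDU (American black duck), WMA (wild mallard), GFM
(game-farm mallard) and `x`-joined hybrid composites; wild-mallard
entries printed as "MALL" and "ABxWM" in the source table are normalised
to WMA / ABDUxWMA.  The `note` column preserves the source table's
side-notes, including its internally inconsistent lineage ids and the
nest whose mtDNA and nuclear evidence disagree; the lineage ids in
`paternal_lineages` follow the lineage column verbatim, which yields a
self-consistent set of 24 paternal lineages over 80 sampled offspring.
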