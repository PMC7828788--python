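{
 "milk_proteins.fasta": "98c21a5088812f0d25580af2125fde35efdf5133142318542b97790e5a6c86a3",
 "is_peptides.tsv": "c52874c7235579b3da87009e55b0b51e03c2d89b2f86fc54929bb9f0033a557a",
 "iv_peptides.tsv": "d81d8fd915b4cdffe16181f1062ea741b6309fc0df6d841bf73091eace6ebf1c",
 "epitopes.tsv": "06ae39b5b9584a483e6a8b3c1c51071e0457849df7d8c6ab6921cead11d17087",
 "binder_counts.tsv": "2ba60d4b0a9de3cf029f87bfe58fad4e614a3fe7e902320827e329854eafd1ab",
 "affinity_ic50.tsv": "03c6be140ca9f0e8a5691e621d67ce6b836ccf94aa3286e30baaa9a3a68a6ff0",
 "cytokines.tsv": "c73192d52e0dac96a95bfa3a6990399b6f5c90be0707fd750441c5eb36753d70",
 "bioactivity.tsv": "4b59d9c271188798788d99538e00e5464e0cd2c3e112044289b4a85747b1df95",
 "ms_identifications.tsv": "45c858bab107c68aa5c917840cc1759f0194b19e04e2f79ea6c581baf6dcb2ce",
 "cleavage_rules.yaml": "039f4f4973a3adb16d903e002fcfa0a3b3a1247e90bafb868cf2ebd1e30d6b91"
}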