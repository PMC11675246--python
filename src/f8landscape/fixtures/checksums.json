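{
  "cluster_correlations.tsv": "c103602261bc8e644438ea585d1d1e22ff02b01d2bb832b9ff0a3d84aa9cedc1",
  "cluster_members.tsv": "7a9ed8d4d158747affa0d3d384bfe763a76e2c5700706642aa0682afe674608f",
  "table1_conserved_common.tsv": "6d3538e1413ad7a1f7f2d2258251e0638287435854f46c47f8548919233b6c1b",
  "table2_vus_shortlist.tsv": "7f1b602ea124e939b7bbb434436f2bf535dc7c2cb95b5c62826f233dcb47019a",
  "ld_block.json": "cdb3d0ed51ede2494a381bb9a0eb57f5c8a367620c2f5b6d2a4107796fbf2f2c"
}
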