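{
  "rsids": [
    "rs5945278", "rs4898407", "rs5945134", "rs73569615", "rs115609690",
    "rs114209171", "rs7886856", "rs17051889", "rs1470586", "rs73567794",
    "rs5945130", "rs5945131"
  ],
  "tissue": "Nerve - Tibial",
  "hg38": {"chrom": "chrX", "start": 155001128, "end": 155051186},
  "hg19": {"chrom": "chrX", "start": 154229503, "end": 154279561}
}
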