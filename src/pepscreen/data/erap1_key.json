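{
  "note": "PLACEHOLDER KEY - NOT AUTHORITATIVE. Residue states and haplotype strings must be transcribed from the primary haplotype literature before use on real genotypes. The structure is validated; the biology here is illustrative.",
  "snps": [
    {"rsid": "rs3734016", "residue_position": 56, "alleles": {"C": "E", "T": "K"}},
    {"rsid": "rs26653", "residue_position": 127, "alleles": {"G": "P", "C": "R"}},
    {"rsid": "rs26618", "residue_position": 276, "alleles": {"T": "I", "C": "M"}},
    {"rsid": "rs27895", "residue_position": 346, "alleles": {"G": "G", "A": "D"}},
    {"rsid": "rs2287987", "residue_position": 349, "alleles": {"T": "M", "C": "V"}},
    {"rsid": "rs30187", "residue_position": 528, "alleles": {"T": "K", "C": "R"}},
    {"rsid": "rs10050860", "residue_position": 575, "alleles": {"C": "D", "T": "N"}},
    {"rsid": "rs17482078", "residue_position": 725, "alleles": {"G": "R", "A": "Q"}},
    {"rsid": "rs27044", "residue_position": 730, "alleles": {"C": "Q", "G": "E"}}
  ],
  "haplotypes": {
    "Hap1": "EPIGMRDRE",
    "Hap2": "EPIGMKDRE",
    "Hap3": "EPMGMKDRQ",
    "Hap4": "EPMGMRDRE",
    "Hap5": "EPIGMRDRQ",
    "Hap6": "ERIGMRDRQ",
    "Hap7": "EPMGVRNQQ",
    "Hap8": "KPMGMRDRQ",
    "Hap9": "EPMDMRDRQ",
    "Hap10": "ERMGVRNQQ"
  }
}
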