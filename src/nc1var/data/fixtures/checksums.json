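{
  "cys_variants.tsv": "434fdc8069e4c80cfce0e0625639330c4db5d2e9ca197433185f25ab03d55047",
  "kidney_failure_summary.tsv": "772852be75d656b05c73aa96969e292b02a05cceb4ca3a1ef3e265ba39b4695d",
  "damage_vs_expected.tsv": "19ea5d38bfe7d862f8754b28ba7e390cbacc1ed56286bcfbc2c9413e93ec7882",
  "gly_variants.tsv": "54d7ac56597edaf53120ceda0fed9b5270002c764e18a4fedc7eb9898735e44e"
}
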