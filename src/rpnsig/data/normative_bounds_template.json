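{
 "_comment": "Template for normative 95% percentile bounds per modality. Fill lower/upper with explicit values (hpt/cpt in deg C, mpt in log10 mN) before extreme-value screening; null values are rejected.",
 "source": "unset-template",
 "bounds": {
  "hpt": [
   null,
   null
  ],
  "cpt": [
   null,
   null
  ],
  "mpt": [
   null,
   null
  ]
 }
}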